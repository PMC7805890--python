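import numpy as np
import pytest

from barntrack import (BACKGROUND, DataError, DetectionMap, Gate, GateEvent,
                       OwnershipField, Scenario, StateSpace, Track, TrackPoint,
                       apply_entry_event, apply_exit_event, backtrace_identity,
                       build_motion_model, check_exit_criterion,
                       inject_gate_observations, reverse_scenario)
from barntrack.gates import exit_hold_frames


@pytest.fixture
def space():
    return StateSpace(n_x=10, n_y=8, cell_size=0.1, n_orient=4)


class TestInjectGateObservations:
    def test_strong_detection_passes_through(self, space):
        gate = Gate("g", 3, 2, 1, "entry", synthetic_prob=0.05)
        vals = np.full(space.shape, 1e-6)
        vals[2, 3, 1] = 0.9
        out = inject_gate_observations(DetectionMap(0, vals), [gate], space)
        assert out.values[2, 3, 1] == 0.9

    def test_weak_detection_raised_to_synthetic(self, space):
        gate = Gate("g", 3, 2, 1, "entry", synthetic_prob=0.05)
        vals = np.full(space.shape, 1e-6)
        out = inject_gate_observations(DetectionMap(0, vals), [gate], space)
        assert out.values[2, 3, 1] == 0.05
        assert out.values[2, 3, 0] == 1e-6        # only the gate state

    def test_any_orientation_gate_raises_all_bins(self, space):
        gate = Gate("g", 3, 2, None, "exit", synthetic_prob=0.05)
        vals = np.full(space.shape, 1e-6)
        out = inject_gate_observations(DetectionMap(0, vals), [gate], space)
        assert (out.values[2, 3, :] == 0.05).all()

    def test_idempotent_and_no_gates_noop(self, space):
        gate = Gate("g", 3, 2, 1, "entry")
        vals = np.random.default_rng(0).random(space.shape)
        once = inject_gate_observations(DetectionMap(0, vals.copy()), [gate], space)
        twice = inject_gate_observations(once, [gate], space)
        assert np.array_equal(once.values, twice.values)
        same = inject_gate_observations(DetectionMap(0, vals.copy()), [], space)
        assert np.array_equal(same.values, vals)


class TestEntryEvent:
    def test_entry_into_empty_scene(self, space):
        gate = Gate("g", 3, 2, 1, "entry")
        field = OwnershipField.empty(space)
        lost = apply_entry_event(field, space, gate, new_object_id=0)
        s_in = space.flat_index(3, 2, 1)
        assert lost == []
        assert field.owner.reshape(-1)[s_in] == 0
        assert field.prob.reshape(-1)[s_in] == 1.0

    def test_previous_owner_renormalized(self, space):
        """Object A holds 0.3 at the gate state and 0.7 far away; after entry
        it keeps only the far state, renormalized to 1."""
        gate = Gate("g", 3, 2, 1, "entry")
        far = space.flat_index(9, 7, 0)
        s_in = space.flat_index(3, 2, 1)
        field = OwnershipField.empty(space)
        field.owner.reshape(-1)[[s_in, far]] = 0
        field.prob.reshape(-1)[s_in] = 0.3
        field.prob.reshape(-1)[far] = 0.7
        lost = apply_entry_event(field, space, gate, new_object_id=1)
        assert lost == []
        assert field.prob.reshape(-1)[far] == pytest.approx(1.0)
        assert field.owner.reshape(-1)[s_in] == 1

    def test_owner_stripped_of_everything_is_lost(self, space):
        gate = Gate("g", 3, 2, 1, "entry")
        s_in = space.flat_index(3, 2, 1)
        field = OwnershipField.empty(space)
        field.owner.reshape(-1)[s_in] = 0
        field.prob.reshape(-1)[s_in] = 1.0
        lost = apply_entry_event(field, space, gate, new_object_id=1)
        assert lost == [0]

    def test_neighbourhood_clearing_displaces_parked_mass(self, space):
        gate = Gate("g", 3, 2, 1, "entry")
        near = space.flat_index(4, 3, 0)          # 1 cell from the gate
        far = space.flat_index(9, 7, 0)
        field = OwnershipField.empty(space)
        field.owner.reshape(-1)[[near, far]] = 0
        field.prob.reshape(-1)[near] = 0.9
        field.prob.reshape(-1)[far] = 0.1
        apply_entry_event(field, space, gate, 1, clear_radius=2)
        assert field.owner.reshape(-1)[near] == BACKGROUND
        assert field.prob.reshape(-1)[far] == pytest.approx(1.0)

    def test_exit_only_gate_rejects_entry(self, space):
        gate = Gate("g", 3, 2, 1, "exit")
        with pytest.raises(DataError):
            apply_entry_event(OwnershipField.empty(space), space, gate, 0)


class TestExitEvent:
    def _model(self, space):
        return build_motion_model(space, 1.0, 1.0, 2, 1)

    def test_owner_of_gate_state_removed(self, space):
        gate = Gate("g", 5, 5, 2, "exit")
        s_out = space.flat_index(5, 5, 2)
        field = OwnershipField.empty(space)
        field.owner.reshape(-1)[s_out] = 3
        field.prob.reshape(-1)[s_out] = 1.0
        removed = apply_exit_event(field, space, gate, self._model(space), [3])
        assert removed == 3
        assert (field.owner == BACKGROUND).all()
        assert (field.prob == 0).all()

    def test_single_object_removed_even_if_far(self, space):
        gate = Gate("g", 5, 5, 2, "exit")
        field = OwnershipField.empty(space)
        s = space.flat_index(0, 0, 0)
        field.owner.reshape(-1)[s] = 1
        field.prob.reshape(-1)[s] = 1.0
        removed = apply_exit_event(field, space, gate, self._model(space), [1])
        assert removed == 1

    def test_neighbourhood_mass_decides_between_objects(self, space):
        """Gate state is background; B holds 0.3 next to the gate, A only
        0.01 — B is the more likely occupant and is removed."""
        gate = Gate("g", 5, 5, 2, "exit")
        field = OwnershipField.empty(space)
        a, b = space.flat_index(4, 5, 1), space.flat_index(5, 4, 0)
        rest_a, rest_b = space.flat_index(0, 0, 0), space.flat_index(9, 0, 0)
        field.owner.reshape(-1)[[a, rest_a]] = 0
        field.prob.reshape(-1)[a] = 0.01
        field.prob.reshape(-1)[rest_a] = 0.99
        field.owner.reshape(-1)[[b, rest_b]] = 1
        field.prob.reshape(-1)[b] = 0.3
        field.prob.reshape(-1)[rest_b] = 0.7
        removed = apply_exit_event(field, space, gate, self._model(space), [0, 1])
        assert removed == 1

    def test_spurious_exit_with_no_live_objects(self, space):
        gate = Gate("g", 5, 5, 2, "exit")
        removed = apply_exit_event(OwnershipField.empty(space), space, gate,
                                   self._model(space), [])
        assert removed is None


class TestExitCriterion:
    def _track(self, space, frames, state):
        return Track(object_id=0, entry_frame=frames[0], points=[
            TrackPoint(f, state, 0, 1.0) for f in frames])

    def test_hold_frames_at_16_fps(self):
        assert exit_hold_frames(16.0, 0.5) == 9

    def test_nine_consecutive_frames_fire(self, space):
        gate = Gate("ms", 5, 5, None, "exit")
        s = space.flat_index(5, 5, 3)
        track = self._track(space, range(10, 19), s)
        assert check_exit_criterion(track, [gate], space, fps=16.0) == ("ms", 10)

    def test_eight_frames_do_not_fire(self, space):
        gate = Gate("ms", 5, 5, None, "exit")
        s = space.flat_index(5, 5, 3)
        track = self._track(space, range(10, 18), s)
        assert check_exit_criterion(track, [gate], space, fps=16.0) is None

    def test_broken_run_resets(self, space):
        gate = Gate("ms", 5, 5, None, "exit")
        s = space.flat_index(5, 5, 3)
        away = space.flat_index(0, 0, 0)
        pts = [TrackPoint(f, s, 0, 1.0) for f in range(10, 15)]
        pts.append(TrackPoint(15, away, 0, 1.0))
        pts += [TrackPoint(f, s, 0, 1.0) for f in range(16, 24)]
        track = Track(object_id=0, entry_frame=10, points=pts)
        assert check_exit_criterion(track, [gate], space, fps=16.0) is None

    def test_entry_gates_never_fire(self, space):
        gate = Gate("in", 5, 5, None, "entry")
        s = space.flat_index(5, 5, 0)
        track = self._track(space, range(0, 40), s)
        assert check_exit_criterion(track, [gate], space, fps=16.0) is None


class TestReversal:
    def _scenario(self, space, n_frames, fps=16.0):
        gates = [Gate("in", 1, 7, 3, "entry"), Gate("out", 8, 0, None, "exit")]
        events = [GateEvent.at_time(10.0, fps, "in", 77, "entry"),
                  GateEvent.at_time(40.0, fps, "out", 77, "exit")]
        return Scenario(fps=fps, gates=gates, events=events)

    def test_double_reversal_is_identity(self, space):
        n = 960
        maps = np.random.default_rng(3).random((n,) + space.shape).astype(np.float32)
        scen = self._scenario(space, n)
        r_maps, r_scen = reverse_scenario(maps, scen)
        rr_maps, rr_scen = reverse_scenario(r_maps, r_scen)
        assert np.array_equal(maps, rr_maps)
        assert [(e.kind, e.frame_index, e.gate_id, e.animal_id)
                for e in rr_scen.events] == \
               [(e.kind, e.frame_index, e.gate_id, e.animal_id)
                for e in scen.events]
        assert [g.role for g in rr_scen.gates] == [g.role for g in scen.gates]

    def test_roles_and_times_swap(self, space):
        n = 960                                   # 60 s at 16 FPS
        maps = np.zeros((n,) + space.shape, dtype=np.float32)
        scen = self._scenario(space, n)
        _, r_scen = reverse_scenario(maps, scen)
        assert {g.gate_id: g.role for g in r_scen.gates} == \
               {"in": "exit", "out": "entry"}
        by_kind = {e.kind: e for e in r_scen.events}
        # the 10 s entry becomes an exit at ~50 s (frame-centred mapping)
        assert by_kind["exit"].frame_index == n - 1 - 160
        assert by_kind["exit"].time_s == pytest.approx(50.0, abs=1.0 / 16.0)
        assert by_kind["entry"].frame_index == n - 1 - 640


class TestBacktraceIdentity:
    def test_gate_instantiated_track_gets_animal_id(self):
        tr = Track(object_id=0, entry_frame=160, entry_gate="in")
        ev = GateEvent.at_time(10.0, 16.0, "in", 1832, "entry")
        out = backtrace_identity([tr], [ev])
        assert out[0].animal_id == 1832

    def test_manual_track_keeps_synthetic_id(self):
        tr = Track(object_id=0, animal_id="S1", entry_frame=0)
        out = backtrace_identity([tr], [GateEvent(1.0, 16, "in", 5, "entry")])
        assert out[0].animal_id == "S1"

    def test_empty_event_list_unchanged(self):
        tr = Track(object_id=0, entry_frame=3, entry_gate="in")
        assert backtrace_identity([tr], [])[0].animal_id is None

    def test_more_registrations_than_tracks_is_data_error(self):
        tr = Track(object_id=0, entry_frame=16, entry_gate="in")
        evs = [GateEvent.at_time(1.0, 16.0, "in", 1, "entry"),
               GateEvent.at_time(1.0, 16.0, "in", 2, "entry")]
        with pytest.raises(DataError):
            backtrace_identity([tr], evs)
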