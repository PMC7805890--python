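import numpy as np
import pytest

from barntrack import (BACKGROUND, DetectionMap, Gate, OwnershipField,
                       Scenario, SequencingError, StateSpace,
                       build_motion_model, estimate_object_states,
                       most_likely_predecessor, motion_model_from_kernel,
                       normalize_per_object, propagate_frame, run_sequence,
                       step_frame)


class TestMicroScene:
    """Hand-evaluated single step on 3 collinear cells (stay 0.6 / step 0.2,
    previous probabilities 0.7 / 0.3 / 0, detections 0.5 / 0.8 / 0.1)."""

    def test_most_likely_predecessor(self, micro_scene):
        space, model, field, _ = micro_scene
        assert most_likely_predecessor(field, model, 0) == (0, pytest.approx(0.42))
        assert most_likely_predecessor(field, model, 1) == (1, pytest.approx(0.18))
        assert most_likely_predecessor(field, model, 2) == (1, pytest.approx(0.06))

    def test_propagate_raw_probabilities(self, micro_scene):
        space, model, field, dmap = micro_scene
        raw = propagate_frame(field, model, dmap)
        assert np.allclose(raw.ptilde.ravel(), [0.21, 0.144, 0.006], atol=1e-12)
        assert (raw.owner == 0).all()

    def test_normalization(self, micro_scene):
        space, model, field, dmap = micro_scene
        raw = propagate_frame(field, model, dmap)
        out, lost = normalize_per_object(raw, [0])
        assert np.allclose(out.prob.ravel(),
                           [0.5833333333, 0.4, 0.0166667], atol=1e-7)
        assert out.prob.sum() == pytest.approx(1.0, abs=1e-12)
        assert lost == []

    def test_state_estimate(self, micro_scene):
        space, model, field, dmap = micro_scene
        raw = propagate_frame(field, model, dmap)
        out, _ = normalize_per_object(raw, [0])
        (pt,) = estimate_object_states(out, [0])
        assert pt.state == 0
        assert pt.map_prob == pytest.approx(0.5833333333, abs=1e-9)

    def test_step_frame_composes_the_three_operations(self, micro_scene):
        space, model, field, dmap = micro_scene
        scenario = Scenario(fps=16.0)
        new_field, points, lifecycle = step_frame(field, model, dmap,
                                                  scenario, live_ids=[0])
        assert np.allclose(new_field.prob.ravel(),
                           [0.5833333333, 0.4, 0.0166667], atol=1e-7)
        assert points[0].state == 0
        assert lifecycle == {"new": [], "removed": [], "lost": []}


def test_point_mass_kernel_is_identity(line3_space):
    model = build_motion_model(line3_space, 0.0, 0.0, pos_radius=1,
                               orient_radius=0)
    field = OwnershipField.empty(line3_space)
    field.owner[0, :, 0] = [0, 0, BACKGROUND]
    field.prob[0, :, 0] = [0.4, 0.6, 0.0]
    for s in range(2):
        e, score = most_likely_predecessor(field, model, s)
        assert e == s
    ones = DetectionMap(1, np.ones(line3_space.shape))
    raw = propagate_frame(field, model, ones)
    assert np.allclose(raw.ptilde, field.prob)   # identity propagation
    assert np.array_equal(raw.owner, field.owner)


def test_sequencing_error_on_nonconsecutive_frame(micro_scene):
    space, model, field, dmap = micro_scene
    bad = DetectionMap(5, dmap.values)
    with pytest.raises(SequencingError):
        propagate_frame(field, model, bad)


def test_predecessor_tie_breaks_to_smallest_flat_index(line3_space):
    # uniform kernel, uniform probabilities: every predecessor of cell 1 ties
    kernel = np.full((3, 3, 1), 0.0)
    kernel[1, :, 0] = 1.0 / 3.0
    model = motion_model_from_kernel(line3_space, kernel, 1, 0)
    field = OwnershipField.empty(line3_space)
    field.owner[:] = 0
    field.prob[0, :, 0] = [1 / 3, 1 / 3, 1 / 3]
    e, _ = most_likely_predecessor(field, model, 1)
    assert e == 0
    raw = propagate_frame(field, model, DetectionMap(1, np.ones(line3_space.shape)))
    assert raw.pred_flat[0, 1, 0] == 0


def test_estimate_tie_breaks_to_smallest_flat_index():
    space = StateSpace(n_x=5, n_y=2, cell_size=1.0, n_orient=1)
    field = OwnershipField.empty(space, frame_index=3)
    field.owner[:] = 0
    flat = field.prob.reshape(-1)
    flat[4] = 0.5
    flat[9] = 0.5
    (pt,) = estimate_object_states(field, [0])
    assert pt.state == 4


def test_lost_object_reported_not_raised(line3_space):
    model = build_motion_model(line3_space, 0.0, 0.0, 1, 0)
    field = OwnershipField.empty(line3_space)
    field.owner[0, 0, 0] = 0
    field.prob[0, 0, 0] = 0.0                   # object with no mass left
    raw = propagate_frame(field, model,
                          DetectionMap(1, np.full(line3_space.shape, 0.5)))
    out, lost = normalize_per_object(raw, [0])
    assert lost == [0]
    assert estimate_object_states(out, [0]) == []


class TestRunSequence:
    def _delta_maps(self, space, path, peak=0.9, floor=1e-6):
        maps = np.full((len(path),) + space.shape, floor, dtype=np.float32)
        for t, s in enumerate(path):
            maps[t].reshape(-1)[s] = peak
        return maps

    def test_noiseless_path_recovered_exactly(self):
        space = StateSpace(n_x=8, n_y=3, cell_size=0.1, n_orient=1)
        model = build_motion_model(space, 1.0, 0.0, pos_radius=1,
                                   orient_radius=0)
        path = [space.flat_index(x, 1, 0) for x in (0, 1, 2, 2, 3, 4)]
        maps = self._delta_maps(space, path)
        scenario = Scenario(fps=16.0, initial_objects=[(path[0], "c1")])
        tracks, diag = run_sequence(maps, space, model, scenario)
        assert [p.state for p in tracks[0].points] == path
        assert tracks[0].status == "active"

    def test_empty_sequence_and_empty_scene(self):
        space = StateSpace(n_x=4, n_y=4, cell_size=0.1, n_orient=2)
        model = build_motion_model(space, 1.0, 1.0, 1, 1)
        tracks, diag = run_sequence(np.zeros((0,) + space.shape), space,
                                    model, Scenario(fps=16.0))
        assert tracks == []
        maps = np.full((5,) + space.shape, 1e-6, dtype=np.float32)
        tracks, diag = run_sequence(maps, space, model, Scenario(fps=16.0))
        assert tracks == []

    def test_deterministic_rerun(self):
        space = StateSpace(n_x=10, n_y=10, cell_size=0.1, n_orient=2)
        model = build_motion_model(space, 1.0, 1.0, 1, 1)
        rng = np.random.default_rng(11)
        maps = rng.random((12,) + space.shape).astype(np.float32)
        gate = Gate("g", 5, 5, 0, role="entry")
        from barntrack import GateEvent
        scenario = Scenario(fps=16.0, gates=[gate],
                            events=[GateEvent(0.0, 0, "g", 7, "entry")])
        t1, _ = run_sequence(maps.copy(), space, model, scenario)
        t2, _ = run_sequence(maps.copy(), space, model, scenario)
        assert [(p.frame_index, p.state, p.map_prob) for p in t1[0].points] == \
               [(p.frame_index, p.state, p.map_prob) for p in t2[0].points]

    def test_permutation_equivariance_of_labels(self):
        space = StateSpace(n_x=12, n_y=6, cell_size=0.1, n_orient=2)
        model = build_motion_model(space, 1.0, 1.0, 1, 1)
        rng = np.random.default_rng(4)
        maps = rng.random((10,) + space.shape).astype(np.float32)
        a = (space.flat_index(2, 2, 0), "A")
        b = (space.flat_index(9, 4, 1), "B")
        tr_ab, _ = run_sequence(maps.copy(), space, model,
                                Scenario(fps=16.0, initial_objects=[a, b]))
        tr_ba, _ = run_sequence(maps.copy(), space, model,
                                Scenario(fps=16.0, initial_objects=[b, a]))
        by_id_ab = {t.animal_id: [p.state for p in t.points] for t in tr_ab}
        by_id_ba = {t.animal_id: [p.state for p in t.points] for t in tr_ba}
        assert by_id_ab == by_id_ba


def test_linear_domain_survives_floor_level_detections():
    """Hundreds of frames at the detection floor: the per-object
    normalization keeps the recursion finite and conserved (no underflow
    to zero, no NaN), which is what justifies staying out of log space."""
    space = StateSpace(n_x=12, n_y=12, cell_size=0.1, n_orient=4)
    model = build_motion_model(space, 1.0, 1.0, 2, 1)
    maps = np.full((400,) + space.shape, 1e-6, dtype=np.float32)
    scenario = Scenario(fps=16.0,
                        initial_objects=[(space.flat_index(6, 6, 0), "c")])
    tracks, diag = run_sequence(maps, space, model, scenario,
                                check_conservation=True)
    assert diag.max_conservation_error < 1e-9
    assert tracks[0].status == "active"
    assert len(tracks[0].points) == 400
    assert all(np.isfinite(p.map_prob) and p.map_prob > 0
               for p in tracks[0].points)


def test_ownership_partitions_states(micro_scene):
    space, model, field, dmap = micro_scene
    raw = propagate_frame(field, model, dmap)
    out, _ = normalize_per_object(raw, [0])
    assert set(np.unique(out.owner)) <= {BACKGROUND, 0}
    assert (out.prob[out.owner == BACKGROUND] == 0).all()
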