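"""Frame loop: composing propagation, normalization and gate events.

The order of operations within one frame is fixed:

1. inject synthetic gate observations into the detection map,
2. propagate owners and probabilities,
3. normalize per object (objects with zero mass become *lost*),
4. apply entry events,
5. apply exit events (only in ``exit_mode="gate"``),
6. estimate per-object states,
7. update the exit-criterion dwell counters (and, in
   ``exit_mode="criterion"``, remove objects whose dwell at an exit gate
   exceeded the hold time).

``run_sequence`` is deterministic given identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import DataError
from .gates import (Gate, Scenario, apply_entry_event, apply_exit_event,
                    exit_hold_frames, inject_gate_observations)
from .motion import MotionModel
from .state_space import DEFAULT_DETECTION_FLOOR, DetectionMap, StateSpace
from .tracker import (BACKGROUND, OwnershipField, Track, TrackPoint,
                      _SeparableTables, estimate_object_states,
                      normalize_per_object, propagate_frame)

__all__ = ["run_sequence", "step_frame", "RunDiagnostics"]

log = logging.getLogger(__name__)


@dataclass
class RunDiagnostics:
    """Per-run bookkeeping surfaced on :class:`~barntrack.api.TrackingResults`."""

    n_frames: int = 0
    n_spurious_exit_events: int = 0
    n_lost: int = 0
    max_conservation_error: float = 0.0
    live_counts: list = dc_field(default_factory=list)


class _Engine:
    def __init__(self, space: StateSpace, model: MotionModel,
                 scenario: Scenario, exit_mode: str = "gate",
                 detection_floor: float = DEFAULT_DETECTION_FLOOR,
                 hold_s: float = 0.5, check_conservation: bool = False):
        if exit_mode not in ("gate", "criterion"):
            raise ValueError("exit_mode must be 'gate' or 'criterion'")
        scenario.validate(space)
        self.space = space
        self.model = model
        self.scenario = scenario
        self.exit_mode = exit_mode
        self.floor = detection_floor
        self.check_conservation = check_conservation
        self.tables = _SeparableTables(model) if model.separable else None
        self.hold_frames = exit_hold_frames(scenario.fps, hold_s)
        self.exit_gates = [g for g in scenario.gates if g.role in ("exit", "both")]
        self.field = OwnershipField.empty(space, frame_index=0)
        self.tracks: dict[int, Track] = {}
        self.live: set[int] = set()
        self.next_id = 0
        # per-object exit dwell counters: id -> [gate_id, run_len, run_start]
        self.dwell: dict[int, list] = {}
        self.diag = RunDiagnostics()
        self.events_by_frame: dict[int, list] = {}
        for e in scenario.events:
            self.events_by_frame.setdefault(e.frame_index, []).append(e)

    # -- lifecycle ---------------------------------------------------------
    def _new_track(self, frame: int, gate: Gate | None, animal_id=None) -> int:
        oid = self.next_id
        self.next_id += 1
        self.tracks[oid] = Track(object_id=oid, animal_id=animal_id,
                                 entry_frame=frame,
                                 entry_gate=gate.gate_id if gate else None)
        self.live.add(oid)
        self.dwell[oid] = [None, 0, -1]
        return oid

    def _mark_lost(self, oid: int) -> None:
        self.live.discard(oid)
        self.dwell.pop(oid, None)
        self.tracks[oid].status = "lost"
        self.diag.n_lost += 1

    def _mark_exited(self, oid: int, gate_id: str, frame: int) -> None:
        owner = self.field.owner.reshape(-1)
        prob = self.field.prob.reshape(-1)
        mask = owner == oid
        prob[mask] = 0.0
        owner[mask] = BACKGROUND
        self.live.discard(oid)
        self.dwell.pop(oid, None)
        tr = self.tracks[oid]
        tr.status = "exited"
        tr.exit_gate = gate_id
        tr.exit_frame = frame

    # -- per-frame work ----------------------------------------------------
    def _apply_events(self, frame: int, d: DetectionMap) -> None:
        for e in self.events_by_frame.get(frame, ()):
            if e.kind == "entry":
                gate = self.scenario.gate(e.gate_id)
                if gate.role == "exit":
                    continue  # entry registration at a pure exit gate: ignore
                oid = self._new_track(frame, gate)
                lost_prev = apply_entry_event(self.field, self.space, gate,
                                              oid, d,
                                              clear_radius=self.model.pos_radius)
                for prev in lost_prev:
                    if prev in self.live:
                        self._mark_lost(prev)
        if self.exit_mode == "gate":
            for e in self.events_by_frame.get(frame, ()):
                if e.kind != "exit":
                    continue
                gate = self.scenario.gate(e.gate_id)
                if gate.role == "entry":
                    continue
                removed = apply_exit_event(self.field, self.space, gate,
                                           self.model, self.live)
                if removed is None:
                    self.diag.n_spurious_exit_events += 1
                else:
                    self._mark_exited(removed, gate.gate_id, frame)

    def _record_points(self, points: list[TrackPoint]) -> None:
        for pt in points:
            self.tracks[pt.object_id].points.append(pt)

    def _update_dwell(self, frame: int, points: list[TrackPoint]) -> None:
        fired = []
        for pt in points:
            if pt.object_id not in self.dwell:
                continue
            here = None
            for g in self.exit_gates:
                if g.matches_state(self.space, pt.state):
                    here = g.gate_id
                    break
            counter = self.dwell[pt.object_id]
            if here is None:
                counter[0], counter[1], counter[2] = None, 0, -1
            elif counter[0] == here and counter[2] + counter[1] == frame:
                counter[1] += 1
            else:
                counter[0], counter[1], counter[2] = here, 1, frame
            if (self.exit_mode == "criterion" and counter[0] is not None
                    and counter[1] >= self.hold_frames):
                fired.append((pt.object_id, counter[0], counter[2]))
        for oid, gate_id, run_start in fired:
            self._mark_exited(oid, gate_id, run_start)

    def _check_conservation(self) -> None:
        from .tracker import _object_sums
        if not self.live:
            return
        sums = _object_sums(self.field.prob, self.field.owner,
                            max(self.live) + 1)
        err = max(abs(sums[o] - 1.0) for o in self.live)
        self.diag.max_conservation_error = max(
            self.diag.max_conservation_error, float(err))

    def init_frame0(self, d0: DetectionMap) -> None:
        for flat_state, synth_id in self.scenario.initial_objects:
            oid = self._new_track(0, gate=None, animal_id=synth_id)
            owner = self.field.owner.reshape(-1)
            prob = self.field.prob.reshape(-1)
            owner[flat_state] = oid
            prob[flat_state] = 1.0
        self._apply_events(0, d0)
        points = estimate_object_states(self.field, self.live)
        self._record_points(points)
        self._update_dwell(0, points)
        if self.check_conservation:
            self._check_conservation()
        self.diag.live_counts.append(len(self.live))

    def step(self, d: DetectionMap) -> list[TrackPoint]:
        d = inject_gate_observations(d, self.scenario.gates, self.space,
                                     inplace=True)
        raw = propagate_frame(self.field, self.model, d, self.tables)
        self.field, lost = normalize_per_object(raw, self.live)
        for oid in lost:
            self._mark_lost(oid)
        self._apply_events(d.frame_index, d)
        points = estimate_object_states(self.field, self.live)
        self._record_points(points)
        self._update_dwell(d.frame_index, points)
        if self.check_conservation:
            self._check_conservation()
        self.diag.live_counts.append(len(self.live))
        if log.isEnabledFor(logging.DEBUG):
            log.debug("frame %d: %d live object(s), %d lost",
                      d.frame_index, len(self.live), len(lost))
        return points


def step_frame(field: OwnershipField, model: MotionModel, d: DetectionMap,
               scenario: Scenario, live_ids, exit_mode: str = "gate"):
    """One exposed tracking step on an explicit field (functional surface).

    Returns ``(new_field, track_points, lifecycle)`` where ``lifecycle`` is a
    dict with ``new``, ``removed`` and ``lost`` object-id lists.  For whole
    recordings use :func:`run_sequence`, which keeps track bookkeeping.
    """
    engine = _Engine(model.space, model, scenario, exit_mode=exit_mode)
    engine.field = field.copy()
    engine.live = set(live_ids)
    engine.next_id = (max(engine.live) + 1) if engine.live else 0
    for oid in engine.live:
        engine.tracks[oid] = Track(object_id=oid)
        engine.dwell[oid] = [None, 0, -1]
    before = set(engine.live)
    points = engine.step(d)
    after = set(engine.live)
    lifecycle = {
        "new": sorted(after - before),
        "removed": sorted(t.object_id for t in engine.tracks.values()
                          if t.status == "exited"),
        "lost": sorted(t.object_id for t in engine.tracks.values()
                       if t.status == "lost"),
    }
    return engine.field, points, lifecycle


def run_sequence(maps, space: StateSpace, model: MotionModel,
                 scenario: Scenario, exit_mode: str = "gate",
                 detection_floor: float = DEFAULT_DETECTION_FLOOR,
                 check_conservation: bool = False):
    """Track a whole recording; returns ``(tracks, diagnostics)``.

    ``maps`` is a ``(n_frames, n_y, n_x, n_orient)`` array of detection
    likelihoods in [0, 1].  Values are floored to ``detection_floor``
    frame by frame.  Returns one :class:`Track` per object ever
    instantiated.
    """
    maps = np.asarray(maps)
    if maps.ndim != 4 or maps.shape[1:] != space.shape:
        raise DataError(
            f"maps must have shape (n_frames, {space.shape}), got {maps.shape}")
    engine = _Engine(space, model, scenario, exit_mode=exit_mode,
                     detection_floor=detection_floor,
                     check_conservation=check_conservation)
    n_frames = maps.shape[0]
    engine.diag.n_frames = n_frames
    if n_frames == 0:
        return [], engine.diag
    if float(maps.min()) < -1e-9 or float(maps.max()) > 1.0 + 1e-9:
        raise DataError("detection values outside [0, 1]")
    last = max(engine.events_by_frame, default=0)
    if last >= n_frames:
        raise DataError("gate event beyond the end of the map sequence")
    buf = np.empty(space.shape, dtype=np.float64)
    np.maximum(maps[0], detection_floor, out=buf, casting="unsafe")
    engine.init_frame0(DetectionMap(frame_index=0, values=buf))
    for t in range(1, n_frames):
        np.maximum(maps[t], detection_floor, out=buf, casting="unsafe")
        engine.step(DetectionMap(frame_index=t, values=buf))
    tracks = [engine.tracks[oid] for oid in sorted(engine.tracks)]
    return tracks, engine.diag
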