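"""Gate events: entry instantiation, exit removal, identity assignment.

Selection gates with RFID readers sit at fixed states of the grid.  When an
entry gate registers an animal, a new tracked object is instantiated at the
gate state; when an exit gate registers one, the object currently most
likely to be at the gate state is removed.  Between gate events the number
of live objects is constant, which is what makes the per-state ownership
recursion well posed.

Two auxiliary mechanisms from the original protocol are implemented here:

* *Synthetic gate observations*: every frame, the detection likelihood at
  each gate state is raised to at least ``synthetic_prob`` (default 0.05),
  so that a track can sit at a gate during the interval between the RFID
  registration and the animal being fully visible (or vice versa on exit).
* *Time reversal*: exit registrations are typically better timed than entry
  registrations (an exit gate fires only once the animal has left), so the
  whole sequence can be played backwards with entry and exit gates swapping
  roles.  Tracks are then traced backwards from the RFID read to the moment
  of actual entry, which is how each visual track acquires its real animal
  identity (:func:`backtrace_identity`).

An alternative evaluation mode withholds the gate exit events from the
tracker entirely: exits are detected by the 0.5 s criterion
(:func:`check_exit_criterion`) and the registrations are used only for
scoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import DataError
from .motion import MotionModel
from .state_space import DetectionMap, StateSpace
from .tracker import BACKGROUND, OwnershipField, Track

__all__ = [
    "Gate",
    "GateEvent",
    "Scenario",
    "inject_gate_observations",
    "apply_entry_event",
    "apply_exit_event",
    "check_exit_criterion",
    "exit_hold_frames",
    "reverse_scenario",
    "backtrace_identity",
]


@dataclass(frozen=True)
class Gate:
    """A physical gate bound to a grid cell.

    ``orient_bin=None`` means the gate matches any orientation at its cell
    (written ``"any"`` in config files); entry through such a gate
    instantiates the object at the orientation with the strongest current
    detection.
    """

    gate_id: str
    x: int
    y: int
    orient_bin: int | None = None
    role: str = "both"          # "entry", "exit" or "both"
    synthetic_prob: float = 0.05

    def __post_init__(self) -> None:
        if self.role not in ("entry", "exit", "both"):
            raise ValueError("gate role must be entry, exit or both")
        if not (0.0 < self.synthetic_prob < 1.0):
            raise ValueError("synthetic_prob must lie in (0, 1)")

    def validate(self, space: StateSpace) -> None:
        if not (0 <= self.x < space.n_x and 0 <= self.y < space.n_y):
            raise DataError(f"gate {self.gate_id} lies outside the grid")
        if self.orient_bin is not None and not 0 <= self.orient_bin < space.n_orient:
            raise DataError(f"gate {self.gate_id} orientation bin out of range")

    def state_indices(self, space: StateSpace) -> np.ndarray:
        """Flat indices of the gate's states (all bins when orientation is any)."""
        if self.orient_bin is None:
            ks = np.arange(space.n_orient)
        else:
            ks = np.array([self.orient_bin])
        return space.flat_index(np.full_like(ks, self.x),
                                np.full_like(ks, self.y), ks)

    def matches_state(self, space: StateSpace, flat_state: int) -> bool:
        x, y, k = space.from_flat(flat_state)
        if (x, y) != (self.x, self.y):
            return False
        return self.orient_bin is None or k == self.orient_bin

    def with_role(self, role: str) -> "Gate":
        return Gate(self.gate_id, self.x, self.y, self.orient_bin, role,
                    self.synthetic_prob)


@dataclass(frozen=True)
class GateEvent:
    """One RFID registration: an animal passing a gate."""

    time_s: float
    frame_index: int
    gate_id: str
    animal_id: object
    kind: str  # "entry" or "exit"

    def __post_init__(self) -> None:
        if self.kind not in ("entry", "exit"):
            raise ValueError("event kind must be entry or exit")

    @classmethod
    def at_time(cls, time_s: float, fps: float, gate_id: str, animal_id,
                kind: str) -> "GateEvent":
        return cls(time_s=time_s, frame_index=int(round(time_s * fps)),
                   gate_id=gate_id, animal_id=animal_id, kind=kind)


@dataclass
class Scenario:
    """Gate layout, registration log and initial occupancy of a recording.

    ``initial_objects`` lists ``(flat_state, synthetic_id)`` pairs for
    animals already present in the first frame (they carry synthetic
    identities because no registration instantiated them).
    """

    fps: float
    gates: list = dc_field(default_factory=list)
    events: list = dc_field(default_factory=list)
    initial_objects: list = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.fps > 0):
            raise ValueError("fps must be > 0")
        frames = [e.frame_index for e in self.events]
        if frames != sorted(frames):
            raise DataError("gate events must be sorted by frame")

    def gate(self, gate_id: str) -> Gate:
        for g in self.gates:
            if g.gate_id == gate_id:
                return g
        raise DataError(f"unknown gate id {gate_id!r}")

    def validate(self, space: StateSpace) -> None:
        for g in self.gates:
            g.validate(space)
        ids = {g.gate_id for g in self.gates}
        for e in self.events:
            if e.gate_id not in ids:
                raise DataError(f"event references unknown gate {e.gate_id!r}")


def inject_gate_observations(d: DetectionMap, gates, space: StateSpace,
                             inplace: bool = False) -> DetectionMap:
    """Raise the detection likelihood at each gate state to its synthetic floor.

    The value is only ever raised (``max``), never lowered, so the operation
    is idempotent and real detections pass through untouched.
    """
    values = d.values if inplace else d.values.copy()
    for gate in gates:
        idx = gate.state_indices(space)
        flat = values.reshape(-1)
        flat[idx] = np.maximum(flat[idx], gate.synthetic_prob)
    if inplace:
        return d
    return DetectionMap(frame_index=d.frame_index, values=values)


def _entry_state(gate: Gate, space: StateSpace,
                 d: DetectionMap | None) -> int:
    if gate.orient_bin is not None:
        return space.flat_index(gate.x, gate.y, gate.orient_bin)
    if d is None:
        return space.flat_index(gate.x, gate.y, 0)
    bins = d.values[gate.y, gate.x, :]
    return space.flat_index(gate.x, gate.y, int(np.argmax(bins)))


def apply_entry_event(field: OwnershipField, space: StateSpace, gate: Gate,
                      new_object_id: int, d: DetectionMap | None = None,
                      clear_radius: int = 0) -> list[int]:
    """Instantiate ``new_object_id`` at the gate state with probability one.

    Previous owners of the claimed states lose them and are renormalized
    over their remaining states; owners left with nothing are returned so
    the caller can flag them lost.

    ``clear_radius > 0`` additionally claims the whole spatial neighbourhood
    of the gate cell (all orientations): the entering animal's body occupies
    the gate area, so probability mass another object keeps parked there —
    typically a track held at the gate by the synthetic observations — is
    physically displaced.  Without this, such parked mass renormalizes onto
    the ring around the gate and can capture the newcomer's detections.
    """
    if gate.role == "exit":
        raise DataError(f"gate {gate.gate_id} does not allow entry")
    s_in = _entry_state(gate, space, d)
    owner = field.owner.reshape(-1)
    prob = field.prob.reshape(-1)
    claimed = np.zeros(owner.shape, dtype=bool)
    claimed[s_in] = True
    if clear_radius > 0:
        ys, xs = _neighborhood_slices(space, gate.x, gate.y, clear_radius)
        block = np.zeros(space.shape, dtype=bool)
        block[ys, xs, :] = True
        claimed |= block.reshape(-1)
    lost = []
    for prev in np.unique(owner[claimed]):
        prev = int(prev)
        if prev == BACKGROUND or prev == new_object_id:
            continue
        mine = owner == prev
        q = float(prob[claimed & mine].sum())
        keep = mine & ~claimed
        remaining = float(prob[mine].sum()) - q
        if remaining <= 0.0 or not keep.any():
            if keep.any():
                prob[keep] = 0.0
                owner[keep] = BACKGROUND
            lost.append(prev)
        else:
            prob[keep] /= remaining
    prob[claimed] = 0.0
    owner[claimed] = BACKGROUND
    owner[s_in] = new_object_id
    prob[s_in] = 1.0
    return lost


def _neighborhood_slices(space: StateSpace, x: int, y: int, radius: int):
    ys = slice(max(0, y - radius), min(space.n_y, y + radius + 1))
    xs = slice(max(0, x - radius), min(space.n_x, x + radius + 1))
    return ys, xs


def apply_exit_event(field: OwnershipField, space: StateSpace, gate: Gate,
                     model: MotionModel, live_ids) -> int | None:
    """Remove the object most likely to be at the gate state.

    If the gate state is owned by a live object, that object is removed.
    Otherwise the live object with the largest probability mass inside the
    kernel-support neighbourhood of the gate cell is removed (ties toward
    the smallest object id).  Returns the removed id, or ``None`` when no
    live object exists (the event is then spurious and only logged by the
    caller).
    """
    if gate.role == "entry":
        raise DataError(f"gate {gate.gate_id} does not allow exit")
    live = sorted(live_ids)
    if not live:
        return None
    idx = gate.state_indices(space)
    owner = field.owner.reshape(-1)
    prob = field.prob.reshape(-1)
    owners_here = owner[idx]
    probs_here = prob[idx]
    live_set = set(live)
    target = None
    best_p = -1.0
    for o, p in zip(owners_here, probs_here):
        if o in live_set and p > best_p:
            best_p = p
            target = int(o)
    if target is None:
        ys, xs = _neighborhood_slices(space, gate.x, gate.y, model.pos_radius)
        sub_owner = field.owner[ys, xs, :].reshape(-1)
        sub_prob = field.prob[ys, xs, :].reshape(-1)
        masses = {o: 0.0 for o in live}
        for o, p in zip(sub_owner, sub_prob):
            if o in masses:
                masses[o] += p
        target = max(live, key=lambda o: (masses[o], -o))
    mask = owner == target
    prob[mask] = 0.0
    owner[mask] = BACKGROUND
    return target


def exit_hold_frames(fps: float, hold_s: float = 0.5) -> int:
    """Consecutive frames required for "more than ``hold_s`` seconds".

    Read strictly: at 16 FPS, 8 frames is exactly 0.5 s and does not fire;
    ``floor(hold_s * fps) + 1 = 9`` frames does.
    """
    return int(math.floor(hold_s * fps)) + 1


def check_exit_criterion(track: Track, gates, space: StateSpace, fps: float,
                         hold_s: float = 0.5):
    """First exit-gate dwell exceeding ``hold_s`` seconds, if any.

    Scans the track's estimated states for a run of consecutive frames all
    matching one exit-role gate; returns ``(gate_id, first_frame_of_run)``
    for the earliest qualifying run, else ``None``.
    """
    exit_gates = [g for g in gates if g.role in ("exit", "both")]
    if not exit_gates:
        return None
    need = exit_hold_frames(fps, hold_s)
    run_gate = None
    run_start = None
    run_len = 0
    prev_frame = None
    for pt in track.points:
        here = None
        for g in exit_gates:
            if g.matches_state(space, pt.state):
                here = g.gate_id
                break
        consecutive = prev_frame is not None and pt.frame_index == prev_frame + 1
        if here is not None and here == run_gate and consecutive:
            run_len += 1
        elif here is not None:
            run_gate = here
            run_start = pt.frame_index
            run_len = 1
        else:
            run_gate = None
            run_len = 0
        if run_gate is not None and run_len >= need:
            return run_gate, run_start
        prev_frame = pt.frame_index
    return None


def reverse_scenario(maps: np.ndarray, scenario: Scenario):
    """Play the recording backwards: exit gates become entry gates and vice
    versa, events swap kind, and timestamps map frame -> n_frames-1-frame.

    Reversing twice restores the original maps, roles and times exactly.
    ``initial_objects`` are passed through unchanged; animals present at the
    start of the reversed sequence must be marked by the caller (in the
    original protocol they were marked manually with synthetic ids).
    """
    maps = np.asarray(maps)
    n_frames = maps.shape[0]
    rev_maps = maps[::-1].copy()
    role_swap = {"entry": "exit", "exit": "entry", "both": "both"}
    rev_gates = [g.with_role(role_swap[g.role]) for g in scenario.gates]
    kind_swap = {"entry": "exit", "exit": "entry"}
    rev_events = []
    for e in scenario.events:
        f = n_frames - 1 - e.frame_index
        if f < 0:
            raise DataError("event frame beyond the end of the map sequence")
        rev_events.append(GateEvent(time_s=f / scenario.fps, frame_index=f,
                                    gate_id=e.gate_id, animal_id=e.animal_id,
                                    kind=kind_swap[e.kind]))
    rev_events.sort(key=lambda e: (e.frame_index, str(e.gate_id), e.kind))
    return rev_maps, Scenario(fps=scenario.fps, gates=rev_gates,
                              events=rev_events,
                              initial_objects=list(scenario.initial_objects))


def backtrace_identity(tracks, events) -> list:
    """Attach the registering animal id to each gate-instantiated track.

    A track instantiated by an entry registration carries that animal's id
    along its whole length, back to the first frame.  Tracks without a
    matching registration (manually marked initial animals) keep whatever
    synthetic id they already have.  Two registrations claiming the same
    track, or one registration claiming two tracks, is a data error.
    """
    events_by_key: dict[tuple, list] = {}
    for e in events:
        if e.kind == "entry":
            events_by_key.setdefault((e.frame_index, e.gate_id), []).append(e)
    tracks_by_key: dict[tuple, list] = {}
    for tr in tracks:
        if tr.entry_gate is None or tr.entry_frame is None:
            continue
        tracks_by_key.setdefault((tr.entry_frame, tr.entry_gate), []).append(tr)
    for key, evs in events_by_key.items():
        trs = sorted(tracks_by_key.get(key, []), key=lambda t: t.object_id)
        if not trs:
            continue  # registration that instantiated nothing: not our track
        if len(evs) > len(trs):
            frame, gate = key
            raise DataError(
                f"{len(evs)} registrations at gate {gate!r}, frame {frame} "
                f"claim only {len(trs)} instantiated track(s)")
        # simultaneous registrations at one gate pair with the objects they
        # instantiated, in instantiation order
        for ev, tr in zip(evs, trs):
            tr.animal_id = ev.animal_id
    return tracks
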