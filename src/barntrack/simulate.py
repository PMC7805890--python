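"""Synthetic barn scenes: cow trajectories, gate logs and detection maps.

The simulator stands in for the physical barn and the CNN detector.  It
emulates a rectangular waiting area (default 6 x 18 m) in front of four
automatic milking stations, recorded top-down at 16 frames per second.
Cows enter through an entry gate following a Poisson-like arrival schedule,
wander with a correlated random walk (Ornstein-Uhlenbeck speed, heading
following the motion direction, mild mutual repulsion), and eventually walk
to a chosen milking-station gate and leave; every entry and exit is written
to the gate log with the cow's animal id.

Detection-likelihood maps are rendered from the true states: per frame each
cow yields, with probability ``detect_prob``, a Gaussian likelihood bump
(peak 0.9) at its true state, blurred spatially by ``peak_sigma_cells`` and
in orientation by ``orient_noise_bins``; Poisson clutter bumps with weight
``clutter_weight`` appear at uniformly random states; everything is clamped
to ``[floor, 1]``.  The peak value of 0.9 (not 1.0) mimics realistic
detector confidence and keeps synthetic gate observations distinguishable.

All randomness flows from a single seeded generator: equal seeds give
byte-identical ground truth and maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .errors import DataError
from .gates import Gate, GateEvent, Scenario
from .state_space import DEFAULT_DETECTION_FLOOR, StateSpace, build_state_space

__all__ = [
    "NoiseSpec",
    "SceneConfig",
    "GroundTruth",
    "default_gate_layout",
    "simulate_scene",
    "render_detection_maps",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Detector-emulation noise parameters."""

    detect_prob: float = 0.95
    peak_sigma_cells: float = 1.0
    clutter_rate: float = 0.2
    clutter_weight: float = 0.3
    orient_noise_bins: int = 0
    peak_value: float = 0.9
    floor: float = DEFAULT_DETECTION_FLOOR

    def __post_init__(self) -> None:
        for name in ("detect_prob", "clutter_weight", "peak_value"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.clutter_rate < 0 or self.peak_sigma_cells < 0:
            raise ValueError("rates and sigmas must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseSpec":
        """Delta detections: every cow detected every frame, no clutter."""
        return cls(detect_prob=1.0, peak_sigma_cells=0.0, clutter_rate=0.0,
                   orient_noise_bins=0)


@dataclass(frozen=True)
class SceneConfig:
    """Scenario parameters for one synthetic recording."""

    width_m: float = 6.0
    height_m: float = 18.0
    cell_size: float = 0.1
    n_orient: int = 8
    fps: float = 16.0
    duration_s: float = 180.0
    n_cows: int = 5
    seed: int = 0
    noise: NoiseSpec = dc_field(default_factory=NoiseSpec)
    gates: tuple = ()              # () -> default layout
    max_speed_cells: float = 0.8   # per frame; < 1 keeps grid steps in {-1,0,1}
    mean_speed_cells: float = 0.45
    turn_sigma: float = 0.12       # rad per frame
    min_entry_gap_s: float = 4.0   # a gate passes one animal every few
                                   # seconds; the previous animal has walked
                                   # clear of the gate footprint by then
    repulsion_radius_m: float = 0.6  # body-scale collision avoidance
    first_cow_id: int = 1001

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be > 0")
        if self.n_cows < 0:
            raise ValueError("n_cows must be >= 0")
        if not (0 < self.max_speed_cells < 1):
            raise ValueError("max_speed_cells must lie in (0, 1) cells/frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    def state_space(self) -> StateSpace:
        return build_state_space(self.width_m, self.height_m, self.cell_size,
                                 self.n_orient)

    def gate_list(self, space: StateSpace) -> list[Gate]:
        gates = list(self.gates) if self.gates else default_gate_layout(space)
        for g in gates:
            g.validate(space)
        return gates


def default_gate_layout(space: StateSpace) -> list[Gate]:
    """One entry gate on the far wall, four milking-station exit gates.

    The exit gates sit along the near (y = 0) wall, evenly spaced, matching
    any orientation; the entry gate faces into the area (-y direction).
    """
    entry_bin = space.orient_bin(-np.pi / 2.0)
    exits_x = np.linspace(0.125, 0.875, 4) * space.n_x
    gates = [Gate(gate_id="entry", x=space.n_x // 2, y=space.n_y - 2,
                  orient_bin=entry_bin, role="entry")]
    for i, gx in enumerate(exits_x, start=1):
        gates.append(Gate(gate_id=f"ms{i}", x=int(gx), y=2,
                          orient_bin=None, role="exit"))
    return gates


@dataclass
class GroundTruth:
    """True per-frame states per cow plus the resulting gate log."""

    space: StateSpace
    config: SceneConfig
    n_frames: int
    # per cow: animal_id -> (entry_frame, flat-state array, exit_frame or None)
    cows: dict = dc_field(default_factory=dict)
    events: list = dc_field(default_factory=list)
    gates: list = dc_field(default_factory=list)

    def state_at(self, animal_id, frame: int) -> int | None:
        entry, states, _ = self.cows[animal_id]
        j = frame - entry
        if 0 <= j < len(states):
            return int(states[j])
        return None

    def scenario(self) -> Scenario:
        return Scenario(fps=self.config.fps, gates=list(self.gates),
                        events=sorted(self.events,
                                      key=lambda e: (e.frame_index,
                                                     str(e.gate_id), e.kind)))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for cow, (entry, states, _) in sorted(self.cows.items()):
            x, y, k = self.space.from_flat(np.asarray(states))
            for j in range(len(states)):
                rows.append((entry + j, cow, int(x[j]), int(y[j]), int(k[j])))
        return pd.DataFrame(rows, columns=["frame", "cow_id", "x", "y",
                                           "orient_bin"])


def _wrap_angle(a: float) -> float:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


class _Cow:
    def __init__(self, animal_id, entry_frame, pos, heading, exit_gate):
        self.animal_id = animal_id
        self.entry_frame = entry_frame
        self.pos = pos                  # float (x, y) in cell units
        self.heading = heading
        self.speed = 0.3
        self.exit_gate = exit_gate
        self.seek_frame = None          # frame at which it starts seeking
        self.states: list[int] = []
        self.exit_frame = None


def simulate_scene(config: SceneConfig) -> GroundTruth:
    """Generate ground-truth trajectories and the gate log.

    Deterministic given ``config.seed``.  Every cow produces one entry
    event; cows that reach their chosen milking station before the end of
    the recording also produce one exit event.  Per-frame grid
    displacements are bounded by one cell per axis and one orientation bin.
    """
    space = config.state_space()
    gates = config.gate_list(space)
    entry_gates = [g for g in gates if g.role in ("entry", "both")]
    exit_gates = [g for g in gates if g.role in ("exit", "both")]
    if config.n_cows > 0 and (not entry_gates or not exit_gates):
        raise DataError("scenario needs at least one entry and one exit gate")
    rng = np.random.default_rng(config.seed)
    n_frames = config.n_frames
    truth = GroundTruth(space=space, config=config, n_frames=n_frames,
                        gates=gates)
    if config.n_cows == 0 or n_frames == 0:
        return truth

    # arrival schedule: Poisson-like, all within the first part of the
    # recording, spaced by at least min_entry_gap_s (a gate admits one
    # animal at a time)
    gaps = rng.exponential(0.25 * n_frames / config.n_cows, size=config.n_cows)
    arrivals = np.minimum(np.cumsum(gaps), 0.5 * n_frames).astype(np.int64)
    min_gap = max(1, int(round(config.min_entry_gap_s * config.fps)))
    for i in range(1, len(arrivals)):
        arrivals[i] = max(arrivals[i], arrivals[i - 1] + min_gap)
    bin_w = space.bin_width
    max_turn = min(0.9 * bin_w, 0.45)
    cows: list[_Cow] = []
    pending = []
    for i in range(config.n_cows):
        gate = entry_gates[int(rng.integers(len(entry_gates)))]
        exit_gate = exit_gates[int(rng.integers(len(exit_gates)))]
        heading = (space.bin_angle(gate.orient_bin) if gate.orient_bin is not None
                   else float(rng.uniform(0, 2 * np.pi)))
        cow = _Cow(animal_id=config.first_cow_id + i,
                   entry_frame=int(arrivals[i]),
                   pos=np.array([gate.x, gate.y], dtype=float),
                   heading=heading, exit_gate=exit_gate)
        dwell = int(rng.uniform(0.10, 0.35) * n_frames)
        cow.seek_frame = cow.entry_frame + dwell
        cow._entry_gate = gate
        pending.append(cow)

    active: list[_Cow] = []
    for frame in range(n_frames):
        while pending and pending[0].entry_frame <= frame:
            cow = pending.pop(0)
            active.append(cow)
            truth.events.append(GateEvent(
                time_s=frame / config.fps, frame_index=frame,
                gate_id=cow._entry_gate.gate_id, animal_id=cow.animal_id,
                kind="entry"))
        finished = []
        for cow in active:
            if cow.states:  # move every frame after the entry frame
                seeking = frame >= cow.seek_frame
                if seeking:
                    target = np.array([cow.exit_gate.x, cow.exit_gate.y],
                                      dtype=float)
                    to_target = target - cow.pos
                    desired = float(np.arctan2(to_target[1], to_target[0]))
                    turn = 0.5 * _wrap_angle(desired - cow.heading)
                    turn += rng.normal(0.0, 0.25 * config.turn_sigma)
                else:
                    turn = rng.normal(0.0, config.turn_sigma)
                cow.heading = _wrap_angle(cow.heading
                                          + float(np.clip(turn, -max_turn, max_turn)))
                cow.speed += (0.15 * (config.mean_speed_cells - cow.speed)
                              + rng.normal(0.0, 0.06))
                cow.speed = float(np.clip(cow.speed, 0.05, config.max_speed_cells))
                step = cow.speed * np.array([np.cos(cow.heading),
                                             np.sin(cow.heading)])
                # collision avoidance at body scale: cows are ~0.6 m wide
                # and cannot overlap
                rep_r = config.repulsion_radius_m / config.cell_size
                for other in active:
                    if other is cow:
                        continue
                    diff = cow.pos - other.pos
                    dist = float(np.hypot(*diff))
                    if dist < rep_r:
                        away = diff / dist if dist > 1e-9 else np.array([1.0, 0.0])
                        step = step + 0.45 * (1.0 - dist / rep_r) * away
                new_pos = cow.pos + np.clip(step, -config.max_speed_cells,
                                            config.max_speed_cells)
                # walls: clamp position; turn away gradually (the per-frame
                # heading change stays below one orientation bin)
                hit = False
                for ax, hi in ((0, space.n_x - 1), (1, space.n_y - 1)):
                    if new_pos[ax] < 0.0 or new_pos[ax] > hi:
                        hit = True
                        desired = (np.pi - cow.heading if ax == 0
                                   else -cow.heading)
                        adj = np.clip(_wrap_angle(desired - cow.heading),
                                      -max_turn, max_turn)
                        cow.heading = _wrap_angle(cow.heading + float(adj))
                if hit:
                    new_pos = np.clip(new_pos, 0.0,
                                      [space.n_x - 1, space.n_y - 1])
                delta = np.clip(new_pos - cow.pos, -config.max_speed_cells,
                                config.max_speed_cells)
                # hard non-overlap: never approach another animal closer
                # than body scale; slide tangentially or stand instead
                for other in active:
                    if other is cow:
                        continue
                    diff = (cow.pos + delta) - other.pos
                    dist_new = float(np.hypot(*diff))
                    dist_old = float(np.hypot(*(cow.pos - other.pos)))
                    if dist_new < rep_r and dist_new < dist_old:
                        radial = ((cow.pos - other.pos) / dist_old
                                  if dist_old > 1e-9 else np.array([1.0, 0.0]))
                        delta = delta - np.dot(delta, radial) * radial
                        delta = np.clip(delta, -config.max_speed_cells,
                                        config.max_speed_cells)
                cow.pos = np.clip(cow.pos + delta, 0.0,
                                  [space.n_x - 1, space.n_y - 1])
            cx = int(np.clip(round(cow.pos[0]), 0, space.n_x - 1))
            cy = int(np.clip(round(cow.pos[1]), 0, space.n_y - 1))
            k = space.orient_bin(cow.heading)
            cow.states.append(space.flat_index(cx, cy, k))
            if (frame >= cow.seek_frame and cx == cow.exit_gate.x
                    and cy == cow.exit_gate.y):
                cow.exit_frame = frame
                truth.events.append(GateEvent(
                    time_s=frame / config.fps, frame_index=frame,
                    gate_id=cow.exit_gate.gate_id, animal_id=cow.animal_id,
                    kind="exit"))
                finished.append(cow)
        for cow in finished:
            active.remove(cow)
            truth.cows[cow.animal_id] = (cow.entry_frame,
                                         np.array(cow.states, dtype=np.int64),
                                         cow.exit_frame)
    for cow in active + pending:
        if cow.states:
            truth.cows[cow.animal_id] = (cow.entry_frame,
                                         np.array(cow.states, dtype=np.int64),
                                         None)
    truth.events.sort(key=lambda e: (e.frame_index, str(e.gate_id), e.kind))
    return truth


def _bump_window(values: np.ndarray, y: int, x: int, k: int, peak: float,
                 sigma: float, orient_bins: int, space: StateSpace) -> None:
    """max-composite one Gaussian bump into ``values`` (in place)."""
    if sigma <= 0 and orient_bins <= 0:
        values[y, x, k] = max(values[y, x, k], peak)
        return
    r = int(np.ceil(3 * sigma)) if sigma > 0 else 0
    ro = min(orient_bins, space.n_orient // 2) if orient_bins > 0 else 0
    ys = slice(max(0, y - r), min(space.n_y, y + r + 1))
    xs = slice(max(0, x - r), min(space.n_x, x + r + 1))
    dy = np.arange(ys.start, ys.stop) - y
    dx = np.arange(xs.start, xs.stop) - x
    if sigma > 0:
        spatial = np.exp(-(dy[:, None] ** 2 + dx[None, :] ** 2)
                         / (2.0 * sigma ** 2))
    else:
        spatial = np.ones((len(dy), len(dx)))
    dk = np.arange(-ro, ro + 1)
    if orient_bins > 0:
        ang = np.exp(-(dk ** 2) / (2.0 * float(orient_bins) ** 2))
    else:
        ang = np.ones(1)
    bump = peak * spatial
    for j, dkv in enumerate(dk):
        kk = int((k + dkv) % space.n_orient)
        np.maximum(values[ys, xs, kk], bump * ang[j], out=values[ys, xs, kk])


def render_detection_maps(truth: GroundTruth, space: StateSpace | None = None,
                          noise: NoiseSpec | None = None,
                          seed: int | None = None) -> np.ndarray:
    """Render the per-frame detection-likelihood maps from the ground truth.

    Returns a ``(n_frames, n_y, n_x, n_orient)`` float32 array in
    ``[floor, 1]``.  ``seed`` defaults to ``config.seed + 1`` so that scene
    and rendering noise are independent but jointly reproducible.
    """
    space = space or truth.space
    noise = noise or truth.config.noise
    if seed is None:
        seed = truth.config.seed + 1
    rng = np.random.default_rng(seed)
    n_frames = truth.n_frames
    maps = np.full((n_frames,) + space.shape, noise.floor, dtype=np.float32)
    per_frame: dict[int, list] = {}
    for cow, (entry, states, _) in sorted(truth.cows.items()):
        for j, s in enumerate(states):
            per_frame.setdefault(entry + j, []).append(int(s))
    for t in range(n_frames):
        frame = maps[t]
        for s in per_frame.get(t, ()):
            if noise.detect_prob >= 1.0 or rng.random() < noise.detect_prob:
                x, y, k = space.from_flat(s)
                _bump_window(frame, y, x, k, noise.peak_value,
                             noise.peak_sigma_cells, noise.orient_noise_bins,
                             space)
        n_clutter = rng.poisson(noise.clutter_rate) if noise.clutter_rate > 0 else 0
        for _ in range(n_clutter):
            s = int(rng.integers(space.n_states))
            x, y, k = space.from_flat(s)
            _bump_window(frame, y, x, k, noise.clutter_weight,
                         noise.peak_sigma_cells, noise.orient_noise_bins,
                         space)
    np.clip(maps, noise.floor, 1.0, out=maps)
    return maps
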