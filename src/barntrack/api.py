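"""High-level modelling surface: ProbabilityMapTracker -> TrackingResults.

The tracker is exposed in the style of a statistical model object: construct
it from the observed data (a detection-likelihood map sequence plus the gate
scenario), call :meth:`ProbabilityMapTracker.fit` to run the recursive
estimation over all frames, and inspect the returned
:class:`TrackingResults` (tracks, diagnostics, ``summary()``, plotting,
evaluation against held-out registrations).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import RunDiagnostics, run_sequence
from .evaluate import EvalReport, match_tracks_to_registrations, summarize_performance
from .gates import Scenario, backtrace_identity
from .motion import MotionModel, build_motion_model
from .simulate import GroundTruth, SceneConfig, render_detection_maps, simulate_scene
from .state_space import DEFAULT_DETECTION_FLOOR, StateSpace

__all__ = ["ProbabilityMapTracker", "TrackingResults", "track_scene"]


class ProbabilityMapTracker:
    """Multi-object tracker over a detection-likelihood map sequence.

    Parameters
    ----------
    maps : ndarray, shape (n_frames, n_y, n_x, n_orient)
        Per-state detection likelihoods in [0, 1].
    space : StateSpace
        The shared discrete state space.
    scenario : Scenario
        Gate layout, registration events and initial occupancy.
    motion_model : MotionModel, optional
        Defaults to the truncated-Gaussian model with standard parameters.
    exit_mode : {"gate", "criterion"}
        ``"gate"`` removes objects on gate exit registrations; in
        ``"criterion"`` mode the registrations are withheld from the tracker
        (exits fire on the 0.5 s dwell criterion) and remain available for
        scoring.
    """

    def __init__(self, maps, space: StateSpace, scenario: Scenario,
                 motion_model: MotionModel | None = None,
                 exit_mode: str = "gate",
                 detection_floor: float = DEFAULT_DETECTION_FLOOR):
        self.maps = np.asarray(maps)
        self.space = space
        self.scenario = scenario
        self.motion_model = motion_model or build_motion_model(space)
        self.exit_mode = exit_mode
        self.detection_floor = detection_floor

    @classmethod
    def from_files(cls, maps_path, scenario_path, gates_path=None,
                   exit_mode: str = "gate"):
        """Build a tracker from a maps container, scenario YAML and gate CSV."""
        from .io import load_gate_log, load_maps, load_scenario_config
        maps, space = load_maps(maps_path)
        scenario, model = load_scenario_config(scenario_path, space)
        if gates_path is not None:
            events = load_gate_log(gates_path, scenario.fps)
            scenario = Scenario(fps=scenario.fps, gates=scenario.gates,
                                events=events,
                                initial_objects=scenario.initial_objects)
        return cls(maps, space, scenario, motion_model=model,
                   exit_mode=exit_mode)

    @classmethod
    def from_truth(cls, truth: GroundTruth, exit_mode: str = "gate",
                   seed: int | None = None, **kwargs):
        """Render detection maps from simulated ground truth and wrap them."""
        maps = render_detection_maps(truth, seed=seed)
        return cls(maps, truth.space, truth.scenario(), exit_mode=exit_mode,
                   **kwargs)

    def fit(self, assign_identities: bool = True,
            check_conservation: bool = False) -> "TrackingResults":
        """Run the recursion over all frames and return the results object."""
        tracks, diag = run_sequence(self.maps, self.space, self.motion_model,
                                    self.scenario, exit_mode=self.exit_mode,
                                    detection_floor=self.detection_floor,
                                    check_conservation=check_conservation)
        if assign_identities:
            backtrace_identity(tracks, self.scenario.events)
        return TrackingResults(model=self, tracks=tracks, diagnostics=diag)


class TrackingResults:
    """Estimated tracks plus run diagnostics."""

    def __init__(self, model: ProbabilityMapTracker, tracks,
                 diagnostics: RunDiagnostics):
        self.model = model
        self.tracks = tracks
        self.diagnostics = diagnostics

    @property
    def n_tracks(self) -> int:
        return len(self.tracks)

    def track_for(self, animal_id):
        for tr in self.tracks:
            if tr.animal_id == animal_id:
                return tr
        return None

    def to_dataframe(self) -> pd.DataFrame:
        from .io import tracks_to_dataframe
        return tracks_to_dataframe(self.tracks, self.model.space)

    def evaluate(self, events=None, truth: GroundTruth | None = None,
                 tolerance_s: float = 60.0) -> EvalReport:
        """Score the tracks against exit registrations (default: the
        scenario's own event log)."""
        events = events if events is not None else self.model.scenario.events
        records = match_tracks_to_registrations(
            self.tracks, events, self.model.scenario.fps, truth=truth,
            tolerance_s=tolerance_s)
        return summarize_performance(records, tolerance_s)

    def summary(self) -> str:
        d = self.diagnostics
        by_status: dict[str, int] = {}
        for tr in self.tracks:
            by_status[tr.status] = by_status.get(tr.status, 0) + 1
        lines = [
            "ProbabilityMapTracker results",
            "-----------------------------",
            f"frames processed        {d.n_frames:8d}",
            f"objects instantiated    {self.n_tracks:8d}",
        ]
        for status in ("active", "exited", "lost"):
            if status in by_status:
                lines.append(f"  {status:<21s} {by_status[status]:8d}")
        if d.n_spurious_exit_events:
            lines.append(f"spurious exit events    {d.n_spurious_exit_events:8d}")
        if d.max_conservation_error:
            lines.append(
                f"max |sum p - 1| per object  {d.max_conservation_error:.2e}")
        return "\n".join(lines)

    def plot_tracks(self, ax=None):
        """Debug plot: estimated (x, y) paths on the waiting-area grid."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 8))
        space = self.model.space
        for tr in self.tracks:
            if not tr.points:
                continue
            x, y, _ = space.from_flat(tr.states())
            label = tr.animal_id if tr.animal_id is not None else f"obj{tr.object_id}"
            ax.plot(x, y, lw=1, label=str(label))
        ax.set_xlim(-0.5, space.n_x - 0.5)
        ax.set_ylim(space.n_y - 0.5, -0.5)
        ax.set_xlabel("x [cells]")
        ax.set_ylabel("y [cells]")
        ax.set_aspect("equal")
        ax.legend(fontsize=6, loc="upper right")
        return ax


def track_scene(config: SceneConfig, exit_mode: str = "criterion",
                map_seed: int | None = None):
    """Simulate, render, track and score one synthetic scene.

    Returns ``(results, truth, report)``: the convenience pipeline used by
    the command line, the examples and the robustness studies.
    """
    truth = simulate_scene(config)
    tracker = ProbabilityMapTracker.from_truth(truth, exit_mode=exit_mode,
                                               seed=map_seed)
    results = tracker.fit()
    report = results.evaluate(events=truth.events, truth=truth)
    return results, truth, report
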