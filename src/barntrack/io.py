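"""File formats: detection-map containers, gate logs, scenario configs, tracks.

Detection-map sequences are stored as one dense HDF5 dataset of shape
``(frames, n_y, n_x, n_orient)`` (float32) with a JSON sidecar
(``<name>.json``) recording the state-space fields; gate logs and tracks are
plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import DataError
from .gates import Gate, GateEvent, Scenario
from .motion import MotionModel, build_motion_model
from .state_space import StateSpace
from .tracker import Track

__all__ = [
    "save_maps", "load_maps",
    "save_gate_log", "load_gate_log",
    "save_scenario_config", "load_scenario_config",
    "tracks_to_dataframe", "save_tracks",
    "save_camera_calibration", "load_camera_calibration",
    "load_marker_correspondences",
]


def _sidecar(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".json")


def save_maps(path, maps: np.ndarray, space: StateSpace) -> None:
    maps = np.asarray(maps, dtype=np.float32)
    if maps.ndim != 4 or maps.shape[1:] != space.shape:
        raise DataError("maps must have shape (frames, n_y, n_x, n_orient)")
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=maps, compression="gzip", shuffle=True)
    _sidecar(path).write_text(json.dumps({
        "n_x": space.n_x, "n_y": space.n_y, "cell_size": space.cell_size,
        "n_orient": space.n_orient, "origin": list(space.origin),
    }, indent=2))


def load_maps(path):
    side = _sidecar(path)
    if not side.exists():
        raise DataError(f"missing state-space sidecar {side}")
    meta = json.loads(side.read_text())
    space = StateSpace(n_x=int(meta["n_x"]), n_y=int(meta["n_y"]),
                       cell_size=float(meta["cell_size"]),
                       n_orient=int(meta["n_orient"]),
                       origin=tuple(meta.get("origin", (0.0, 0.0))))
    with h5py.File(path, "r") as f:
        maps = f["maps"][()]
    if maps.shape[1:] != space.shape:
        raise DataError("maps do not match their sidecar state space")
    return maps, space


def save_gate_log(path, events) -> None:
    pd.DataFrame([{
        "time_s": e.time_s, "gate_id": e.gate_id,
        "animal_id": e.animal_id, "kind": e.kind,
    } for e in events]).to_csv(path, index=False)


def load_gate_log(path, fps: float):
    df = pd.read_csv(path)
    required = {"time_s", "gate_id", "animal_id", "kind"}
    if not required.issubset(df.columns):
        raise DataError(f"gate log must have columns {sorted(required)}")
    events = [GateEvent.at_time(float(r.time_s), fps, str(r.gate_id),
                                r.animal_id, str(r.kind))
              for r in df.itertuples()]
    return sorted(events, key=lambda e: (e.frame_index, str(e.gate_id), e.kind))


def _gate_to_dict(g: Gate) -> dict:
    return {"gate_id": g.gate_id, "x": g.x, "y": g.y,
            "orient_bin": "any" if g.orient_bin is None else int(g.orient_bin),
            "role": g.role, "synthetic_prob": g.synthetic_prob}


def _gate_from_dict(d: dict) -> Gate:
    ob = d.get("orient_bin", "any")
    return Gate(gate_id=str(d["gate_id"]), x=int(d["x"]), y=int(d["y"]),
                orient_bin=None if ob in ("any", None) else int(ob),
                role=str(d.get("role", "both")),
                synthetic_prob=float(d.get("synthetic_prob", 0.05)))


def save_scenario_config(path, scenario: Scenario, model: MotionModel) -> None:
    cfg = {
        "fps": scenario.fps,
        "gates": [_gate_to_dict(g) for g in scenario.gates],
        "motion": {
            "sigma_pos": model.sigma_pos, "sigma_orient": model.sigma_orient,
            "pos_radius": model.pos_radius, "orient_radius": model.orient_radius,
        },
        "initial_objects": [[int(s), i] for s, i in scenario.initial_objects],
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_scenario_config(path, space: StateSpace, events=None):
    """Read a scenario YAML; returns ``(Scenario, MotionModel)``."""
    cfg = yaml.safe_load(Path(path).read_text())
    gates = [_gate_from_dict(d) for d in cfg.get("gates", [])]
    mot = cfg.get("motion", {})
    model = build_motion_model(
        space,
        sigma_pos=float(mot.get("sigma_pos", 1.0)),
        sigma_orient=float(mot.get("sigma_orient", 1.0)),
        pos_radius=int(mot.get("pos_radius", 2)),
        orient_radius=int(mot.get("orient_radius", 2)))
    initial = [(int(s), i) for s, i in cfg.get("initial_objects", [])]
    scenario = Scenario(fps=float(cfg["fps"]), gates=gates,
                        events=list(events or []), initial_objects=initial)
    return scenario, model


def save_camera_calibration(path, cam, homography) -> None:
    """One YAML per camera: intrinsics, distortion and plane homography."""
    from .geometry import CameraModel, PlaneHomography  # noqa: F401 (types)
    cfg = {
        "focal": list(cam.focal),
        "principal_point": list(cam.principal_point),
        "distortion": list(cam.distortion),
        "image_size": list(cam.image_size),
        "homography": [[float(v) for v in row] for row in homography.matrix],
        "plane_height_m": homography.plane_height_m,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def load_camera_calibration(path):
    """Returns ``(CameraModel, PlaneHomography)`` from a calibration YAML."""
    from .geometry import CameraModel, PlaneHomography
    cfg = yaml.safe_load(Path(path).read_text())
    cam = CameraModel(focal=tuple(cfg["focal"]),
                      principal_point=tuple(cfg["principal_point"]),
                      distortion=tuple(cfg.get("distortion", (0.0, 0.0))),
                      image_size=tuple(cfg.get("image_size", (800, 600))))
    homog = PlaneHomography(np.array(cfg["homography"], dtype=np.float64),
                            plane_height_m=float(cfg.get("plane_height_m",
                                                         1.49)))
    return cam, homog


def load_marker_correspondences(path):
    """Marker CSV with columns u, v (pixels) and X, Y (meters on the plane);
    returns ``(pixel_pts, plane_pts)`` arrays for homography estimation."""
    df = pd.read_csv(path)
    required = {"u", "v", "X", "Y"}
    if not required.issubset(df.columns):
        raise DataError(f"marker file must have columns {sorted(required)}")
    return df[["u", "v"]].to_numpy(float), df[["X", "Y"]].to_numpy(float)


def tracks_to_dataframe(tracks, space: StateSpace) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for pt in tr.points:
            x, y, k = space.from_flat(pt.state)
            rows.append({
                "frame": pt.frame_index, "object_id": tr.object_id,
                "animal_id": tr.animal_id if tr.animal_id is not None else "",
                "x": x, "y": y, "orient_bin": k,
                "map_prob": pt.map_prob, "status": tr.status,
            })
    return pd.DataFrame(rows, columns=["frame", "object_id", "animal_id",
                                       "x", "y", "orient_bin", "map_prob",
                                       "status"])


def save_tracks(path, tracks, space: StateSpace) -> None:
    tracks_to_dataframe(tracks, space).to_csv(path, index=False)
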