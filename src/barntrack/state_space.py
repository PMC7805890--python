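"""Discrete state space for grid-based tracking.

A *state* is a tuple ``(x, y, k)``: a grid cell on the (dewarped, metrically
uniform) shoulder plane plus an orientation bin.  The tracker, the motion model
and the detection-likelihood maps all share one :class:`StateSpace`, which
fixes the indexing convention once:

* ``x`` increases rightward, ``y`` downward; indices are 0-based.
* Orientation bin ``k`` is centred on angle ``2*pi*k/n_orient`` (bin 0 on the
  +x axis, bins counter-clockwise) and covers the half-open interval
  ``[centre - pi/n_orient, centre + pi/n_orient)``, wrapping mod ``2*pi``.
* The flat index of ``(x, y, k)`` is ``(y * n_x + x) * n_orient + k``.

Detection maps carry one likelihood value in ``[0, 1]`` per state per frame.
Values are clamped to a small positive floor before tracking: the recursion is
multiplicative, so an exact zero would lock a state out forever.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = [
    "StateSpace",
    "DetectionMap",
    "build_state_space",
    "validate_detection_map",
    "DEFAULT_DETECTION_FLOOR",
]

#: Default likelihood floor applied to detection maps.
DEFAULT_DETECTION_FLOOR = 1e-6


@dataclass(frozen=True)
class StateSpace:
    """Discrete set of states (grid cells x orientation bins).

    Parameters
    ----------
    n_x, n_y : int
        Number of grid columns / rows.
    cell_size : float
        Side length of one grid cell in meters.
    n_orient : int
        Number of equally spaced orientation bins over the full circle.
    origin : (float, float)
        World coordinates (meters) of the centre of cell ``(0, 0)``.
    """

    n_x: int
    n_y: int
    cell_size: float
    n_orient: int
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1 or self.n_orient < 1:
            raise ValueError("n_x, n_y and n_orient must all be >= 1")
        if not (self.cell_size > 0):
            raise ValueError("cell_size must be > 0")

    @property
    def n_states(self) -> int:
        return self.n_x * self.n_y * self.n_orient

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape used for per-state grids: ``(n_y, n_x, n_orient)``."""
        return (self.n_y, self.n_x, self.n_orient)

    @property
    def bin_width(self) -> float:
        return 2.0 * math.pi / self.n_orient

    # -- index conversions -------------------------------------------------
    def flat_index(self, x, y, k):
        """Flat index of state ``(x, y, k)``; accepts scalars or arrays."""
        x = np.asarray(x)
        y = np.asarray(y)
        k = np.asarray(k)
        if np.any((x < 0) | (x >= self.n_x) | (y < 0) | (y >= self.n_y)
                  | (k < 0) | (k >= self.n_orient)):
            raise IndexError("state coordinates out of range")
        out = (y * self.n_x + x) * self.n_orient + k
        return int(out) if out.ndim == 0 else out

    def from_flat(self, idx):
        """Inverse of :meth:`flat_index`: returns ``(x, y, k)``."""
        idx = np.asarray(idx)
        if np.any((idx < 0) | (idx >= self.n_states)):
            raise IndexError("flat state index out of range")
        k = idx % self.n_orient
        cell = idx // self.n_orient
        x = cell % self.n_x
        y = cell // self.n_x
        if idx.ndim == 0:
            return int(x), int(y), int(k)
        return x, y, k

    # -- orientation -------------------------------------------------------
    def orient_bin(self, angle):
        """Bin containing ``angle`` (radians); total and wrapping mod 2*pi."""
        angle = np.asarray(angle, dtype=float)
        binned = np.floor(angle / self.bin_width + 0.5).astype(np.int64) % self.n_orient
        return int(binned) if binned.ndim == 0 else binned

    def bin_angle(self, k) -> float:
        """Centre angle of orientation bin ``k``."""
        return (np.asarray(k) % self.n_orient) * self.bin_width

    # -- world coordinates -------------------------------------------------
    def cell_center(self, x, y):
        """World coordinates (meters) of the centre of cell ``(x, y)``."""
        x0, y0 = self.origin
        return (x0 + np.asarray(x) * self.cell_size,
                y0 + np.asarray(y) * self.cell_size)

    def world_to_cell(self, X, Y):
        """Grid cell containing world point ``(X, Y)`` (nearest cell centre)."""
        x0, y0 = self.origin
        x = np.rint((np.asarray(X) - x0) / self.cell_size).astype(np.int64)
        y = np.rint((np.asarray(Y) - y0) / self.cell_size).astype(np.int64)
        return x, y


@dataclass
class DetectionMap:
    """Per-frame detection likelihoods, one value in [0, 1] per state."""

    frame_index: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise DataError("detection map must be a (n_y, n_x, n_orient) array")


def build_state_space(width_m: float, height_m: float, cell_size: float,
                      n_orient: int) -> StateSpace:
    """Discretize a ``width_m`` x ``height_m`` area into a state grid.

    Cell counts are rounded up so that the grid covers the whole area; the
    6 x 18 m waiting area at the default 0.1 m resolution with 32 orientation
    bins yields 60 x 180 x 32 = 345,600 states.
    """
    if not (width_m > 0 and height_m > 0 and cell_size > 0):
        raise ValueError("area dimensions and cell_size must be positive")
    if n_orient < 1:
        raise ValueError("n_orient must be >= 1")
    n_x = math.ceil(width_m / cell_size)
    n_y = math.ceil(height_m / cell_size)
    return StateSpace(n_x=n_x, n_y=n_y, cell_size=cell_size, n_orient=n_orient)


def validate_detection_map(dmap: DetectionMap, space: StateSpace,
                           floor: float = DEFAULT_DETECTION_FLOOR) -> DetectionMap:
    """Check a detection map against its state space and clamp to [floor, 1].

    Raises :class:`~barntrack.errors.DataError` when the shape does not match
    the space or when any value lies outside [0, 1] beyond a 1e-9 tolerance.
    """
    if not (0.0 < floor < 1.0):
        raise ValueError("floor must lie in (0, 1)")
    vals = np.asarray(dmap.values, dtype=np.float64)
    if vals.shape != space.shape:
        raise DataError(
            f"detection map shape {vals.shape} does not match state space {space.shape}")
    if vals.min() < -1e-9 or vals.max() > 1.0 + 1e-9:
        raise DataError("detection values outside [0, 1]")
    return DetectionMap(frame_index=dmap.frame_index,
                        values=np.clip(vals, floor, 1.0))
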