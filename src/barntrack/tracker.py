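"""Recursive multi-object tracking on detection-likelihood maps.

The tracker maintains, for every state ``s`` of the grid, the identity
``o_{s,t}`` of the object currently most likely to occupy it (or a
BACKGROUND sentinel) and the probability ``p_{s,t}`` that this object is in
state ``s``.  One frame of tracking is:

1. For each state, find the most likely predecessor under the motion model,
   ``e_s = argmax_ŝ  p_{ŝ,t-1} * p(s | ŝ)``.
2. Propagate ownership, ``o_{s,t} = o_{e_s,t-1}``, and form the raw
   probability ``p̃_{s,t} = d_{s,t} * p_{e_s,t-1} * p(s | e_s)`` from the
   detection likelihood ``d_{s,t}``.  A state whose best predecessor score
   is zero belongs to the background.
3. Renormalize per object: each live object's owned probabilities are scaled
   to sum to one.  An object whose total mass vanishes owns no states; it is
   flagged *lost* and never resurrected.
4. Estimate each object's state as the argmax of its owned probabilities.

Ownership is single-valued per state, which structurally enforces that two
objects can never share a state.  Ties in both argmaxes are broken toward
the smallest flat state index so that runs are bit-for-bit reproducible.

Arithmetic stays in the linear domain: the per-frame, per-object
normalization bounds the dynamic range, and the detection floor keeps every
state reachable.

Two interchangeable propagation paths exist: a generic dense scan that
accepts arbitrary kernels, and a numba-compiled separable three-pass
max-product used for Gaussian-built models on large grids.  Both implement
the identical argmax and tie-break semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numba
import numpy as np

from .errors import SequencingError
from .motion import MotionModel
from .state_space import DetectionMap, StateSpace

__all__ = [
    "BACKGROUND",
    "OwnershipField",
    "RawField",
    "TrackPoint",
    "Track",
    "most_likely_predecessor",
    "propagate_frame",
    "normalize_per_object",
    "estimate_object_states",
]

#: Owner value for states not assigned to any live object.
BACKGROUND = -1


@dataclass
class OwnershipField:
    """Per-state owner and probability at one frame."""

    frame_index: int
    owner: np.ndarray = dc_field(repr=False)   # int32, (n_y, n_x, n_orient)
    prob: np.ndarray = dc_field(repr=False)    # float64, same shape

    @classmethod
    def empty(cls, space: StateSpace, frame_index: int = 0) -> "OwnershipField":
        return cls(frame_index=frame_index,
                   owner=np.full(space.shape, BACKGROUND, dtype=np.int32),
                   prob=np.zeros(space.shape, dtype=np.float64))

    def copy(self) -> "OwnershipField":
        return OwnershipField(self.frame_index, self.owner.copy(), self.prob.copy())


@dataclass
class RawField:
    """Propagated but not yet normalized field (owners and p̃)."""

    frame_index: int
    owner: np.ndarray = dc_field(repr=False)
    ptilde: np.ndarray = dc_field(repr=False)
    pred_flat: np.ndarray = dc_field(repr=False)  # chosen predecessor per state, -1 = none


@dataclass(frozen=True)
class TrackPoint:
    """Estimated state of one object at one frame."""

    frame_index: int
    state: int
    object_id: int
    map_prob: float


@dataclass
class Track:
    """Lifecycle and trajectory of one tracked object."""

    object_id: int
    animal_id: object = None
    points: list = dc_field(default_factory=list)
    entry_frame: int | None = None
    exit_frame: int | None = None
    entry_gate: str | None = None
    exit_gate: str | None = None
    status: str = "active"

    @property
    def last_frame(self) -> int | None:
        return self.points[-1].frame_index if self.points else None

    def states(self) -> np.ndarray:
        return np.array([p.state for p in self.points], dtype=np.int64)

    def frames(self) -> np.ndarray:
        return np.array([p.frame_index for p in self.points], dtype=np.int64)


# ---------------------------------------------------------------------------
# Reference single-state operation (kept literal and slow).
# ---------------------------------------------------------------------------

def most_likely_predecessor(field: OwnershipField, model: MotionModel,
                            s: int) -> tuple[int, float]:
    """Most likely previous state of ``s`` and its score.

    Scans only predecessors within the kernel support; ties are broken by
    the smallest flat predecessor index.  Returns ``(-1, 0.0)`` when every
    reachable predecessor carries zero probability.
    """
    space = model.space
    x, y, k = space.from_flat(s)
    pr, orr = model.pos_radius, model.orient_radius
    best_score = -1.0
    best_pred = -1
    for dy in range(-pr, pr + 1):
        yp = y - dy
        if yp < 0 or yp >= space.n_y:
            continue
        for dx in range(-pr, pr + 1):
            xp = x - dx
            if xp < 0 or xp >= space.n_x:
                continue
            for dk in model.orient_deltas():
                kp = (k - dk) % space.n_orient
                score = (field.prob[yp, xp, kp]
                         * model.kernel[dy + pr, dx + pr, dk + orr])
                pred = space.flat_index(xp, yp, kp)
                if score > best_score or (score == best_score and pred < best_pred):
                    best_score = score
                    best_pred = pred
    if best_score <= 0.0:
        return -1, 0.0
    return best_pred, float(best_score)


# ---------------------------------------------------------------------------
# Generic dense propagation (arbitrary kernels).
# ---------------------------------------------------------------------------

def _propagate_generic(prob: np.ndarray, model: MotionModel):
    """Dense scan over the displacement support; returns (best, pred_flat)."""
    space = model.space
    n_y, n_x, n_o = space.shape
    pr, orr = model.pos_radius, model.orient_radius
    best = np.full(space.shape, -1.0)
    pred = np.full(space.shape, np.iinfo(np.int64).max, dtype=np.int64)
    kk = np.arange(n_o)
    yy = np.arange(n_y)[:, None, None]
    xx = np.arange(n_x)[None, :, None]
    for dy in range(-pr, pr + 1):
        ys_t = slice(max(0, dy), n_y + min(0, dy))
        ys_s = slice(max(0, -dy), n_y + min(0, -dy))
        for dx in range(-pr, pr + 1):
            xs_t = slice(max(0, dx), n_x + min(0, dx))
            xs_s = slice(max(0, -dx), n_x + min(0, -dx))
            for dk in model.orient_deltas():
                kval = model.kernel[dy + pr, dx + pr, dk + orr]
                kp = (kk - dk) % n_o
                cand = prob[ys_s, xs_s, :][:, :, kp] * kval
                cand_pred = (((yy[ys_t] - dy) * n_x + (xx[:, xs_t] - dx)) * n_o
                             + kp[None, None, :])
                tgt_best = best[ys_t, xs_t, :]
                tgt_pred = pred[ys_t, xs_t, :]
                take = (cand > tgt_best) | ((cand == tgt_best) & (cand_pred < tgt_pred))
                best[ys_t, xs_t, :] = np.where(take, cand, tgt_best)
                pred[ys_t, xs_t, :] = np.where(take, cand_pred, tgt_pred)
    return best, pred


# ---------------------------------------------------------------------------
# Separable numba propagation (Gaussian-built kernels).
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _pass_orient(prob, kp_tab, g_tab, A, argk):  # pragma: no cover - compiled
    n_y, n_x, n_o = prob.shape
    m = kp_tab.shape[1]
    for y in range(n_y):
        for x in range(n_x):
            for k in range(n_o):
                best = -1.0
                bi = -1
                for j in range(m):
                    kp = kp_tab[k, j]
                    c = prob[y, x, kp] * g_tab[k, j]
                    if c > best:
                        best = c
                        bi = kp
                A[y, x, k] = best
                argk[y, x, k] = bi


@numba.njit(cache=True)
def _pass_x(A, argk, f, r, B, argxk):  # pragma: no cover - compiled
    n_y, n_x, n_o = A.shape
    for y in range(n_y):
        for x in range(n_x):
            for k in range(n_o):
                best = -1.0
                bx = -1
                for dx in range(r, -r - 1, -1):  # xp ascending -> first max wins
                    xp = x - dx
                    if 0 <= xp < n_x:
                        c = A[y, xp, k] * f[dx + r]
                        if c > best:
                            best = c
                            bx = xp
                B[y, x, k] = best
                argxk[y, x, k] = bx * n_o + argk[y, bx, k]


@numba.njit(cache=True)
def _pass_y(B, argxk, f, r, C, pred_flat):  # pragma: no cover - compiled
    n_y, n_x, n_o = B.shape
    for y in range(n_y):
        for x in range(n_x):
            for k in range(n_o):
                best = -1.0
                by = -1
                for dy in range(r, -r - 1, -1):  # yp ascending
                    yp = y - dy
                    if 0 <= yp < n_y:
                        c = B[yp, x, k] * f[dy + r]
                        if c > best:
                            best = c
                            by = yp
                C[y, x, k] = best
                pred_flat[y, x, k] = by * (n_x * n_o) + argxk[by, x, k]


@numba.njit(cache=True)
def _finish_propagate(C, pred_flat, d, owner_prev, inv_norm,
                      ptilde, owner_new):  # pragma: no cover - compiled
    n = C.size
    Cf = C.ravel()
    pf = pred_flat.ravel()
    df = d.ravel()
    opf = owner_prev.ravel()
    ptf = ptilde.ravel()
    onf = owner_new.ravel()
    for i in range(n):
        c = Cf[i]
        if c <= 0.0:
            ptf[i] = 0.0
            onf[i] = BACKGROUND
            pf[i] = -1
        else:
            p = pf[i]
            onf[i] = opf[p]
            ptf[i] = df[i] * c * inv_norm


class _SeparableTables:
    """Per-model lookup tables for the separable propagation path."""

    def __init__(self, model: MotionModel):
        n_o = model.space.n_orient
        orr = model.orient_radius
        g = model.g_orient
        pairs_by_k = []
        for k in range(n_o):
            pairs = sorted((int((k - dk) % n_o), float(g[dk + orr]))
                           for dk in model.orient_deltas())
            pairs_by_k.append(pairs)
        m = len(pairs_by_k[0])
        self.kp_tab = np.array([[p[0] for p in row] for row in pairs_by_k],
                               dtype=np.int64)
        self.g_tab = np.array([[p[1] for p in row] for row in pairs_by_k],
                              dtype=np.float64)
        assert self.kp_tab.shape == (n_o, m)


def _propagate_separable(prob: np.ndarray, model: MotionModel,
                         tables: _SeparableTables):
    shape = prob.shape
    A = np.empty(shape)
    argk = np.empty(shape, dtype=np.int64)
    B = np.empty(shape)
    argxk = np.empty(shape, dtype=np.int64)
    C = np.empty(shape)
    pred = np.empty(shape, dtype=np.int64)
    _pass_orient(prob, tables.kp_tab, tables.g_tab, A, argk)
    _pass_x(A, argk, model.f_pos, model.pos_radius, B, argxk)
    _pass_y(B, argxk, model.f_pos, model.pos_radius, C, pred)
    return C, pred


def propagate_frame(field: OwnershipField, model: MotionModel,
                    d: DetectionMap, _tables: _SeparableTables | None = None) -> RawField:
    """One propagation step: owners and raw probabilities for frame ``t``.

    ``d.frame_index`` must equal ``field.frame_index + 1``.  The returned
    probabilities are *not* normalized; feed them to
    :func:`normalize_per_object`.
    """
    if d.frame_index != field.frame_index + 1:
        raise SequencingError(
            f"detection map frame {d.frame_index} does not follow field frame "
            f"{field.frame_index}")
    if d.values.shape != model.space.shape:
        raise SequencingError("detection map shape does not match state space")
    prob = np.ascontiguousarray(field.prob, dtype=np.float64)
    if model.separable:
        if _tables is None:
            _tables = _SeparableTables(model)
        best, pred = _propagate_separable(prob, model, _tables)
        inv_norm = 1.0 / model.norm
    else:
        best, pred = _propagate_generic(prob, model)
        inv_norm = 1.0  # generic path multiplies by normalized kernel values
    ptilde = np.empty_like(best)
    owner_new = np.empty_like(field.owner)
    dvals = np.ascontiguousarray(d.values, dtype=np.float64)
    _finish_propagate(best, pred, dvals, np.ascontiguousarray(field.owner),
                      inv_norm, ptilde, owner_new)
    return RawField(frame_index=d.frame_index, owner=owner_new,
                    ptilde=ptilde, pred_flat=pred)


# ---------------------------------------------------------------------------
# Normalization and state estimation.
# ---------------------------------------------------------------------------

@numba.njit(cache=True)
def _normalize_inplace(ptilde, owner, n_objects):  # pragma: no cover - compiled
    mass = np.zeros(n_objects)
    pt = ptilde.ravel()
    ow = owner.ravel()
    for i in range(pt.size):
        o = ow[i]
        if o >= 0:
            mass[o] += pt[i]
    for i in range(pt.size):
        o = ow[i]
        if o >= 0 and mass[o] > 0.0:
            pt[i] = pt[i] / mass[o]
    return mass


@numba.njit(cache=True)
def _object_argmax(prob, owner, n_objects):  # pragma: no cover - compiled
    arg = np.full(n_objects, -1, dtype=np.int64)
    top = np.full(n_objects, -1.0)
    pr = prob.ravel()
    ow = owner.ravel()
    for i in range(pr.size):
        o = ow[i]
        if o >= 0 and pr[i] > top[o]:
            top[o] = pr[i]
            arg[o] = i
    return arg, top


@numba.njit(cache=True)
def _object_sums(prob, owner, n_objects):  # pragma: no cover - compiled
    s = np.zeros(n_objects)
    pr = prob.ravel()
    ow = owner.ravel()
    for i in range(pr.size):
        o = ow[i]
        if o >= 0:
            s[o] += pr[i]
    return s


def normalize_per_object(raw: RawField, live_ids) -> tuple[OwnershipField, list[int]]:
    """Scale each live object's owned probabilities to sum to one.

    Returns the normalized field and the list of live objects whose total
    propagated mass was zero (they own no states and are to be flagged lost).
    Normalization mutates ``raw.ptilde`` into the normalized probabilities.
    """
    live_ids = list(live_ids)
    n_objects = (max(live_ids) + 1) if live_ids else 0
    if n_objects:
        mass = _normalize_inplace(raw.ptilde, raw.owner, n_objects)
        lost = [o for o in live_ids if mass[o] == 0.0]
    else:
        lost = []
    field = OwnershipField(frame_index=raw.frame_index, owner=raw.owner,
                           prob=raw.ptilde)
    return field, lost


def estimate_object_states(field: OwnershipField, live_ids) -> list[TrackPoint]:
    """Per-object MAP state: argmax of owned probabilities (ties -> smallest
    flat index).  Objects that own no states yield no point."""
    live_ids = sorted(live_ids)
    if not live_ids:
        return []
    n_objects = max(live_ids) + 1
    arg, top = _object_argmax(field.prob, field.owner, n_objects)
    points = []
    for o in live_ids:
        if arg[o] >= 0:
            points.append(TrackPoint(frame_index=field.frame_index,
                                     state=int(arg[o]), object_id=o,
                                     map_prob=float(top[o])))
    return points
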