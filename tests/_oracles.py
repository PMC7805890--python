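"""Independent brute-force oracles for the tracking recursion.

The oracle enumerates *every* state pair through ``transition_prob`` (no
neighbourhood shortcuts, no separable passes) and evaluates the recursion
literally: most-likely-predecessor argmax, ownership propagation, raw
probability product, per-object normalization and per-object MAP estimate.
It shares no propagation code with the implementation under test.
"""

from __future__ import annotations

import numpy as np

from barntrack.motion import MotionModel, transition_prob
from barntrack.state_space import StateSpace
from barntrack.tracker import BACKGROUND


def dense_transition_matrix(model: MotionModel) -> np.ndarray:
    """T[s_prev, s_next] built by explicit loops over all state pairs."""
    n = model.space.n_states
    T = np.zeros((n, n))
    for s_prev in range(n):
        for s_next in range(n):
            T[s_prev, s_next] = transition_prob(model, s_prev, s_next)
    return T


def brute_force_step(prob: np.ndarray, owner: np.ndarray, d: np.ndarray,
                     model: MotionModel, T: np.ndarray | None = None):
    """One full tracking step evaluated from the dense transition matrix.

    Returns ``(owner_next, prob_next, pred, estimates)`` where ``pred`` is
    the chosen predecessor per state (-1 for background) and ``estimates``
    maps live object ids to their MAP flat state.
    """
    if T is None:
        T = dense_transition_matrix(model)
    pf = prob.reshape(-1)
    of = owner.reshape(-1)
    df = d.reshape(-1)
    scores = pf[:, None] * T          # scores[s_prev, s_next]
    best = scores.max(axis=0)
    pred = scores.argmax(axis=0)      # first max == smallest flat predecessor
    background = best <= 0.0
    pred = np.where(background, -1, pred)
    owner_next = np.where(background, BACKGROUND, of[pred])
    ptilde = np.where(background, 0.0, df * best)
    prob_next = np.zeros_like(ptilde)
    estimates = {}
    for o in np.unique(owner_next):
        if o == BACKGROUND:
            continue
        mask = owner_next == o
        mass = ptilde[mask].sum()
        if mass > 0:
            prob_next[mask] = ptilde[mask] / mass
            idx = np.flatnonzero(mask)
            estimates[int(o)] = int(idx[np.argmax(prob_next[idx])])
    shape = prob.shape
    return (owner_next.reshape(shape).astype(np.int32),
            prob_next.reshape(shape), pred.reshape(shape), estimates)


def brute_force_step_pure_python(prob, owner, d, model: MotionModel):
    """Triple-loop re-derivation used to validate the matrix oracle itself."""
    space = model.space
    n = space.n_states
    pf = list(prob.reshape(-1))
    of = list(owner.reshape(-1))
    df = list(d.reshape(-1))
    owner_next = [BACKGROUND] * n
    ptilde = [0.0] * n
    for s in range(n):
        best, best_pred = -1.0, -1
        for s_prev in range(n):
            score = pf[s_prev] * transition_prob(model, s_prev, s)
            if score > best:
                best, best_pred = score, s_prev
        if best > 0.0:
            owner_next[s] = of[best_pred]
            ptilde[s] = df[s] * best
    prob_next = [0.0] * n
    for o in set(owner_next) - {BACKGROUND}:
        mass = sum(ptilde[s] for s in range(n) if owner_next[s] == o)
        if mass > 0:
            for s in range(n):
                if owner_next[s] == o:
                    prob_next[s] = ptilde[s] / mass
    shape = prob.shape
    return (np.array(owner_next, dtype=np.int32).reshape(shape),
            np.array(prob_next).reshape(shape))


def random_field(space: StateSpace, rng: np.random.Generator,
                 n_objects: int):
    """Random normalized ownership field with up to ``n_objects`` objects."""
    owner = np.full(space.shape, BACKGROUND, dtype=np.int32)
    prob = np.zeros(space.shape)
    if n_objects:
        assignment = rng.integers(-1, n_objects, size=space.shape)
        raw = rng.random(space.shape)
        for o in range(n_objects):
            mask = assignment == o
            mass = raw[mask].sum()
            if mass > 0:
                owner[mask] = o
                prob[mask] = raw[mask] / mass
    return owner, prob
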