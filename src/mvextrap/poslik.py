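"""Combining pairwise classifier performance into position likelihoods.

For a trial (or pool of trials) whose true position is ``s``, the pairwise
vote fractions ``r_ij`` are combined into a likelihood over all k positions:

    p_s(i) = ( sum_{j != i} 1 / r_ij  -  (k - 2) )^-1

with ``r_ji = 1 - r_ij``, then normalised to sum to one.  When every classifier
performs at chance (r = 0.5) the result is uniform, 1/k (~0.027027 for k=37).
The value at the true position, ``p_s(s)``, is the *stimulus-position
likelihood*; indexed by training and test time it forms a temporal
generalisation matrix (TGM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decode import PairwiseScore
from .hexgeom import GridSpec

__all__ = [
    "LikelihoodTensor",
    "combine_pairwise",
    "likelihood_from_scores",
    "stimulus_position_likelihood",
    "average_alignment",
    "accuracy_by_distance",
]

R_CLIP_EPS = 1e-6


def _combine_matrix(R: np.ndarray) -> np.ndarray:
    """Apply the pairwise-combination formula to full r matrices.

    R (..., k, k) with R[..., i, j] the performance of the (i, j) classifier
    (R[..., j, i] = 1 - R[..., i, j]; the diagonal is ignored).  Returns the
    normalised likelihood vector(s) (..., k).
    """
    k = R.shape[-1]
    if k < 2:
        raise ValueError("need at least 2 classes")
    R = np.clip(R, R_CLIP_EPS, 1.0 - R_CLIP_EPS)
    inv = 1.0 / R
    idx = np.arange(k)
    inv[..., idx, idx] = 0.0
    denom = inv.sum(axis=-1) - (k - 2)
    p = 1.0 / denom
    return p / p.sum(axis=-1, keepdims=True)


def combine_pairwise(r_values: np.ndarray, k: int, eps: float = R_CLIP_EPS) -> np.ndarray:
    """Likelihood over k positions from one set of pairwise performances.

    ``r_values`` has length C(k, 2), ordered by pairs (i, j), i < j,
    lexicographically, each the performance of the (i, j) classifier (the
    fraction of trials assigned label i).  Values are clipped to
    ``[eps, 1 - eps]`` to keep the formula finite for perfect classifiers.
    """
    r_values = np.asarray(r_values, dtype=float)
    if k < 2:
        raise ValueError("need at least 2 classes")
    if r_values.shape[-1] != k * (k - 1) // 2:
        raise ValueError("r_values length must be C(k, 2)")
    if np.any(r_values < 0) or np.any(r_values > 1):
        raise ValueError("pairwise performances must lie in [0, 1]")
    iu = np.triu_indices(k, 1)
    R = np.empty(r_values.shape[:-1] + (k, k))
    R[..., iu[0], iu[1]] = np.clip(r_values, eps, 1 - eps)
    R[..., iu[1], iu[0]] = 1.0 - np.clip(r_values, eps, 1 - eps)
    R[..., np.arange(k), np.arange(k)] = 0.5
    return _combine_matrix(R)


@dataclass
class LikelihoodTensor:
    """Position likelihoods per (train time, test time, presented class).

    p : (n_train, n_test, k, k) float32 — ``p[tt, te, s, i]`` is the
    likelihood assigned to position ``i`` when the presented position is
    ``s``; each (tt, te, s) cell sums to one over ``i``.
    """

    p: np.ndarray
    class_ids: np.ndarray
    train_times_ms: np.ndarray
    test_times_ms: np.ndarray
    n_per_class: np.ndarray
    kind: str = "static"
    averaged_over: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return self.class_ids.size

    @property
    def chance(self) -> float:
        return 1.0 / self.k


def likelihood_from_scores(score: PairwiseScore, eps: float = R_CLIP_EPS) -> LikelihoodTensor:
    """Apply the combination formula to a full PairwiseScore tensor.

    Work is chunked over training times to bound the size of the expanded
    (k x k) r-matrix intermediate.
    """
    k = score.k
    iu = np.triu_indices(k, 1)
    n_tr, n_te = score.r.shape[:2]
    p = np.empty((n_tr, n_te, k, k), dtype=np.float32)
    R = np.empty((n_te, k, k, k))  # reused per training time
    for it in range(n_tr):
        F = np.clip(score.r[it].astype(float), eps, 1 - eps)  # (n_te, k_s, P)
        R[..., iu[0], iu[1]] = F
        R[..., iu[1], iu[0]] = 1.0 - F
        R[..., np.arange(k), np.arange(k)] = 0.5
        p[it] = _combine_matrix(R)
    return LikelihoodTensor(p, score.class_ids.copy(), score.train_times_ms.copy(),
                            score.test_times_ms.copy(), score.n_per_class.copy(),
                            score.kind)


def stimulus_position_likelihood(tensor: LikelihoodTensor,
                                 subtract_chance: bool = False) -> np.ndarray:
    """TGM of the likelihood at the presented position, averaged over classes.

    Chance subtraction (1/k) is for presentation only; statistics operate on
    the unsubtracted likelihood against the permutation null.
    """
    k = tensor.k
    tgm = tensor.p[:, :, np.arange(k), np.arange(k)].mean(axis=-1)
    if subtract_chance:
        tgm = tgm - tensor.chance
    return tgm


def average_alignment(stacks, axis: int = 0) -> np.ndarray:
    """Unweighted mean of aligned likelihood time courses.

    ``stacks`` is a sequence (or array) of identically shaped arrays, e.g. one
    per crossing instance, direction or participant; levels are averaged with
    equal weight, in the order crossings -> directions -> participants when
    applied repeatedly.
    """
    arr = np.asarray(stacks, dtype=float)
    if arr.shape[axis] == 0:
        raise ValueError("nothing to average: empty stack")
    return arr.mean(axis=axis)


def accuracy_by_distance(score: PairwiseScore, grid: GridSpec,
                         bins: int | None = None) -> pd.DataFrame:
    """Matched-time pairwise accuracy grouped by inter-position distance.

    Distances are expressed in units of the grid spacing.  By default every
    distinct distance (rounded to 3 decimals) forms its own group; with
    ``bins`` set, pairs are pooled into that many equal-count distance bins
    (the coarse grouping used for plotting distance curves — the outermost
    exact distances contain only a handful of pairs).  Returns one row per
    (group, training time) with the group-mean accuracy, the group's mean
    distance and the number of pairs.
    """
    acc = score.matched_time_accuracy()  # (n_train, n_pairs)
    D = grid.distances()
    ids = score.class_ids
    dist = D[ids[score.pairs[:, 0]], ids[score.pairs[:, 1]]] / grid.spacing_dva
    if bins is None:
        groups = np.round(dist, 3)
    else:
        qs = np.quantile(dist, np.linspace(0, 1, bins + 1)[1:-1])
        groups = np.searchsorted(qs, dist).astype(float)
    rows = []
    for g in np.unique(groups):
        sel = groups == g
        for it, t in enumerate(score.train_times_ms):
            rows.append({"distance_spacing": float(g) if bins is None
                         else float(dist[sel].mean()),
                         "group": float(g), "n_pairs": int(sel.sum()),
                         "train_time_ms": float(t),
                         "accuracy": float(acc[it, sel].mean())})
    return pd.DataFrame(rows)
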