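"""Permutation nulls, Yuen's trimmed-mean t, and cluster-based correction.

The significance of the stimulus-position likelihood is assessed against a
label-permutation null: classifiers are trained once, then position labels of
the test trials are shuffled at the aggregation step (no re-training) and the
likelihood recomputed, 1000 times per participant by default.  Group-level
inference uses a one-sample Yuen's t (20% trimming) of the participants'
observed likelihoods against their own permutation-null means, one-tailed,
with cluster-based correction over time (cluster-forming alpha 0.05, maximal
cluster-mass null).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .poslik import combine_pairwise, R_CLIP_EPS, _combine_matrix

__all__ = [
    "NullDistribution",
    "ClusterResult",
    "Cluster",
    "yuen_t",
    "yuen_t_1samp",
    "permutation_null",
    "observed_diag_likelihood",
    "cluster_correct",
    "group_significance",
]

DEFAULT_N_PERM = 1000
DEFAULT_TRIM = 0.2
CLUSTER_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Yuen's trimmed-mean t


def _trimmed_stats(x: np.ndarray, trim: float):
    """Trimmed mean, winsorized SSD and effective n along axis 0."""
    x = np.sort(np.asarray(x, dtype=float), axis=0)
    n = x.shape[0]
    g = int(np.floor(trim * n))
    h = n - 2 * g
    if h < 2:
        raise ValueError("over-trimming: fewer than 2 values remain")
    core = x[g: n - g]
    tmean = core.mean(axis=0)
    wins = np.concatenate([np.repeat(x[g][None], g, axis=0), core,
                           np.repeat(x[n - g - 1][None], g, axis=0)], axis=0)
    ssd_w = ((wins - wins.mean(axis=0)) ** 2).sum(axis=0)
    return tmean, ssd_w, h


def _tail_p(t, df, tail: str):
    if tail == "one":
        return stats.t.sf(t, df)
    if tail == "two":
        return 2.0 * stats.t.sf(np.abs(t), df)
    raise ValueError("tail must be 'one' or 'two'")


def yuen_t(sample_a, sample_b, trim: float = DEFAULT_TRIM, tail: str = "two") -> dict:
    """Two-sample Yuen's t-test on trimmed means with winsorized variances.

    With ``trim = 0`` this reduces exactly to Welch's unequal-variance t-test.
    A one-tailed test is of ``mean(a) > mean(b)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 5 or b.size < 5:
        raise ValueError("each sample needs at least 5 values")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    ma, ssa, ha = _trimmed_stats(a, trim)
    mb, ssb, hb = _trimmed_stats(b, trim)
    da = (a.size - 1) * (ssa / (a.size - 1)) / (ha * (ha - 1))
    db = (b.size - 1) * (ssb / (b.size - 1)) / (hb * (hb - 1))
    t = (ma - mb) / np.sqrt(da + db)
    df = (da + db) ** 2 / (da ** 2 / (ha - 1) + db ** 2 / (hb - 1))
    return {"t": float(t), "df": float(df), "p": float(_tail_p(t, df, tail))}


def yuen_t_1samp(sample, popmean: float = 0.0, trim: float = DEFAULT_TRIM,
                 tail: str = "one", axis0_matrix: bool = False):
    """One-sample Yuen's t against ``popmean``.

    With ``axis0_matrix=True``, ``sample`` is (n, m) and the test is applied
    to each of the m columns at once (vectorised); returns arrays.
    """
    x = np.asarray(sample, dtype=float)
    if not axis0_matrix:
        x = x[:, None]
    n = x.shape[0]
    if n < 5:
        raise ValueError("need at least 5 values")
    if not 0.0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    tmean, ssd_w, h = _trimmed_stats(x, trim)
    d = ssd_w / (h * (h - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (tmean - popmean) / np.sqrt(d)
    t = np.where(d > 0, t, 0.0)
    df = h - 1
    p = _tail_p(t, df, tail)
    if axis0_matrix:
        return {"t": t, "df": float(df), "p": p}
    return {"t": float(t[0]), "df": float(df), "p": float(p[0])}


def yuen_df_1samp(n: int, trim: float = DEFAULT_TRIM) -> int:
    g = int(np.floor(trim * n))
    return n - 2 * g - 1


# ---------------------------------------------------------------------------
# permutation null of the diagonal likelihood


@dataclass
class NullDistribution:
    """Diagonal stimulus-position likelihood under label permutations.

    values : (n_perm, n_times) — group/participant likelihood per permutation
    """

    values: np.ndarray
    times_ms: np.ndarray
    n_perm: int
    seed: int
    chance: float


def _diag_likelihood_from_votes(votes: np.ndarray, y: np.ndarray, k: int,
                                pairs: np.ndarray) -> np.ndarray:
    """Mean p_s(s) over classes from per-trial hard votes.

    votes : (n_times, n_pairs, n_trials) in {0, 1}; y: class code per trial.
    """
    n_times, n_pairs, n = votes.shape
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), y] = 1.0
    cnt = onehot.sum(axis=0)
    if np.any(cnt == 0):
        raise ValueError("every class needs at least one trial")
    F = (votes.reshape(n_times * n_pairs, n).astype(np.float32) @ onehot)
    F = (F / cnt[None, :]).reshape(n_times, n_pairs, k).transpose(0, 2, 1)
    iu = np.triu_indices(k, 1)
    Fc = np.clip(F.astype(float), R_CLIP_EPS, 1.0 - R_CLIP_EPS)
    R = np.empty((n_times, k, k, k))
    R[..., iu[0], iu[1]] = Fc
    R[..., iu[1], iu[0]] = 1.0 - Fc
    R[..., np.arange(k), np.arange(k)] = 0.5
    p = _combine_matrix(R)  # (n_times, k_s, k)
    return p[:, np.arange(k), np.arange(k)].mean(axis=-1)


def observed_diag_likelihood(score) -> np.ndarray:
    """Diagonal stimulus-position likelihood recomputed from per-trial votes.

    Uses the same aggregation path as :func:`permutation_null` with the
    identity permutation, so observed and null values are exactly comparable.
    """
    if score.diag_votes is None:
        raise ValueError("PairwiseScore carries no per-trial diagonal votes")
    return _diag_likelihood_from_votes(score.diag_votes, score.diag_labels,
                                       score.k, score.pairs)


def permutation_null(score, n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> NullDistribution:
    """Label-permutation null of the diagonal stimulus-position likelihood.

    Classifier outputs are fixed; only the position labels of the test trials
    are permuted before the pairwise votes are aggregated and combined into
    likelihoods, so the permuted results are uninformative about position
    while preserving every other property of the scores.
    """
    if score.diag_votes is None:
        raise ValueError("PairwiseScore carries no per-trial diagonal votes")
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: unstable p-value resolution")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x9E12]))
    y = score.diag_labels
    values = np.empty((n_perm, score.diag_votes.shape[0]))
    for p in range(n_perm):
        values[p] = _diag_likelihood_from_votes(score.diag_votes,
                                                rng.permutation(y), score.k,
                                                score.pairs)
    return NullDistribution(values, score.train_times_ms.copy(), n_perm,
                            int(seed), 1.0 / score.k)


# ---------------------------------------------------------------------------
# cluster-based correction


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    mass: float
    p: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    threshold: float
    cluster_alpha: float
    n_perm: int

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _cluster_masses(t_series: np.ndarray, threshold: float):
    above = t_series > threshold
    masses, bounds = [], []
    i = 0
    n = t_series.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            masses.append(float(t_series[i: j + 1].sum()))
            bounds.append((i, j))
            i = j + 1
        else:
            i += 1
    return masses, bounds


def cluster_correct(t_obs: np.ndarray, t_null: np.ndarray, threshold: float,
                    times_ms: np.ndarray, cluster_alpha: float = CLUSTER_ALPHA) -> ClusterResult:
    """Cluster-based multiple-comparisons correction over time.

    Contiguous supra-threshold runs of the observed t-series are scored by
    their summed t (cluster mass) and compared with the distribution of the
    maximal cluster mass across permutations; cluster p-values use the +1
    correction, so they are bounded below by 1/(n_perm + 1).
    """
    t_obs = np.asarray(t_obs, dtype=float)
    t_null = np.atleast_2d(np.asarray(t_null, dtype=float))
    if t_null.shape[1] != t_obs.size:
        raise ValueError("observed and permutation t-series must share the time grid")
    n_perm = t_null.shape[0]
    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        masses, _ = _cluster_masses(t_null[p], threshold)
        if masses:
            null_max[p] = max(masses)
    masses, bounds = _cluster_masses(t_obs, threshold)
    clusters = []
    for mass, (i, j) in zip(masses, bounds):
        pval = (1.0 + np.sum(null_max >= mass)) / (n_perm + 1.0)
        clusters.append(Cluster(float(times_ms[i]), float(times_ms[j]), mass, float(pval)))
    return ClusterResult(clusters, float(threshold), cluster_alpha, n_perm)


def group_significance(observed: np.ndarray, nulls: np.ndarray,
                       trim: float = DEFAULT_TRIM,
                       cluster_alpha: float = CLUSTER_ALPHA,
                       times_ms: np.ndarray | None = None) -> ClusterResult:
    """Group-level significance of the likelihood time course.

    observed : (n_participants, n_times) likelihood
    nulls : (n_participants, n_perm, n_times) per-participant permutation null

    Each participant's observed likelihood is referenced to their own
    permutation-null mean; a one-sample, one-tailed Yuen's t is computed per
    timepoint, and the same statistic per permutation builds the max-mass
    cluster null.  The cluster-forming threshold is the one-tailed critical t
    at ``cluster_alpha`` for the trimmed df.
    """
    observed = np.asarray(observed, dtype=float)
    nulls = np.asarray(nulls, dtype=float)
    n_part, n_times = observed.shape
    if nulls.shape[0] != n_part or nulls.shape[2] != n_times:
        raise ValueError("nulls must be (participants, permutations, times)")
    n_perm = nulls.shape[1]
    ref = nulls.mean(axis=1)  # (participants, times)
    t_obs = yuen_t_1samp(observed - ref, 0.0, trim, "one", axis0_matrix=True)["t"]
    diffs = nulls - ref[:, None, :]  # (participants, perms, times)
    flat = diffs.transpose(0, 1, 2).reshape(n_part, n_perm * n_times)
    t_null = yuen_t_1samp(flat, 0.0, trim, "one", axis0_matrix=True)["t"]
    t_null = t_null.reshape(n_perm, n_times)
    df = yuen_df_1samp(n_part, trim)
    threshold = float(stats.t.ppf(1.0 - cluster_alpha, df))
    return cluster_correct(t_obs, t_null, threshold,
                           times_ms if times_ms is not None else np.arange(n_times),
                           cluster_alpha)
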