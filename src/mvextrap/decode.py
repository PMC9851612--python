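"""Pairwise shrinkage-LDA decoding of stimulus position.

Classifiers are trained per timepoint on static trials for every pairwise
combination of stimulus positions (666 pairs for 37 positions), with the
pooled covariance regularised towards a scaled identity
``S_reg = (1 - gamma) S + gamma (trace(S)/d) I`` (gamma = 0.05 by default).
They are evaluated on held-out static trials (5-fold cross-validation) over
the whole training-time grid, and on motion trials re-epoched around the
times at which the moving stimulus crosses each grid position.

Scores are class-conditional vote fractions: for trials whose true position is
``s``, ``r[train_time, test_time, s, pair(i, j)]`` is the fraction of those
trials that the (i, j) classifier labels ``i``.  These are exactly the
ingredients of the pairwise-combination likelihood (see :mod:`mvextrap.poslik`),
and satisfy ``r_ji = 1 - r_ij`` by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hexgeom import TrajectorySpec
from .synthgen import EpochArray

__all__ = [
    "DecoderSpec",
    "PairwiseScore",
    "TrainedClassifiers",
    "make_pairs",
    "fit_lda_pair",
    "balance_classes",
    "pairwise_cv_static",
    "train_pairwise_full",
    "crossing_epochs",
    "test_pairwise_on_motion",
    "haufe_patterns",
]

DEFAULT_GAMMA = 0.05
DEFAULT_N_FOLDS = 5
TRAIN_WINDOW_MS = (0.0, 350.0)
MOTION_TEST_WINDOW_MS = (-500.0, 500.0)


@dataclass
class DecoderSpec:
    """Configuration of the pairwise decoding analysis."""

    gamma: float = DEFAULT_GAMMA
    n_folds: int = DEFAULT_N_FOLDS
    train_window_ms: tuple[float, float] = TRAIN_WINDOW_MS
    static_test_window_ms: tuple[float, float] = TRAIN_WINDOW_MS
    score_mode: str = "votes"  # "votes" (hard labels) | "posterior"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if self.score_mode not in ("votes", "posterior"):
            raise ValueError("score_mode must be 'votes' or 'posterior'")


@dataclass
class PairwiseScore:
    """Class-conditional pairwise vote fractions.

    r : (n_train_times, n_test_times, n_classes, n_pairs) float32
        ``r[tt, te, s, p]`` = fraction of true-class-``s`` test trials labelled
        with the pair's lower position index by classifier ``pairs[p]``.
    diag_votes : (n_train_times, n_pairs, n_trials) uint8, optional
        Per-trial hard votes at matched train/test times, kept so permutation
        nulls can re-aggregate under shuffled labels without re-training.
    """

    r: np.ndarray
    pairs: np.ndarray  # (n_pairs, 2) position indices, i < j
    class_ids: np.ndarray  # position ids corresponding to the class axis
    train_times_ms: np.ndarray
    test_times_ms: np.ndarray
    n_per_class: np.ndarray
    kind: str = "static"
    diag_votes: np.ndarray | None = None
    diag_labels: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    @property
    def k(self) -> int:
        return self.class_ids.size

    def matched_time_accuracy(self) -> np.ndarray:
        """Per-pair accuracy at matched train/test times, (n_train, n_pairs).

        Accuracy of the (i, j) classifier is the average of the fraction of
        class-i trials labelled i and class-j trials labelled j.
        """
        tt = np.arange(self.train_times_ms.size)
        te = np.array([int(np.argmin(np.abs(self.test_times_ms - t)))
                       for t in self.train_times_ms])
        ri = self.r[tt, te][:, self.pairs[:, 0], np.arange(self.n_pairs)]
        rj = self.r[tt, te][:, self.pairs[:, 1], np.arange(self.n_pairs)]
        return 0.5 * (ri + (1.0 - rj))


@dataclass
class TrainedClassifiers:
    """Pairwise LDA weights per training time: W (n_times, n_pairs, d), b (n_times, n_pairs)."""

    W: np.ndarray
    b: np.ndarray
    pairs: np.ndarray
    class_ids: np.ndarray
    train_times_ms: np.ndarray
    covariances: np.ndarray | None = None  # (n_times, d, d) pooled feature covariance


def make_pairs(k: int) -> np.ndarray:
    """All position index pairs (i, j) with i < j, lexicographic order."""
    iu = np.triu_indices(k, 1)
    return np.stack(iu, axis=1)


# ---------------------------------------------------------------------------
# LDA


def fit_lda_pair(Xi: np.ndarray, Xj: np.ndarray, gamma: float = DEFAULT_GAMMA):
    """Shrinkage-LDA discriminant for one pair of classes.

    Weights solve ``S_reg w = mu_i - mu_j`` with
    ``S_reg = (1 - gamma) S + gamma (trace(S)/d) I`` where ``S`` is the pooled
    within-class covariance; the bias places the boundary midway between the
    projected class means.  Positive discriminant means class i.
    """
    Xi = np.asarray(Xi, dtype=float)
    Xj = np.asarray(Xj, dtype=float)
    if Xi.shape[0] < 2 or Xj.shape[0] < 2:
        raise ValueError("need at least 2 trials per class")
    mi, mj = Xi.mean(0), Xj.mean(0)
    Ci, Cj = Xi - mi, Xj - mj
    d = Xi.shape[1]
    S = (Ci.T @ Ci + Cj.T @ Cj) / (Xi.shape[0] + Xj.shape[0] - 2)
    Sreg = (1.0 - gamma) * S + gamma * (np.trace(S) / d) * np.eye(d)
    try:
        w = np.linalg.solve(Sreg, mi - mj)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "singular pooled covariance; use a shrinkage gamma > 0") from err
    b = -float(w @ (mi + mj)) / 2.0
    return {"weights": w, "bias": b}


def balance_classes(labels: np.ndarray, pair: tuple[int, int], seed=0) -> np.ndarray:
    """Trial indices with equal counts for the two classes of ``pair``.

    All minority-class trials are kept; the majority class is subsampled
    without replacement, reproducibly under ``seed``.
    """
    labels = np.asarray(labels)
    i, j = pair
    idx_i = np.flatnonzero(labels == i)
    idx_j = np.flatnonzero(labels == j)
    if idx_i.size == 0 or idx_j.size == 0:
        raise ValueError(f"empty class in pair {pair}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(i), int(j)]))
    n = min(idx_i.size, idx_j.size)
    if idx_i.size > n:
        idx_i = rng.choice(idx_i, size=n, replace=False)
    if idx_j.size > n:
        idx_j = rng.choice(idx_j, size=n, replace=False)
    return np.sort(np.concatenate([idx_i, idx_j]))


def _balanced_indices(y: np.ndarray, k: int, pairs: np.ndarray, seed):
    """Per-pair balanced trial indices, or None when counts are already equal.

    The subsample is a function of labels, pair and seed only, so callers
    compute it once per training set and reuse it across timepoints.
    """
    counts = np.bincount(y, minlength=k)
    if np.any(counts < 2):
        lacking = np.flatnonzero(counts < 2)
        raise ValueError(f"insufficient trials for class(es) {lacking.tolist()}")
    if np.all(counts == counts[0]):
        return None
    return [balance_classes(y, (int(i), int(j)), seed=seed) for i, j in pairs]


def _train_all_pairs(X: np.ndarray, y: np.ndarray, k: int, pairs: np.ndarray,
                     gamma: float, balanced_idx=None):
    """Batched pairwise LDA at one timepoint.  X (n, d), y codes in 0..k-1.

    With equal class counts (``balanced_idx is None``) per-class scatter
    matrices are pooled per pair in one batched solve.  Otherwise each pair is
    fitted on its pre-computed balanced trial subset.
    """
    d = X.shape[1]
    eye = np.eye(d)
    if balanced_idx is None:
        counts = np.bincount(y, minlength=k)
        means = np.stack([X[y == c].mean(0) for c in range(k)])
        scat = np.stack([(X[y == c] - means[c]).T @ (X[y == c] - means[c])
                         for c in range(k)])
        i, j = pairs[:, 0], pairs[:, 1]
        denom = (counts[i] + counts[j] - 2).astype(float)
        S = (scat[i] + scat[j]) / denom[:, None, None]
        tr = np.trace(S, axis1=1, axis2=2) / d
        Sreg = (1.0 - gamma) * S + gamma * tr[:, None, None] * eye
        dmu = means[i] - means[j]
        W = np.linalg.solve(Sreg, dmu[:, :, None])[:, :, 0]
        b = -0.5 * np.einsum("pd,pd->p", W, means[i] + means[j])
        return W, b
    P = pairs.shape[0]
    S = np.empty((P, d, d))
    dmu = np.empty((P, d))
    msum = np.empty((P, d))
    for p, (i, j) in enumerate(pairs):
        idx = balanced_idx[p]
        Xi = X[idx[y[idx] == i]]
        Xj = X[idx[y[idx] == j]]
        mi, mj = Xi.mean(0), Xj.mean(0)
        Ci, Cj = Xi - mi, Xj - mj
        S[p] = (Ci.T @ Ci + Cj.T @ Cj) / (Xi.shape[0] + Xj.shape[0] - 2)
        dmu[p] = mi - mj
        msum[p] = mi + mj
    tr = np.trace(S, axis1=1, axis2=2) / d
    Sreg = (1.0 - gamma) * S + gamma * tr[:, None, None] * eye
    W = np.linalg.solve(Sreg, dmu[:, :, None])[:, :, 0]
    b = -0.5 * np.einsum("pd,pd->p", W, msum)
    return W, b


def _scores_to_votes(margins: np.ndarray, mode: str) -> np.ndarray:
    if mode == "votes":
        return margins > 0
    return 1.0 / (1.0 + np.exp(-margins))


def _class_fractions(votes: np.ndarray, starts: np.ndarray,
                     counts: np.ndarray) -> np.ndarray:
    """Mean vote per class: votes (P, n, T) -> (T, k, P); trials must already
    be sorted by class so that class c occupies rows starts[c]:starts[c]+counts[c]."""
    sums = np.add.reduceat(votes, starts, axis=1, dtype=np.float32)  # (P, k, T)
    frac = sums / counts[None, :, None].astype(np.float32)
    return frac.transpose(2, 1, 0)


def _time_indices(times_ms: np.ndarray, window_ms: tuple[float, float]) -> np.ndarray:
    idx = np.flatnonzero((times_ms >= window_ms[0] - 1e-9) & (times_ms <= window_ms[1] + 1e-9))
    if idx.size == 0:
        raise ValueError(f"window {window_ms} contains no samples")
    return idx


def _encode_labels(labels: np.ndarray):
    class_ids = np.unique(labels)
    codes = np.searchsorted(class_ids, labels)
    return class_ids, codes


# ---------------------------------------------------------------------------
# static cross-validation


def pairwise_cv_static(epochs: EpochArray, spec: DecoderSpec | None = None) -> PairwiseScore:
    """Cross-validated pairwise decoding of static trials over the full
    train-time x test-time grid (temporal generalisation)."""
    spec = spec or DecoderSpec()
    class_ids, y = _encode_labels(epochs.labels)
    k = class_ids.size
    pairs = make_pairs(k)
    counts = np.bincount(y, minlength=k)
    if np.any(counts < spec.n_folds):
        bad = class_ids[counts < spec.n_folds]
        raise ValueError(f"fewer trials than folds for position(s) {bad.tolist()}")

    tr_idx = _time_indices(epochs.times_ms, spec.train_window_ms)
    te_idx = _time_indices(epochs.times_ms, spec.static_test_window_ms)
    train_times = epochs.times_ms[tr_idx]
    test_times = epochs.times_ms[te_idx]
    # matched-time column of the test grid for each training time
    diag_col = np.array([int(np.argmin(np.abs(test_times - t))) for t in train_times])

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xF01D]))
    fold_of = np.empty(epochs.n_trials, dtype=int)
    for c in range(k):
        idx = rng.permutation(np.flatnonzero(y == c))
        for f, chunk in enumerate(np.array_split(idx, spec.n_folds)):
            fold_of[chunk] = f

    X = epochs.data
    r = np.zeros((train_times.size, test_times.size, k, pairs.shape[0]), dtype=np.float32)
    diag_votes = np.zeros((train_times.size, pairs.shape[0], epochs.n_trials), dtype=np.uint8)
    d = epochs.n_channels
    for f in range(spec.n_folds):
        te_mask = fold_of == f
        tr_mask = ~te_mask
        # test trials sorted by class so per-class aggregation is contiguous
        te_trials = np.flatnonzero(te_mask)
        te_trials = te_trials[np.argsort(y[te_trials], kind="stable")]
        y_te = y[te_trials]
        n_te = te_trials.size
        cnt = np.bincount(y_te, minlength=k)
        starts = np.concatenate([[0], np.cumsum(cnt)[:-1]])
        X2d = np.ascontiguousarray(
            X[te_trials][:, :, te_idx].transpose(1, 0, 2).reshape(d, n_te * te_idx.size),
            dtype=np.float32)
        y_tr = y[tr_mask]
        bal = _balanced_indices(y_tr, k, pairs, spec.seed)
        Xtr = X[tr_mask]
        M = np.empty((pairs.shape[0], n_te * te_idx.size), dtype=np.float32)
        for it, t in enumerate(tr_idx):
            W, b = _train_all_pairs(Xtr[:, :, t], y_tr, k, pairs, spec.gamma, bal)
            np.matmul(W.astype(np.float32), X2d, out=M)
            M += b[:, None].astype(np.float32)
            margins = M.reshape(pairs.shape[0], n_te, te_idx.size)
            votes = _scores_to_votes(margins, spec.score_mode)
            r[it] += _class_fractions(votes, starts, cnt)
            diag_votes[it][:, te_trials] = margins[:, :, diag_col[it]] > 0
    r /= spec.n_folds
    return PairwiseScore(r, pairs, class_ids, train_times, test_times,
                         counts.astype(int), "static", diag_votes, y.copy())


def train_pairwise_full(epochs: EpochArray, spec: DecoderSpec | None = None,
                        keep_covariance: bool = True) -> TrainedClassifiers:
    """Train pairwise classifiers on *all* static trials per training time
    (used for testing on motion, where no cross-validation is needed)."""
    spec = spec or DecoderSpec()
    class_ids, y = _encode_labels(epochs.labels)
    k = class_ids.size
    pairs = make_pairs(k)
    tr_idx = _time_indices(epochs.times_ms, spec.train_window_ms)
    d = epochs.n_channels
    W = np.empty((tr_idx.size, pairs.shape[0], d))
    b = np.empty((tr_idx.size, pairs.shape[0]))
    covs = np.empty((tr_idx.size, d, d)) if keep_covariance else None
    bal = _balanced_indices(y, k, pairs, spec.seed)
    for it, t in enumerate(tr_idx):
        Xt = epochs.data[:, :, t]
        W[it], b[it] = _train_all_pairs(Xt, y, k, pairs, spec.gamma, bal)
        if keep_covariance:
            covs[it] = np.cov(Xt, rowvar=False)
    return TrainedClassifiers(W, b, pairs, class_ids, epochs.times_ms[tr_idx], covs)


# ---------------------------------------------------------------------------
# motion


def crossing_epochs(motion_epochs: EpochArray, trajectories: list[TrajectorySpec],
                    window_ms: tuple[float, float] = MOTION_TEST_WINDOW_MS,
                    exclude_first: bool = True) -> EpochArray:
    """Re-epoch motion trials around each position crossing.

    One aligned epoch per (trial, crossing), labelled with the crossed
    position; the first crossing of each trajectory is dropped by default
    because it is confounded with the stimulus-onset response.  Alignment is
    to the sample nearest the crossing time; crossings whose window would
    exceed the mother epoch are skipped with a warning.
    """
    traj_by_id = {t.traj_id: t for t in trajectories}
    sr = motion_epochs.srate_hz
    h_lo = int(round(abs(window_ms[0]) * sr / 1000.0))
    h_hi = int(round(window_ms[1] * sr / 1000.0))
    times = motion_epochs.times_ms
    aligned_times = np.arange(-h_lo, h_hi + 1) * (1000.0 / sr)
    chunks, labels, src_trial, src_traj, direction, ordinal = [], [], [], [], [], []
    skipped = 0
    for n in range(motion_epochs.n_trials):
        traj = traj_by_id[int(motion_epochs.labels[n])]
        start = 1 if exclude_first else 0
        for i_cross in range(start, traj.n_crossings):
            pos_id, t_ms = traj.crossings[i_cross]
            c = int(np.argmin(np.abs(times - t_ms)))
            if c - h_lo < 0 or c + h_hi >= times.size:
                skipped += 1
                continue
            chunks.append(motion_epochs.data[n, :, c - h_lo: c + h_hi + 1])
            labels.append(pos_id)
            src_trial.append(n)
            src_traj.append(traj.traj_id)
            direction.append(traj.direction_index)
            ordinal.append(i_cross)
    if skipped:
        warnings.warn(f"skipped {skipped} crossings whose window exceeded the epoch")
    if not chunks:
        raise ValueError("no crossings fall within the motion epochs")
    return EpochArray(np.stack(chunks), aligned_times, np.array(labels),
                      sr, "motion_aligned",
                      meta={"src_trial": np.array(src_trial),
                            "src_traj": np.array(src_traj),
                            "direction": np.array(direction),
                            "crossing_ordinal": np.array(ordinal),
                            "is_last_crossing": np.array(
                                [traj_by_id[t].n_crossings - 1 == o
                                 for t, o in zip(src_traj, ordinal)]),
                            **{k: v for k, v in motion_epochs.meta.items()}})


def test_pairwise_on_motion(clf: TrainedClassifiers, aligned: EpochArray,
                            score_mode: str = "votes") -> PairwiseScore:
    """Apply static-trained classifiers to crossing-aligned motion epochs.

    Scores are aggregated against the crossing's position label, pooling all
    aligned epochs of a position (crossings of every trajectory and direction).
    """
    if aligned.n_channels != clf.W.shape[2]:
        raise ValueError("channel count differs between classifiers and test data")
    class_ids = clf.class_ids
    k = class_ids.size
    y_raw = np.searchsorted(class_ids, np.asarray(aligned.labels))
    y_raw = np.clip(y_raw, 0, k - 1)
    if np.any(class_ids[y_raw] != aligned.labels):
        raise ValueError("aligned epochs contain labels the classifiers never saw")
    # epochs sorted by class so per-class aggregation is contiguous
    order = np.argsort(y_raw, kind="stable")
    y = y_raw[order]
    cnt = np.bincount(y, minlength=k)
    if np.any(cnt == 0):
        raise ValueError(f"no aligned epochs for position(s) "
                         f"{class_ids[cnt == 0].tolist()}")
    starts = np.concatenate([[0], np.cumsum(cnt)[:-1]])
    n_tr, n_te = clf.train_times_ms.size, aligned.times_ms.size
    n, d = aligned.n_trials, aligned.n_channels
    P = clf.pairs.shape[0]
    X2d = np.ascontiguousarray(
        aligned.data[order].transpose(1, 0, 2).reshape(d, n * n_te), dtype=np.float32)
    # matched-time column (train time t <-> aligned test time t)
    diag_col = np.array([int(np.argmin(np.abs(aligned.times_ms - t)))
                         for t in clf.train_times_ms])
    r = np.empty((n_tr, n_te, k, P), dtype=np.float32)
    diag_votes = np.zeros((n_tr, P, n), dtype=np.uint8)
    M = np.empty((P, n * n_te), dtype=np.float32)
    votes_buf = np.empty((P, n, n_te), dtype=bool)
    for it in range(n_tr):
        np.matmul(clf.W[it].astype(np.float32), X2d, out=M)
        M += clf.b[it][:, None].astype(np.float32)
        margins = M.reshape(P, n, n_te)
        if score_mode == "votes":
            votes = np.greater(margins, 0, out=votes_buf)
        else:
            votes = _scores_to_votes(margins, score_mode)
        r[it] = _class_fractions(votes, starts, cnt)
        diag_votes[it] = margins[:, :, diag_col[it]] > 0
    return PairwiseScore(r, clf.pairs, class_ids, clf.train_times_ms.copy(),
                         aligned.times_ms.copy(), cnt.astype(int), "motion",
                         diag_votes, y.copy())


# ---------------------------------------------------------------------------
# activation patterns


def haufe_patterns(weights: np.ndarray, feature_covariance: np.ndarray) -> np.ndarray:
    """Activation pattern(s) from classifier weights: ``cov @ w``, unit norm.

    Turns backward-model weights into forward-model activation patterns by
    combining them with the covariance of the training features; patterns (not
    weights) are interpretable as scalp topographies.
    """
    w = np.asarray(weights, dtype=float)
    cov = np.asarray(feature_covariance, dtype=float)
    if cov.shape[0] != cov.shape[1] or w.shape[-1] != cov.shape[0]:
        raise ValueError("dimension mismatch between weights and covariance")
    pat = w @ cov.T
    return pat / np.linalg.norm(pat, axis=-1, keepdims=True)
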