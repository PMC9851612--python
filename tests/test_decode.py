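"""Pairwise shrinkage-LDA decoding: classifier math, CV scores, crossings."""

import numpy as np
import pytest

from mvextrap.decode import (
    DecoderSpec,
    balance_classes,
    crossing_epochs,
    fit_lda_pair,
    haufe_patterns,
    make_pairs,
    pairwise_cv_static,
    train_pairwise_full,
)
from mvextrap.decode import test_pairwise_on_motion as apply_to_motion
from mvextrap.hexgeom import build_grid, enumerate_trajectories
from mvextrap.synthgen import EpochArray, sample_times


class TestLdaPair:
    def test_two_feature_hand_case_with_diagonal_covariance(self):
        # class i: mean (2, 0), scatter diag(2, 8); class j: mean (0, 2), same
        # scatter. Pooled S = diag(4, 16)/6; w = S^-1 (2, -2) = (3, -3/4)
        base_i = np.array([[1.0, 0.0], [3.0, 0.0], [2.0, 2.0], [2.0, -2.0]])
        base_j = np.array([[-1.0, 2.0], [1.0, 2.0], [0.0, 4.0], [0.0, 0.0]])
        fit = fit_lda_pair(base_i, base_j, gamma=0.0)
        assert np.allclose(fit["weights"], [3.0, -0.75], atol=1e-12)
        # boundary midway between projected means
        mi, mj = base_i.mean(0), base_j.mean(0)
        assert fit["bias"] == pytest.approx(-fit["weights"] @ (mi + mj) / 2)

    def test_full_shrinkage_aligns_weights_with_mean_difference(self):
        rng = np.random.default_rng(31)
        Xi = rng.normal((3.0, 0.0, 0.0), 1.0, size=(40, 3))
        Xj = rng.normal((0.0, 0.0, 0.0), 1.0, size=(40, 3))
        fit = fit_lda_pair(Xi, Xj, gamma=1.0)
        dmu = Xi.mean(0) - Xj.mean(0)
        cos = fit["weights"] @ dmu / np.linalg.norm(fit["weights"]) / np.linalg.norm(dmu)
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_well_separated_clouds_classified_perfectly(self):
        rng = np.random.default_rng(32)
        Xi = rng.normal((10.0, 0.0), 1.0, size=(50, 2))
        Xj = rng.normal((0.0, 0.0), 1.0, size=(50, 2))
        fit = fit_lda_pair(Xi[:25], Xj[:25], gamma=0.05)
        scores_i = Xi[25:] @ fit["weights"] + fit["bias"]
        scores_j = Xj[25:] @ fit["weights"] + fit["bias"]
        assert np.all(scores_i > 0) and np.all(scores_j < 0)

    def test_matches_sklearn_shrinkage_lda(self):
        sklearn = pytest.importorskip("sklearn.discriminant_analysis")
        rng = np.random.default_rng(33)
        Xi = rng.normal(0.5, 1.0, size=(30, 6))
        Xj = rng.normal(0.0, 1.0, size=(30, 6))
        fit = fit_lda_pair(Xi, Xj, gamma=0.05)
        clf = sklearn.LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.05)
        X = np.vstack([Xi, Xj])
        y = np.r_[np.ones(30), np.zeros(30)]
        clf.fit(X, y)
        # identical decision boundary up to scale: compare classifications
        rng2 = np.random.default_rng(34)
        Xt = rng2.normal(0.25, 1.0, size=(200, 6))
        ours = (Xt @ fit["weights"] + fit["bias"]) > 0
        theirs = clf.predict(Xt).astype(bool)
        assert np.mean(ours == theirs) > 0.97

    def test_singular_covariance_advises_shrinkage(self):
        X = np.zeros((5, 3))
        with pytest.raises(ValueError, match="gamma"):
            fit_lda_pair(X, X + 1.0, gamma=0.0)

    def test_minimum_trials_enforced(self):
        with pytest.raises(ValueError):
            fit_lda_pair(np.zeros((1, 2)), np.ones((5, 2)))


class TestBalanceClasses:
    labels = np.array([0] * 10 + [1] * 7 + [2] * 3)

    def test_equal_classes_fully_retained(self):
        idx = balance_classes(np.array([0] * 10 + [1] * 10), (0, 1), seed=0)
        assert idx.size == 20

    def test_majority_subsampled_to_minority(self):
        idx = balance_classes(self.labels, (0, 1), seed=1)
        lab = self.labels[idx]
        assert (lab == 0).sum() == (lab == 1).sum() == 7

    def test_seed_reproducible(self):
        a = balance_classes(self.labels, (0, 1), seed=2)
        b = balance_classes(self.labels, (0, 1), seed=2)
        assert np.array_equal(a, b)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance_classes(self.labels, (0, 5))


def synth_epochs(n_classes=4, n_per=12, n_ch=6, sep=3.0, seed=0, srate=128.0):
    """Linearly separable class means, unit noise, constant in time."""
    rng = np.random.default_rng(seed)
    means = rng.normal(0, sep, size=(n_classes, n_ch))
    times = sample_times((0.0, 100.0), srate)
    labels = np.repeat(np.arange(n_classes), n_per)
    data = means[labels][:, :, None] + rng.normal(0, 1.0,
                                                  size=(labels.size, n_ch, times.size))
    return EpochArray(data, times, labels, srate, "static")


class TestPairwiseCv:
    def test_pair_count_is_c_k_2(self):
        assert make_pairs(37).shape == (666, 2)
        score = pairwise_cv_static(synth_epochs(), DecoderSpec(
            train_window_ms=(0, 100), static_test_window_ms=(0, 100)))
        assert score.n_pairs == 6
        assert score.r.shape[2] == 4

    def test_vote_fraction_complementarity(self):
        # r_ji = 1 - r_ij by construction: the fraction of class-j trials
        # voted i plus the fraction voted j is one
        score = pairwise_cv_static(synth_epochs(), DecoderSpec(
            train_window_ms=(0, 100), static_test_window_ms=(0, 100)))
        assert np.all(score.r >= 0) and np.all(score.r <= 1)
        acc = score.matched_time_accuracy()
        assert np.all(acc >= 0) and np.all(acc <= 1)

    def test_separable_classes_decoded_perfectly(self):
        score = pairwise_cv_static(synth_epochs(sep=8.0), DecoderSpec(
            train_window_ms=(0, 100), static_test_window_ms=(0, 100)))
        assert score.matched_time_accuracy().mean() > 0.99

    def test_shuffled_labels_score_at_chance(self):
        ep = synth_epochs(n_classes=4, n_per=20, sep=3.0, seed=5)
        rng = np.random.default_rng(6)
        ep.labels = rng.permutation(ep.labels)
        score = pairwise_cv_static(ep, DecoderSpec(
            train_window_ms=(0, 100), static_test_window_ms=(0, 100)))
        acc = score.matched_time_accuracy().mean()
        # cross-validated accuracy under the null sits at/just below 0.5: the
        # classifier fits noise that is anti-correlated with the held-out fold
        # (the usual small-sample pessimism of CV), so allow that bias on top
        # of the binomial band but reject anything resembling real decoding
        assert acc < 0.5 + 0.02
        assert acc > 0.5 - 0.08

    def test_fold_seed_only_perturbs_scores_slightly(self):
        ep = synth_epochs(n_classes=3, n_per=20, sep=4.0, seed=7)
        accs = []
        for s in (1, 2, 3):
            spec = DecoderSpec(train_window_ms=(0, 100),
                               static_test_window_ms=(0, 100), seed=s)
            accs.append(pairwise_cv_static(ep, spec).matched_time_accuracy().mean())
        assert np.ptp(accs) < 0.05

    def test_insufficient_trials_named(self):
        ep = synth_epochs(n_classes=3, n_per=4)
        with pytest.raises(ValueError):
            pairwise_cv_static(ep, DecoderSpec(n_folds=5,
                                               train_window_ms=(0, 100),
                                               static_test_window_ms=(0, 100)))


class TestCrossingEpochs:
    @pytest.fixture(scope="class")
    def motion_setup(self):
        grid = build_grid(3)
        trajs = enumerate_trajectories(grid)
        srate = 128.0
        max_dur = max(t.duration_ms for t in trajs)
        times = sample_times((-100.0, max_dur + 100.0), srate)
        by_crossings = {t.n_crossings: t for t in trajs}
        labels = np.array([by_crossings[7].traj_id, by_crossings[4].traj_id])
        data = np.zeros((2, 3, times.size))
        ep = EpochArray(data, times, labels, srate, "motion")
        return ep, trajs

    def test_first_crossing_excluded_counts(self, motion_setup):
        ep, trajs = motion_setup
        aligned = crossing_epochs(ep, trajs)
        # 7-crossing trial -> 6 epochs, 4-crossing trial -> 3 epochs
        assert aligned.n_trials == 6 + 3
        src = aligned.meta["src_trial"]
        assert (src == 0).sum() == 6 and (src == 1).sum() == 3

    def test_aligned_axis_spans_the_window(self, motion_setup):
        ep, trajs = motion_setup
        aligned = crossing_epochs(ep, trajs)
        assert aligned.times_ms[0] == pytest.approx(-500.0)
        assert aligned.times_ms[-1] == pytest.approx(500.0)
        assert aligned.srate_hz == ep.srate_hz

    def test_keeping_first_crossing(self, motion_setup):
        ep, trajs = motion_setup
        aligned = crossing_epochs(ep, trajs, exclude_first=False)
        assert aligned.n_trials == 7 + 4

    def test_out_of_range_window_skips_with_warning(self, motion_setup):
        ep, trajs = motion_setup
        with pytest.warns(UserWarning):
            aligned = crossing_epochs(ep, trajs, window_ms=(-1200.0, 1200.0))
        assert aligned.n_trials < 9


class TestMotionTesting:
    def test_channel_mismatch_rejected(self):
        ep = synth_epochs()
        clf = train_pairwise_full(ep, DecoderSpec(train_window_ms=(0, 100)))
        bad = synth_epochs(n_ch=5)
        bad.kind = "motion_aligned"
        with pytest.raises(ValueError):
            apply_to_motion(clf, bad)

    def test_static_patterns_recovered_on_matching_test_data(self):
        ep = synth_epochs(sep=6.0, seed=9)
        clf = train_pairwise_full(ep, DecoderSpec(train_window_ms=(0, 100)))
        probe = synth_epochs(sep=6.0, seed=9)  # same class means, same draw
        probe.kind = "motion_aligned"
        score = apply_to_motion(clf, probe)
        assert score.matched_time_accuracy().mean() > 0.95


class TestHaufe:
    def test_identity_covariance_returns_weights_direction(self):
        w = np.array([3.0, 4.0])
        pat = haufe_patterns(w, np.eye(2))
        assert np.allclose(pat, w / 5.0)

    def test_two_channel_hand_case(self):
        # cov diag(2, 1) and w = (1, 1) -> pattern ~ (2, 1)
        pat = haufe_patterns(np.array([1.0, 1.0]), np.diag([2.0, 1.0]))
        assert np.allclose(pat, np.array([2.0, 1.0]) / np.sqrt(5.0))

    def test_pattern_matches_generating_topography(self):
        # LDA weights on anisotropic noise are tilted; the Haufe transform
        # recovers the underlying activation direction
        rng = np.random.default_rng(35)
        mix = np.array([[1.0, 0.8], [0.0, 1.0]])
        a = np.array([1.0, 0.0])  # activation pattern
        z = rng.normal(size=(400, 2)) @ mix.T
        y = rng.integers(0, 2, 400)
        X = z + np.outer(y - 0.5, a) * 4
        fit = fit_lda_pair(X[y == 1], X[y == 0], gamma=0.05)
        pat = haufe_patterns(fit["weights"], np.cov(X, rowvar=False))
        cos = abs(pat @ a) / np.linalg.norm(a)
        assert cos > 0.95

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            haufe_patterns(np.ones(3), np.eye(2))
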