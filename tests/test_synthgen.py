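"""Forward-model generator: topographies, evoked cascades, noise, gaze."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from mvextrap.hexgeom import build_grid, build_schedule, enumerate_trajectories
from mvextrap.prep import reject_by_fixation
from mvextrap.synthgen import (
    NoiseSpec,
    SimConfig,
    ar1_noise,
    build_forward_model,
    make_topographies,
    motion_signal,
    sample_times,
    simulate_dataset,
    simulate_gaze,
    simulate_motion_epoch,
    simulate_static_epoch,
    static_signal,
)


class TestTopographies:
    def test_shape_and_unit_norm(self, grid3):
        T = make_topographies(grid3, 64, seed=0)
        assert T.shape == (37, 64)
        assert np.allclose(np.linalg.norm(T, axis=1), 1.0)

    def test_self_correlation_is_one(self, grid3):
        T = make_topographies(grid3, 32, seed=1)
        C = np.corrcoef(T)
        assert np.allclose(np.diag(C), 1.0)

    def test_correlation_decays_with_distance(self, grid3):
        T = make_topographies(grid3, 64, seed=2)
        C = np.corrcoef(T)
        D = grid3.distances()
        iu = np.triu_indices(37, 1)  # all 666 pairs
        rho = spearmanr(D[iu], C[iu]).statistic
        assert rho < -0.5

    def test_channel_count_validated(self, grid3):
        with pytest.raises(ValueError):
            make_topographies(grid3, 1)


class TestStaticEpochs:
    def single_comp_model(self, grid, **kw):
        return build_forward_model(grid, n_channels=16, latencies_ms=(90.0,),
                                   widths_ms=(25.0,), gains=(5.0,), seed=3, **kw)

    def test_noiseless_peak_at_component_latency(self):
        grid = build_grid(1)
        model = self.single_comp_model(grid)
        times = sample_times((-100, 350), model.srate_hz)
        sig = static_signal(model, 3, times)
        ch = np.argmax(np.abs(sig).max(axis=1))
        t_peak = times[np.argmax(np.abs(sig[ch]))]
        assert abs(t_peak - 90.0) <= 1000.0 / 128.0 / 2

    def test_pre_onset_expectation_zero(self):
        grid = build_grid(1)
        model = self.single_comp_model(grid)
        times = sample_times((-100, 350), model.srate_hz)
        sig = static_signal(model, 0, times)
        # pre-onset only the far Gaussian tail remains (< 0.1% of the gain)
        assert np.all(np.abs(sig[:, times < 0]) < 5e-3)

    def test_zero_gains_and_zero_noise_give_silence(self):
        grid = build_grid(1)
        model = build_forward_model(grid, n_channels=8, gains=(0.0, 0.0, 0.0),
                                    noise=NoiseSpec(white_sd=0.0), seed=4)
        ep = simulate_static_epoch(model, 2, seed=0)
        assert np.allclose(ep.data, 0.0)

    def test_trial_averaged_peak_within_one_sample(self):
        grid = build_grid(1)
        model = self.single_comp_model(grid)
        times = sample_times((-100, 350), model.srate_hz)
        acc = np.zeros((model.n_channels, times.size))
        for s in range(200):
            acc += simulate_static_epoch(model, 0, seed=s).data[0]
        acc /= 200
        clean = static_signal(model, 0, times)
        ch = np.argmax(np.abs(clean).max(axis=1))
        sign = np.sign(clean[ch, np.argmax(np.abs(clean[ch]))])
        t_peak = times[np.argmax(sign * acc[ch])]
        assert abs(t_peak - 90.0) <= 1000.0 / 128.0

    def test_unknown_position_rejected(self):
        grid = build_grid(1)
        model = self.single_comp_model(grid)
        with pytest.raises(ValueError):
            simulate_static_epoch(model, 99)

    def test_label_permutation_symmetry(self):
        # permuting position ids together with topography rows permutes epochs
        grid = build_grid(1)
        model = self.single_comp_model(grid, noise=NoiseSpec(white_sd=0.0))
        times = sample_times((-100, 350), model.srate_hz)
        perm = np.array([3, 0, 1, 2, 5, 6, 4])
        sigs = np.stack([static_signal(model, p, times) for p in range(7)])
        model.components[0].topo = model.components[0].topo[perm]
        sigs_p = np.stack([static_signal(model, p, times) for p in range(7)])
        assert np.allclose(sigs_p, sigs[perm])


class TestMotionEpochs:
    def test_delta_equal_latency_expresses_crossing_topography(self):
        grid = build_grid(1)
        traj = enumerate_trajectories(grid)[1]  # a line through several positions
        model = build_forward_model(grid, n_channels=16, latencies_ms=(90.0,),
                                    widths_ms=(25.0,), gains=(5.0,),
                                    extrap_shift_ms=90.0,
                                    noise=NoiseSpec(white_sd=0.0), seed=5)
        times = sample_times((-100, traj.duration_ms + 100), model.srate_hz)
        sig = motion_signal(model, traj, times)
        for pos_id, t_ms in traj.crossings:
            idx = np.argmin(np.abs(times - t_ms))
            expected = 5.0 * model.components[0].topo[pos_id]
            got = sig[: model.n_signal_channels, idx]
            # nearest-sample alignment: allow the small within-sample drift
            assert np.corrcoef(expected, got)[0, 1] > 0.99

    def test_delta_zero_expresses_lagged_position(self):
        grid = build_grid(1)
        trajs = enumerate_trajectories(grid)
        traj = next(t for t in trajs if t.n_crossings == 3)
        model = build_forward_model(grid, n_channels=16, latencies_ms=(400.0,),
                                    widths_ms=(25.0,), gains=(5.0,),
                                    extrap_shift_ms=0.0,
                                    noise=NoiseSpec(white_sd=0.0), seed=6)
        times = sample_times((-100, traj.duration_ms + 100), model.srate_hz)
        sig = motion_signal(model, traj, times)
        # at the second crossing's time + latency, the first... the expressed
        # topography equals the position occupied latency ms earlier
        pos_prev, t_prev = traj.crossings[0]
        idx = np.argmin(np.abs(times - (t_prev + 400.0)))
        got = sig[: model.n_signal_channels, idx]
        expected = 5.0 * model.components[0].topo[pos_prev]
        assert np.corrcoef(expected, got)[0, 1] > 0.99

    def test_padding_extends_epoch_with_signal_free_tail(self):
        grid = build_grid(1)
        traj = enumerate_trajectories(grid)[0]
        model = build_forward_model(grid, n_channels=8,
                                    noise=NoiseSpec(white_sd=0.0), seed=7)
        ep = simulate_motion_epoch(model, traj, seed=0,
                                   pad_to_ms=traj.duration_ms + 500.0)
        tail = ep.times_ms > traj.duration_ms + 250.0
        assert np.allclose(ep.data[0][:, tail], 0.0)


class TestNoise:
    def test_ar1_lag1_autocorrelation(self):
        rng = np.random.default_rng(8)
        x = ar1_noise(rng, (1, 100_000), coef=0.3, sd=1.0)[0]
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1 - 0.3) <= 0.05

    def test_marginal_sd_matches(self):
        rng = np.random.default_rng(9)
        x = ar1_noise(rng, (2, 50_000), coef=0.6, sd=2.5)
        assert np.allclose(x.std(axis=1), 2.5, atol=0.1)

    def test_coefficient_validated(self):
        with pytest.raises(ValueError):
            ar1_noise(np.random.default_rng(0), (1, 10), coef=1.0, sd=1.0)


class TestGaze:
    @pytest.fixture(scope="class")
    def sched(self):
        grid = build_grid(1)
        trajs = enumerate_trajectories(grid)
        return grid, build_schedule(grid, trajs, 1, 3, 0, seed=2)

    def test_full_pursuit_without_jitter_equals_stimulus_position(self, sched):
        grid, schedule = sched
        gz = simulate_gaze(schedule, grid, jitter_sd_dva=0.0, pursuit_gain=1.0, seed=0)
        on = (gz.times_ms >= 0) & (gz.times_ms <= 250)
        for i, lab in enumerate(gz.labels):
            assert np.allclose(gz.data[i][:, on].T, grid.xy[lab])
            assert np.allclose(gz.data[i][:, ~on], 0.0)

    def test_large_jitter_trials_flagged_by_fixation_rejection(self, sched):
        grid, schedule = sched
        gz = simulate_gaze(schedule, grid, jitter_sd_dva=3.0, pursuit_gain=0.0, seed=1)
        rep = reject_by_fixation(gz, radius_dva=2.1)
        assert len(rep.rejected_indices) > 0

    def test_gain_validated(self, sched):
        grid, schedule = sched
        with pytest.raises(ValueError):
            simulate_gaze(schedule, grid, pursuit_gain=1.5)


class TestDataset:
    def test_counts_follow_schedule(self, tiny_dataset):
        ds = tiny_dataset
        assert ds.static.n_trials == 7 * 12
        assert ds.motion.n_trials == 18 * 4
        counts = np.bincount(ds.static.labels)
        assert np.all(counts == 12)

    def test_same_seed_bit_identical(self):
        cfg = SimConfig(rings=1, n_channels=6, n_sessions=1, static_reps=3,
                        motion_reps=1)
        a = simulate_dataset(cfg, seed=11)
        b = simulate_dataset(cfg, seed=11)
        assert np.array_equal(a.static.data, b.static.data)
        assert np.array_equal(a.motion.data, b.motion.data)
        assert np.array_equal(a.gaze.data, b.gaze.data)

    def test_shared_schedule_seed_different_noise(self):
        cfg = SimConfig(rings=1, n_channels=6, n_sessions=1, static_reps=3,
                        motion_reps=1, schedule_seed=5)
        a = simulate_dataset(cfg, seed=1)
        b = simulate_dataset(cfg, seed=2)
        assert np.array_equal(a.static.labels, b.static.labels)
        assert not np.allclose(a.static.data, b.static.data)

    def test_truth_carries_generative_parameters(self, tiny_dataset):
        assert tiny_dataset.truth.extrap_shift_ms == 0.0
        lats = [c.latency_ms for c in tiny_dataset.truth.components]
        assert lats == sorted(lats)
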