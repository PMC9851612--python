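"""End-to-end latency model: simulate -> prep -> decode -> likelihood -> latency -> stats.

The public surface follows the fitted-model idiom: :class:`MotionLatencyModel`
is built from epoched data (or simulated via :meth:`from_simulation`), its
:meth:`fit` runs the full decoding/latency analysis and returns a
:class:`MotionLatencyResults` carrying the latency lines, their comparison
(the slope difference, the intercept difference — the recovered extrapolation
shift — and the mean line distance), diagnostics and a ``summary()`` table.
Group-level aggregation across participants and the eye-position control
analysis are provided as functions over those objects.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from . import decode, latfit, permstat, poslik, prep
from .hexgeom import GridSpec, TrajectorySpec
from .synthgen import EpochArray, NoiseSpec, SimConfig, SimulatedDataset, simulate_dataset

__all__ = [
    "RunConfig",
    "MotionLatencyModel",
    "MotionLatencyResults",
    "RunReport",
    "run_all",
    "gaze_control",
]


@dataclass
class RunConfig:
    """Nested configuration for a full run; round-trips through YAML."""

    sim: SimConfig = field(default_factory=SimConfig)
    decoder: decode.DecoderSpec = field(default_factory=decode.DecoderSpec)
    r2_cutoff: float = latfit.ADJ_R2_CUTOFF
    knot_candidates: tuple = latfit.KNOT_CANDIDATES
    n_boot: int = 1000
    n_perm: int = permstat.DEFAULT_N_PERM
    trim: float = permstat.DEFAULT_TRIM
    cluster_alpha: float = permstat.CLUSTER_ALPHA
    run_stats: bool = True
    n_participants: int = 1
    seed: int = 0

    @classmethod
    def desk_scale(cls, **overrides) -> "RunConfig":
        """Reduced problem size for interactive use: one session with 15
        static repetitions per position and 5 per motion vector, 32 channels,
        200 permutations/bootstrap resamples."""
        sim = SimConfig(n_sessions=1, static_reps=15, motion_reps=5, n_channels=32)
        cfg = cls(sim=sim, n_boot=200, n_perm=200)
        return replace(cfg, **overrides)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["sim"]["noise"]["spatial_mix"] is not None:
            d["sim"]["noise"]["spatial_mix"] = np.asarray(
                d["sim"]["noise"]["spatial_mix"]).tolist()
        for k in ("latencies_ms", "widths_ms", "gains"):
            d["sim"][k] = list(d["sim"][k])
        for k in ("train_window_ms", "static_test_window_ms"):
            d["decoder"][k] = list(d["decoder"][k])
        d["knot_candidates"] = list(d["knot_candidates"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = dict(d.pop("sim"))
        noise = dict(sim.pop("noise"))
        if noise.get("spatial_mix") is not None:
            noise["spatial_mix"] = np.asarray(noise["spatial_mix"])
        for k in ("latencies_ms", "widths_ms", "gains"):
            sim[k] = tuple(sim[k])
        dec = dict(d.pop("decoder"))
        for k in ("train_window_ms", "static_test_window_ms"):
            dec[k] = tuple(dec[k])
        d["knot_candidates"] = tuple(d["knot_candidates"])
        return cls(sim=SimConfig(noise=NoiseSpec(**noise), **sim),
                   decoder=decode.DecoderSpec(**dec), **d)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "RunConfig":
        try:
            with open(source) as fh:
                d = yaml.safe_load(fh)
        except (OSError, ValueError):
            d = yaml.safe_load(source)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------


@dataclass
class MotionLatencyResults:
    """Fitted latency analysis for one participant (or dataset).

    The headline quantity is ``comparison.intercept_diff_ms``: how much
    earlier position representations are activated for moving than for static
    stimuli within the feedforward window.  In a simulation this recovers the
    generative extrapolation shift.
    """

    config: RunConfig
    static_line: latfit.LatencyLine
    motion_line: latfit.LatencyLine
    comparison: latfit.LineComparison
    feedforward_window_ms: tuple[float, float]
    piecewise: latfit.PiecewiseFit
    static_peaks: latfit.PeakSeries
    motion_peaks: latfit.PeakSeries
    gaussian_fits: list
    static_tgm: np.ndarray
    motion_tgm: np.ndarray
    train_times_ms: np.ndarray
    static_test_times_ms: np.ndarray
    motion_test_times_ms: np.ndarray
    chance: float
    rejections: dict
    static_score: decode.PairwiseScore | None = None
    motion_score: decode.PairwiseScore | None = None
    static_null: permstat.NullDistribution | None = None
    motion_null: permstat.NullDistribution | None = None
    truth_extrap_shift_ms: float | None = None

    def summary(self) -> str:
        c = self.comparison
        w = self.feedforward_window_ms
        lines = [
            "Motion extrapolation latency analysis",
            "=" * 53,
            f"positions: {int(round(1 / self.chance)):d}    "
            f"training times: {self.train_times_ms.size}    chance: {self.chance:.6f}",
            f"feedforward window: {w[0]:.1f} - {w[1]:.1f} ms "
            f"(piecewise fit, {self.piecewise.n_knots} knots, "
            f"adj R2 = {self.piecewise.adj_r2:.3f})",
            "-" * 53,
            "condition   slope        intercept (ms)       n",
        ]
        for ln in (self.static_line, self.motion_line):
            lines.append(f"{ln.condition:<10s}  {ln.slope:6.3f}       "
                         f"{ln.intercept_ms:8.1f}        {ln.n:4d}")
        lines += [
            "-" * 53,
            f"slope difference (motion - static): {c.slope_diff: .3f}"
            + (f"   (t = {c.slope_diff_t:.2f}, p = {c.slope_diff_p:.3g})"
               if np.isfinite(c.slope_diff_t) else ""),
            f"intercept difference (static - motion, common slope): "
            f"{c.intercept_diff_ms: .1f} ms"
            + (f"   (t = {c.intercept_diff_t:.2f}, p = {c.intercept_diff_p:.3g})"
               if np.isfinite(c.intercept_diff_t) else ""),
            f"mean line distance over window: {c.mean_distance_ms: .1f} ms",
        ]
        if self.truth_extrap_shift_ms is not None:
            lines.append(f"generative extrapolation shift: "
                         f"{self.truth_extrap_shift_ms:.1f} ms")
        return "\n".join(lines)

    def plot_tgm(self, which: str = "motion", ax=None):
        """Temporal generalisation matrix (chance subtracted)."""
        import matplotlib.pyplot as plt

        tgm = self.motion_tgm if which == "motion" else self.static_tgm
        tt = self.motion_test_times_ms if which == "motion" else self.static_test_times_ms
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(tgm - self.chance, origin="lower", aspect="auto",
                       extent=[tt[0], tt[-1], self.train_times_ms[0],
                               self.train_times_ms[-1]], cmap="RdBu_r")
        ax.set_xlabel("test time (ms)")
        ax.set_ylabel("training time (ms)")
        ax.figure.colorbar(im, ax=ax, label="likelihood - chance")
        return ax

    def plot_latency(self, ax=None):
        """Peak latency vs training time with both fitted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs, ys = self.static_peaks.selected()
        xm, ym = self.motion_peaks.selected()
        ax.plot(xs, ys, "o", color="seagreen", ms=4, label="static")
        ax.plot(xm, ym, "o", color="darkorange", ms=4, label="motion")
        w = np.array(self.feedforward_window_ms)
        ax.plot(w, self.static_line.predict(w), color="seagreen")
        ax.plot(w, self.motion_line.predict(w), color="darkorange")
        ax.axline((0, 0), slope=1, ls=":", color="grey", lw=1)
        ax.set_xlabel("training time (ms)")
        ax.set_ylabel("time of peak likelihood (ms)")
        ax.legend()
        return ax

    def to_report_dict(self) -> dict:
        c = self.comparison
        return {
            "slope_static": self.static_line.slope,
            "intercept_static_ms": self.static_line.intercept_ms,
            "slope_motion": self.motion_line.slope,
            "intercept_motion_ms": self.motion_line.intercept_ms,
            "slope_diff": c.slope_diff,
            "intercept_diff_ms": c.intercept_diff_ms,
            "mean_distance_ms": c.mean_distance_ms,
            "feedforward_window_ms": list(self.feedforward_window_ms),
            "n_knots": int(self.piecewise.n_knots),
            "rejections": {k: {"n_rejected": len(v.rejected_indices),
                               "fraction": v.fraction_rejected}
                           for k, v in self.rejections.items()},
        }


class MotionLatencyModel:
    """Latency analysis of position decoding for static vs. moving stimuli.

    Parameters
    ----------
    static, motion
        Epoched EEG (trials x channels x samples) labelled with position ids
        (static) or trajectory ids (motion).
    grid, trajectories
        The stimulus geometry the labels refer to.
    gaze
        Two-channel gaze epochs aligned to the static trials (used for
        fixation-based rejection; optional).
    """

    def __init__(self, static: EpochArray, motion: EpochArray, grid: GridSpec,
                 trajectories: list[TrajectorySpec], gaze: EpochArray | None = None,
                 config: RunConfig | None = None,
                 truth_extrap_shift_ms: float | None = None):
        self.static = static
        self.motion = motion
        self.grid = grid
        self.trajectories = trajectories
        self.gaze = gaze
        self.config = config or RunConfig()
        self.truth_extrap_shift_ms = truth_extrap_shift_ms

    @classmethod
    def from_simulation(cls, config: RunConfig, seed: int | None = None
                        ) -> "MotionLatencyModel":
        ds = simulate_dataset(config.sim, config.seed if seed is None else seed)
        return cls(ds.static, ds.motion, ds.grid, ds.trajectories, ds.gaze,
                   config, truth_extrap_shift_ms=ds.config.extrap_shift_ms)

    # -- preprocessing ------------------------------------------------------

    def _prep_static(self):
        rejections = {}
        st = self.static
        gz = self.gaze
        refs = st.meta.get("ref_channels")
        if refs is not None:
            st = prep.rereference(st, tuple(refs)[:2])
            keep_ch = [c for c in range(st.n_channels) if c not in refs]
            st.data = st.data[:, keep_ch, :]
        st = prep.baseline_correct(st)
        if gz is not None:
            fix = prep.reject_by_fixation(gz)
            rejections["fixation"] = fix
            keep = fix.kept_indices()
            st = st.subset(keep)
            gz = gz.subset(keep)
        sd = prep.reject_epochs_by_sd(st, prep.SD_Z_STATIC)
        rejections["static_sd"] = sd
        st = st.subset(sd.kept_indices())
        if gz is not None:
            gz = gz.subset(sd.kept_indices())
        st = prep.demean_by_condition(st, "all")
        return st, gz, rejections

    def _prep_motion(self):
        mo = self.motion
        refs = mo.meta.get("ref_channels")
        if refs is not None:
            mo = prep.rereference(mo, tuple(refs)[:2])
            keep_ch = [c for c in range(mo.n_channels) if c not in refs]
            mo.data = mo.data[:, keep_ch, :]
        mo = prep.baseline_correct(mo)
        sd = prep.reject_epochs_by_sd(mo, prep.SD_Z_MOTION)
        mo = mo.subset(sd.kept_indices())
        n_cross = {t.traj_id: t.n_crossings for t in self.trajectories}
        keys = np.array([n_cross[int(t)] for t in mo.labels])
        mo = prep.demean_by_condition(mo, "keys", keys)
        return mo, sd

    # -- fitting ------------------------------------------------------------

    def fit(self, keep_scores: bool = False) -> MotionLatencyResults:
        cfg = self.config
        static, gaze, rejections = self._prep_static()
        motion, motion_sd = self._prep_motion()
        rejections["motion_sd"] = motion_sd

        score_s = decode.pairwise_cv_static(static, cfg.decoder)
        clf = decode.train_pairwise_full(static, cfg.decoder, keep_covariance=False)
        aligned = decode.crossing_epochs(motion, self.trajectories)
        score_m = decode.test_pairwise_on_motion(clf, aligned, cfg.decoder.score_mode)

        lik_s = poslik.likelihood_from_scores(score_s)
        lik_m = poslik.likelihood_from_scores(score_m)
        tgm_s = poslik.stimulus_position_likelihood(lik_s)
        tgm_m = poslik.stimulus_position_likelihood(lik_m)

        static_peaks = latfit.static_peak_times(tgm_s, score_s.train_times_ms,
                                                score_s.test_times_ms)
        motion_peaks, gfits = latfit.motion_peak_times(
            tgm_m, score_m.train_times_ms, score_m.test_times_ms, cfg.r2_cutoff)

        xm, ym = motion_peaks.selected()
        pw = latfit.select_knot_count(xm, ym, cfg.knot_candidates)
        window = latfit.feedforward_window(pw)

        in_win_m = motion_peaks.included & \
            (motion_peaks.train_times_ms >= window[0]) & \
            (motion_peaks.train_times_ms <= window[1])
        in_win_s = (static_peaks.train_times_ms >= window[0]) & \
            (static_peaks.train_times_ms <= window[1])
        static_line = latfit.fit_latency_line(
            static_peaks.train_times_ms[in_win_s],
            static_peaks.peak_times_ms[in_win_s], "static")
        motion_line = latfit.fit_latency_line(
            motion_peaks.train_times_ms[in_win_m],
            motion_peaks.peak_times_ms[in_win_m], "motion")
        comparison = latfit.compare_lines(static_line, motion_line, window)

        null_s = null_m = None
        if cfg.run_stats and cfg.n_perm > 0:
            null_s = permstat.permutation_null(score_s, cfg.n_perm, cfg.seed)
            null_m = permstat.permutation_null(score_m, cfg.n_perm, cfg.seed + 1)

        return MotionLatencyResults(
            config=cfg, static_line=static_line, motion_line=motion_line,
            comparison=comparison, feedforward_window_ms=window, piecewise=pw,
            static_peaks=static_peaks, motion_peaks=motion_peaks,
            gaussian_fits=gfits, static_tgm=tgm_s, motion_tgm=tgm_m,
            train_times_ms=score_s.train_times_ms,
            static_test_times_ms=score_s.test_times_ms,
            motion_test_times_ms=score_m.test_times_ms,
            chance=1.0 / score_s.k, rejections=rejections,
            static_score=score_s if keep_scores else None,
            motion_score=score_m if keep_scores else None,
            static_null=null_s, motion_null=null_m,
            truth_extrap_shift_ms=self.truth_extrap_shift_ms)


# ---------------------------------------------------------------------------
# group-level orchestration


@dataclass
class RunReport:
    """Machine-readable summary of a full (possibly multi-participant) run."""

    config: dict
    seed: int
    n_participants: int
    participant_results: list
    group: dict
    gaze: dict | None
    timings_s: dict

    def to_json(self, path=None) -> str:
        text = json.dumps({
            "config": self.config, "seed": self.seed,
            "n_participants": self.n_participants,
            "participants": self.participant_results, "group": self.group,
            "gaze": self.gaze, "timings_s": self.timings_s}, indent=2,
            default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _participant_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence([int(seed), 0xA27])
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_all(config: RunConfig, seed: int | None = None) -> RunReport:
    """Run the complete pipeline for ``config.n_participants`` simulated
    participants and aggregate group-level latency results and statistics."""
    seed = config.seed if seed is None else int(seed)
    t0 = time.time()
    timings = {}
    seeds = _participant_seeds(seed, config.n_participants)
    results: list[MotionLatencyResults] = []
    obs_motion, null_motion = [], []
    for ps in seeds:
        model = MotionLatencyModel.from_simulation(config, seed=ps)
        res = model.fit(keep_scores=config.run_stats)
        if config.run_stats and res.motion_score is not None:
            obs_motion.append(permstat.observed_diag_likelihood(res.motion_score))
            null_motion.append(res.motion_null.values)
            res.static_score = res.motion_score = None  # free memory
        results.append(res)
    timings["fit_s"] = time.time() - t0

    group: dict = {}
    tgm_m = np.mean([r.motion_tgm for r in results], axis=0)
    tgm_s = np.mean([r.static_tgm for r in results], axis=0)
    r0 = results[0]
    static_peaks = latfit.static_peak_times(tgm_s, r0.train_times_ms,
                                            r0.static_test_times_ms)
    motion_peaks, _ = latfit.motion_peak_times(tgm_m, r0.train_times_ms,
                                               r0.motion_test_times_ms,
                                               config.r2_cutoff)
    xm, ym = motion_peaks.selected()
    pw = latfit.select_knot_count(xm, ym, config.knot_candidates)
    window = latfit.feedforward_window(pw)
    in_m = motion_peaks.included & (motion_peaks.train_times_ms >= window[0]) \
        & (motion_peaks.train_times_ms <= window[1])
    in_s = (static_peaks.train_times_ms >= window[0]) \
        & (static_peaks.train_times_ms <= window[1])
    sline = latfit.fit_latency_line(static_peaks.train_times_ms[in_s],
                                    static_peaks.peak_times_ms[in_s], "static")
    mline = latfit.fit_latency_line(motion_peaks.train_times_ms[in_m],
                                    motion_peaks.peak_times_ms[in_m], "motion")
    comp = latfit.compare_lines(sline, mline, window)
    group.update({
        "feedforward_window_ms": list(window),
        "slope_static": sline.slope, "intercept_static_ms": sline.intercept_ms,
        "slope_motion": mline.slope, "intercept_motion_ms": mline.intercept_ms,
        "slope_diff": comp.slope_diff,
        "intercept_diff_ms": comp.intercept_diff_ms,
        "mean_distance_ms": comp.mean_distance_ms,
    })
    if config.run_stats and len(obs_motion) >= 5:
        cres = permstat.group_significance(np.asarray(obs_motion),
                                           np.asarray(null_motion),
                                           config.trim, config.cluster_alpha,
                                           r0.train_times_ms)
        group["significant_clusters_motion_diag"] = [
            {"start_ms": c.start_ms, "end_ms": c.end_ms, "mass": c.mass, "p": c.p}
            for c in cres.significant()]
    timings["group_s"] = time.time() - t0 - timings["fit_s"]
    return RunReport(config.to_dict(), seed, config.n_participants,
                     [r.to_report_dict() for r in results], group, None, timings)


def gaze_control(config: RunConfig, seed: int | None = None,
                 datasets: list | None = None) -> dict:
    """Eye-position control: the identical decode/likelihood/stats chain
    applied to the 2-channel gaze traces of static trials.

    Returns a report section with the group-level cluster result; with no
    pursuit component in the gaze (``pursuit_gain = 0``) no timepoint should
    survive correction.  ``datasets`` substitutes pre-built participant
    datasets for fresh simulations.
    """
    seed = config.seed if seed is None else int(seed)
    if datasets is None:
        seeds = _participant_seeds(seed, config.n_participants)
        datasets = [simulate_dataset(config.sim, ps) for ps in seeds]
    observed, nulls = [], []
    for i, ds in enumerate(datasets):
        if ds.gaze is None:
            raise ValueError("dataset has no /gaze group: gaze traces are "
                             "required for the eye-position control")
        score = decode.pairwise_cv_static(ds.gaze, config.decoder)
        observed.append(permstat.observed_diag_likelihood(score))
        nulls.append(permstat.permutation_null(score, config.n_perm,
                                               seed + i).values)
    observed = np.asarray(observed)
    nulls = np.asarray(nulls)
    cres = permstat.group_significance(observed, nulls, config.trim,
                                       config.cluster_alpha)
    sig = cres.significant()
    return {
        "n_participants": len(seeds),
        "n_perm": config.n_perm,
        "any_significant": bool(sig),
        "clusters": [{"start": c.start_ms, "end": c.end_ms, "p": c.p}
                     for c in cres.clusters],
        "mean_observed": float(observed.mean()),
    }
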