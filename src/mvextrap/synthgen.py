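"""Synthetic EEG generator with a known motion-extrapolation shift.

The forward model emulates the statistical structure that the decoding
analysis assumes to be present in the recorded data:

* a cascade of stimulus-evoked components, each with its own latency,
  temporal width, gain and position-specific channel topography.  Topographies
  are drawn from a Gaussian process over the 2-D grid, so nearby positions
  evoke correlated patterns (the retinotopy premise: pairwise decodability
  grows with position separation);
* an extrapolation shift ``delta_ms``: during motion every component expresses
  the topography of the stimulus position at ``t - latency + delta``, i.e. the
  represented position of a moving stimulus is advanced along the trajectory.
  ``delta = 0`` means each stage carries its full accumulated lag;
  ``delta = latency_1`` makes the first stage real-time aligned;
* spatially mixed AR(1) noise and fixational gaze jitter with an optional
  smooth-pursuit component.

The generator is deterministic under a seed and stores its true parameters so
that the full pipeline can be run as a parameter-recovery experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import ConvexHull

from .hexgeom import (DEFAULT_SPACING_DVA, GridSpec, TrajectorySpec, TrialSchedule,
                      build_grid, build_schedule, enumerate_trajectories)

__all__ = [
    "EpochArray",
    "Component",
    "NoiseSpec",
    "ForwardModel",
    "SimConfig",
    "SimulatedDataset",
    "make_topographies",
    "build_forward_model",
    "simulate_static_epoch",
    "simulate_motion_epoch",
    "simulate_gaze",
    "simulate_dataset",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class EpochArray:
    """Epoched multi-channel time series.

    data : (n_trials, n_channels, n_samples), nominal microvolts (dva for gaze)
    times_ms : sample times relative to the alignment event
    labels : per-trial position id (static/gaze/aligned) or trajectory id (motion)
    """

    data: np.ndarray
    times_ms: np.ndarray
    labels: np.ndarray
    srate_hz: float
    kind: str  # static | motion | gaze | motion_aligned
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[2] != self.times_ms.size:
            raise ValueError("times_ms length must match sample count")
        if self.data.shape[0] != self.labels.size:
            raise ValueError("labels length must match trial count")
        dt = np.diff(self.times_ms)
        if dt.size and not np.allclose(dt, 1000.0 / self.srate_hz, atol=1e-6):
            raise ValueError("times_ms must be uniformly spaced at the sampling rate")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochArray":
        return EpochArray(self.data.copy(), self.times_ms.copy(), self.labels.copy(),
                          self.srate_hz, self.kind, dict(self.meta))

    def time_index(self, t_ms: float) -> int:
        """Index of the sample nearest to ``t_ms``."""
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def subset(self, idx) -> "EpochArray":
        idx = np.asarray(idx)
        return EpochArray(self.data[idx], self.times_ms.copy(), self.labels[idx],
                          self.srate_hz, self.kind, dict(self.meta))

    def to_mne(self, ch_names=None):
        """Convert to an :class:`mne.EpochsArray` (volts)."""
        import mne

        ch_names = ch_names or [f"ch{i}" for i in range(self.n_channels)]
        info = mne.create_info(ch_names, sfreq=self.srate_hz, ch_types="eeg")
        return mne.EpochsArray(self.data * 1e-6, info, tmin=self.times_ms[0] / 1000.0,
                               verbose="error")


def sample_times(window_ms: tuple[float, float], srate_hz: float) -> np.ndarray:
    """Uniform sample grid covering ``window_ms`` (inclusive) at ``srate_hz``."""
    n0 = int(np.floor(window_ms[0] * srate_hz / 1000.0))
    n1 = int(np.ceil(window_ms[1] * srate_hz / 1000.0))
    return np.arange(n0, n1 + 1) * (1000.0 / srate_hz)


# ---------------------------------------------------------------------------
# forward model


@dataclass
class Component:
    """One stage of the evoked cascade.

    ``topo`` holds the topographies of the grid positions.  ``topo_field``
    (optional) extends the same Gaussian-process draw to lattice points beyond
    the grid, so that a moving stimulus outside the grid expresses its own
    smoothly continued topography rather than a frozen copy of the nearest
    edge position (retinotopy does not stop at the outermost flash position).
    Its first ``n_positions`` rows coincide with ``topo``.
    """

    latency_ms: float
    width_ms: float
    gain: float
    topo: np.ndarray  # (n_positions, n_channels), rows unit norm
    topo_field: np.ndarray | None = None  # (n_field_points, n_channels)
    #: flash-evoked only: feedback reactivations ride on the static response
    #: but are not re-expressed by the moving stimulus (the late flash-evoked
    #: signal reflects reactivation of earlier patterns, which is what lets
    #: static-trained classifiers at late training times still generalise to
    #: the feedforward motion response)
    static_only: bool = False


@dataclass
class NoiseSpec:
    """Additive sensor noise: spatially mixed AR(1) processes.

    ``white_sd`` is the stationary per-channel standard deviation (uV);
    ``spatial_corr`` the common pairwise channel correlation induced by the
    default mixing matrix (overridden by an explicit ``spatial_mix``).
    """

    white_sd: float = 4.0
    ar1_coef: float = 0.3
    spatial_corr: float = 0.2
    spatial_mix: np.ndarray | None = None

    def mixing(self, n_channels: int) -> np.ndarray:
        if self.spatial_mix is not None:
            m = np.asarray(self.spatial_mix, dtype=float)
            if m.shape != (n_channels, n_channels):
                raise ValueError("spatial_mix shape mismatch")
            return m
        c = float(self.spatial_corr)
        cov = (1.0 - c) * np.eye(n_channels) + c * np.ones((n_channels, n_channels))
        return np.linalg.cholesky(cov)


@dataclass
class ForwardModel:
    """Generative model mapping stimulus position/time to channel data."""

    grid: GridSpec
    components: list[Component]
    extrap_shift_ms: float = 0.0
    srate_hz: float = 128.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_ref_channels: int = 2  # trailing all-zero mastoid reference channels
    field_xy: np.ndarray | None = None  # lattice carrying topo_field rows
    rolloff_dva: float = DEFAULT_SPACING_DVA  # peripheral amplitude rolloff scale

    def __post_init__(self):
        lats = [c.latency_ms for c in self.components]
        if any(b <= a for a, b in zip(lats, lats[1:])):
            raise ValueError("component latencies must be strictly increasing")
        for c in self.components:
            if c.topo.shape[0] != self.grid.n_positions:
                raise ValueError("topography rows must match grid positions")
            norms = np.linalg.norm(c.topo, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("topography rows must have unit norm")

    @property
    def n_signal_channels(self) -> int:
        return self.components[0].topo.shape[1]

    @property
    def n_channels(self) -> int:
        return self.n_signal_channels + self.n_ref_channels

    @property
    def ref_channels(self) -> tuple[int, int]:
        n = self.n_signal_channels
        return tuple(range(n, n + self.n_ref_channels))


# Pattern structure across positions has two parts: a stochastic local GP
# (scale ``smoothness_dva``) for fine position tuning, and two smooth global
# gradient patterns (random orthonormal channel loadings multiplied by the x
# and y stimulus coordinates) emulating coarse retinotopic organisation —
# hemifield and eccentricity.  The gradients keep pattern separation growing
# out to the largest position separations (a stationary kernel saturates
# after a few length scales) and, being linear in position, they flip the
# pairwise discriminant exactly at the pair midline, adding no asymmetry to
# the motion likelihood bumps.  The weight is the gradient amplitude relative
# to the GP at the edge of the field.
TOPO_GRADIENT_WEIGHT = 1.5


def _topography_field(xy: np.ndarray, n_channels: int, smoothness_dva: float,
                      seed) -> np.ndarray:
    """GP-plus-gradients draw of channel topographies, unit-norm rows."""
    rng = np.random.default_rng(seed)
    d = xy[:, None, :] - xy[None, :, :]
    D2 = d[..., 0] ** 2 + d[..., 1] ** 2
    K = np.exp(-D2 / (2.0 * smoothness_dva ** 2)) + 1e-9 * np.eye(xy.shape[0])
    L = np.linalg.cholesky(K)
    T = L @ rng.standard_normal((xy.shape[0], n_channels))
    Q = np.linalg.qr(rng.standard_normal((n_channels, 2)))[0]  # (ch, 2)
    radius = float(np.max(np.hypot(xy[:, 0], xy[:, 1]))) or 1.0
    T = T + (xy @ Q.T) * (TOPO_GRADIENT_WEIGHT * np.sqrt(n_channels) / radius)
    T /= np.linalg.norm(T, axis=1, keepdims=True)
    return T


def make_topographies(grid: GridSpec, n_channels: int, smoothness_dva: float = 5.0,
                      seed=0) -> np.ndarray:
    """Draw position-specific channel topographies over the grid.

    Each channel combines an independent draw from a zero-mean Gaussian
    process (squared-exponential kernel, scale ``smoothness_dva``) with two
    smooth global gradient patterns in x and y (coarse retinotopy), so row
    (position) similarity decays with inter-position distance and pattern
    separation keeps growing out to the largest separations.  Rows are unit
    norm.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    return _topography_field(grid.xy, n_channels, smoothness_dva, seed)


def _extended_lattice(grid: GridSpec, ext_rings: int) -> np.ndarray:
    """Lattice points of the grid plus ``ext_rings`` surrounding rings,
    ordered so the first ``grid.n_positions`` rows are the grid positions."""
    big = build_grid(grid.ring_count + ext_rings, grid.spacing_dva)
    key = {tuple(np.round(p, 6)) for p in grid.xy}
    outside = np.array([i for i, p in enumerate(big.xy)
                        if tuple(np.round(p, 6)) not in key])
    return np.vstack([grid.xy, big.xy[outside]])


# Quasi-continuous feedforward cascade: stages every 20 ms whose widths
# overlap, so the dominant position representation drifts smoothly with
# latency (a discrete 2-3 stage cascade instead produces a staircase of
# preferred latencies, which neither the real visual hierarchy nor the
# latency analysis assumes).  Gains are equal across stages: with the broad
# position tuning of motion responses, unequal gains skew the multi-stage
# mixture towards the stronger stages and bias fitted peak latencies.
DEFAULT_LATENCIES_MS = tuple(50.0 + 10.0 * k for k in range(13))  # 50..170 ms
DEFAULT_WIDTHS_MS = (15.0,) * 13
DEFAULT_GAINS = (4.0,) * 13
# After the feedforward sweep the same stage patterns reactivate in reverse
# order (information flowing back down the hierarchy): stage k's topography
# reappears at FEEDBACK_MIRROR_MS - latency_k with a weaker gain.  This gives
# the peak-latency series its rise-then-fall shape, whose turning point the
# piecewise regression identifies as the end of the feedforward sweep.
FEEDBACK_MIRROR_MS = 360.0
DEFAULT_FEEDBACK_GAIN = 2.0


def build_forward_model(
    grid: GridSpec,
    n_channels: int = 64,
    latencies_ms=DEFAULT_LATENCIES_MS,
    widths_ms=DEFAULT_WIDTHS_MS,
    gains=DEFAULT_GAINS,
    smoothness_dva: float = 5.0,
    extrap_shift_ms: float = 0.0,
    srate_hz: float = 128.0,
    noise: NoiseSpec | None = None,
    seed=0,
    ext_rings: int = 3,
    rolloff_dva: float | None = None,
    feedback_gain: float = 0.0,
    feedback_mirror_ms: float = FEEDBACK_MIRROR_MS,
) -> ForwardModel:
    """Construct a ForwardModel with GP topographies, one draw per component.

    The GP field is drawn over the grid extended by ``ext_rings`` lattice
    rings, so that motion simulation has principled topographies for stimulus
    positions beyond the outermost flash position (the default covers the
    7 dva lead distance of the trajectories).  With ``feedback_gain > 0``
    every stage's topography is reactivated at the mirrored latency
    ``feedback_mirror_ms - latency`` (reverse order, weaker gain).
    """
    ss = np.random.SeedSequence([_as_seed_int(seed), 0x70F0])
    field_xy = _extended_lattice(grid, ext_rings) if ext_rings > 0 else grid.xy
    comps = []
    for lam, w, g, child in zip(latencies_ms, widths_ms, gains, ss.spawn(len(latencies_ms))):
        f = _topography_field(field_xy, n_channels, smoothness_dva, child)
        comps.append(Component(float(lam), float(w), float(g),
                               topo=f[: grid.n_positions], topo_field=f))
    if feedback_gain > 0:
        for c in list(comps):
            lam_fb = float(feedback_mirror_ms) - c.latency_ms
            if lam_fb <= c.latency_ms:
                continue
            comps.append(Component(lam_fb, c.width_ms, float(feedback_gain),
                                   topo=c.topo, topo_field=c.topo_field,
                                   static_only=True))
    comps.sort(key=lambda c: c.latency_ms)
    return ForwardModel(grid=grid, components=comps, extrap_shift_ms=float(extrap_shift_ms),
                        srate_hz=float(srate_hz), noise=noise or NoiseSpec(),
                        field_xy=field_xy,
                        rolloff_dva=grid.spacing_dva if rolloff_dva is None
                        else float(rolloff_dva))


def _as_seed_int(seed) -> int:
    if isinstance(seed, (int, np.integer)):
        return int(seed)
    return int(np.random.default_rng(seed).integers(0, 2**31 - 1))


# ---------------------------------------------------------------------------
# noise


def ar1_noise(rng: np.random.Generator, shape_ct: tuple[int, int], coef: float,
              sd: float) -> np.ndarray:
    """Stationary AR(1) noise, marginal SD ``sd``, shape (channels, samples)."""
    if not 0.0 <= coef < 1.0:
        raise ValueError("ar1_coef must be in [0, 1)")
    burn = 64
    w = rng.standard_normal((shape_ct[0], shape_ct[1] + burn))
    x = sps.lfilter([np.sqrt(1.0 - coef**2)], [1.0, -coef], w, axis=-1)
    return sd * x[:, burn:]


def _trial_noise(rng, model: ForwardModel, n_samples: int) -> np.ndarray:
    n_sig = model.n_signal_channels
    eps = ar1_noise(rng, (n_sig, n_samples), model.noise.ar1_coef, model.noise.white_sd)
    mixed = model.noise.mixing(n_sig) @ eps
    out = np.zeros((model.n_channels, n_samples))
    out[:n_sig] = mixed
    return out  # reference channels stay zero (already-referenced recording)


# ---------------------------------------------------------------------------
# signal synthesis


def _component_envelope(times_ms: np.ndarray, comp: Component) -> np.ndarray:
    return comp.gain * np.exp(-((times_ms - comp.latency_ms) ** 2) / (2.0 * comp.width_ms ** 2))


def static_signal(model: ForwardModel, position_id: int, times_ms: np.ndarray) -> np.ndarray:
    """Noiseless evoked response to a flash at ``position_id`` (channels x samples)."""
    if not 0 <= position_id < model.grid.n_positions:
        raise ValueError(f"unknown position id {position_id}")
    sig = np.zeros((model.n_channels, times_ms.size))
    for comp in model.components:
        env = _component_envelope(times_ms, comp)
        sig[: model.n_signal_channels] += comp.topo[position_id][:, None] * env[None, :]
    return sig


STATIC_EPOCH_WINDOW_MS = (-100.0, 350.0)


def simulate_static_epoch(model: ForwardModel, position_id: int,
                          epoch_window_ms: tuple[float, float] = STATIC_EPOCH_WINDOW_MS,
                          seed=0) -> EpochArray:
    """Single static-flash trial: evoked cascade plus noise."""
    times = sample_times(epoch_window_ms, model.srate_hz)
    rng = np.random.default_rng(seed)
    data = static_signal(model, position_id, times) + _trial_noise(rng, model, times.size)
    return EpochArray(data[None], times, np.array([position_id]), model.srate_hz, "static")


class _TopoInterpolator:
    """Barycentric interpolation of a topography map over the lattice plane.

    Inside the convex hull of the supplied points the value at a continuous
    position is the barycentric (piecewise-linear) interpolation of the three
    surrounding lattice topographies.  Outside, the query point is projected
    onto the nearest point of the hull boundary first (with the extended
    topography field of :func:`build_forward_model` this only concerns the
    far corners of trajectory lead-in segments).
    """

    def __init__(self, xy: np.ndarray, values: np.ndarray):
        self._interp = LinearNDInterpolator(xy, values)
        hull = ConvexHull(xy)
        self._hull_pts = xy[hull.vertices]
        self._centroid = xy.mean(axis=0)

    def _project_to_hull(self, pts: np.ndarray) -> np.ndarray:
        P = self._hull_pts
        nv = len(P)
        best = np.full(pts.shape[0], np.inf)
        proj = np.empty_like(pts)
        for a in range(nv):
            p0, p1 = P[a], P[(a + 1) % nv]
            d = p1 - p0
            t = np.clip(((pts - p0) @ d) / (d @ d), 0.0, 1.0)
            cand = p0 + t[:, None] * d
            dist = np.einsum("ij,ij->i", pts - cand, pts - cand)
            upd = dist < best
            best[upd] = dist[upd]
            proj[upd] = cand[upd]
        # nudge inward so the linear interpolant is defined on the boundary
        return proj + 1e-9 * (self._centroid - proj)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        out = self._interp(pts)
        bad = np.isnan(out[..., 0]) if out.ndim > 1 else np.isnan(out)
        if np.any(bad):
            out[bad] = self._interp(self._project_to_hull(pts[bad]))
        return out


def _component_interpolator(model: ForwardModel, comp: Component) -> _TopoInterpolator:
    if comp.topo_field is not None and model.field_xy is not None:
        return _TopoInterpolator(model.field_xy, comp.topo_field)
    return _TopoInterpolator(model.grid.xy, comp.topo)


class _HullRolloff:
    """Evoked-amplitude attenuation beyond the stimulus grid.

    Sensor-level responses to far-peripheral stimulation are weak (cortical
    magnification), so while the disc travels its lead-in/lead-out segments
    outside the grid its evoked amplitude is rolled off with a Gaussian
    profile over the distance to the grid's convex hull (scale
    ``rolloff_dva``; unit gain anywhere on or inside the grid).
    """

    def __init__(self, grid: GridSpec, rolloff_dva: float):
        hull = ConvexHull(grid.xy)
        self._pts = grid.xy[hull.vertices]
        self._scale = float(rolloff_dva)
        # hull edge inward normals for inside test
        nv = len(self._pts)
        e = np.roll(self._pts, -1, axis=0) - self._pts
        self._normals = np.stack([-e[:, 1], e[:, 0]], axis=1)
        centroid = grid.xy.mean(axis=0)
        flip = np.einsum("ij,ij->i", self._normals, centroid - self._pts) < 0
        self._normals[flip] *= -1

    def _dist_outside(self, pts: np.ndarray) -> np.ndarray:
        inside = np.all(np.einsum("ej,pej->pe", self._normals,
                                  pts[:, None, :] - self._pts[None]) >= 0, axis=1)
        d = np.zeros(pts.shape[0])
        if np.any(~inside):
            P = self._pts
            nv = len(P)
            best = np.full((~inside).sum(), np.inf)
            q = pts[~inside]
            for a in range(nv):
                p0, p1 = P[a], P[(a + 1) % nv]
                seg = p1 - p0
                t = np.clip(((q - p0) @ seg) / (seg @ seg), 0.0, 1.0)
                cand = p0 + t[:, None] * seg
                best = np.minimum(best, np.hypot(*(q - cand).T))
            d[~inside] = best
        return d

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        if self._scale <= 0:
            return np.ones(pts.shape[0])
        d = self._dist_outside(np.atleast_2d(pts))
        return np.exp(-(d ** 2) / (2.0 * self._scale ** 2))


def motion_signal(model: ForwardModel, traj: TrajectorySpec, times_ms: np.ndarray,
                  interpolators: list[_TopoInterpolator] | None = None) -> np.ndarray:
    """Noiseless response to a moving disc (channels x samples).

    At time ``t`` component ``c`` expresses the topography of the continuous
    stimulus position evaluated at ``t - latency_c + delta``; the component is
    silent while that retarded time falls outside the motion interval, and its
    amplitude rolls off while the stimulus is outside the grid (see
    :class:`_HullRolloff`).
    """
    if interpolators is None:
        interpolators = [_component_interpolator(model, c) for c in model.components]
    rolloff = _HullRolloff(model.grid, model.rolloff_dva)
    sig = np.zeros((model.n_channels, times_ms.size))
    for comp, interp in zip(model.components, interpolators):
        if comp.static_only:
            continue
        tr = times_ms - comp.latency_ms + model.extrap_shift_ms
        present = (tr >= 0.0) & (tr <= traj.duration_ms)
        if not np.any(present):
            continue
        pts = traj.position_at(tr[present])
        topo_t = interp(pts)  # (n_present, n_channels)
        amp = comp.gain * rolloff(pts)
        sig[: model.n_signal_channels, present] += (topo_t * amp[:, None]).T
    return sig


def simulate_motion_epoch(model: ForwardModel, traj: TrajectorySpec, seed=0,
                          pad_to_ms: float | None = None) -> EpochArray:
    """Single motion trial, epoched from 100 ms before onset to 100 ms after offset.

    ``pad_to_ms`` extends the epoch (noise only after motion offset) so that
    trials of different trajectory lengths share one rectangular array.
    """
    end = max(traj.duration_ms, pad_to_ms or 0.0)
    times = sample_times((-100.0, end + 100.0), model.srate_hz)
    rng = np.random.default_rng(seed)
    data = motion_signal(model, traj, times) + _trial_noise(rng, model, times.size)
    return EpochArray(data[None], times, np.array([traj.traj_id]), model.srate_hz, "motion")


def simulate_gaze(schedule: TrialSchedule, grid: GridSpec,
                  jitter_sd_dva: float = 0.4, pursuit_gain: float = 0.0,
                  srate_hz: float = 128.0,
                  epoch_window_ms: tuple[float, float] = STATIC_EPOCH_WINDOW_MS,
                  seed=0) -> EpochArray:
    """Gaze traces (x, y in dva) for the static trials of a schedule.

    gaze = fixation + white jitter + pursuit_gain * stimulus displacement while
    the flash is on screen.  ``pursuit_gain = 0`` encodes no position
    information; ``pursuit_gain = 1`` with zero jitter equals the stimulus
    position during the presentation.
    """
    if not 0.0 <= pursuit_gain <= 1.0:
        raise ValueError("pursuit_gain must be in [0, 1]")
    times = sample_times(epoch_window_ms, srate_hz)
    on = (times >= 0.0) & (times <= 250.0)
    rng = np.random.default_rng(seed)
    statics = [e for e in schedule.entries if e.kind == "static"]
    data = np.empty((len(statics), 2, times.size))
    labels = np.empty(len(statics), dtype=int)
    for i, e in enumerate(statics):
        g = jitter_sd_dva * rng.standard_normal((2, times.size))
        g[:, on] += pursuit_gain * grid.xy[e.stim_id][:, None]
        data[i] = g
        labels[i] = e.stim_id
    return EpochArray(data, times, labels, srate_hz, "gaze")


# ---------------------------------------------------------------------------
# whole-dataset simulation


@dataclass
class SimConfig:
    """Generator configuration.  Defaults reproduce the study conditions
    (3-ring grid, 10.36 dva/s, 6 sessions of 42 static repetitions per
    position and 18 per motion vector, 64 EEG channels at 128 Hz)."""

    rings: int = 3
    velocity_dva_s: float = 10.36
    lead_dva: float = 7.0
    n_channels: int = 64
    latencies_ms: tuple = DEFAULT_LATENCIES_MS
    widths_ms: tuple = DEFAULT_WIDTHS_MS
    gains: tuple = DEFAULT_GAINS
    smoothness_dva: float = 5.0
    rolloff_dva: float | None = None  # default: one grid spacing
    feedback_gain: float = DEFAULT_FEEDBACK_GAIN
    feedback_mirror_ms: float = FEEDBACK_MIRROR_MS
    extrap_shift_ms: float = 0.0
    srate_hz: float = 128.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_sessions: int = 6
    static_reps: int = 42
    motion_reps: int = 18
    jitter_sd_dva: float = 0.4
    pursuit_gain: float = 0.0
    schedule_seed: int | None = None

    @property
    def spacing_dva(self) -> float:
        return self.velocity_dva_s * 0.400


@dataclass
class SimulatedDataset:
    static: EpochArray
    motion: EpochArray
    gaze: EpochArray
    truth: ForwardModel
    grid: GridSpec
    trajectories: list[TrajectorySpec]
    schedule: TrialSchedule
    config: SimConfig


def simulate_dataset(config: SimConfig, seed: int = 0) -> SimulatedDataset:
    """Simulate one participant: static, motion and gaze epochs plus ground truth.

    Bit-identical under the same seed.  The schedule (hence label sequence)
    is controlled by ``config.schedule_seed`` when set, so different dataset
    seeds can share identical trial orderings with fresh noise.
    """
    ss = np.random.SeedSequence([int(seed), 0xD47A])
    s_topo, s_stat, s_mot, s_gaze, s_sched = ss.spawn(5)
    grid = build_grid(config.rings, config.spacing_dva)
    trajs = enumerate_trajectories(grid, config.velocity_dva_s, config.lead_dva)
    sched_seed = config.schedule_seed if config.schedule_seed is not None \
        else _as_seed_int(s_sched)
    schedule = build_schedule(grid, trajs, config.n_sessions, config.static_reps,
                              config.motion_reps, seed=sched_seed)
    model = build_forward_model(
        grid, config.n_channels, config.latencies_ms, config.widths_ms, config.gains,
        config.smoothness_dva, config.extrap_shift_ms, config.srate_hz, config.noise,
        seed=s_topo, rolloff_dva=config.rolloff_dva,
        feedback_gain=config.feedback_gain,
        feedback_mirror_ms=config.feedback_mirror_ms)

    # static trials
    stat_entries = [e for e in schedule.entries if e.kind == "static"]
    times_s = sample_times(STATIC_EPOCH_WINDOW_MS, model.srate_hz)
    clean_static = np.stack([static_signal(model, p, times_s)
                             for p in range(grid.n_positions)])
    rng_s = np.random.default_rng(s_stat)
    Xs = np.empty((len(stat_entries), model.n_channels, times_s.size))
    ys = np.empty(len(stat_entries), dtype=int)
    for i, e in enumerate(stat_entries):
        Xs[i] = clean_static[e.stim_id] + _trial_noise(rng_s, model, times_s.size)
        ys[i] = e.stim_id
    static = EpochArray(Xs, times_s, ys, model.srate_hz, "static",
                        meta={"ref_channels": model.ref_channels})

    # motion trials, padded to the longest trajectory
    mot_entries = [e for e in schedule.entries if e.kind == "motion"]
    max_dur = max(t.duration_ms for t in trajs)
    times_m = sample_times((-100.0, max_dur + 100.0), model.srate_hz)
    interps = [_component_interpolator(model, c) for c in model.components]
    clean_motion = {t.traj_id: motion_signal(model, t, times_m, interps) for t in trajs}
    rng_m = np.random.default_rng(s_mot)
    Xm = np.empty((len(mot_entries), model.n_channels, times_m.size))
    ym = np.empty(len(mot_entries), dtype=int)
    for i, e in enumerate(mot_entries):
        Xm[i] = clean_motion[e.stim_id] + _trial_noise(rng_m, model, times_m.size)
        ym[i] = e.stim_id
    motion = EpochArray(Xm, times_m, ym, model.srate_hz, "motion",
                        meta={"ref_channels": model.ref_channels})

    gaze = simulate_gaze(schedule, grid, config.jitter_sd_dva, config.pursuit_gain,
                         config.srate_hz, seed=s_gaze)
    return SimulatedDataset(static, motion, gaze, model, grid, trajs, schedule, config)
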