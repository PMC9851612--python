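"""Preprocessing of epoched data.

Order of application in the pipeline: mastoid re-referencing, baseline
correction over the 100 ms before onset, fixation-based rejection (static
trials only, strict 2.1 dva threshold), SD-threshold epoch rejection
(z = 4 static, z = 5 motion) and per-condition demeaning.  No filtering is
applied anywhere, to avoid distorting event timing.

Rejection operations never modify data; they return a :class:`RejectionReport`
and the caller subsets the epochs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synthgen import EpochArray

__all__ = [
    "RejectionReport",
    "rereference",
    "baseline_correct",
    "reject_epochs_by_sd",
    "reject_by_fixation",
    "demean_by_condition",
]

SD_Z_STATIC = 4.0
SD_Z_MOTION = 5.0
FIXATION_RADIUS_DVA = 2.1


@dataclass(frozen=True)
class RejectionReport:
    rejected_indices: tuple[int, ...]
    reason: str  # "sd_threshold" | "fixation"
    threshold_used: float
    n_total: int

    @property
    def fraction_rejected(self) -> float:
        return len(self.rejected_indices) / self.n_total if self.n_total else 0.0

    def kept_indices(self) -> np.ndarray:
        mask = np.ones(self.n_total, dtype=bool)
        mask[list(self.rejected_indices)] = False
        return np.flatnonzero(mask)


def rereference(epochs: EpochArray, ref_channel_ids: tuple[int, int]) -> EpochArray:
    """Subtract the mean of the two reference (mastoid) channels from every channel."""
    a, b = ref_channel_ids
    if not (0 <= a < epochs.n_channels and 0 <= b < epochs.n_channels):
        raise ValueError(f"reference channels {ref_channel_ids} not in data "
                         f"({epochs.n_channels} channels)")
    out = epochs.copy()
    ref = 0.5 * (epochs.data[:, a, :] + epochs.data[:, b, :])
    out.data = epochs.data - ref[:, None, :]
    return out


def baseline_correct(epochs: EpochArray,
                     window_ms: tuple[float, float] = (-100.0, 0.0)) -> EpochArray:
    """Subtract the per-trial, per-channel mean over ``window_ms`` (upper bound
    exclusive) from the whole epoch."""
    lo, hi = window_ms
    sel = (epochs.times_ms >= lo) & (epochs.times_ms < hi)
    if not np.any(sel):
        raise ValueError("baseline window contains no samples")
    out = epochs.copy()
    out.data = epochs.data - epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return out


def reject_epochs_by_sd(epochs: EpochArray, z_threshold: float = SD_Z_STATIC) -> RejectionReport:
    """Flag epochs whose amplitude SD is an outlier on any channel.

    For every channel the per-epoch amplitude SD (over the full epoch window)
    is computed; an epoch is rejected when, for any channel, its SD exceeds
    the mean of that channel's per-epoch SDs by more than ``z_threshold``
    channel-wise SDs (strictly greater, so ties are kept).
    """
    if epochs.n_trials < 3:
        raise ValueError("need at least 3 epochs for SD-based rejection")
    sd = epochs.data.std(axis=2)  # (trials, channels)
    m = sd.mean(axis=0)
    s = sd.std(axis=0)
    degenerate = s == 0
    if np.all(degenerate):
        warnings.warn("all epochs identical per channel; no SD rejections")
    limit = m + z_threshold * s
    limit[degenerate] = np.inf
    rej = np.flatnonzero(np.any(sd > limit[None, :], axis=1))
    return RejectionReport(tuple(int(i) for i in rej), "sd_threshold",
                           float(z_threshold), epochs.n_trials)


def reject_by_fixation(gaze: EpochArray, radius_dva: float = FIXATION_RADIUS_DVA,
                       stimulus_window_ms: tuple[float, float] = (0.0, 250.0)) -> RejectionReport:
    """Flag trials where gaze leaves the fixation zone while the stimulus is on.

    A trial is rejected iff any sample within ``stimulus_window_ms`` lies at a
    Euclidean distance strictly greater than ``radius_dva`` from fixation.
    Applied to static trials only; motion trials are never rejected on this
    basis (they are used for testing only).
    """
    if gaze.n_channels != 2:
        raise ValueError("gaze epochs must have exactly 2 channels (x, y)")
    lo, hi = stimulus_window_ms
    sel = (gaze.times_ms >= lo) & (gaze.times_ms <= hi)
    dist = np.hypot(gaze.data[:, 0, sel], gaze.data[:, 1, sel])
    rej = np.flatnonzero(np.any(dist > radius_dva, axis=1))
    return RejectionReport(tuple(int(i) for i in rej), "fixation",
                           float(radius_dva), gaze.n_trials)


def demean_by_condition(epochs: EpochArray, grouping: str = "all",
                        group_keys: np.ndarray | None = None) -> EpochArray:
    """Subtract the across-trial mean time course (channel x sample) per group.

    ``grouping="all"`` pools every trial into one group (static trials: the
    average across all stimulus locations).  ``grouping="keys"`` groups trials
    by ``group_keys`` (motion trials: the number of positions the trajectory
    crosses, so vectors of the same length share a mean).
    """
    if grouping == "all":
        keys = np.zeros(epochs.n_trials, dtype=int)
    elif grouping == "keys":
        if group_keys is None:
            raise ValueError("group_keys required for grouping='keys'")
        keys = np.asarray(group_keys)
        if keys.size != epochs.n_trials:
            raise ValueError("group_keys length must match trial count")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    out = epochs.copy()
    for k in np.unique(keys):
        sel = keys == k
        if sel.sum() == 1:
            warnings.warn(f"demeaning group {k!r} has a single trial; it becomes zero")
        out.data[sel] = epochs.data[sel] - epochs.data[sel].mean(axis=0, keepdims=True)
    return out
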