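"""Shared fixtures: geometry objects and scaled simulated datasets.

Heavy end-to-end artefacts (group recovery runs) are session-scoped and cached
so that several tests can share one computation.
"""

from dataclasses import replace

import numpy as np
import pytest

from mvextrap import decode
from mvextrap.hexgeom import build_grid, enumerate_trajectories
from mvextrap.model import RunConfig, run_all


@pytest.fixture(scope="session")
def grid3():
    return build_grid(3)


@pytest.fixture(scope="session")
def trajectories3(grid3):
    return enumerate_trajectories(grid3)


def recovery_config(delta_ms: float) -> RunConfig:
    """Scaled-down study conditions for full-pipeline parameter recovery.

    Three simulated participants (the latency analysis, like the original
    one, operates on the participant-averaged likelihood; single-draw
    topography idiosyncrasies average out), each with one session of 12
    static repetitions per position and 6 per motion vector, 32 channels,
    classifiers trained over 40-300 ms (covering the simulated feedforward
    cascade and its feedback reversal).
    """
    cfg = RunConfig.desk_scale(run_stats=False)
    return replace(
        cfg,
        sim=replace(cfg.sim, extrap_shift_ms=delta_ms, static_reps=12,
                    motion_reps=6, n_channels=32),
        decoder=decode.DecoderSpec(train_window_ms=(40.0, 300.0)),
        n_participants=3)


_recovery_cache: dict = {}


@pytest.fixture(scope="session")
def recovery_report():
    """Factory returning (cached) group-level reports per injected shift."""

    def _get(delta_ms: float, seed: int = 1):
        key = (delta_ms, seed)
        if key not in _recovery_cache:
            _recovery_cache[key] = run_all(recovery_config(delta_ms), seed=seed)
        return _recovery_cache[key]

    return _get


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small 1-ring dataset for fast integration tests."""
    from mvextrap.synthgen import SimConfig, simulate_dataset

    cfg = SimConfig(rings=1, n_channels=12, n_sessions=1, static_reps=12,
                    motion_reps=4)
    return simulate_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def static_scores_default():
    """Cross-validated static decoding of one desk-scale default dataset."""
    from mvextrap.synthgen import SimConfig, simulate_dataset
    from mvextrap import prep

    ds = simulate_dataset(SimConfig(n_sessions=1, static_reps=20, motion_reps=1,
                                    n_channels=32), seed=1)
    st = prep.rereference(ds.static, ds.static.meta["ref_channels"][:2])
    keep = [c for c in range(st.n_channels)
            if c not in ds.static.meta["ref_channels"]]
    st.data = st.data[:, keep, :]
    st = prep.baseline_correct(st)
    st = prep.demean_by_condition(st, "all")
    return decode.pairwise_cv_static(st, decode.DecoderSpec()), ds.grid
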