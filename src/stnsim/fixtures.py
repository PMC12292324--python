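"""Deterministic fixture generators and regression digests.

Everything the test-suite needs is generated from code and a seed:
perfectly periodic trains (the CV_ISI = 0 oracle), well-separated
pre/post spike-pair protocols (the closed-form STDP oracle), and SHA-256
digests of full simulation outputs for regression pinning.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .simulator import SimulationConfig, run_simulation
from .synaptic_input import SpikeTrain

__all__ = [
    "make_regular_train",
    "make_paired_spike_protocol",
    "simulation_digest",
    "snapshot_regression",
    "NAMED_CONFIGS",
]


def make_regular_train(period: float, duration: float,
                       dt: float = 0.1) -> SpikeTrain:
    """Spikes at period, 2*period, ... below ``duration`` (CV_ISI = 0)."""
    if period <= 0:
        raise ValueError("period must be positive")
    times = np.arange(period, duration, period, dtype=float)
    return SpikeTrain(times=times, duration=duration, dt=dt)


def make_paired_spike_protocol(delta_t: float, n_pairs: int,
                               pair_interval: float):
    """Well-separated pre/post spike pairs at a fixed lag.

    Pre spike k occurs at k*pair_interval, the matching post spike at
    k*pair_interval + delta_t (so delta_t < 0 means pre-before-post,
    the potentiating order).  ``pair_interval`` must exceed |delta_t| so
    the pairs never interleave.
    """
    if pair_interval <= abs(delta_t):
        raise ValueError("pair_interval must exceed |delta_t|: pairs overlap")
    base = np.arange(1, n_pairs + 1, dtype=float) * pair_interval
    post = base
    pre = base + delta_t  # delta_t = t_pre - t_post
    return pre, post


def simulation_digest(cfg: SimulationConfig) -> str:
    """SHA-256 over spike times and final weights of one run.

    Spike times are rounded to the time grid (0.1 us) before hashing so
    the digest depends on the dynamics, not on float formatting.
    """
    res = run_simulation(cfg)
    h = hashlib.sha256()
    h.update(np.round(res.spike_times.times, 4).tobytes())
    h.update(np.round(res.final_gbar, 12).tobytes())
    return h.hexdigest()


NAMED_CONFIGS = {
    "healthy_direct": SimulationConfig(i_app_mean=33.0, i_app_sigma=0.0,
                                       refractory_mean=6.0, duration=500.0,
                                       seed=0),
    "pd_noisy": SimulationConfig(i_app_mean=23.0, i_app_sigma=1.0,
                                 refractory_mean=6.0, refractory_sigma=1.0,
                                 duration=500.0, seed=0),
}


def snapshot_regression(config_id: str, expected_digest: str | None = None) -> str:
    """Digest of a named configuration; optionally compare to a stored one.

    Raises ``AssertionError`` with both digests when they differ.
    """
    if config_id not in NAMED_CONFIGS:
        raise KeyError(f"unknown config id {config_id!r}")
    digest = simulation_digest(NAMED_CONFIGS[config_id])
    if expected_digest is not None and digest != expected_digest:
        raise AssertionError(
            f"regression digest mismatch for {config_id!r}: "
            f"got {digest}, expected {expected_digest}")
    return digest
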