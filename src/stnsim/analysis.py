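"""Spike-train statistics, correlated current inputs and hypothesis tests.

Provides the coefficient of variation of inter-spike intervals (CV_ISI),
firing rates, the shared-noise construction used to study correlation
transfer between two unconnected neurons, plain sums-of-products
correlation estimators, and the Welch two-sample t-test used to compare
plasticity conditions.

Degenerate inputs (too few spikes, zero variance) yield NaN rather than
raising, so that trial aggregation can distinguish "undefined" from 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .simulator import SimulationConfig, make_streams, run_simulation
from .synaptic_input import SpikeTrain

__all__ = [
    "IsiSummary",
    "CorrelatedInputPair",
    "cv_isi",
    "isi_summary",
    "firing_rate",
    "correlated_current_pair",
    "sample_correlation",
    "output_correlation",
    "correlation_transfer_curve",
    "two_sample_ttest",
]


@dataclass
class IsiSummary:
    """Mean, SD (population) and CV of the inter-spike intervals (ms)."""

    intervals: np.ndarray
    mean: float
    sd: float
    cv: float


def _times(spike_times) -> np.ndarray:
    if isinstance(spike_times, SpikeTrain):
        return spike_times.times
    return np.asarray(spike_times, dtype=float)


def cv_isi(spike_times, ddof: int = 0) -> float:
    """Coefficient of variation of the inter-spike intervals.

    sigma_ISI / mu_ISI, with the population SD (ddof=0) by default.
    Returns NaN for fewer than three spikes (fewer than two intervals),
    which is distinct from the exact 0 of a periodic train.
    """
    t = _times(spike_times)
    if t.size < 3:
        return float("nan")
    isi = np.diff(t)
    mu = isi.mean()
    if mu == 0:
        return float("nan")
    return float(isi.std(ddof=ddof) / mu)


def isi_summary(spike_times, ddof: int = 0) -> IsiSummary:
    t = _times(spike_times)
    isi = np.diff(t)
    if isi.size < 2:
        return IsiSummary(intervals=isi, mean=float("nan"),
                          sd=float("nan"), cv=float("nan"))
    return IsiSummary(intervals=isi, mean=float(isi.mean()),
                      sd=float(isi.std(ddof=ddof)),
                      cv=cv_isi(t, ddof=ddof))


def firing_rate(spike_times, duration: float) -> float:
    """Spike count divided by duration, in Hz (duration in ms)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return _times(spike_times).size / duration * 1000.0


@dataclass
class CorrelatedInputPair:
    """Two current series sharing a tunable fraction of their noise."""

    c: float
    mu: float
    sigma: float
    i1: np.ndarray
    i2: np.ndarray
    dt: float


def correlated_current_pair(mu: float, sigma: float, c: float,
                            duration: float, dt: float, seed: int,
                            mixing: str = "sqrt") -> CorrelatedInputPair:
    """Currents I_i = mu + sigma*(sqrt(1-c)*xi_i + sqrt(c)*xi_c).

    ``xi_1``, ``xi_2`` are private standard-Gaussian streams and ``xi_c``
    is shared; under the default square-root mixing the variance of each
    current is sigma^2 for every c and the input correlation equals c.
    ``mixing="linear"`` uses the literal weights (1-c) and c instead.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("mixing fraction c must lie in [0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if mixing not in ("sqrt", "linear"):
        raise ValueError(f"unknown mixing {mixing!r}")
    n = int(round(duration / dt))
    streams = make_streams(seed)
    xi_c = streams["shared_input"].standard_normal(n)
    xi_1 = streams["private_input_1"].standard_normal(n)
    xi_2 = streams["private_input_2"].standard_normal(n)
    if mixing == "sqrt":
        w_priv, w_shared = math.sqrt(1.0 - c), math.sqrt(c)
    else:
        w_priv, w_shared = 1.0 - c, c
    i1 = mu + sigma * (w_priv * xi_1 + w_shared * xi_c)
    i2 = mu + sigma * (w_priv * xi_2 + w_shared * xi_c)
    return CorrelatedInputPair(c=c, mu=mu, sigma=sigma, i1=i1, i2=i2, dt=dt)


def sample_correlation(x, y) -> float:
    """Pearson correlation via plain sums of products.

    cov(x, y) / sqrt(var(x) var(y)) with uncorrected sums: the 1/(L-1)
    factors cancel.  NaN when either series has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length series of length >= 2")
    dx = x - x.mean()
    dy = y - y.mean()
    vx = float(dx @ dx)
    vy = float(dy @ dy)
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    return float((dx @ dy) / math.sqrt(vx * vy))


def output_correlation(train1, train2, bin_width: float = 10.0,
                       duration: float | None = None,
                       start: float = 0.0) -> float:
    """Correlation of binned spike counts of two trains.

    Both trains are counted in common bins of ``bin_width`` ms between
    ``start`` and ``duration`` and the count vectors are fed to
    :func:`sample_correlation`.  NaN when either train is empty.
    """
    t1 = _times(train1)
    t2 = _times(train2)
    if duration is None:
        if isinstance(train1, SpikeTrain):
            duration = train1.duration
        else:
            raise ValueError("duration required for raw time arrays")
    if t1.size == 0 or t2.size == 0:
        return float("nan")
    edges = np.arange(start, duration + bin_width, bin_width)
    c1, _ = np.histogram(t1, bins=edges)
    c2, _ = np.histogram(t2, bins=edges)
    return sample_correlation(c1, c2)


def correlation_transfer_curve(base_cfg: SimulationConfig, c_grid,
                               n_trials: int = 10, mu: float | None = None,
                               sigma: float = 4.0, bin_width: float = 10.0,
                               base_seed: int = 0, discard: float = 1000.0):
    """Input vs output correlation for two unconnected neurons.

    For each mixing fraction c, ``n_trials`` paired simulations are run
    in which the two neurons receive correlated injected currents built
    by :func:`correlated_current_pair` as their only input (this is a
    current-injection paradigm: the Poisson bombardment is disabled so
    the shared signal is the common noise component).  The first
    ``discard`` ms are excluded from the output correlation so that the
    common calcium-settling transient does not masquerade as transfer.
    Returns one record per c with the measured mean input correlation
    and the mean and SD of the output (binned spike-count) correlation.
    """
    import pandas as pd

    if mu is None:
        mu = base_cfg.i_app_mean
    base_cfg = base_cfg.copy(rate_exc=0.0, rate_inh=0.0)
    rows = []
    for ci, c in enumerate(c_grid):
        r_in, r_out = [], []
        for k in range(n_trials):
            pair_seed = base_seed + 1000 * ci + k
            pair = correlated_current_pair(mu, sigma, float(c),
                                           base_cfg.duration, base_cfg.dt,
                                           seed=pair_seed)
            # the neurons are unconnected and their synaptic bombardment
            # is independent; the only shared signal is the common part
            # of the injected currents
            cfg1 = base_cfg.copy(seed=base_seed + 2 * k,
                                 external_current=pair.i1)
            cfg2 = base_cfg.copy(seed=base_seed + 2 * k + 1,
                                 external_current=pair.i2)
            res1 = run_simulation(cfg1)
            res2 = run_simulation(cfg2)
            r_in.append(sample_correlation(pair.i1, pair.i2))
            r_out.append(output_correlation(res1.spike_times,
                                            res2.spike_times,
                                            bin_width=bin_width,
                                            start=min(discard,
                                                      base_cfg.duration / 2)))
        r_out = np.asarray(r_out, dtype=float)
        valid = r_out[~np.isnan(r_out)]
        rows.append({
            "c": float(c),
            "r_in_mean": float(np.mean(r_in)),
            "r_out_mean": float(valid.mean()) if valid.size else float("nan"),
            "r_out_sd": float(valid.std(ddof=1)) if valid.size > 1 else float("nan"),
            "n_trials": n_trials,
        })
    return pd.DataFrame(rows)


def two_sample_ttest(a, b, equal_var: bool = False) -> dict:
    """Two-sample t-test (Welch by default), two-sided, alpha = 0.05.

    Returns ``{"t", "p", "significant"}``; NaNs for degenerate samples
    (fewer than two observations or both samples without variance).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        return {"t": float("nan"), "p": float("nan"), "significant": False}
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return {"t": 0.0, "p": 1.0, "significant": False}
        return {"t": float("nan"), "p": float("nan"), "significant": False}
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return {"t": float(t), "p": float(p), "significant": bool(p < 0.05)}
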