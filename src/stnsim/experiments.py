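"""Scripted multi-trial experiments: condition comparisons and sweeps.

These functions wrap the simulator into the protocols used throughout the
study: paired 10-trial comparisons of the plastic vs non-plastic neuron
under a given drive/refractory condition, sensitivity sweeps of the
refractory-noise amplitude and of the STDP depression amplitude, and
ISI-distribution panels.  Trial k of every arm uses seed base_seed + k, so
the plastic and non-plastic arms see identical synaptic input and noise
realisations (a paired design that removes input variance from the
contrast).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .analysis import cv_isi, firing_rate, two_sample_ttest
from .simulator import SimulationConfig, run_simulation

__all__ = [
    "ConditionSpec",
    "ComparisonReport",
    "healthy_condition",
    "pd_condition",
    "human_pd_condition",
    "animal_pd_condition",
    "run_trials",
    "run_condition_comparison",
    "run_sensitivity_refractory",
    "run_sensitivity_aminus",
    "run_isi_panels",
]


@dataclass
class ConditionSpec:
    """One experimental condition: drive, refractoriness, noise, flags."""

    label: str
    i_app: float
    refractory_mean: float
    sigma_app: float = 0.0
    sigma_ref: float = 0.0
    stdp: bool = True
    dbs: bool = False
    duration: float = 1000.0
    n_trials: int = 10
    base_seed: int = 0
    config_overrides: dict = field(default_factory=dict)

    def copy(self, **changes) -> "ConditionSpec":
        return replace(self, **changes)

    def to_config(self, seed: int | None = None,
                  stdp: bool | None = None) -> SimulationConfig:
        cfg = SimulationConfig(
            duration=self.duration,
            i_app_mean=self.i_app,
            i_app_sigma=self.sigma_app,
            refractory_mean=self.refractory_mean,
            refractory_sigma=self.sigma_ref,
            stdp_enabled=self.stdp if stdp is None else stdp,
            dbs_enabled=self.dbs,
            seed=self.base_seed if seed is None else seed,
            **self.config_overrides,
        )
        return cfg


def healthy_condition(**changes) -> ConditionSpec:
    """Healthy STN cell: I_app = 33 pA, short 6 ms refractory period."""
    spec = ConditionSpec(label="healthy", i_app=33.0, refractory_mean=6.0,
                         sigma_app=1.0, sigma_ref=1.0)
    return spec.copy(**changes) if changes else spec


def pd_condition(**changes) -> ConditionSpec:
    """Parkinsonian STN cell: reduced drive I_app = 23 pA, 6 ms refractory."""
    spec = ConditionSpec(label="pd", i_app=23.0, refractory_mean=6.0,
                         sigma_app=1.0, sigma_ref=1.0)
    return spec.copy(**changes) if changes else spec


def human_pd_condition(**changes) -> ConditionSpec:
    """PD condition calibrated to human single-unit data:
    I_app = 23 pA, t_ref = 21 ms, sigma_app = sigma_ref = 8."""
    spec = ConditionSpec(label="pd_human", i_app=23.0, refractory_mean=21.0,
                         sigma_app=8.0, sigma_ref=8.0)
    return spec.copy(**changes) if changes else spec


def animal_pd_condition(**changes) -> ConditionSpec:
    """PD condition calibrated to non-human-primate data:
    I_app = 23 pA, t_ref = 28 ms, sigma_app = sigma_ref = 18."""
    spec = ConditionSpec(label="pd_animal", i_app=23.0, refractory_mean=28.0,
                         sigma_app=18.0, sigma_ref=18.0)
    return spec.copy(**changes) if changes else spec


def run_trials(spec: ConditionSpec, stdp: bool | None = None) -> pd.DataFrame:
    """Seeded trials of one condition; per-trial rate, CV_ISI and count."""
    rows = []
    for k in range(spec.n_trials):
        cfg = spec.to_config(seed=spec.base_seed + k, stdp=stdp)
        res = run_simulation(cfg)
        t = res.spike_times
        rows.append({
            "trial": k,
            "seed": cfg.seed,
            "firing_rate_hz": firing_rate(t, spec.duration),
            "cv_isi": cv_isi(t),
            "spike_count": len(t),
        })
    return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """Per-trial metrics and summary statistics of a paired STDP contrast."""

    condition: ConditionSpec
    stdp_trials: pd.DataFrame
    no_stdp_trials: pd.DataFrame
    summary: pd.DataFrame
    tests: dict

    def to_text(self) -> str:
        lines = [f"condition: {self.condition.label}  "
                 f"(I_app={self.condition.i_app} pA, "
                 f"t_ref={self.condition.refractory_mean} ms, "
                 f"sigma_app={self.condition.sigma_app}, "
                 f"sigma_ref={self.condition.sigma_ref}, "
                 f"n_trials={self.condition.n_trials})",
                 self.summary.to_string()]
        for metric, res in self.tests.items():
            lines.append(f"t-test {metric}: t={res['t']:.3f} p={res['p']:.4g} "
                         f"significant={res['significant']}")
        return "\n".join(lines)


def run_condition_comparison(spec: ConditionSpec) -> ComparisonReport:
    """Paired 10-trial comparison of the plastic vs non-plastic neuron.

    Both arms reuse the same per-trial seeds; each metric is compared
    with a Welch two-sample t-test at alpha = 0.05.
    """
    with_stdp = run_trials(spec, stdp=True)
    without_stdp = run_trials(spec, stdp=False)
    metrics = ["firing_rate_hz", "cv_isi", "spike_count"]
    summary = pd.DataFrame({
        ("stdp", "mean"): with_stdp[metrics].mean(),
        ("stdp", "sd"): with_stdp[metrics].std(ddof=1),
        ("no_stdp", "mean"): without_stdp[metrics].mean(),
        ("no_stdp", "sd"): without_stdp[metrics].std(ddof=1),
    })
    tests = {m: two_sample_ttest(with_stdp[m].to_numpy(),
                                 without_stdp[m].to_numpy())
             for m in metrics}
    return ComparisonReport(condition=spec, stdp_trials=with_stdp,
                            no_stdp_trials=without_stdp, summary=summary,
                            tests=tests)


def run_sensitivity_refractory(spec: ConditionSpec,
                               noise_grid) -> pd.DataFrame:
    """Mean spike count as a function of the refractory-noise amplitude."""
    rows = []
    for sigma in noise_grid:
        trials = run_trials(spec.copy(sigma_ref=float(sigma)))
        rows.append({
            "sigma_ref": float(sigma),
            "mean_spike_count": trials["spike_count"].mean(),
            "sd_spike_count": trials["spike_count"].std(ddof=1),
            "mean_cv_isi": trials["cv_isi"].mean(),
            "n_trials": spec.n_trials,
        })
    return pd.DataFrame(rows)


def run_sensitivity_aminus(spec: ConditionSpec, aminus_grid) -> pd.DataFrame:
    """Mean spike count as a function of the STDP depression amplitude."""
    rows = []
    for a_minus in aminus_grid:
        counts, cvs = [], []
        for k in range(spec.n_trials):
            cfg = spec.to_config(seed=spec.base_seed + k, stdp=True)
            cfg = cfg.copy(stdp=cfg.stdp.copy(a_minus=float(a_minus)))
            res = run_simulation(cfg)
            counts.append(len(res.spike_times))
            cvs.append(cv_isi(res.spike_times))
        rows.append({
            "a_minus": float(a_minus),
            "mean_spike_count": float(np.mean(counts)),
            "sd_spike_count": float(np.std(counts, ddof=1)) if len(counts) > 1 else float("nan"),
            "mean_cv_isi": float(np.nanmean(cvs)),
            "n_trials": spec.n_trials,
        })
    return pd.DataFrame(rows)


DEFAULT_TRANSFER_GRID = (0.0, 0.2, 0.4, 0.6, 0.8)


def run_correlation_transfer(n_trials: int = 10, base_seed: int = 0,
                             c_grid=DEFAULT_TRANSFER_GRID,
                             mu: float = -5.0, sigma: float = 4.0,
                             bin_width: float = 10.0) -> pd.DataFrame:
    """Two-neuron correlation-transfer experiment at the packaged
    operating point.

    The neurons are driven by correlated injected currents alone, at a
    fluctuation-driven operating point (mean drive just below rheobase,
    calcium started at its fixed point) where threshold crossings are
    governed by the noise: this is the regime in which input
    correlations propagate to output spike-count correlations.  The
    fully shared endpoint c = 1 is excluded from the default grid
    because two neurons with literally identical input reproduce each
    other's train (a duplication limit, not correlation transfer).
    """
    from .analysis import correlation_transfer_curve
    from .model_core import NeuronParameters

    cfg = SimulationConfig(
        i_app_mean=mu, refractory_mean=6.0, refractory_sigma=1.0,
        duration=2500.0, neuron=NeuronParameters(ca_init=0.03))
    return correlation_transfer_curve(cfg, c_grid, n_trials=n_trials,
                                      sigma=sigma, bin_width=bin_width,
                                      base_seed=base_seed, discard=500.0)


def run_isi_panels(specs, bins="fd") -> dict:
    """ISI histograms and CV_ISI for a list of conditions.

    One simulation per condition (the condition's base seed); histogram
    edges use the Freedman-Diaconis rule by default.
    """
    panels = {}
    for spec in specs:
        res = run_simulation(spec.to_config())
        isi = res.spike_times.isi()
        if isi.size >= 2:
            counts, edges = np.histogram(isi, bins=bins)
        else:
            counts, edges = np.zeros(0, dtype=int), np.zeros(1)
        panels[spec.label] = {
            "isi": isi,
            "hist_counts": counts,
            "hist_edges": edges,
            "cv_isi": cv_isi(res.spike_times),
            "firing_rate_hz": firing_rate(res.spike_times, spec.duration),
            "spike_count": len(res.spike_times),
        }
    return panels
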