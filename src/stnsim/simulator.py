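"""Forward-Euler integration of the coupled SDE-ODE membrane system.

One step of the loop, in order:

1. decay the STDP traces,
2. draw this bin's presynaptic Poisson spikes, inject conductance and
   apply the presynaptic STDP events,
3. advance the membrane potential (Euler-Maruyama for the additive
   Gaussian current noise), the gating variables and the calcium balance,
4. apply the threshold/reset rule; a threshold crossing records a spike,
   resets V, samples a fresh Gaussian refractory period and dispatches
   the postsynaptic STDP event.

Every stochastic ingredient (excitatory trains, inhibitory trains,
membrane noise, refractory jitter) draws from its own named RNG stream
derived from the run seed, so switching one noise source on or off never
perturbs the draws of another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import (ConfigurationError, NeuronParameters, NeuronState,
                         initial_state)
from .plasticity import StdpParameters
from .synaptic_input import SpikeTrain

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "SimulationDiverged",
    "make_streams",
    "noise_increment",
    "run_simulation",
]

# Fixed order of the named RNG streams spawned from the run seed.
STREAM_NAMES = (
    "poisson_exc",
    "poisson_inh",
    "membrane_noise",
    "refractory",
    "shared_input",
    "private_input_1",
    "private_input_2",
)


class SimulationDiverged(RuntimeError):
    """Raised when the membrane potential leaves the physical range."""


def make_streams(seed: int) -> dict:
    """Independent named RNG streams for one simulation run."""
    return {
        name: np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        for i, name in enumerate(STREAM_NAMES)
    }


def noise_increment(sigma: float, dt: float, cm: float, draws: np.ndarray,
                    scheme: str = "euler_maruyama") -> np.ndarray:
    """Per-step voltage increment contributed by the Gaussian current noise.

    ``euler_maruyama`` treats sigma*eta(t) as white noise and scales the
    standard-normal draws by sigma*sqrt(dt)/cm; ``piecewise_constant``
    treats the draw as a constant current over the step, scaling by
    sigma*dt/cm.
    """
    if scheme == "euler_maruyama":
        return sigma * math.sqrt(dt) / cm * np.asarray(draws)
    if scheme == "piecewise_constant":
        return sigma * dt / cm * np.asarray(draws)
    raise ConfigurationError(f"unknown noise scheme {scheme!r}")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one run of the model."""

    duration: float = 1000.0
    dt: float = 0.1

    i_app_mean: float = 33.0      # pA; 33 healthy, 23 Parkinsonian
    i_app_sigma: float = 0.0      # pA, additive Gaussian noise amplitude

    refractory_mean: float = 6.0  # ms
    refractory_sigma: float = 0.0

    dbs_enabled: bool = False
    stdp_enabled: bool = True

    n_exc: int = 20
    n_inh: int = 80
    rate_exc: float = 10.0        # Hz per excitatory train
    rate_inh: float = 10.0        # Hz per inhibitory train
    gbar_exc: float = 1.5         # nS, initial excitatory peak conductance
    gbar_inh: float = 0.5         # nS, fixed inhibitory peak conductance
    tau_exc: float = 2.0          # ms
    tau_inh: float = 5.0          # ms
    e_exc: float = 0.0            # mV
    e_inh: float = -65.0          # mV

    neuron: NeuronParameters = field(default_factory=NeuronParameters)
    stdp: StdpParameters = field(default_factory=StdpParameters)

    seed: int = 0
    noise_scheme: str = "euler_maruyama"   # or "piecewise_constant"
    refractory_mode: str = "clamp"         # or "integrate"

    # Optional externally supplied applied-current series (pA per step);
    # overrides i_app_mean / i_app_sigma when given (used by the
    # correlation-transfer protocol).
    external_current: np.ndarray | None = None

    record_traces: bool = False
    trace_stride: int = 10

    def __post_init__(self) -> None:
        if self.duration < 0 or self.dt <= 0:
            raise ConfigurationError("need duration >= 0 and dt > 0")
        if self.refractory_mode not in ("integrate", "clamp"):
            raise ConfigurationError(
                f"unknown refractory mode {self.refractory_mode!r}")
        if self.noise_scheme not in ("euler_maruyama", "piecewise_constant"):
            raise ConfigurationError(
                f"unknown noise scheme {self.noise_scheme!r}")

    def copy(self, **changes) -> "SimulationConfig":
        return replace(self, **changes)


@dataclass
class SimulationResult:
    """Spike train, final synaptic weights and optional sampled traces."""

    spike_times: SpikeTrain
    spike_steps: np.ndarray
    final_gbar: np.ndarray
    refractory_samples: np.ndarray
    n_ca_clamped: int
    n_refractory_clipped: int
    config: SimulationConfig
    traces: dict | None = None
    final_state: NeuronState | None = None

    @property
    def spike_count(self) -> int:
        return len(self.spike_times)


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Integrate the full model for ``cfg.duration`` ms.

    Deterministic for a fixed config (including the seed).  Raises
    :class:`SimulationDiverged` if the membrane potential becomes
    non-finite or leaves [-500, 500] mV.
    """
    par = cfg.neuron
    stdp = cfg.stdp
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    streams = make_streams(cfg.seed)

    # --- presynaptic Poisson spikes, drawn up front ---------------------
    p_exc = cfg.rate_exc * 1e-3 * dt
    p_inh = cfg.rate_inh * 1e-3 * dt
    if n_steps:
        exc = streams["poisson_exc"].random((n_steps, cfg.n_exc)) < p_exc
        inh_counts = (streams["poisson_inh"].random((n_steps, cfg.n_inh))
                      < p_inh).sum(axis=1)
        exc_rows, exc_cols = np.nonzero(exc)
        exc_ptr = np.searchsorted(exc_rows, np.arange(n_steps + 1))
    else:
        inh_counts = np.zeros(0, dtype=int)
        exc_cols = np.zeros(0, dtype=int)
        exc_ptr = np.zeros(1, dtype=int)

    # --- membrane noise, drawn up front ---------------------------------
    if cfg.external_current is not None:
        ext = np.asarray(cfg.external_current, dtype=float)
        if ext.size != n_steps:
            raise ConfigurationError(
                "external_current must have one sample per time step")
        dv_noise = None
    elif cfg.i_app_sigma > 0 and n_steps:
        dv_noise = noise_increment(cfg.i_app_sigma, dt, par.cm,
                                   streams["membrane_noise"].standard_normal(n_steps),
                                   cfg.noise_scheme)
        ext = None
    else:
        dv_noise = None
        ext = None
    rng_ref = streams["refractory"]

    # --- local bindings for the hot loop --------------------------------
    state = initial_state(par)
    v, hh, nn, rr, cc, ca = state.v, state.h, state.n, state.r, state.c, state.ca
    g_exc = 0.0
    g_inh = 0.0
    weights = np.full(cfg.n_exc, cfg.gbar_exc, dtype=float)
    trace_m = 0.0
    trace_p = np.zeros(cfg.n_exc)

    exp = math.exp
    sin = math.sin
    two_pi_f = 2.0 * math.pi * par.dbs_frequency_per_ms
    cm = par.cm
    g_leak, e_leak = par.g_leak, par.e_leak
    g_na, e_na = par.g_na, par.e_na
    g_k, e_k = par.g_k, par.e_k
    g_t, e_t, e_ca = par.g_t, par.e_t, par.e_ca
    g_ca_max = par.g_ca
    g_ahp, e_ahp, k1 = par.g_ahp, par.e_ahp, par.k1
    dbs_offset, dbs_amplitude = par.dbs_offset, par.dbs_amplitude
    phi_h, phi_n, phi_r, phi_c = par.phi_h, par.phi_n, par.phi_r, par.phi_c
    eps, k_ca = par.eps, par.k_ca
    v_th, v_reset = par.v_threshold, par.v_reset
    b_offset = 1.0 / (1.0 + exp(4.0))
    t_as_printed = par.t_current_variant == "as_printed"
    ca_as_printed = par.ca_influx_sign == "as_printed"
    clamp_mode = cfg.refractory_mode == "clamp"
    stdp_on = cfg.stdp_enabled
    a_plus, a_minus, gbar_max = stdp.a_plus, stdp.a_minus, stdp.gbar_max
    decay_m = 1.0 - dt / stdp.tau_minus
    decay_p = 1.0 - dt / stdp.tau_plus
    decay_e = 1.0 - dt / cfg.tau_exc
    decay_i = 1.0 - dt / cfg.tau_inh
    e_exc_rev, e_inh_rev = cfg.e_exc, cfg.e_inh
    mu_app = cfg.i_app_mean
    mu_ref, sigma_ref = cfg.refractory_mean, cfg.refractory_sigma
    dbs_on = cfg.dbs_enabled

    ref_rem = 0.0
    spike_times: list = []
    spike_steps: list = []
    ref_samples: list = []
    n_ca_clamped = 0
    n_ref_clipped = 0

    record = cfg.record_traces
    if record:
        stride = max(1, int(cfg.trace_stride))
        n_rec = n_steps // stride + 1
        rec_t = np.empty(n_rec)
        rec_v = np.empty(n_rec)
        rec_ge = np.empty(n_rec)
        rec_gi = np.empty(n_rec)
        rec_m = np.empty(n_rec)
        rec_ca = np.empty(n_rec)
        rec_i = 0

    for step in range(n_steps):
        t = step * dt

        if record and step % stride == 0:
            rec_t[rec_i] = t
            rec_v[rec_i] = v
            rec_ge[rec_i] = g_exc
            rec_gi[rec_i] = g_inh
            rec_m[rec_i] = trace_m
            rec_ca[rec_i] = ca
            rec_i += 1

        # 1. trace decay
        if stdp_on:
            trace_m *= decay_m
            trace_p *= decay_p

        # 2. synaptic conductances: decay, then inject this bin's spikes
        g_exc *= decay_e
        g_inh *= decay_i
        lo, hi = exc_ptr[step], exc_ptr[step + 1]
        if hi > lo:
            idx = exc_cols[lo:hi]
            g_exc += weights[idx].sum()
            if stdp_on:
                trace_p[idx] += a_plus
                w = weights[idx] + trace_m * gbar_max
                weights[idx] = np.clip(w, 0.0, gbar_max)
        k_inh = inh_counts[step]
        if k_inh:
            g_inh += k_inh * cfg.gbar_inh

        # 3. membrane, gating and calcium (forward Euler)
        in_refractory = ref_rem > 0.0
        if in_refractory:
            ref_rem -= dt

        m_inf = 1.0 / (1.0 + exp(-(v + 30.0) / 15.0))
        a_inf = 1.0 / (1.0 + exp(-(v + 63.0) / 7.8))
        b_inf = 1.0 / (1.0 + exp(-(rr - 0.4) / 0.1)) - b_offset
        i_leak = g_leak * (v - e_leak)
        i_na = g_na * m_inf * m_inf * m_inf * hh * (v - e_na)
        i_k = g_k * nn * nn * nn * nn * (v - e_k)
        if t_as_printed:
            i_t = g_t * a_inf ** 3 * b_inf * b_inf * rr * (v - e_t)
        else:
            i_t = g_t * a_inf ** 3 * b_inf * b_inf * (v - e_ca)
        i_ca = g_ca_max * cc * cc * (v - e_ca)
        i_ahp = g_ahp * (v - e_ahp) * ca / (ca + k1)
        i_syn = -g_exc * (v - e_exc_rev) - g_inh * (v - e_inh_rev)

        drive = ext[step] if ext is not None else mu_app
        if dbs_on:
            drive += dbs_offset + dbs_amplitude * sin(two_pi_f * t)

        dv = dt * (-i_leak - i_na - i_k - i_t - i_ca - i_ahp
                   + i_syn + drive) / cm
        if dv_noise is not None:
            dv += dv_noise[step]

        # gating relaxation and calcium balance
        h_inf = 1.0 / (1.0 + exp((v + 39.0) / 3.1))
        n_inf = 1.0 / (1.0 + exp(-(v + 32.0) / 8.0))
        r_inf = 1.0 / (1.0 + exp((v + 67.0) / 2.0))
        c_inf = 1.0 / (1.0 + exp(-(v + 20.0) / 8.0))
        tau_h = 1.0 + 500.0 / (1.0 + exp((v + 57.0) / 3.0))
        tau_n = 1.0 + 100.0 / (1.0 + exp((v + 80.0) / 26.0))
        tau_r = 7.1 + 17.5 / (1.0 + exp((v + 68.0) / 2.2))
        tau_c = 1.0 + 10.0 / (1.0 + exp((v + 80.0) / 26.0))
        hh += dt * phi_h * (h_inf - hh) / tau_h
        nn += dt * phi_n * (n_inf - nn) / tau_n
        rr += dt * phi_r * (r_inf - rr) / tau_r
        cc += dt * phi_c * (c_inf - cc) / tau_c
        influx = (i_ca - i_t) if ca_as_printed else (-i_ca - i_t)
        ca += dt * eps * (influx - k_ca * ca)
        if ca < 0.0:
            ca = 0.0
            n_ca_clamped += 1

        if in_refractory and clamp_mode:
            v = v_reset
        else:
            v += dv

        if not -500.0 < v < 500.0:
            raise SimulationDiverged(
                f"V = {v:.3g} mV at t = {t:.1f} ms (step {step})")

        # 4. threshold / reset
        if v >= v_th and ref_rem <= 0.0:
            spike_times.append(t + dt)
            spike_steps.append(step + 1)
            v = v_reset
            tref = mu_ref + sigma_ref * rng_ref.standard_normal() \
                if sigma_ref > 0 else mu_ref
            if tref < 0.0:
                tref = 0.0
                n_ref_clipped += 1
            ref_rem = tref
            ref_samples.append(tref)
            if stdp_on:
                trace_m -= a_minus
                np.clip(weights + trace_p * gbar_max, 0.0, gbar_max,
                        out=weights)

    traces = None
    if record:
        traces = {
            "t": rec_t[:rec_i],
            "v": rec_v[:rec_i],
            "g_exc": rec_ge[:rec_i],
            "g_inh": rec_gi[:rec_i],
            "m": rec_m[:rec_i],
            "ca": rec_ca[:rec_i],
        }

    final = NeuronState(v=v, h=hh, n=nn, r=rr, c=cc, ca=ca,
                        refractory_remaining=max(ref_rem, 0.0))
    return SimulationResult(
        spike_times=SpikeTrain(times=np.asarray(spike_times),
                               duration=cfg.duration, dt=dt),
        spike_steps=np.asarray(spike_steps, dtype=np.int64),
        final_gbar=weights,
        refractory_samples=np.asarray(ref_samples),
        n_ca_clamped=n_ca_clamped,
        n_refractory_clipped=n_ref_clipped,
        config=cfg,
        traces=traces,
        final_state=final,
    )
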