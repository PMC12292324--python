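"""Membrane currents, gating kinetics and calcium dynamics of an STN cell.

The cell is a modified Hodgkin-Huxley (HH) model of a subthalamic nucleus
(STN) projection neuron.  Five ionic currents shape the subthreshold
dynamics -- leak, fast sodium, delayed-rectifier potassium, low-threshold
T-type calcium and high-threshold calcium -- plus a calcium-activated
potassium current (AHP) responsible for the after-hyperpolarisation.
Action potentials themselves are emitted by a hybrid threshold/reset rule
(see :mod:`stnsim.simulator`) rather than by explicit spike-generating
sodium dynamics, so the membrane equation here only has to be accurate in
the subthreshold voltage range.

All functions in this module are pure: they map a state and a parameter
set to numbers.  Units follow the conductance-based convention in which a
conductance in nS times a voltage in mV is treated as a current in pA, and
time is measured in ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ConfigurationError",
    "NeuronParameters",
    "NeuronState",
    "steady_state",
    "time_constant",
    "ionic_currents",
    "dbs_current",
    "gating_and_calcium_derivatives",
    "initial_state",
]


class ConfigurationError(ValueError):
    """Raised for unknown gate identifiers or inconsistent parameters."""


# 1/(1+e^4): the offset that anchors b_inf(r) near zero at rest.
_B_OFFSET = 1.0 / (1.0 + math.exp(4.0))


@dataclass
class NeuronParameters:
    """Biophysical constants of the STN membrane model.

    Conductances are in nS, reversal potentials in mV.  ``cm`` is the
    effective capacitance of the forward-Euler scheme: the default 1.0
    absorbs the nominal membrane capacitance into the current scale, so
    the Euler update is dV = dt * (sum of currents).  With the nominal
    10 nF and currents of tens of pA the membrane would relax four
    orders of magnitude more slowly than the millisecond-scale spiking
    dynamics the model is meant to produce, so the unit bookkeeping here
    is deliberately nominal.  ``phi_*`` are the rate scalars
    multiplying each gating relaxation, ``eps`` and ``k_ca`` govern the
    calcium balance and ``k1`` is the half-saturation constant of the AHP
    current's calcium occupancy Ca/(Ca+k1).
    """

    cm: float = 1.0

    g_leak: float = 2.25
    e_leak: float = -60.0
    g_na: float = 37.0
    e_na: float = 55.0
    g_k: float = 45.0
    e_k: float = -80.0
    g_t: float = 0.5
    e_t: float = 0.0
    g_ca: float = 2.0
    e_ca: float = 140.0
    g_ahp: float = 20.0
    e_ahp: float = -80.0

    phi_h: float = 0.75
    phi_n: float = 0.75
    phi_r: float = 0.2
    phi_c: float = 0.08

    eps: float = 3.75e-5
    k_ca: float = 22.5
    k1: float = 15.0

    v_threshold: float = -55.0
    v_reset: float = -70.0
    v_init: float = -65.0
    # Optional override of the initial calcium level.  The default rule
    # (a_inf/(a_inf+b_inf), about 0.69) starts far above the operating
    # point near 0.03 and relaxes over ~1.2 s; protocols that need a
    # stationary neuron from t=0 can start calcium at its fixed point.
    ca_init: float | None = None

    # Sinusoidal DBS drive I = dbs_offset + dbs_amplitude*sin(2*pi*f*t).
    dbs_offset: float = 5.0
    dbs_amplitude: float = 5.0
    dbs_frequency_per_ms: float = 1.0

    # Structural variants of the ambiguously specified terms.  The T-type
    # current is either the literal product g_t*a^3*b^2*r*(V - e_t) or the
    # classic Rubin-Terman form g_t*a^3*b^2*(V - e_ca); the calcium influx
    # term enters the balance equation with either sign convention.
    t_current_variant: str = "as_printed"  # or "rubin_terman"
    ca_influx_sign: str = "as_printed"     # "as_printed": +I_ca - I_t

    def __post_init__(self) -> None:
        for name in ("g_leak", "g_na", "g_k", "g_t", "g_ca", "g_ahp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"conductance {name} must be >= 0")
        if not self.v_reset < self.v_threshold:
            raise ConfigurationError("v_reset must lie below v_threshold")
        if self.eps <= 0 or self.k_ca <= 0:
            raise ConfigurationError("eps and k_ca must be positive")
        if self.t_current_variant not in ("as_printed", "rubin_terman"):
            raise ConfigurationError(
                f"unknown t_current_variant {self.t_current_variant!r}")
        if self.ca_influx_sign not in ("as_printed", "classic"):
            raise ConfigurationError(
                f"unknown ca_influx_sign {self.ca_influx_sign!r}")

    def copy(self, **changes) -> "NeuronParameters":
        return replace(self, **changes)


@dataclass
class NeuronState:
    """Instantaneous state of the membrane model.

    ``v`` is the membrane potential (mV); ``h``, ``n``, ``r`` and ``c``
    are gating variables in [0, 1]; ``ca`` is the intracellular calcium
    concentration (arbitrary units, clamped at 0 by the integrator);
    ``refractory_remaining`` is the time (ms) left in the current
    refractory period.
    """

    v: float
    h: float
    n: float
    r: float
    c: float
    ca: float
    refractory_remaining: float = 0.0


def _sigmoid(x: float) -> float:
    # Guard against overflow in exp for very hyperpolarised arguments.
    if x < -500.0:
        return 0.0
    if x > 500.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-x))


def steady_state(gate: str, x: float) -> float:
    """Voltage- (or, for ``b``, r-) dependent steady-state activation.

    ``gate`` is one of ``m, h, n, a, r, c, b``.  All are logistic
    sigmoids; ``b`` is evaluated on the slow T-type gating variable r and
    is shifted down by 1/(1+e^4) so that it vanishes as r -> 0.
    """
    if gate == "m":
        return _sigmoid((x + 30.0) / 15.0)
    if gate == "h":
        return _sigmoid(-(x + 39.0) / 3.1)
    if gate == "n":
        return _sigmoid((x + 32.0) / 8.0)
    if gate == "a":
        return _sigmoid((x + 63.0) / 7.8)
    if gate == "r":
        return _sigmoid(-(x + 67.0) / 2.0)
    if gate == "c":
        return _sigmoid((x + 20.0) / 8.0)
    if gate == "b":
        return _sigmoid((x - 0.4) / 0.1) - _B_OFFSET
    raise ConfigurationError(f"unknown gate {gate!r}")


def time_constant(gate: str, v: float) -> float:
    """Relaxation time constant (ms) of gate ``h``, ``n``, ``r`` or ``c``."""
    if gate == "h":
        return 1.0 + 500.0 * _sigmoid(-(v + 57.0) / 3.0)
    if gate == "n":
        return 1.0 + 100.0 * _sigmoid(-(v + 80.0) / 26.0)
    if gate == "r":
        return 7.1 + 17.5 * _sigmoid(-(v + 68.0) / 2.2)
    if gate == "c":
        return 1.0 + 10.0 * _sigmoid(-(v + 80.0) / 26.0)
    raise ConfigurationError(f"unknown gate {gate!r} (no time constant)")


def ionic_currents(state: NeuronState, params: NeuronParameters) -> dict:
    """All six intrinsic membrane currents (pA) at the given state.

    Instantaneous activations (m for sodium, a and b for the T current)
    are taken at their steady-state values; h, n, r, c and Ca are the
    dynamical state variables.
    """
    v = state.v
    m = steady_state("m", v)
    i_leak = params.g_leak * (v - params.e_leak)
    i_na = params.g_na * m ** 3 * state.h * (v - params.e_na)
    i_k = params.g_k * state.n ** 4 * (v - params.e_k)
    a = steady_state("a", v)
    b = steady_state("b", state.r)
    if params.t_current_variant == "as_printed":
        i_t = params.g_t * a ** 3 * b ** 2 * state.r * (v - params.e_t)
    else:  # rubin_terman
        i_t = params.g_t * a ** 3 * b ** 2 * (v - params.e_ca)
    i_ca = params.g_ca * state.c ** 2 * (v - params.e_ca)
    i_ahp = params.g_ahp * (v - params.e_ahp) * state.ca / (state.ca + params.k1)
    return {
        "i_leak": i_leak,
        "i_na": i_na,
        "i_k": i_k,
        "i_t": i_t,
        "i_ca": i_ca,
        "i_ahp": i_ahp,
    }


def dbs_current(t: float, params: NeuronParameters) -> float:
    """Sinusoidal DBS drive (pA) at time ``t`` (ms): offset + A*sin(2*pi*f*t)."""
    return params.dbs_offset + params.dbs_amplitude * math.sin(
        2.0 * math.pi * params.dbs_frequency_per_ms * t)


def gating_and_calcium_derivatives(state: NeuronState,
                                   params: NeuronParameters) -> dict:
    """Time derivatives (per ms) of h, n, r, c and the calcium balance.

    Each gate relaxes towards its steady state at rate phi/tau; calcium
    follows d(Ca)/dt = eps * (I_ca - I_t - k_ca * Ca) (sign convention
    switchable via ``ca_influx_sign``).
    """
    v = state.v
    dh = params.phi_h * (steady_state("h", v) - state.h) / time_constant("h", v)
    dn = params.phi_n * (steady_state("n", v) - state.n) / time_constant("n", v)
    dr = params.phi_r * (steady_state("r", v) - state.r) / time_constant("r", v)
    dc = params.phi_c * (steady_state("c", v) - state.c) / time_constant("c", v)
    currents = ionic_currents(state, params)
    if params.ca_influx_sign == "as_printed":
        influx = currents["i_ca"] - currents["i_t"]
    else:  # classic: both calcium currents deplete the driving term
        influx = -currents["i_ca"] - currents["i_t"]
    dca = params.eps * (influx - params.k_ca * state.ca)
    return {"dh": dh, "dn": dn, "dr": dr, "dc": dc, "dca": dca}


def initial_state(params: NeuronParameters) -> NeuronState:
    """Resting state: every gate at its steady state for V = v_init.

    The initial calcium level is a_inf/(a_inf + b_inf) with b_inf
    evaluated on the initial value of the r gate.
    """
    v0 = params.v_init
    a0 = steady_state("a", v0)
    r0 = steady_state("r", v0)
    b0 = steady_state("b", r0)
    denom = a0 + b0
    if denom == 0.0:
        raise ConfigurationError("a_inf + b_inf vanishes at v_init")
    ca0 = a0 / denom if params.ca_init is None else params.ca_init
    return NeuronState(
        v=v0,
        h=steady_state("h", v0),
        n=steady_state("n", v0),
        r=r0,
        c=steady_state("c", v0),
        ca=ca0,
        refractory_remaining=0.0,
    )
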