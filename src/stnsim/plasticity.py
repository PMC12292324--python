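"""Pair-based spike-timing-dependent plasticity with exponential traces.

The STDP window is the classic biphasic exponential: a presynaptic spike
followed by a postsynaptic spike within tau_plus potentiates, the reverse
order depresses.  Online, the window is implemented with two kinds of
low-pass traces rather than explicit spike-pair bookkeeping:

* ``M`` -- one postsynaptic trace, pushed down by A_minus at every
  postsynaptic spike and decaying back to 0 with tau_minus.  M is never
  positive; sampled at a presynaptic spike it yields the depression.
* ``P_i`` -- one trace per presynaptic neuron, pushed up by A_plus at
  every spike of neuron i and decaying with tau_plus.  P is never
  negative; sampled at a postsynaptic spike it yields the potentiation.

Peak synaptic conductances are updated multiplicatively against the
ceiling ``gbar_max`` (dw = trace * gbar_max) and hard-clipped to
[0, gbar_max].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StdpParameters",
    "TraceState",
    "stdp_delta_w",
    "decay_traces",
    "on_presynaptic_spike",
    "on_postsynaptic_spike",
]


@dataclass
class StdpParameters:
    """Amplitudes (dimensionless weight fractions), time windows (ms) and
    the weight ceiling (nS) of the pair-based rule."""

    a_plus: float = 0.005
    a_minus: float = 0.0105
    tau_plus: float = 20.0
    tau_minus: float = 30.0
    gbar_max: float = 1.5

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("STDP amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.gbar_max <= 0:
            raise ValueError("gbar_max must be positive")

    def copy(self, **changes) -> "StdpParameters":
        return replace(self, **changes)


@dataclass
class TraceState:
    """Online spike-timing traces: scalar M <= 0 and per-synapse P >= 0."""

    m: float = 0.0
    p: np.ndarray = field(default_factory=lambda: np.zeros(20))

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)


def stdp_delta_w(t_pre: float, t_post: float, p: StdpParameters) -> float:
    """Closed-form weight change (dimensionless) for one isolated spike pair.

    Pre before post (t_post > t_pre) potentiates by
    A_plus * exp((t_pre - t_post)/tau_plus); post before pre depresses by
    A_minus * exp(-(t_pre - t_post)/tau_minus).  Simultaneous spikes
    produce no change (both branches are strict inequalities).
    """
    if t_post > t_pre:
        return p.a_plus * math.exp((t_pre - t_post) / p.tau_plus)
    if t_post < t_pre:
        return -p.a_minus * math.exp(-(t_pre - t_post) / p.tau_minus)
    return 0.0


def decay_traces(traces: TraceState, dt: float, p: StdpParameters) -> TraceState:
    """One forward-Euler decay step of both traces (in place)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    traces.m *= (1.0 - dt / p.tau_minus)
    traces.p *= (1.0 - dt / p.tau_plus)
    return traces


def on_presynaptic_spike(i: int, traces: TraceState, weights: np.ndarray,
                         p: StdpParameters) -> None:
    """Event update for a spike of presynaptic neuron ``i`` (in place).

    The synapse's own trace P_i jumps by A_plus and its peak conductance
    absorbs the (non-positive) postsynaptic trace: w_i += M * gbar_max,
    clipped to [0, gbar_max].
    """
    if not 0 <= i < traces.p.size:
        raise IndexError(f"synapse index {i} out of range")
    traces.p[i] += p.a_plus
    weights[i] = min(max(weights[i] + traces.m * p.gbar_max, 0.0), p.gbar_max)


def on_postsynaptic_spike(traces: TraceState, weights: np.ndarray,
                          p: StdpParameters) -> None:
    """Event update for a postsynaptic spike (in place).

    M jumps down by A_minus and every synapse absorbs its own
    (non-negative) presynaptic trace: w_i += P_i * gbar_max, clipped.
    """
    traces.m -= p.a_minus
    np.clip(weights + traces.p * p.gbar_max, 0.0, p.gbar_max, out=weights)
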