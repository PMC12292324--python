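"""Poisson presynaptic spike trains and conductance-based synaptic currents.

The neuron is bombarded by ``n_exc`` excitatory and ``n_inh`` inhibitory
presynaptic trains.  Each train is a Bernoulli approximation to a Poisson
process: in every time bin of width dt a spike occurs with probability
rate*dt.  A presynaptic spike at an excitatory synapse i increments the
pooled excitatory conductance gE by that synapse's peak conductance
``gbar[i]`` (which is what plasticity acts on); inhibitory synapses are
static and share a single peak conductance.  Between spikes both pooled
conductances decay exponentially with their own time constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SpikeTrain",
    "SynapseBank",
    "generate_poisson_train",
    "decay_and_inject",
    "synaptic_current",
    "write_spike_trains",
    "read_spike_trains",
]


@dataclass
class SpikeTrain:
    """Ordered spike times (ms) on a discrete simulation grid."""

    times: np.ndarray
    duration: float
    dt: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.times.size and (self.times[0] < 0 or self.times[-1] >= self.duration + self.dt):
            raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def count(self) -> int:
        return len(self)

    def isi(self) -> np.ndarray:
        """Inter-spike intervals (ms)."""
        return np.diff(self.times)


def generate_poisson_train(rate_hz: float, duration: float, dt: float,
                           rng) -> SpikeTrain:
    """Bernoulli-per-bin Poisson spike train.

    ``rate_hz`` is the firing rate in spikes/s; the per-bin spike
    probability is (rate_hz/1000)*dt so at most one spike can occur per
    bin.  ``rng`` is a :class:`numpy.random.Generator` or an integer seed.
    """
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = rate_hz * 1e-3 * dt
    if p >= 1.0:
        import warnings
        warnings.warn("rate*dt >= 1: Bernoulli approximation saturates",
                      stacklevel=2)
    n_bins = int(round(duration / dt))
    hits = rng.random(n_bins) < p
    times = np.nonzero(hits)[0] * dt
    return SpikeTrain(times=times.astype(float), duration=duration, dt=dt)


def decay_and_inject(g: float, spikes_now: int, gbar_each: float,
                     tau: float, dt: float) -> float:
    """One forward-Euler step of the pooled conductance.

    g decays by the factor (1 - dt/tau) and every spike arriving in this
    step injects ``gbar_each``.  The result is never negative as long as
    dt < tau and the inputs are non-negative.
    """
    if tau <= 0 or dt <= 0:
        raise ValueError("tau and dt must be positive")
    return g * (1.0 - dt / tau) + spikes_now * gbar_each


def synaptic_current(g_exc: float, g_inh: float, v: float,
                     e_exc: float, e_inh: float) -> dict:
    """Ohmic synaptic currents (pA) and their depolarising total.

    I_E = gE (V - E_E), I_I = gI (V - E_I); the net current entering the
    membrane equation is I_syn = -I_E - I_I, so excitation (V < E_E)
    depolarises and inhibition (V > E_I) hyperpolarises.
    """
    i_exc = g_exc * (v - e_exc)
    i_inh = g_inh * (v - e_inh)
    return {"i_exc": i_exc, "i_inh": i_inh, "i_syn": -i_exc - i_inh}


@dataclass
class SynapseBank:
    """Peak conductances and pooled conductance state of all synapses.

    Excitatory synapses carry individual peak conductances ``gbar``
    (the quantities modified by STDP); inhibitory synapses share the
    fixed peak ``gbar_inh``.
    """

    n_exc: int = 20
    n_inh: int = 80
    gbar_init: float = 1.5
    gbar_inh: float = 0.5
    tau_exc: float = 2.0
    tau_inh: float = 5.0
    e_exc: float = 0.0
    e_inh: float = -65.0
    gbar: np.ndarray = field(default=None)  # type: ignore[assignment]
    g_exc: float = 0.0
    g_inh: float = 0.0

    def __post_init__(self) -> None:
        if self.gbar is None:
            self.gbar = np.full(self.n_exc, self.gbar_init, dtype=float)
        else:
            self.gbar = np.asarray(self.gbar, dtype=float)
            if self.gbar.shape != (self.n_exc,):
                raise ValueError("gbar must have length n_exc")


def write_spike_trains(path, trains: dict) -> None:
    """Write spike trains as two-column text ``train_id<TAB>time_ms``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("train_id\ttime_ms\n")
        for train_id, train in trains.items():
            times = train.times if isinstance(train, SpikeTrain) else np.asarray(train)
            for t in times:
                fh.write(f"{train_id}\t{t:.6g}\n")


def read_spike_trains(path, duration: float = None, dt: float = 0.1) -> dict:
    """Read trains written by :func:`write_spike_trains`.

    When ``duration`` is omitted it is taken as the last spike time plus
    one bin.
    """
    path = Path(path)
    groups: dict = {}
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("train_id"):
            fh.seek(0)
        for line in fh:
            if not line.strip():
                continue
            train_id, t = line.split("\t")
            groups.setdefault(train_id, []).append(float(t))
    out = {}
    for train_id, times in groups.items():
        times = np.sort(np.asarray(times, dtype=float))
        dur = duration if duration is not None else (times[-1] + dt if times.size else dt)
        out[train_id] = SpikeTrain(times=times, duration=dur, dt=dt)
    return out
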