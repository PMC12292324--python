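"""STDP window, trace dynamics and weight-bound invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stnsim.fixtures import make_paired_spike_protocol
from stnsim.plasticity import (StdpParameters, TraceState, decay_traces,
                               on_postsynaptic_spike, on_presynaptic_spike,
                               stdp_delta_w)

PARAMS = StdpParameters(a_plus=0.005, a_minus=0.00525,
                        tau_plus=20.0, tau_minus=20.0, gbar_max=1.5)


class TestPairWindow:
    def test_potentiation_at_one_time_constant(self):
        dw = stdp_delta_w(0.0, PARAMS.tau_plus, PARAMS)
        assert dw == pytest.approx(0.005 * math.exp(-1), rel=1e-12)
        assert dw == pytest.approx(1.839397e-3, rel=1e-5)

    def test_depression_at_one_time_constant(self):
        dw = stdp_delta_w(20.0, 0.0, PARAMS)
        assert dw == pytest.approx(-0.00525 * math.exp(-1), rel=1e-12)
        assert dw == pytest.approx(-1.931367e-3, rel=1e-5)

    def test_window_vanishes_at_large_lag(self):
        assert abs(stdp_delta_w(0.0, 2000.0, PARAMS)) < 1e-40
        assert abs(stdp_delta_w(2000.0, 0.0, PARAMS)) < 1e-40

    def test_simultaneous_spikes_are_neutral(self):
        assert stdp_delta_w(5.0, 5.0, PARAMS) == 0.0

    @given(st.floats(-200, 200), st.floats(-200, 200))
    @settings(max_examples=200, deadline=None)
    def test_sign_follows_spike_order(self, t_pre, t_post):
        dw = stdp_delta_w(t_pre, t_post, PARAMS)
        if t_post > t_pre:
            assert dw > 0
        elif t_post < t_pre:
            assert dw < 0
        else:
            assert dw == 0


class TestTraces:
    def test_zero_traces_are_fixed_point(self):
        traces = TraceState(m=0.0, p=np.zeros(4))
        decay_traces(traces, 0.1, PARAMS)
        assert traces.m == 0.0 and np.all(traces.p == 0.0)

    def test_one_step_decay_arithmetic(self):
        traces = TraceState(m=-1.0, p=np.full(2, PARAMS.a_plus))
        decay_traces(traces, 0.1, PARAMS)
        assert traces.m == pytest.approx(-1.0 * (1 - 0.1 / 20.0))
        assert traces.p[0] == pytest.approx(PARAMS.a_plus * 0.995)

    def test_euler_decay_approaches_exponential(self):
        traces = TraceState(m=-PARAMS.a_minus, p=np.zeros(1))
        dt = 0.01
        for _ in range(int(PARAMS.tau_minus / dt)):
            decay_traces(traces, dt, PARAMS)
        assert traces.m == pytest.approx(-PARAMS.a_minus * math.exp(-1),
                                         rel=1e-3)

    def test_presynaptic_event(self):
        traces = TraceState(m=-PARAMS.a_minus, p=np.zeros(3))
        weights = np.full(3, PARAMS.gbar_max)
        on_presynaptic_spike(1, traces, weights, PARAMS)
        assert traces.p[1] == PARAMS.a_plus and traces.p[0] == 0.0
        assert weights[1] == pytest.approx(
            PARAMS.gbar_max * (1 - PARAMS.a_minus))
        assert weights[0] == PARAMS.gbar_max  # untouched

    def test_presynaptic_event_clips_at_zero(self):
        traces = TraceState(m=-1.0, p=np.zeros(1))
        weights = np.array([0.01])
        on_presynaptic_spike(0, traces, weights, PARAMS)
        assert weights[0] == 0.0

    def test_postsynaptic_event(self):
        traces = TraceState(m=0.0, p=np.array([PARAMS.a_plus, 0.0]))
        weights = np.array([0.0, PARAMS.gbar_max])
        on_postsynaptic_spike(traces, weights, PARAMS)
        assert traces.m == -PARAMS.a_minus
        assert weights[0] == pytest.approx(PARAMS.a_plus * PARAMS.gbar_max)
        assert weights[1] == PARAMS.gbar_max  # clipped at the ceiling

    def test_index_out_of_range(self):
        traces = TraceState(m=0.0, p=np.zeros(2))
        with pytest.raises(IndexError):
            on_presynaptic_spike(5, traces, np.zeros(2), PARAMS)


@given(st.lists(st.tuples(st.sampled_from(["pre", "post", "decay"]),
                          st.integers(0, 3)), min_size=1, max_size=300))
@settings(max_examples=100, deadline=None)
def test_trace_signs_and_weight_bounds_under_random_events(events):
    """M stays non-positive, P non-negative and weights inside [0, gmax]
    for any interleaving of events."""
    traces = TraceState(m=0.0, p=np.zeros(4))
    weights = np.full(4, 0.75)
    for kind, idx in events:
        if kind == "pre":
            on_presynaptic_spike(idx, traces, weights, PARAMS)
        elif kind == "post":
            on_postsynaptic_spike(traces, weights, PARAMS)
        else:
            decay_traces(traces, 0.1, PARAMS)
        assert traces.m <= 0.0
        assert np.all(traces.p >= 0.0)
        assert np.all((weights >= 0.0) & (weights <= PARAMS.gbar_max))


@pytest.mark.parametrize("delta", [-50.0, -20.0, -5.0, -1.0, 1.0, 5.0, 20.0, 50.0])
def test_trace_mechanism_matches_closed_form_for_isolated_pairs(delta):
    """For one isolated pre/post pair at lag delta, the event-driven trace
    update reproduces the closed-form window value scaled by gbar_max, up
    to the forward-Euler decay error O(dt/tau)."""
    dt = 0.01
    pre, post = make_paired_spike_protocol(delta, n_pairs=1,
                                           pair_interval=400.0)
    events = sorted([(t, "pre") for t in pre] + [(t, "post") for t in post])
    w0 = 0.75
    traces = TraceState(m=0.0, p=np.zeros(1))
    weights = np.array([w0])
    t = 0.0
    for ev_time, kind in events:
        while t < ev_time - 1e-9:
            decay_traces(traces, dt, PARAMS)
            t += dt
        if kind == "pre":
            on_presynaptic_spike(0, traces, weights, PARAMS)
        else:
            on_postsynaptic_spike(traces, weights, PARAMS)
    expected = w0 + stdp_delta_w(pre[0], post[0], PARAMS) * PARAMS.gbar_max
    tol = PARAMS.a_plus * PARAMS.gbar_max * (dt / min(PARAMS.tau_plus,
                                                      PARAMS.tau_minus)) * 50
    assert weights[0] == pytest.approx(expected, abs=tol)


def test_cumulative_pairing_accumulates_linearly():
    """n well-separated potentiating pairs shift the weight by about
    n * A_plus * exp(delta/tau) * gbar_max before clipping."""
    dt = 0.05
    delta = -10.0
    n_pairs = 60
    pre, post = make_paired_spike_protocol(delta, n_pairs=n_pairs,
                                           pair_interval=500.0)
    events = sorted([(t, "pre") for t in pre] + [(t, "post") for t in post])
    traces = TraceState(m=0.0, p=np.zeros(1))
    weights = np.array([0.0])
    t = 0.0
    for ev_time, kind in events:
        steps = int(round((ev_time - t) / dt))
        for _ in range(steps):
            decay_traces(traces, dt, PARAMS)
        t = ev_time
        if kind == "pre":
            on_presynaptic_spike(0, traces, weights, PARAMS)
        else:
            on_postsynaptic_spike(traces, weights, PARAMS)
    expected = n_pairs * PARAMS.a_plus * math.exp(delta / PARAMS.tau_plus) \
        * PARAMS.gbar_max
    assert weights[0] == pytest.approx(expected, rel=0.05)


def test_zero_amplitudes_freeze_weights():
    p0 = StdpParameters(a_plus=0.0, a_minus=0.0)
    traces = TraceState(m=0.0, p=np.zeros(2))
    weights = np.array([0.3, 1.2])
    for _ in range(50):
        on_presynaptic_spike(0, traces, weights, p0)
        on_postsynaptic_spike(traces, weights, p0)
        decay_traces(traces, 0.1, p0)
    assert np.array_equal(weights, [0.3, 1.2])


def test_overlapping_pairs_rejected():
    with pytest.raises(ValueError):
        make_paired_spike_protocol(10.0, n_pairs=3, pair_interval=5.0)
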