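"""Membrane kinetics: sigmoid midpoints, monotonicity, currents, state."""

import math

import numpy as np
import pytest

from stnsim.model_core import (ConfigurationError, NeuronParameters,
                               NeuronState, dbs_current,
                               gating_and_calcium_derivatives, initial_state,
                               ionic_currents, steady_state, time_constant)

B_OFFSET = 1.0 / (1.0 + math.exp(4.0))
VGRID = np.linspace(-100.0, 40.0, 281)


@pytest.mark.parametrize("gate,arg,expected", [
    ("m", -30.0, 0.5),
    ("h", -39.0, 0.5),
    ("n", -32.0, 0.5),
    ("a", -63.0, 0.5),
    ("r", -67.0, 0.5),
    ("c", -20.0, 0.5),
    ("b", 0.4, 0.5 - B_OFFSET),
])
def test_steady_state_midpoints(gate, arg, expected):
    assert steady_state(gate, arg) == pytest.approx(expected, abs=1e-15)


def test_b_steady_state_value():
    # direct evaluation of the resolved formula at its half-activation
    assert steady_state("b", 0.4) == pytest.approx(0.48201379, abs=1e-6)


@pytest.mark.parametrize("gate,increasing", [
    ("m", True), ("n", True), ("a", True), ("c", True),
    ("h", False), ("r", False),
])
def test_steady_state_monotone_in_voltage(gate, increasing):
    values = np.array([steady_state(gate, v) for v in VGRID])
    diffs = np.diff(values)
    assert np.all(diffs > 0) if increasing else np.all(diffs < 0)
    assert np.all((values >= 0) & (values <= 1))


@pytest.mark.parametrize("gate,v,expected", [
    ("h", -57.0, 251.0),
    ("n", -80.0, 51.0),
    ("r", -68.0, 15.85),
    ("c", -80.0, 6.0),
])
def test_time_constant_midpoints(gate, v, expected):
    assert time_constant(gate, v) == pytest.approx(expected, abs=1e-12)


def test_time_constants_positive_and_bounded():
    bounds = {"h": (1.0, 501.0), "n": (1.0, 101.0),
              "r": (7.1, 24.6), "c": (1.0, 11.0)}
    for gate, (lo, hi) in bounds.items():
        taus = np.array([time_constant(gate, v) for v in VGRID])
        # the sigmoids saturate to the asymptotes in float arithmetic
        assert np.all(taus >= lo) and np.all(taus <= hi)
        assert np.all(taus > 0)


def test_unknown_gate_rejected():
    with pytest.raises(ConfigurationError):
        steady_state("x", 0.0)
    with pytest.raises(ConfigurationError):
        time_constant("m", 0.0)  # m has no dynamics


class TestIonicCurrents:
    params = NeuronParameters()

    def state(self, **kw):
        base = dict(v=-60.0, h=0.5, n=0.5, r=0.5, c=0.5, ca=0.5)
        base.update(kw)
        return NeuronState(**base)

    def test_leak_vanishes_at_reversal(self):
        cur = ionic_currents(self.state(v=self.params.e_leak), self.params)
        assert cur["i_leak"] == 0.0

    def test_leak_arithmetic(self):
        cur = ionic_currents(self.state(v=-55.0), self.params)
        assert cur["i_leak"] == pytest.approx(2.25 * 5.0)

    def test_ahp_vanishes_without_calcium(self):
        cur = ionic_currents(self.state(ca=0.0), self.params)
        assert cur["i_ahp"] == 0.0

    @pytest.mark.parametrize("name,e_rev", [
        ("i_leak", -60.0), ("i_na", 55.0), ("i_k", -80.0),
        ("i_ca", 140.0), ("i_ahp", -80.0),
    ])
    def test_ohmic_sign_relative_to_reversal(self, name, e_rev):
        above = ionic_currents(self.state(v=e_rev + 5.0), self.params)[name]
        below = ionic_currents(self.state(v=e_rev - 5.0), self.params)[name]
        assert above > 0 > below

    def test_t_current_variants_differ(self):
        printed = ionic_currents(self.state(), self.params)["i_t"]
        classic = ionic_currents(
            self.state(), self.params.copy(t_current_variant="rubin_terman"))["i_t"]
        assert printed != classic
        # printed variant: gT * a^3 * b^2 * r * (V - 0)
        a = steady_state("a", -60.0)
        b = steady_state("b", 0.5)
        assert printed == pytest.approx(0.5 * a ** 3 * b ** 2 * 0.5 * -60.0)


class TestDbsCurrent:
    params = NeuronParameters()

    def test_onset_value(self):
        assert dbs_current(0.0, self.params) == pytest.approx(5.0)

    def test_quarter_period_peak(self):
        assert dbs_current(0.25, self.params) == pytest.approx(10.0)

    def test_zero_mean_oscillation(self):
        t = np.linspace(0.0, 1.0, 1001)[:-1]
        values = np.array([dbs_current(x, self.params) for x in t])
        assert values.mean() == pytest.approx(5.0, abs=1e-12)
        assert values.min() >= 0.0 and values.max() <= 10.0


class TestDerivativesAndInitialState:
    params = NeuronParameters()

    def test_gating_fixed_point(self):
        v = -57.0
        state = NeuronState(v=v, h=steady_state("h", v),
                            n=steady_state("n", v), r=steady_state("r", v),
                            c=steady_state("c", v), ca=0.3)
        d = gating_and_calcium_derivatives(state, self.params)
        for key in ("dh", "dn", "dr", "dc"):
            assert d[key] == pytest.approx(0.0, abs=1e-15)

    def test_calcium_balance_fixed_point(self):
        state = initial_state(self.params)
        cur = ionic_currents(state, self.params)
        ca_eq = (cur["i_ca"] - cur["i_t"]) / self.params.k_ca
        # i_ca/i_t depend on ca only through nothing: ca enters i_ahp only
        balanced = NeuronState(v=state.v, h=state.h, n=state.n, r=state.r,
                               c=state.c, ca=ca_eq)
        d = gating_and_calcium_derivatives(balanced, self.params)
        assert d["dca"] == pytest.approx(0.0, abs=1e-15)

    def test_depression_rate_from_empty_gate(self):
        state = NeuronState(v=-57.0, h=0.0, n=0.5, r=0.5, c=0.5, ca=0.3)
        d = gating_and_calcium_derivatives(state, self.params)
        assert d["dh"] == pytest.approx(
            0.75 * steady_state("h", -57.0) / 251.0)

    def test_initial_state_definitions(self):
        state = initial_state(self.params)
        v0 = self.params.v_init
        assert state.v == v0 == -65.0
        assert state.h == steady_state("h", v0)
        assert state.n == steady_state("n", v0)
        assert state.r == steady_state("r", v0)
        assert state.c == steady_state("c", v0)
        a0 = steady_state("a", v0)
        b0 = steady_state("b", steady_state("r", v0))
        assert state.ca == pytest.approx(a0 / (a0 + b0))
        assert state.refractory_remaining == 0.0


def test_parameter_invariants_enforced():
    with pytest.raises(ConfigurationError):
        NeuronParameters(g_leak=-1.0)
    with pytest.raises(ConfigurationError):
        NeuronParameters(v_reset=-50.0)  # above threshold
    with pytest.raises(ConfigurationError):
        NeuronParameters(t_current_variant="bogus")
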