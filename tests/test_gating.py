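"""Two-gate ASIC1a current model: steady states, rates, gate ODEs."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from asicsim import (
    ASICGateState,
    StabilityError,
    asic_current,
    equilibrium_gates,
    make_constant,
    make_step,
    rate,
    simulate_voltage_clamp,
    steady_state,
    step_gates,
)
from asicsim.params import RateFunctionParams, SteadyStateParams
from asicsim.sweeps import ramp_wave


class TestSteadyState:
    def test_midpoint_occupancy_is_half(self, asic_params):
        for gate in (asic_params.act, asic_params.sens):
            assert steady_state(gate, gate.midpoint) == pytest.approx(0.5)

    def test_spot_values_match_hand_evaluation(self, asic_params):
        # independent evaluations of the published steady-state forms
        assert steady_state(asic_params.act, 6.0) == pytest.approx(
            0.9922221006656836, rel=1e-12)
        assert steady_state(asic_params.sens, 6.0) < 1e-10  # fully desensitized
        assert asic_params.act.midpoint == pytest.approx(
            7 - np.log10(23.67) / 2.797)

    def test_midpoint_independent_of_steepening(self):
        for f in (1.0, 1.48):
            p = SteadyStateParams(K=23.67, H=2.797, F=f)
            assert steady_state(p, p.midpoint) == pytest.approx(0.5)
            assert p.midpoint == SteadyStateParams(K=23.67, H=2.797).midpoint

    def test_monotone_over_physiological_range(self, asic_params):
        ph = np.linspace(5.0, 8.5, 301)
        a = steady_state(asic_params.act, ph)
        s = steady_state(asic_params.sens, ph)
        assert np.all(np.diff(a) < 0)  # activation opens on acidification
        assert np.all(np.diff(s) > 0)
        assert np.all((a > 0) & (a < 1) & (s > 0) & (s < 1))

    def test_rejects_nonfinite_ph(self, asic_params):
        with pytest.raises(ValueError):
            steady_state(asic_params.act, np.nan)

    @given(ph=st.floats(min_value=5.0, max_value=8.5))
    def test_bounded_in_unit_interval(self, ph):
        p = SteadyStateParams(K=11.18, H=-9.448, delta=0.15)
        assert 0.0 < float(steady_state(p, ph)) < 1.0


class TestRate:
    def test_spot_values_match_hand_evaluation(self, asic_params):
        # at pH = c1 the first sigmoid contributes exactly a1/2
        assert rate(asic_params.rate_act, 6.392) == pytest.approx(
            0.17549007466811548, rel=1e-12)
        # recovery rate near physiological pH: time constant of seconds
        assert rate(asic_params.rate_sens, 7.4) == pytest.approx(
            3.0466e-4, rel=1e-3)

    def test_positive_and_bounded(self, asic_params):
        ph = np.linspace(-5, 20, 501)
        for p in (asic_params.rate_act, asic_params.rate_sens):
            r = rate(p, ph)
            assert np.all(r > 0)
            assert np.all(r < p.ceiling)

    def test_sigmoid_limits(self):
        p = RateFunctionParams(a1=0.5, b1=5.0, c1=6.5, a2=2.0, b2=-5.0, c2=8.0)
        # b1 > 0: first term -> a1 at acidic extreme; b2 < 0: second -> 0
        assert rate(p, -50.0) == pytest.approx(p.a1, rel=1e-6)
        assert rate(p, 50.0) == pytest.approx(p.a2, rel=1e-6)

    def test_amplitudes_must_be_positive(self):
        with pytest.raises(ValueError):
            RateFunctionParams(a1=-1.0, b1=1, c1=7, a2=1.0, b2=-1, c2=7)


class TestStepGates:
    def test_steady_state_is_fixed_point(self, asic_params):
        st0 = equilibrium_gates(6.5, asic_params)
        st1 = step_gates(st0, 6.5, 0.05, asic_params)
        assert st1.a == pytest.approx(st0.a, abs=1e-15)
        assert st1.s == pytest.approx(st0.s, abs=1e-15)

    @pytest.mark.parametrize("dt", [0.1, 0.01])
    def test_relaxation_matches_closed_form(self, asic_params, dt):
        """At constant pH the Euler trajectory converges O(dt) to
        a_inf + (a0 - a_inf) exp(-r t)."""
        ph = 6.8
        n = int(round(50.0 / dt))
        st_ = ASICGateState(a=0.0, s=1.0)
        for _ in range(n):
            st_ = step_gates(st_, ph, dt, asic_params)
        r = float(rate(asic_params.rate_act, ph))
        a_inf = float(steady_state(asic_params.act, ph))
        exact = a_inf + (0.0 - a_inf) * np.exp(-r * n * dt)
        assert st_.a == pytest.approx(exact, abs=2.0 * r * dt)
        assert 0.0 <= st_.a <= 1.0 and 0.0 <= st_.s <= 1.0

    def test_euler_error_shrinks_linearly_with_dt(self, asic_params):
        ph, t_end = 6.8, 50.0
        r = float(rate(asic_params.rate_act, ph))
        a_inf = float(steady_state(asic_params.act, ph))
        errs = []
        for dt in (0.2, 0.02):
            st_ = ASICGateState(a=0.0, s=1.0)
            for _ in range(int(round(t_end / dt))):
                st_ = step_gates(st_, ph, dt, asic_params)
            errs.append(abs(st_.a - (a_inf * (1 - np.exp(-r * t_end)))))
        assert errs[1] < 0.2 * errs[0]  # ~10x smaller for 10x smaller dt

    def test_unstable_dt_rejected(self, asic_params):
        # at alkaline pH the fast rate approaches its a2 plateau (~234 ms^-1)
        with pytest.raises(StabilityError):
            step_gates(ASICGateState(0.5, 0.5), 9.5, 0.1, asic_params)


class TestASICCurrent:
    def test_reversal_potential_zeroes_current(self, asic_params):
        st_ = ASICGateState(1.0, 1.0)
        assert asic_current(st_, asic_params.e_asic, asic_params) == 0.0

    def test_defining_product(self, asic_params):
        st_ = ASICGateState(0.5, 0.5)
        assert asic_current(st_, -60.0, asic_params) == pytest.approx(
            10 * 0.25 * (-110.0))

    def test_closed_gate_conducts_nothing(self, asic_params):
        for vm in (-100.0, 0.0, 100.0):
            assert asic_current(ASICGateState(0.0, 1.0), vm, asic_params) == 0


class TestVoltageClamp:
    def test_constant_neutral_ph_gives_flat_tiny_current(self, asic_params):
        wave = make_constant(7.4, 2000.0)
        tr = simulate_voltage_clamp(wave, asic_params, dt=0.05)
        window = float(steady_state(asic_params.act, 7.4)
                       * steady_state(asic_params.sens, 7.4))
        expected = asic_params.g_asic * window * (-60 - asic_params.e_asic)
        assert np.allclose(tr.values, expected, atol=1e-9)
        assert abs(expected) < 1.0  # near-zero window current

    def test_acid_step_transient_inward_then_desensitizes(self, asic_params):
        wave = make_step(7.4, 6.0, 500.0, 1.0, duration=8000.0)
        tr = simulate_voltage_clamp(wave, asic_params, dt=0.01)
        peak = tr.values.min()
        assert peak < -500.0  # large inward current
        assert abs(tr.values[-1]) < 0.02 * abs(peak)  # s gate closes

    def test_deactivation_on_return_to_neutral(self, asic_params):
        acid = make_step(7.4, 6.0, 100.0, 1.0, duration=220.0)
        back = make_step(6.0, 7.4, 0.0, 1.0, duration=300.0)
        wave = acid.then(back)
        tr = simulate_voltage_clamp(wave, asic_params, dt=0.01)
        k_ret = int(220.0 / 0.01)
        i_before = tr.values[k_ret]
        i_after = tr.values[k_ret + int(20.0 / 0.01)]  # ~6 deactivation taus
        assert abs(i_after) < 0.05 * abs(i_before)

    def test_zero_window_limit_for_mild_ramp(self, asic_params):
        """A ramp ending at pH >= 7.2 passes < 1% of the 1-s-ramp-to-6.0 peak."""
        tr_acid = simulate_voltage_clamp(
            ramp_wave(6.0, 1.0, plateau=10_000.0), asic_params, dt=0.05)
        tr_mild = simulate_voltage_clamp(
            ramp_wave(7.2, 1.0, plateau=10_000.0), asic_params, dt=0.05)
        assert np.abs(tr_mild.values).max() < \
            0.01 * np.abs(tr_acid.values).max()

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_gates_bounded_for_random_waveforms(self, asic_params, seed):
        rng = np.random.default_rng(seed)
        levels = rng.uniform(5.0, 8.5, size=4)
        wave = make_constant(float(levels[0]), 200.0)
        for lv in levels[1:]:
            wave = wave.then(make_step(wave.value_at_end(), float(lv), 0.0,
                                       float(rng.uniform(0, 50)),
                                       duration=200.0))
        _, a, s = simulate_voltage_clamp(wave, asic_params, dt=0.005,
                                         record_gates=True)
        for g in (a.values, s.values):
            assert np.all((g >= 0.0) & (g <= 1.0))

    def test_kernel_matches_python_stepper(self, asic_params):
        wave = make_step(7.4, 6.4, 10.0, 5.0, duration=100.0)
        dt = 0.01
        tr, a_tr, s_tr = simulate_voltage_clamp(wave, asic_params, dt=dt,
                                                record_gates=True)
        st_ = equilibrium_gates(7.4, asic_params)
        ph = wave.grid(dt)
        for k in range(0, 2000):
            assert a_tr.values[k] == pytest.approx(st_.a, abs=1e-12)
            assert s_tr.values[k] == pytest.approx(st_.s, abs=1e-12)
            st_ = step_gates(st_, float(ph[k]), dt, asic_params)
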