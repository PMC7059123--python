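"""Trace metrics: peak/charge, exponential and Hill fits, spike detection,
phase-plane analysis."""

import numpy as np
import pytest

from asicsim import (
    Trace,
    detect_aps,
    fit_hill,
    fit_monoexponential,
    normalize_to_fast,
    peak_and_charge,
    phase_plane,
)
from asicsim.analysis import charge_window


def spike_train(n_spikes: int, period_ms: float, dt: float = 0.05,
                total_ms: float | None = None) -> Trace:
    """Stereotyped triangular APs (-65 mV baseline, +30 mV peaks)."""
    total_ms = total_ms or (n_spikes + 2) * period_ms
    t = np.arange(0.0, total_ms, dt)
    v = np.full_like(t, -65.0)
    width = 2.0  # ms from onset to peak and back
    for i in range(n_spikes):
        t0 = 100.0 + i * period_ms
        tri = 1.0 - np.abs(t - (t0 + width)) / width
        v = np.maximum(v, -65.0 + 95.0 * np.clip(tri, 0.0, 1.0))
    return Trace(v, dt, "mV")


class TestPeakAndCharge:
    def test_rectangular_pulse(self):
        dt = 1.0
        i = np.zeros(3000)
        i[1000:2000] = -100.0
        tr = Trace(i, dt, "uA/cm^2")
        i_peak, q = peak_and_charge(tr)
        assert i_peak == -100.0
        assert q == pytest.approx(-0.1, rel=1e-3)  # mC/cm^2

    def test_zero_trace(self):
        i_peak, q = peak_and_charge(Trace(np.zeros(100), 1.0, "uA/cm^2"))
        assert i_peak == 0.0 and q == 0.0

    def test_empty_window_rejected(self):
        tr = Trace(np.zeros(100), 1.0, "uA/cm^2")
        with pytest.raises(ValueError):
            peak_and_charge(tr, (50.0, 40.0))

    def test_charge_converges_with_sampling(self):
        t = np.arange(0, 500, 0.5)
        pulse = -80.0 * np.exp(-((t - 100) / 30.0) ** 2)
        q_coarse = peak_and_charge(Trace(pulse, 0.5, "uA/cm^2"))[1]
        t2 = np.arange(0, 500, 0.25)
        q_fine = peak_and_charge(
            Trace(-80.0 * np.exp(-((t2 - 100) / 30.0) ** 2), 0.25,
                  "uA/cm^2"))[1]
        assert abs(q_fine - q_coarse) < 1e-3 * abs(q_coarse)

    def test_charge_window_caps_at_one_percent_of_peak(self):
        t = np.arange(0, 2000, 1.0)
        i = -100.0 * np.exp(-np.maximum(t - 100, 0) / 50.0)
        i[t < 100] = 0.0
        tr = Trace(i, 1.0, "uA/cm^2")
        w = charge_window(tr, 0.0)
        assert w[1] == pytest.approx(100 + 50 * np.log(100), abs=2.0)


class TestNormalizeToFast:
    def test_reference_maps_to_one(self):
        out = normalize_to_fast({"fast": -800.0, "slow": -200.0}, "fast")
        assert out["fast"] == 1.0
        assert out["slow"] == pytest.approx(0.25)

    def test_gain_invariance(self):
        a = normalize_to_fast({"fast": -800.0, "slow": -200.0}, "fast")
        b = normalize_to_fast({"fast": -80.0, "slow": -20.0}, "fast")
        assert a == b

    def test_zero_reference_rejected(self):
        with pytest.raises(ZeroDivisionError):
            normalize_to_fast({"fast": 0.0}, "fast")


class TestMonoExponential:
    def test_exact_exponential_recovered(self):
        dt = 1.0
        t = np.arange(0, 3000, dt)
        tr = Trace(-50.0 * np.exp(-t / 350.0) + 5.0, dt, "uA/cm^2")
        fit = fit_monoexponential(tr, (0.0, 2999.0), "decay")
        assert fit.success
        assert fit.tau == pytest.approx(350.0, rel=1e-3)
        assert fit.offset == pytest.approx(5.0, abs=1e-6)

    def test_noisy_exponential_within_5_percent(self, rng):
        dt = 1.0
        t = np.arange(0, 3000, dt)
        clean = -50.0 * np.exp(-t / 350.0)
        tr = Trace(clean + rng.normal(0, 1.0, len(t)), dt, "uA/cm^2")
        fit = fit_monoexponential(tr, (0.0, 2999.0), "decay")
        assert fit.success
        assert fit.tau == pytest.approx(350.0, rel=0.05)

    def test_constant_trace_flagged(self):
        tr = Trace(np.full(500, 3.0), 1.0, "uA/cm^2")
        fit = fit_monoexponential(tr, (0.0, 499.0), "decay")
        assert not fit.success

    def test_too_few_samples_rejected(self):
        tr = Trace(np.arange(5.0), 1.0, "uA/cm^2")
        with pytest.raises(ValueError):
            fit_monoexponential(tr, (0.0, 4.0), "decay")


class TestHillFit:
    @staticmethod
    def hill(ph, i_max=1.0, ph50=6.5, nh=2.0):
        return i_max / (1.0 + 10.0 ** (nh * (ph - ph50)))

    def test_exact_recovery(self):
        ph = np.linspace(5.5, 7.5, 9)
        fit = fit_hill(list(zip(ph, self.hill(ph))))
        assert fit.success
        assert fit.ph50 == pytest.approx(6.5, abs=1e-3)
        assert fit.n_h == pytest.approx(2.0, rel=1e-3)
        assert fit.i_max == pytest.approx(1.0, rel=1e-3)
        assert fit.predict(fit.ph50) == pytest.approx(fit.i_max / 2)

    def test_ssd_direction_recovered(self):
        ph = np.linspace(6.8, 7.6, 9)
        resp = 1.0 / (1.0 + 10.0 ** (-9.0 * (ph - 7.2)))
        fit = fit_hill(list(zip(ph, resp)))
        assert fit.success
        assert fit.sign == -1
        assert fit.ph50 == pytest.approx(7.2, abs=1e-3)

    def test_flat_input_flagged(self):
        ph = np.linspace(6.0, 7.5, 8)
        fit = fit_hill(list(zip(ph, np.full(8, 0.7))))
        assert not fit.success

    def test_too_few_points_flagged(self):
        fit = fit_hill([(6.0, 1.0), (7.0, 0.0), (6.5, 0.5)])
        assert not fit.success


class TestDetectAPs:
    def test_flat_trace_has_no_spikes(self):
        mets = detect_aps(Trace(np.full(10_000, -60.0), 0.05, "mV"))
        assert mets.count == 0
        assert not mets.frequency_defined

    def test_constructed_train_count_and_frequency(self):
        """12 spikes spaced 166.3 ms: firing time = 11 intervals plus the
        final repolarisation ~ 1.832 s, frequency ~ 6.5 Hz."""
        tr = spike_train(12, 166.3)
        mets = detect_aps(tr)
        assert mets.count == 12
        # extra beyond the 11 periods: peak-to--20 fall (2*50/95 ms) plus the
        # 2-ms rise minus the onset 0-crossing delay (2*65/95 ms)
        expected_ft = 11 * 166.3 + 2.0 + 2 * 50 / 95 - 2 * 65 / 95
        assert mets.firing_time == pytest.approx(expected_ft, abs=1.0)
        assert mets.frequency == pytest.approx(12 / (expected_ft / 1000),
                                               rel=0.01)

    def test_single_spike_has_undefined_frequency(self):
        mets = detect_aps(spike_train(1, 100.0))
        assert mets.count == 1
        assert not mets.frequency_defined

    def test_subthreshold_oscillations_not_counted(self):
        dt = 0.05
        t = np.arange(0, 1000, dt)
        v = -30.0 + 25.0 * np.sin(2 * np.pi * t / 50.0)  # peaks at -5 mV
        assert detect_aps(Trace(v, dt, "mV")).count == 0

    def test_rearm_hysteresis_blocks_double_counting(self):
        dt = 0.05
        t = np.arange(0, 200, dt)
        v = np.full_like(t, -65.0)
        # one spike whose repolarisation wobbles around 0 without reaching -20
        v[(t > 50) & (t <= 54)] = 20.0
        v[(t > 54) & (t <= 58)] = -5.0
        v[(t > 58) & (t <= 62)] = 15.0
        assert detect_aps(Trace(v, dt, "mV")).count == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_count_invariant_to_small_noise(self, seed):
        tr = spike_train(8, 120.0)
        rng = np.random.default_rng(seed)
        noisy = Trace(tr.values + rng.uniform(-1.0, 1.0, len(tr.values)),
                      tr.dt, "mV")
        assert detect_aps(noisy).count == 8


class TestPhasePlane:
    def test_known_corner_recovered(self):
        """Piecewise-linear dV/dt-vs-V with a corner at -45 mV."""
        dt = 0.01
        v = [-60.0]
        while v[-1] < 10.0:
            d = 0.2 if v[-1] < -45.0 else 0.2 + 15.0 * (v[-1] + 45.0)
            v.append(v[-1] + d * dt)
        v = np.array(v + [-10.0, -40.0, -65.0])
        pp = phase_plane(Trace(v, dt, "mV"), 0)
        assert pp.success
        assert pp.threshold == pytest.approx(-45.0, abs=0.5)

    def test_burst_upstroke_decreases_and_threshold_depolarizes(self,
                                                                fast_burst):
        res, mets = fast_burst
        pps = [phase_plane(res.vm, i, mets) for i in range(mets.count)]
        assert pps[0].success and pps[-1].success
        # Na_v inactivation accumulates: first AP has the fastest upstroke
        assert pps[0].max_upstroke > pps[-1].max_upstroke
        middle = (mets.count + 1) // 2 - 1
        assert pps[middle].success
        assert pps[middle].threshold >= pps[0].threshold - 0.1
        for pp in pps:
            if pp.success:
                assert pp.threshold < res.vm.values.max()
                assert pp.max_upstroke > 0

    def test_time_reversed_upstroke_flagged(self, fast_burst):
        """Reversing a rising flank leaves no upward threshold crossing, so
        there is no spike to analyse."""
        res, mets = fast_burst
        k = int(mets.spike_times[0] / res.vm.dt)
        rise = res.vm.values[:k + int(1.0 / res.vm.dt)]
        rev = Trace(rise[::-1].copy(), res.vm.dt, "mV")
        assert detect_aps(rev).count == 0
        pp = phase_plane(rev, 0)
        assert not pp.success

    def test_missing_spike_index_rejected(self):
        tr = spike_train(2, 100.0)
        with pytest.raises(IndexError):
            phase_plane(tr, 5)
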