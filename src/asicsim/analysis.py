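"""Metrics derived from simulated or recorded traces: peak current and
transported charge, mono-exponential and Hill fits, action-potential
detection and burst statistics, and phase-plane (dV/dt versus V) analysis.

Spike criterion
---------------
An action potential is an upward crossing of 0 mV; detection re-arms only
after the potential falls back below -20 mV, so damped suprathreshold
oscillations are not double counted.  The burst firing time runs from the
first spike's 0-mV crossing to the downward -20-mV crossing after the last
spike, and the firing frequency is the spike count divided by that time.

Phase-plane threshold
---------------------
On the dV/dt-versus-V curve of a single spike, a straight line is fitted to
the sub-threshold flat part (|dV/dt| < 1 mV/ms) and another to the upstroke
(points between 10% and 40% of the maximal dV/dt); the threshold is the V
of their intersection.  The maximal upstroke velocity is the maximum of
dV/dt over the spike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .traces import Trace

__all__ = [
    "APBurstMetrics",
    "PhasePlaneMetrics",
    "HillFit",
    "ExpFit",
    "peak_and_charge",
    "charge_window",
    "normalize_to_fast",
    "fit_monoexponential",
    "fit_exponential_points",
    "fit_hill",
    "detect_aps",
    "phase_plane",
]

SPIKE_THRESHOLD_MV = 0.0
SPIKE_REARM_MV = -20.0


# ---------------------------------------------------------------------------
# Current metrics


def peak_and_charge(tr: Trace, window: tuple[float, float] | None = None
                    ) -> tuple[float, float]:
    """Signed peak current (uA cm^-2) and transported charge (mC cm^-2).

    The peak is the extremum of |I| within the window (its signed value is
    returned); the charge is the trapezoidal time integral of I, converted
    from uA ms cm^-2 to mC cm^-2.
    """
    sub = tr if window is None else tr.window(*window)
    if len(sub.values) == 0:
        raise ValueError("empty window")
    i_peak = sub.values[np.argmax(np.abs(sub.values))]
    q = float(np.trapezoid(sub.values, dx=sub.dt)) * 1e-6
    return float(i_peak), q


def charge_window(tr: Trace, onset: float,
                  fraction: float = 0.01) -> tuple[float, float]:
    """Integration window from stimulus onset until |I| falls back below
    ``fraction`` of the peak (capped at the trace end)."""
    sub = tr.window(onset, tr.t0 + tr.duration)
    absv = np.abs(sub.values)
    k_peak = int(np.argmax(absv))
    below = np.nonzero(absv[k_peak:] < fraction * absv[k_peak])[0]
    t_end = sub.t0 + (k_peak + below[0]) * sub.dt if len(below) else \
        tr.t0 + tr.duration
    return (onset, t_end)


def normalize_to_fast(metrics: dict, fast_key) -> dict:
    """Express per-ramp metric values relative to the fast-ramp reference."""
    ref = metrics[fast_key]
    if ref == 0:
        raise ZeroDivisionError("fast reference response is zero")
    return {k: v / ref for k, v in metrics.items()}


# ---------------------------------------------------------------------------
# Curve fits


@dataclass
class ExpFit:
    """Mono-exponential fit y = A exp(-t/tau) + C."""

    tau: float
    amplitude: float
    offset: float
    success: bool
    message: str = ""

    @property
    def rate(self) -> float:
        return 1.0 / self.tau


def _exp_model(t, amplitude, tau, offset):
    return amplitude * np.exp(-t / tau) + offset


def fit_exponential_points(x: np.ndarray, y: np.ndarray) -> ExpFit:
    """Least-squares mono-exponential fit to scattered (x, y) points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        return ExpFit(math.nan, math.nan, math.nan, False, "too few points")
    order = np.argsort(x)
    x, y = x[order], y[order]
    span = float(np.ptp(y))
    scale = max(abs(float(np.mean(y))), 1e-12)
    if span < 1e-9 * scale:
        return ExpFit(math.nan, 0.0, float(np.mean(y)), False,
                      "no amplitude (constant data)")
    model = Model(_exp_model)
    a0 = y[0] - y[-1]
    # initial tau from the 1/e crossing of the normalised transient, with a
    # deterministic multistart fallback for plateau-heavy series
    tloc = x - x[0]
    frac = (y - y[-1]) / a0 if a0 != 0 else np.zeros_like(y)
    below = np.nonzero(frac < np.exp(-1.0))[0]
    tau_cross = tloc[below[0]] if len(below) and below[0] > 0 else math.nan
    span = max(float(tloc[-1]), 1e-9)
    starts = [t for t in (tau_cross, span / 5.0, span / 20.0)
              if np.isfinite(t) and t > 0]
    res = None
    for tau0 in starts:
        pars = model.make_params(amplitude=a0, tau=tau0, offset=y[-1])
        pars["tau"].set(min=1e-12)
        try:
            cand = model.fit(y, pars, t=tloc)
        except Exception:  # pragma: no cover - lmfit failure path
            continue
        if res is None or float(np.sum(cand.residual ** 2)) < \
                float(np.sum(res.residual ** 2)):
            res = cand
    if res is None:  # pragma: no cover
        return ExpFit(math.nan, math.nan, math.nan, False, "fit failed")
    amp = float(res.params["amplitude"].value)
    resid_sd = float(np.std(res.residual))
    if not res.success or abs(amp) < 3.0 * resid_sd:
        return ExpFit(float(res.params["tau"].value), amp,
                      float(res.params["offset"].value), False,
                      "amplitude indistinguishable from noise"
                      if res.success else res.message)
    return ExpFit(float(res.params["tau"].value), amp,
                  float(res.params["offset"].value), True)


def fit_monoexponential(tr: Trace, window: tuple[float, float],
                        direction: str = "decay") -> ExpFit:
    """Mono-exponential fit of a trace segment (>= 10 samples).

    ``direction`` is advisory ("rise" or "decay"); the sign of the fitted
    amplitude encodes it either way.
    """
    if direction not in ("rise", "decay"):
        raise ValueError("direction must be 'rise' or 'decay'")
    sub = tr.window(*window)
    if len(sub.values) < 10:
        raise ValueError("need at least 10 samples in the fit window")
    return fit_exponential_points(sub.time, sub.values)


@dataclass
class HillFit:
    """Hill fit I = Imax / (1 + 10^(sign * n_h * (pH - pH50)))."""

    i_max: float
    ph50: float
    n_h: float
    sign: int  # +1: response grows with acidification (activation);
    # -1: response grows with alkalinisation (SSD-type curves)
    success: bool
    message: str = ""

    def predict(self, ph):
        ph = np.asarray(ph, dtype=float)
        return self.i_max / (1.0 + 10.0 ** (self.sign * self.n_h *
                                            (ph - self.ph50)))


def _hill_model(ph, i_max, ph50, slope):
    return i_max / (1.0 + 10.0 ** (slope * (ph - ph50)))


def fit_hill(points) -> HillFit:
    """Least-squares Hill fit of (pH, response) points.

    Requires at least 4 points spanning the transition; monotone-flat input
    or a midpoint outside the sampled pH range is flagged.
    """
    pts = np.asarray([(p[0], p[1]) if not hasattr(p, "ph") else
                      (p.ph, p.response) for p in points], dtype=float)
    if len(pts) < 4:
        return HillFit(math.nan, math.nan, math.nan, 0, False,
                       "need >= 4 points")
    ph, y = pts[:, 0], pts[:, 1]
    order = np.argsort(ph)
    ph, y = ph[order], y[order]
    ymax = float(np.max(np.abs(y)))
    if ymax == 0 or float(np.ptp(y)) < 0.05 * ymax:
        return HillFit(math.nan, math.nan, math.nan, 0, False,
                       "no transition in range (flat input)")
    # initial guesses: midpoint from the 50% crossing, slope sign from trend
    rising = y[-1] > y[0]  # response grows with pH -> slope < 0
    half = 0.5 * (np.min(y) + np.max(y))
    ph50_0 = float(np.interp(half, y if rising else y[::-1],
                             ph if rising else ph[::-1]))
    slope0 = -2.0 if rising else 2.0
    model = Model(_hill_model)
    pars = model.make_params(i_max=float(np.max(np.abs(y))) *
                             np.sign(y[np.argmax(np.abs(y))]),
                             ph50=ph50_0, slope=slope0)
    try:
        res = model.fit(y, pars, ph=ph)
    except Exception as exc:  # pragma: no cover
        return HillFit(math.nan, math.nan, math.nan, 0, False, str(exc))
    ph50 = float(res.params["ph50"].value)
    slope = float(res.params["slope"].value)
    ok = bool(res.success) and ph[0] - 0.5 <= ph50 <= ph[-1] + 0.5
    return HillFit(float(res.params["i_max"].value), ph50, abs(slope),
                   int(np.sign(slope)) or 1, ok,
                   "" if ok else "midpoint outside data range")


# ---------------------------------------------------------------------------
# Spike detection and phase-plane analysis


@dataclass
class APBurstMetrics:
    """Spike count, burst firing time and firing frequency of one trace."""

    spike_times: np.ndarray  # ms, upward 0-mV crossings
    count: int
    firing_time: float  # ms; NaN if < 1 spike
    frequency: float  # Hz = count / firing_time; NaN (undefined) if < 2 spikes
    frequency_defined: bool


def _crossings(v: np.ndarray, level: float, upward: bool) -> np.ndarray:
    prev, cur = v[:-1], v[1:]
    if upward:
        idx = np.nonzero((prev < level) & (cur >= level))[0]
    else:
        idx = np.nonzero((prev >= level) & (cur < level))[0]
    return idx


def detect_aps(tr: Trace, threshold: float = SPIKE_THRESHOLD_MV,
               rearm: float = SPIKE_REARM_MV) -> APBurstMetrics:
    """Count action potentials and derive burst statistics from a Vm trace."""
    v = tr.values
    up = _crossings(v, threshold, upward=True)
    down_rearm = _crossings(v, rearm, upward=False)
    spikes = []
    armed_from = -1
    for k in up:
        if k >= armed_from:
            spikes.append(k)
            # next spike only counts after v falls below the re-arm level
            later = down_rearm[np.searchsorted(down_rearm, k)] \
                if np.searchsorted(down_rearm, k) < len(down_rearm) else None
            armed_from = len(v) if later is None else later + 1
    if not spikes:
        return APBurstMetrics(np.array([]), 0, math.nan, math.nan, False)

    def interp_cross(k: int, level: float) -> float:
        f = (level - v[k]) / (v[k + 1] - v[k])
        return tr.t0 + (k + f) * tr.dt

    spike_times = np.array([interp_cross(k, threshold) for k in spikes])
    last = spikes[-1]
    after = down_rearm[down_rearm > last]
    t_end = interp_cross(int(after[0]), rearm) if len(after) else \
        tr.t0 + tr.duration
    firing_time = t_end - spike_times[0]
    if len(spikes) >= 2 and firing_time > 0:
        freq = len(spikes) / (firing_time / 1000.0)
        return APBurstMetrics(spike_times, len(spikes), firing_time, freq, True)
    return APBurstMetrics(spike_times, len(spikes), firing_time, math.nan,
                          False)


@dataclass
class PhasePlaneMetrics:
    """Spike threshold and maximal upstroke velocity from dV/dt vs V."""

    threshold: float  # mV
    max_upstroke: float  # mV/ms
    success: bool
    message: str = ""


def phase_plane(tr: Trace, spike_index: int,
                metrics: APBurstMetrics | None = None,
                flat_limit: float = 1.0,
                steep_band: tuple[float, float] = (0.10, 0.40)
                ) -> PhasePlaneMetrics:
    """Two-tangent threshold and maximal dV/dt of one spike in a Vm trace.

    dV/dt is computed by central differences.  The analysed segment runs
    from the end of the previous spike (or the trace start) to the Vm peak
    of the requested spike.
    """
    mets = metrics or detect_aps(tr)
    if mets.count == 0:
        return PhasePlaneMetrics(math.nan, math.nan, False, "no spikes")
    if not 0 <= spike_index < mets.count:
        raise IndexError(f"spike index {spike_index} out of range "
                         f"(count {mets.count})")
    v = tr.values
    dvdt = np.gradient(v, tr.dt)
    t_cross = mets.spike_times[spike_index]
    k_cross = int((t_cross - tr.t0) / tr.dt)
    # start: after the previous spike's repolarisation below the re-arm
    # level, capped to a 200-ms pre-spike window for isolated spikes
    k_start = max(0, k_cross - int(round(200.0 / tr.dt)))
    if spike_index > 0:
        prev = int((mets.spike_times[spike_index - 1] - tr.t0) / tr.dt)
        below = np.nonzero(v[prev:k_cross] < SPIKE_REARM_MV)[0]
        if len(below):
            k_start = max(k_start, prev + int(below[0]))
    # end: Vm peak of this spike
    k_stop = min(len(v) - 1, k_cross + int(round(10.0 / tr.dt)))
    k_peak = k_cross + int(np.argmax(v[k_cross:k_stop + 1]))
    seg_v = v[k_start:k_peak + 1]
    seg_d = dvdt[k_start:k_peak + 1]
    if len(seg_v) < 8:
        return PhasePlaneMetrics(math.nan, math.nan, False,
                                 "spike too short for tangent fits")
    max_up = float(np.max(seg_d))
    if max_up <= 0:
        return PhasePlaneMetrics(math.nan, max_up, False, "no upstroke")
    k_max = int(np.argmax(seg_d))
    # flat tangent: the sub-threshold branch before the upstroke knee.  In a
    # fast burst the inter-spike depolarisation never falls fully flat, so
    # the cut-off adapts to 5% of the maximal upstroke velocity.
    limit = max(flat_limit, 0.05 * max_up)
    above = np.nonzero(seg_d >= limit)[0]
    k_up = int(above[0]) if len(above) else len(seg_d)
    flat_sel = np.abs(seg_d[:k_up]) < limit
    flat_v, flat_d = seg_v[:k_up][flat_sel], seg_d[:k_up][flat_sel]
    # steep tangent: ascending-limb points between 10% and 40% of max dV/dt
    idx = np.arange(len(seg_d))
    lo, hi = steep_band[0] * max_up, steep_band[1] * max_up
    steep_sel = (seg_d >= lo) & (seg_d <= hi) & (idx >= k_up - 1) & \
        (idx <= k_max)
    steep_v, steep_d = seg_v[steep_sel], seg_d[steep_sel]
    if len(flat_v) < 3 or len(steep_v) < 3:
        return PhasePlaneMetrics(math.nan, max_up, False,
                                 "spike too short for tangent fits")
    p_flat = np.polyfit(flat_v, flat_d, 1)
    p_steep = np.polyfit(steep_v, steep_d, 1)
    denom = p_steep[0] - p_flat[0]
    if abs(denom) < 1e-12:
        return PhasePlaneMetrics(math.nan, max_up, False,
                                 "tangents are parallel")
    thr = float((p_flat[1] - p_steep[1]) / denom)
    return PhasePlaneMetrics(thr, max_up, True)
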