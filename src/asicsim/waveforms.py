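"""pH-versus-time waveforms: steps with finite solution exchange, linear
ramps and the piecewise-polynomial sigmoid ramp used to mimic syringe-pump
solution mixing.

A waveform is a contiguous sequence of segments, each a polynomial in local
time ``tau = t - t0`` of degree at most two, so every supported shape
(constant, linear, quadratic ease) shares one representation and sampling
path.  Waveforms are continuous in pH at all segment joins by construction.

The sigmoid ramp consists of a quadratic ease-in over the first ``0.5*rt``,
a linear mid-section over ``rt`` and a quadratic ease-out over the last
``0.5*rt`` (``rt`` being the rise-time parameter; the whole ramp lasts
``2*rt``).  Requiring pH and dpH/dt to be continuous at all four junctions
determines all six polynomial coefficients in closed form.  The 90-10% fall
time of such a ramp is ``(2 - 2*sqrt(0.15)) * rt`` (both crossings fall in
the quadratic ease segments; see :data:`FALL_TIME_PER_RT`), which is how
experimental fall times map onto ``rt``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "PHWaveform",
    "SigmoidRampSpec",
    "make_constant",
    "make_step",
    "make_linear_ramp",
    "make_sigmoid_ramp",
    "solve_sigmoid_coefficients",
    "sigmoid_continuity_residuals",
    "fall_time_90_10",
    "rt_from_fall_time",
    "FALL_TIME_PER_RT",
]

# 90-10% fall time of the sigmoid ramp, in units of rt.  Derived from the
# ease-in quadratic: the fraction of the total drop completed at local time
# tau <= 0.5*rt is tau^2 / (1.5*rt^2), so the 10% point sits at
# tau = rt*sqrt(0.15) and, by symmetry, the 90% point at 2*rt - rt*sqrt(0.15).
FALL_TIME_PER_RT = 2.0 - 2.0 * math.sqrt(0.15)


def rt_from_fall_time(fall_time: float) -> float:
    """Sigmoid rise-time parameter producing a given 90-10% fall time (ms)."""
    if fall_time <= 0:
        raise ValueError("fall time must be positive")
    return fall_time / FALL_TIME_PER_RT


class PHWaveform:
    """Piecewise-polynomial extracellular pH versus time (ms).

    Parameters
    ----------
    starts, coeffs
        ``starts[i]`` is the start time of segment ``i``; the segment's pH at
        local time ``tau`` is ``c0 + c1*tau + c2*tau**2`` with
        ``coeffs[i] = (c0, c1, c2)``.  Segments are contiguous; the last one
        extends to ``duration``.
    """

    def __init__(self, starts: Sequence[float], coeffs: Sequence[Sequence[float]],
                 duration: float):
        self.starts = np.asarray(starts, dtype=float)
        self.coeffs = np.asarray(coeffs, dtype=float).reshape(-1, 3)
        if self.starts.ndim != 1 or len(self.starts) != len(self.coeffs):
            raise ValueError("starts and coeffs must have matching lengths")
        if len(self.starts) == 0 or self.starts[0] != 0.0:
            raise ValueError("first segment must start at t = 0")
        if np.any(np.diff(self.starts) <= 0):
            raise ValueError("segment starts must be strictly increasing")
        if duration <= self.starts[-1] and len(self.starts) > 1:
            raise ValueError("duration must exceed the last segment start")
        self.duration = float(duration)

    # -- sampling -----------------------------------------------------------
    def sample(self, t) -> np.ndarray:
        """Evaluate pH at times ``t`` (ms); error outside [0, duration]."""
        t = np.asarray(t, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("sample times must be finite")
        if t.size and (t.min() < -1e-9 or t.max() > self.duration + 1e-9):
            raise ValueError(
                f"waveform undefined outside [0, {self.duration}] ms"
            )
        idx = np.searchsorted(self.starts, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.starts) - 1)
        tau = t - self.starts[idx]
        c = self.coeffs[idx]
        return c[..., 0] + c[..., 1] * tau + c[..., 2] * tau * tau

    def grid(self, dt: float, duration: float | None = None) -> np.ndarray:
        """pH sampled on the uniform grid 0, dt, ..., duration."""
        duration = self.duration if duration is None else duration
        n = int(np.floor(duration / dt + 1e-9)) + 1
        return self.sample(np.arange(n) * dt)

    def value_at_end(self) -> float:
        return float(self.sample(self.duration))

    # -- composition --------------------------------------------------------
    def then(self, other: "PHWaveform") -> "PHWaveform":
        """Concatenate ``other`` after this waveform (times shifted)."""
        starts = np.concatenate([self.starts, other.starts + self.duration])
        coeffs = np.concatenate([self.coeffs, other.coeffs])
        return PHWaveform(starts, coeffs, self.duration + other.duration)

    def max_continuity_jump(self) -> float:
        """Largest |pH| discontinuity at any segment join (0 if continuous)."""
        jumps = []
        for i in range(1, len(self.starts)):
            t = self.starts[i]
            tau = t - self.starts[i - 1]
            c = self.coeffs[i - 1]
            left = c[0] + c[1] * tau + c[2] * tau * tau
            jumps.append(abs(left - self.coeffs[i][0]))
        return max(jumps, default=0.0)


@dataclass(frozen=True)
class SigmoidRampSpec:
    """Closed-form coefficients of the piecewise sigmoid pH ramp.

    Pieces (mid segment in absolute time, eases in local time):
    ease-in ``pH_i + a1*(t-t_i)^2 + b1*(t-t_i)``, linear mid ``a2*t + b2``,
    ease-out ``pH_f + a3*(t-t_i-2rt)^2 + b3*(t-t_i-2rt)``.
    """

    ph_i: float
    ph_f: float
    t_i: float
    rt: float
    a1: float
    b1: float
    a2: float
    b2: float
    a3: float
    b3: float

    @property
    def junctions(self) -> tuple[float, float, float, float]:
        return (self.t_i, self.t_i + 0.5 * self.rt,
                self.t_i + 1.5 * self.rt, self.t_i + 2.0 * self.rt)

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        t0, t1, t2, t3 = self.junctions
        out = np.full(t.shape, self.ph_i)
        m = (t > t0) & (t <= t1)
        tau = t[m] - t0
        out[m] = self.ph_i + self.a1 * tau**2 + self.b1 * tau
        m = (t > t1) & (t <= t2)
        out[m] = self.a2 * t[m] + self.b2
        m = (t > t2) & (t <= t3)
        sig = t[m] - t3
        out[m] = self.ph_f + self.a3 * sig**2 + self.b3 * sig
        out[t > t3] = self.ph_f
        return out


def solve_sigmoid_coefficients(ph_i: float, ph_f: float, t_i: float,
                               rt: float) -> SigmoidRampSpec:
    """Determine the sigmoid-ramp coefficients from the continuity equations.

    pH and dpH/dt are continuous at the four junctions; the mid-segment slope
    is ``(ph_f - ph_i) / (1.5 * rt)``.
    """
    if rt <= 0:
        raise ValueError("rise time rt must be positive")
    q = (ph_f - ph_i) / (1.5 * rt)  # mid-segment slope, pH/ms
    a1 = 0.5 * q / (0.5 * rt)  # slope grows linearly 0 -> q over 0.5*rt
    b1 = 0.0  # zero slope at ramp onset
    a2 = q
    # value continuity at t_i + 0.5*rt: ph_i + a1*(rt/2)^2 = a2*t + b2
    b2 = ph_i + a1 * (0.5 * rt) ** 2 - a2 * (t_i + 0.5 * rt)
    a3 = -a1
    b3 = 0.0  # zero slope at ramp end
    return SigmoidRampSpec(ph_i, ph_f, t_i, rt, a1, b1, a2, b2, a3, b3)


def sigmoid_continuity_residuals(spec: SigmoidRampSpec) -> np.ndarray:
    """Value and slope mismatches at the four junctions (8 numbers).

    All residuals are zero to machine precision for coefficients produced by
    :func:`solve_sigmoid_coefficients`.
    """
    t0, t1, t2, t3 = spec.junctions
    s = spec

    def seg0(t):
        return s.ph_i, 0.0

    def seg1(t):
        tau = t - t0
        return s.ph_i + s.a1 * tau**2 + s.b1 * tau, 2 * s.a1 * tau + s.b1

    def seg2(t):
        return s.a2 * t + s.b2, s.a2

    def seg3(t):
        sig = t - t3
        return s.ph_f + s.a3 * sig**2 + s.b3 * sig, 2 * s.a3 * sig + s.b3

    def seg4(t):
        return s.ph_f, 0.0

    res = []
    for t, (left, right) in zip((t0, t1, t2, t3),
                                ((seg0, seg1), (seg1, seg2),
                                 (seg2, seg3), (seg3, seg4))):
        vl, dl = left(t)
        vr, dr = right(t)
        res.extend([vr - vl, dr - dl])
    return np.array(res)


# ---------------------------------------------------------------------------
# Builders


def make_constant(ph: float, duration: float) -> PHWaveform:
    if duration <= 0:
        raise ValueError("duration must be positive")
    return PHWaveform([0.0], [[ph, 0.0, 0.0]], duration)


def make_step(ph_from: float, ph_to: float, t_switch: float,
              exchange: float, duration: float | None = None) -> PHWaveform:
    """Step between two pH values with a finite linear solution exchange.

    The pH changes linearly over ``[t_switch, t_switch + exchange]``;
    ``exchange = 0`` gives an ideal step.  Typical values are 1 ms (excised
    outside-out patches) and 200 ms (whole-cell recordings).
    """
    if exchange < 0:
        raise ValueError("exchange time must be non-negative")
    if t_switch < 0:
        raise ValueError("t_switch must be non-negative")
    if duration is None:
        duration = t_switch + exchange + 1000.0
    if duration < t_switch + exchange:
        raise ValueError("duration too short for the requested step")
    starts = [0.0]
    coeffs = [[ph_from, 0.0, 0.0]]
    if t_switch == 0.0:
        starts, coeffs = [], []
    if exchange > 0:
        starts.append(t_switch)
        coeffs.append([ph_from, (ph_to - ph_from) / exchange, 0.0])
    starts.append(t_switch + exchange)
    coeffs.append([ph_to, 0.0, 0.0])
    if starts[0] != 0.0:
        starts.insert(0, 0.0)
        coeffs.insert(0, [ph_from, 0.0, 0.0])
    # drop duplicate-start segments (ideal step at t=0)
    starts_u, coeffs_u = [], []
    for s, c in zip(starts, coeffs):
        if starts_u and s == starts_u[-1]:
            coeffs_u[-1] = c
        else:
            starts_u.append(s)
            coeffs_u.append(c)
    return PHWaveform(starts_u, coeffs_u, duration)


def make_linear_ramp(ph0: float, ph_final: float, t_start: float,
                     ramp_duration: float,
                     duration: float | None = None) -> PHWaveform:
    """Linear pH ramp pH(t) = pH(0) - q*t with q set by end pH and duration."""
    if ramp_duration <= 0:
        raise ValueError("ramp duration must be positive")
    if duration is None:
        duration = t_start + ramp_duration + 1000.0
    q = (ph0 - ph_final) / ramp_duration  # pH per ms, positive for a drop
    starts = [0.0, t_start, t_start + ramp_duration]
    coeffs = [[ph0, 0.0, 0.0], [ph0, -q, 0.0], [ph_final, 0.0, 0.0]]
    if t_start == 0:
        starts, coeffs = starts[1:], coeffs[1:]
        starts[0] = 0.0
    return PHWaveform(starts, coeffs, duration)


def make_sigmoid_ramp(ph_i: float, ph_f: float, t_i: float,
                      rt: float | None = None,
                      fall_time: float | None = None,
                      duration: float | None = None) -> PHWaveform:
    """Sigmoid (eased) pH ramp; specify either ``rt`` or the 90-10% ``fall_time``."""
    if (rt is None) == (fall_time is None):
        raise ValueError("specify exactly one of rt and fall_time")
    if rt is None:
        rt = rt_from_fall_time(fall_time)
    spec = solve_sigmoid_coefficients(ph_i, ph_f, t_i, rt)
    if duration is None:
        duration = t_i + 2 * rt + 1000.0
    t0, t1, t2, t3 = spec.junctions
    # local-time quadratic coefficients per segment
    q = spec.a2
    starts = [0.0, t0, t1, t2, t3]
    mid_start_value = ph_i + spec.a1 * (0.5 * rt) ** 2
    # ease-out in local tau from t2: value = ph_f + a3*(tau - 0.5*rt)^2
    #   = (ph_f + a3*rt^2/4) + (-a3*rt)*tau + a3*tau^2
    coeffs = [
        [ph_i, 0.0, 0.0],
        [ph_i, spec.b1, spec.a1],
        [mid_start_value, q, 0.0],
        [ph_f + spec.a3 * (0.5 * rt) ** 2, -spec.a3 * rt, spec.a3],
        [ph_f, 0.0, 0.0],
    ]
    if t_i == 0:
        starts, coeffs = starts[1:], coeffs[1:]
        starts[0] = 0.0
    return PHWaveform(starts, coeffs, duration)


def fall_time_90_10(wave: PHWaveform, n: int = 200_001) -> float:
    """90-10% fall time of a monotonically falling waveform (ms).

    The drop is normalised between the waveform's initial and final plateau
    values; the result is the time between the crossings of 90% and 10% of
    the remaining fraction (i.e., after 10% and 90% of the total drop).
    """
    t = np.linspace(0.0, wave.duration, n)
    ph = wave.sample(t)
    ph_i, ph_f = ph[0], ph[-1]
    drop = ph_i - ph_f
    if drop <= 0:
        raise ValueError("waveform has no falling phase")
    frac = (ph_i - ph) / drop  # fraction of drop completed, 0 -> 1
    if np.any(np.diff(frac) < -1e-9):
        raise ValueError("waveform is not monotone during the fall")

    def crossing(level: float) -> float:
        k = int(np.searchsorted(frac, level))
        if k == 0 or k >= n:
            raise ValueError("drop does not span the 10-90% band")
        f0, f1 = frac[k - 1], frac[k]
        return t[k - 1] + (level - f0) / (f1 - f0) * (t[k] - t[k - 1])

    return crossing(0.9) - crossing(0.1)
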