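"""Grid experiments over ramp conditions and channel parameters.

Every sweep simulates the full model per grid cell and records derived
metrics in a long-format pandas DataFrame (one row per cell), suitable for
CSV export and heat-map rendering.  The forward model is deterministic, so
rerunning a grid reproduces bit-identical metrics.

Conventions
-----------
- Ramps are the piecewise sigmoid shape starting from pH 7.4 after a 5-s
  hold, specified by their 90-10% fall time (FT).
- Per-cell simulation lasts ``hold + 2*FT_max + plateau`` so slow ramps
  reach quasi-steady behaviour, and all cells of a grid share one counting
  window.
- The "middle" action potential of a burst is the one at index
  ceil(count/2) (1-based) in spike order.
- Cells whose parameters fire spontaneously at rest (pH 7.4) are flagged;
  their ramp-evoked counts are still reported but should not be read as
  acid-evoked signalling.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .analysis import charge_window, detect_aps, peak_and_charge, phase_plane
from .gating import simulate_voltage_clamp
from .neuron import simulate_constant_ph, simulate_current_clamp
from .params import ASICModelParams, NeuronParams
from .waveforms import make_sigmoid_ramp, rt_from_fall_time

__all__ = [
    "ramp_wave",
    "current_charge_map",
    "firing_map",
    "conductance_sensitivity",
    "nav_sweep",
    "is_spontaneously_firing",
    "spontaneous_sm_boundary",
    "burst_metrics_for_ramp",
]

PH_START = 7.4
HOLD_MS = 5_000.0
PLATEAU_MS = 30_000.0


def ramp_wave(end_ph: float, fall_time_s: float,
              hold: float = HOLD_MS, plateau: float = PLATEAU_MS,
              duration: float | None = None):
    """Sigmoid pH ramp 7.4 -> end_ph with the given 90-10% fall time (s)."""
    ft = fall_time_s * 1000.0
    rt = rt_from_fall_time(ft)
    if duration is None:
        duration = hold + 2.0 * rt + plateau
    return make_sigmoid_ramp(PH_START, end_ph, hold, rt=rt,
                             duration=duration)


def current_charge_map(end_phs=tuple(np.round(np.arange(5.8, 7.21, 0.1), 2)),
                       fall_times_s=(1, 2, 4, 8, 16, 32),
                       clamp_vm: float = -60.0,
                       params: ASICModelParams | None = None,
                       dt: float = 0.1,
                       hold: float = HOLD_MS,
                       plateau: float = PLATEAU_MS) -> pd.DataFrame:
    """Voltage-clamp peak current and transported charge per (end pH, FT).

    Columns: end_ph, fall_time_s, i_peak (uA cm^-2, signed), charge
    (mC cm^-2), failed.
    """
    params = params or ASICModelParams()
    if len(end_phs) == 0 or len(fall_times_s) == 0:
        raise ValueError("grids must be non-empty")
    duration = hold + 2 * rt_from_fall_time(max(fall_times_s) * 1000.0) \
        + plateau
    rows = []
    for ph in end_phs:
        for ft in fall_times_s:
            row = {"end_ph": float(ph), "fall_time_s": float(ft),
                   "i_peak": math.nan, "charge": math.nan, "failed": False}
            try:
                wave = ramp_wave(ph, ft, hold, plateau, duration)
                tr = simulate_voltage_clamp(wave, params, vm=clamp_vm, dt=dt)
                w = charge_window(tr, hold)
                i_peak, q = peak_and_charge(tr, w)
                row.update(i_peak=i_peak, charge=q)
            except Exception:
                row["failed"] = True
            rows.append(row)
    return pd.DataFrame(rows)


def burst_metrics_for_ramp(end_ph: float, fall_time_s: float,
                           params: NeuronParams | None = None,
                           dt: float = 0.01,
                           hold: float = HOLD_MS,
                           plateau: float = PLATEAU_MS,
                           duration: float | None = None,
                           record_aux: bool = False):
    """Simulate one ramp in current clamp and return (result, burst metrics)."""
    wave = ramp_wave(end_ph, fall_time_s, hold, plateau, duration)
    res = simulate_current_clamp(wave, params, dt=dt, record_aux=record_aux)
    return res, detect_aps(res.vm)


def firing_map(end_phs=tuple(np.round(np.arange(5.6, 7.01, 0.2), 2)),
               fall_times_s=tuple(np.arange(0.5, 9.01, 0.5)),
               params: NeuronParams | None = None,
               dt: float = 0.01,
               hold: float = HOLD_MS,
               plateau: float = PLATEAU_MS) -> pd.DataFrame:
    """AP count and firing time per (end pH, FT) in current clamp.

    All cells share one simulation/counting window set by the slowest ramp.
    """
    if len(end_phs) == 0 or len(fall_times_s) == 0:
        raise ValueError("grids must be non-empty")
    duration = hold + 2 * rt_from_fall_time(max(fall_times_s) * 1000.0) \
        + plateau
    rows = []
    for ph in end_phs:
        for ft in fall_times_s:
            row = {"end_ph": float(ph), "fall_time_s": float(ft),
                   "ap_count": np.nan, "firing_time_ms": np.nan,
                   "frequency_hz": np.nan, "failed": False}
            try:
                _, mets = burst_metrics_for_ramp(ph, ft, params, dt, hold,
                                                 plateau, duration)
                row.update(ap_count=mets.count,
                           firing_time_ms=mets.firing_time,
                           frequency_hz=mets.frequency)
            except Exception:
                row["failed"] = True
            rows.append(row)
    return pd.DataFrame(rows)


def is_spontaneously_firing(params: NeuronParams | None = None,
                            ph: float = PH_START,
                            duration: float = 20_000.0,
                            dt: float = 0.01) -> bool:
    """Spontaneous-signalling criterion: >= 2 APs in 20 s at constant pH 7.4
    starting from equilibrium."""
    res = simulate_constant_ph(ph, duration, params, dt=dt)
    return detect_aps(res.vm).count >= 2


def spontaneous_sm_boundary(params: NeuronParams | None = None,
                            lo: float = -5.0, hi: float = 0.0,
                            tol: float = 0.05, dt: float = 0.01) -> float:
    """m-gate voltage shift below which the resting model fires spontaneously.

    Bisection on s_m between ``lo`` (firing) and ``hi`` (quiescent); returns
    the midpoint of the final bracket.
    """
    params = params or NeuronParams()

    def firing(s_m: float) -> bool:
        p = replace(params, mods=replace(params.mods, s_m=s_m))
        return is_spontaneously_firing(p, dt=dt)

    if not firing(lo):
        raise ValueError(f"model does not fire spontaneously at s_m={lo}")
    if firing(hi):
        raise ValueError(f"model fires spontaneously already at s_m={hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if firing(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_CONDUCTANCES = ("g_asic", "g_na", "g_k", "g_l")


def _scaled_params(base: NeuronParams, name: str, scale: float) -> NeuronParams:
    if name == "g_asic":
        return replace(base, asic=replace(base.asic,
                                          g_asic=base.asic.g_asic * scale))
    return replace(base, **{name: getattr(base, name) * scale})


def conductance_sensitivity(scales=(0.9, 1.0, 1.1),
                            fall_times_s=(1, 2, 3, 5, 8),
                            end_ph: float = 6.0,
                            params: NeuronParams | None = None,
                            dt: float = 0.01,
                            plateau: float = PLATEAU_MS) -> pd.DataFrame:
    """AP count and firing time under +-10% conductance perturbations.

    Rows carry both the ramp fall time and the total ramp time (2*rt), since
    sensitivity results are conventionally plotted against total ramp time.
    """
    base = params or NeuronParams()
    duration = HOLD_MS + 2 * rt_from_fall_time(max(fall_times_s) * 1000.0) \
        + plateau
    rows = []
    for name in _CONDUCTANCES:
        for scale in scales:
            p = _scaled_params(base, name, scale)
            spont = is_spontaneously_firing(p, dt=dt)
            for ft in fall_times_s:
                row = {"conductance": name, "scale": float(scale),
                       "fall_time_s": float(ft),
                       "total_ramp_time_s":
                           2 * rt_from_fall_time(ft * 1000.0) / 1000.0,
                       "ap_count": np.nan, "firing_time_ms": np.nan,
                       "spontaneous": spont, "failed": False}
                try:
                    _, mets = burst_metrics_for_ramp(end_ph, ft, p, dt,
                                                     HOLD_MS, plateau,
                                                     duration)
                    row.update(ap_count=mets.count,
                               firing_time_ms=mets.firing_time)
                except Exception:
                    row["failed"] = True
                rows.append(row)
    return pd.DataFrame(rows)


_NAV_PARAMS = ("s_m", "f_m", "s_h", "f_h")


def nav_sweep(parameter: str, values,
              fall_times_s=(1.0, 5.0, 18.0),
              end_ph: float = 6.0,
              params: NeuronParams | None = None,
              dt: float = 0.01,
              plateau: float = PLATEAU_MS) -> pd.DataFrame:
    """Na_v perturbation sweep with per-AP phase-plane metrics.

    For each (parameter value, ramp fall time) cell: AP count, firing time,
    and threshold / maximal upstroke velocity of the first, middle and last
    AP of the burst.  Spontaneously firing parameter values are flagged.
    """
    if parameter not in _NAV_PARAMS:
        raise ValueError(f"parameter must be one of {_NAV_PARAMS}")
    base = params or NeuronParams()
    duration = HOLD_MS + 2 * rt_from_fall_time(max(fall_times_s) * 1000.0) \
        + plateau
    rows = []
    for value in values:
        if not np.isfinite(value):
            raise ValueError("sweep values must be finite")
        p = replace(base, mods=replace(base.mods, **{parameter: float(value)}))
        spont = is_spontaneously_firing(p, dt=dt)
        for ft in fall_times_s:
            row = {"parameter": parameter, "value": float(value),
                   "fall_time_s": float(ft), "spontaneous": spont,
                   "ap_count": np.nan, "firing_time_ms": np.nan,
                   "failed": False}
            for pos in ("first", "middle", "last"):
                row[f"threshold_{pos}"] = np.nan
                row[f"max_upstroke_{pos}"] = np.nan
            try:
                res, mets = burst_metrics_for_ramp(end_ph, ft, p, dt,
                                                   HOLD_MS, plateau, duration)
                row.update(ap_count=mets.count,
                           firing_time_ms=mets.firing_time)
                if mets.count >= 1:
                    middle = (mets.count + 1) // 2 - 1
                    for pos, idx in (("first", 0), ("middle", middle),
                                     ("last", mets.count - 1)):
                        pp = phase_plane(res.vm, idx, mets)
                        if pp.success:
                            row[f"threshold_{pos}"] = pp.threshold
                            row[f"max_upstroke_{pos}"] = pp.max_upstroke
            except Exception:
                row["failed"] = True
            rows.append(row)
    return pd.DataFrame(rows)
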