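"""The two-gate kinetic model of the ASIC1a current.

The channel is described by a fast activation gate ``a`` and a slow
sensitization gate ``s``, each obeying first-order relaxation toward a
pH-dependent steady state::

    da/dt = r_a(pH) * (a_inf(pH) - a)
    ds/dt = r_s(pH) * (s_inf(pH) - s)

and the current density is ``I = g * a * s * (Vm - E_rev)``.  Opening
requires acidification (a_inf rises as pH falls) while sustained mild
acidification closes the ``s`` gate without opening (steady-state
desensitization); the small overlap of the two steady-state curves carries
the window current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import ASICModelParams, RateFunctionParams, SteadyStateParams
from .traces import Trace
from .waveforms import PHWaveform

__all__ = [
    "ASICGateState",
    "steady_state",
    "rate",
    "step_gates",
    "asic_current",
    "equilibrium_gates",
    "simulate_voltage_clamp",
    "SimulationError",
    "StabilityError",
]


class SimulationError(RuntimeError):
    """Numerical failure during integration; carries the failing step index."""

    def __init__(self, message: str, step: int):
        super().__init__(f"{message} (step {step})")
        self.step = step


class StabilityError(SimulationError):
    """Euler stability guard dt*r < 1 violated."""


@dataclass(frozen=True)
class ASICGateState:
    """Occupancies of the activation (a) and sensitization (s) gates."""

    a: float
    s: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.s <= 1.0):
            raise ValueError("gate occupancies must lie in [0, 1]")


def _check_ph(ph) -> np.ndarray:
    ph = np.asarray(ph, dtype=float)
    if not np.all(np.isfinite(ph)):
        raise ValueError("pH must be finite")
    return ph


def steady_state(p: SteadyStateParams, ph):
    """Steady-state gate occupancy at a given pH, in (0, 1).

    Strictly monotone in pH: decreasing for H > 0 (activation-type gates,
    which open on acidification), increasing for H < 0.
    """
    ph = _check_ph(ph)
    expo = p.F * (np.log10(p.K) + p.H * (ph - 7.0 - p.delta))
    return 1.0 / (1.0 + 10.0 ** expo)


def rate(p: RateFunctionParams, ph):
    """Gate relaxation rate at a given pH (ms^-1); positive, below a1 + a2."""
    ph = _check_ph(ph)
    with np.errstate(over="ignore"):
        return (p.a1 / (1.0 + np.exp(p.b1 * (ph - p.c1)))
                + p.a2 / (1.0 + np.exp(p.b2 * (ph - p.c2))))


def equilibrium_gates(ph: float, p: ASICModelParams) -> ASICGateState:
    """Gates at their steady states for the given pH."""
    return ASICGateState(a=float(steady_state(p.act, ph)),
                         s=float(steady_state(p.sens, ph)))


def step_gates(st: ASICGateState, ph: float, dt: float,
               p: ASICModelParams) -> ASICGateState:
    """One forward-Euler step of both gates at the given (constant) pH.

    Raises :class:`StabilityError` if dt * r >= 1 for either gate, the
    regime where explicit Euler overshoots the fixed point.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    ph = float(_check_ph(ph))
    ra = float(rate(p.rate_act, ph))
    rs = float(rate(p.rate_sens, ph))
    if dt * ra >= 1.0 or dt * rs >= 1.0:
        raise StabilityError(
            f"dt*r = {max(dt * ra, dt * rs):.3g} >= 1; reduce dt", 0
        )
    a = st.a + dt * ra * (float(steady_state(p.act, ph)) - st.a)
    s = st.s + dt * rs * (float(steady_state(p.sens, ph)) - st.s)
    return ASICGateState(a=a, s=s)


def asic_current(st: ASICGateState, vm: float, p: ASICModelParams):
    """ASIC1a current density g*a*s*(Vm - E), in uA cm^-2 (negative = inward)."""
    return p.g_asic * st.a * st.s * (vm - p.e_asic)


def _raise_for_status(status: int, dt: float) -> None:
    if status == _kernels.STATUS_OK:
        return
    if status >= 0:
        raise SimulationError("membrane potential blow-up (|Vm| > 200 mV)",
                              status)
    raise StabilityError(f"gate-rate stability guard dt*r >= 1 at dt={dt}",
                         -status - 2)


def simulate_voltage_clamp(wave: PHWaveform, p: ASICModelParams,
                           vm: float = -60.0, dt: float = 0.01,
                           duration: float | None = None,
                           record_gates: bool = False):
    """Forward-Euler voltage-clamp simulation of the ASIC1a current.

    Gates start at their equilibrium for ``wave(0)``; the returned current
    Trace is sampled at ``dt``.  With ``record_gates=True`` a tuple
    ``(current, a_trace, s_trace)`` is returned instead.
    """
    duration = wave.duration if duration is None else duration
    ph = wave.grid(dt, duration)
    st0 = equilibrium_gates(float(ph[0]), p)
    out_i = np.empty_like(ph)
    out_a = np.empty_like(ph)
    out_s = np.empty_like(ph)
    status = _kernels.voltage_clamp_kernel(
        ph, dt, vm,
        p.steady_state_array("a"), p.rate_array("a"),
        p.steady_state_array("s"), p.rate_array("s"),
        p.g_asic, p.e_asic, st0.a, st0.s, out_i, out_a, out_s,
    )
    _raise_for_status(status, dt)
    meta = {"clamp_mV": vm, "dt": dt}
    cur = Trace(out_i, dt, "uA/cm^2", meta=meta)
    if record_gates:
        return cur, Trace(out_a, dt, "occupancy"), Trace(out_s, dt, "occupancy")
    return cur
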