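"""Hodgkin-Huxley neuron with an embedded ASIC1a conductance.

Membrane equation (current densities in uA cm^-2)::

    c_m dVm/dt = -(g_Na m^3 h (Vm-E_Na) + g_K n^4 (Vm-E_K)
                   + g_L (Vm-E_L) + I_ASIC1a + I_stim)

The Na_v/K_v rate functions are the classic squid-axon forms expressed on an
absolute voltage axis with rest at -60 mV; the h-gate rates run at one tenth
of the classic speed (total rate ~0.1 ms^-1 at 0 mV versus ~3.8 ms^-1 for
the m-gate).  The m/h rate functions can be shifted along the voltage axis
(s_m, s_h, in mV) or scaled by a common factor (f_m, f_h) that changes
kinetics without moving the steady-state curves.

The removable singularities of alpha_m and alpha_n (where the numerator
crosses zero) are evaluated by the analytic limit x/(e^x - 1) -> 1 within a
guard band of 1e-6 mV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import _kernels
from .gating import ASICGateState, SimulationError, StabilityError, \
    equilibrium_gates, steady_state
from .params import ASICModelParams, NavModifiers, NeuronParams
from .traces import Trace
from .waveforms import PHWaveform, make_constant

__all__ = [
    "NeuronState",
    "alpha_beta",
    "gate_steady_state",
    "nav_half_activation",
    "nav_half_inactivation",
    "nav_rate_at",
    "equilibrium_state",
    "holding_current",
    "simulate_current_clamp",
    "CurrentClampResult",
]

_GATES = ("m", "h", "n")


@dataclass(frozen=True)
class NeuronState:
    """The six dynamical variables advanced by the integrator."""

    v_m: float
    m: float
    h: float
    n: float
    asic: ASICGateState

    def as_array(self) -> np.ndarray:
        return np.array([self.v_m, self.m, self.h, self.n,
                         self.asic.a, self.asic.s])


def _alpha_m(v):
    u = 2.5 - 0.1 * v
    small = np.abs(u) < 1e-6
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 - 0.5 * u, safe / np.expm1(safe))
    return out


def _beta_m(v):
    return 4.0 * np.exp(-v / 18.0)


def _alpha_h(v):
    return 0.007 * np.exp(-v / 20.0)


def _beta_h(v):
    return 0.1 / (1.0 + np.exp(3.0 - 0.1 * v))


def _alpha_n(v):
    w = 1.0 - 0.1 * v
    small = np.abs(w) < 1e-6
    safe = np.where(small, 1.0, w)
    return np.where(small, 0.1 * (1.0 - 0.5 * w), 0.1 * safe / np.expm1(safe))


def _beta_n(v):
    return 0.125 * np.exp(-v / 80.0)


_ALPHA = {"m": _alpha_m, "h": _alpha_h, "n": _alpha_n}
_BETA = {"m": _beta_m, "h": _beta_h, "n": _beta_n}


def alpha_beta(gate: str, vm, mods: NavModifiers | None = None):
    """Opening and closing rates (ms^-1) of gate m, h or n at Vm (mV).

    The m/h rates honour the voltage shift and common scale factor in
    ``mods``.  A shift s moves the gate's voltage dependence (its V1/2) by
    exactly +s, i.e. the unshifted functions are evaluated at Vm - s; a
    negative s_m therefore hyperpolarises activation and increases
    excitability.  Scaling multiplies both rates, leaving the steady state
    alpha/(alpha+beta) unchanged.
    """
    if gate not in _GATES:
        raise ValueError(f"unknown gate {gate!r}")
    mods = mods or NavModifiers()
    vm = np.asarray(vm, dtype=float)
    if not np.all(np.isfinite(vm)):
        raise ValueError("Vm must be finite")
    shift = {"m": mods.s_m, "h": mods.s_h, "n": 0.0}[gate]
    scale = {"m": mods.f_m, "h": mods.f_h, "n": 1.0}[gate]
    v = vm - shift + 60.0
    return scale * _ALPHA[gate](v), scale * _BETA[gate](v)


def gate_steady_state(gate: str, vm, mods: NavModifiers | None = None):
    a, b = alpha_beta(gate, vm, mods)
    return a / (a + b)


def nav_half_activation(mods: NavModifiers | None = None) -> float:
    """Vm (mV) at which the Na+ conductance activation factor m_inf^3 = 1/2.

    The half-activation of the conductance, not of the gating variable:
    m_inf itself equals 0.5^(1/3) ~ 0.794 at this potential.
    """
    def f(v):
        return float(gate_steady_state("m", v, mods)) ** 3 - 0.5

    try:
        return brentq(f, -100.0, 50.0, xtol=1e-10)
    except ValueError as exc:
        raise ValueError("half-activation not bracketed in [-100, 50] mV") from exc


def nav_half_inactivation(mods: NavModifiers | None = None) -> float:
    """Vm (mV) at which the inactivation gate steady state h_inf = 1/2."""
    def f(v):
        return float(gate_steady_state("h", v, mods)) - 0.5

    try:
        return brentq(f, -100.0, 50.0, xtol=1e-10)
    except ValueError as exc:
        raise ValueError("half-inactivation not bracketed in [-100, 50] mV") from exc


def nav_rate_at(gate: str, vm: float, mods: NavModifiers | None = None) -> float:
    """Total relaxation rate alpha + beta of a gate at Vm (ms^-1)."""
    a, b = alpha_beta(gate, vm, mods)
    return float(a + b)


def equilibrium_state(ph: float, vm_rest: float = -60.0,
                      p: NeuronParams | None = None) -> NeuronState:
    """All gates at steady state for (pH, Vm_rest); Vm set to Vm_rest."""
    p = p or NeuronParams()
    return NeuronState(
        v_m=vm_rest,
        m=float(gate_steady_state("m", vm_rest, p.mods)),
        h=float(gate_steady_state("h", vm_rest, p.mods)),
        n=float(gate_steady_state("n", vm_rest, p.mods)),
        asic=equilibrium_gates(ph, p.asic),
    )


def holding_current(target_vm: float, ph: float,
                    p: NeuronParams | None = None) -> float:
    """Stimulation current pinning the resting potential at ``target_vm``.

    At rest all gates sit at their steady states, so the holding current is
    simply minus the net ionic current at the target potential (closed
    form, no root finding).
    """
    p = p or NeuronParams()
    st = equilibrium_state(ph, target_vm, p)
    i_na = p.g_na * st.m**3 * st.h * (target_vm - p.e_na)
    i_k = p.g_k * st.n**4 * (target_vm - p.e_k)
    i_l = p.g_l * (target_vm - p.e_l)
    i_asic = p.asic.g_asic * st.asic.a * st.asic.s * (target_vm - p.asic.e_asic)
    return -(i_na + i_k + i_l + i_asic)


@dataclass
class CurrentClampResult:
    """Membrane potential plus the per-current decomposition of one run."""

    vm: Trace
    currents: dict[str, Trace] | None
    gates: dict[str, Trace] | None
    dt: float
    params: NeuronParams

    def conservation_residual(self) -> float:
        """Max |c_m dV/dt + sum(I)| over all steps (zero up to round-off).

        Requires the run to have recorded currents.
        """
        if self.currents is None:
            raise ValueError("run did not record currents")
        v = self.vm.values
        total = sum(tr.values for tr in self.currents.values())
        total = total + self.params.i_stim
        dvdt = np.diff(v) / self.dt
        return float(np.max(np.abs(self.params.c_m * dvdt + total[:-1])))


def _pack_params(p: NeuronParams) -> np.ndarray:
    return np.array([
        p.c_m, p.g_na, p.g_k, p.g_l, p.e_na, p.e_k, p.e_l, p.i_stim,
        p.asic.g_asic, p.asic.e_asic,
        p.mods.s_m, p.mods.f_m, p.mods.s_h, p.mods.f_h,
    ])


def simulate_current_clamp(wave: PHWaveform, p: NeuronParams | None = None,
                           duration: float | None = None, dt: float = 0.01,
                           record_aux: bool = True,
                           initial: NeuronState | None = None) -> CurrentClampResult:
    """Forward-Euler current-clamp simulation under a pH waveform.

    Initial conditions are the equilibrium at the waveform's starting pH and
    a resting potential of -60 mV unless an explicit state is given.  The
    integrator raises on membrane-potential blow-up (|Vm| > 200 mV) with the
    failing step index.
    """
    p = p or NeuronParams()
    duration = wave.duration if duration is None else duration
    ph = wave.grid(dt, duration)
    st = initial or equilibrium_state(float(ph[0]), -60.0, p)
    out_v = np.empty_like(ph)
    if record_aux:
        out_cur = np.empty((4, len(ph)))
        out_gate = np.empty((5, len(ph)))
    else:
        out_cur = np.empty((4, 1))
        out_gate = np.empty((5, 1))
    status = _kernels.current_clamp_kernel(
        ph, dt, _pack_params(p),
        p.asic.steady_state_array("a"), p.asic.rate_array("a"),
        p.asic.steady_state_array("s"), p.asic.rate_array("s"),
        st.as_array(), out_v, out_cur, out_gate, record_aux,
    )
    if status >= 0:
        raise SimulationError("membrane potential blow-up (|Vm| > 200 mV)",
                              status)
    if status != _kernels.STATUS_OK:
        raise StabilityError("gate-rate stability guard dt*r >= 1",
                             -status - 2)
    vm = Trace(out_v, dt, "mV", meta={"dt": dt})
    currents = gates = None
    if record_aux:
        currents = {name: Trace(out_cur[i], dt, "uA/cm^2")
                    for i, name in enumerate(("na", "k", "leak", "asic"))}
        gates = {name: Trace(out_gate[i], dt, "occupancy")
                 for i, name in enumerate(("m", "h", "n", "a", "s"))}
    return CurrentClampResult(vm=vm, currents=currents, gates=gates, dt=dt,
                              params=p)


def simulate_constant_ph(ph: float, duration: float,
                         p: NeuronParams | None = None, dt: float = 0.01,
                         record_aux: bool = False) -> CurrentClampResult:
    """Convenience wrapper: current clamp at a constant pH from equilibrium."""
    return simulate_current_clamp(make_constant(ph, duration), p,
                                  dt=dt, record_aux=record_aux)
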