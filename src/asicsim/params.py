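"""Model parameters for the ASIC1a two-gate kinetic model and the host neuron.

The ASIC1a current is modelled in the Hodgkin-Huxley spirit with a fast
activation gate ``a`` and a slow (de)sensitization gate ``s``::

    I_ASIC1a = g_asic * a * s * (Vm - E_asic)

Each gate relaxes toward a pH-dependent steady state with a pH-dependent
rate.  The steady-state occupancy of a gate is a Hill-type function of pH,

    f(pH) = 1 / (1 + K**F * 10**(F*H*(pH - 7 - delta)))

where ``K`` positions the curve along the pH axis, ``H`` is a slope factor
whose sign encodes direction, ``F`` is an optional steepening factor applied
to the activation gate, and ``delta`` shifts the curve along the pH axis
(used for the sensitization gate).  The midpoint pH, where f = 1/2, is
``7 + delta - log10(K)/H`` and is independent of ``F``.

Gate rates are double sigmoids of pH (the sum of a fast, acid-limb term and
a slow, alkaline-limb term)::

    r(pH) = a1/(1 + exp(b1*(pH - c1))) + a2/(1 + exp(b2*(pH - c2)))

All times are milliseconds, rates ms^-1, potentials mV, conductances
mS cm^-2, currents uA cm^-2 and capacitances uF cm^-2 throughout the
package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Union

import numpy as np
import yaml

__all__ = [
    "SteadyStateParams",
    "RateFunctionParams",
    "ASICModelParams",
    "NavModifiers",
    "NeuronParams",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class SteadyStateParams:
    """Parameters of a gate's steady-state occupancy curve f(pH)."""

    K: float
    H: float
    F: float = 1.0
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not (self.K > 0):
            raise ValueError(f"K must be positive, got {self.K}")
        if not (self.F > 0):
            raise ValueError(f"F must be positive, got {self.F}")
        if self.H == 0:
            raise ValueError("H must be nonzero")

    @property
    def midpoint(self) -> float:
        """pH at which the occupancy equals 1/2 (independent of F)."""
        return 7.0 + self.delta - math.log10(self.K) / self.H


@dataclass(frozen=True)
class RateFunctionParams:
    """Coefficients of the double-sigmoid gate rate r(pH), in ms^-1."""

    a1: float
    b1: float
    c1: float
    a2: float
    b2: float
    c2: float

    def __post_init__(self) -> None:
        if not (self.a1 > 0 and self.a2 > 0):
            raise ValueError("rate amplitudes a1, a2 must be positive")

    @property
    def ceiling(self) -> float:
        """Upper bound a1 + a2 on the rate over all pH."""
        return self.a1 + self.a2

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.a1, self.b1, self.c1, self.a2, self.b2, self.c2], dtype=float
        )


def _default_act() -> SteadyStateParams:
    return SteadyStateParams(K=23.67, H=2.797, F=1.48, delta=0.0)


def _default_sens() -> SteadyStateParams:
    return SteadyStateParams(K=11.18, H=-9.448, F=1.0, delta=0.15)


def _default_rate_act() -> RateFunctionParams:
    return RateFunctionParams(0.3487, 10.14, 6.392, 234.3, -5.553, 8.595)


def _default_rate_sens() -> RateFunctionParams:
    return RateFunctionParams(0.002531, 13.94, 6.769, 0.0008942, -18.39, 7.436)


@dataclass(frozen=True)
class ASICModelParams:
    """Complete parameter set of the two-gate ASIC1a current model.

    Defaults are the final published constants of the model (activation gate
    steepened by 1.48, sensitization curve shifted alkaline by 0.15 pH
    units).
    """

    g_asic: float = 10.0  # mS cm^-2
    e_asic: float = 50.0  # mV
    act: SteadyStateParams = field(default_factory=_default_act)
    sens: SteadyStateParams = field(default_factory=_default_sens)
    rate_act: RateFunctionParams = field(default_factory=_default_rate_act)
    rate_sens: RateFunctionParams = field(default_factory=_default_rate_sens)

    def steady_state_array(self, gate: str) -> np.ndarray:
        p = self.act if gate == "a" else self.sens
        return np.array([p.K, p.H, p.F, p.delta], dtype=float)

    def rate_array(self, gate: str) -> np.ndarray:
        p = self.rate_act if gate == "a" else self.rate_sens
        return p.as_array()


@dataclass(frozen=True)
class NavModifiers:
    """Perturbations of the Na_v gates m and h.

    ``s_m``/``s_h`` shift the rate functions along the voltage axis (mV);
    ``f_m``/``f_h`` scale both the opening and closing rate by a common
    factor, changing kinetics without altering the voltage dependence.
    """

    s_m: float = 0.0
    f_m: float = 1.0
    s_h: float = 0.0
    f_h: float = 1.0

    def __post_init__(self) -> None:
        if not (self.f_m > 0 and self.f_h > 0):
            raise ValueError("rate scale factors f_m, f_h must be positive")


@dataclass(frozen=True)
class NeuronParams:
    """Hodgkin-Huxley neuron with an embedded ASIC1a conductance."""

    c_m: float = 1.0  # uF cm^-2
    g_na: float = 135.0  # mS cm^-2
    g_k: float = 45.0
    g_l: float = 0.5
    e_na: float = 55.0  # mV
    e_k: float = -72.0
    e_l: float = -49.387
    i_stim: float = 0.0  # uA cm^-2, positive = outward by convention
    mods: NavModifiers = field(default_factory=NavModifiers)
    asic: ASICModelParams = field(default_factory=ASICModelParams)

    def with_(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Structured-text (YAML) round trip


def _params_to_dict(p: Union[ASICModelParams, NeuronParams]) -> dict:
    return asdict(p)


def save_params(p: Union[ASICModelParams, NeuronParams], path: Union[str, Path]) -> None:
    """Write a parameter set to a YAML parameter file."""
    kind = "neuron" if isinstance(p, NeuronParams) else "asic"
    doc = {"kind": kind, "params": _params_to_dict(p)}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _asic_from_dict(d: dict) -> ASICModelParams:
    return ASICModelParams(
        g_asic=d["g_asic"],
        e_asic=d["e_asic"],
        act=SteadyStateParams(**d["act"]),
        sens=SteadyStateParams(**d["sens"]),
        rate_act=RateFunctionParams(**d["rate_act"]),
        rate_sens=RateFunctionParams(**d["rate_sens"]),
    )


def load_params(path: Union[str, Path]) -> Union[ASICModelParams, NeuronParams]:
    """Read a parameter set written by :func:`save_params`."""
    doc = yaml.safe_load(Path(path).read_text())
    d = doc["params"]
    if doc["kind"] == "asic":
        return _asic_from_dict(d)
    return NeuronParams(
        c_m=d["c_m"],
        g_na=d["g_na"],
        g_k=d["g_k"],
        g_l=d["g_l"],
        e_na=d["e_na"],
        e_k=d["e_k"],
        e_l=d["e_l"],
        i_stim=d["i_stim"],
        mods=NavModifiers(**d["mods"]),
        asic=_asic_from_dict(d["asic"]),
    )
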