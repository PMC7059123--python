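"""Synthetic voltage-clamp recordings for exercising the fitting pipeline.

A recording is the model current under a protocol waveform, scaled by a
cell-size gain and corrupted by additive white Gaussian noise — a minimal
stand-in for patch-clamp noise that is adequate for testing least-squares
stages (no 1/f, seal-leak or capacitive-transient modelling).

Two recording configurations are emulated: whole-cell (200-ms solution
exchange, 1-ms sampling, integrated at 0.1 ms) and excised outside-out
patches (1-ms exchange, 0.02-ms sampling, integrated at 0.01 ms).  The
default ``auto`` configuration assigns the fast protocols (activation
series, deactivation) to outside-out patches and the slow ones to whole
cells, as in the experiments the protocols emulate.

Suites are written as a directory of CSV traces plus one JSON manifest
carrying the protocol options, seed and ground-truth parameters, so a suite
round-trips losslessly through plain-text files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np

from .gating import simulate_voltage_clamp
from .params import ASICModelParams
from .protocols import Protocol, protocol_library
from .traces import Trace, read_trace

__all__ = [
    "SyntheticRecordingConfig",
    "Recording",
    "add_noise",
    "generate_recording",
    "generate_protocol_suite",
    "write_suite",
    "read_suite",
]

_CONFIGS = {
    # exchange ms, sampling dt ms, integration dt ms
    "whole_cell": (200.0, 1.0, 0.1),
    "outside_out": (1.0, 0.02, 0.01),
}

# protocols resolved by patch configuration when cfg.configuration == "auto"
_FAST_PROTOCOLS = ("activation_series", "deactivation")

_SUITE_PROTOCOLS = (
    "activation_series",
    "deactivation",
    "steady_state_activation",
    "ssd_curve",
    "ssd_kinetics",
    "recovery_kinetics",
)


@dataclass(frozen=True)
class SyntheticRecordingConfig:
    """Ground truth and acquisition settings for synthetic recordings."""

    params: ASICModelParams = field(default_factory=ASICModelParams)
    configuration: str = "auto"  # whole_cell | outside_out | auto
    noise_sd: float = 5.0  # uA cm^-2, additive white Gaussian
    gain: float = 1.0  # cell-size scale, current-density -> recorded amplitude
    seed: int = 0
    vm: float = -60.0  # clamp potential, mV

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.configuration not in (*_CONFIGS, "auto"):
            raise ValueError(f"unknown configuration {self.configuration!r}")

    def resolve(self, protocol_name: str) -> tuple[float, float, float]:
        """(exchange, sampling dt, integration dt) for a protocol."""
        if self.configuration != "auto":
            return _CONFIGS[self.configuration]
        key = "outside_out" if protocol_name in _FAST_PROTOCOLS \
            else "whole_cell"
        return _CONFIGS[key]


@dataclass
class Recording:
    """One synthetic recording: the protocol, the noisy trace, metadata."""

    protocol: Protocol
    trace: Trace
    meta: dict


def add_noise(trace: Trace, sd: float, rng: np.random.Generator) -> Trace:
    """Additive i.i.d. Gaussian noise; zero sd returns the values unchanged."""
    values = trace.values if sd == 0 else \
        trace.values + rng.normal(0.0, sd, size=len(trace.values))
    return Trace(values, trace.dt, trace.unit, t0=trace.t0,
                 meta=dict(trace.meta))


def generate_recording(cfg: SyntheticRecordingConfig, protocol: Protocol,
                       rng: np.random.Generator | None = None) -> Recording:
    """Simulate the model current under a protocol and add recording noise.

    The current is integrated at the configuration's integration step, then
    downsampled to the acquisition sampling interval, scaled by the gain and
    corrupted by Gaussian noise (reproducible from the seed).
    """
    exchange, dt_sample, dt_int = cfg.resolve(protocol.name)
    rng = rng or np.random.default_rng(cfg.seed)
    clean = simulate_voltage_clamp(protocol.wave, cfg.params, vm=cfg.vm,
                                   dt=dt_int)
    stride = int(round(dt_sample / dt_int))
    sampled = clean.downsampled(stride)
    scaled = Trace(cfg.gain * sampled.values, sampled.dt, sampled.unit,
                   meta=dict(sampled.meta))
    noisy = add_noise(scaled, cfg.noise_sd, rng)
    noisy.meta.update({
        "protocol": protocol.name,
        "configuration": cfg.configuration,
        "exchange_ms": exchange,
        "noise_sd": cfg.noise_sd,
        "gain": cfg.gain,
        "seed": cfg.seed,
    })
    return Recording(protocol=protocol, trace=noisy, meta=dict(noisy.meta))


def generate_protocol_suite(cfg: SyntheticRecordingConfig,
                            names: tuple[str, ...] = _SUITE_PROTOCOLS,
                            **overrides) -> dict[str, Recording]:
    """One tagged recording per protocol, covering the full kinetics suite.

    ``overrides`` maps protocol name -> builder options dict.
    """
    rng = np.random.default_rng(cfg.seed)
    suite = {}
    for name in names:
        options = dict(overrides.get(name, {}))
        options.setdefault("exchange", cfg.resolve(name)[0])
        protocol = protocol_library(name, **options)
        suite[name] = generate_recording(cfg, protocol, rng)
    return suite


# ---------------------------------------------------------------------------
# Plain-text persistence


def write_suite(suite: dict[str, Recording], directory: Union[str, Path],
                cfg: SyntheticRecordingConfig) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {
        "configuration": cfg.configuration,
        "noise_sd": cfg.noise_sd,
        "gain": cfg.gain,
        "seed": cfg.seed,
        "vm": cfg.vm,
        "ground_truth": asdict(cfg.params),
    }, "recordings": {}}
    for name, rec in suite.items():
        rec.trace.write(directory / f"{name}.csv")
        manifest["recordings"][name] = {
            "options": rec.protocol.options,
            "meta": rec.meta,
        }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_suite(directory: Union[str, Path]
               ) -> tuple[dict[str, Recording], SyntheticRecordingConfig]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    c = manifest["config"]
    gt = c["ground_truth"]
    from .params import RateFunctionParams, SteadyStateParams

    params = ASICModelParams(
        g_asic=gt["g_asic"], e_asic=gt["e_asic"],
        act=SteadyStateParams(**gt["act"]),
        sens=SteadyStateParams(**gt["sens"]),
        rate_act=RateFunctionParams(**gt["rate_act"]),
        rate_sens=RateFunctionParams(**gt["rate_sens"]),
    )
    cfg = SyntheticRecordingConfig(
        params=params, configuration=c["configuration"],
        noise_sd=c["noise_sd"], gain=c["gain"], seed=c["seed"], vm=c["vm"],
    )
    suite = {}
    for name, entry in manifest["recordings"].items():
        protocol = protocol_library(name, **entry["options"])
        trace = read_trace(directory / f"{name}.csv")
        suite[name] = Recording(protocol=protocol, trace=trace,
                                meta=entry["meta"])
    return suite, cfg
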