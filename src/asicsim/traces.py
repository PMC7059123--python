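"""Uniformly sampled time series (current density, voltage or pH).

Traces are written as two-column CSV (``time_ms,value``) with a JSON
side-car file holding the unit, the sampling interval and any protocol
metadata, so recordings round-trip losslessly through plain-text files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["Trace", "read_trace"]


@dataclass
class Trace:
    """A uniformly sampled signal starting at ``t0`` with step ``dt`` (ms)."""

    values: np.ndarray
    dt: float
    unit: str  # "mV" | "uA/cm^2" | "pH"
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self.values)) * self.dt

    @property
    def duration(self) -> float:
        return (len(self.values) - 1) * self.dt

    def window(self, t_start: float, t_end: float) -> "Trace":
        """Sub-trace covering [t_start, t_end] (absolute times, ms)."""
        if t_end <= t_start:
            raise ValueError("empty window")
        i0 = max(0, int(np.ceil((t_start - self.t0) / self.dt - 1e-9)))
        i1 = min(len(self.values) - 1, int(np.floor((t_end - self.t0) / self.dt + 1e-9)))
        if i1 < i0:
            raise ValueError("window outside trace")
        return Trace(self.values[i0:i1 + 1], self.dt, self.unit,
                     t0=self.t0 + i0 * self.dt, meta=self.meta)

    def downsampled(self, stride: int) -> "Trace":
        return Trace(self.values[::stride], self.dt * stride, self.unit,
                     t0=self.t0, meta=self.meta)

    # -- persistence ---------------------------------------------------------
    def write(self, path: Union[str, Path]) -> None:
        path = Path(path)
        pd.DataFrame({"time_ms": self.time, "value": self.values}).to_csv(
            path, index=False
        )
        sidecar = {"unit": self.unit, "dt": self.dt, "t0": self.t0,
                   "meta": self.meta}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1)
        )


def read_trace(path: Union[str, Path]) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Trace(df["value"].to_numpy(), sidecar["dt"], sidecar["unit"],
                 t0=sidecar["t0"], meta=sidecar.get("meta", {}))
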