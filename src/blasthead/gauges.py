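"""Gauge traces: uniformly sampled pressure (and von Mises) time histories."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GaugeTrace"]


@dataclass
class GaugeTrace:
    """Uniformly sampled time history recorded at a named gauge.

    Parameters
    ----------
    time:
        Sample times in seconds, uniformly spaced, strictly increasing.
    pressure:
        Pressure at each sample, Pa.  Whether this is absolute or gauge
        (over-)pressure is up to the producer; solvers in this package
        record gauge pressure unless stated otherwise.
    von_mises:
        Optional von Mises stress channel, Pa.
    label:
        Gauge name, e.g. ``"standoff_1.0m"`` or ``"frontal_cortex"``.
    """

    time: np.ndarray
    pressure: np.ndarray
    von_mises: np.ndarray | None = None
    label: str = "gauge"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.von_mises is not None:
            self.von_mises = np.asarray(self.von_mises, dtype=float)
            if self.von_mises.shape != self.time.shape:
                raise ValueError("von_mises and time must have equal length")
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValueError("trace needs at least two samples")
        if self.pressure.shape != self.time.shape:
            raise ValueError("pressure and time must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def dt(self) -> float:
        """Sampling interval in seconds (median spacing)."""
        return float(np.median(np.diff(self.time)))

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def shifted(self, offset_pa: float, label: str | None = None) -> "GaugeTrace":
        """Return a copy with a constant pressure offset added."""
        return GaugeTrace(
            time=self.time.copy(),
            pressure=self.pressure + offset_pa,
            von_mises=None if self.von_mises is None else self.von_mises.copy(),
            label=self.label if label is None else label,
            meta=dict(self.meta),
        )

    def to_csv(self, path: str | Path) -> None:
        """Write ``time_s,pressure_pa[,von_mises_pa]`` with LF line endings."""
        cols = {"time_s": self.time, "pressure_pa": self.pressure}
        if self.von_mises is not None:
            cols["von_mises_pa"] = self.von_mises
        pd.DataFrame(cols).to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path, label: str | None = None) -> "GaugeTrace":
        df = pd.read_csv(path)
        required = {"time_s", "pressure_pa"}
        if not required.issubset(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(required)}")
        vm = df["von_mises_pa"].to_numpy() if "von_mises_pa" in df.columns else None
        return cls(
            time=df["time_s"].to_numpy(),
            pressure=df["pressure_pa"].to_numpy(),
            von_mises=vm,
            label=label or Path(path).stem,
        )

    def __len__(self) -> int:
        return int(self.time.size)
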