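"""Lysis time series: the common tabular currency of the package.

A :class:`LysisSeries` is a time grid in hours together with the tumor cell
count at each time, optionally accompanied by the immune cell count (only
the cellular automaton produces one).  Time resolution is one hour for the
discrete models (one automaton step = one hour).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LysisSeries"]


@dataclass
class LysisSeries:
    """Tumor-cell counts on a strictly increasing time grid (hours).

    Parameters
    ----------
    time_hr
        Time points in hours, strictly increasing, starting at 0.
    tumor_cells
        Tumor cell count at each time point (non-negative).
    immune_cells
        Optional immune cell count at each time point.
    truncated
        True when a simulation stopped before tumor extinction (step cap
        reached or no immune cells left).
    """

    time_hr: np.ndarray
    tumor_cells: np.ndarray
    immune_cells: np.ndarray | None = None
    truncated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_hr = np.asarray(self.time_hr, dtype=float)
        self.tumor_cells = np.asarray(self.tumor_cells, dtype=float)
        if self.time_hr.ndim != 1 or self.time_hr.shape != self.tumor_cells.shape:
            raise ValueError("time_hr and tumor_cells must be 1-D and equal length")
        if len(self.time_hr) == 0:
            raise ValueError("empty series")
        if np.any(np.diff(self.time_hr) <= 0):
            raise ValueError("time_hr must be strictly increasing")
        if np.any(self.tumor_cells < 0):
            raise ValueError("tumor_cells must be non-negative")
        if self.immune_cells is not None:
            self.immune_cells = np.asarray(self.immune_cells, dtype=float)
            if self.immune_cells.shape != self.time_hr.shape:
                raise ValueError("immune_cells length mismatch")

    def __len__(self) -> int:
        return len(self.time_hr)

    @property
    def initial_count(self) -> float:
        return float(self.tumor_cells[0])

    def is_nonincreasing(self, atol: float = 0.0) -> bool:
        return bool(np.all(np.diff(self.tumor_cells) <= atol))

    def to_frame(self) -> pd.DataFrame:
        data = {"time_hr": self.time_hr, "tumor_cells": self.tumor_cells}
        if self.immune_cells is not None:
            data["immune_cells"] = self.immune_cells
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "LysisSeries":
        df = pd.read_csv(path)
        immune = df["immune_cells"].to_numpy() if "immune_cells" in df else None
        return cls(
            time_hr=df["time_hr"].to_numpy(),
            tumor_cells=df["tumor_cells"].to_numpy(),
            immune_cells=immune,
        )
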