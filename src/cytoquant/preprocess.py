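"""Spillover compensation and display transforms.

Compensation inverts the spillover matrix S (observed = true @ S, diagonal
1) on the fluorescence channels; scatter is untouched and negative
compensated values are kept (quantitation handles them).  The arcsinh
display transform is used only for gate geometry — all quantitative
statistics (medians, ABC) are computed on compensated linear values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import EventTable

__all__ = ["SpilloverMatrix", "TransformSpec", "compensate", "transform"]

SCATTER_CHANNELS = ("FSC-A", "FSC-H", "FSC-W", "SSC-A", "SSC-H", "SSC-W", "Time")


@dataclass
class SpilloverMatrix:
    """Square spillover matrix indexed by fluorescence channel names.

    ``matrix[i, j]`` is the fraction of channel *i*'s true signal observed in
    detector *j*; the diagonal is exactly 1.
    """

    channels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        n = len(self.channels)
        if self.matrix.shape != (n, n):
            raise ValueError(f"spillover matrix shape {self.matrix.shape} != ({n}, {n})")
        if not np.allclose(np.diag(self.matrix), 1.0, atol=1e-12):
            raise ValueError("spillover matrix diagonal must be exactly 1")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("spillover matrix is singular")

    @classmethod
    def identity(cls, channels: list[str]) -> "SpilloverMatrix":
        return cls(list(channels), np.eye(len(channels)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpilloverMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: spillover rows/columns must share channel names")
        return cls([str(c) for c in df.columns], df.to_numpy(dtype=np.float64))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.channels, columns=self.channels).to_csv(path)


def compensate(table: EventTable, spill: SpilloverMatrix) -> EventTable:
    """Replace fluorescence columns by ``observed @ inv(spill)``.

    All matrix channels must be present in the table; scatter channels are
    untouched.  A ``CYTOQ_COMPENSATED`` keyword records the operation.
    Raises ``KeyError`` on channel mismatch, ``ValueError`` on a singular
    matrix (checked at construction).
    """
    missing = [c for c in spill.channels if c not in table.channels]
    if missing:
        raise KeyError(f"spillover channels missing from table: {missing}")
    idx = [table.channel_index(c) for c in spill.channels]
    events = table.events.copy()
    events[:, idx] = events[:, idx] @ np.linalg.inv(spill.matrix)
    return table.with_events(events, CYTOQ_COMPENSATED="1")


@dataclass
class TransformSpec:
    """Per-channel display transform: identity (scatter) or arcsinh.

    ``cofactors`` maps channel name -> arcsinh cofactor (>0); channels not
    listed use the identity.  Default cofactor 150 is typical for
    conventional-cytometer fluorescence.
    """

    cofactors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ch, cf in self.cofactors.items():
            if not cf > 0:
                raise ValueError(f"cofactor for {ch} must be > 0, got {cf}")

    @classmethod
    def arcsinh_all(cls, channels: list[str], cofactor: float = 150.0,
                    skip_scatter: bool = True) -> "TransformSpec":
        chans = [c for c in channels if not (skip_scatter and c in SCATTER_CHANNELS)]
        return cls({c: cofactor for c in chans})

    def apply_channel(self, name: str, values: np.ndarray) -> np.ndarray:
        cf = self.cofactors.get(name)
        return values if cf is None else np.arcsinh(values / cf)


def transform(table: EventTable, spec: TransformSpec) -> EventTable:
    """Transformed copy for gating geometry; linear values are kept upstream.

    Each listed channel must exist in the table.
    """
    missing = [c for c in spec.cofactors if c not in table.channels]
    if missing:
        raise KeyError(f"transform spec channels missing from table: {missing}")
    events = table.events.copy()
    for ch, cf in spec.cofactors.items():
        j = table.channel_index(ch)
        events[:, j] = np.arcsinh(events[:, j] / cf)
    return table.with_events(events, CYTOQ_TRANSFORMED="arcsinh")
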