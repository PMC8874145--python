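"""Bead calibration, ABC conversion, FMO background cutoffs, subset stats.

PE-conjugated antibodies carry one fluorochrome per antibody, so the number
of PE molecules measured on a cell equals its antibody binding capacity
(ABC).  A four-peak calibration bead tube with known PE molecules per bead
is fitted as an ordinary least-squares line on log10 scales,

    log10(ABC) = slope * log10(PE fluorescence) + intercept,

and used to convert cellular PE signal to ABC.  Per gated subset, the
background cutoff is the 90th percentile of ABC in the fluorescence-minus-
one (FMO) control, and subsets with fewer than 66 events are omitted from
statistical evaluation.  All quantiles (median, Q1/Q3, the 90th percentile)
use linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .events import EventTable
from .gating import GateResult

__all__ = [
    "CalibrationCurve",
    "SubsetStats",
    "BackgroundCutoffTable",
    "PeakFindingError",
    "find_bead_peaks",
    "fit_calibration",
    "fluorescence_to_abc",
    "background_cutoffs",
    "subset_statistics",
    "summarize_resolution",
    "stats_frame",
    "MIN_EVENTS",
]

MIN_EVENTS = 66  # minimum cell count for statistical evaluation
_MIN_PEAK_EVENTS = 50
_MIN_PEAK_GAP_LOG10 = 0.25  # adjacent bead peaks closer than this are unresolved


class PeakFindingError(ValueError):
    """Bead tube does not contain the expected number of resolvable peaks."""


@dataclass
class CalibrationCurve:
    """Log-log line mapping PE fluorescence to ABC, with peak diagnostics."""

    slope: float
    intercept: float
    peak_medians: tuple[float, ...] = ()
    lot_levels: tuple[float, ...] = ()
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")
        pm = np.asarray(self.peak_medians)
        if pm.size and not np.all(np.diff(pm) > 0):
            raise ValueError("peak medians must be strictly increasing")


def find_bead_peaks(bead_table: EventTable, channel: str = "PE-A") -> np.ndarray:
    """Median fluorescence of the 4 bead peaks, ascending.

    One-dimensional k-means (k=4) on log10 fluorescence, initialised at the
    evenly spaced octile quantiles — deterministic given the data and
    invariant to event order.  Raises :class:`PeakFindingError` when fewer
    than 4 well-separated clusters are present (adjacent peak medians closer
    than ``10**0.25``-fold, or a cluster with under 50 beads).
    """
    values = bead_table.column(channel)
    values = np.sort(values[values > 0])
    if values.size < 4 * _MIN_PEAK_EVENTS:
        raise PeakFindingError(
            f"bead tube has {values.size} positive events; need >= {4 * _MIN_PEAK_EVENTS}")
    x = np.log10(values)
    centers = np.quantile(x, [0.125, 0.375, 0.625, 0.875])
    assign = np.zeros(x.size, dtype=np.intp)
    for _ in range(200):
        new_assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for k in range(4):
            sel = x[assign == k]
            if sel.size:
                centers[k] = sel.mean()
        centers = np.sort(centers)

    medians = []
    for k in range(4):
        sel = x[assign == k]
        if sel.size < _MIN_PEAK_EVENTS:
            raise PeakFindingError(f"peak {k + 1} has only {sel.size} events — "
                                   "fewer than 4 resolvable peaks")
        medians.append(np.median(sel))
    medians = np.asarray(medians)
    if np.any(np.diff(medians) < _MIN_PEAK_GAP_LOG10):
        raise PeakFindingError("adjacent bead peaks are not resolvable "
                               f"(log10 medians {np.round(medians, 3)})")
    return 10.0 ** medians


def fit_calibration(peak_medians, lot) -> CalibrationCurve:
    """OLS fit of log10(lot level) on log10(peak median fluorescence).

    ``lot`` is a :class:`~cytoquant.simulate.BeadLotSpec` or a 4-vector of
    PE-molecules-per-bead levels.  Warns when R² < 0.99 (a poorly resolved
    or mis-ordered bead acquisition).
    """
    levels = np.asarray(getattr(lot, "levels", lot), dtype=float)
    medians = np.asarray(peak_medians, dtype=float)
    if medians.shape != (4,) or levels.shape != (4,):
        raise ValueError("need exactly 4 peak medians and 4 lot levels")
    if np.any(medians <= 0):
        raise ValueError(f"nonpositive peak median in {medians}; beads must be positive")
    fit = sps.linregress(np.log10(medians), np.log10(levels))
    r2 = float(fit.rvalue ** 2)
    if r2 < 0.99:
        warnings.warn(f"calibration R^2 = {r2:.4f} < 0.99 — check bead acquisition",
                      stacklevel=2)
    return CalibrationCurve(float(fit.slope), float(fit.intercept),
                            tuple(medians), tuple(levels), r2)


def fluorescence_to_abc(values, curve: CalibrationCurve, return_flags: bool = False):
    """Convert PE fluorescence to ABC: ``10**(slope*log10(F) + intercept)``.

    Nonpositive fluorescence (possible after compensation) maps to ABC 0 and
    is flagged below-detection rather than dropped, so subset event counts
    are preserved.  Strictly increasing in F for F > 0.
    """
    values = np.asarray(values, dtype=float)
    flags = values <= 0
    abc = np.zeros_like(values)
    pos = ~flags
    abc[pos] = 10.0 ** (curve.slope * np.log10(values[pos]) + curve.intercept)
    return (abc, flags) if return_flags else abc


@dataclass
class BackgroundCutoffTable:
    """Per-subset background cutoff in ABC units, from an FMO control."""

    cutoffs: dict[str, float] = field(default_factory=dict)
    min_events: int = MIN_EVENTS

    def __post_init__(self) -> None:
        for code, cut in self.cutoffs.items():
            if cut < 0:
                raise ValueError(f"{code}: negative cutoff {cut}")

    def __contains__(self, code: str) -> bool:
        return code in self.cutoffs

    def __getitem__(self, code: str) -> float:
        return self.cutoffs[code]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.cutoffs.items()),
                     columns=["code", "background_cutoff_abc"]).to_csv(path, index=False)


def background_cutoffs(
    fmo_result: GateResult,
    fmo_abc: np.ndarray,
    min_events: int = MIN_EVENTS,
) -> BackgroundCutoffTable:
    """90th percentile of FMO ABC per leaf subset.

    ``fmo_abc`` is the ABC vector of the gated FMO tube (same event order as
    the gate result).  Leaves with fewer than ``min_events`` events are
    omitted.
    """
    fmo_abc = np.asarray(fmo_abc, dtype=float)
    cutoffs = {}
    for code in fmo_result.leaf_order:
        sel = fmo_abc[fmo_result.leaf_mask(code)]
        if sel.size >= min_events:
            cutoffs[code] = float(np.quantile(sel, 0.90))
    return BackgroundCutoffTable(cutoffs, min_events)


@dataclass
class SubsetStats:
    """Per-subset quantitation of one stained tube."""

    code: str
    n: int
    median_pe: float
    median_abc: float
    q1_abc: float
    q3_abc: float
    iqr_abc: float
    background_cutoff: float | None
    percent_positive: float | None
    below_min_count: bool


def subset_statistics(
    result: GateResult,
    pe: np.ndarray,
    abc: np.ndarray,
    cutoffs: BackgroundCutoffTable | None = None,
    min_events: int = MIN_EVENTS,
) -> list[SubsetStats]:
    """Median PE, median/Q1/Q3/IQR of ABC and percent positive per leaf.

    Percent positive is ``100 * #(ABC > cutoff) / n`` against the subset's
    FMO cutoff; when a leaf is absent from the cutoff table the statistic is
    reported unavailable (``None``) but the rest is still computed.  Leaves
    below ``min_events`` are flagged; empty leaves are skipped.
    """
    pe = np.asarray(pe, dtype=float)
    abc = np.asarray(abc, dtype=float)
    out: list[SubsetStats] = []
    for code in result.leaf_order:
        mask = result.leaf_mask(code)
        n = int(mask.sum())
        if n == 0:
            continue
        a = abc[mask]
        q1, med, q3 = np.quantile(a, [0.25, 0.50, 0.75])
        cutoff = cutoffs[code] if (cutoffs is not None and code in cutoffs) else None
        pct = float(100.0 * np.mean(a > cutoff)) if cutoff is not None else None
        out.append(SubsetStats(
            code=code, n=n,
            median_pe=float(np.median(pe[mask])),
            median_abc=float(med), q1_abc=float(q1), q3_abc=float(q3),
            iqr_abc=float(q3 - q1),
            background_cutoff=cutoff, percent_positive=pct,
            below_min_count=n < min_events,
        ))
    return out


def stats_frame(stats: list[SubsetStats]) -> pd.DataFrame:
    """Tidy one-row-per-subset DataFrame of :class:`SubsetStats`."""
    return pd.DataFrame([vars(s) for s in stats])


def summarize_resolution(cutoffs: BackgroundCutoffTable | dict[str, float]):
    """Median/min/max over all per-subset background cutoffs (ABC units)."""
    values = np.asarray(list((cutoffs.cutoffs if isinstance(cutoffs, BackgroundCutoffTable)
                              else cutoffs).values()), dtype=float)
    if values.size == 0:
        raise ValueError("empty cutoff table")
    return float(np.median(values)), float(values.min()), float(values.max())
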