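"""Antibody titration analytics: barcode demultiplexing, titration curves,
Stain Index and optimal-titer selection; also clone benchmarking.

The titration mixture barcodes six cell types with two cell-tracking dyes
at three intensity levels each, so a positive and a negative population are
present for nearly every reagent in a single tube.  Events are demultiplexed
by rectangular regions in the (Blue, Deep Red) tracker plane; blood events
can further be split into lymphocytes/monocytes/granulocytes on scatter.

Stain Index uses a robust spread of the negative population (84.13th
percentile minus median — one normal-equivalent SD), SI = (median_pos −
median_neg) / (2 × rSD_neg); the classical SD variant is available.  The
default titer policy picks the most dilute step still at ≥90% of the
maximal positive signal ("edge of saturation"), stepping one further when
the negative line's background exceeds a multiple of the FMO level; the
"max-SI-minus-one" policy picks one step more dilute than the Stain-Index
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import EventTable
from .quant import SubsetStats
from .simulate import BarcodeScheme

__all__ = [
    "demultiplex",
    "TitrationCurve",
    "build_titration_curves",
    "stain_index",
    "stain_index_series",
    "StainIndexResult",
    "TiterRecommendation",
    "TiterSelectionError",
    "select_titer",
    "benchmark_clones",
    "BenchmarkReport",
    "DEFAULT_BLOOD_SCATTER_REGIONS",
]

P8413 = 0.8413  # one-normal-SD upper quantile

#: SSC-A bands splitting demultiplexed blood events (linear units)
DEFAULT_BLOOD_SCATTER_REGIONS = {
    "blood lymphocytes": (0.0, 45_000.0),
    "blood monocytes": (45_000.0, 100_000.0),
    "blood granulocytes": (100_000.0, np.inf),
}


def _level_boundaries(levels: dict[str, float]) -> tuple[list[str], np.ndarray]:
    names = sorted(levels, key=levels.get)
    vals = np.array([levels[n] for n in names])
    return names, np.sqrt(vals[:-1] * vals[1:])  # geometric midpoints


def demultiplex(
    table: EventTable,
    scheme: BarcodeScheme,
    split_blood: dict[str, tuple[float, float]] | None = None,
    blood_name: str = "blood",
) -> np.ndarray:
    """Assign each event to a barcoded cell type (or None).

    Tracker intensities are classified into negative/low/high by half-open
    regions split at the geometric midpoints between the scheme's level
    medians; an event lying exactly on a boundary is left unassigned, as is
    any (Blue, Deep Red) combination not in the scheme.  With
    ``split_blood`` (SSC-A bands), blood events are relabelled by scatter
    region.  Raises ``KeyError`` if a tracker channel is missing.
    """
    blue = table.column(scheme.blue_channel)
    red = table.column(scheme.red_channel)
    level_names, bounds = _level_boundaries(scheme.levels)

    def classify(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        idx = np.searchsorted(bounds, x, side="left")
        on_boundary = np.isin(x, bounds)
        return idx, on_boundary

    b_idx, b_edge = classify(blue)
    r_idx, r_edge = classify(red)
    lookup = {(bl, rl): name for name, (bl, rl) in scheme.codes.items()}

    labels = np.full(table.n_events, None, dtype=object)
    for (bl, rl), name in lookup.items():
        bi = level_names.index(bl)
        ri = level_names.index(rl)
        labels[(b_idx == bi) & (r_idx == ri)] = name
    labels[b_edge | r_edge] = None

    if split_blood:
        ssc = table.column("SSC-A")
        blood_mask = labels == blood_name
        relabeled = np.full(table.n_events, None, dtype=object)
        for region, (lo, hi) in split_blood.items():
            relabeled[blood_mask & (ssc >= lo) & (ssc < hi)] = region
        labels = np.where(blood_mask, relabeled, labels)
    return labels


@dataclass
class TitrationCurve:
    """Per-cell-type dilution curves of one reagent.

    ``points`` is tidy: one row per (cell_type, dilution) with median PE,
    robust SD of PE (84.13th percentile − median) and event count.
    """

    reagent: str
    dilutions: tuple[float, ...]
    points: pd.DataFrame
    fmo_level: float | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dilutions)
        if d.size == 0 or np.any(np.diff(d) >= 0):
            raise ValueError("dilutions must be nonempty and strictly decreasing")

    def series(self, cell_type: str, column: str = "median_pe") -> pd.Series:
        sub = self.points[self.points["cell_type"] == cell_type]
        return sub.set_index("dilution")[column].reindex(list(self.dilutions))


def build_titration_curves(
    series: list[EventTable],
    scheme: BarcodeScheme,
    dilutions: tuple[float, ...],
    fmo_table: EventTable | None = None,
    reagent: str = "",
    split_blood: dict[str, tuple[float, float]] | None = None,
) -> TitrationCurve:
    """Demultiplex each dilution tube and summarise PE per cell type.

    Raises ``ValueError`` on a tube/dilution count mismatch.  The FMO
    reference level is the median PE over all demultiplexed events of the
    FMO tube.
    """
    if len(series) != len(dilutions):
        raise ValueError(f"{len(series)} tubes for {len(dilutions)} dilutions")
    rows = []
    for tube, dilution in zip(series, dilutions):
        labels = demultiplex(tube, scheme, split_blood=split_blood)
        pe = tube.column("PE-A")
        for cell_type in pd.unique(labels[labels != None]):  # noqa: E711
            sel = pe[labels == cell_type]
            med = float(np.median(sel))
            rows.append({"cell_type": cell_type, "dilution": dilution,
                         "median_pe": med,
                         "rsd_pe": float(np.quantile(sel, P8413) - med),
                         "n": int(sel.size)})
    fmo_level = None
    if fmo_table is not None:
        labels = demultiplex(fmo_table, scheme, split_blood=split_blood)
        sel = fmo_table.column("PE-A")[labels != None]  # noqa: E711
        fmo_level = float(np.median(sel)) if sel.size else None
    return TitrationCurve(reagent, tuple(dilutions),
                          pd.DataFrame(rows, columns=["cell_type", "dilution",
                                                      "median_pe", "rsd_pe", "n"]),
                          fmo_level)


def stain_index(pos: np.ndarray, neg: np.ndarray, robust: bool = True) -> float:
    """Separation of a positive from a negative population.

    ``SI = (median(pos) − median(neg)) / (2 × spread(neg))`` with spread the
    robust SD (P84.13 − median) by default, or the classical sample SD with
    ``robust=False``.  Returns NaN (undefined) for a zero-spread negative.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positive and negative vectors must be nonempty")
    med_neg = float(np.median(neg))
    spread = float(np.quantile(neg, P8413) - med_neg) if robust \
        else float(np.std(neg, ddof=1))
    if spread <= 0:
        return float("nan")
    return (float(np.median(pos)) - med_neg) / (2.0 * spread)


@dataclass
class StainIndexResult:
    """Stain Index per dilution for one chosen positive/negative pair."""

    positive: str
    negative: str
    dilutions: tuple[float, ...]
    si: tuple[float, ...]
    robust: bool = True

    def argmax(self) -> int:
        vals = np.asarray(self.si, dtype=float)
        if np.all(np.isnan(vals)):
            raise ValueError("Stain Index undefined at every dilution")
        return int(np.nanargmax(vals))


def stain_index_series(
    series: list[EventTable],
    scheme: BarcodeScheme,
    dilutions: tuple[float, ...],
    positive: str,
    negative: str,
    robust: bool = True,
    split_blood: dict[str, tuple[float, float]] | None = None,
) -> StainIndexResult:
    """Stain Index at each dilution for one positive/negative cell-type pair."""
    if len(series) != len(dilutions):
        raise ValueError(f"{len(series)} tubes for {len(dilutions)} dilutions")
    out = []
    for tube in series:
        labels = demultiplex(tube, scheme, split_blood=split_blood)
        pe = tube.column("PE-A")
        out.append(stain_index(pe[labels == positive], pe[labels == negative], robust))
    return StainIndexResult(positive, negative, tuple(dilutions), tuple(out), robust)


class TiterSelectionError(ValueError):
    """No tested dilution satisfies the selection policy."""


@dataclass
class TiterRecommendation:
    dilution: float
    policy: str
    flags: list[str] = field(default_factory=list)

    @property
    def rationale(self) -> str:
        return "; ".join(self.flags) if self.flags else "criteria met"


def select_titer(
    curve: TitrationCurve,
    positive: str,
    negative: str | None = None,
    si: StainIndexResult | None = None,
    policy: str = "saturation",
    saturation_fraction: float = 0.90,
    background_multiple: float = 2.0,
) -> TiterRecommendation:
    """Recommend the optimal titer from a titration curve.

    ``saturation`` (default): the most dilute step whose positive median is
    still >= ``saturation_fraction`` of the maximal positive median; if the
    negative cell type's median there exceeds ``background_multiple`` times
    the FMO level, step one dilution lower (flagged).  ``max-SI`` picks the
    Stain-Index maximum; ``max-SI-minus-one`` one step more dilute than it.
    Dilutions are ordered from most to least concentrated; at least 3 are
    required.
    """
    dil = list(curve.dilutions)
    if len(dil) < 3:
        raise TiterSelectionError("need at least 3 tested dilutions")
    flags: list[str] = []

    if policy in ("max-SI", "max-SI-minus-one"):
        if si is None:
            raise ValueError(f"policy {policy!r} requires a StainIndexResult")
        idx = si.argmax()
        if policy == "max-SI-minus-one":
            if idx + 1 < len(dil):
                idx += 1
            else:
                flags.append("SI maximum at the most dilute step; cannot step lower")
        return TiterRecommendation(dil[idx], policy, flags)

    if policy != "saturation":
        raise ValueError(f"unknown titer policy {policy!r}")

    medians = curve.series(positive).to_numpy(dtype=float)
    if np.all(np.isnan(medians)):
        raise TiterSelectionError(f"no data for positive cell type {positive!r}")
    peak = np.nanmax(medians)
    satisfying = np.flatnonzero(medians >= saturation_fraction * peak)
    if satisfying.size == 0:
        raise TiterSelectionError(
            "no dilution reaches the saturation criterion — retest at higher concentration")
    idx = int(satisfying.max())  # most dilute still near-saturating
    if idx == len(dil) - 1:
        flags.append("plateau extends to the most dilute step tested")
    else:
        flags.append("plateau reached")

    if negative is not None and curve.fmo_level is not None and curve.fmo_level > 0:
        neg_median = curve.series(negative).to_numpy(dtype=float)
        if not np.isnan(neg_median[idx]) and \
                neg_median[idx] > background_multiple * curve.fmo_level:
            flags.append("background exceeded at saturation pick; stepped one dilution lower")
            if idx + 1 < len(dil):
                idx += 1
    return TiterRecommendation(dil[idx], "saturation", flags)


@dataclass
class BenchmarkReport:
    """Cross-clone comparison of ABC on shared subsets."""

    table: pd.DataFrame  # subset, clone, median_abc, ratio_to_clone_median, flagged
    pairwise: pd.DataFrame  # subset, clone_a, clone_b, ratio
    flag_threshold: float

    @property
    def flagged_clones(self) -> dict[str, list[str]]:
        f = self.table[self.table["flagged"]]
        return {c: sorted(g["subset"]) for c, g in f.groupby("clone")}


def benchmark_clones(
    clone_stats: dict[str, list[SubsetStats]],
    flag_threshold: float = 1.5,
) -> BenchmarkReport:
    """Benchmark >=1 clones of the same target on shared gated subsets.

    For every subset present in all clones' statistics, reports median ABC
    by clone, all pairwise ratios, and flags clones whose ABC deviates more
    than ``flag_threshold``-fold (either direction) from the across-clone
    median — the pattern of an epitope differentially accessible to one
    clone.  Raises ``ValueError`` when clones share no subsets.
    """
    per_clone = {c: {s.code: s.median_abc for s in stats}
                 for c, stats in clone_stats.items()}
    shared = set.intersection(*[set(v) for v in per_clone.values()]) if per_clone else set()
    if not shared:
        raise ValueError("clones share no gated subsets")
    clones = sorted(per_clone)
    rows, pairs = [], []
    for subset in sorted(shared):
        values = {c: per_clone[c][subset] for c in clones}
        center = float(np.median(list(values.values())))
        for c in clones:
            ratio = values[c] / center if center > 0 else np.nan
            flagged = len(clones) > 1 and (
                ratio > flag_threshold or ratio < 1.0 / flag_threshold)
            rows.append({"subset": subset, "clone": c, "median_abc": values[c],
                         "ratio_to_clone_median": ratio, "flagged": bool(flagged)})
        for i, a in enumerate(clones):
            for b in clones[i + 1:]:
                pairs.append({"subset": subset, "clone_a": a, "clone_b": b,
                              "ratio": values[a] / values[b] if values[b] else np.nan})
    return BenchmarkReport(
        pd.DataFrame(rows, columns=["subset", "clone", "median_abc",
                                    "ratio_to_clone_median", "flagged"]),
        pd.DataFrame(pairs, columns=["subset", "clone_a", "clone_b", "ratio"]),
        flag_threshold,
    )
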