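"""Cross-donor / cross-laboratory reproducibility summaries.

Aggregates per-subset median-ABC records over donors and laboratories into
coefficients of variation (CV = 100 x sample SD / mean) and fold-change
tables.  Intra-lab CV is computed across donors within each lab and then
averaged over labs; inter-lab CV pools all donor-lab medians of a marker x
subset cell.  Groups with fewer than two values have an undefined CV and
are flagged rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CrossSiteRecord", "CVSummary", "cv_summary", "fold_change"]

RECORD_COLUMNS = ["marker", "population", "donor", "lab", "median_abc"]


@dataclass(frozen=True)
class CrossSiteRecord:
    """One donor x lab measurement of one marker on one subset."""

    marker: str
    population: str
    donor: str
    lab: str
    median_abc: float


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records[RECORD_COLUMNS].copy()
    else:
        df = pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)
    if df.duplicated(["marker", "population", "donor", "lab"]).any():
        dup = df[df.duplicated(["marker", "population", "donor", "lab"])]
        raise ValueError(f"duplicate (marker, population, donor, lab) records:\n{dup}")
    return df


def _cv(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(100.0 * values.std(ddof=1) / mean)


@dataclass
class CVSummary:
    """Per marker x population: intra- and inter-lab CV (percent)."""

    table: pd.DataFrame  # marker, population, intra_lab_cv, inter_lab_cv, n_values, defined

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def mean_intra_lab_cv(self) -> float:
        return float(self.table["intra_lab_cv"].mean())

    @property
    def mean_inter_lab_cv(self) -> float:
        return float(self.table["inter_lab_cv"].mean())


def cv_summary(records) -> CVSummary:
    """CV per marker x population across donors and laboratories.

    ``records`` is an iterable of :class:`CrossSiteRecord` or an equivalent
    tidy DataFrame.  Empty input gives an empty summary; groups with a
    single value are reported with NaN CV and ``defined=False``.
    """
    df = _records_frame(records)
    rows = []
    for (marker, population), grp in df.groupby(["marker", "population"], sort=True):
        lab_cvs = [_cv(lab_grp["median_abc"].to_numpy())
                   for _, lab_grp in grp.groupby("lab")]
        lab_cvs = [c for c in lab_cvs if not np.isnan(c)]
        intra = float(np.mean(lab_cvs)) if lab_cvs else float("nan")
        inter = _cv(grp["median_abc"].to_numpy())
        rows.append({"marker": marker, "population": population,
                     "intra_lab_cv": intra, "inter_lab_cv": inter,
                     "n_values": int(len(grp)),
                     "defined": not (np.isnan(intra) or np.isnan(inter))})
    return CVSummary(pd.DataFrame(
        rows, columns=["marker", "population", "intra_lab_cv", "inter_lab_cv",
                       "n_values", "defined"]))


def fold_change(a, b, label_a: str = "a", label_b: str = "b") -> pd.DataFrame:
    """Ratio of median ABC (a/b) per subset shared by two stat sets.

    ``a``/``b`` are lists of :class:`~cytoquant.quant.SubsetStats` or
    mappings ``code -> median ABC``.  A zero denominator gives NaN and a
    flag.  Raises ``ValueError`` when no subsets overlap.
    """
    def as_map(x) -> dict[str, float]:
        if isinstance(x, dict):
            return {str(k): float(v) for k, v in x.items()}
        return {s.code: float(s.median_abc) for s in x}

    ma, mb = as_map(a), as_map(b)
    shared = sorted(set(ma) & set(mb))
    if not shared:
        raise ValueError("no overlapping subsets between the two stat sets")
    rows = []
    for code in shared:
        num, den = ma[code], mb[code]
        ratio = num / den if den != 0 else float("nan")
        if den == 0:
            direction = "undefined"
        elif ratio > 1:
            direction = f"{label_a}>{label_b}"
        elif ratio < 1:
            direction = f"{label_a}<{label_b}"
        else:
            direction = "equal"
        rows.append({"subset": code, f"median_abc_{label_a}": num,
                     f"median_abc_{label_b}": den, "ratio": ratio,
                     "direction": direction, "undefined": den == 0})
    return pd.DataFrame(rows)
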