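"""Experiment master table (EMT) parsing/validation and protocol generation.

The EMT is the plate-layout table mapping each well to one PE-conjugated
reagent (CD name, clone, gene, vendor, titer volume) plus experiment
metadata.  It drives both the printable staining protocol (master-mix and
pipetting volumes) and the FCS annotation step.

Per-well staining arithmetic: the PE reagent is made up to 10 µl with
diluent, 40 µl of cell suspension (2x10^6 cells) brings the well to 50 µl,
and 25 µl of backbone antibody mix brings it to 75 µl.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

__all__ = [
    "AnnotationRecord",
    "ExperimentMasterTable",
    "ProtocolDocument",
    "EmtValidationError",
    "load_and_validate_emt",
    "generate_protocol",
    "PE_WELL_VOLUME_UL",
    "CELLS_VOLUME_UL",
    "BACKBONE_MIX_VOLUME_UL",
    "CELLS_PER_WELL",
]

WELL_RE = re.compile(r"^[A-H](1[0-2]|[1-9])$")

PE_WELL_VOLUME_UL = 10.0  # PE reagent + diluent per well
CELLS_VOLUME_UL = 40.0  # cell suspension added per well
BACKBONE_MIX_VOLUME_UL = 25.0  # backbone antibody mix per well
CELLS_PER_WELL = 2_000_000

REQUIRED_COLUMNS = ["well", "cd", "clone", "gene", "vendor", "titer", "volume_ul"]
#: reagent label marking the fluorescence-minus-one control well (no PE mAb)
FMO_LABEL = "FMO"


class EmtValidationError(ValueError):
    """EMT failed validation; ``violations`` lists the row-level problems."""

    def __init__(self, violations: list[str]):
        super().__init__("EMT validation failed:\n  " + "\n  ".join(violations))
        self.violations = violations


@dataclass(frozen=True)
class AnnotationRecord:
    """One well's reagent identity and plate position."""

    well: str
    cd: str
    clone: str
    gene: str
    vendor: str
    titer: str
    volume_ul: float
    plate: str = "P1"

    @property
    def is_fmo(self) -> bool:
        return self.cd.strip().upper() == FMO_LABEL


@dataclass
class ExperimentMasterTable:
    """Validated plate layout plus experiment metadata."""

    records: list[AnnotationRecord]
    experiment: str = "EXP"
    operator: str = "operator"
    lab: str = "lab"
    date: str = ""
    backbone_panel: str = "innate"

    def __post_init__(self) -> None:
        violations = validate_records(self.records)
        if violations:
            raise EmtValidationError(violations)

    @property
    def n_wells(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def validate_records(records: list[AnnotationRecord]) -> list[str]:
    """Row-level violations: bad/duplicate wells, missing ids, bad volumes."""
    violations = []
    seen: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(records):
        if not WELL_RE.match(rec.well):
            violations.append(f"row {i}: invalid well {rec.well!r}")
        key = (rec.plate, rec.well)
        if key in seen:
            violations.append(f"row {i}: duplicate well {rec.well} on plate {rec.plate}")
        seen[key] = i
        if not rec.is_fmo:
            for ident in ("cd", "clone"):
                if not str(getattr(rec, ident)).strip():
                    violations.append(f"row {i} (well {rec.well}): missing {ident}")
        if not rec.volume_ul > 0:
            violations.append(
                f"row {i} (well {rec.well}): nonpositive volume {rec.volume_ul} µl"
            )
        elif rec.volume_ul > PE_WELL_VOLUME_UL and not rec.is_fmo:
            violations.append(
                f"row {i} (well {rec.well}): PE volume {rec.volume_ul} µl exceeds "
                f"the {PE_WELL_VOLUME_UL} µl PE+diluent budget"
            )
    if records and not any(r.is_fmo for r in records):
        violations.append(f"no FMO control well (cd == {FMO_LABEL!r}) on the plate")
    return violations


def _read_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def load_and_validate_emt(path: str | Path, **metadata: str) -> ExperimentMasterTable:
    """Load an EMT from CSV/TSV/XLSX and validate it.

    Column names are matched case-insensitively; ``metadata`` overrides the
    experiment/operator/lab/date fields (otherwise taken from like-named
    columns when present).  Raises :class:`EmtValidationError` listing every
    violation, or ``ValueError`` for missing mandatory columns.
    """
    path = Path(path)
    df = _read_table(path)
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"EMT {path} lacks mandatory columns: {missing}")

    records = []
    for _, row in df.iterrows():
        records.append(
            AnnotationRecord(
                well=str(row["well"]).strip(),
                cd=str(row["cd"]).strip(),
                clone=str(row.get("clone", "") or ""),
                gene=str(row.get("gene", "") or ""),
                vendor=str(row.get("vendor", "") or ""),
                titer=str(row.get("titer", "") or ""),
                volume_ul=float(row["volume_ul"]),
                plate=str(row.get("plate", "P1") or "P1"),
            )
        )
    fields = {}
    for name in ("experiment", "operator", "lab", "date", "backbone_panel"):
        if name in metadata:
            fields[name] = metadata[name]
        elif name in df.columns and df[name].notna().any():
            fields[name] = str(df[name].dropna().iloc[0])
    return ExperimentMasterTable(records, **fields)


@dataclass
class ProtocolDocument:
    """Printable staining protocol: per-well pipetting table and mix totals."""

    emt: ExperimentMasterTable
    overage_fraction: float
    timestamp: str
    wells: pd.DataFrame  # well, reagent, PE µl, diluent µl, totals
    backbone_mix_total_ul: float
    diluent_total_ul: float
    cells_needed: float
    cell_suspension_ul: float = field(init=False)

    def __post_init__(self) -> None:
        self.cell_suspension_ul = CELLS_VOLUME_UL * self.emt.n_wells * (1 + self.overage_fraction)

    def to_text(self) -> str:
        lines = [
            f"Staining protocol — experiment {self.emt.experiment}",
            f"generated {self.timestamp} by {self.emt.operator} ({self.emt.lab})",
            f"panel: {self.emt.backbone_panel}; wells: {self.emt.n_wells}; "
            f"overage: {self.overage_fraction:.0%}",
            "",
            f"Backbone mix to prepare: {self.backbone_mix_total_ul:.1f} µl "
            f"({BACKBONE_MIX_VOLUME_UL:.0f} µl/well)",
            f"Diluent to prepare:      {self.diluent_total_ul:.1f} µl",
            f"Cells required:          {self.cells_needed:.3g} "
            f"({CELLS_PER_WELL:.0g}/well in {CELLS_VOLUME_UL:.0f} µl)",
            "",
            self.wells.to_string(index=False),
        ]
        return "\n".join(lines) + "\n"


def generate_protocol(
    emt: ExperimentMasterTable,
    overage_fraction: float = 0.10,
    timestamp: str | None = None,
) -> ProtocolDocument:
    """Compute per-well pipetting volumes and master-mix totals.

    Per well: diluent = 10 µl − PE volume; +40 µl cells (2x10^6) = 50 µl;
    +25 µl backbone mix = 75 µl.  Totals scale linearly with well count and
    carry the overage fraction.  ``timestamp`` may be injected for
    reproducible output; defaults to current UTC time.
    """
    if not 0 <= overage_fraction < 1:
        raise ValueError(f"overage fraction {overage_fraction} outside [0, 1)")
    rows = []
    for rec in emt.records:
        pe = 0.0 if rec.is_fmo else rec.volume_ul
        if pe > PE_WELL_VOLUME_UL:
            raise ValueError(f"well {rec.well}: PE volume {pe} µl exceeds {PE_WELL_VOLUME_UL} µl")
        rows.append(
            {
                "well": rec.well,
                "reagent": rec.cd if not rec.is_fmo else FMO_LABEL,
                "clone": rec.clone,
                "pe_ul": pe,
                "diluent_ul": PE_WELL_VOLUME_UL - pe,
                "cells_ul": CELLS_VOLUME_UL,
                "backbone_ul": BACKBONE_MIX_VOLUME_UL,
                "total_ul": PE_WELL_VOLUME_UL + CELLS_VOLUME_UL + BACKBONE_MIX_VOLUME_UL,
            }
        )
    wells = pd.DataFrame(rows)
    scale = emt.n_wells * (1 + overage_fraction)
    return ProtocolDocument(
        emt=emt,
        overage_fraction=overage_fraction,
        timestamp=timestamp or datetime.now(timezone.utc).isoformat(timespec="seconds"),
        wells=wells,
        backbone_mix_total_ul=BACKBONE_MIX_VOLUME_UL * scale,
        diluent_total_ul=float(wells["diluent_ul"].sum()) * (1 + overage_fraction),
        cells_needed=CELLS_PER_WELL * scale,
    )
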