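"""FCS list-mode file reading/writing and batch annotation.

Writes FCS 3.0 (``$DATATYPE`` F, little-endian, ``/`` delimiter) and reads
FCS 2.0/3.0/3.1 with float, double or integer data.  Also implements the
plate-workflow plumbing: parsing the cytometer's default export filenames
(``Specimen_001_A1_A01_001.fcs``) and batch renaming/annotation of acquired
files with reagent identifiers from the experiment master table, injected as
namespaced keywords (``CYTOQ_*``) so vendor keywords are never clobbered.
"""

from __future__ import annotations

import logging
import re
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .events import EventTable

if TYPE_CHECKING:  # pragma: no cover
    from .emt import ExperimentMasterTable

__all__ = [
    "read_fcs",
    "write_fcs",
    "parse_default_filename",
    "annotate_batch",
    "AnnotationReport",
    "FcsFormatError",
    "KEYWORD_PREFIX",
]

logger = logging.getLogger(__name__)

DELIM = "/"
KEYWORD_PREFIX = "CYTOQ_"

#: EMT column -> injected FCS keyword
ANNOTATION_KEYWORDS = {
    "cd": KEYWORD_PREFIX + "CD",
    "clone": KEYWORD_PREFIX + "CLONE",
    "gene": KEYWORD_PREFIX + "GENE",
    "vendor": KEYWORD_PREFIX + "VENDOR",
    "titer": KEYWORD_PREFIX + "TITER",
    "experiment": KEYWORD_PREFIX + "EXPERIMENT",
    "operator": KEYWORD_PREFIX + "OPERATOR",
    "lab": KEYWORD_PREFIX + "LAB",
    "well": KEYWORD_PREFIX + "WELL",
    "plate": KEYWORD_PREFIX + "PLATE",
}

# Default export name used by the acquisition software, e.g.
# Specimen_001_A1_A01_001.fcs -> well token "A1".
_DEFAULT_NAME_RE = re.compile(
    r"^(?P<specimen>.+)_(?P<num>\d+)_(?P<well>[A-H](?:1[0-2]|[1-9]))_"
    r"[A-H](?:0[1-9]|1[0-2])_(?P<seq>\d+)\.fcs$"
)


class FcsFormatError(ValueError):
    """Raised for malformed FCS files or unwritable tables."""


# ---------------------------------------------------------------------------
# TEXT segment encoding/decoding


def _encode_text(keywords: dict[str, str], delim: str = DELIM) -> bytes:
    parts = [delim]
    for key, value in keywords.items():
        if delim in key:
            raise FcsFormatError(f"keyword name {key!r} contains the delimiter {delim!r}")
        value = str(value)
        if value == "":
            value = " "  # empty values are not representable in FCS TEXT
        parts.append(key + delim + value.replace(delim, delim * 2) + delim)
    return "".join(parts).encode("utf-8")


def _decode_text(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[:1].decode("latin-1")
    body = raw[1:].decode("utf-8", errors="replace")
    if body.endswith(delim):
        body = body[:-1]
    # split on single delimiters; doubled delimiters produce empty tokens that
    # stand for one escaped delimiter joining their neighbours
    tokens = body.split(delim)
    fields: list[str] = []
    current = tokens[0]
    i = 1
    while i < len(tokens):
        if tokens[i] == "" and i + 1 < len(tokens):
            current += delim + tokens[i + 1]
            i += 2
        else:
            fields.append(current)
            current = tokens[i]
            i += 1
    fields.append(current)
    if len(fields) % 2:
        fields = fields[:-1]
    return {fields[j]: fields[j + 1] for j in range(0, len(fields), 2)}


# ---------------------------------------------------------------------------
# reading


def _header_offsets(header: bytes) -> tuple[str, list[int]]:
    version = header[:6].decode("ascii", errors="replace").strip()
    offsets = []
    for i in range(6):
        tok = header[10 + 8 * i : 18 + 8 * i].decode("ascii", errors="replace").strip()
        offsets.append(int(tok) if tok else 0)
    return version, offsets


def read_fcs(path: str | Path) -> EventTable:
    """Read an FCS 2.0/3.0/3.1 file into an :class:`EventTable`.

    Channel names come from ``$PnN``; all TEXT keywords are preserved
    (including ``$PnS`` display aliases).  Supports ``$DATATYPE`` F/D/I in
    list mode.
    """
    data = Path(path).read_bytes()
    if len(data) < 58:
        raise FcsFormatError(f"{path}: file shorter than an FCS header")
    version, off = _header_offsets(data[:58])
    if not version.startswith("FCS"):
        raise FcsFormatError(f"{path}: not an FCS file (header {version!r})")
    if version not in ("FCS2.0", "FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r}")
    text_begin, text_end = off[0], off[1]
    if not (0 < text_begin < text_end < len(data)):
        raise FcsFormatError(f"{path}: malformed TEXT offsets {text_begin}..{text_end}")
    keywords = _decode_text(data[text_begin : text_end + 1])

    data_begin = int(keywords.get("$BEGINDATA", "0") or 0) or off[2]
    data_end = int(keywords.get("$ENDDATA", "0") or 0) or off[3]
    if data_end and not (0 < data_begin <= data_end + 1 <= len(data) + 1):
        raise FcsFormatError(f"{path}: malformed DATA offsets {data_begin}..{data_end}")

    n_par = int(keywords["$PAR"])
    n_tot = int(keywords["$TOT"])
    channels = [keywords.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]

    datatype = keywords.get("$DATATYPE", "F").upper()
    byteord = keywords.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    if keywords.get("$MODE", "L").upper() != "L":
        raise FcsFormatError(f"{path}: only list mode ($MODE L) is supported")

    if n_tot == 0:
        events = np.empty((0, n_par), dtype=np.float64)
        return EventTable(channels, events, keywords)

    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {int(keywords.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in (16, 32):
            raise FcsFormatError(f"{path}: unsupported integer layout $PnB={bits}")
        width = int(keywords["$P1B"]) // 8
        dtype = np.dtype(f"{endian}u{width}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    nbytes = n_tot * n_par * dtype.itemsize
    raw = data[data_begin : data_begin + nbytes]
    if len(raw) < nbytes:
        raise FcsFormatError(f"{path}: DATA segment truncated ({len(raw)} < {nbytes} bytes)")
    events = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)
    return EventTable(channels, events, keywords)


# ---------------------------------------------------------------------------
# writing


def _data_bytes(table: EventTable) -> bytes:
    return np.ascontiguousarray(table.events, dtype="<f4").tobytes()


def write_fcs(table: EventTable, path: str | Path) -> Path:
    """Write an :class:`EventTable` as FCS 3.0, float32 little-endian.

    User keywords are embedded verbatim (values containing the ``/``
    delimiter are escaped); structural keywords are recomputed.  Channel
    names containing the delimiter are rejected.
    """
    path = Path(path)
    n_tot, n_par = table.events.shape
    for name in table.channels:
        if DELIM in name:
            raise FcsFormatError(f"channel name {name!r} contains the TEXT delimiter {DELIM!r}")

    structural = {"$BEGINANALYSIS": "0", "$ENDANALYSIS": "0", "$BEGINSTEXT": "0",
                  "$ENDSTEXT": "0", "$NEXTDATA": "0", "$MODE": "L", "$DATATYPE": "F",
                  "$BYTEORD": "1,2,3,4", "$PAR": str(n_par), "$TOT": str(n_tot)}
    skip = set(structural) | {"$BEGINDATA", "$ENDDATA"}
    skip.update(k for k in table.keywords
                if re.fullmatch(r"\$P\d+[NBER]", k))

    keywords = dict(structural)
    for i, name in enumerate(table.channels, start=1):
        keywords[f"$P{i}N"] = name
        keywords[f"$P{i}B"] = "32"
        keywords[f"$P{i}E"] = "0,0"
        keywords[f"$P{i}R"] = "262144"
        alias = table.keywords.get(f"$P{i}S")
        if alias:
            keywords[f"$P{i}S"] = alias
    for key, value in table.keywords.items():
        if key not in skip and not key.startswith("__"):
            keywords[key] = str(value)

    payload = _data_bytes(table)
    # fixed-width offset fields so TEXT length does not depend on their value
    keywords["$BEGINDATA"] = "0" * 10
    keywords["$ENDDATA"] = "0" * 10
    text = _encode_text(keywords)
    header_len = 58
    data_begin = header_len + len(text)
    data_end = data_begin + len(payload) - 1 if payload else data_begin
    keywords["$BEGINDATA"] = str(data_begin).zfill(10)
    keywords["$ENDDATA"] = str(data_end).zfill(10)
    text = _encode_text(keywords)
    assert header_len + len(text) == data_begin

    def fmt(n: int) -> bytes:
        return str(n if n <= 99_999_999 else 0).rjust(8).encode("ascii")

    header = b"FCS3.0    " + fmt(header_len) + fmt(header_len + len(text) - 1)
    header += fmt(data_begin) + fmt(data_end) + fmt(0) + fmt(0)
    assert len(header) == 58
    path.write_bytes(header + text + payload)
    return path


# ---------------------------------------------------------------------------
# filename parsing and batch annotation


def parse_default_filename(name: str) -> str:
    """Extract the well token from a default cytometer export filename.

    >>> parse_default_filename("Specimen_001_A1_A01_001.fcs")
    'A1'
    """
    m = _DEFAULT_NAME_RE.match(Path(name).name)
    if m is None:
        raise ValueError(f"filename {name!r} does not match the default export pattern")
    return m.group("well")


@dataclass
class AnnotationReport:
    """Outcome of an annotation batch: per-file status plus unmatched rows."""

    annotated: list[tuple[Path, Path, str]] = field(default_factory=list)  # (src, dst, well)
    skipped_files: list[tuple[Path, str]] = field(default_factory=list)  # (src, reason)
    unmatched_wells: list[str] = field(default_factory=list)  # EMT wells with no file

    @property
    def ok(self) -> bool:
        return not self.skipped_files and not self.unmatched_wells

    def to_frame(self) -> pd.DataFrame:
        rows = [{"file": str(s), "output": str(d), "well": w, "status": "annotated"}
                for s, d, w in self.annotated]
        rows += [{"file": str(s), "output": "", "well": "", "status": f"skipped: {r}"}
                 for s, r in self.skipped_files]
        rows += [{"file": "", "output": "", "well": w, "status": "no file for EMT well"}
                 for w in self.unmatched_wells]
        return pd.DataFrame(rows, columns=["file", "output", "well", "status"])


def _safe_token(value: str) -> str:
    return re.sub(r"[^A-Za-z0-9.+-]+", "-", str(value)).strip("-") or "NA"


def annotate_batch(
    files: Iterable[str | Path],
    emt: "ExperimentMasterTable",
    out_dir: str | Path,
) -> AnnotationReport:
    """Annotate and rename a batch of acquired FCS files from the EMT.

    Each file's well is parsed from its name (default export pattern, or a
    previously annotated name carrying a ``CYTOQ_WELL`` keyword), matched to
    the EMT row for that well, re-written with the reagent/experiment
    keywords, and renamed ``<experiment>_<plate>_<well>_<CD>_<clone>.fcs``
    under ``out_dir``.  Originals are untouched.  Nonconforming filenames and
    wells absent from the EMT are reported, not fatal; annotation is
    idempotent (keywords are overwritten, event data unchanged).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = AnnotationReport()
    by_well = {rec.well: rec for rec in emt.records}
    seen_wells: set[str] = set()

    for f in files:
        f = Path(f)
        well = None
        try:
            well = parse_default_filename(f.name)
        except ValueError:
            try:  # already-annotated file: well recorded in its keywords
                well = read_fcs(f).keywords.get(KEYWORD_PREFIX + "WELL") or None
            except (FcsFormatError, OSError, KeyError):
                well = None
        if well is None:
            logger.warning("skipping %s: cannot determine well", f)
            report.skipped_files.append((f, "unparseable filename"))
            continue
        rec = by_well.get(well)
        if rec is None:
            logger.warning("skipping %s: well %s not in EMT", f, well)
            report.skipped_files.append((f, f"well {well} not in EMT"))
            continue
        seen_wells.add(well)
        table = read_fcs(f)
        meta = {"cd": rec.cd, "clone": rec.clone, "gene": rec.gene, "vendor": rec.vendor,
                "titer": rec.titer, "experiment": emt.experiment, "operator": emt.operator,
                "lab": emt.lab, "well": rec.well, "plate": rec.plate}
        for col, kw in ANNOTATION_KEYWORDS.items():
            table.keywords[kw] = str(meta[col])
        dst = out_dir / "_".join(
            _safe_token(t) for t in (emt.experiment, rec.plate, rec.well, rec.cd, rec.clone)
        )
        dst = dst.with_suffix(".fcs")
        write_fcs(table, dst)
        logger.info("annotated %s -> %s (well %s)", f, dst, well)
        report.annotated.append((f, dst, well))

    report.unmatched_wells = sorted(set(by_well) - seen_wells)
    return report
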