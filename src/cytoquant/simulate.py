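"""Synthetic list-mode data with the statistical structure the pipeline assumes.

Generates multi-subset leukocyte tubes, fluorescence-minus-one (FMO)
controls, four-peak PE calibration-bead tubes and barcoded six-cell-type
titration series, so the whole analysis chain is testable without acquired
data.

Model: fluorescence marginals are log-normal in linear units with the
location parameter equal to the population median (``sigma**2 =
log(1+CV**2)``); scatter channels are normal, truncated at zero; FSC-H is
tied to FSC-A through a near-unity ratio so singlet gating works.  Antibody
binding over a dilution series follows a saturation (Langmuir) law with a
linear nonspecific term, ``bound(c) = bmax*c/(kd+c) + ns_slope*c``.  Every
generated event carries a hidden ground-truth population label (kept in
memory, never written to FCS).  All randomness flows from one explicit seed
per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .events import EventTable
from .panels import AUTOFLUORESCENCE, BRIGHT_LEVEL, POSITIVE_LEVEL, TITRATION_CHANNELS
from .preprocess import SCATTER_CHANNELS, SpilloverMatrix

__all__ = [
    "PopulationSpec",
    "BeadLotSpec",
    "BindingModel",
    "BarcodeScheme",
    "generate_tube",
    "generate_bead_tube",
    "generate_titration_series",
    "pe_signal_for_abc",
    "innate_populations",
    "adaptive_populations",
    "titration_cell_types",
    "DEFAULT_BARCODES",
    "DEFAULT_DILUTIONS",
    "DEFAULT_ABC_PROFILE",
    "TRACKER_LEVELS",
]

FLUOR_CV = 0.5  # default CV of fluorescence markers (linear scale)
SCATTER_CV = 0.08  # default CV of scatter channels
FSC_DEFAULT = 100_000.0
SSC_DEFAULT = 20_000.0
FSC_H_RATIO_SD = 0.03  # spread of the FSC-A/FSC-H singlet ratio
DOUBLET_LABEL = "doublet"
DEBRIS_LABEL = "debris"


@dataclass
class PopulationSpec:
    """One population of a tube: mixing fraction and per-channel marginals.

    ``channel_locations`` gives the linear-scale median per channel; unlisted
    fluorescence channels sit at autofluorescence, unlisted scatter channels
    at generic leukocyte values.  ``true_abc`` is the known bound-antibody
    count on the PE channel, used by the generator (via a stated calibration
    truth) and by test oracles.
    """

    name: str
    fraction: float
    channel_locations: dict[str, float] = field(default_factory=dict)
    channel_cvs: dict[str, float] = field(default_factory=dict)
    true_abc: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError(f"{self.name}: fraction {self.fraction} outside [0, 1]")
        for ch, cv in self.channel_cvs.items():
            if not cv > 0:
                raise ValueError(f"{self.name}: CV for {ch} must be > 0")
        if self.true_abc is not None and self.true_abc < 0:
            raise ValueError(f"{self.name}: true_abc must be >= 0")

    def location(self, channel: str) -> float:
        if channel in self.channel_locations:
            return self.channel_locations[channel]
        if channel == "FSC-A":
            return FSC_DEFAULT
        if channel == "SSC-A":
            return SSC_DEFAULT
        return AUTOFLUORESCENCE

    def cv(self, channel: str) -> float:
        if channel in self.channel_cvs:
            return self.channel_cvs[channel]
        return SCATTER_CV if channel in SCATTER_CHANNELS else FLUOR_CV


@dataclass
class BeadLotSpec:
    """Calibration bead lot: exactly 4 known PE-molecules-per-bead levels."""

    levels: tuple[float, float, float, float] = (500.0, 5_000.0, 50_000.0, 500_000.0)
    peak_cv: float = 0.10

    def __post_init__(self) -> None:
        if len(self.levels) != 4:
            raise ValueError("a bead lot has exactly 4 PE levels")
        lv = np.asarray(self.levels, dtype=float)
        if not (np.all(lv > 0) and np.all(np.diff(lv) > 0)):
            raise ValueError("bead levels must be positive and strictly increasing")
        if not self.peak_cv > 0:
            raise ValueError("peak_cv must be > 0")


@dataclass
class BindingModel:
    """Saturation-binding law for one antibody on one cell type (ABC units).

    ``bound(c) = bmax*c/(kd+c) + ns_slope*c`` at stock-fraction
    concentration ``c``; ``kd`` is the half-saturation concentration and
    ``ns_slope`` the linear nonspecific coefficient.
    """

    bmax: float
    kd: float
    ns_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.bmax < 0 or self.ns_slope < 0:
            raise ValueError("bmax and ns_slope must be >= 0")
        if not self.kd > 0:
            raise ValueError("kd must be > 0")

    def bound(self, concentration: float) -> float:
        c = float(concentration)
        return self.bmax * c / (self.kd + c) + self.ns_slope * c


#: linear-scale tracker medians for the three barcode levels; adjacent
#: levels are separated 20-30x so demultiplexing is near-perfect
TRACKER_LEVELS = {"negative": 100.0, "low": 3_000.0, "high": 60_000.0}

#: cell type -> (CellTracker Blue level, CellTracker Deep Red level).
#: Mouse 300.19 and U266 carry high/low Blue; THP-1 and Jurkat high/low
#: Deep Red; blood leukocytes both dyes; Raji is left unstained.
DEFAULT_BARCODES = {
    "300.19": ("high", "negative"),
    "U266": ("low", "negative"),
    "THP-1": ("negative", "high"),
    "Jurkat": ("negative", "low"),
    "blood": ("high", "high"),
    "Raji": ("negative", "negative"),
}


@dataclass
class BarcodeScheme:
    """Two-dye, three-level barcode assignment of the titration cell types."""

    codes: dict[str, tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_BARCODES))
    levels: dict[str, float] = field(default_factory=lambda: dict(TRACKER_LEVELS))
    blue_channel: str = "Tracker-Blue"
    red_channel: str = "Tracker-DeepRed"

    def __post_init__(self) -> None:
        for name, (b, r) in self.codes.items():
            if b not in self.levels or r not in self.levels:
                raise ValueError(f"{name}: unknown tracker level ({b}, {r})")
        if len(set(self.codes.values())) != len(self.codes):
            raise ValueError("barcode positions must be distinct per cell type")

    def tracker_locations(self, cell_type: str) -> tuple[float, float]:
        if cell_type not in self.codes:
            raise KeyError(f"no barcode defined for cell type {cell_type!r}")
        b, r = self.codes[cell_type]
        return self.levels[b], self.levels[r]


# ---------------------------------------------------------------------------
# core generator


def _lognormal(rng: np.random.Generator, median: float, cv: float, n: int) -> np.ndarray:
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(np.log(max(median, 1e-12)), sigma, size=n))


def _truncnormal(rng: np.random.Generator, loc: float, cv: float, n: int) -> np.ndarray:
    return np.clip(rng.normal(loc, cv * loc if loc > 0 else 1.0, size=n), 0.0, None)


def generate_tube(
    populations: list[PopulationSpec],
    channels: list[str],
    n_events: int,
    seed: int,
    spillover: SpilloverMatrix | None = None,
    doublet_fraction: float = 0.0,
    keywords: dict[str, str] | None = None,
) -> EventTable:
    """Draw one tube: multinomial population counts, per-channel marginals.

    Population fractions must sum to 1 (±1e-9).  The returned table carries
    a hidden ground-truth ``labels`` array; doublets (if requested) have
    summed FSC-A, shared FSC-H and the label ``doublet``.  When a spillover
    matrix is given, true fluorescence signals are right-multiplied by it so
    compensation can exactly invert the mixing.  Deterministic given seed.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    total = sum(p.fraction for p in populations)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"population fractions sum to {total!r}, expected 1")
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate population names in {names}")
    for p in populations:
        for ch in p.channel_locations:
            if ch not in channels:
                raise KeyError(f"{p.name}: unknown channel {ch!r}")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_events, [p.fraction for p in populations])
    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    fsc_a_idx = channels.index("FSC-A") if "FSC-A" in channels else None
    fsc_h_idx = channels.index("FSC-H") if "FSC-H" in channels else None

    for pop, n in zip(populations, counts):
        block = np.empty((n, len(channels)))
        for j, ch in enumerate(channels):
            if ch == "FSC-H" and "FSC-H" not in pop.channel_locations and fsc_a_idx is not None:
                continue  # derived from FSC-A below
            loc, cv = pop.location(ch), pop.cv(ch)
            if ch in SCATTER_CHANNELS:
                block[:, j] = _truncnormal(rng, loc, cv, n)
            else:
                block[:, j] = _lognormal(rng, loc, cv, n)
        if fsc_h_idx is not None and "FSC-H" not in pop.channel_locations \
                and fsc_a_idx is not None:
            ratio = rng.normal(1.0, FSC_H_RATIO_SD, size=n)
            block[:, fsc_h_idx] = block[:, fsc_a_idx] / np.clip(ratio, 0.5, 1.5)
        blocks.append(block)
        labels.append(np.full(n, pop.name, dtype=object))

    events = np.vstack(blocks) if blocks else np.empty((0, len(channels)))
    label_arr = np.concatenate(labels) if labels else np.empty(0, dtype=object)
    order = rng.permutation(events.shape[0])
    events, label_arr = events[order], label_arr[order]

    if doublet_fraction > 0 and events.shape[0] > 1 and fsc_a_idx is not None:
        n_doub = int(round(doublet_fraction * events.shape[0]))
        pick = rng.choice(events.shape[0], size=n_doub, replace=False)
        partner = rng.integers(0, events.shape[0], size=n_doub)
        events[pick, fsc_a_idx] += events[partner, fsc_a_idx]
        label_arr[pick] = DOUBLET_LABEL

    if spillover is not None:
        idx = [channels.index(c) for c in spillover.channels]
        events[:, idx] = events[:, idx] @ spillover.matrix

    kw = {"$SRC": "cytoquant.simulate", "CYTOQ_SEED": str(seed)}
    if keywords:
        kw.update(keywords)
    return EventTable(list(channels), events, kw, labels=label_arr)


def pe_signal_for_abc(abc: float, slope: float = 1.0, intercept: float = 0.0) -> float:
    """Median PE fluorescence producing ``abc`` under the stated calibration
    truth ``log10(ABC) = slope*log10(F) + intercept`` (specific signal only;
    autofluorescence is added separately)."""
    if abc <= 0:
        return 0.0
    return float(10 ** ((np.log10(abc) - intercept) / slope))


def generate_bead_tube(
    lot: BeadLotSpec,
    slope: float = 1.0,
    intercept: float = 0.0,
    n_events: int = 20_000,
    seed: int = 0,
) -> EventTable:
    """Four-peak calibration-bead tube.

    Peak median fluorescences satisfy the stated true log-log line against
    the lot's PE levels.  Warns (does not fail) when ``peak_cv`` is large
    enough for adjacent peaks to overlap.
    """
    medians = [pe_signal_for_abc(level, slope, intercept) for level in lot.levels]
    sigma = np.sqrt(np.log1p(lot.peak_cv ** 2))
    gaps = np.diff(np.log(medians))
    if np.any(gaps < 4 * sigma):
        warnings.warn("bead peaks may overlap: peak_cv too large for lot spacing",
                      stacklevel=2)
    pops = [
        PopulationSpec(f"bead-{i + 1}", 0.25, {"PE-A": m, "FSC-A": 50_000, "SSC-A": 30_000},
                       {"PE-A": lot.peak_cv})
        for i, m in enumerate(medians)
    ]
    return generate_tube(pops, ["FSC-A", "FSC-H", "SSC-A", "PE-A"], n_events, seed,
                         keywords={"CYTOQ_TUBE": "beads"})


#: two-fold dilution series spanning the 1/5..1/3200 titration range (the
#: final step is 2.5-fold so the endpoints are exact)
DEFAULT_DILUTIONS = tuple(1.0 / d for d in (5, 10, 20, 40, 80, 160, 320, 640, 1280, 3200))


def generate_titration_series(
    cell_types: list[tuple[PopulationSpec, BindingModel]],
    barcodes: BarcodeScheme,
    dilutions: tuple[float, ...] = DEFAULT_DILUTIONS,
    n_events: int = 20_000,
    seed: int = 0,
    slope: float = 1.0,
    intercept: float = 0.0,
    include_fmo: bool = False,
) -> list[EventTable]:
    """One barcoded mixture tube per dilution (plus an optional FMO tube).

    All cell types appear at equal expected fractions.  Per cell type, the
    expected specific PE signal at concentration ``c`` follows the binding
    law converted through the stated calibration truth, on top of
    autofluorescence; tracker channels follow the barcode scheme.  With
    ``include_fmo`` a final unstained tube (PE at autofluorescence) is
    appended.  Raises ``KeyError`` if a cell type lacks a barcode.
    """
    if not cell_types:
        raise ValueError("need at least one cell type")
    if len(dilutions) == 0:
        raise ValueError("dilution list must be nonempty")
    if np.any(np.diff(dilutions) >= 0):
        raise ValueError("dilutions must be strictly decreasing in concentration")
    for pop, _ in cell_types:
        barcodes.tracker_locations(pop.name)  # KeyError if missing

    frac = 1.0 / len(cell_types)
    tubes: list[EventTable] = []
    concentrations = list(dilutions) + ([None] if include_fmo else [])
    for k, c in enumerate(concentrations):
        pops = []
        for pop, model in cell_types:
            blue, red = barcodes.tracker_locations(pop.name)
            abc = model.bound(c) if c is not None else 0.0
            pe = AUTOFLUORESCENCE + pe_signal_for_abc(abc, slope, intercept)
            locs = dict(pop.channel_locations)
            locs.update({barcodes.blue_channel: blue, barcodes.red_channel: red,
                         "PE-A": pe})
            pops.append(PopulationSpec(pop.name, frac, locs, dict(pop.channel_cvs),
                                       true_abc=abc))
        label = "FMO" if c is None else f"1/{round(1 / c)}"
        tubes.append(
            generate_tube(pops, TITRATION_CHANNELS, n_events, seed + 1000 * (k + 1),
                          keywords={"CYTOQ_TUBE": "titration", "CYTOQ_DILUTION": label})
        )
    return tubes


# ---------------------------------------------------------------------------
# default study tubes


def _pop(name: str, fraction: float, ssc: float, markers: dict[str, float],
         pe: float, abc: float | None) -> PopulationSpec:
    locs = {"SSC-A": ssc, "PE-A": pe}
    locs.update(markers)
    return PopulationSpec(name, fraction, locs, true_abc=abc)


P = POSITIVE_LEVEL

#: innate-tube populations: (fraction, SSC median, positive backbone markers)
_INNATE_DESIGN: dict[str, tuple[float, float, dict[str, float]]] = {
    "Neutrophils": (0.40, 150_000, {"CD45": P, "CD16": P}),
    "Eosinophils": (0.03, 300_000, {"CD45": P}),
    "Basophils": (0.01, 25_000, {"CD45": P, "CD123": P}),
    "class Mono": (0.08, 60_000, {"CD45": P, "CD14": P, "HLA-DR": P, "CD11c": P}),
    "inter Mono": (0.015, 60_000, {"CD45": P, "CD14": P, "CD16": P, "HLA-DR": P, "CD11c": P}),
    "nonc Mono": (0.015, 55_000, {"CD45": P, "CD16": P, "HLA-DR": P, "CD11c": P}),
    "mDC": (0.008, 40_000, {"CD45": P, "CD11c": P, "HLA-DR": BRIGHT_LEVEL}),
    "pDC": (0.005, 30_000, {"CD45": P, "CD123": P, "HLA-DR": P}),
    "ILC-1": (0.001, 18_000, {"CD45": P, "CD127": P}),
    "ILC-2": (0.001, 18_000, {"CD45": P, "CD127": P, "CRTH2": P}),
    "ILC-3": (0.001, 18_000, {"CD45": P, "CD127": P, "CD117": P}),
    "NK cells": (0.06, 20_000, {"CD45": P, "CD56": P, "CD16": P}),
    "T&B cells": (0.374, 20_000, {"CD45": P, "CD3": P}),
}

#: adaptive-tube populations
_ADAPTIVE_DESIGN: dict[str, tuple[float, float, dict[str, float]]] = {
    "Tgd": (0.02, 20_000, {"CD45": P, "CD3": P, "TCRgd": P}),
    "CD4 naive": (0.14, 20_000, {"CD45": P, "CD3": P, "CD4": P, "CD45RA": P,
                                 "CD27": P, "CD127": 15_000}),
    "CD4 CM": (0.10, 20_000, {"CD45": P, "CD3": P, "CD4": P, "CD27": P, "CD127": 15_000}),
    "CD4 EM": (0.06, 20_000, {"CD45": P, "CD3": P, "CD4": P, "CD127": 15_000}),
    "CD4 TEMRA": (0.02, 20_000, {"CD45": P, "CD3": P, "CD4": P, "CD45RA": P,
                                 "CD127": 15_000}),
    "Treg": (0.03, 20_000, {"CD45": P, "CD3": P, "CD4": P, "CD25": P, "CD27": P}),
    "Tfh": (0.03, 20_000, {"CD45": P, "CD3": P, "CD4": P, "CXCR5": P, "CD27": P,
                           "CD127": 15_000}),
    "CD8 naive": (0.07, 20_000, {"CD45": P, "CD3": P, "CD8": P, "CD45RA": P, "CD27": P}),
    "CD8 CM": (0.04, 20_000, {"CD45": P, "CD3": P, "CD8": P, "CD27": P}),
    "CD8 EM": (0.04, 20_000, {"CD45": P, "CD3": P, "CD8": P}),
    "CD8 TEMRA": (0.03, 20_000, {"CD45": P, "CD3": P, "CD8": P, "CD45RA": P}),
    "B naive": (0.05, 20_000, {"CD45": P, "CD19": P, "IgD": P}),
    "B dn": (0.01, 20_000, {"CD45": P, "CD19": P}),
    "B nat Eff": (0.02, 20_000, {"CD45": P, "CD19": P, "IgD": P, "CD27": P}),
    "B sw Mem": (0.02, 20_000, {"CD45": P, "CD19": P, "CD27": P}),
    "NK & innate": (0.32, 20_000, {"CD45": P}),
}

#: default true-ABC profile of the profiled PE marker across subsets — a
#: myeloid-biased pattern spanning the assay's dynamic range
DEFAULT_ABC_PROFILE: dict[str, float] = {
    "Neutrophils": 90_000, "Eosinophils": 25_000, "Basophils": 12_000,
    "class Mono": 80_000, "inter Mono": 40_000, "nonc Mono": 3_000,
    "mDC": 8_000, "pDC": 6_000, "ILC-1": 2_000, "ILC-2": 2_500, "ILC-3": 2_000,
    "NK cells": 4_000, "T&B cells": 1_000,
    "Tgd": 75_000, "CD4 naive": 70_000, "CD4 CM": 65_000, "CD4 EM": 60_000,
    "CD4 TEMRA": 55_000, "Treg": 50_000, "Tfh": 52_000,
    "CD8 naive": 48_000, "CD8 CM": 45_000, "CD8 EM": 42_000, "CD8 TEMRA": 40_000,
    "B naive": 3_000, "B dn": 2_500, "B nat Eff": 2_200, "B sw Mem": 2_400,
    "NK & innate": 1_500,
}


def _build_populations(design: dict, fmo: bool, abc_profile: dict[str, float] | None,
                       slope: float, intercept: float) -> list[PopulationSpec]:
    profile = DEFAULT_ABC_PROFILE if abc_profile is None else abc_profile
    pops = []
    for name, (fraction, ssc, markers) in design.items():
        abc = 0.0 if fmo else float(profile.get(name, 0.0))
        pe = AUTOFLUORESCENCE + pe_signal_for_abc(abc, slope, intercept)
        pops.append(_pop(name, fraction, ssc, markers, pe, abc))
    return pops


def innate_populations(fmo: bool = False, abc_profile: dict[str, float] | None = None,
                       slope: float = 1.0, intercept: float = 0.0) -> list[PopulationSpec]:
    """Default innate-tube mixture (12 leaf subsets + T/B filler).

    With ``fmo=True`` the PE channel sits at autofluorescence for every
    population (the fluorescence-minus-one control).
    """
    return _build_populations(_INNATE_DESIGN, fmo, abc_profile, slope, intercept)


def adaptive_populations(fmo: bool = False, abc_profile: dict[str, float] | None = None,
                         slope: float = 1.0, intercept: float = 0.0) -> list[PopulationSpec]:
    """Default adaptive-tube mixture (15 leaf subsets + non-T/B filler)."""
    return _build_populations(_ADAPTIVE_DESIGN, fmo, abc_profile, slope, intercept)


def titration_cell_types(
    bmax: dict[str, float] | None = None,
    kd: float = 1 / 100,
    ns_slope: float = 0.0,
) -> list[tuple[PopulationSpec, BindingModel]]:
    """Default six-cell-type titration mixture.

    The default target is myeloid-marker-like: strongly bound on blood
    leukocytes and THP-1, weaker on the lymphoid lines, and zero on the
    mouse 300.19 line (the universal negative control).
    """
    default_bmax = {"blood": 80_000.0, "THP-1": 60_000.0, "Jurkat": 5_000.0,
                    "U266": 8_000.0, "Raji": 4_000.0, "300.19": 0.0}
    bmax = default_bmax if bmax is None else bmax
    scatter = {"blood": 90_000.0, "THP-1": 70_000.0, "Jurkat": 25_000.0,
               "U266": 30_000.0, "Raji": 25_000.0, "300.19": 22_000.0}
    out = []
    for name in DEFAULT_BARCODES:
        pop = PopulationSpec(name, 1 / 6, {"SSC-A": scatter[name]})
        out.append((pop, BindingModel(bmax.get(name, 0.0), kd, ns_slope)))
    return out
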