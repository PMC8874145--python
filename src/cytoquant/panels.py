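"""Backbone panels, subset reference table and default gating templates.

Two backbone tubes identify the reported leukocyte subsets: an *innate*
tube (granulocytes, monocytes, dendritic cells, NK and innate lymphoid
cells; 12 leaf subsets) and an *adaptive* tube (T- and B-cell subsets
including TCRγδ+, Treg and Tfh; 15 leaf subsets).  Fluorescence channels
are named by their backbone marker; the variable PE-conjugated reagent is
always read on ``PE-A``.

The gate-boundary constants below are the package defaults; they are the
same numbers the synthetic-data generator uses to place its populations, so
template gating on simulated tubes is near-exact by construction.  Real
instruments need tube-specific boundaries, supplied via template JSON.
"""

from __future__ import annotations

import pandas as pd

from .gating import AnyOf, GateNode, GatingTemplate, RatioBand, Rectangle, Threshold

__all__ = [
    "INNATE_CHANNELS",
    "ADAPTIVE_CHANNELS",
    "TITRATION_CHANNELS",
    "SUBSET_REFERENCE",
    "reference_cutoffs",
    "innate_template",
    "adaptive_template",
    "POSITIVITY_CUT",
    "AUTOFLUORESCENCE",
    "POSITIVE_LEVEL",
    "BRIGHT_LEVEL",
]

SCATTER = ["FSC-A", "FSC-H", "SSC-A"]

INNATE_MARKERS = ["CD45", "CD3", "CD19", "CD16", "CD14", "CD123", "HLA-DR",
                  "CD11c", "CD127", "CRTH2", "CD117", "CD56"]
ADAPTIVE_MARKERS = ["CD45", "CD3", "CD19", "CD45RA", "CD27", "CD4", "CD8",
                    "TCRgd", "CD25", "CD127", "CXCR5", "IgD"]

INNATE_CHANNELS = SCATTER + INNATE_MARKERS + ["PE-A"]
ADAPTIVE_CHANNELS = SCATTER + ADAPTIVE_MARKERS + ["PE-A"]
#: titration mixture tube: scatter, the two cell-tracking dyes, and PE
TITRATION_CHANNELS = SCATTER + ["Tracker-Blue", "Tracker-DeepRed", "PE-A"]

# --- default gate boundaries (linear units), shared with the generator -----

AUTOFLUORESCENCE = 80.0  # negative-marker median
POSITIVE_LEVEL = 25_000.0  # positive-marker median
BRIGHT_LEVEL = 60_000.0  # "++" markers (e.g. HLA-DR on mDC)
POSITIVITY_CUT = 1_500.0  # +/- threshold between the two
BRIGHT_CUT = 8_000.0  # + vs ++
DEBRIS_FSC_CUT = 30_000.0
SINGLET_RATIO = (0.85, 1.15)  # FSC-A/FSC-H band
SSC_HIGH_CUT = 100_000.0  # low/med vs high side scatter
SSC_VERY_HIGH_CUT = 220_000.0  # high vs very high (eosinophils)
SSC_LYMPHOID_CUT = 45_000.0  # "SSC very low" lymphoid gate


# --- subset reference table ------------------------------------------------

#: (population code, tube, immunophenotype, published FMO background cutoff
#: in ABC units).  The cutoffs are the study's reported per-subset minimal
#: ABC resolution; they ship as reference data for resolution summaries and
#: for comparing new FMO runs against the published baseline.
SUBSET_REFERENCE: list[tuple[str, str, str, int]] = [
    ("Neutrophils", "innate", "CD45+/CD3-/CD19-/SSC high/CD16+", 408),
    ("Eosinophils", "innate", "CD45+/CD3-/CD19-/SSC very high/CD16-", 632),
    ("Basophils", "innate", "CD45+/CD3-/CD19-/SSC low/CD123+/HLA-DR-", 357),
    ("class Mono", "innate", "CD45+/CD3-/CD19-/SSC low/CD123-/HLA-DR+/CD11c+/CD14+CD16-", 384),
    ("inter Mono", "innate", "CD45+/CD3-/CD19-/SSC low/CD123-/HLA-DR+/CD11c+/CD14+CD16+", 353),
    ("nonc Mono", "innate", "CD45+/CD3-/CD19-/SSC low/CD123-/HLA-DR+/CD11c+/CD14-CD16+", 350),
    ("mDC", "innate", "CD45+/CD3-/CD19-/SSC low/CD123-/CD11c+/CD16-CD14-/HLA-DR++", 396),
    ("pDC", "innate", "CD45+/CD3-/CD19-/SSC low/CD123+ HLA-DR+", 309),
    ("ILC-1", "innate", "CD45+/CD3-/CD19-/SSC very low/CD127+/CD16-/CRTH2-CD117-", 336),
    ("ILC-2", "innate", "CD45+/CD3-/CD19-/SSC very low/CD127+/CD16-/CRTH2+CD117-", 312),
    ("ILC-3", "innate", "CD45+/CD3-/CD19-/SSC very low/CD127+/CD16-/CRTH2-CD117+", 459),
    ("NK cells", "innate", "CD45+/CD3-/CD19-/SSC very low/CD123-/HLA-DR-/CD14-/CD127-/"
     "CD56+ and/or CD16+", 229),
    ("Tgd", "adaptive", "CD45+/SSC low/CD3+/TCRgd+", 461),
    ("CD4 naive", "adaptive", "CD3+/CD4+/CD8-/CD45RA+/CD27+", 369),
    ("CD4 CM", "adaptive", "CD3+/CD4+/CD8-/CD45RA-/CD27+", 471),
    ("CD4 EM", "adaptive", "CD3+/CD4+/CD8-/CD45RA-/CD27-", 406),
    ("CD4 TEMRA", "adaptive", "CD3+/CD4+/CD8-/CD45RA+/CD27-", 360),
    ("Treg", "adaptive", "CD3+/CD4+/CD8-/CD25+CD127-", 305),
    ("Tfh", "adaptive", "CD3+/CD4+/CD8-/CD45RA-/CXCR5+", 415),
    ("CD8 naive", "adaptive", "CD3+/CD4-/CD8+/CD45RA+/CD27+", 384),
    ("CD8 CM", "adaptive", "CD3+/CD4-/CD8+/CD45RA-/CD27+", 425),
    ("CD8 EM", "adaptive", "CD3+/CD4-/CD8+/CD45RA-/CD27-", 396),
    ("CD8 TEMRA", "adaptive", "CD3+/CD4-/CD8+/CD45RA+/CD27-", 338),
    ("B naive", "adaptive", "CD45+/SSC low/CD3-/CD19+/IgD+/CD27-", 773),
    ("B dn", "adaptive", "CD45+/SSC low/CD3-/CD19+/IgD-/CD27-", 732),
    ("B nat Eff", "adaptive", "CD45+/SSC low/CD3-/CD19+/IgD+/CD27+", 786),
    ("B sw Mem", "adaptive", "CD45+/SSC low/CD3-/CD19+/IgD-/CD27+", 727),
]


def reference_cutoffs(tube: str | None = None) -> dict[str, float]:
    """Published per-subset FMO background cutoff (ABC units)."""
    return {code: float(cut) for code, t, _, cut in SUBSET_REFERENCE
            if tube is None or t == tube}


def subset_reference_frame() -> pd.DataFrame:
    return pd.DataFrame(SUBSET_REFERENCE,
                        columns=["code", "tube", "immunophenotype", "background_cutoff_abc"])


# --- template builders -----------------------------------------------------


def _pos(ch: str, cut: float = POSITIVITY_CUT) -> Threshold:
    return Threshold(ch, cut, "above")


def _neg(ch: str, cut: float = POSITIVITY_CUT) -> Threshold:
    return Threshold(ch, cut, "below")


def _quad(ch_a: str, ch_b: str, sa: str, sb: str, cut: float = POSITIVITY_CUT) -> Rectangle:
    def b(side):
        return (cut, None) if side == "+" else (None, cut)
    (a_lo, a_hi), (b_lo, b_hi) = b(sa), b(sb)
    return Rectangle(((ch_a, a_lo, a_hi), (ch_b, b_lo, b_hi)))


def _pre_gates() -> tuple[GateNode, GateNode]:
    """Debris exclusion (low FSC) then doublet exclusion (FSC-A/FSC-H band)."""
    singlets = GateNode("singlets", RatioBand("FSC-A", "FSC-H", *SINGLET_RATIO))
    non_debris = GateNode("non-debris", Threshold("FSC-A", DEBRIS_FSC_CUT, "above"),
                          [singlets])
    return non_debris, singlets


def innate_template() -> GatingTemplate:
    """Innate tube: debris/doublet exclusion, CD45+, CD3-CD19-, then side-
    scatter branches to granulocytes, monocyte/DC subsets, ILCs and NK."""
    non_debris, singlets = _pre_gates()

    eos = GateNode("Eosinophils", _neg("CD16"))
    ssc_vhigh = GateNode("SSC very high", Threshold("SSC-A", SSC_VERY_HIGH_CUT, "above"), [eos])

    neut = GateNode("Neutrophils", _pos("CD16"))
    ssc_high = GateNode("SSC high",
                        Rectangle((("SSC-A", SSC_HIGH_CUT, SSC_VERY_HIGH_CUT),)), [neut])

    baso = GateNode("Basophils", _neg("HLA-DR"))
    pdc = GateNode("pDC", _pos("HLA-DR"))
    cd123_pos = GateNode("CD123+", _pos("CD123"), [baso, pdc])

    mono_class = GateNode("class Mono", _quad("CD14", "CD16", "+", "-"))
    mono_inter = GateNode("inter Mono", _quad("CD14", "CD16", "+", "+"))
    mono_nonc = GateNode("nonc Mono", _quad("CD14", "CD16", "-", "+"))
    mdc = GateNode("mDC", Rectangle((("CD14", None, POSITIVITY_CUT),
                                     ("CD16", None, POSITIVITY_CUT),
                                     ("HLA-DR", BRIGHT_CUT, None))))
    mono_dc = GateNode("HLA-DR+CD11c+", _quad("HLA-DR", "CD11c", "+", "+"),
                       [mono_class, mono_inter, mono_nonc, mdc])

    ilc1 = GateNode("ILC-1", _quad("CRTH2", "CD117", "-", "-"), requires=("CD56",))
    ilc2 = GateNode("ILC-2", _quad("CRTH2", "CD117", "+", "-"))
    ilc3 = GateNode("ILC-3", _quad("CRTH2", "CD117", "-", "+"))
    ilc = GateNode("ILC", _quad("CD127", "CD16", "+", "-"), [ilc1, ilc2, ilc3])
    nk = GateNode("NK cells", AnyOf((_pos("CD56"), _pos("CD16"))))
    cd127_neg = GateNode("CD127-", _neg("CD127"), [nk])
    lymphoid = GateNode("SSC very low", Threshold("SSC-A", SSC_LYMPHOID_CUT, "below"),
                        [ilc, cd127_neg])
    cd14_neg = GateNode("CD14-", _neg("CD14"), [lymphoid])
    hladr_neg = GateNode("HLA-DR-", _neg("HLA-DR"), [cd14_neg])
    cd123_neg = GateNode("CD123-", _neg("CD123"), [mono_dc, hladr_neg])

    ssc_low = GateNode("SSC low", Threshold("SSC-A", SSC_HIGH_CUT, "below"),
                       [cd123_pos, cd123_neg])

    lin_neg = GateNode("CD3-CD19-", Rectangle((("CD3", None, POSITIVITY_CUT),
                                               ("CD19", None, POSITIVITY_CUT))),
                       [ssc_high, ssc_vhigh, ssc_low])
    cd45 = GateNode("CD45+", _pos("CD45"), [lin_neg])
    singlets.children = [cd45]
    root = GateNode("all", None, [non_debris])

    phenos = {c: p for c, t, p, _ in SUBSET_REFERENCE if t == "innate"}
    return GatingTemplate("innate", root, phenos)


def adaptive_template() -> GatingTemplate:
    """Adaptive tube: lymphocytes (CD45+ SSC low), then TCRγδ+, CD4/CD8
    T-cell maturation subsets (with Tfh and Treg removed first, as in
    sequential manual gating) and the four IgD/CD27 B-cell subsets."""
    non_debris, singlets = _pre_gates()

    tgd = GateNode("Tgd", _pos("TCRgd"))

    tfh = GateNode("Tfh", _quad("CD45RA", "CXCR5", "-", "+"))
    treg = GateNode("Treg", _quad("CD25", "CD127", "+", "-"))
    cd4_subsets = [GateNode("CD4 naive", _quad("CD45RA", "CD27", "+", "+")),
                   GateNode("CD4 CM", _quad("CD45RA", "CD27", "-", "+")),
                   GateNode("CD4 EM", _quad("CD45RA", "CD27", "-", "-")),
                   GateNode("CD4 TEMRA", _quad("CD45RA", "CD27", "+", "-"))]
    cd4 = GateNode("CD4 T", _quad("CD4", "CD8", "+", "-"), [tfh, treg] + cd4_subsets)

    cd8_subsets = [GateNode("CD8 naive", _quad("CD45RA", "CD27", "+", "+")),
                   GateNode("CD8 CM", _quad("CD45RA", "CD27", "-", "+")),
                   GateNode("CD8 EM", _quad("CD45RA", "CD27", "-", "-")),
                   GateNode("CD8 TEMRA", _quad("CD45RA", "CD27", "+", "-"))]
    cd8 = GateNode("CD8 T", _quad("CD4", "CD8", "-", "+"), cd8_subsets)

    tcr_ab = GateNode("TCRgd-", _neg("TCRgd"), [cd4, cd8])
    t_cells = GateNode("T cells", Rectangle((("CD3", POSITIVITY_CUT, None),
                                             ("CD19", None, POSITIVITY_CUT))),
                       [tgd, tcr_ab])

    b_subsets = [GateNode("B naive", _quad("IgD", "CD27", "+", "-")),
                 GateNode("B nat Eff", _quad("IgD", "CD27", "+", "+")),
                 GateNode("B sw Mem", _quad("IgD", "CD27", "-", "+")),
                 GateNode("B dn", _quad("IgD", "CD27", "-", "-"))]
    b_cells = GateNode("B cells", Rectangle((("CD3", None, POSITIVITY_CUT),
                                             ("CD19", POSITIVITY_CUT, None))),
                       b_subsets)

    lymph = GateNode("CD45+SSClow", Rectangle((("CD45", POSITIVITY_CUT, None),
                                               ("SSC-A", None, SSC_HIGH_CUT))),
                     [t_cells, b_cells])
    singlets.children = [lymph]
    root = GateNode("all", None, [non_debris])

    phenos = {c: p for c, t, p, _ in SUBSET_REFERENCE if t == "adaptive"}
    return GatingTemplate("adaptive", root, phenos)
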