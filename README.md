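# cytoquant

Quantitative surface-antigen expression profiling on blood leukocytes by
flow cytometry, as a reproducible desk-scale pipeline.

Immunophenotyping panels can identify dozens of leukocyte subsets, but raw
fluorescence intensities are not comparable across instruments, sites or
reagent lots. The standardized workflow implemented here converts the
signal of a PE-conjugated "target" antibody into **antibody binding
capacity (ABC)** — antibody molecules bound per cell — using calibration
beads carrying four known numbers of PE molecules. Because PE conjugation
is 1:1 fluorochrome:antibody, a log–log line fitted through the four bead
peaks,

    log10(ABC) = slope · log10(F_PE) + intercept,

maps any cell's PE fluorescence to a molecule count. Around that core the
package implements the full plate-based workflow:

- **FCS 3.0 I/O** and batch renaming/annotation of acquired files from an
  Experiment Master Table (EMT), injecting reagent identifiers as
  namespaced FCS keywords (`cytoquant.fcs`, `cytoquant.emt`);
- staining-protocol generation with master-mix arithmetic
  (10 µl PE reagent + diluent, 40 µl cells = 2×10⁶, 25 µl backbone mix);
- **spillover compensation** (matrix inversion) and arcsinh display
  transforms (`cytoquant.preprocess`);
- **hierarchical template gating** of 27 leukocyte subsets — 12 innate
  (granulocytes, monocyte and dendritic-cell subsets, ILC-1/2/3, NK) and
  15 adaptive (TCRγδ⁺, CD4/CD8 naive–CM–EM–TEMRA, Treg, Tfh, four B-cell
  subsets) (`cytoquant.gating`, `cytoquant.panels`);
- **quantitation**: bead-peak finding (1-D k-means on log10 F), OLS
  calibration, ABC conversion, per-subset background cutoffs as the 90th
  percentile of ABC in the fluorescence-minus-one (FMO) control, median /
  IQR / percent-positive statistics with an n ≥ 66 minimum-cell-count rule
  (`cytoquant.quant`);
- **titration analytics**: demultiplexing of a six-cell-type mixture
  barcoded with two cell-tracking dyes at three levels, per-cell-type
  dilution curves, Stain Index `SI = (med⁺ − med⁻) / (2·rSD⁻)` with a
  robust spread (84.13th percentile − median), and optimal-titer selection
  at the edge of saturation (`cytoquant.titration`);
- **cross-site summaries**: intra-/inter-laboratory CVs and fold changes
  of median ABC (`cytoquant.crosssite`);
- a **synthetic-data generator** (`cytoquant.simulate`) that emulates the
  study's tubes — population mixtures with known labels, FMO controls,
  four-peak bead tubes, barcoded titration series with saturation-binding
  PE signal — so every stage is testable without acquired data.

## Worked example

```sh
cytoquant simulate --seed 7 --out sim --n-events 80000
cytoquant quantify --in sim --out quant
cytoquant titrate  --in sim --out titr
cytoquant report   --out rep --cutoffs quant/cutoffs_innate.csv \
                   --cutoffs quant/cutoffs_adaptive.csv
```

prints

```
wrote 17 files to sim
27 subset rows; calibration slope 1.0000 (R^2 1.00000); FMO resolution median 147 ABC [117..163]
recommended titer: 1/10 (plateau reached)
background resolution across 27 subsets: median 147, min 117, max 163 ABC units
```

`quant/subset_stats.csv` holds one row per tube × subset, e.g.

```
tube,code,n,median_pe,median_abc,...,background_cutoff,percent_positive,below_min_count
innate,Neutrophils,31879,89790.30,89654.42,...,145.69,100.0,False
innate,ILC-3,67,1854.95,1851.84,...,147.27,100.0,False
```

Reading: the calibration fitted from the simulated bead tube recovered the
generator's identity line (slope 1.0000, R² = 1); neutrophils were
simulated with a true ABC of 90,000 and measured at 89,654 (−0.4%); the
ILC-3 subset cleared the 66-event minimum with 67 cells. The FMO-derived
background cutoffs of this clean synthetic run sit near the
autofluorescence level (median 147 ABC); the published reference cutoffs
for real acquisitions ship with the package
(`cytoquant.panels.SUBSET_REFERENCE`, median 396, range 229–786 ABC) and
are what `cytoquant report` summarises when no cutoff files are given. The
titration run recommends 1/10 — the most dilute step still within 90% of
the maximal positive signal.

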