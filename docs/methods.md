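# Methods

## The measurement model

The pipeline quantifies how many molecules of one surface antigen a cell
carries. A PE-conjugated monoclonal antibody (1:1 fluorochrome:antibody)
is added to a backbone panel that identifies the leukocyte subsets; the PE
fluorescence of each cell is converted to antibody binding capacity (ABC)
through a calibration fitted on beads with four known PE-molecules-per-
bead levels. The calibration is ordinary least squares of log10(lot level)
on log10(peak median fluorescence), so conversion needs no inversion:
`ABC = 10^(slope·log10 F + intercept)`. Fitting all four peaks jointly
absorbs the difference between two-point and multi-point bead conventions.
R² is reported and a warning is raised below 0.99.

Bead peaks are found by one-dimensional k-means (k = 4) on log10
fluorescence, initialised at the evenly spaced octile quantiles of the
sorted data — deterministic and order-invariant. Peaks with fewer than 50
beads, or adjacent peak medians closer than 10^0.25-fold, raise an
"unresolvable peaks" error rather than returning a dubious fit.

Compensated fluorescence can be negative; such events convert to ABC 0
and are flagged below-detection rather than dropped, so subset event
counts (and the n ≥ 66 rule) are unaffected by compensation noise.

## Gating

Subsets are the leaves of fixed-threshold template trees (one per tube).
Debris (low FSC-A) is removed first, then doublets via an FSC-A/FSC-H
ratio band (default 0.85–1.15). Events descend the tree and follow the
first child gate they satisfy; geometrically disjoint siblings (the
CD45RA/CD27 maturation quadrants, the CD14/CD16 monocyte split) are
order-independent, while deliberately sequential gates (Tfh, then Treg,
then the remaining CD4 quadrants) mirror the sequential manual strategy.
Events failing every child stop at that node and stay unassigned — they
are not errors. An "and/or" union geometry covers the NK definition
(CD56⁺ and/or CD16⁺) and degrades gracefully on a reduced panel: with the
CD56 channel absent the CD16 arm still gates, while ILC-1 — defined by
negativity for everything, trustworthy only when CD56 can exclude NK
cells — is flagged unavailable by `validate_template`.

Quantitative statistics (median PE, ABC quantiles) are always computed on
compensated **linear** values; the arcsinh display transform (default
cofactor 150) affects gate geometry only, and since thresholds and event
values transform together under any monotone map, gating with linear
thresholds is equivalent.

Numeric gate boundaries are template parameters (JSON-serialisable). The
package defaults are the same constants the synthetic generator uses to
place its populations, which makes template gating on simulated tubes
near-exact by construction; real acquisitions need instrument-specific
boundaries.

## Background cutoffs and subset statistics

Per subset, the background cutoff is the 90th percentile of ABC in the
fluorescence-minus-one (FMO) control gated with the same template; percent
positive is the fraction of stained-tube events above that cutoff. All
quantiles — median, Q1/Q3, the 90th percentile — use linear interpolation
between order statistics (the common scientific-software default; the
nearest-rank alternative was not adopted, and one convention is used
everywhere including the test oracles). Subsets with fewer than 66 events
are omitted from cutoff tables and flagged in statistics tables. Cutoffs
are computed per tube (per donor/lab), never pooled.

The package ships the published per-subset background cutoffs of the
27-subset reference (median 396, min 229, max 786 ABC units) as reference
data for resolution summaries and comparisons.

## Titration

Six barcoded cell types (four human lines, the mouse 300.19 line as
universal negative, and blood leukocytes) are mixed at equal rates, so one
tube contains a positive and a negative population for nearly any reagent.
Demultiplexing classifies the two tracker channels into
negative/low/high by half-open regions split at geometric midpoints
between the level medians; events exactly on a boundary are left
unassigned rather than snapped to the nearest region. Blood events can be
sub-split into lymphocytes/monocytes/granulocytes on SSC bands.

Stain Index uses the robust spread of the negative population,
rSD = P84.13 − median (one normal-equivalent SD), SI = (med⁺ − med⁻)/(2·rSD⁻);
the exact published variant of the robust modification is ambiguous, so
the classical-SD form is available as an option. Titer policies:

- **saturation** (default): the most dilute step whose positive median is
  ≥ 90% (configurable) of the maximal positive median; if the negative
  line's median there exceeds 2× the FMO level, step one dilution lower —
  trading a little intensity for low false-positive background;
- **max-SI** / **max-SI-minus-one**: the Stain-Index maximum, or one step
  more dilute than it.

Clone benchmarking compares median ABC of ≥ 2 clones of the same target on
shared subsets and flags a clone deviating more than 1.5-fold (either
direction) from the across-clone median — the signature of an epitope
differentially accessible to one clone.

## Cross-site summaries

CV = 100 × sample SD (n−1) / mean. Intra-lab CV is computed across donors
within each lab and averaged over labs; inter-lab CV pools all donor-lab
medians of a marker × subset cell. The aggregation across subsets into a
single "mean CV" is ambiguous in the field; both levels are exposed and
the pooling choice is configurable by operating on the tidy table.

## The synthetic generator

The generator emulates the statistical structure the pipeline assumes, not
cytometer physics:

- fluorescence marginals are **log-normal in linear units** with location
  = population median (σ² = ln(1+CV²), default CV 0.5) — a modeling
  choice matching typical cytometry marginals, not an empirical claim;
- scatter channels are normal truncated at zero (default CV 0.08); FSC-H
  is tied to FSC-A by a near-unity ratio (SD 0.03) so singlet gating
  works; optional doublets get summed FSC-A and shared FSC-H;
- positive/negative marker separation is ≥ 10× by default (negative
  ≈ 80, positive ≈ 25,000 linear units), so per-leaf gating accuracy
  ≥ 99% is expected by construction;
- population fractions follow realistic blood composition (neutrophils
  40%, classical monocytes 8%, ILC subsets 0.1% each, ...), so rare-subset
  behaviour of the n ≥ 66 rule emerges naturally with tube size;
- bead tubes place four log-normal peaks exactly on a stated true
  calibration line; titration tubes follow a saturation (Langmuir) law
  `bound(c) = bmax·c/(kd+c) + ns·c` converted through the same line on top
  of autofluorescence; tracker levels sit at 100/3,000/60,000;
- a spillover matrix can be applied as a right-multiplication of true
  signals so compensation inverts it exactly;
- every event keeps a hidden ground-truth label (never written to FCS);
  all randomness flows from one explicit seed per call, and identical
  seeds give bit-identical tables.

Consequently, passing tests demonstrate the correctness of the pipeline's
arithmetic, gating logic and statistical conventions on data that satisfy
the model's assumptions. They do not demonstrate robustness to what the
generator omits: autofluorescence spreading error, spillover-spreading
noise, instrument drift, population overlap, or donor biology. The
donor-level ABC results of real acquisitions are out of scope at desk
scale.

## Problem sizes and numerical choices

Default problem sizes: 200,000 events per tube for gating-accuracy
evaluation (rare subsets then carry ~200 events), 20,000 beads for
calibration, 50,000 events for ABC-recovery checks, 12,000 events per
titration tube — sizes at which median sampling error is well inside the
stated tolerances (slope ±0.02, median ABC ±5%). FCS files are written as
FCS 3.0, float32 little-endian, `/`-delimited TEXT; reading accepts
2.0/3.0/3.1 with float, double or 16/32-bit integer list-mode data.
Injected annotation keywords are namespaced `CYTOQ_*` so vendor keywords
are never clobbered; re-annotation overwrites them (idempotent) and never
touches the DATA segment. Protocol arithmetic uses a configurable 10%
master-mix overage.

## Known limitations

- Gate thresholds are fixed template parameters; no density-based
  auto-thresholding or clustering-based gating.
- PE is the only quantified fluorochrome (the 1:1 conjugation premise);
  no MESF/ABC unit bridging.
- No spillover estimation from single-stain controls; the matrix is an
  input.
- The Langmuir law is used to *generate* titration data and as a test
  oracle; titer selection itself is intentionally model-free.
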