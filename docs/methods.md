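# Methods

## Gating and the relative-MFI statistic

A raw tube is reduced to live singlets in three steps: a scatter floor on
forward- and side-scatter area removes debris; events whose forward-scatter
area/height ratio falls outside a window (default 0.7–1.4) are removed as
doublets, since aggregates accumulate pulse area roughly twice as fast as
height; events above a viability-dye ceiling are removed as dead. Gate
placements are instrument- and panel-specific, so all three are
configuration values; the defaults are tuned to the synthetic generator's
scales. An optional acquisition-order trim (default off) drops a leading
and trailing fraction of events as a stand-in for a time gate against
electronic noise; no published thresholds exist for it. A live-event count
below 10,000 produces a warning, not an error — it is an acquisition
practice, not an analysis requirement.

Marker intensity is summarized by the geometric mean over gated events,
the natural location statistic for log-normally distributed fluorescence.
Nonpositive values (possible in compensated real exports, absent in
simulation) are excluded rather than floored, and the exclusion count is
reported so pathological tubes are visible. The relative MFI is the
stained-tube geometric mean divided by the matched FMO control's; it is
scale-free, so any common rescaling of detector gain cancels.

## Calls and thresholds

- **Expression.** rMFI < 1.5 ⇒ absent. The comparison is strict, so a line
  sitting exactly at 1.5 counts as expressed; this boundary convention is
  required for internal consistency of the reference cohort's published
  negativity counts.
- **Induction.** fold = rMFI(post)/rMFI(pre), rounded *half-up* to one
  decimal before comparison with 1.5 (`fold_rounding_decimals=1`,
  configurable; `None` compares raw ratios). Cohort tables are printed at
  one-decimal precision, and the rounded policy is the one that reproduces
  the reference cohort's published non-induction and responder counts from
  its printed table. One borderline case is inherent to sub-decimal
  boundary effects: a PD-L1 fold of 1.4545… rounds to 1.5 and is counted
  induced, which makes the PD-L1 non-induction count 6 where the cohort's
  narrative gives 7. Documented, not resolved — no rounding policy
  reproduces both numbers simultaneously.
- **Percent-positive and bimodality.** An event is positive when it exceeds
  the 99th percentile of the FMO channel distribution (quantile
  configurable; the originating protocol's gate is unpublished). A marker
  is called bimodal when it is expressed and the positive fraction lies in
  (0.10, 0.90) — slightly wider than the 18–88% subpopulation range
  observed in the reference cohort, so all observed cases qualify.
- **Response class.** Complete = all five markers induced; null = none;
  partial = otherwise. "Diminished response" = not complete.
- **Mechanism flags (advisory).** MHC-I-loss candidate: baseline HLA-ABC at
  or below 1.5 (inclusive ceiling — the canonical B2M-loss line sits
  exactly at the expression threshold) and not induced while ≥ 1 other
  marker is induced; a supplied surface-B2M stain below threshold upgrades
  to a confirmed B2M-loss pattern. Upstream-defect candidate: null
  response; a supplied IFNGR1 stain absent on the surface but present
  intracellularly upgrades to a receptor-loss pattern. Without auxiliary
  stains the flags degrade gracefully to candidates.

## Cell-cycle quantification

The G1 (2N) peak is located as a mode of a Gaussian-KDE-smoothed density;
among modes reaching ≥ 30% of the maximum density the leftmost is chosen,
so G2-dominant profiles do not misplace the anchor. Phase gates are fixed
multiples of the peak position (sub-G1 < 0.85, G1 < 1.25, S < 1.75,
G2 < 2.5; configurable — the originating protocol publishes no numbers),
making the quantifier invariant to channel scale. Events ≥ 2.5 × peak are
excluded and counted. Because S-phase cells carry DNA content anywhere
between 2N and 4N, the raw mid gate sees only the central slice of the S
plateau; the quantifier extrapolates the plateau density across the full
2N–4N span and subtracts the spilled S mass from the flanking G1/G2 gates.
This rectangle background correction is not a fitted deconvolution
(Dean–Jett–Fox/Watson modeling remains out of scope) and assumes an
approximately uniform S distribution; heavily skewed S profiles would bias
it. With the default G1 CV range (≤ 0.15, default 0.05) recovery on
simulated histograms is within ~1 percentage point at 100k events.

The per-line IFNγ effect mixes two change scales deliberately: sub-G1 uses
an *absolute* change (> 10 percentage points ⇒ cell death up), S phase a
*relative* change (> 30% in either direction ⇒ replication up/down). This
pairing is the only one consistent with every row of the reference
cohort's effect annotations (e.g. a +8.6-point sub-G1 shift unflagged; a
−32% relative S drop flagged). An S phase appearing from exactly zero is
reported as S-up by convention. "nd" rows are excluded from cell-cycle
census denominators.

Ingested (replicate-averaged) phase tables need not sum to 100: sums in
[85, 115] pass silently per the published-table norm, sums outside that
band up to [50, 150] warn (observed real rows reach ~135), and anything
beyond is rejected as corrupt. Internally quantified fractions sum to 100
by construction.

## Cohort statistics

Spearman rho uses average ranks (tie-corrected) with the t-approximation
p-value, pairwise-complete over missing cells; constant columns are
reported as undefined rather than 0. The Mann–Whitney comparison uses exact
permutation enumeration (correct under ties; two-sided p = twice the
smaller tail, capped at 1) when both groups have ≤ 8 observations, else the
tie-corrected, continuity-corrected normal approximation. The approximation
tracks the exact p within 0.02 for group sizes ≥ 5; at size 4 the worst
gap is ~0.03. Group comparisons map GNAQ/GNA11 lines to the uveal group
and all others to cutaneous. No multiple-testing correction is applied by
default (reference analyses report raw p-values); two-sided throughout.

## ssGSEA

Genes are ordered by decreasing expression, ties broken by gene identifier
for determinism. The score is the sum over the ordered list of the
difference between the weighted in-set empirical CDF — an in-set gene at
descending position *i* of *N* weighs (N − i)^α — and the uniform
out-of-set ECDF. α defaults to 0.25 (the published ssGSEA convention); at
α = 0 the score is purely rank-based and invariant under strictly monotone
transforms. No cross-sample renormalization of score ranges is applied by
default (group differences are assessed by rank tests, which such a
renormalization would not affect); an option exists. The scorer consumes an
already-normalized genes × samples matrix; count normalization is out of
scope.

## Synthetic data

The generator produces exactly the data shapes the pipeline consumes, with
ground truth:

- **Marker tubes.** Fluorescence is log10-normal (strictly positive — no
  compensation artifacts, since no compensation handling is modeled). The
  FMO channel is N(μ, σ) on the log scale (defaults μ = 2.0, σ = 0.2
  decades, i.e. background ~100 a.u.); the stained tube shifts a fraction
  *p* of events by log10(r)/p so the overall geometric-mean ratio equals
  the target r exactly in expectation, and *p* < 1 yields the bimodal
  profiles observed in real panels. Dead cells (viability dye ~3.6 decades
  vs 2.0 live) and doublets (area ≈ 2 × the singlet area/height relation)
  are injected at configurable rates. Default 10,000 events per tube,
  matching the routine live-event acquisition floor.
- **DNA content.** G1 ~ N(g1, cv·g1), G2 ~ N(2g1, 2cv·g1), S uniform on
  (g1, 2g1), sub-G1 uniform on (0.2g1, 0.85g1) — the sub-G1 upper edge
  coincides with the default sub-G1 gate so that population partitions
  cleanly. Realized counts are multinomial in the target fractions.
- **Cohorts.** Per-line true baseline rMFIs and induction folds are drawn
  log-normally per marker (defaults chosen to emulate a melanoma panel:
  MHC-I broadly positive, HLA-DR/NGFR highly variable, PD-L1 at
  background; uveal lines shifted down for HLA-DR/NGFR/PD-L2). Engineered
  defects — global null responder (all folds ≈ 1) and MHC-I loss (HLA-ABC
  at background in both conditions) — are drawn per line, at most one per
  line. Default group sizes (11, 10, 10, 8) mirror the reference panel.
  Seeds propagate hierarchically (cohort → tube) via `SeedSequence`, so
  any single tube is reproducible in isolation.

What the simulator does **not** emulate: spectral spillover/compensation,
acquisition-time drift, autofluorescence heterogeneity, multi-marker
panels in one tube, or non-uniform S-phase kinetics. Tests passing on
synthetic data therefore validate the estimators and calling rules under
the stated distributional model, not instrument-specific artifacts of real
acquisitions; the published-cohort fixtures provide the complementary
real-data check of every calling rule.

## Numerical choices

- Fold rounding is half-up with a 1e-9 epsilon absorbing binary-float
  representation error, so ratios of one-decimal table entries land on the
  intended side of ties.
- Geometric means exclude (never floor) nonpositive events and report the
  count.
- KDE peak detection samples at most 20k events on a 512-point grid
  between the 0.5th and 99.5th percentiles.
- Exact Mann–Whitney tail comparisons use a 1e-9 tolerance on U to treat
  tie-induced equal statistics as equal.
- Degenerate inputs raise named errors: empty gates, all-nonpositive
  channels, undetectable G1 peaks, empty gene-set intersections, duplicate
  line ids or gene ids.

## Problem sizes in the test suite

Stochastic properties run at their natural scales: relative-MFI recovery
over 100 seeded runs of 20k events; cell-cycle recovery at 100k events;
Mann–Whitney power and group-comparison checks over 100–200 seeded
replicates; ssGSEA oracle equivalence exhaustively over all subsets of
≤ 8-gene universes. The full suite completes in well under a minute.
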