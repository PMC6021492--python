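# ifnsig

Quantitative profiling of interferon-γ (IFNγ) responses in melanoma cell
lines from flow-cytometry data.

Resistance to PD-1/PD-L1 checkpoint blockade in melanoma is associated with
defects in IFNγ signaling and antigen presentation. A practical way to
probe the integrity of the pathway in a cell line is to stimulate with IFNγ
and measure the surface induction of five canonical IFNγ targets — HLA-ABC
(MHC class I), HLA-DR (MHC class II), NGFR (CD271), PD-L1 and PD-L2 — by
flow cytometry, alongside cell-cycle effects from DNA-content histograms.
`ifnsig` implements that analysis end to end for cytometrists and tumor
immunologists: from event-level data (real CSV exports or fully synthetic
tubes with known ground truth) to cohort-level counts, statistics, and
resistance-mechanism flags.

## The statistics at the core

For each marker, one antibody-stained tube is acquired together with a
fluorescence-minus-one (FMO) control. After gating to live singlets, the
**relative MFI** is

> rMFI = GeoMean(stained) / GeoMean(FMO),

with GeoMean the geometric mean fluorescence over gated events. Calls are
threshold-based:

- **expression**: rMFI < 1.5 ⇒ no antigen expression (1.5 itself counts as
  expressed);
- **induction**: fold = rMFI(post-IFNγ) / rMFI(baseline), rounded half-up
  to one decimal; fold < 1.5 ⇒ no induction;
- **response class**: *complete* = all five markers induced, *null* = none,
  *partial* otherwise;
- **cell-cycle effect**: sub-G1 increase of > 10 percentage points flags
  cell death; a relative S-phase change of > 30% flags increased or
  diminished DNA replication.

Cohort statistics use tie-corrected Spearman rank correlations and
two-sided Mann–Whitney tests (exact permutation enumeration for small
groups). A single-sample gene-set enrichment (ssGSEA) scorer is included
for transcriptome signatures of interferon response.

## Worked example

The package ships a 39-line melanoma reference cohort (11 BRAF-mutant, 10
NRAS-mutant, 10 BRAF/NRAS wild-type, 8 GNAQ/GNA11-mutant uveal lines) as
CSV fixtures: per-line relative MFIs of the five markers before/after 72 h
IFNγ, and sub-G1/G1/S/G2 phase percentages in both conditions.

```bash
ifnsig run --out results/
```

prints

```
complete responders: 13/39
minimal cell-cycle change: 23/38
```

meaning only 13 of 39 lines induce all five targets (two thirds of the
panel has a diminished IFNγ response), and 23 of the 38 lines with
cell-cycle data show no appreciable cell-cycle change under IFNγ.
`results/` then contains the per-line classification (folds, induced
flags, response class, mechanism flags — e.g. the B2M-loss pattern of an
MHC-I line that fails to induce while all other markers respond, and the
receptor-loss pattern of a global null responder), the baseline Spearman
correlation matrix, cutaneous-vs-uveal Mann–Whitney comparisons, and the
per-line cell-cycle effect calls. The same stages are available as library
functions and as `ifnsig simulate|gate|score|phenotype|cellcycle|stats|ssgsea`
subcommands.

Synthetic data with known ground truth comes from `ifnsig.synthetic`:

```python
from ifnsig import MarkerSimConfig, generate_marker_tubes, gate_events, \
    geometric_mfi, relative_mfi

stained, fmo = generate_marker_tubes(
    MarkerSimConfig(true_relative_mfi=4.3, n_events=20_000, seed=1,
                    dead_fraction=0.1, doublet_fraction=0.05))
rel = relative_mfi(geometric_mfi(gate_events(stained), "MARKER"),
                   geometric_mfi(gate_events(fmo), "MARKER"))
print(round(rel, 2))  # 4.29 — the true ratio 4.3 within Monte-Carlo error
```

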