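# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `trescreen`.  Notation: promoters are indexed by `p`,
barcodes by `j`, samples by `s`, conditions by `c`.

## Motif catalog

PWM seeds are IUPAC strings with an L×4 weight matrix (columns A,C,G,T).
Resolution is a strict two-pass procedure: (1) runs of the fully degenerate
code `N` are trimmed from both ends — only `N`, other degenerate codes at
the termini are kept; (2) every remaining degenerate position is replaced by
the base with the maximal PWM weight at that position.  Ties are broken
toward the alphabetically first base, which makes the catalog deterministic;
this tie rule is a package choice, not a biochemical statement.  An all-`N`
seed is an error ("empty motif"), as is a degenerate position whose PWM row
is all zero.

Deduplication removes any motif whose entire sequence occurs as a contiguous
forward-strand substring of another motif (e.g. `AAAAA` inside `CAAAAAC`).
Reverse-complement containment is *not* removed: the two orientations
present different binding-site arrays once multimerized, and collapsing them
is not clearly conservative.  Exact duplicates keep the first occurrence;
input order is preserved.

Negative controls are base-composition-preserving scrambles of experimental
motifs, redrawn until they differ from the source, are not
substrings/superstrings of it, and (optionally) contain none of the
restriction sites the oligo design must avoid.  Homopolymers cannot be
scrambled and are skipped with a warning.

## TRE-unit design

An experimental unit is assembled as

```
flank_5p | motif | spacer | motif | spacer | motif | spacer | motif
         | rotation segment | 3' filler | flank_3p
```

with a fixed total length of 160 nt (the synthesis length; configurable).

**Helical phasing.** The spacer length `s` is the smallest nonnegative
integer minimizing the circular deviation of `L + s` (motif length plus
spacer) from a half-integer number of helical turns,
`min_k |L + s − T(k + ½)|` with period `T = 10.5` bp/turn (canonical B-DNA;
configurable).  For integer lengths and `T = 10.5` the attainable minimum is
exactly 0.25 bp, so every adjacent motif pair in a designed unit deviates
from perfect anti-phasing by at most a quarter base pair.

**Configurations.** Each experimental motif yields 2 spacer sets × 3
rotations = 6 units.  Spacer sets are alternative random-sequence draws
(one rng seed per set); rotations insert 0/4/8 nt between the last motif
copy and the filler, turning the whole motif array by ≈0, ⅓ and ⅔ of a turn
relative to the downstream minimal promoter.  Negative-control motifs get a
single configuration; fixed commercial units pass through unmodified and
may exceed 160 nt.  Every unit is crossed with the three minimal promoters
(minTK, minProm, minCMV), so the promoter count is 3× the unit count.

**Restriction screening.** The assembled oligo is scanned for the cloning
enzymes' sites (MluI `ACGCGT`, SpeI `ACTAGT`, KpnI `GGTACC`, XbaI
`TCTAGA`); any occurrence outside the designed flank positions triggers a
redraw of the random segments (up to `max_redraws`, default 1000).  Two
structural safeguards make this terminate in practice:

- The shipped default flanks are 18-nt primer sites plus the cloning sites,
  with the bases adjoining the variable insert chosen (`…CC` / `GG…`) so
  that no forbidden site can span a fixed-flank/insert junction regardless
  of the insert sequence.  (18 nt rather than a more usual 20 so the worst
  case — a 20-nt motif at spacer 6 and rotation 8 — still fits in 160 nt.)
- If a site is unremovable at the phase-optimal spacer (the zero-spacer
  case, where two motif copies abut and may jointly spell a site), the
  designer escalates to the next spacer length with the same 0.25-bp phase
  deviation (`s + 10` or `s + 11` for `T = 10.5`) before giving up.

A motif that itself contains a forbidden site cannot be designed and raises
an error naming the motif.  Coordinates in unit layouts are 0-based,
half-open; rebuilding the oligo from its layout reproduces it exactly.

## Barcode dictionary

Dictionary sequencing reads the unit core (the oligo between the fixed
flanks) and the barcode from opposite ends of the amplicon.  An observed
unit read is assigned to the unique expected core within Levenshtein
distance 2 (via edlib); ties at the minimal distance are treated as
non-matches.  Distances are computed against the expected cores directly
rather than via a pre-clustering step — at desk scale the clustering used
by large production runs is purely a throughput device and does not change
the acceptance contract.  A barcode observed with two or more distinct
promoters — different units, or the same unit in pools carrying different
minimal promoters — is discarded entirely, which makes the final map
injective as a function.  Minimal-promoter identity is carried as pool
metadata on the read files, mirroring a library built in per-promoter
pools.

## Barcode counting

Counts per sample are tallies of the first 24 nt of each read.  Reads whose
24-nt prefix exactly matches a spike-in reference prefix are tallied
separately before anything else; reads shorter than 24 nt or with non-ACGT
characters in the prefix are dropped and counted.  The retained tally is
collapsed by greedy sphere clustering at Levenshtein radius 1: repeatedly
take the highest-count unassigned barcode (count ties broken
lexicographically) as a centroid and absorb all unassigned barcodes within
the radius.  This is the "sphere" mode of the standard message-passing
clusterers; the exact internals of those tools are not reproduced, but the
greedy contract is, deterministically.  Since all barcodes have equal
length, a radius-1 Levenshtein neighborhood reduces to Hamming distance 1,
which the implementation exploits with half-string bucketing (pairs within
distance 1 must agree exactly on one half).

A cluster is retained iff its centroid is a dictionary barcode and every
other member that is also in the dictionary maps to the same promoter; the
cluster's summed reads are assigned to the centroid.  Cluster totals
conserve reads by construction.

Sample QC is flag-only: a sample is flagged when its fraction of TRE
barcode reads (TRE / (TRE + spike-in + dropped)) falls below
`max(0.5 × cohort median fraction, 0.5)`.  Both constants are configurable;
no threshold is published for this rule, so the default is deliberately
permissive and no sample is ever dropped automatically.

## Quantification

RPM is `count × 10⁶ / sample total`.  The transcription-rate estimate per
promoter and RNA sample is the **aggregate ratio**
`Σ_j RPM_RNA(j) / Σ_j RPM_DNA(j)` over the promoter's dictionary barcodes;
when several DNA replicates exist they are averaged on the RPM scale before
the sum.  A promoter with zero DNA RPM is flagged undefined, never imputed.
The aggregate ratio is invariant to rescaling any sample's raw counts.

Depth factors are upper-quartile: `Q75(counts of s) / Q75(counts of
reference)` with linear-interpolation quantiles, computed after removing
barcodes that are zero in *every* sample while keeping the remaining zeros
(the edgeR upper-quartile convention).  The alternative of truncating to
each sample's nonzero counts (available via `nonzero_only=True`) couples
the effective quantile level to the sample's zero fraction, which biases
the factors of deeper samples and was measured to inject several percent of
coherent error under realistic depth variation; the adopted convention is
scale-equivariant.  The convention in force is recorded in the factors'
metadata.

Profile summaries use agglomerative clustering (Euclidean distance,
complete linkage) for row/column dendrogram orders, and a biplot from the
rank-2 SVD of the column-standardized matrix (rows get PC scores, columns
get loadings; constant columns are dropped with a warning, rows with
undefined values are dropped).

## Differential activity

Each promoter is tested separately on its barcodes' raw counts, capped at
the 100 barcodes most abundant in the plasmid DNA (ties broken
lexicographically).  The model is a joint negative-binomial fit over both
count matrices:

- DNA: `x_js ~ NB(mean = g_s · d_j, dispersion α_DNA)`
- RNA: `y_js ~ NB(mean = f_s · d_j · exp(β_{c(s)}), dispersion α_RNA)`

where `d_j` is the latent per-barcode plasmid abundance, `g_s`/`f_s` are
the upper-quartile depth factors of the DNA/RNA samples (computed once per
matrix; the batch structure of the libraries enters through them), and
`β_c` are condition effects.  Barcodes with all-zero DNA are excluded from
the fit.  The full model has one free `β` per condition; the reduced model
a single shared `β`; the LRT statistic `2(ℓ_full − ℓ_reduced)` is referred
to a χ² distribution with `#conditions − 1` degrees of freedom (Wilks).
The condition contrast is estimated on the natural-log scale and reported
in log₂.  FDR is Benjamini–Hochberg (the generic "FDR" of standard MPRA
analyses).

Numerical choices:

- **Joint rather than plug-in.**  Fitting `d_j` to DNA alone and plugging
  it into the RNA model charges the DNA estimation noise to `α_RNA`
  (measured inflation 0.20 → 0.28 at 3 DNA replicates × 80 reads/barcode),
  which makes the LRT conservative and costs roughly a third of the power
  at small effects.  The joint fit propagates DNA uncertainty properly and
  recovers the true dispersion.
- **Dispersion.**  `α_RNA` is estimated by profile maximum likelihood under
  the full model with a Cox–Reid adjustment (−½ log det of the observed
  information over the nuisance mean parameters `log d_j` and `β`), which
  removes the Neyman–Scott downward bias induced by one nuisance abundance
  per barcode; it is then held fixed for the reduced fit, which guarantees
  a nonnegative LRT.  Bounds: α ∈ [10⁻⁸, 50].  `α_DNA` is a bias-corrected
  method-of-moments estimate — it only controls how strongly the DNA counts
  pin the abundances, and the test is insensitive to its exact value.
- **Optimization.**  Alternating Newton updates — per-condition effects,
  then all `log d_j` in one vectorized step over the stacked DNA+RNA
  matrix, then an explicit 1-D step along the scale direction
  (`log d_j + c`, `β − c`), which is anchored by the DNA data only and is
  otherwise the slow mode of the alternation.  The dispersion profile is
  warm-started across evaluations.
- **Degenerate promoters.**  All-zero RNA (or no DNA-supported barcode)
  yields an undefined fold change, `p = 1`, and a flag; such promoters stay
  in the BH denominator.

Calibration, verified by simulation at study scale (2000 promoters, 80
barcodes, 3 replicates/arm, mean 80 reads/barcode, dispersion 0.2): null
p-values are uniform (KS test), the LRT statistic follows χ²(1), and no
false discoveries survive BH 5% in a typical null screen.

**A known property, not a defect:** upper-quartile depth factors are
computed from the observed counts, so when a sizeable fraction of promoters
responds in the *same direction*, the treated samples' quartiles rise and
the normalization absorbs part of the global response — measured at a
stable 24% of a 1.15-fold effect when 25% of promoters respond upward
(arm-level shift 0.034 ± 0.004 ln across seeds), which both shrinks the
apparent effects and shifts every null promoter coherently.  Real screens
respond in both directions, where the bias largely cancels — which is why
the generator's default draws effect direction at random — but any pipeline
normalizing by a data-derived quantile shares this behavior under one-sided
global responses (reproducible here with `effect_direction="up"`).

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
tested; defaults are chosen once to mirror a real plasmid screen:

| parameter | default | meaning |
|---|---|---|
| barcode representation | log-normal, mean 82 / median 65, floor 1 | barcodes per promoter in the plasmid library |
| copy proportions | Dirichlet(1) within promoter | skewed plasmid barcode shares |
| `dna_depth`, `rna_depth` | 80 | mean reads per barcode (RNA: at baseline rate 1) |
| `nb_dispersion` | 0.2 | NB dispersion of DNA and RNA counts (no published value; typical bulk-count overdispersion) |
| baseline rates | log-uniform over a 300-fold span | per-promoter transcription rates |
| `effect_size` | configurable multiplier | fold-change magnitude of responsive promoters |
| `effect_direction` | `both` | responsive promoters induce or repress with equal probability (`up`/`down` force one direction) |
| `sample_depth_sigma` | 0.15 | log-normal sd of per-sample sequencing depth |
| `substitution_error_rate` | 0.001 (≤ 0.05) | per-base substitution rate in barcode reads |
| `spike_in_fraction` | 0.05 | fraction of reads from spike-in references |
| barcode separation | pairwise Levenshtein ≥ 3 | read-level screens only |

RNA counts are `NB(rna_depth × copy share × n_barcodes × rate × effect ×
sample depth)`; DNA counts omit rate and effect.  Read-level simulation
additionally emits dictionary read pairs (unit core + barcode, error-free
by default), per-sample barcode reads with substitution errors, and
spike-in reads; everything is serialized as plain text (FASTA/FASTQ/TSV/
JSON) with the seed recorded, and identical seeds give byte-identical
outputs.  The ≥3-edit barcode separation floor makes radius-1 clustering
identifiable, as it is for random 24-mers at realistic library sizes.

Not emulated: PCR jackpotting, index hopping, quality-score error profiles,
UMI structure, batch-specific biases beyond per-sample depth.  Passing
tests on these simulations therefore demonstrate the pipeline's arithmetic
and statistical calibration under the stated generative model, not
robustness to those artifacts.

## Problem sizes

The default test suite runs the calibration checks at 2000 promoters with
6 null-simulation repeats, and the acceptance script at 20 repeats; the
sensitivity probe uses 2000 promoters (500 affected).  These sizes were
chosen to keep Monte-Carlo error on the reported proportions small relative
to the thresholds being checked while remaining desk-scale.

## Known limitations

- The differential model is an analogue of the gamma-Poisson convolution
  used by the established MPRA comparative tool: it matches that tool's
  design formulas, degrees of freedom, and Wilks-based p-values, not its
  likelihood bit-for-bit.
- Containment deduplication is forward-strand only.
- Heterotypic (mixed-motif) promoters, dose-response curve fitting, and
  quantification-mode (α/γ) decomposition are out of scope.
- The published flank/primer sequences of any specific library live in
  supplementary material; the shipped flanks are functional defaults and
  fully configurable.
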