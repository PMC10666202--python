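# Methods

## Coordinate model

All coordinates are 0-based half-open; BED is the native convention and
GTF (1-based closed) is converted at the parser boundary.  Midpoints of
even-length regions round down.  Genes with several annotated transcripts
collapse to one record at the 5'-most TSS by default (`collapse=False`
keeps all distinct TSSs); one row per gene matches the expression table,
which is keyed by gene id.  The 500 kb candidate bound is inclusive and is
measured from the *original* element midpoint to the TSS, before the
500 bp extension.

## Bin-track conventions

Tracks live on a fixed 100 bp grid.  Bins absent from a track are treated
as `(p_active = 0, p_enh_given_active = 0)` with a logged warning: absent
signal is read as inactive rather than as an error, which keeps sparse
tracks usable.  A 500 bp region aligned to the grid covers exactly five
bins; a misaligned region overlaps six, and the five with the largest
overlap are kept — the two flanking bins tie at 50 bp each, in which case
the rightmost is dropped.  This tie rule is a documented implementation
choice, not an inference about any upstream tool's behaviour.

The two-stage activity model shipped here (random forests for
active-vs-inactive and enhancer-vs-promoter-given-active, fixed seeds) is
a self-contained learner over per-bin signal matrices.  It exists so the
pipeline can be exercised end to end from simulated histone-signal
matrices; ChIP-seq read counting, normalisation and peak calling are out
of scope.

## Regulatory distance

The window of a pair is the open interval between its two extended 500 bp
regions, snapped inward to the grid so that no bin partially overlapping
either region is counted (this avoids double-counting element bins in
both the region profile and the window).  The count is of bins with
channel probability strictly above 0.5; the normalised value divides by
the window's bin total, with the empty window defined as (0, 0) — "no
regulatory activity between" is the natural meaning of an empty window.

## Cross-biosample statistics

Activity rules per panel: expressed (`signal > 0`) for CAGE; top quartile
(exactly `ceil(0.25·n)` biosamples, ties broken by value then biosample
index) for the two DNase panels; mean probability strictly above 0.5 for
the activity-probability panel.

The rank-sum test is one-sided with alternative "target signal greater in
enhancer-active biosamples" — the direction the features are designed to
detect.  Groups with both sizes ≤ 8 are tested by exhaustive enumeration
of all assignments of the pooled midranks; larger groups use the normal
approximation with tie and continuity corrections.  An empty group makes
the test undefined and returns p = 1.

Fisher's combination uses the natural logarithm (so does the reported
negative log).  An element missing from a panel's matrix counts as *not
measured*: that panel drops out and the chi-square degrees of freedom
shrink (k measured panels → df 2k).  A present all-zero row, by contrast,
is a valid measurement.  p-values are clamped at 1e-300 before taking
logs so the feature stays finite.

`cor_CRUP` is an ordinary Pearson correlation of per-cell-type EP sums vs
PP sums; zero variance in either vector yields 0 (no evidence), and a
pair absent from the cross-cell-type panel also scores 0 with a warning.

## Classifier

Gradient-boosted trees with the logistic objective, deterministic
histogram tree method, single thread.  Presets: `gm12878_optimized`
(depth 5, 300 trees, lr 0.1, colsample 0.7, gamma 1.0, lambda 0,
subsample 0.9) and `lcl_final` (depth 10, gamma 0.25, lambda 1, otherwise
identical).  `scale_pos_weight` defaults to 5; seed defaults to 0.  The
full 300 rounds are always run — no early stopping, reproducing the fixed
configuration.  Models persist as the backend-native JSON plus a sidecar
manifest (feature names, config, training-data fingerprint) so the
feature-name contract is enforced on load.

Weight importance is the normalised split count per feature.  LOFO
retrains the model without each feature (or named group of correlated
features) on identical folds and seed and reports the change in pooled
out-of-fold F1; removing every feature degenerates to a majority-class
predictor, which under imbalance predicts no positives (F1 = 0).

## Cross-validation and curation

Chromosome folds are built greedily: chromosomes sorted by descending
pair count (ties by name) are assigned to the currently lightest fold.
The published benchmark's exact chromosome→fold mapping is data, not
algorithm; a user-supplied mapping can replace the greedy one.  F1 is
computed at the strict 0.5 threshold; AUPRC uses step-wise precision
interpolation (average precision).  Curation: positives must have an
expressed target (TPM > 0, strict); negatives are kept only when they
share a TSS or enhancer with a positive; consensus merging keys pairs by
(enhancer, gene), lets a positive in any source win, and subsamples
negatives (seeded, without replacement) to a required negative:positive
ratio — the ratio is a required argument because no canonical value
exists.

## Synthetic universe

Defaults, chosen once as a realistic desk-scale regime: 23 chromosomes,
300 genes × 3 enhancers each (≈900 designated pairs; the acceptance runs
use 667 genes ≈ 2000 pairs), positive fraction 0.2 (≈1:4, consistent with
the ×5 positive weight), 64 biosamples per panel (a scaled-down stand-in
for public panels of 66–848 biosamples), 104 cell types in the
correlation panel, element lengths 150–350 bp.

Noise model: per-chromosome logit fields are Gaussian white noise smoothed
with a σ = 3-bin kernel (unit variance preserved), so neighbouring bins
correlate as real tracks do; baseline `logit P(active) = −2.5` gives ≈8%
background activity.  Panel signals are log-normal (the CAGE panel
zero-inflated at 50%), activity-probability panel rows Beta(2, 5).

Planted effects for positive pairs, each with its own dial (0 = absent):
`ep_shift`/`pp_shift` (+6 on the logit at the enhancer/TSS bins),
`expression_shift` (+8 TPM-scale, guaranteeing expressed targets),
`panel_shift` (target signal ×(1+3) in enhancer-active biosamples, with
positive enhancers genuinely active in ~30% of biosamples in the
probability panel), `rd_suppression` (−2 logit in the window),
`distance_decay` (positive distances ~ 5 kb + Exp(100 kb), capped at
450 kb; 0 falls back to the uniform null draw), and `crossct_rho` (latent
shared factor giving EP/PP sum correlation ≈0.8 before clipping).  One
association per gene is planted in the panels (via its first positive
enhancer), so genes with several positive enhancers behave like real
pleiotropic targets.  `SimConfig.null()` zeroes every dial, making the
label assignment pure noise.

What the simulation does *not* emulate: mapping artefacts, copy-number
and GC biases, assay-specific noise floors, correlated negatives from
shared TADs, or realistic gene/enhancer density variation.  Passing tests
therefore demonstrate that the implementation recovers the signal
structure the features target — not field performance on real data.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline at ≈2000 pairs
with 12 folds, and smaller unit fixtures at ≈140 pairs — sizes chosen so
the planted-signal statistics are stable while the whole suite stays
fast.  Determinism: every random draw flows from a single generator seed;
xgboost uses the histogram method on one thread; file writers emit
round-trippable decimal floats, so rewriting a bundle or feature table is
byte-identical.

## Known limitations

* The two-stage activity model is a generic learner, not a reproduction
  of any published track-caller's feature engineering.
* The asymptotic rank-sum branch differs from exact enumeration by up to
  ~0.01 in p near the cutoff sizes; Fisher combination treats the four
  panels as independent, which real panels only approximate.
* Performance numbers on synthetic data (AUPRC ≈ 1 in strong mode) are a
  correctness check of the pipeline, not a forecast of real-data F1.
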