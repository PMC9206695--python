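# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of `huangjiu-core`.

## Semiquantification

Concentrations come from a single-point internal-standard relation,

    C = d · (A_c / A_is) · C_is        [µg/L]

with analyte and internal-standard peak areas `A_c`, `A_is`, the in-vial
internal-standard concentration `C_is`, and a vial dilution factor `d`.
For the reference protocol — 0.5 mL sample plus 5.44 mL ethanol and
60 µL of 8800 µg/L 2-octanol, 6.0 mL total — the in-vial concentration
is `C_is = 8800 × 60/6000 = 88 µg/L` and `d = 6.0/0.5 = 12`.  Both are
configuration fields (`QuantConfig`), never hard-coded: the factor 12 is
a volume-ratio reconstruction, and other protocols will differ.  The
method is semiquantitative — one internal standard, no per-compound
response factors or calibration curves — so concentrations are
comparable across samples, less so across compounds.

"Not detected" (ND) is an explicit mask everywhere.  A timepoint summary
is ND only when every replicate is ND; the mean is taken over detected
replicates and SE = SD/√n needs at least two.  Detection counts are
taken over the 6 timepoint summaries, not the 18 replicate injections; a
compound is *stable* at ≥ 5 detections (`min_detections`, configurable).
The high-content filter uses a strict inequality (> 1000 µg/L at some
timepoint).  Compound-class calls (straight-chain saturated
alkan-1-ols) are table-driven from a packaged annotation keyed
case-insensitively, not parsed from names.

## Diversity

Simpson is reported in dominance form `D = Σ pᵢ²` (larger = less
diverse); the complement `1 − D` is an option.  Chao1 uses the
bias-corrected estimator `S_obs + F₁(F₁−1)/(2(F₂+1))`, defined even
without doubletons; the classical form `F₁²/(2F₂)` is available and
raises on `F₂ = 0`.  Chao1 needs integer counts and is skipped for
relative-abundance tables.  Rarefaction is out of scope.

## Association networks

All-pairs Pearson correlation with two-sided p-values from `t = r·√((n−2)
/(1−r²))` on n−2 degrees of freedom, BH step-up FDR (via statsmodels)
and a significance gate at p ≤ 0.05 (and q ≤ 0.05 when FDR is on).
`|r| > 0.95` sets a *robust* flag but never filters: both gates are
independently switchable because different analyses legitimately report
raw-p, adjusted-p or r-thresholded edge sets.

ND concentrations enter correlations as 0 by default (absence of a
compound is signal); `drop-pairwise` excludes ND samples per pair.
Samples can be matched at replicate level (n = 18) or on timepoint means
(n = 6).  The `AssocConfig` default is replicate-level; **the pipeline's
correlation gate defaults to timepoint means**, because the three
parallel mashes are technical replicates sharing a timepoint mean — at
replicate level the effective sample size is ~6, and n = 18 p-values
overstate the degrees of freedom, admitting chance edges.

## O2PLS

The two-way orthogonal PLS decomposition

    X = T Wᵀ + T_o P_oxᵀ + E_x ,   Y = U Cᵀ + U_o P_oyᵀ + E_y

is fit by: (i) joint loadings W, C from the leading singular triplets of
XᵀY; (ii) for each of nx (ny) orthogonal components, the dominant
direction of the joint-score-predicted-but-loading-orthogonal part of
the block is extracted and the block deflated; (iii) joint parts are
recomputed on the deflated blocks and the inner relation B is the least
squares regression of U on T.  Loadings have unit-norm columns; the
element of largest magnitude in each column is made positive so fits are
sign-deterministic.  Invariants checked by the test suite: joint scores
are exactly orthogonal to the block's orthogonal scores, and joint +
orthogonal + residual sums of squares reconstruct each block's total to
1e-6 relative.

Block scaling follows the standard two-block preprocessing: mean-center
both blocks by column, scale the metabolite (Y) columns to unit
variance, then scale each block to a total sum of squares of 1.  A
z-score mode (every column centered and unit-variance) exists as an
alternative.  We deliberately do **not** z-score the taxa block in the
pipeline: equalizing taxon variances drowns genuinely covarying
high-abundance genera in the aggregated chance correlation of the many
rare genera.

### Permutation test

The null reshuffles the rows of Y (a seeded permutation per iteration,
default 1000), breaking the X–Y sample linkage while preserving each
block's internal structure, and refits the model.  Permuted loading
vectors are sign-aligned to the observed component (sign of the dot
product) and pooled per component and side into one empirical null;
a variable is significant when its observed loading falls below the α/2
or above the 1−α/2 quantile (inclusive, type-7) in *any* joint
component.  Pooling across variables is necessary: per-variable nulls at
1000 permutations would make the α/2 = 0.025 tail unresolvable.

Two calibration caveats, both verified by tests:

* Per component the flagged fraction calibrates to α under an
  exchangeable null (the acceptance suite checks 20 runs × 200
  permutations against 3 binomial SE).  The union over n components
  grows with n, so the calibration statement is per-component (n = 1 in
  the check).
* Pooling assumes comparable loading scales across variables.  Without
  column variance scaling, very-high-variance variables (the dominant
  genus) have wider individual nulls than the pool and are flagged more
  often than α; downstream gates (abundance + stable-HA correlation)
  absorb this in the pipeline.

Component counts are not prescribed by the method; defaults are n = 2
joint and nx = ny = 1 orthogonal components, all settable.  The packaged
demo uses n = 7: one joint dimension per potentially driven HA-side
direction (5 planted producer–HA pairs) plus headroom for compositional
nuisance — at exactly the planted rank, the dominant genus's chance
covariance can displace the weakest producer's component, and the
permutation null calibrates the extra components at no cost.

## Core selection

A genus is core when it passes every enabled gate: permutation
significance (on by default), top 20% of mean relative abundance
(ceiling of `fraction × n_taxa`, ties broken lexicographically so the
set size is deterministic), and at least one significant correlation
with a stable HA.  The correlation gate uses adjusted p when the
association stage ran with FDR, raw p otherwise.  Evidence per genus
(abundance rank, loadings verdict, supporting edges) and full
provenance (config echo, seed, input hashes) are part of the report.
The stability requirement is "≥ 1 stable HA linked", not "all linked
HAs stable".

## Synthetic data

The generator emulates a 10-day fermentation sampled every 2 days in
triplicate: 6 timepoints × 3 replicates, 50 genera.  Structure:

* **Producers** (default 5) follow smooth templates — logistic growth or
  a Gaussian bump, chosen per taxon by the seeded RNG — normalized to
  unit mean so a producer's baseline (log-uniform 0.02–0.05) is its mean
  abundance, placing producers in the top abundance stratum by
  construction.
* **Background genera** draw i.i.d. log-normal timepoint means (SD 0.5
  in log space) around constant baselines (log-uniform 1e-4–1e-2).
* **The dominant genus** holds a target share of the community with
  log-normal jitter (SD 0.2) on its odds.  The target sits slightly
  above the requested floor (`f + 0.15(1−f)`) so the floor survives
  noise; through compositional closure its upward fluctuations suppress
  every other genus, reproducing the mostly negative co-occurrence edges
  of a dominance-structured community.
* **Replicates** share the timepoint mean and differ only by
  multiplicative log-normal noise (`noise_sd`, default 0.1 — roughly
  proportional error, as in GC-MS and compositional sequencing data).
* **HAs**: driven HAs are exact linear maps of producer relative
  abundance (slope `effect_size × 20 000 µg/L` per unit relative
  abundance) times the same multiplicative noise; undriven HAs are pure
  log-normal noise around small baselines (~50–500 µg/L).  Values below
  the detection limit are masked ND at generation time.
* **Peak tables** invert the quantification relation at a fixed
  internal-standard area, so quantify ∘ generate is the identity on
  concentrations to floating-point precision.

What the generator does *not* emulate: sequencing count noise and
sparsity, taxon–taxon ecological interactions beyond closure, nonlinear
or lagged production kinetics, HA degradation, batch effects.  Passing
tests therefore demonstrate that the chain recovers linear,
contemporaneous producer signals under compositional constraints — not
that it would resolve the harder confounding of real fermentations.

## Problem sizes and determinism

Default study sizes mirror the emulated design (18 samples, 50 genera,
10 HAs); the permutation test uses 1000 reshuffles as in the reference
procedure, 200 in the repeated calibration checks (20 independent runs).
End-to-end recovery is measured over 20 generator seeds: mean producer
recall and mean decoy precision both ≥ 0.9 under the demo conditions.
Every stochastic step takes an explicit seed through
`numpy.random.default_rng`; identical config + seed reproduce every
artifact bit for bit.

## Known limitations

* Six timepoints bound the effective sample size; correlation p-values
  at timepoint level have 4 degrees of freedom and limited power.
* The pooled permutation null is anti-conservative for extreme-variance
  variables (see above).
* Pearson correlation on relative abundances ignores compositional
  coupling (no SparCC-style correction; out of scope).
* The semiquantification carries no compound-specific response factors,
  so cross-compound comparisons (totals, high-content calls) inherit
  that approximation from the underlying protocol.
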