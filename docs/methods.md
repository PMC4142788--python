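# Methods

## Lesion definition

Acute tissue dysfunction is modeled as the union of two binary sources on
a shared, mirror-symmetric template grid:

* the **infarct core** (an input mask, drawn upstream from DWI/ADC), and
* **hypoperfusion**, defined per voxel by interhemispheric time-to-peak
  (TTP) asymmetry: voxel `v` on the analysis hemisphere is hypoperfused
  when `TTP[v] − TTP[mirror(v)] > 4 s`. The 4-second threshold is the
  PET-validated cutoff for dysfunctional tissue used in acute perfusion
  studies; the inequality is strict.

The homolog `mirror(v)` is the reflection of the voxel index across the
grid midplane, which requires an even voxel count along the midline axis
so that no voxel is its own homolog. Only analysis-side (left-hemisphere,
lower-index half by convention) voxels are ever marked: the comparison is
left-against-right, not bidirectional. Voxels whose homolog falls outside
the brain mask are excluded. Patients lacking a TTP map degrade gracefully
to infarct-only masks with a logged warning.

The voxel count of each dysfunction mask is the *functional lesion
volume*, the covariate used everywhere downstream.

## Phenotypes

AOS status is a pure count rule over four subtest abnormality flags
(3–4 abnormal → AOS, 0–1 → no AOS, exactly 2 → indeterminate). How each
flag was scored from speech samples is upstream of the package: flags are
inputs, because consensus clinical scoring is not computable. Forward
digit span follows the two-trials-per-length protocol: testing stops at
the first length with both trials failed; the span is the longest length
with at least one pass; trials recorded past the stopping point are
ignored; a record with no trials yields an *undefined* span (excluded
pairwise from span analyses, not coerced to 0). Impairment is span < 5;
aphasia is WAB AQ < 93.8 (both strict).

## Cohort statistics

The AOS × vSTM association uses the Pearson χ² closed form
`n(ad−bc)² / ((a+b)(c+d)(a+c)(b+d))` on the 2×2 table, uncorrected by
default (a Yates-corrected variant is available); any zero margin is an
error, not a silent zero. The span-by-AOS comparison is an OLS ANCOVA
`span ~ 1 + AOS + volume`; the group term is tested as the squared
coefficient t (equivalently a Type-III F) on (1, n−3) df, and adjusted
means are evaluated at the grand covariate mean. When the covariate is
constant the fit degenerates to a one-way comparison whose F value is the
one-way ANOVA F, still reported on (1, n−3) — the covariate's df cost is
kept so that the reporting structure is invariant.

## Voxelwise mapping and permutation correction

The behavioral score is residualized on functional lesion volume **once**;
the identical residual vector (observed, or permuted under the null) flows
through one shared code path. This "residualize-then-permute" scheme keeps
the covariate adjustment exactly symmetric between observed and null
statistics and keeps per-voxel cost flat.

At each voxel with at least `min_lesion_count` (default 5) patients in
both the lesioned and intact groups, a pooled-variance two-sample t is
computed, sign-oriented so that t > 0 means the lesioned group performs
worse. Binary phenotypes enter as 0/1 performance scores. Voxels failing
the count filter are invalid and excluded from clustering. Zero-variance
voxels with a nonzero group difference are flagged degenerate and assigned
the smallest positive double as p (they are maximally significant in
substance); they are *not* dropped.

Suprathreshold voxels (p < 0.01 two-sided, default) are grouped by
26-connectivity (configurable to 6 or 18). The permutation null permutes
the score vector across patients while lesion masks stay fixed, preserving
the anatomy's spatial covariance. Two null-pooling modes:

* `pooled` (default): every null cluster size across all permutations
  enters one pool — the literal reading of "larger than 95% of the
  significant clusters in the random permutations". This does not strictly
  control FWER.
* `max_per_permutation`: one maximum per permutation (0 when none) — the
  standard FWER-controlling variant.

The size threshold is the 95th percentile (linear interpolation) of the
null sizes; observed clusters pass on a strictly-greater comparison. Ties
on small integer sizes make the procedure slightly conservative; measured
FWER on null simulations (100 cohorts × 500 permutations, n = 200, 16³
grid, max-per-permutation) is 0.01–0.05. If no permutation produces any
cluster the threshold is 0 (logged). All permutation randomness derives
from the config seed; identical configs give bit-identical reports.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, at desk scale
(default 24³ grid, left hemisphere = 6912 voxels, 76 patients):

* **Lesions** are 26-connected masks grown by stochastic accretion from a
  seed voxel, with log-uniform target sizes (default 20–150 voxels) —
  right-skewed like real stroke volume distributions. Seeds are drawn from
  a dilated neighborhood of the critical regions with probability 0.8
  (else uniformly over the hemisphere), emulating the perisylvian
  concentration of middle-cerebral-artery infarcts that gives real cohorts
  their coverage peak.
* **Perfusion**: TTP is a constant baseline (15 s) plus a 6 s delay over
  the infarct and a stochastic perilesional halo (each 26-neighbor shell
  voxel hypoperfused with probability 0.3). Because 6 > 4, the lesion
  definition stage recovers the true dysfunction mask exactly — a designed
  identity used by the tests.
* **Deficits** are caused by *coverage* of planted critical regions (two
  overlapping spheres, 257 and 179 voxels, 78 shared), not single voxels:
  deficit iff coverage > θ (defaults 0.15 / 0.16), flipped with
  probability ε = 0.02, plus a logistic lesion-size confound
  (γ·expit(6(u−0.5)), γ = 0.08 / 0.06, u = scaled lesion volume) injected
  deliberately so the covariate stage has something real to remove.
  Defaults were calibrated once so expected prevalences match the modeled
  cohort: measured 22.3% AOS (reference 17/76 = 22.4%) and 19.3% span
  impairment (reference 15/76 = 19.7%) over 40 cohorts.
* **Behavior** is generated to reproduce the assigned phenotypes exactly
  under the scoring rules (flag counts 3–4 vs 0–1; trial sequences that
  score to a target span below/above 5).

What the generator does **not** emulate: vascular-territory lesion shapes,
registration error, perfusion deconvolution physics, graded behavioral
severity, or inter-rater noise in flag scoring. Passing recovery tests
therefore show that the *inference machinery* is correct and calibrated,
not that any particular anatomical claim about real patients would
replicate.

## Numerical and scale choices

* Group sums for the vectorized t map are computed per permutation block
  (chunks of 128) as matrix products; sums of squares are clipped at 0
  against cancellation error. Agreement with an independent scalar
  two-sample t is verified to 1e-10.
* Statistic maps are written with invalid voxels encoded as 0 plus a
  companion validity volume (no NaNs); infinite (degenerate) t values are
  written as the largest finite double.
* Validation runs use 500 permutations and the following sizes, chosen to
  make the Monte-Carlo bands tight enough to be meaningful: FWER at 100
  null cohorts × 500 permutations; planted-region recovery at 20 cohorts
  of n = 150 (noise-free, ε = γ = 0), where both maps reach Dice ≥ 0.5
  against their true regions in ≥ 95% of cohorts and the map overlap
  intersects the planted shared sub-region. Full set-coverage of the
  shared sub-region is not expected: cluster correction trims region
  edges, so the meaningful overlap check is locational.
* Dice of two empty masks is defined as 0 (warned), avoiding 0/0.

## Known limitations

* The χ² statistic is the asymptotic Pearson form; no exact test for
  small cells (margins of the modeled cohort are large enough).
* The binary-outcome t-test treats 0/1 AOS as numeric, by design; a
  Liebermeister-style exact voxel test is out of scope.
* The pooled null mode is faithful to the classic description but
  anticonservative; use `max_per_permutation` when strict FWER control
  matters.
* Single-voxel homolog mirroring assumes perfect template symmetry; no
  neighborhood-based homolog matching is implemented.
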