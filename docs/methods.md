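# Methods

This note records the statistical model, the numerical choices, and the
design decisions behind `ftirdx`, in the spirit of a model-description
vignette. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and conventions

A dataset is a wavenumber axis (cm⁻¹, stored descending, near-uniform grid)
plus an absorbance matrix with per-spectrum metadata: specimen id,
replicate index, and one of six ordered histological classes (normal,
inflammatory, Barrett's, LGD, HGD, OAC). Replicate point spectra of one
specimen are averaged **before** modelling, so that sample counts, split
sizes and confusion-matrix rows are per specimen (35/13/26/4/9/22 for the
default study shape). Modelling replicates individually is possible
(`run_mccv_dataset(average=False)`) but non-default: per-specimen counts
are what the reported confusion tables are denominated in, and replicate
spectra of one specimen are strongly correlated, so treating them as
independent samples would overstate the effective sample size.

Interval operations (fingerprint cut, amide window) use closed intervals in
cm⁻¹ with a ~1e-9 relative edge tolerance, so the closed-interval semantics
survive floating-point grid construction. On the default grid
(4000→600 cm⁻¹ at 300/78 ≈ 3.846 cm⁻¹, i.e. an 8 cm⁻¹-resolution
instrument with 2× zero-filling), the [900, 1800] cut retains exactly 235
wavenumbers.

## Pre-treatment

1. **Cut** to 900–1800 cm⁻¹ — a pure column selection.
2. **Rubber-band baseline**: the baseline is the lower convex hull of the
   points (ν, A(ν)) between the two spectral endpoints, computed by a
   monotone-chain scan; the corrected spectrum is exact zero at every hull
   vertex, non-negative elsewhere, and the operation is idempotent.
   This is the canonical single-iteration hull form, with no added support
   points; the method is conventionally named after stretching a rubber
   band under the spectrum.
3. **Amide I normalisation**: division by the maximum absorbance inside
   1600–1700 cm⁻¹ (peak-height, not area, normalisation — the band is
   referred to as a *peak* and peak-height is the common instrument-software
   meaning). A window maximum ≤ 0 is a hard error, not silently skipped.

Baseline correction and peak normalisation together cancel any positive
per-spectrum scaling, which is why this chain (rather than, say, vector
normalisation) suits contact-pressure-sensitive ATR data.

## QDA with shrinkage

The discriminant score is
`Q_ik = (x−x̄_k)ᵀ Σ_k⁻¹ (x−x̄_k) + log|Σ_k| − 2 log π_k`, minimised over
classes; it equals −2 log(π_k φ_k(x)) up to an additive constant shared by
all classes, so the rule is the Gaussian-posterior argmax. Scores are
computed through Cholesky factorisations, never an explicit inverse.

With classes as small as 4 specimens on 6–25 variables the raw class
covariance is singular. Each Σ_k is therefore shrunk toward the pooled
within-class covariance, `Σ_k ← (1−λ)Σ_k + λΣ_pooled` with λ = 0.5 by
default (λ = 1 recovers LDA-like shared covariance), plus a trace-scaled
ridge (1e-8 · trace/d) only if the shrunk matrix still fails a Cholesky
factorisation. Priors are empirical class frequencies by default (the score
contains an explicit prior term); uniform or user-supplied priors are
options. Exact score ties are broken toward the larger prior, then the
earlier class in training order.

## PCA front-end

PCA-QDA fits a mean-centred PCA on the training spectra and hands the
scores to QDA. Component signs are fixed by making the largest-magnitude
loading entry positive, so refits are deterministic. The default keeps
**exactly six components**, the standard operating point for this kind of
tissue study. A cumulative-variance-target rule (smallest m reaching a
target, with an optional cap) is implemented and configurable, but is not
the default: on band-structured synthetic spectra the leading one to three
components already exceed a 93.5% target while the contrasts that separate
the rare dysplasia classes (a few percent of total variance, because those
classes are small) live in later components — a variance target silently
discards them, whereas the fixed six-component front-end retains every
class-mean direction of a six-class problem.

## Risk cost G and wavenumber selection

For a validation spectrum, g_n is the squared Mahalanobis distance to its
own class mean divided by the distance to the nearest wrong-class mean;
G is the mean of g_n. Distances use class means from the training split
only and, by default, the pooled within-class covariance over the candidate
variables (robust when the smallest class has 2–3 training specimens);
per-class covariances with shrinkage are an option, and in that mode G is
invariant under invertible linear maps of the variables. A validation
spectrum that coincides with a wrong-class centre has infinite risk and is
flagged; this also makes degenerate zero-variance variables (e.g. the exact
zeros the rubber band leaves at the spectral endpoints) unselectable, since
every class centre collapses to the same point there.

**SPA** seeds a chain at every wavenumber, repeatedly appends the column
with maximal norm after projection onto the orthogonal complement of the
chosen columns, scores every prefix of every chain with G, and returns the
(start, length) minimiser — deterministic given its inputs. **GA** evolves
binary inclusion masks: tournament selection of size 2, single-point
crossover at probability 0.60, per-bit mutation at 0.01, one elite carried
over unchanged (making the best-so-far trace non-increasing), random-bit
repair of chromosomes outside the configured variable bounds, 100
generations of 200 chromosomes, and three independent restarts with the
best restart returned. The encoding, selection scheme, elitism and repair
are the simplest canonical choices consistent with a chromosome-based
selector; all are recorded in the run manifest. The number of selected
variables is unbounded by default (bounds are configuration options).

Inside a fitted Pipeline, both selectors carve an internal stratified
70/30 split from their training data to provide G's validation spectra,
with a seeded generator; selection therefore never sees the outer
validation specimens.

## Monte Carlo cross-validation

Each iteration holds out round(0.2·n_k) specimens per class (at least one
training specimen always retained; LGD with n = 4 holds out exactly one),
refits the *entire* model — PCA or wavenumber selection included — on the
training 80%, and predicts the held-out specimens. Refitting selection
inside the loop avoids the optimistic bias of selecting variables on data
that later serves as validation; a `selection_once` switch provides the
legacy protocol (front-end fitted once on all data) for comparison.
Iteration failures are counted and skipped; more than 5% failing aborts.

Two summaries are reported: (a) the accumulated confusion counts rescaled
so each row sums to the class specimen count, integerised by the
largest-remainder rule (row sums conserved exactly) — the "average
validation output" convention of published confusion tables; and (b) the
mean and standard deviation of each per-iteration figure of merit.
Sensitivity, specificity and F-score are one-vs-rest per class; empty
denominators yield NaN ("undefined"), never 0.

## Bootstrap robustness and band confirmation

The misclassification probability bootstrap resamples specimens with
replacement within each class, refits the model, predicts the out-of-bag
specimens, and reports the mean over specimens of each specimen's
out-of-bag misclassification rate. Specimens never out-of-bag (rare for
a few hundred replicates) are excluded with a warning. Under permuted
labels with six balanced classes the estimate sits at chance, 5/6.

Selected wavenumbers are confirmed by a two-tailed Mann–Whitney rank test
per wavenumber between a class pair: exact null distribution when both
groups have ≤ 8 specimens, normal approximation with tie correction
otherwise; p-values are reported raw and flagged at 0.05 (optional
Benjamini–Hochberg is deliberately not applied by default, matching common
practice in this literature of reporting uncorrected band-level tests).
Constant values across both groups report p = 1 with a degeneracy flag.

## Synthetic data generator

Each spectrum is a sum of six Gaussian bands at wavenumbers with
established tissue assignments (1745 lipid ester, 1690 nucleic acid,
1640 amide I, 1540 amide II, 1393 methylene, 1225 phosphate), plus a
random linear + quadratic baseline, a multiplicative replicate gain
(sd 0.02), and additive white noise (sd 0.004 in units where amide I ≈ 1).
Specimen-level biology is a log-normal factor per band (sd 0.025 — small
relative inter-specimen band-ratio variation, keeping absorbances
positive). Amide I is identical across classes, so normalisation is
well-posed and carries no class information.

Class identity enters through per-band amplitude offsets. The five
informative bands carry mutually near-orthogonal class-contrast patterns of
comparable magnitude, with monotone disease-stage trends on the nucleic
acid (1690) and phosphate (1225) bands. Near-orthogonality is deliberate:
it spreads between-class variance over several principal directions, as in
real tissue data where independent biochemical constituents vary, rather
than collapsing all six classes onto one progression line. Two knobs set
the difficulty: `separation` (s) scales all between-class offsets (s = 0:
classes identical, downstream accuracy at chance; s = 10: fully separable),
and `overlap` (o) pulls the inflammatory amplitude means toward the normal
ones (o = 1: identical — confusion confined to that 2×2 block). Defaults
s = 5, o = 0.8 reproduce the qualitative published pattern: perfect
separation of Barrett's through OAC with partial normal/inflammatory
confusion.

What the generator does **not** emulate: ATR penetration-depth dispersion,
Mie scattering, paraffin residues, correlated (pink) instrument noise,
water-vapour lines, or real within-specimen heterogeneity (replicate
variation is i.i.d.). Passing tests therefore demonstrate correctness of
the algorithms and the qualitative class-structure behaviour, not clinical
performance; the published real-data accuracies (90.9/86.4/63.6%) are
descriptive values for a dataset that is not publicly deposited and are
not reproduced here.

## Problem sizes and runtime choices

The test suite and acceptance script use desk-scale problem sizes chosen as
package defaults for routine verification: 100 Monte Carlo iterations
(the 1000-iteration default remains for full runs), GA settings of 10
generations × 30 chromosomes × 1 restart with at most 8 variables when the
GA is refitted inside every cross-validation iteration, and 100–150
bootstrap replicates. The full-size GA (100 × 200 × 3) is exercised once on
an 8-wavenumber problem, where its solution is checked against exhaustive
search over all 255 subsets. Monte Carlo means at these sizes carry
standard errors of a few tenths of a percentage point, which is the
resolution at which results should be read.

## Known limitations

* The G-cost's pooled covariance default means SPA/GA selection geometry
  differs from the per-class QDA geometry used at prediction time; this is
  intentional (stability for tiny classes) but means the selector does not
  optimise exactly the deployed classifier's risk.
* The bootstrap misclassification estimator is the generic out-of-bag
  form; published variants differ in detail and published probability
  values are not comparable across estimators.
* Exact QDA score ties are broken deterministically, but ties are
  measure-zero except in degenerate constructed cases.
* The wide CSV reader loads the whole file into memory; datasets are
  assumed to be laboratory-scale (thousands of spectra), not imaging-scale.
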