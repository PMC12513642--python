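# Methods

`gyroshape` analyzes per-repetition wrist-gyroscope angular-velocity curves
— arm curls and knocking motions recorded from children with Duchenne
muscular dystrophy (DMD), spinal muscular atrophy (SMA), and healthy
controls — by separating *when* a movement happens from *what shape* it has,
and then linking the shape variation to clinical measures.

## Elastic registration

A repetition is a scalar curve β(t) on a uniform grid.  All repetitions are
resampled to a common grid of N = 200 points on [0, 1]; rescaling time loses
nothing because the gyroscope measures a rate, so speed information survives
in the curve's amplitude.

Registration works in the square-root velocity representation
q = sign(β′)·√|β′|, computed with centered differences (one-sided at the
endpoints; an optional Hann pre-smoothing flag exists for rough inputs and
is off by default).  Under a boundary-pinned increasing time warp γ the SRVF
transforms as (q∘γ)·√γ′, an isometry of L2, so the optimal alignment of
curve 2 to curve 1 minimizes ‖q₁ − (q₂∘γ)√γ′‖ and the attained minimum is
the amplitude distance d_a, invariant to warping of either curve.

The minimization is solved in two stages:

1. **Dynamic programming** over monotone lattice paths with local slopes
   p/q, 1 ≤ p, q ≤ 3 — a standard elastic-FDA lattice balancing accuracy and
   cost.  Exact cost ties prefer the path nearest the diagonal, so the
   least-warped minimizer is returned deterministically.  Segment costs use
   per-segment trapezoid quadrature with linear interpolation of q₂.
2. **Smooth local refinement.**  The lattice quantizes γ′ to the seven
   admissible slopes, which caps the attainable misfit at several percent of
   ‖q‖ (the √γ′ factor jumps between quantized levels).  The DP path is
   therefore Hann-smoothed and refined by L-BFGS over log γ′ sampled at 20
   uniform knots (linearly interpolated, exponentiated, integrated, and
   renormalized — every iterate is a valid diffeomorphism).  If the refined
   misfit exceeds the raw lattice optimum the refinement restarts from the
   unsmoothed path and the better of the two is kept.  On constructed
   warp-recovery problems this reduces the residual from ~6–8% to ~0.5% of
   ‖q‖.  The raw lattice optimum is preserved in `AlignmentResult.dp_cost`.

`amplitude_distance` evaluates both alignment directions and returns the
smaller.  The underlying distance is symmetric; each direction is an upper
bound on it, and taking the minimum suppresses refinement noise that can
otherwise reach ~7% on difficult two-oscillation (knock) pairs — enough to
matter for the 5% warp-invariance guarantee the package tests.

## Karcher mean and phase–amplitude separation

The mean shape solves min_μ Σᵢ min_γ ‖μ − (qᵢ∘γ)√γ′‖², iterated by
aligning every SRVF to the current mean (fast lattice alignment, no
refinement) and replacing the mean with the cross-sectional average of the
aligned SRVFs.  Initialization is the input SRVF closest in L2 to the plain
cross-sectional average — deterministic and robust to warping of the inputs.
Iteration stops when the relative L2 change of the mean drops below
`tol = 1e-4` or after `max_iter = 20` iterations; non-convergence (common
for large noisy ensembles, where the update noise floor sits near the
tolerance) produces a warning and a usable result, never an exception.  A
final alignment pass against the converged mean uses the full smooth
refinement.

Each curve then decomposes as βᵢ = β̃ᵢ∘γᵢ\*: the amplitude β̃ᵢ is the
aligned curve and the phase γᵢ\* the inverse of its aligning warp, so the
reconstruction identity holds by construction up to interpolation error
(measured < 0.1% relative L2 on test ensembles; the package guarantees 2%).
By default phases are re-centered so their pointwise mean is the identity,
with the mean shape re-warped accordingly (`center_phases` flag).

A caution about the centered mean's *parametrization*: it equals, to first
order, the true template warped by the ensemble's average warp.  When warps
are drawn from a symmetric law the average warp is an O(1/√n) sampling
residue, so the realized mean is only as mirror-symmetric as that residue
allows — the same order as the pointwise Euclidean mean's asymmetry.  The
meaningful statement is amplitude-level: the shape mean's *amplitude
distance* to the true template is roughly an order of magnitude smaller than
the Euclidean mean's, and that is the property the test suite asserts
robustly.  A realized-parametrization asymmetry comparison between the two
means is also exercised in the acceptance suite and documents this
limitation when it fails.

## Shape PCA

Aligned SRVFs are mean-centered; the sample covariance (1/(n−1)) is
decomposed by SVD.  Directions are scaled so the discrete L2 inner product
dt·Σuv approximates the integral inner product: components are
L2-orthonormal, eigenvalues are per-mode score variances, and
`variance_fractions` sum to one over the full spectrum.  Signs are fixed at
fit time so each direction has nonnegative inner product with the grid-wise
standard-deviation profile of the data; cross-run sign alignment (needed
when PCA is refitted many times) is handled separately by the index
pipeline.  Three components are retained by default per activity; the first
two feed the index.

On this kind of data VPC1 sweeps movement speed (overall amplitude — a
slower curl is a uniformly smaller angular-velocity curve) and VPC2 motion
asymmetry (peak height relative to trough depth — e.g. a slow effortful
upward phase with a fast gravity-assisted downward phase).  `mode_traversal`
reconstructs μ ± s·√λ_k·U_k as curves for visual labelling, and
`asymmetry_statistic` ((|peak| − |trough|)/(|peak| + |trough|)) makes the
VPC2 label testable.

Two caveats shape the recovery tests.  The speed and asymmetry *loading
directions are not orthogonal* in SRVF space (their cosine is ≈ −0.7 for the
curl template), so PCA's orthogonal components cannot coincide with them
individually; what is recoverable is (i) the 2-D loading *subspace* — the
span of the least-squares regressions of aligned SRVFs on the standardized
ground-truth latents — and (ii) strong per-mode score–latent correlations.
Second, the square root in the SRVF amplifies measurement noise near the
stationary points of β, so recovery presumes well-filtered repetitions (see
the generator's noise model below).

## The statistical layer

**Subject embedding.**  Shape PCA is repeated `n_runs` times (100 by
default; smaller where runtime matters, stated per script) with one visit
drawn uniformly per subject per run; each run's components are sign-aligned
to the first run's (flip if the inner product is negative); the embedding is
the across-run mean VPC score per subject, with across-run standard
deviations kept as a dispersion diagnostic.  By default the phase-amplitude
separation is refitted on every run's curve set; a `refit_alignment=False`
mode reuses one global separation and refits only the PCA per run, which is
an order of magnitude faster and nearly indistinguishable on synthetic
cohorts.

**PLS canonical index.**  Two-block canonical-mode PLS (symmetric
deflation, exact SVD per component, standardized blocks) links the four
wearable features (VPC1/VPC2 × curl/knock) to the clinical block (age,
average echogenicity, normalized elbow torque, Brooke score; the healthy
cohort is excluded because Brooke is not collected there; Brooke is treated
as a numeric ordinal).  Canonical mode was chosen because the quantity of
interest is a canonical correlation; the component count is configurable.
The first X-side weight vector is the motor-function index.

**Bootstrap.**  Each of `n_boot` replicates (10000 by default) resamples
subjects with replacement into a training set of ⌊0.7·n⌋; subjects never
drawn form the hold-out.  PLS is fitted on the training set and the Pearson
correlation of each held-out score pair recorded.  Replicates with fewer
than 3 held-out subjects or a zero-variance score are skipped and counted.
Replicate weight vectors are sign-aligned to the full-data point fit so
coefficient histograms are comparable.  Both 2.5–97.5 and 5–95 percentile
intervals are reported; 5–95 is the default display.  All randomness flows
from one `numpy` Generator seed, so distributions are bit-reproducible.

**Correlation panel.**  Per-cohort Pearson correlations of each VPC feature
with each clinical measure, complete cases per pair, Brooke omitted for
healthy; zero-variance pairs are reported as undefined (NaN), never as 0.

**Mixed model.**  A random-intercept-per-subject linear mixed model of
per-visit VPC1 on age, cohort, and age×cohort (treatment coding against
healthy), fitted by REML via `statsmodels`; this module owns the design,
the two-sided Wald tests, Benjamini–Hochberg adjustment across the reported
fixed effects, and significance flags at α = 0.01.  Singular or
non-converged fits are reported through a `note` attribute with the table.

**Baseline comparison.**  The identical bootstrap harness applied to three
feature extractions from the same curves (first visit per subject): elastic
shape PCA on aligned SRVFs, PCA on the raw unaligned curves ("functional PCA
without alignment"), and NMF on nonnegatively shifted unaligned curves (both
baselines via scikit-learn).  The output mirrors a per-method, per-component
table of bootstrap medians and percentile intervals.

## Synthetic cohort generator

No wearable dataset of this kind is publicly deposited, so the generator is
first-class, tested code that creates data with exactly the structure the
analysis assumes:

- **Templates** (formulas declared in `simulate.py`): curl = windowed single
  oscillation sin(2πt)·sin²(πt), knock = two cycles sin(4πt)·sin²(πt);
  amplitude = 120 deg/s × speed (a typical pediatric arm-curl peak rate);
  positive lobes scaled by (1 − asymmetry), so the template's peak/trough
  statistic is −a/(2−a) in closed form.
- **Warps**: γ(t) = t + c·sin(πt)/π with c ~ U(−intensity, intensity),
  strictly increasing for |c| < 1; default intensity 0.5.
- **Latents**: per-cohort normal speed and asymmetry (healthy 1.00 ± 0.08 /
  0.05 ± 0.04; DMD 0.75 ± 0.18 / 0.12 ± 0.08; SMA 0.65 ± 0.18 / 0.28 ± 0.10
  — patients slower with wider spread, SMA carrying the strongest asymmetry),
  with small visit-to-visit jitter (0.04 / 0.03).  Patient speed additionally
  declines with age (−0.02/yr DMD, −0.025/yr SMA about the age midpoint;
  healthy flat), emulating progressive loss of function, which is what the
  age × cohort mixed model is designed to detect.
- **Clinical columns**: linear in the latents plus noise — echogenicity
  rises as speed falls, torque tracks speed, Brooke is a rounded clamped
  1–6 ordinal, missing for healthy; age uniform on 5–17.
- **Noise**: band-limited (six random Fourier modes), SD 0.3 deg/s.  This
  emulates segmented, low-pass-filtered repetitions: consumer gyros at these
  bandwidths have ~0.05 deg/s RMS noise against ~120 deg/s signals, and the
  SRVF's square root amplifies whatever roughness survives filtering, so the
  generator models preprocessed data rather than a raw stream.  White,
  unfiltered noise at deg/s scale would bury the asymmetry mode and is
  deliberately out of scope.
- **Default sizes** mirror the emulated study's analysis set (15 DMD, 7 SMA,
  9 healthy; 1–3 visits); `recovery_preset` provides a single pooled
  population of 200 subjects with *independent* latents (speed 0.8 ± 0.2,
  asymmetry 0.15 ± 0.15 — the pooled across-cohort spans) for recovery
  tests, where cohort-induced latent correlation would otherwise confound
  per-mode attribution.
- A `warped_bump_ensemble` helper builds the classic registration illustration: a
  symmetric Gaussian bump, amplitude-only scaling, then random warps.

What passing tests on this generator show: the pipeline recovers the
latent structure it was designed to recover when phase, amplitude and noise
enter the data the way the model assumes.  What they do not show: robustness
to segmentation errors, non-template movement strategies, sensor drift, or
activity mislabelling — none of which the generator emulates.

## Numerical choices and degenerate inputs

- Grids must be uniform within 1e-9 relative; repetitions shorter than
  8 samples are rejected at I/O.
- Warps snap endpoint values within 1e-9 to exactly {0, T}; inverses are
  computed by monotone interpolation with an epsilon nudge where float
  precision flattens a step.
- A flat curve has an undefined asymmetry statistic: 0 is returned with a
  warning.  Constant feature columns are dropped from PLS with a warning.
  Zero-variance correlation entries are NaN, flagged undefined.
- `n_retained` greater than n−1 is truncated with a warning; invalid mode
  indices raise.
- Pipeline seeds: one top-level seed is split into named per-stage seeds
  (all < 2³¹) recorded in the manifest; re-running a manifest's config
  reproduces every artifact bit for bit.

## Problem sizes used by the shipped scripts

`scripts/acceptance.py` runs the full analysis at the default study scale
(31 subjects), a 200-subject recovery cohort, a 21-curve warped-bump family,
25 embedding repetitions in the fast projection-only mode, 2000 index
bootstrap replicates and 1000 baseline replicates — sizes chosen so the
whole recomputation completes in minutes on one CPU while leaving every
estimate comfortably inside its tolerance.  The
test suite uses the same or smaller sizes per property.

## Known limitations

- Scalar curves only; no multidimensional SRVF, rotation invariance, or
  open-curve shape spaces.
- Phase is discarded after separation; no horizontal (phase) PCA.
- The Karcher iteration optimizes over the DP lattice, so its fixed point
  is a lattice-constrained approximation of the true Fréchet mean.
- The canonical index is correlational; no causal or longitudinal claims.
- The mixed model assumes a random intercept only; random slopes are out of
  scope at these cohort sizes.
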