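# Methods

This note documents the statistical procedures implemented in `wallcast`,
the choices made where the design was genuinely open, and what the synthetic
cohorts do and do not establish about real race telemetry.

## Race labeling

A race's pace profile is a contiguous sequence of segments (start, length,
pace). The base pace is the overlap-weighted mean over the 5–20 km window —
the opening 5 km are excluded because early-race pacing is erratic — so
mixed 250/500/1000 m profiles and segments straddling the window edges are
handled exactly. Relative pace is evaluated for segments *starting* at or
beyond 25 km. Labels:

* **HTW**: some maximal run of consecutive segments with relative pace
  strictly above 1.25 has total length ≥ 5 km;
* **NHTW**: otherwise, some maximal run strictly below 1.10 has total
  length ≥ 10 km;
* **EXCLUDED**: neither.

Choices worth flagging: run lengths are compared *inclusively* (≥ 5 km, ≥
10 km) because segment quantization makes a strict "more than" fragile at
exactly-critical runs; ratio comparisons are strict as stated; the NHTW
stretch must be a single continuous run ("consistently"), not cumulative —
both are configurable on `LabelRule`. A race satisfying both criteria on
disjoint stretches is HTW: the defining event takes precedence. Races not
covering 30 km cannot be evaluated against either run-length criterion and
are EXCLUDED. Runs truncated by the finish line count with their realized
length.

## Functional representation

Curves live on T = [0, 21] km. All three segment lengths tile [0, 21 km]
exactly, so every runner's first-half segments cover the domain with no
edge extrapolation (a 1000 m segment starting at 21,000 m would straddle
the true halfway point at 21,097.5 m and is treated as second-half pace).

Smoothing is *unpenalized* least squares onto a clamped cubic B-spline
basis with equally spaced interior knots, observations at segment midpoints.
Regularisation comes from dimension selection: for each variable, the basis
dimension minimizing the mean generalized cross-validation score over
training series,

    GCV = (SSE/m) / (1 - df/m)^2,   df = n_basis,

over the candidate grid {8, …, 30} (capped at one below the sparsest
series length — 20 for 1000 m sampling). One dimension is chosen per
variable and shared across runners. Series with fewer points than the
largest candidate are skipped with a warning.

Standardization is pointwise on a 512-point equispaced grid: mean and SD
functions (ddof = 1, floored at 1e-8) come from training curves only and
are applied unchanged to test curves. A z-scored curve is a ratio of
splines, not a spline, so the standardized grid values are projected back
onto the basis for downstream coefficient-space work; the projection is
linear, hence training means remain exactly zero. A scalar per-variable
standardization would also have been defensible; the pointwise functional
convention was chosen and the refit error (typically ~1e-3 relative) is
irrelevant to everything downstream, which is internally consistent in the
refit space.

## FPCA

With curves as coefficient vectors c_i and basis Gram matrix G, the
L2 geometry is exact: eigen-decomposing the sample covariance of G^{1/2}c_i
gives eigenfunction coefficients G^{-1/2}w_k (L2-orthonormal on T) and
scores z_ik = (c_i - c̄)'G u_k. This is algebraically identical to a
grid-quadrature FPCA in the limit of a fine grid, and the test suite checks
it against a trapezoid-weighted 512-point grid PCA oracle.

K_j is the smallest count reaching 99% cumulative eigenvalue fraction,
floored at 1 and capped at min(n_basis, n_train − 1); the threshold is
applied per variable (the natural reading when smoothing is also per
variable). Eigenfunction signs are fixed so ∫u_k dt ≥ 0, falling back to a
positive largest-magnitude coefficient; this makes coefficient-function
signs reproducible across runs.

## Collinearity screen

VIFs are computed per score column (regression on all other columns with
intercept; perfect collinearity reported as ∞, not raised). A *variable* is
flagged when one of its columns has VIF > 10 **and** that column correlates
(|r| > 0.7) with a column of a different variable — the conjunctive reading
of the screening rule, with an "or" mode available. Flagged variables are
removed one at a time, worst max-VIF first (alphabetical tie-break), until
nothing is flagged; the iteration stops rather than empty the predictor
set. A `pinned_removal` mode applies a fixed removal list for replication
runs. The reported `max_vif_after` is recomputed from the retained columns.

## Functional logistic regression

The scalar-on-function model with coefficient functions expanded in each
variable's eigenfunctions reduces, by orthonormality, to ridge logistic
regression on the scores; the package verifies the equivalence numerically
(composite Simpson on 2049 points, agreement well below 1e-6 — a 512-point
trapezoid rule is too coarse to certify that tolerance, which is why the
quadrature check uses the finer Simpson grid). The penalized likelihood

    sum_i [y_i eta_i - log(1 + e^{eta_i})] - (lambda/2) sum_j ||b_j||^2

(intercept unpenalized, preserving prevalence calibration) is maximized by
damped Newton iterations to gradient ∞-norm ≤ 1e-8; step halving keeps the
objective monotone up to float rounding. λ is selected from 20 log-spaced
points on [1e-4, 1e3] by stratified 5-fold cross-validation maximizing
mean out-of-fold F1 (HTW positive, threshold 0.5), ties resolved toward the
larger λ; the fold count, grid and threshold are conventions, not givens.
Scores enter as produced by FPCA — components with larger eigenvalues have
larger scale and are therefore penalized relatively less; this is a known
caveat of ridge on unstandardized scores and is deliberate, since it
preserves the functional-model interpretation of λ.

Importance is ‖b_j‖₂ (= ‖β_j‖_{L2(T)} by Parseval), descending, ties
alphabetical. The reported norm is basis-dependent: rescaling a variable's
scores and coefficients inversely leaves predictions unchanged but changes
the norm (covered by a test as a documented caveat).

## Pipeline and split

Exclusion precedes splitting (the stratification includes the pace label,
so labels must exist at split time). Strata are sex × quantile-binned
finish time × quantile-binned age × label with 4 bins per continuous
variable; strata under 5 members are merged into the nearest finish-time
bin sharing the other keys, falling back to the largest same-label stratum.
Within each final stratum the train count is round(0.8·n). Everything
training-derived — GCV dimensions, standardization parameters, FPCA
systems, the screen and the model — is computed from training runners only;
a test asserts that deleting all test runners reproduces every training
artifact bit-for-bit.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
fixed to the study conditions the package targets:

* **Curves**: per variable, population mean (piecewise-linear in distance)
  plus three smooth random-effect modes — normalized Legendre shapes for
  level, linear drift and curvature, with loading SDs in the variable's
  units scaled (1, 0.3, 0.2) of a per-variable scale — plus iid segment
  noise scaled by √(500 m / segment length), mimicking fewer steps averaged
  per shorter segment.
* **Risk**: latent logit = intercept + Σ_j ∫ w_j(t)·(centered curve_j)(t) dt
  (fine-grid trapezoid), with nonzero weight curves only on step length
  (positive before 10 km, negative after), ground contact time and vertical
  stiffness (v-shaped: positive at the start, ≈0 at 5–10 km, rising after).
  The latent logit SD under the defaults is ≈2.0. The intercept is
  calibrated numerically (Gauss–Hermite + root-finding) so the expected HTW
  share of labeled runners equals 0.46; the labeled prevalence and the
  46/54 class split it targets, the 0.537 excluded fraction, the 1277:160
  sex ratio and the 50.4 ± 8.6 y age distribution are the cohort
  conditions the package treats as given.
* **Pace collinearity**: pace mode loadings are a standardized blend of
  −0.82·step length, −0.50·cadence and a 0.28 residual, giving pace score
  columns VIF ≈ 13 and cross-correlations ≈ 0.8 — enough for the screen to
  remove pace (and only pace) under default thresholds.
* **Second half**: relative pace follows a smoothstep ramp (onset uniform
  in [20, 30] km, ramp 3 km) to a plateau drawn per outcome — HTW in
  (1.30, 1.45), NHTW in (1.00, 1.07), excluded in (1.14, 1.21) — with
  0.3%-SD noise clipped at 3σ. These margins make the rendered profile
  *provably* satisfy the intended label for every onset in range (e.g. the
  worst-case HTW plateau starts by 33 km, leaving a 9.2 km run above
  1.28), which is why generator truth and rule-based labels agree on 100%
  of runners.

What the synthetic cohorts do **not** emulate: real marginal distributions
of the 16 form variables (unpublished), between-variable correlations
beyond the pace coupling, weather/elevation/drafting, DNFs, missing
segments (injection exists but is off by default), and any nonlinearity in
the risk link. Passing tests therefore certify the *machinery* — labeling,
smoothing, FPCA algebra, screening, optimization, leakage hygiene and
recoverability of a planted functional signal at realistic n — not
real-world predictive accuracy.

## Numerical choices and degenerate inputs

Gram matrices use per-knot-span Gauss–Legendre (exact for the product
degree). Rank-deficient smoothing designs raise with a suggestion to reduce
n_basis. Zero pointwise SD is floored at 1e-8 with a warning; an
all-identical training set yields K = 1 with zero eigenvalues and zero
scores. Perfectly collinear score columns report VIF = ∞ rather than raise.
Single-class labels and non-convergent fits raise informative errors.
Problem sizes in the test suite (cohorts of 300–2,000 runners, 20-seed
null/signal sweeps at n = 700) were chosen so the planted-signal checks
have comfortable statistical margins while the whole suite stays fast.

## Known limitations

* GCV treats segment means as homoskedastic within a series; no roughness
  penalty is offered.
* The screen removes whole variables, never individual components.
* Severity of the slowdown is not modelled — the outcome is binary.
* Coefficient-function confidence bands are not provided.
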