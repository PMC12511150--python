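# Methods

This note documents the models, estimators and numerical choices behind
`pointkin`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one defensible option
existed.

## Preprocessing and landmark extraction

Marker positions are low-pass filtered with a 3rd-order Butterworth filter
(5 Hz cutoff) applied forward and backward (`filtfilt`), giving zero phase
and unit DC gain; the effective magnitude response is the square of the
single-pass response. Positions are filtered, derivatives are not
re-filtered. Velocity and acceleration come from three-point numerical
differentiation: central differences in the interior, one-sided two-point
differences at the ends (exact for affine signals everywhere and for
quadratics in the interior).

Two conventions matter and are deliberate:

- **Tangential speed.** The thresholded quantity is the Euclidean norm of
  the 3D velocity. A signed axis projection would make a 10%-of-peak rule
  ill-defined for movements along different axes.
- **Scalar acceleration = d(speed)/dt**, not the norm of the vector
  acceleration. This keeps deceleration signed (negative), so the peak
  deceleration PD is well-defined and reported as a magnitude. Uniform
  circular motion therefore has ~zero scalar acceleration despite a nonzero
  centripetal vector acceleration — a property the tests document.

Movement onset/offset are the first/last samples where speed *strictly
exceeds* 10% of its peak. Onset/offset are kept at sample resolution (no
sub-sample interpolation): at 120 Hz the quantization is ≤ 8.3 ms, and a
reproducible integer-index rule is preferred over an interpolation scheme
with its own tie and noise sensitivities. Landmarks: PV and its index on
[onset, offset]; PA = max acceleration on [onset, index(PV)]; PD = |min
acceleration| on [index(PV), offset] (accelerate-then-brake logic of a
unimodal profile); relative times rDPX = 100·(index(PX) − onset)/(offset −
onset). Ties at an extremum break to the earliest sample and set a flag.

**Exclusion rules.** Trials with any missing motion sample are removed
first; then trials whose MD strictly exceeds mean + 3 SD, with mean and SD
computed over the grand pool of all non-missing trials. The pool choice is
a genuine free parameter (per-cell and per-participant pools are equally
defensible a priori); the grand pool is the default because the exclusion
is meant to catch globally aberrant trials, not condition effects.
Equality at the boundary retains the trial ("exceeds" is strict).

## Synthetic studies

The generator emulates a factorial pointing experiment: 27 participants ×
2 postures × 2 visual environments × 4 allocentric directions × 4 blocks ×
3 trials (5184 trials), straight 30 cm reaches sampled at 120 Hz with
0.4 s of quiescence on each side.

The generative speed curve is beta-shaped, v(τ) ∝ τ^(a−1)(1−τ)^(b−1) with
a + b = 6, parameterized by its mode: (a−1)/(a+b−2) = rdpv/100. One
parameter therefore controls exactly the asymmetry the analysis measures,
and at rdpv = 50 the curve *is* the minimum-jerk speed profile
30τ²(1−τ)², which serves as the symmetric fixture. The curve is sampled on
the 120 Hz grid (durations are quantized to the grid) and scaled so its
trapezoidal time-integral equals the amplitude exactly; positions are its
cumulative trapezoidal integral along a straight path. Straight paths
rather than shoulder-rotation arcs: tangential speed is path-shape
invariant for every quantity analysed here, and straight paths keep the
oracles analytic.

Defaults (the simulated study conditions):

| parameter | default | meaning |
|---|---|---|
| rdpv targets | up 44, down 50, left/right 47 (%) | gravity asymmetry, identical in both environments and postures |
| participant rdpv SD | 1.5 % points | per participant × cell offset |
| trial rdpv SD | 3.0 % points | per-trial jitter |
| MD | 0.5 ± 0.05 s, truncated ±2.5 SD | per-trial duration draw |
| noise | 0.5 mm SD, i.i.d. Gaussian | marker jitter before filtering |

The rdpv gap of 6 points between up and down with ~3-point
within-participant spread mirrors the magnitude of reported vertical
asymmetries; lateral directions sit midway. MD and noise magnitudes are
plausible placeholders — no per-condition magnitudes were available to
copy — and are labelled as such: recovery tests validate the machinery,
not the literal millisecond values.

Two corruption modes are injected with ground-truth bookkeeping: duration
outliers (regenerated with duration drawn in mean + 6–8 SD) and
missing-sample trials (a contiguous span blanked). Durations are truncated
at ±2.5 generative SD rather than ±3 so that the *measured* MD — which
differs from the generative duration through segmentation truncation and
1/120 s quantization — cannot straddle the 3-SD exclusion boundary: with a
±3 cut, ~2 clean trials per 5184 would be expected to cross it and the
injected corruptions would no longer be identifiable by construction.

What the generator does **not** emulate: curved shoulder-rotation paths,
signal-dependent or autocorrelated motor noise, feedback corrections,
marker dropout other than the injected spans, VR latency, or any
environment- or posture-dependent kinematic difference (the defaults place
the null on those factors). Passing tests therefore show the pipeline
recovers what this model generates — they cannot certify behaviour on
real markers with, e.g., soft-tissue artefacts.

## Inferential branch

Retained trials are averaged to participant × (posture, environment,
direction) cell means — 16 cells per participant. Per landmark:

- **Normality gate**: Shapiro–Wilk per cell; the nonparametric branch is
  taken iff any of the 16 cells rejects at 0.05. With genuinely Gaussian
  data the 16-test family passes with probability ≈ 0.95¹⁶ ≈ 0.44, so the
  gate trips often by design — both branches are first-class.
- **Parametric**: three-way fully-within RM-ANOVA via the
  inclusion–exclusion sums-of-squares decomposition, each effect tested
  against its own effect-by-participant interaction (e.g. direction:
  F(3, 3(n−1)), so F(3, 78) at n = 27). η_p² = SS_effect/(SS_effect +
  SS_error). For effects with > 1 df, Mauchly's test runs on the
  covariance of orthonormal contrast scores (with the Box correction
  factor in the χ² approximation); when it rejects at 0.05 the
  Greenhouse–Geisser ε (= tr(S)²/(df·‖S‖²_F), clamped to [1/df, 1], and
  identically 1 for 2-level effects) multiplies both degrees of freedom.
- **Nonparametric**: Friedman χ² over the 16 cells (average ranks,
  χ²(15) asymptotic). The all-tied degenerate case returns statistic 0,
  p = 1. The χ²(k−1) asymptotic is a large-sample approximation: at n = 4,
  k = 3 it agrees with the exact rank-permutation null to ~0.01 in the
  rejection region but can differ by ~0.2 mid-range — acceptable because
  the test is only consulted for significance.
- **Planned comparisons**: exactly 16 pairs — 8 environment contrasts
  (virtual vs physical at fixed posture × direction) and 8 direction
  contrasts (up vs down, right vs left within each posture × environment);
  vertical-vs-lateral pairs are never tested. Per-test threshold
  0.05/16 = 0.003125. Parametric branch: paired t contrasts on the cell
  means (pooled-error contrasts would require sphericity across
  heterogeneous cells that cannot be verified pair-wise); nonparametric:
  Wilcoxon signed-rank. Follow-up simple-main-effect contrasts for a
  posture × direction interaction use the same paired-contrast machinery
  within posture, Bonferroni-corrected within the family of 4.

**Wilcoxon signed-rank**: zero differences are dropped (Wilcoxon's
original treatment — implementations differ, so this is stated); |d| is
ranked with average ranks. For n ≤ 25 the two-sided p is exact, computed
by dynamic programming over the generating function of the signed-rank sum
(equivalent to enumerating all 2ⁿ sign assignments; doubled ranks keep the
grid integral under ties), as the probability of a sum at least as far
from the null centre as observed. Above n = 25 the tie-corrected normal
approximation with continuity correction is used — so study-scale data
(n = 27) sit just inside the approximation regime, which the calibration
test shows is conservative at the 0.003125 threshold.

## SPM{t} with random-field-theory thresholds

Each retained trial's speed and scalar-acceleration series are linearly
interpolated onto 101 nodes spanning onset→offset (0–100% of movement
time, the field's standard grid); amplitude is *not* normalized, only
time. Trials are averaged to participant × cell mean profiles and the 16
planned comparisons are tested node-wise with the paired t statistic.
Inference is two-tailed with α split across tails (α/2 per tail).

Smoothness is estimated from the mean-centred paired differences
(residuals) by the normalized-gradient estimator: FWHM = √(4 ln 2) / RMS
gradient of unit-variance-scaled residuals, clamped to [1, n_nodes]. The
critical threshold t* solves the expected-Euler-characteristic bound for a
1D t-field,

P(T_ν > t) + R · √(4 ln 2)/(2π) · (1 + t²/ν)^(−(ν−1)/2) = α_tail,

with resels R = (n_nodes − 1)/FWHM, by monotone bisection (Brent) to
1e-6. In the R → 0 limit t* reduces to the pointwise t quantile; it is
never below it. Suprathreshold clusters are maximal runs of nodes with
|t| > t*, reported as (start%, end%, sign); cluster extent/mass p-values
and permutation SPM are out of scope.

Monte-Carlo calibration (the acceptance computation): 2000 replicates of
27 paired 101-node curves whose differences are Gaussian noise smoothed
with a 20-node-FWHM kernel (generated with padding so the crop is
stationary) give an empirical family-wise false-positive rate of ≈ 0.045
at α = 0.05 — within two Monte-Carlo standard errors of nominal.

## Numerical and fixture choices

- Every stochastic component is driven by one `numpy` Generator seed;
  identical seeds give bit-identical trajectories, tables and CSV files
  (fixed column order and float formats).
- Filter preconditions: series longer than the `filtfilt` pad length
  (12 samples at order 3); missing samples are rejected, never
  interpolated — gaps route the trial to the exclusion stage.
- Parameter-recovery fixtures: the noiseless generative-recovery sweep
  (rdpv targets 35–65) uses 1.2 s movements so that one sample of
  segmentation quantization (the resolution limit of the integer-index
  rule) is worth ~0.7 rDPV points, below the 1-point agreement the sweep
  asserts; at the study's 0.5 s default one sample is worth ~2.4 points,
  which is why per-trial agreement there is quantization-limited while
  per-cell *means* at the default targets still track the analytic oracle
  to well under 1 point. The filter-idempotence fixture uses 2.5 s
  movements for the same reason.
- Test problem sizes: oracle-equivalence checks run at n = 5 participants
  (ANOVA), n ≤ 12 pairs (Wilcoxon enumeration), n = 4 × k = 3 (Friedman
  enumeration); the hypothesis-pattern power checks run 12 full-pipeline
  replicates of the complete 5184-trial study; SPM calibration uses 2000
  replicates.

## Known limitations

- The RFT threshold assumes a smooth stationary Gaussian field; for very
  rough residuals (FWHM near the 1-node clamp) the bound is approximate
  and conservative.
- The exclusion pool for the MD rule is global; datasets with strong
  per-condition duration differences may prefer the per-cell pool (a
  config option, not the default).
- Mauchly's χ² approximation needs n − 1 > effect df; below that the test
  is undefined and no correction is applied (ε is still reported).
- The simulator's lying posture re-maps the body, not the room: direction
  labels and vectors are allocentric, so posture has no kinematic effect
  unless the rdpv target map says otherwise.
- The Friedman/Wilcoxon asymptotics and the normality gate inherit the
  usual small-sample caveats of their textbook forms; the tests quantify
  them at the sizes used here, not universally.
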