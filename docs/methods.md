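# Methods

## The model

Spirometric indices (FEV1, FVC, FEV1/FVC, FEF25–75%) are positive, mildly
skewed, and change non-linearly with age and height. Each index, per sex, is
modelled with the LMS method: at covariates (age, height) the measurand has a
Box-Cox Cole–Green (BCCG) distribution with median M, coefficient of
variation S and Box-Cox power L, so that

    z = ((y/M)^L − 1) / (L·S)        (L ≠ 0; ln(y/M)/S at L = 0)

is standard normal. The three curves are

    ln M = a + b·ln(height_cm) + c·ln(age_y) + spline_M(age)
    ln S = s0 + s1·ln(age_y) + spline_S(age)
    L    = l0 + spline_L(age)

For the FEV1/FVC ratio the height term is dropped by default (its reference
curves are age-only; an override exists). Modelling ln S keeps S > 0; L is
unconstrained and constant in age by default, with an optional spline.

The lower limit of normal is the 5th reference percentile,
LLN = exp[ln M + ln(1 − z95·L·S)/L] with the lognormal limit M·exp(−z95·S)
at L = 0. Two Z-score modes coexist and every output labels which was used:

* **paper** (default): the clinical linear formula SD = (M − LLN)/1.645,
  Z = (observed − M)/SD, with the literal rounded constant 1.645. It is exact
  at observed ∈ {M, LLN} and a linear approximation elsewhere; on the fitted
  (L, S) ranges it stays within 0.25 of the exact z for |z| ≤ 2 (checked
  numerically in the tests).
* **exact**: the BCCG transform itself.

The LLN uses the full-precision z95 = Φ⁻¹(0.95) by default so that it is
*exactly* the 5% quantile; `z_crit=1.645` reproduces the rounded clinical
value (agreement better than 1e-4 relative on spirometry-like L·S — the
rounding error is amplified by S/(1 − z·L·S), so the two diverge only as
L·S approaches 1/1.645, far outside fitted ranges).

## Fitting

Maximum likelihood over all coefficients. Spline terms are natural cubic
regression splines with knots at evenly spaced age quantiles; the basis is
cardinal (coefficient = curve value at its knot) with a sum-to-zero
constraint so the spline never competes with the intercept. The `df` dial is
the number of free spline coefficients (df = 0 removes the term): effective
dimension is exact, so AIC = −2ℓ + 2·edf and SBC = −2ℓ + ln(n)·edf need no
penalty-trace bookkeeping. This realises the penalized-smoothing idea as
basis-dimension control rather than a ridge penalty — simpler, exactly
deterministic, and with honest information criteria; the cost is that
flexibility moves in integer steps.

Optimization is staged L-BFGS-B with analytic gradients: the M and S curves
first at fixed L = 1, then everything jointly, to relative log-likelihood
tolerance 1e-6 (ftol 1e-12, gtol 1e-7; stalled line searches are restarted,
and accepted only when the log-likelihood no longer moves). The objective
trace over iterations is stored on the fitted model so likelihood ascent can
be audited. Starting values: OLS of ln y for the median curve, its residual
SD for S, L = 1. Fits are deterministic given data and spec.

Model selection fits a df grid per index/sex and keeps the criterion
minimiser (SBC by default; AIC always reported), ties broken toward smaller
total df. The default CLI grid searches df_M ∈ {0..5} with df_S = df_L = 0
(S keeps its parametric ln-age term): a full 6³ cross-grid per index/sex is
possible via configuration but rarely informative at n ≈ 200–400 per sex.

Degenerate inputs: subjects missing an index are dropped per index with a
logged count; fewer than 50 subjects of a sex is a configuration error;
prediction outside the fitted age×height hull is flagged (`extrapolated`),
not refused. The Cole–Green truncation mass Φ(−1/(|L|·S)) is recorded on
every fit; it is ~1e-10 for the volume indices and inherently ~1e-4 for
FEF25–75% (S ≈ 0.3), and a warning is raised only above 1e-2.

## The synthetic cohort generator

No raw data from the emulated study population are available, so validation
runs on synthetic cohorts with a known ground truth:

* **Ages** uniform on [4, 82]. The real study was a convenience sample with
  unreported age distribution; uniform sampling is a stand-in that maximises
  spline identifiability, not a claim about the study.
* **Heights**: sex-specific monotone (PCHIP) growth curves through standard
  pediatric anchors, flat beyond age 21 at the adult means of the emulated
  population (172 cm men, 158 cm women), plus Gaussian noise (conditional SD
  6.0/5.5 cm). The *marginal* height SD then lands near the reported values
  because the age spread contributes most of it.
* **Weight**: BMI ramp (15.5 at age 4 to the adult sex mean) × height²,
  carried for I/O fidelity and unused by the models.
* **Spirometry**: each index drawn independently from the true BCCG model at
  the subject's covariates. True medians are anchored at nine ages to
  physiologic profiles calibrated so adult values bracket the emulated
  population's reported means (male FEV1 3.85 L at 38 y/172 cm vs reported
  mean 3.65; female 2.95 L at 38 y); FVC anchors are FEV1/ratio so the three
  stay mutually consistent. True S declines log-linearly with age (0.15 →
  0.115 for volumes; 0.09 → 0.072 ratio; 0.30 → 0.26 FEF). True L constants:
  0.9 (FEV1, FVC, FEF) and 1.5 (ratio, left-skewed). The anchor decomposition
  into a + c·ln(age) + spline is done by least squares at build time, so the
  stored truth has exactly the fitted models' structural form.

One integer seed drives all randomness; identical config + truth + seed
reproduce byte-identical cohorts. The generator does **not** emulate
measurement error, quality-control failures, disease, smoking, or the
physiological coupling FEV1 ≤ FVC (indices are modelled independently, as in
practice; an optional flag redraws violating pairs). Passing tests therefore
demonstrate correctness of the method under a well-specified model at study
scale — not robustness to the messiness of real field spirometry.

## Validation experiments

Problem sizes mirror the emulated study: cohorts of 418 F + 204 M. The
median age-curve uses df_M = 5 in these experiments — ample for the smooth
pediatric-rise/plateau/decline profile over an 80-year span (about one knot
per 13 years) while keeping each fit well under a second.

* **Z calibration** (10 replicates, all indices): fitting sample scored
  under its own equations; per-index grand mean paper-Z within ±0.05
  averaged over replicates, and the rate of non-significant age-group
  t-tests (groups with n ≥ 30) consistent with the 5% test level. A
  replicate-level ±0.05 band would be narrower than the sampling SD of a
  grand mean at n = 622 (~0.04), hence the averaging.
* **Residual range** (20 replicates): max |exact residual z| of refits on
  their own sample, expected inside the ±5 clinical band (the median at
  n = 622 sits near 3.2, matching extreme-value theory for ~600 normal
  deviates).
* **Recovery** (20 replicates): relative RMSE of the fitted median curve on
  a test grid (ages 6–80 at growth-curve mean height ± 1 SD, inside the
  hull), median < 3%; and fresh-draw below-LLN coverage, median within
  [3.5%, 6.5%].

The truth L chosen in [0.9, 1.5] keeps the paper-mode Z mean offset
(≈ S·(1−L)/2 relative to SD) below ~0.02; a strongly skewed truth (say
L = 0.5 with S = 0.3) would shift the linear Z's mean by ~0.09 purely from
the formula's linearity, which the emulated population's near-zero reported
Z means rule out.

## Numerical choices

* L = 0 handled by an explicit branch at |L| < 1e-6 using `expm1`, keeping
  the transform continuous in L.
* Sampling redraws deviates outside the BCCG support (probability < 1e-6 at
  fitted parameters); the quantile function raises a domain error naming the
  truncation bound.
* Optimizer bounds: L ∈ [−4, 4], sigma intercept ∈ [−8, 3] — generous
  envelopes that only prevent numerically absurd excursions.
* Bland–Altman differences are oriented external − fitted; limits of
  agreement at mean ± 1.96·SD. One-sample CI95 uses the t distribution
  (normal approximation by flag). Zero-variance groups: p = 1 at the null,
  p = 0 off it. No multiple-testing correction across groups/indices (none
  is customary in this validation setting); output metadata records this.
* Age bins follow the conventional gappy labels (< 10, 10–21, 22–29, …,
  > 70) as contiguous half-open intervals [0,10), [10,22), [22,30), …,
  [70,∞).

## Known limitations

* Uniform ages and independent per-index draws are idealisations (above).
* The paper-mode Z is a linear approximation; its error grows with |z| and
  S (bounded by 0.25 at |z| ≤ 2 on fitted ranges, larger in far tails).
* df moves in integer steps; no continuous smoothing-parameter selection.
* Constant-in-age L is the default; age-varying L is available but its
  selection at n ≈ 200–400 per sex is weakly identified.
* No ULN is provided (percentiles cover the need); Z-scores are not
  interpreted clinically.
* External reference standards are supported only as user-supplied YAML
  coefficient tables (`external: true`); no third-party coefficients ship
  with the package, and the comparison driver uses a clearly-labelled
  synthetic comparator instead.
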