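# Methods

## Spectral estimation

Recordings are segmented into epochs of `epoch_seconds` (default 5 s)
with `overlap_fraction` (default 0.8) overlap. Epoch length and
start-to-start step are rounded to whole samples; at 500 samples/s the
default step is exactly 500 samples, so placement never drifts, and the
epoch count is `floor((T − L)/step) + 1`. Recordings yielding fewer than
`min_epochs` (default 10, i.e. 50 s of data) are excluded.

Each epoch is mean-removed (the only detrending applied; it prevents a
DC leak into the lowest bins) and Hamming-tapered; one-sided
periodograms with density normalization (`|X|²/(fs·Σw²)`, interior bins
doubled) are averaged pointwise. No zero-padding is used, so the bin
spacing equals `1/epoch_seconds` exactly — 0.2 Hz at the defaults — and
the normalization convention is immaterial to PAF because the log-log
line fit below is invariant to a global power scale.

## PAF estimation

The estimator models log10 power as an aperiodic line plus a single
alpha peak:

1. Take (log10 f, log10 P) over the fit range 1–55 Hz.
2. Fit the line by Huber M-estimation with tuning constant M = 1.35
   (IRLS; scale re-estimated each iteration as 1.4826 × median absolute
   deviation of residuals; convergence on the coefficient vector at
   1e-8, at most 200 iterations — statsmodels' RLM with the HuberT norm
   and MAD scale implements exactly this). The line is fitted to *all*
   points in range, alpha band included: Huber downweighting of the
   peak's large residuals is what keeps the background estimate
   unbiased, and is the reason this beats ordinary least squares when a
   peak is present.
3. Flatten: `ratio(f) = P(f) / 10^(intercept + slope·log10 f)`,
   i.e. subtract the line in log space and exponentiate. A pure power
   law flattens to 1 everywhere.
4. Fit `ratio(f) ≈ 1 + A·exp(−(f−c)²/(2w²))` to the 7–13 Hz band by
   nonlinear least squares (baseline fixed at 1, no free offset).
   Initialization: c at the in-band argmax, A at (max ratio − 1), w at
   1 Hz. Bounds: c ∈ [6, 14] (the optimizer may roam past the band; the
   band rule is applied afterwards), w ∈ [0.2, 6] Hz, A ≥ 0. The fitted
   vertex c is the PAF.

A peak is **absent** when: the band holds fewer than 5 grid points; the
optimizer fails; the fitted amplitude does not exceed the detection
threshold; or the fitted center falls outside 7–13 Hz. Absence is a
value, not an error, and each absent result carries a reason code.

**Detection threshold.** The bare rule "amplitude > 0 and center in
band" declares a peak in most pure-noise spectra, because the Gaussian
latches onto the largest in-band noise excursion. The estimator
therefore requires the fitted amplitude to exceed `peak_threshold`
(default 2.0) times a robust noise scale — 1.4826 × MAD of the
flattened residuals outside 6–14 Hz. The value 2.0 is the convention
popularized by spectral-parameterization tooling (FOOOF's
`peak_threshold`); with it, pure 1/f recordings at the default 120-s
duration essentially never yield a spurious peak while injected peaks
down to a = 0.05 log10-units remain detectable (both properties are
exercised in the test suite). Setting `peak_threshold=0` restores the
bare rule.

**Fit quality.** R² is computed in log10-power space over the 1–55 Hz
range between the observed spectrum and the full model (aperiodic line
plus, when present, the log of the fitted peak ratio). Log space is
where both components are fitted. Note R² reflects the whole-spectrum
fit, not peak-location accuracy: synthetic spectra with small `noise_sd`
give R² near 1, far above what heterogeneous real recordings produce.

**Sign conventions.** Log base 10 throughout (the base cancels in the
PAF). The aperiodic `slope` is the signed log-log slope, expected
negative; the generator's `exponent` χ is its magnitude.

## Region aggregation

The 68 Desikan–Killiany parcels map to 10 macro-regions, 5 lobes per
hemisphere: frontal 11 parcels, parietal 5, occipital 4, cingulate 4,
temporal 9 plus the insula. The five-lobe scheme leaves the insula
unplaced; it is assigned to temporal by adjacency, and the mapping ships
as a plain two-column text table so users can override it (any override
must still contain 68 mirror-symmetric entries).

Within each macro-region, PAF is the arithmetic mean over parcels with a
valid (present) estimate; a macro-region with no valid parcel is
missing. Validity proportions are reported as
100 × (valid estimates) / (parcels × participants).

## Statistical battery

Codings: TD = 0 / ASD = 1, DR = 0 / EO = 1, female = 0 / male = 1; age
in months. Missingness is handled complete-case per model.

- **Descriptive comparisons** from per-group summaries: pooled-variance
  Student t computed from (mean, SE, n) per group (SE → SD via
  `sd = se·√n`), df = n₁+n₂−2; sex by Pearson chi-square without
  continuity correction. Published cohort-description tables often label
  the ± values "SD" while printing t statistics only consistent with
  standard errors; the summary-based reconstruction here treats them as
  SEs.
- **Reactivity mixed models** per region:
  `PAF ~ diagnosis * condition + age + sex` with a random intercept per
  participant, fitted by maximum likelihood, Wald z tests (REML is
  available as an option). Significance is gated at p < 0.05/5 across
  the five lobes (hemispheres of a lobe are correlated, so lobes — not
  regions — count as comparisons); within-group follow-up models
  (`PAF ~ condition + age + sex` + random intercept) are gated at
  p < 0.05/2. At n = 51 subjects the Wald z test is mildly liberal (the
  replicate-null calibration in the acceptance checks measures the
  realized rate); this is a property of the method, not corrected for.
- **Change-score regressions** per region: OLS of ΔPAF = EO − DR on
  baseline DR PAF, diagnosis, age and sex, with HC1
  heteroscedasticity-robust standard errors (the conventional default of
  the software family this analysis style comes from); an optional
  diagnosis × baseline interaction tests group differences in the
  baseline dependence.
- **Trait association**: OLS of log SRS on ΔPAF, age and sex, HC1
  errors. The natural log is used; the base scales coefficients by a
  constant factor only. Nonpositive raw SRS scores are rejected before
  the transform.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes,
at the study's conditions: 29 TD / 22 ASD children, ages uniform over
60–95 months, male proportions 16/29 and 14/22.

Generative model for the true peak center of subject *i*, region *r*:

```
DR:  μ_ir = 9.0 + β_diag·ASD + β_age·(age−75) + β_sex·male + u_i + e_ir
EO:  μ_ir(EO) = μ_ir + Δ_ir
Δ_ir = β_cond + β_int·ASD + γ·(μ_ir − E[μ_ir | covariates]) + η_ir
```

with a shared subject intercept u_i (SD 0.3 Hz — a tunable default, not
a claim about cross-region correlation, which the source data do not
characterize), region-level scatter e (SD 0.25 Hz) and change noise η
(SD 0.35 Hz). The per-region fixed-effect defaults are the coefficient
profile of the reference analysis (strong occipital condition effects,
a negative temporal interaction of −0.662 Hz on the right, age ≈
+0.03–0.044 Hz/month). The baseline coupling γ (default −0.6) acts on
the *idiosyncratic* part of the DR value — its deviation from the
covariate prediction — which makes the injected condition/interaction
coefficients exactly the estimands of the mixed model and γ exactly the
estimand of the covariate-adjusted change-score regression (coupling to
the raw DR value instead would leak group baseline differences into the
interaction).

Log-SRS is `3.95 − 0.324·Δ(temporal right) + 0.017·(age−75) +
0.205·male + N(0, 0.4)`, exponentiated and rounded. Group differences
in SRS arise only through the reactivity coupling (plus noise), keeping
the association coefficient cleanly identified; the simulated TD/ASD
gap in mean SRS is therefore smaller than the empirical one.

Parcel-level spectra get the macro-region's true center plus N(0,
0.1 Hz) jitter, a per-subject aperiodic background (offset N(1.0, 0.3),
exponent N(1.5, 0.15) truncated at 0.5), peak amplitude 0.4 log10-units,
width 1.2 Hz, and log-spectral noise SD 0.05. Peak-detection failure is
simulated by zeroing the amplitude of random parcel cells at
group-specific rates (TD 0.15, ASD 0.45), chosen so the simulated
micro-level validity proportions fall in the reported TD ≈ 70–98% /
ASD ≈ 42–69% ranges while macro-aggregation rescues nearly all
subjects.

Time series are synthesized by inverse-FFT spectral shaping: the target
one-sided density is converted to Fourier amplitudes with independent
uniform random phases. The realization's Welch PSD fluctuates around
the target with ordinary periodogram variability (exact in
expectation).

**What the generator does not emulate:** sensor-level artifacts, ICA
residuals, head-model and source-leakage structure, non-Gaussian or
multi-peak alpha, condition-dependent aperiodic slope changes, and
realistic spectral heterogeneity (hence simulated fit R² runs far above
real-data values). Passing recovery tests therefore demonstrates the
correctness of the estimators and models under the assumed structure —
not robustness to everything real MEG contains.

## Replicate simulation studies

Recovery and calibration studies regenerate cohorts from the truth path
(parcel centers with simulated detection failure, aggregated to
macro-regions) rather than refitting every spectrum, isolating the
statistical machinery from spectral-fitting noise and keeping 200-
(recovery) and 500-replicate (null calibration) studies in the
few-minute range on one CPU. Single-region designs are used for
replicate fits; the full 10-region, 6936-spectrum pipeline is exercised
once at study scale in the acceptance run and at reduced scale in the
test suite.

## Numerical choices and degenerate inputs

- Huber IRLS on exactly collinear data converges immediately (any
  weighting reproduces the exact line).
- `curve_fit` on an exactly flat band keeps the initial amplitude 0 and
  the result is absent (`no_positive_excursion`).
- Frequencies must be strictly positive and strictly increasing; power
  must be positive over the fit range (log undefined otherwise) and
  nonnegative elsewhere.
- Epoch steps below one sample (overlap → 1) are rejected; pipeline
  configs reject overlap > 0.95 outright.
- Mixed-model non-convergence and singular random-effect fits are
  reported via flags/metadata on the result, never silently dropped;
  the LBFGS optimizer occasionally fails on near-boundary variance
  estimates, in which case a Powell refit is attempted.
- All tables are sorted on stable keys before writing, and manifests
  contain no timestamps, so identical (config, seed) runs are
  byte-identical.

## Known limitations

- The single-peak Gaussian cannot represent split alpha peaks; the
  least-squares fit resolves multimodal residuals to one compromise
  center by design.
- The aperiodic model has no knee parameter; spectra with a bend inside
  1–55 Hz will tilt the line.
- The Wald z inference is slightly liberal at n ≈ 50 subjects (measured
  by the null calibration study); consumers needing exact small-sample
  error control should bootstrap or use Satterthwaite-type corrections
  outside this package.
- The detection threshold trades false positives against sensitivity to
  very small peaks; it is exposed (`peak_threshold`) rather than fixed.
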