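# Methods

## The diagnostic problem and the model

After radiochemotherapy, a growing contrast-enhancing lesion in a treated
glioma is either true tumor progression (TP) or a treatment-related change
(TRC). The package implements a sequential decision rule over two
quantitative imaging markers with complementary error profiles:

1. **Stage 1 (perfusion gate).** Call TP if rCBV_max > c₁. High hotspot
   perfusion is highly specific for tumor — normal or mildly elevated rCBV
   does not rule tumor out (many gliomas are poorly perfused), so a
   negative gate is uninformative and defers the call.
2. **Stage 2 (PET rule).** On deferred patients, call TP if TBR_max > c₂
   **or** Slope < c₃ (a flat or falling late time-activity curve, i.e.
   tracer washout, is the tumor-typical dynamic pattern); call TRC only
   when both are negative.

All comparisons are strict; values exactly on a cutoff are negative calls.
Each cutoff is fitted independently on the full training cohort by
maximizing sensitivity × specificity over the midpoints between consecutive
distinct observed values (rCBV_max and TBR_max higher-positive, Slope
lower-positive). Stage 2 applies the globally fitted c₂/c₃, not cutoffs
refitted on the deferred subset — it is the same marker scale, only a
preselected population. Leave-one-out cross-validation refits all three
cutoffs on every fold, so the validation covers the whole fitting
procedure, not just the final thresholds.

The product criterion is deliberate and differs from Youden's J
(sensitivity + specificity − 1): the product prefers balanced operating
points more strongly. A constructed counterexample where the two criteria
select different thresholds is part of the test suite. Criterion ties break
toward higher specificity, then toward the lower threshold.

## Perfusion quantification

Signal is converted to ΔR2\*(t) = −ln(S(t)/S₀)/TE with S₀ the mean over a
pre-bolus baseline window (default frames 0–8 of 50). Leakage correction is
the linear two-parameter model

    ΔR2*_target(t) ≈ K1 · ΔR2*_ref(t) − K2 · ∫₀ᵗ ΔR2*_ref dτ,

solved in closed form from the 2×2 normal equations; the corrected curve is
target + K2·R(t). Sign convention: K2 > 0 corresponds to T1-dominant
extravasation that depresses the measured curve, so correction can only
raise the integrated area. The reference curve is the mean over
nonenhancing (contralateral) series. CBV is the trapezoidal area of the
corrected ΔR2\* over the whole post-baseline acquisition — no gamma-variate
fit is interposed, matching whole-curve vendor behavior and avoiding fit
fragility; negative lobes are integrated as-is. A constant reference is
rejected as degenerate (it carries no bolus shape to regress on).

rCBV_max is the mean of the k largest per-voxel CBV values in the tumor
mask (default k = 10; the clinical equivalent is a visually placed
maximum-CBV ROI of unstated size, so k is exposed as configuration) divided
by the mean over an equally sized contralateral ROI taken in fixed index
order — the contralateral ROI is *not* maximized, it represents typical
normal tissue. Masks are boolean volumes in index space; mirroring is not
automated because contralateral placement is a manual, anatomy-aware step.

## PET parameterization

SUV = activity concentration [Bq/g] × body weight [g] / injected activity
[Bq]. TBRs are ratios of time-averaged tumor (mean or max) to background
SUV over the 20–40 min uptake window (the window is configurable; dose and
weight cancel in the ratio). TTP is the frame mid-time of the tumor-mean
maximum, earliest frame on ties. Slope is the equally weighted OLS slope of
tumor-mean SUV against time in minutes over frames with mid-times in
[20, 40], scaled by 60 to SUV/h; frame durations are not weighted because
they are not part of the input contract.

## Synthetic cohorts: what they emulate and what they do not

**Parameter mode** draws each marker from a class-conditional distribution
calibrated to a target median and *unscaled* median absolute deviation
(median(|x − median|), no 1.4826 factor — matching how such cohort tables
report spread). Positive-valued markers (rCBV_max, TBR_max, TBR_mean, TTP)
are lognormal: μ = ln(median) and σ solved by root-finding so that
P(|X − median| ≤ MAD) = 1/2, the defining MAD property (tolerance 1e−8 on
the probability; requires MAD < median). Slope is normal
(σ = MAD/Φ⁻¹(0.75)) because its values straddle zero. Defaults reproduce
the reference cohort summaries: 83 TP / 21 TRC; rCBV_max 2.90 (1.00) vs
2.03 (0.52); TBR_max 2.20 (0.40) vs 1.90 (0.40); TBR_mean 2.00 (0.20) vs
1.90 (0.20); Slope 0.23 (0.45) vs 0.74 (0.41) SUV/h; TTP 32.5 (5.00) min in
both classes. A Gaussian copula couples rCBV_max and TBR_max; its
normal-scale ρ is calibrated analytically (bivariate-lognormal moment
formula) so the *observed-scale* Pearson r hits the target (default 0.55)
within a class. TTP is identically distributed in both classes — it is
generated, measured and reported, but by construction carries no signal,
mirroring its role as the marker that fails ROC screening.

**Curve mode** generates the raw inputs: a gamma-variate reference bolus
(onset at frame 10, shape α = 3, scale 1.5 frames, peak ΔR2\* 0.01 s⁻¹ —
the bolus shape is a free choice; any smooth unimodal curve exercises the
correction algebra identically) and a tumor curve that *is* the
Boxerman–Weisskoff generating model (K1 = true CBV ratio, configurable K2),
so the fit recovers both coefficients exactly at zero noise. Noise is
additive Gaussian on the signal, not Rician: the correction fit is linear,
so the noise family is not structural, and Gaussian keeps the Monte-Carlo
tests interpretable. PET curves have an exactly linear 20–40 min phase at
the true slope; the peak is placed at the frame nearest the true TTP by
adding a perturbation orthogonal to {1, t} on the window frames, which
provably leaves both the OLS slope and the window mean (hence the TBRs)
unchanged — so slope, TTP, TBR_mean and TBR_max all round-trip exactly.

**The deterministic fixture** is a 104-patient cohort (83 TP / 21 TRC)
whose marker values sit at ±0.10 around the cutoffs (2.85, 1.95, 0.69),
never on them. Group sizes (44 gated TP; then 37 + 2 TP and 12 + 9 TRC at
stage 2) are the unique integer solution consistent with the reference flow
counts 44/60/49/11, overall sensitivity 81/83, stage-2 sensitivity 37/39
and stage-2 NPV 9/11. Because each marker takes exactly two distinct
values, the fitted midpoint cutoffs land exactly on 2.85/1.95/0.69, and
leave-one-out refits are unchanged in every fold — the fixture is a fixed
point of the whole procedure. (The corresponding published stage-2
specificity/PPV figures of 0.45/0.78 cannot be realized by any integer
confusion table consistent with the counts above, which give 9/21 = 0.43
and 37/49 = 0.76; the fixture follows the mutually consistent subset.)

What the generators do **not** emulate: 3D anatomy, registration and motion
errors, arterial input variability, scanner harmonization, Rician noise
floors, ROI-delineation variability, or any link between a patient's DSC
and PET noise realizations. Passing tests therefore demonstrate correctness
of the estimators and the decision logic under the stated generative
assumptions — not clinical performance on real data, where the cutoffs are
known to be dataset- and toolbox-specific.

## Statistical machinery

* Mann–Whitney U via midranks; exact enumeration when n₁ + n₂ ≤ 12 with no
  ties, otherwise normal approximation with tie-corrected variance and
  continuity correction. Two identical constant samples return U = n₁n₂/2,
  p = 1.
* ROC thresholds at midpoints between distinct scores plus ±∞ endpoints;
  trapezoidal AUC (identical to the midrank U/(n₁n₂) — asserted
  internally); lower-positive markers are negated internally and thresholds
  reported in original units. AUC CI and p against 0.5 use the DeLong
  placement-variance estimator — the method is standard and
  assumption-light where no method is otherwise dictated; a perfectly
  separated sample has zero DeLong variance and is reported with a
  degenerate CI.
* Proportion CIs are Clopper–Pearson exact (coverage ≥ 95% by
  construction, verified empirically in the suite at n ∈ {21, 60, 83,
  104}); rates with zero denominators are undefined and carry no CI.
* Cohen's κ uses marginal-product expected agreement, with κ ≡ 1 when both
  raters are constant and identical (p_e = 1).
* Display rounding is half-away-from-zero: 2 decimals for rates, integer
  percent for headline accuracy/sensitivity (0.625 → 0.63, 86.54% → 87%);
  JSON output always retains full precision.

## Numerical choices and degenerate inputs

Lognormal calibration uses Brent root-finding on σ ∈ (10⁻⁶, 10) with a
sign-change precheck (failure raises a calibration error; MAD ≥ median is
rejected). The leakage fit refuses singular or near-singular normal
equations (condition number > 10¹²) and constant references. Nonpositive
DSC signal names the offending frame. TTP ties take the earliest frame.
Missing or non-finite marker values are rejected, never imputed. Infinite
cutoffs are accepted as degenerate gates (c₁ = +∞ reduces the sequential
rule to the PET rule; c₁ = −∞ calls everything TP at stage 1), which the
property tests exercise.

## Problem sizes

Defaults throughout are the study-scale conditions: 104-patient cohorts
(83/21), 50-frame DSC series, 5-min PET frames spanning 2.5–47.5 min.
Monte-Carlo checks use 200 replicates (leakage-fit noise recovery), 2,000
binomials per n (CI coverage), and 10⁴ scores per class (AUC calibration,
binormal construction with mean separation √2·Φ⁻¹(AUC), which makes the
population AUC exact by design).

## Known limitations

No prebolus-T1 modeling, AIF deconvolution, CBF/MTT, kinetic compartment
modeling, partial-volume correction, or image-space segmentation; inputs
arrive as ROI-level curves or pre-masked voxel sets. The fitted cutoffs are
estimates on whatever cohort is supplied and should not be transported
across scanners or post-processing pipelines without recalibration.
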