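# Methods

This note documents the models implemented in `glymphflow`, the design of the
synthetic-cohort generator, the numerical choices, and what the test suite
does and does not establish about real clinical data.

## Morphometry

Perivascular spaces (PVS) and ventricles are quantified as **relative area
ratios on single axial slices**: the structure's area divided by the area of
a reference region at the same level (brain parenchyma at the frontal-cortex
or ventricle level, the total basal ganglia, or the cerebellum at the level
of the fourth ventricle). Areas are foreground-pixel counts times the pixel
area, so the ratio is independent of pixel spacing whenever both masks are
rasterised from the same geometry.

Binarization defaults to **Otsu's threshold** — the de-facto default of
ImageJ-style workflows — with a manual-threshold override; a constant image
is rejected as degenerate rather than silently thresholded. "Inversion" is a
polarity convention: on T2 images the fluid-filled PVS and ventricles are
bright, and after binarize-and-invert they are the mask foreground. The
convention is recorded on the mask (`polarity`). An optional
connected-component size filter (`min_size`, default 1 = off) is exposed
because despeckling choices in manual workflows vary; it is off by default.
Everything is per-slice; no volumetry is attempted, since the measurements
the analysis consumes are defined at single anatomical levels.

## DCE model

Tissue gadolinium concentration follows the **extended (modified
two-compartment) Tofts model**

    Ct(t) = vp·Cp(t) + Ktrans ∫₀ᵗ Cp(τ) e^(−kep(t−τ)) dτ,

with Ktrans and kep in 1/min, ve = Ktrans/kep, and the physical constraint
ve + vp ≤ 1 enforced on parameter objects. The plasma term is included by
default (`vp_enabled=True`) and can be switched off to obtain the standard
two-parameter model.

* **Convolution.** The AIF is treated as piecewise linear and the
  convolution integral is evaluated by an exact per-interval recursion
  (closed-form integral of a linear segment against the exponential kernel,
  with a series branch for kep·Δt < 1e−4 that recovers the trapezoid rule as
  kep → 0). This is unconditionally stable on non-uniform grids and avoids
  FFT wrap-around; at the ~120-sample curves used here it is also fast.
* **Fitting.** Bounded nonlinear least squares (`scipy.optimize
  .least_squares`, TRF) over (Ktrans, kep, vp) with box bounds
  (0–5, 0–10, 0–0.5) and a fixed three-point multi-start grid spanning slow
  to fast exchange; the best-cost solution is returned with its residual RMS
  and a convergence flag (non-convergence is flagged, never raised). On
  noiseless forward curves the fit recovers parameters to machine precision;
  at SNR 20 the median |relative error| of Ktrans over 200 replicate curves
  is ≈ 1–2%.
* **Signal conversion.** Spoiled-gradient-echo steady state,
  S ∝ sin α (1 − E₁)/(1 − cos α E₁) with E₁ = exp(−TR·R1) and
  R1(t) = 1/T10 + r1·C(t). The equilibrium magnetisation is anchored on the
  pre-contrast baseline and the native T10; TE decay is neglected
  (TE = 0.8 ms ≪ T2*). Defaults: TR 2.8 ms, flip angle ≈ 15°, r1 = 5.0
  /mM/s (gadobutrol at 3 T), T10 = 1500 ms. Samples outside the invertible
  branch are clipped and counted, with a warning.
* **AIF.** `generate_aif` evaluates a bi-exponential population AIF with a
  configurable onset delay and a linear rise over the injection duration
  (default 10 s), which keeps Cp continuous so that trapezoid quadrature on
  the acquisition grid is accurate. The default shape is the Weinmann
  population parameterisation (a₁ = 3.99, a₂ = 4.78 kg/L; m₁ = 0.144,
  m₂ = 0.0111 /min); amplitude is linear in dose (mmol/kg → mM).

## CTC features

Features are computed per ROI-mean curve after subtracting the baseline
(mean of the pre-injection frames; default 5 frames):

* **peak concentration** — maximum of the baseline-subtracted raw curve, in
  mM. The peak *location* is taken from a 3-frame moving-average-smoothed
  copy: anchoring the post-peak segment at the raw argmax would select a
  noise spike and systematically inflate the wash-out estimate on short
  tails.
* **wash-in rate** — maximum forward-difference slope of the smoothed curve
  between contrast onset (first frame exceeding baseline + 3 baseline SDs)
  and the peak, in mM/min.
* **wash-out rate** — negated least-squares slope of the smoothed segment
  from the peak to the final frame, in mM/min, so clearance is positive. A
  flat or rising tail yields a non-positive value and is flagged
  (`washout_flagged`), not rejected.

mM/min was adopted as the rate unit throughout. The wash-in/wash-out
definitions are the common semi-quantitative DCE conventions; with smoothing
window 1 the pipeline degenerates to raw-curve estimates.

## Curve typing

Curves are clustered on the two features (wash-in rate, peak concentration),
**z-scored jointly across the pooled comparison groups** (a `standardize`
switch disables this). K-means uses k-means++ with 10 restarts; to make the
assignment invariant to input row order, the model is fitted on a
lexicographically sorted copy of the features and each row is then assigned
to the nearest fitted centroid. The cluster count is chosen by the **elbow
method**, operationalised as the k maximising the second difference of the
WCSS trace (ties → smallest k). For type labelling k = 2 is used: type I
(periarterial pattern) is the cluster with the greater centroid peak
concentration, ties broken by the greater centroid wash-in rate. The
pre-treatment comparison (NC + OSA_pre) and the post-treatment comparison
(NC + OSA_post) are clustered as two separate pooled runs.

## Statistics

* **Mann–Whitney U**: two-sided; exact null distribution when the pooled
  sample has ≤ 20 observations and no ties, otherwise the normal
  approximation with tie and continuity corrections. At the small group
  sizes typical here both variants are slightly conservative (empirical
  size ≈ 4–5% at α = 5%).
* **Chi-square**: Pearson, df = 1, no Yates correction, zero marginals
  rejected.
* **ROC**: trapezoidal AUROC over all thresholds; automatic orientation
  (AUROC ≥ 0.5) unless fixed; operating point maximises Youden's J with
  ties resolved toward higher specificity; the p-value against chance is
  the Mann–Whitney p between the class score distributions. AUROC equals
  U/(n₁n₂) exactly, including ties.
* **Spearman matrix**: pairwise-complete, midrank ties, t-approximation
  p-values; constant variables yield NaN with a warning. Strength categories
  (|ρ| ≥ 0.6 strong, ≥ 0.4 moderate, ≥ 0.2 weak — configurable) are an
  interpretive convention. No multiple-testing correction is applied by
  default; a Benjamini–Hochberg switch is available.
* **Severity classes**: AHI < 5 no OSA, 5 ≤ AHI < 30 mild–moderate,
  AHI ≥ 30 severe; LSaO₂ ≥ 90% none, 80 ≤ LSaO₂ < 90 mild, < 80 severe
  hypoxemia. Boundary values follow the printed inequalities.

## Synthetic cohort

The generator emulates a three-group study — NC (25), OSA before CPAP (11),
OSA after CPAP (13) — with a 0.1 mmol/kg dose and a 9 min 59 s acquisition
sampled every 5 s (120 frames; the 5 s spacing is a design choice that
resolves wash-in while matching the total duration).

* **Curves.** Each subject contributes a truncated-Poisson number of curves
  (group means 9.44 / 23.0 / 14.0 — the NC and OSA_pre values follow from
  the per-group curve totals and subject counts of the study design; the
  post-treatment total is internally inconsistent in its source, so its mean
  is a free parameter set between the candidate values). Each curve is
  type I with probability 0.3566 (NC), 0.4384 (OSA_pre) or 0.4608
  (OSA_post), drawn from type-specific Tofts parameter distributions
  (type I: Ktrans 0.13 ± 0.022, kep 0.35 ± 0.042, vp 0.015 ± 0.004;
  type II: Ktrans 0.03 ± 0.006, kep 0.30 ± 0.045, vp 0.006 ± 0.002), run
  through the forward model and corrupted with additive Gaussian noise
  (default SD 0.0018 mM ⇒ SNR ≈ 20 at the mean type-I peak).
* **Acquisition AIF.** The simulated acquisition uses a bolus-dominant
  bi-exponential (a₁ = 8 kg/L, m₁ = 2/min; a₂ = 0.4 kg/L, m₂ = 0.3/min;
  onset 30 s, rise 10 s). The regime matters: under a slow plasma decay the
  tissue curve sits in quasi-equilibrium, where the measured wash-out slope
  is proportional to ve × (AIF decay) and *increases* with any amplitude
  increase — making "higher peak and lower wash-out" simultaneously
  unreachable. With a bolus-dominant input the peak scales with
  Ktrans × AUC and the wash-out with kep × amplitude, so reduced efflux
  genuinely lowers the measured wash-out. This is also the physiologically
  intended reading: impaired glymphatic clearance = slower efflux.
* **Group effects** are multiplicative: OSA_pre type-I curves get an
  amplitude factor 1.1 (on Ktrans and vp; the measured peak rises further
  through the slower efflux) and a kep factor 0.5; OSA_post type-II curves
  get an amplitude factor 1.3. A per-subject latent severity s (N(−2, 0.35)
  for NC, N(0, 1) for OSA) modulates every subject's curves through
  *group-centred* couplings exp(+0.05·(s − E[s|group])) on amplitude and
  exp(−0.30·(s − E[s|group])) on kep, so group means are set by the
  multipliers alone while within-group wash-out falls with severity.
* **Covariates** are one shared linear model in s plus Gaussian noise,
  clipped to instrument ranges (e.g. AHI = 28.9 + 15·s ± 3, LSaO₂ =
  79.7 − 7·s ± 2, MMSE = 27.7 − 1.8·s ± 0.8); the intercepts and slopes are
  anchored to the OSA group's published summary statistics, and the group
  difference arises purely from the severity distributions. This is the
  simplest monotone structure from which Spearman correlations recover the
  expected signs (AHI/ODI negative with type-I wash-out, MMSE/MoCA
  positive).
* **Slice phantoms.** Four levels per subject: brain disc + scattered PVS
  pixels (frontal), basal-ganglia ellipse + PVS pixels, brain disc + two
  mirrored ventricle ellipses, cerebellum disc + fourth-ventricle ellipse.
  Structure areas scale as exp(β·(s − E[s|NC])) (β 0.20–0.40 per structure)
  with a lognormal per-subject jitter (CV 8%); PVS pixels are sampled
  without replacement inside the reference region until the target pixel
  count is reached, so the recorded ground-truth area is exactly the pixel
  count × pixel area and requests exceeding the region raise.
* **Null configuration.** `null_config()` sets every multiplier to 1 and
  equalises the type-I fraction, curve-count and severity distributions
  across groups, making the group label exchangeable; it is the basis of the
  type-I-error calibration.
* **Determinism.** A single seed feeds a `numpy` `SeedSequence`; the
  pipeline splits it into independent per-stage child seeds so toggling one
  stage does not perturb another. Identical config + seed gives bit-identical
  cohorts and reports.

**What the generator does not emulate:** scanner physics and artefacts
(no k-space simulation, no motion, no spatially varying noise), realistic
anatomy (phantom discs and ellipses, PVS as scattered pixels rather than
tubular structures), partial-volume effects, within-subject correlation
beyond the severity coupling, longitudinal pairing of the pre/post arms
(OSA_pre and OSA_post are independent draws), and measured-AIF variability.
Passing tests therefore establish that the *analysis* is correct and
calibrated under its stated model, not that the clinical effect sizes would
be recovered from real scanners.

## Problem sizes and numerical choices

* Null calibration uses 1000 replicate null cohorts of 16 + 16 subjects with
  4 curves/subject and 96-pixel phantom grids — small enough to replicate
  densely, large enough that the Mann–Whitney approximations are in their
  calibrated range.
* Planted-cluster checks use n = 400 points, 100 replicates, populations
  4 SD apart per feature (the two-feature Bayes accuracy at that separation
  is ≈ 99.8%).
* Parameter-recovery checks use 200 replicate curves at SNR 20.
* Ties in K-means elbow selection resolve to the smallest k; degenerate
  (all-identical) feature sets are rejected for k > 1; k-means determinism
  comes from a fixed seed plus the sorted-fit/nearest-centroid assignment.
* Convolution switches to a series expansion when kep·Δt < 1e−4; the SPGR
  inversion clips non-physical samples and reports the count.

## Known limitations

* The wash-out rate of a curve that peaks near the end of the acquisition is
  estimated from a short tail and is noise-limited; such curves are flagged.
* The extended-Tofts constraint ve + vp ≤ 1 caps Ktrans at 0.9·kep in the
  generator; at extreme simulated severities this cap binds and attenuates
  the amplitude coupling.
* Area ratios are single-slice quantities; no partial-volume or slice
  -placement variability is modelled.
* The per-curve type labels in the OSA arms are i.i.d. given the group,
  so per-subject type-I counts are binomial; real subjects likely carry
  correlated anatomy.
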