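# Methods

This note records the models, the synthetic-data assumptions, the numerical
choices, and the known limits of what the test suite demonstrates.

## Signal layer

**Hit detection.** Acquisition is emulated sample-wise on the rectified raw
voltage (μV), with amplitudes expressed in dB re 1 μV
(`20·log10(v/1 μV)`; the 36 dB machine threshold corresponds to 63.1 μV).
A hit opens at the first at/above-threshold sample outside any earlier
hit's closing or lockout window; above-threshold samples within the
*hit-definition time* of the last one extend it; the hit closes that time
after its last above-threshold sample, followed by a lockout during which
no hit may open. Per hit we record onset, peak amplitude (max rectified
sample), average signal level (dB of the mean rectified voltage over the
hit window) and duration. Defaults — hit definition 800 μs, peak
definition 200 μs, lockout 1000 μs — are conventional wide-band AE
acquisition values; the true machine parameters are unpublished, so these
are declared, configurable choices, not inferences. No software band-pass
filter is applied: the wide (20–400 kHz) and narrow (20–80 kHz) acquisition
ranges are represented as a configuration label only. Consequences tested:
raising the threshold cannot increase the hit count on burst-like signals
(pathological dips between merged bursts can violate this in principle);
bursts closer than the hit-definition time merge into one hit; the
detector agrees *exactly* with a per-sample state-machine oracle on random
signals, including adversarial ones hovering at the threshold.

**Segmentation.** The goniometer angle (flexion positive; seated ≈ 90°,
standing ≈ 0–5°; "ascending" = standing up = decreasing angle — the sign
convention is ours) is smoothed with a zero-phase 4th-order Butterworth
low-pass, default cutoff 2 Hz (well above the ~0.2–0.5 Hz movement
cadence); velocity and acceleration are central differences on the
smoothed series. Cycles span the departure below the mid-range crossing to
the return crossing, extended outward to the adjacent seated rests (where
angular speed falls below max(2°/s, 2% of peak)); the crossing level is
computed from the trace's own 5th/95th percentiles, making segmentation
invariant to constant angle offsets. Each half-movement is split at its
maximum angular speed (earliest sample on ties) into
acceleration/deceleration quadrants; on a noiseless raised-cosine cycle of
period T these boundaries are exactly T/4, T/2, 3T/4. Quadrant intervals
are half-open and tile the cycle, so boundary hits are assigned
deterministically to the later quadrant, and per-quadrant counts plus the
off-cycle count always conserve the total. An angle-midpoint split is
deliberately not used: "accelerating/decelerating" is well defined only
relative to the speed peak.

**Biomarkers.** The unit of analysis is one recorded set of five
movements, so each session contributes two observations. Feature profiles
are 2D histograms of (ASL, peak amplitude) per quadrant; default grid
30–90 dB × 36–100 dB, 8×8 bins per quadrant (256-dim flattened), values
outside the ranges clamped into edge bins. The grid is fingerprinted and
the PCA basis refuses profiles from a different grid. Histograms enter the
PCA unnormalized by default so the components carry intensity as well as
shape; a normalized mode exists. The basis (scikit-learn PCA: column-mean
centring, top right singular vectors) is fitted once on a developmental
subset and frozen; evaluation profiles are only projected. Bin counts and
normalization for the original analysis are unstated, hence exposed as
configuration rather than guessed as fixed truths.

## Synthetic data

The measurement-level generator produces
`y = β₀ + a(KL) + β_w·(weight − mean) + β_p·pain + machine offset
+ u_patient + u_session + u_day + u_RP + ε`, all random effects
independent Gaussians shared by their grouping unit; the two sets of a
session differ only by ε. Counts are generated continuous (the analysis
models are Gaussian), with an integer mode (rounded, clipped at 0) for
realism; recovery experiments use the continuous mode. Defaults are the
study-scale estimates: fixed effects β₀ = 160.13, KL successive
differences (−81.77, 22.54, 38.39), weight 2.06 hits/kg, contralateral
pain 57.05; SDs patient 82.06, session-in-patient 46.02, practitioner
6.05, residual 18.74; the day-in-patient default 31.5 is chosen so the
combined session+day variance matches the longitudinal day-in-patient SD
of 55.75. Machine offsets default to (0, 20.39, −66.38) relative to
machine 1; participants are randomised to one machine for all sessions
(the real assignment scheme is unstated). Covariate laws mimic the
reported cohort: KL proportions 12/22/27/7, weight ~ N(85, 16²) kg
(clipped), pain ~ Bernoulli(0.5), plus inert age/sex/BMI/WOMAC/VAS columns
for selection experiments. Day-1 sessions enumerate the three
practitioners in random order; later days use one practitioner drawn from
that day-1 set.

Raw signals: angle traces are raised-cosine excursions with Gaussian
noise and seated rests; hit onsets are multinomial over quadrants
(default 0.4/0.1/0.1/0.4, skewed to the high-load Q1/Q4 phases) and
uniform within a quadrant's intervals; peak amplitudes are
threshold + Exponential(mean 8 dB) truncated at 100 dB, ASL = peak −
Uniform(5, 15) dB — no amplitude law is published, these are explicit
stand-ins. Waveforms embed one decaying-cosine burst per hit (cosine
carrier so the onset sample attains the peak voltage exactly) in Gaussian
noise at least 6 dB below threshold. What the generator does *not*
emulate: physiological waveform shape, sensor-coupling physics,
bilateral cross-talk, non-Gaussian count dispersion, covariate
correlations (e.g. weight–BMI), or missingness mechanisms. Passing
recovery tests therefore demonstrates correctness of the estimation
pipeline under the assumed model, not robustness to real-data violations
of it.

## Estimation

**REML engine.** Both reproducibility models and the association model are
fitted by a purpose-built Gaussian mixed-model engine. The marginal
covariance V = A + σ_RP²·U·Uᵀ has per-patient blocks
A_i = σ_e²I + σ_p²J + σ_w²·blockdiag(J) (tiny, and identical across
identically shaped patients, so each is inverted once) plus a crossed
practitioner term handled by the Woodbury identity with an r×r inner
solve (r = 3 practitioners). −2·(restricted) log-likelihood is
`log|V| + log|XᵀV⁻¹X| + rᵀV⁻¹r + (n−p)·log 2π` at the GLS β. Variance
parameters are optimised on the SD scale by bounded Nelder–Mead
(restarts from jittered initialisations; convergence tolerance 1e-8 per
observation on the criterion), so estimates can sit exactly on the 0
boundary — gradient-based optimisers proved unreliable on this surface.
A relative floor of 1e-6·sd(y) on the residual SD keeps blocks positive
definite when profiling it to 0. The engine reproduces statsmodels
MixedLM (random-intercept case) and lme4 (crossed case) to ~6 significant
figures including the REML log-likelihood; a balanced one-way layout is
also checked against the closed-form ANOVA moment estimators.

**Confidence intervals.** Random-effect SDs get profile-likelihood
intervals from the profiled restricted likelihood (chi-square(1) cut),
truncated at 0 — near-null components correctly report a 0.00 lower
limit. Fixed effects default to Wald-normal intervals; an ML-profile
variant (pinning a coefficient via an offset and re-optimising the
variances) is available, and at these sample sizes the two coincide
closely. Profiling brackets geometrically and falls back to the widest
bracket with a warning if the upper limit does not bracket.

**Model fitting protocol.** Forward selection uses full maximum
likelihood (likelihoods comparable across fixed-effect structures),
adding the candidate with the smallest LRT p-value while p < 0.1;
rank-deficient additions are skipped and logged; the final model is
refitted by REML on complete cases (no imputation), with the dropped-row
count recorded. KL is coded with successive-difference contrasts so each
coefficient is an adjacent-grade difference (grade j minus grade j+1)
and the intercept is the unweighted across-grade average at mean weight
and no contralateral pain. The day-one model treats practitioner as
crossed with patient (each practitioner measured every patient on day 1);
whether the original analysis nested it instead is unknown. The
covariate-adjusted reproducibility variant adds KL, centred weight and
contralateral pain — the original adjustment set is unstated, so this
default is configurable.

**Power.** The trial simulator draws participant means
(SD = sqrt(σ_b² + σ_e²/m)) for two arms, reduces the treated mean by the
effect fraction, and applies a two-sided two-sample t-test; it matches
the closed-form normal-approximation power within binomial error, and a
bisection finds the smallest n reaching a target power under a
deterministic per-n seed stream. The published requirement of roughly 400
participants per group is *not* a target: a naive calculation from the
reported components needs far fewer, so the figure must rest on unstated
assumptions (variance inflation, dropout, analysis model), which the
calculator exposes as explicit inputs instead of hard-coding.

## Recovery experiments and problem sizes

Because the clinical data are not public, headline numbers are verified
by parameter recovery (`kneeae.experiments`, driven by
`scripts/acceptance.py`): the generator is configured with the published
estimates as truths and the fits must return them. Sizes used: day-one
model — 500 patients × 3 sessions × 2 sets; longitudinal model — 500
patients × 6 measurement days × 2 sets (the day random effect is iid, so
only the day count matters, and six days represents the
three-consecutive-days-plus-weekly-visits schedule); association model —
50 replicates of 1000 participants × 2 measurements, reporting replicate
means. At these sizes the Monte-Carlo SE of each recovered SD is ~1–3% of
its value, except the practitioner SD: with only three levels its
single-fit estimator has ~100% sampling CV, so it is only meaningfully
checked as a replicate average. Test-suite simulations use smaller sizes
(tens to hundreds of participants, 60–1000 replicates) chosen so each
check retains ≥ 3–4 SE of resolution.

## Known limitations

* Gaussian models for count data (following the original analysis); the
  integer generator mode exists but no Poisson/negative-binomial fitter.
* The practitioner variance is weakly identified with three levels —
  estimates and intervals for it are honest but near-uninformative.
* Threshold monotonicity of the hit count is a property of burst-like
  signals, not of arbitrary waveforms.
* Only the worst knee's candidates are modelled; contralateral profiles
  and frequency-domain features are out of scope.
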