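# Methods

This note documents the generative model, the estimators, the numerical
choices, and the limits of what the package's passing tests demonstrate.

## Study design being emulated

A cohort of heavy female pork carcasses (default n = 60) contributes two
muscles each: the loin (LTL) and the topside (SM).  Every sample carries
four chemistry traits — ultimate pH, intramuscular fat (IMF, % fresh
weight), collagen content (mg/g) and collagen solubility (%) — a triplet of
handheld-NIRS predicted-IMF readings, and (loin only) three replicate CPMG
relaxometry measurements.  Ten consumers taste each cooked sample in a
session structure: sessions of 12 samples and 20 participants over three
days, each participant evaluating six samples, participants nested in
sessions.  Serving order (the Latin-square arrangement of a real panel) is
not modelled; order effects are absorbed into the residual.

## Synthetic cohort

**Traits.** Each trait/muscle pair is a truncated normal.  Means come from
the published per-muscle summary; SDs are recovered from printed SEMs as
`SD = SEM·√60`; truncation bounds are the printed trait ranges.  Because
the printed ranges are asymmetric about the means, the generator solves for
the pre-truncation location whose truncated mean equals the target mean
(Brent's method on the truncated-normal mean), so large-cohort trait means
land on their configured values.

**Between-muscle dependence.** A shared-carcass latent factor with weight
√ρ per muscle (ρ = √R²_target) makes the latent pair bivariate normal with
correlation ρ, hence squared correlation R²_target.  Under truncation the
latent normals are pushed through the truncated-normal quantile function (a
Gaussian copula), which preserves exact truncated marginals; the Pearson
correlation attenuates mildly (≈6% relative for the pH coupling), which is
why calibrated recovery experiments run untruncated (below).

**Instrument links.** The NIRS device reading is
`latent = a₀ + a₁·IMF + N(0, σ_b²)` with three replicate readings
`latent + N(0, σ_r²)` kept positive; the relaxation amplitude is
`p_2f = c₀ + c₁·(IMF − mean) + c₂·(pH − mean) + N(0, σ²)`.  The remaining
amplitudes p_21, p_22 are drawn around their compartment defaults and
rescaled to fill `1 − p_2f`, preserving the calibrated p_2f exactly;
T_21 and T_22 are Gaussian around their defaults.

**Calibration.** A published simple-regression summary (slope, R², RMSE) of
trait y on instrument output x determines the joint second moments exactly:

    Var(y) = RMSE²/(1 − R²)
    coef   = R²/slope            (generator coefficient of x on y)
    Var(u) = coef²·Var(y)·(1 − R²)/R²   (instrument noise)

These identities invert in closed form (checked to 1e-10 in the tests), so
simulated cohorts reproduce the published summaries in expectation and any
systematic deviation in a recovery experiment indicts the estimator, not
the generator.  When the analysed predictor is the mean of k replicate
readings, σ_r²/k is subtracted from the calibrated total instrument noise.

**Compartment defaults.** `p_2f ≈ 0.05`, `p_21 ≈ 0.85`, `p_22 ≈ 0.10`,
`T_21 = 40 ms`, `T_22 = 150 ms` are package defaults motivated by the
usual assignment of muscle water pools, not published point estimates; they
are configuration-overridable.  The residual SDs of the latent relaxation
parameters (p_21 0.05 raw / ≈0.031 after renormalization, p_22 0.035 raw,
T_21 1.3 ms, T_22 5.8 ms) are calibrated so the single-predictor sensory
models reproduce the published standard errors of their slopes at the study
design size — the only information the source tables carry about these
spreads.

**Sensory panel.** Each 0–100 line score is

    score = intercept(muscle) + Σ_j slope_j·(x_j − center_j)
            + u_session + u_participant(session) + u_carcass + ε

truncated to [0, 100] by default (a switch disables truncation for exact
recovery experiments; truncation induces mild attenuation).  Slope defaults
are the published chemistry→score coefficients; random-effect SDs are *not*
published anywhere and the defaults — session 3, participant 10, carcass 5,
residual 15 score points — are declared arbitrary but produce slope
standard errors matching the published tables within ~10%.  Off-flavor is
Bernoulli through an inverse-logit of a muscle intercept plus the shared
random effects scaled by 0.05 per score point; purchase intent (1–5) and
quality grade (1–4) are threshold cuts of a latent standard normal sharing
the same scaled random effects, with the success-boundary cut placed by
probit inversion so the marginal success probabilities default to the
published values (0.298/0.351 purchase, 0.284/0.318 quality) and the
remaining cuts spaced 0.8 latent SDs apart.

**Acquisition.** Echo times are k·0.3 ms, k = 1…2000 (polarization delay
750 ms is carried as metadata only).  Each echo is the mean of
`points_per_echo` (default 4) points with i.i.d. Gaussian noise of the
per-scan SD; scans are averaged until the estimated SNR exceeds 200 or
`max_scans` is hit (then flagged).  Noise is Gaussian and independent; the
Rician floor at long echo times is ignored, defensible in the SNR > 200
regime.  The true per-scan SNR of such benchtop devices is not published;
the default per-point noise SD of 0.04 (per-scan SNR 50, roughly 15 scans to
threshold) is a guess and configuration-overridable.

**Determinism.** One global seed fans out to fixed-offset child streams per
stage (cohort, NIRS, NMR link, sensory, echo), so disabling a stage does
not shift the randomness of another, and identical config + seed gives
byte-identical CSV outputs.

## Estimators

**Tri-exponential fit.** Bounded nonlinear least squares by variable
projection: for any `(T_21, T_22)` the three absolute amplitudes enter the
model linearly and are solved exactly by NNLS, so the outer optimisation
(scipy `least_squares`, trust-region reflective, ftol = xtol = gtol =
1e-12) runs over the two log time constants only, multi-started from a 4×4
log-spaced grid over the bound boxes T_21 ∈ (10, 100] ms, T_22 ∈
(100, 2000] ms.  The fast time constant is fixed at 10 ms.  Amplitude
nonnegativity is structural (NNLS); fractions are amplitudes over their
sum, the sum being the t = 0 scale.  If the fitted slow time constants come
within 5% of each other the fit is flagged degenerate and the merged
amplitude is reported on p_21 — identifiability loss is surfaced, never
silently returned.  Replicate aggregation averages the five free fitted
parameters (and scale) across the three measurements of a sample; averaging
the echo trains before a single fit is available behind a config switch.

**Noise and SNR.** With a fit in hand, noise SD = RMS fit residual;
without one, the SD of first differences over the last 10% of echoes
divided by √2 (differencing cancels the locally constant tail signal; its
residual curvature leaves a floor around 1e-7 of scale on noiseless
trains).  SNR = t = 0 model intensity over noise SD, the t = 0 intensity
extrapolated by a log-linear fit to the first ten echoes when no model fit
is available.  Both definitions are package choices; the source protocol
names only the SNR > 200 stopping rule.

**Regression layer.** Closed-form simple linear regression; slope SE from
residual variance; p two-sided from t with n − 2 df; R² = 1 − SSE/SST;
RMSE = √(SSE/(n−2)) by default with √(SSE/n) behind a flag (the two differ
by <1% at n = 120).  Correlation matrices use pairwise-complete
observations; the two-muscle trait contrast is the pooled-variance
two-group linear model (no random terms are fitted because none are
published for that table).  No multiple-testing correction is applied,
matching the source analysis.

**Mixed models.** Linear mixed models via statsmodels MixedLM with the
three crossed grouping factors encoded as variance components inside a
single all-spanning group; participant keys are composed as
session:participant so nesting is structural.  REML estimation tries
L-BFGS, then BFGS, then CG, accepting the first converged optimum (checked
against lme4's REML fixed effects on identical data in the test suite); if
none converges the smallest-variance component is dropped with a warning
and the model refit.  Fixed-effect p-values use the Wald normal
approximation — denominator-df corrections (Satterthwaite/Kenward–Roger)
are not reproduced, which makes p-values slightly liberal in small designs;
the type-I-error test budgets for this with a binomial envelope.  The
continuous 0–100 scores use an identity link (the published slope scales,
e.g. ~14 score points per pH unit, are only consistent with an untransformed
response).  One canonical random structure — session / participant-in-
session + carcass — is used everywhere even though the source tables vary
in their notation of it; this is a deliberate, documented simplification.
Binomial success probabilities use a logit-link GLM per muscle (equivalent
to the raw proportion) when no random structure is requested, and the
statsmodels variational Bayesian binomial mixed model with a delta-method
SE otherwise; boundary proportions (0 or 1) are returned directly.

## Recovery experiments and problem sizes

The acceptance experiments simulate at the study's own design sizes: 200
cohorts of n = 120 (pooled NIRS regression) or n = 60 (loin NMR links and
the cross-muscle pH regression), and 100 simulated panel studies of 60
carcasses for the hierarchical-model recoveries (both muscles × 10
consumers for the chemistry model; loin × 10 consumers for the
single-predictor model).  The type-I-error study runs 150 reduced-design
panels (20 carcasses, 5 consumers per sample).  At these sizes the
Monte-Carlo SD of an averaged recovered slope is 1.5–4% of its true value,
comparable to the recovery tolerances; the experiments are therefore
sharp tests of unbiasedness but individual runs sit within a band of that
width around truth.

## What passing tests do and do not show

The generator draws truncated Gaussians with linear links; real pork data
have skewed IMF distributions with occasional high outliers, muscle
heterogeneity within a sample, device drift, and freeze–thaw effects on
relaxation parameters — none of which are modelled.  Parameter recovery
here validates the estimation chain (fit geometry, model reduction,
nesting, calibration algebra); it does not validate the scientific model
against real muscle.  Echo-train noise is white Gaussian; no Rician floor,
no T1 contamination, no temperature dependence.  The NIRS device is a
scalar oracle with linear error — its internal spectral calibration is out
of scope.  Ordinal responses are collapsed to binary successes; no
cumulative-link model is fitted.
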