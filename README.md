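# meatq

Simulation and analysis toolkit for rapid, non-destructive meat-quality
phenotyping studies: benchtop **CPMG NMR relaxometry**, handheld **NIRS**
intramuscular-fat prediction, wet chemistry, and **consumer sensory panels**,
for a two-muscle pork design (loin *Longissimus thoracis et lumborum*, LTL,
and topside *Semimembranosus*, SM).

The package is built for methodologists who want to exercise the full
analysis chain of such a study — multi-exponential T2 decomposition,
regression chemometrics, and mixed-effects sensory association — on
synthetic cohorts with known ground truth, so every estimator can be
validated by parameter recovery before it ever touches real data.

## The models at the core

**Transverse relaxation.** A CPMG echo train from muscle is modelled as a
three-pool decay with the fast pool's time constant fixed to stabilize the
fit:

```
I(t) = s · ( p_2f e^(−t/T_2f) + p_21 e^(−t/T_21) + p_22 e^(−t/T_22) ),   T_2f = 10 ms
```

`p_2f` (macromolecule/fat-associated), `p_21` with `T_21` (water within the
myofibrillar lattice) and `p_22` with `T_22` (inter-myofibrillar water) are
fractions summing to one.  The fitter uses variable projection — amplitudes
solved exactly by nonnegative least squares at each candidate
`(T_21, T_22)` — under a log-spaced multi-start, which makes the multimodal
objective safe and lets degenerate components reach exactly zero.
Acquisition is emulated faithfully: 2000 echoes at 0.3 ms spacing, points
within each echo averaged, scans signal-averaged until SNR > 200.

**Chemometrics.** Simple linear model summaries (slope ± SE, R², two-sided
p at n−2 df, RMSE = √(SSE/(n−2))), Pearson correlation matrices with
pairwise-complete observations, per-sample NIRS triplet aggregation (mean,
geometric mean, maximum), and between-muscle trait regressions (SM on LTL).

**Sensory association.** Consumer line scores (0–100) are linked to
chemistry or instrument outputs with linear mixed models: fixed slopes plus
random intercepts for session, participant nested in session, and carcass.
Binary/ordinal responses (off-flavor, purchase intent, quality grade) get
logit-link binomial models with per-muscle success probabilities.

**Synthetic cohorts.** Trait distributions are truncated normals at
published per-muscle means/SDs/ranges, coupled across muscles by a
shared-carcass latent factor; instrument links (NIRS from IMF, relaxation
amplitudes from IMF and pH) are calibrated *analytically* from published
(slope, R², RMSE) regression summaries via

```
Var(y) = RMSE²/(1−R²),   coef = R²/slope,   Var(noise) = coef²·Var(y)·(1−R²)/R²
```

so recovery experiments probe the estimators, not the generator.

## Worked example

```python
from meatq import synthetic, relaxfit
from meatq.config import AcquisitionConfig, default_cohort_config
from meatq.chemometrics import add_nirs_aggregates, ols_regression

# a 60-carcass cohort with both muscles, NIRS readings attached
cfg = default_cohort_config(n_carcasses=60, seed=1)
cohort = add_nirs_aggregates(synthetic.generate_nirs(synthetic.generate_cohort(cfg), cfg))

# pooled regression of chemical IMF on the mean device output
s = ols_regression(cohort["nirs_mean"], cohort["imf_pct"])
print(f"slope = {s.slope:.3f} ± {s.slope_se:.3f}, R² = {s.r2:.3f}, "
      f"p = {s.p_value:.2g}, RMSE = {s.rmse:.3f}, n = {s.n}")

# one loin measurement: acquire to SNR > 200, then decompose
ltl = cohort[cohort["muscle"] == "LTL"].reset_index(drop=True)
params = synthetic.link_nmr(ltl, cfg.nmr, synthetic.stage_rng(cfg.seed, "nmr"))
train = synthetic.acquire_with_averaging(
    synthetic.nmr_params_from_row(params.iloc[0]), AcquisitionConfig(), seed=1
)
fit = relaxfit.fit_triexponential(train)
print(f"scans = {train.n_scans_averaged}, SNR = {train.snr_estimate:.0f}")
print(f"p_2f = {fit.params.p_2f:.4f}, p_21 = {fit.params.p_21:.3f}, "
      f"T_21 = {fit.params.t_21_ms:.1f} ms, T_22 = {fit.params.t_22_ms:.0f} ms")
```

prints

```
slope = 0.432 ± 0.073, R² = 0.230, p = 2.9e-08, RMSE = 0.379, n = 120
scans = 14, SNR = 205
p_2f = 0.0470, p_21 = 0.835, T_21 = 40.0 ms, T_22 = 151 ms
```

The regression line says each unit of device output corresponds to ~0.43 %
additional chemical IMF in this cohort draw, with the weak R² typical of
low-IMF pork; the relaxometry measurement averaged 14 scans to clear the
SNR-200 stopping rule, and the fit recovers the latent compartment
structure of that sample from its noisy averaged echo train.

The same chain runs end to end from the shell:

```sh
meatq all --seed 1 --outdir run1          # simulate -> fit -> analyze
meatq simulate --config my_config.yaml    # cohort + echo trains + panel only
```

`run1/report.json` then carries every analysis table (muscle contrasts,
success probabilities, chemistry and instrument slope tables, cross-muscle
regressions), and the intermediate CSVs are written alongside.  A fully
commented default configuration ships at
`src/meatq/data/default_config.yaml`.

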