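cohort:
  n_carcasses: 60
  traits:
    pH:
      mean:
        LTL: 5.56
        SM: 5.65
      sd:
        LTL: 0.10844353369380767
        SM: 0.139427400463467
      lower:
        LTL: 5.33
        SM: 5.46
      upper:
        LTL: 5.88
        SM: 5.99
      cross_muscle_r2: 0.273
    collagen_mg_g:
      mean:
        LTL: 4.56
        SM: 4.73
      sd:
        LTL: 0.5654555685462829
        SM: 0.836564402780802
      lower:
        LTL: 3.51
        SM: 3.21
      upper:
        LTL: 5.57
        SM: 8.51
      cross_muscle_r2: 0.214
    collagen_solubility_pct:
      mean:
        LTL: 10.2
        SM: 9.19
      sd:
        LTL: 1.9984594066430272
        SM: 1.8512860394871453
      lower:
        LTL: 6.13
        SM: 5.78
      upper:
        LTL: 18.5
        SM: 13.4
      cross_muscle_r2: 0.104
    imf_pct:
      mean:
        LTL: 1.04
        SM: 1.38
      sd:
        LTL: 0.3950443013131565
        SM: 0.5034878350069643
      lower:
        LTL: 0.443
        SM: 0.579
      upper:
        LTL: 2.25
        SM: 2.84
      cross_muscle_r2: 0.044
  nmr:
    p2f_intercept: 0.05
    coef_imf: 0.0046792
    coef_ph: -0.0273333
    p2f_sd: 0.0035
    p21_mean: 0.85
    p21_sd: 0.05
    p22_mean: 0.1
    p22_sd: 0.035
    t21_mean_ms: 40.0
    t21_sd_ms: 1.3
    t22_mean_ms: 150.0
    t22_sd_ms: 5.8
    t2f_ms: 10.0
    imf_center: 1.04
    ph_center: 5.56
  nirs:
    intercept: 0.5881
    slope: 0.5139
    between_sd: 0.4139
    replicate_sd: 0.1
  truncate: true
  seed: 0
acquisition:
  n_echoes: 2000
  echo_spacing_ms: 0.3
  polarization_delay_ms: 750.0
  points_per_echo: 4
  noise_sd: 0.04
  snr_threshold: 200.0
  max_scans: 512
fit_options:
  fixed_t2f_ms: 10.0
  t21_bounds_ms:
  - 10.0
  - 100.0
  t22_bounds_ms:
  - 100.0
  - 2000.0
  n_starts_per_axis: 4
  tolerance: 1.0e-12
  max_iterations: 200
  start_jitter_seed: 0
  degenerate_ratio: 1.05
sensory:
  intercepts:
    tenderness:
      LTL: 48.8
      SM: 51.7
    juiciness:
      LTL: 48.1
      SM: 54.1
    flavor:
      LTL: 52.0
      SM: 54.0
    overall:
      LTL: 52.0
      SM: 54.7
  slopes:
    tenderness:
      pH: 14.1
      collagen_mg_g: -3.86
      collagen_solubility_pct: -0.79
      imf_pct: 0.4
    juiciness:
      pH: 12.6
      collagen_mg_g: -2.76
      collagen_solubility_pct: -0.83
      imf_pct: 0.88
    flavor:
      pH: 11.7
      collagen_mg_g: -2.6
      collagen_solubility_pct: -0.68
      imf_pct: 2.91
    overall:
      pH: 14.2
      collagen_mg_g: -3.42
      collagen_solubility_pct: -0.69
      imf_pct: 1.58
  centers:
    pH: 5.605
    imf_pct: 1.21
    collagen_mg_g: 4.645
    collagen_solubility_pct: 9.695
  sd_session: 3.0
  sd_participant: 10.0
  sd_carcass: 5.0
  sd_residual: 15.0
  truncate: true
  no_off_flavor_prob:
    LTL: 0.996
    SM: 0.992
  purchase_success_prob:
    LTL: 0.298
    SM: 0.351
  quality_success_prob:
    LTL: 0.284
    SM: 0.318
  logit_re_scale: 0.05
  consumers_per_sample: 10
  samples_per_session: 12
  participants_per_session: 20
  n_days: 3
seed: 0
outdir: meatq_out
stages:
- simulate
- fit
- analyze
n_replicates: 3
average_trains_before_fit: false
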