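"""Distributional and determinism contracts of the synthetic generator."""

import numpy as np
import pandas as pd
import pytest

from meatq import synthetic
from meatq.calibration import RegressionTarget, solve_reverse_link
from meatq.chemometrics import ols_regression
from meatq.config import (
    AcquisitionConfig,
    ConfigurationError,
    NmrLinkConfig,
    default_cohort_config,
    default_sensory_config,
    nirs_link_from_target,
)
from meatq.datatypes import NmrParams


# ---------------------------------------------------------------------------
# cohort


class TestCohort:
    def test_large_cohort_means_match_configured_trait_means(self):
        """Per-muscle pH means recover the configured 5.56 / 5.65 at n=5000."""
        cohort = synthetic.generate_cohort(default_cohort_config(5000, seed=11))
        means = cohort.groupby("muscle")["pH"].mean()
        assert means["LTL"] == pytest.approx(5.56, abs=0.01)
        assert means["SM"] == pytest.approx(5.65, abs=0.01)

    def test_zero_sd_collapses_to_configured_means(self):
        cfg = default_cohort_config(5, seed=1)
        for tc in cfg.traits.values():
            tc.sd = {m: 0.0 for m in tc.sd}
        cohort = synthetic.generate_cohort(cfg)
        for trait, tc in cfg.traits.items():
            for muscle in ("LTL", "SM"):
                vals = cohort.loc[cohort["muscle"] == muscle, trait]
                assert (vals == tc.mean[muscle]).all()

    def test_cross_muscle_squared_correlation_near_target(self):
        """Untruncated generator: squared pH correlation ≈ 0.273 at n=5000."""
        cfg = default_cohort_config(5000, seed=3)
        cfg.truncate = False
        cohort = synthetic.generate_cohort(cfg)
        wide = cohort.pivot(index="carcass_id", columns="muscle", values="pH")
        r2 = np.corrcoef(wide["LTL"], wide["SM"])[0, 1] ** 2
        assert r2 == pytest.approx(0.273, abs=0.03)

    def test_truncation_respects_ranges(self):
        cohort = synthetic.generate_cohort(default_cohort_config(500, seed=5))
        cfg = default_cohort_config()
        for trait, tc in cfg.traits.items():
            for muscle in ("LTL", "SM"):
                vals = cohort.loc[cohort["muscle"] == muscle, trait]
                assert vals.between(tc.lower[muscle], tc.upper[muscle]).all()

    def test_seed_determinism(self):
        a = synthetic.generate_cohort(default_cohort_config(50, seed=9))
        b = synthetic.generate_cohort(default_cohort_config(50, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_negative_sd_rejected(self):
        cfg = default_cohort_config(10)
        cfg.traits["pH"].sd["LTL"] = -1.0
        with pytest.raises(ConfigurationError):
            synthetic.generate_cohort(cfg)


# ---------------------------------------------------------------------------
# NIRS


class TestNirs:
    def test_zero_replicate_sd_gives_identical_readings(self):
        cfg = default_cohort_config(10, seed=2)
        cfg.nirs.replicate_sd = 0.0
        cohort = synthetic.generate_nirs(synthetic.generate_cohort(cfg), cfg)
        assert (cohort["nirs_1"] == cohort["nirs_2"]).all()
        assert (cohort["nirs_2"] == cohort["nirs_3"]).all()

    def test_mean_reading_unbiased_for_latent_value(self):
        """With no between-sample noise the replicate mean converges on the
        configured linear transform of IMF."""
        cfg = default_cohort_config(2000, seed=4)
        cfg.truncate = False
        cfg.nirs.between_sd = 0.0
        cfg.nirs.replicate_sd = 0.3
        cohort = synthetic.generate_nirs(synthetic.generate_cohort(cfg), cfg)
        latent = cfg.nirs.intercept + cfg.nirs.slope * cohort["imf_pct"]
        mean_reading = cohort[["nirs_1", "nirs_2", "nirs_3"]].mean(axis=1)
        resid = mean_reading - latent
        assert abs(resid.mean()) < 3 * cfg.nirs.replicate_sd / np.sqrt(3 * len(cohort))

    def test_loin_calibration_recovers_published_slope(self):
        """Device link calibrated to the loin caption recovers slope 0.638
        within 2% at n = 5000."""
        target = RegressionTarget(0.638, 0.375, 0.311)
        link = solve_reverse_link(target)
        cfg = default_cohort_config(5000, seed=6)
        cfg.truncate = False
        cfg.traits["imf_pct"].sd = {m: float(np.sqrt(link.var_y)) for m in ("LTL", "SM")}
        cfg.nirs = nirs_link_from_target(target, imf_mean=1.04, replicate_sd=0.1)
        cohort = synthetic.generate_nirs(synthetic.generate_cohort(cfg), cfg)
        ltl = cohort[cohort["muscle"] == "LTL"]
        mean_reading = ltl[["nirs_1", "nirs_2", "nirs_3"]].mean(axis=1)
        s = ols_regression(mean_reading, ltl["imf_pct"])
        assert s.slope == pytest.approx(0.638, rel=0.02)

    def test_readings_positive(self):
        cfg = default_cohort_config(200, seed=8)
        cfg.nirs.between_sd = 1.5  # wide noise to provoke the redraw path
        cohort = synthetic.generate_nirs(synthetic.generate_cohort(cfg), cfg)
        assert (cohort[["nirs_1", "nirs_2", "nirs_3"]] > 0).all().all()


# ---------------------------------------------------------------------------
# NMR link


class TestNmrLink:
    def test_zero_links_and_noise_give_identical_params(self, rng):
        cfg = default_cohort_config(20, seed=1)
        cohort = synthetic.generate_cohort(cfg)
        ltl = cohort[cohort["muscle"] == "LTL"].reset_index(drop=True)
        nmr = NmrLinkConfig(
            coef_imf=0.0, coef_ph=0.0, p2f_sd=0.0, p21_sd=0.0, p22_sd=0.0,
            t21_sd_ms=0.0, t22_sd_ms=0.0,
        )
        params = synthetic.link_nmr(ltl, nmr, rng)
        for col in ("p_2f", "p_21", "p_22", "t_21_ms", "t_22_ms"):
            assert params[col].nunique() == 1

    def test_amplitudes_renormalize_to_one(self, rng):
        cfg = default_cohort_config(100, seed=2)
        cohort = synthetic.generate_cohort(cfg)
        ltl = cohort[cohort["muscle"] == "LTL"].reset_index(drop=True)
        params = synthetic.link_nmr(ltl, NmrLinkConfig(), rng)
        total = params[["p_2f", "p_21", "p_22"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)
        assert (params[["p_2f", "p_21", "p_22"]] >= 0).all().all()
        assert (params["t_2f_ms"] < params["t_21_ms"]).all()
        assert (params["t_21_ms"] < params["t_22_ms"]).all()

    def test_ph_calibration_recovers_published_slope(self, rng):
        """Link calibrated to the pH caption: regressing pH on p_2f at
        n = 5000 recovers slope −10.5 within 2%."""
        target = RegressionTarget(-10.5, 0.287, 0.094)
        link = solve_reverse_link(target)
        cfg = default_cohort_config(5000, seed=3)
        cfg.truncate = False
        cfg.traits["pH"].sd = {m: float(np.sqrt(link.var_y)) for m in ("LTL", "SM")}
        cohort = synthetic.generate_cohort(cfg)
        ltl = cohort[cohort["muscle"] == "LTL"].reset_index(drop=True)
        nmr = NmrLinkConfig(coef_imf=0.0, coef_ph=link.coef, p2f_sd=link.noise_sd)
        params = synthetic.link_nmr(ltl, nmr, rng)
        s = ols_regression(params["p_2f"], ltl["pH"])
        assert s.slope == pytest.approx(-10.5, rel=0.02)

    def test_sm_records_rejected(self, rng):
        cfg = default_cohort_config(5, seed=1)
        cohort = synthetic.generate_cohort(cfg)
        with pytest.raises(ConfigurationError):
            synthetic.link_nmr(cohort, NmrLinkConfig(), rng)


# ---------------------------------------------------------------------------
# echo trains


class TestEchoTrains:
    def test_default_acquisition_geometry(self, default_params, noiseless_acq):
        train = synthetic.simulate_echo_train(default_params, noiseless_acq)
        assert len(train) == 2000
        assert train.times_ms[0] == pytest.approx(0.3)
        assert train.times_ms[-1] == pytest.approx(600.0)

    def test_noiseless_t0_extrapolation_equals_scale(self, default_params, noiseless_acq):
        scale = 7.25
        train = synthetic.simulate_echo_train(default_params, noiseless_acq, scale=scale)
        # the model at t -> 0 sums the amplitudes, which are normalized
        t0 = default_params.signal(np.array([0.0]), scale)[0]
        assert t0 == pytest.approx(scale, rel=1e-12)
        assert train.intensities[0] < scale

    def test_monoexponential_identity(self, noiseless_acq):
        """With only the intra-myofibrillar pool, intensity at t = T_21 is
        1/e of the t = 0 value."""
        params = NmrParams(p_2f=0.0, p_21=1.0, p_22=0.0, t_21_ms=60.0, t_22_ms=200.0)
        acq = AcquisitionConfig(n_echoes=1000, echo_spacing_ms=0.3, noise_sd=0.0)
        train = synthetic.simulate_echo_train(params, acq, scale=3.0)
        idx = np.argmin(np.abs(train.times_ms - 60.0))
        assert train.intensities[idx] == pytest.approx(3.0 * np.exp(-1.0), rel=1e-6)

    def test_seed_determinism(self, default_params):
        acq = AcquisitionConfig(n_echoes=100, noise_sd=0.05)
        a = synthetic.simulate_echo_train(default_params, acq, seed=13)
        b = synthetic.simulate_echo_train(default_params, acq, seed=13)
        assert np.array_equal(a.intensities, b.intensities)

    def test_scan_averaging_law(self, default_params):
        """Noise SD of a k-scan average scales as 1/√k (k ∈ {1, 4, 16})."""
        acq = AcquisitionConfig(n_echoes=50, points_per_echo=2, noise_sd=0.1)
        sigma_eff = acq.noise_sd / np.sqrt(acq.points_per_echo)
        times = np.arange(1, acq.n_echoes + 1) * acq.echo_spacing_ms
        clean = default_params.signal(times)
        rng = np.random.default_rng(99)
        reps = 500
        for k in (1, 4, 16):
            errs = []
            for _ in range(reps):
                acc = np.zeros_like(clean)
                for j in range(1, k + 1):
                    acc += (synthetic._one_scan(clean, acq, rng) - acc) / j
                errs.append(acc[0] - clean[0])
            observed = np.std(errs)
            assert observed == pytest.approx(sigma_eff / np.sqrt(k), rel=0.15)


class TestAdaptiveAveraging:
    def test_zero_noise_stops_after_one_scan(self, default_params, noiseless_acq):
        train = synthetic.acquire_with_averaging(default_params, noiseless_acq, seed=1)
        assert train.n_scans_averaged == 1
        assert not train.below_snr_flag
        assert train.snr_estimate > 1e4  # effectively infinite

    def test_scan_count_follows_sqrt_law(self, default_params):
        """Single-scan SNR ≈ 30 should need about (200/30)² ≈ 45 scans."""
        acq = AcquisitionConfig(noise_sd=np.sqrt(4) / 30.0)
        train = synthetic.acquire_with_averaging(default_params, acq, seed=2)
        assert not train.below_snr_flag
        assert train.snr_estimate > 200.0
        assert 30 <= train.n_scans_averaged <= 65

    def test_unreachable_threshold_flags_not_raises(self, default_params):
        acq = AcquisitionConfig(noise_sd=2.0, max_scans=3)
        train = synthetic.acquire_with_averaging(default_params, acq, seed=3)
        assert train.below_snr_flag
        assert train.n_scans_averaged == 3


# ---------------------------------------------------------------------------
# sensory


class TestSensory:
    def _samples(self, n=20, seed=1):
        cfg = default_cohort_config(n, seed=seed)
        return synthetic.generate_cohort(cfg)

    def test_degenerate_config_returns_muscle_intercepts(self):
        cfg = default_sensory_config()
        cfg.sd_session = cfg.sd_participant = cfg.sd_carcass = cfg.sd_residual = 0.0
        cfg.slopes = {r: {} for r in cfg.slopes}
        sens = synthetic.generate_sensory(self._samples(), cfg, seed=5)
        for resp, inter in cfg.intercepts.items():
            for muscle in ("LTL", "SM"):
                vals = sens.loc[sens["muscle"] == muscle, resp]
                assert (vals == inter[muscle]).all()

    def test_variance_decomposition(self):
        """Untruncated score variance ≈ sum of configured variance
        components."""
        cfg = default_sensory_config()
        cfg.truncate = False
        cfg.slopes = {r: {} for r in cfg.slopes}
        samples = self._samples(n=60, seed=2)
        sens = synthetic.generate_sensory(samples, cfg, seed=6)
        expected = (
            cfg.sd_session**2
            + cfg.sd_participant**2
            + cfg.sd_carcass**2
            + cfg.sd_residual**2
        )
        observed = sens["tenderness"].var()
        assert observed == pytest.approx(expected, rel=0.25)

    def test_scores_truncated_to_scale(self):
        cfg = default_sensory_config()
        cfg.sd_residual = 60.0  # force excursions beyond the line scale
        sens = synthetic.generate_sensory(self._samples(), cfg, seed=7)
        for resp in ("tenderness", "juiciness", "flavor", "overall"):
            assert sens[resp].between(0, 100).all()

    def test_panel_structure(self):
        cfg = default_sensory_config()
        samples = self._samples(n=30, seed=3)  # 60 samples = 5 sessions
        sens = synthetic.generate_sensory(samples, cfg, seed=8)
        assert len(sens) == 60 * cfg.consumers_per_sample
        # every sample is tasted by 10 distinct participants
        per_sample = sens.groupby(["carcass_id", "muscle"])["participant_id"].nunique()
        assert (per_sample == cfg.consumers_per_sample).all()
        # participants are session-local and each evaluates 6 samples
        per_part = sens.groupby("participant_id")["session_id"].nunique()
        assert (per_part == 1).all()
        counts = sens.groupby("participant_id").size()
        assert (counts == 6).all()

    def test_ordinal_marginals_near_targets(self):
        cfg = default_sensory_config()
        samples = self._samples(n=300, seed=4)
        sens = synthetic.generate_sensory(samples, cfg, seed=9)
        for muscle, target in cfg.purchase_success_prob.items():
            obs = (
                sens.loc[sens["muscle"] == muscle, "purchase_intent"]
                .isin([4, 5])
                .mean()
            )
            assert obs == pytest.approx(target, abs=0.05)
        for muscle, target in cfg.no_off_flavor_prob.items():
            obs = 1 - sens.loc[sens["muscle"] == muscle, "off_flavor"].mean()
            assert obs == pytest.approx(target, abs=0.02)

    def test_seed_determinism(self):
        cfg = default_sensory_config()
        samples = self._samples()
        a = synthetic.generate_sensory(samples, cfg, seed=10)
        b = synthetic.generate_sensory(samples, cfg, seed=10)
        pd.testing.assert_frame_equal(a, b)
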