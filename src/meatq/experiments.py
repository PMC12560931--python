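"""Calibrated parameter-recovery experiments.

Each experiment calibrates the synthetic generator analytically to a
published regression summary (or the published design constants), simulates
many cohorts or panel studies at the study's design size, runs the package's
estimators, and reports the average recovered quantity.  They exercise the
estimators end to end: the calibration is closed-form, so any systematic
deviation of the recovered averages points at the estimation path, not the
generator.

The calibrated experiments run with range/score truncation disabled because
the closed-form calibration is exact only for the untruncated Gaussian
model; the generator's default (truncated) behaviour is covered by the
distributional tests instead.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from . import chemometrics, relaxfit, sensory, synthetic
from .calibration import RegressionTarget, solve_reverse_link
from .config import (
    AcquisitionConfig,
    CohortConfig,
    NmrLinkConfig,
    SensoryLinkConfig,
    TraitConfig,
    default_cohort_config,
    default_sensory_config,
    nirs_link_from_target,
)
from .datatypes import NmrParams

__all__ = [
    "IMF_VS_NIRS_POOLED",
    "IMF_VS_NIRS_LTL",
    "IMF_VS_P2F",
    "PH_VS_P2F",
    "CROSS_MUSCLE_PH_R2",
    "COLLAGEN_TENDERNESS_SLOPE",
    "P21_TENDERNESS_SLOPE",
    "snr_termination",
    "imf_on_nirs_recovery",
    "trait_on_p2f_recovery",
    "cross_muscle_ph_recovery",
    "collagen_tenderness_recovery",
    "p21_tenderness_recovery",
    "null_slope_rejection",
]

# Published regression summaries the generator is calibrated against:
# chemical IMF on the mean device output (pooled and loin-only), and
# chemical IMF / pH on the fast relaxation amplitude p_2f (loin).
IMF_VS_NIRS_POOLED = RegressionTarget(slope=0.502, r2=0.258, rmse=0.413)
IMF_VS_NIRS_LTL = RegressionTarget(slope=0.638, r2=0.375, rmse=0.311)
IMF_VS_P2F = RegressionTarget(slope=26.5, r2=0.124, rmse=0.366)
PH_VS_P2F = RegressionTarget(slope=-10.5, r2=0.287, rmse=0.094)

#: Published between-muscle squared correlation of ultimate pH.
CROSS_MUSCLE_PH_R2 = 0.273
#: Published tenderness slopes: per mg/g collagen and per unit p_21.
COLLAGEN_TENDERNESS_SLOPE = -3.86
P21_TENDERNESS_SLOPE = 87.1

_STREAM = {
    "snr": 0,
    "nirs": 1,
    "p2f": 2,
    "cross": 3,
    "collagen": 4,
    "p21": 5,
    "null": 6,
}


def _rng(
    seed: int, experiment: str, index: int = 0, sub: int = 0
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=seed, spawn_key=(32 + _STREAM[experiment], sub, index)
        )
    )


def _flat_trait(mean: float, sd: float, cross_r2: float = 0.0) -> TraitConfig:
    """An untruncated trait with the same distribution in both muscles."""
    inf = float("inf")
    return TraitConfig(
        mean={"LTL": mean, "SM": mean},
        sd={"LTL": sd, "SM": sd},
        lower={"LTL": -inf, "SM": -inf},
        upper={"LTL": inf, "SM": inf},
        cross_muscle_r2=cross_r2,
    )


def _untruncated_default_traits() -> dict:
    traits = default_cohort_config().traits
    inf = float("inf")
    for tc in traits.values():
        tc.lower = {m: -inf for m in tc.lower}
        tc.upper = {m: inf for m in tc.upper}
    return traits


# ---------------------------------------------------------------------------
# acquisition


def snr_termination(
    seed: int, single_scan_snr: float = 30.0, acq: AcquisitionConfig | None = None
) -> dict:
    """Terminal SNR and scan count of the adaptive signal-averaging loop.

    The per-point noise is set so a single averaged scan has the requested
    SNR; by the sqrt-of-scans averaging law the loop should stop near
    ``(threshold / single_scan_snr)²`` scans with SNR just above threshold.
    """
    if acq is None:
        acq = AcquisitionConfig()
    acq = replace(
        acq, noise_sd=math.sqrt(acq.points_per_echo) / single_scan_snr
    )
    params = NmrParams(p_2f=0.05, p_21=0.85, p_22=0.10, t_21_ms=40.0, t_22_ms=150.0)
    train = synthetic.acquire_with_averaging(
        params, acq, scale=1.0, rng=_rng(seed, "snr")
    )
    snr = relaxfit.compute_snr(train)
    return {
        "snr": float(snr),
        "n_scans": int(train.n_scans_averaged),
        "below_threshold": bool(train.below_snr_flag),
    }


# ---------------------------------------------------------------------------
# instrument-vs-chemistry regressions


def imf_on_nirs_recovery(
    seed: int,
    target: RegressionTarget = IMF_VS_NIRS_POOLED,
    n_cohorts: int = 200,
    n_samples: int = 120,
    imf_mean: float = 1.21,
    replicate_sd: float = 0.1,
) -> dict:
    """Mean recovered slope/R² of chemical IMF on the mean device reading."""
    link = solve_reverse_link(target)
    nirs = nirs_link_from_target(target, imf_mean=imf_mean, replicate_sd=replicate_sd)
    traits = {
        "pH": _flat_trait(5.6, 0.1),
        "collagen_mg_g": _flat_trait(4.6, 0.5),
        "collagen_solubility_pct": _flat_trait(10.0, 1.8),
        "imf_pct": _flat_trait(imf_mean, math.sqrt(link.var_y)),
    }
    slopes, r2s, rmses = [], [], []
    for i in range(n_cohorts):
        rng = _rng(seed, "nirs", i + 1)
        cfg = CohortConfig(
            n_carcasses=n_samples // 2, traits=traits, nirs=nirs, truncate=False
        )
        cohort = synthetic.generate_cohort(cfg, rng=rng)
        cohort = synthetic.generate_nirs(cohort, cfg, rng=rng)
        cohort = chemometrics.add_nirs_aggregates(cohort)
        s = chemometrics.ols_regression(cohort["nirs_mean"], cohort["imf_pct"])
        slopes.append(s.slope)
        r2s.append(s.r2)
        rmses.append(s.rmse)
    return {
        "slope_mean": float(np.mean(slopes)),
        "r2_mean": float(np.mean(r2s)),
        "rmse_mean": float(np.mean(rmses)),
        "n_cohorts": n_cohorts,
        "n_per_cohort": n_samples,
    }


def trait_on_p2f_recovery(
    seed: int,
    target: RegressionTarget,
    trait: str,
    n_cohorts: int = 200,
    n_carcasses: int = 60,
) -> dict:
    """Mean recovered slope of a chemistry trait on the latent p_2f (loin)."""
    link = solve_reverse_link(target)
    base = default_cohort_config()
    trait_mean = base.traits[trait].mean["LTL"]
    traits = _untruncated_default_traits()
    traits[trait].sd = {m: math.sqrt(link.var_y) for m in ("LTL", "SM")}
    nmr = NmrLinkConfig(
        coef_imf=link.coef if trait == "imf_pct" else 0.0,
        coef_ph=link.coef if trait == "pH" else 0.0,
        p2f_sd=link.noise_sd,
        imf_center=traits["imf_pct"].mean["LTL"],
        ph_center=traits["pH"].mean["LTL"],
    )
    slopes, r2s = [], []
    # independent streams per calibrated trait so the experiments decouple
    sub = {"imf_pct": 1, "pH": 2}.get(trait, 0)
    for i in range(n_cohorts):
        rng = _rng(seed, "p2f", i + 1, sub=sub)
        cfg = CohortConfig(n_carcasses=n_carcasses, traits=traits, nmr=nmr, truncate=False)
        cohort = synthetic.generate_cohort(cfg, rng=rng)
        ltl = cohort[cohort["muscle"] == "LTL"].reset_index(drop=True)
        params = synthetic.link_nmr(ltl, nmr, rng)
        s = chemometrics.ols_regression(params["p_2f"], ltl[trait])
        slopes.append(s.slope)
        r2s.append(s.r2)
    return {
        "slope_mean": float(np.mean(slopes)),
        "r2_mean": float(np.mean(r2s)),
        "trait_mean": trait_mean,
        "n_cohorts": n_cohorts,
        "n_per_cohort": n_carcasses,
    }


def cross_muscle_ph_recovery(
    seed: int, n_cohorts: int = 200, n_carcasses: int = 60
) -> dict:
    """Mean recovered R² of topside pH regressed on loin pH."""
    traits = _untruncated_default_traits()
    slopes, r2s = [], []
    for i in range(n_cohorts):
        rng = _rng(seed, "cross", i + 1)
        cfg = CohortConfig(n_carcasses=n_carcasses, traits=traits, truncate=False)
        cohort = synthetic.generate_cohort(cfg, rng=rng)
        s = chemometrics.cross_muscle_regression(cohort, traits=("pH",))["pH"]
        slopes.append(s.slope)
        r2s.append(s.r2)
    return {
        "r2_mean": float(np.mean(r2s)),
        "slope_mean": float(np.mean(slopes)),
        "n_cohorts": n_cohorts,
        "n_per_cohort": n_carcasses,
    }


# ---------------------------------------------------------------------------
# sensory mixed-model recovery


def _untruncated_sensory() -> SensoryLinkConfig:
    cfg = default_sensory_config()
    cfg.truncate = False
    return cfg


def collagen_tenderness_recovery(
    seed: int, n_sims: int = 100, n_carcasses: int = 60
) -> dict:
    """Mean recovered collagen→tenderness slope from the hierarchical model.

    The generator's true coefficient is the published value; the model is
    the full fixed structure (muscle + IMF + collagen + solubility + pH)
    with session / participant-in-session / carcass random intercepts, at
    the study's design size (60 carcasses × 2 muscles × 10 consumers).
    """
    sens_cfg = _untruncated_sensory()
    sens_cfg.slopes["tenderness"]["collagen_mg_g"] = COLLAGEN_TENDERNESS_SLOPE
    slopes, ses = [], []
    for i in range(n_sims):
        rng = _rng(seed, "collagen", i + 1)
        cohort_cfg = default_cohort_config(n_carcasses=n_carcasses)
        cohort = synthetic.generate_cohort(cohort_cfg, rng=rng)
        sens = synthetic.generate_sensory(cohort, sens_cfg, rng=rng)
        table = sensory.fit_chemistry_slopes(sens, cohort, "tenderness")
        slopes.append(float(table.loc["collagen_mg_g", "slope"]))
        ses.append(float(table.loc["collagen_mg_g", "se"]))
    return {
        "slope_mean": float(np.mean(slopes)),
        "se_mean": float(np.mean(ses)),
        "n_sims": n_sims,
    }


def p21_tenderness_recovery(
    seed: int, n_sims: int = 100, n_carcasses: int = 60
) -> dict:
    """Mean recovered p_21→tenderness slope from the single-predictor model.

    Loin only: 60 samples × 10 consumers, tenderness driven by the centered
    intra-myofibrillar amplitude at the published coefficient.
    """
    sens_cfg = _untruncated_sensory()
    nmr_cfg = NmrLinkConfig()
    slopes, ses = [], []
    for i in range(n_sims):
        rng = _rng(seed, "p21", i + 1)
        cohort_cfg = default_cohort_config(n_carcasses=n_carcasses)
        cohort = synthetic.generate_cohort(cohort_cfg, rng=rng)
        ltl = cohort[cohort["muscle"] == "LTL"].reset_index(drop=True)
        params = synthetic.link_nmr(ltl, nmr_cfg, rng)
        samples = ltl.merge(params, on="carcass_id")
        sens = synthetic.generate_sensory(
            samples,
            sens_cfg,
            rng=rng,
            slopes={"tenderness": {"p_21": P21_TENDERNESS_SLOPE}},
        )
        table = sensory.fit_single_predictor_slope(
            sens,
            params[["carcass_id", "p_21"]],
            "tenderness",
            "p_21",
            include_ols=False,
        )
        slopes.append(float(table.loc["p_21", "slope"]))
        ses.append(float(table.loc["p_21", "se"]))
    return {
        "slope_mean": float(np.mean(slopes)),
        "se_mean": float(np.mean(ses)),
        "n_sims": n_sims,
    }


def null_slope_rejection(
    seed: int, n_sims: int = 150, n_carcasses: int = 20, alpha: float = 0.05
) -> dict:
    """Type-I error of the chemistry-slope model when all true slopes are 0.

    Runs a reduced design (fewer carcasses and consumers) to keep many
    replicates affordable; the nominal level should still hold.
    """
    sens_cfg = _untruncated_sensory()
    for resp in sens_cfg.slopes:
        sens_cfg.slopes[resp] = {k: 0.0 for k in sens_cfg.slopes[resp]}
    sens_cfg.consumers_per_sample = 5
    sens_cfg.samples_per_session = 8
    sens_cfg.participants_per_session = 10
    pvals = {p: [] for p in sensory.CHEMISTRY_PREDICTORS}
    for i in range(n_sims):
        rng = _rng(seed, "null", i + 1)
        cohort_cfg = default_cohort_config(n_carcasses=n_carcasses)
        cohort = synthetic.generate_cohort(cohort_cfg, rng=rng)
        sens = synthetic.generate_sensory(cohort, sens_cfg, rng=rng)
        table = sensory.fit_chemistry_slopes(sens, cohort, "tenderness")
        for p in pvals:
            pvals[p].append(float(table.loc[p, "p_value"]))
    rates = {p: float(np.mean(np.array(v) < alpha)) for p, v in pvals.items()}
    return {"rejection_rates": rates, "n_sims": n_sims, "alpha": alpha}
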