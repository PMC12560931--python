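"""Seeded synthetic-data generator for the full meat-quality study design.

This module draws every layer of the emulated experiment:

* a carcass cohort with both muscles (loin LTL and topside SM), traits from
  truncated normals with a shared-carcass latent factor inducing the
  configured between-muscle R²;
* device outputs: a NIRS predicted-IMF triplet per sample, and the latent
  relaxation-parameter vector per loin sample;
* CPMG echo trains from the tri-exponential decay model, with within-echo
  point averaging and adaptive signal averaging to a target SNR;
* a consumer sensory panel (sessions, participants nested in sessions,
  ten consumers per sample) with linear score models, a binary off-flavor
  response and ordinal purchase-intent / quality-grade responses.

Everything is deterministic under the configured seed; independent child
streams are derived per stage with fixed offsets so that disabling one stage
does not shift the randomness of another.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtri

from .config import (
    AcquisitionConfig,
    CohortConfig,
    ConfigurationError,
    NmrLinkConfig,
    SensoryLinkConfig,
    TRAITS,
)
from .datatypes import EchoTrain, NmrParams
from . import relaxfit

__all__ = [
    "stage_rng",
    "generate_cohort",
    "generate_nirs",
    "link_nmr",
    "simulate_echo_train",
    "acquire_with_averaging",
    "assign_panel",
    "generate_sensory",
]

#: Fixed child-stream offsets per pipeline stage.
STREAMS = {"cohort": 0, "nirs": 1, "nmr": 2, "sensory": 3, "echo": 4}


def stage_rng(seed: int, stage: str, index: int = 0) -> np.random.Generator:
    """Child generator for one stage, at a fixed offset from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(STREAMS[stage], index))
    )


# ---------------------------------------------------------------------------
# cohort


def _matched_loc(mean: float, sd: float, lower: float, upper: float) -> float:
    """Pre-truncation location whose truncated-normal mean equals ``mean``.

    Asymmetric ranges pull the truncated mean away from the location
    parameter; solving for the location keeps the generated trait means on
    their configured values.
    """
    if sd == 0 or not (np.isfinite(lower) or np.isfinite(upper)):
        return mean

    def shift(loc):
        a, b = (lower - loc) / sd, (upper - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    span = 4.0 * sd
    try:
        return float(brentq(shift, mean - span, mean + span, xtol=1e-10))
    except ValueError:  # pragma: no cover - extreme truncation only
        return mean


def _draw_trait_pair(tc, n: int, rng: np.random.Generator, truncate: bool):
    """Draw (LTL, SM) values for one trait across ``n`` carcasses.

    A shared-carcass latent factor of weight sqrt(rho), rho =
    sqrt(cross_muscle_r2), makes the latent pair bivariate normal with
    correlation rho, so the squared between-muscle correlation matches the
    configured R².  Under truncation the latent normals are mapped through
    the truncated-normal quantile function (a Gaussian copula): marginals
    are exactly truncated normal with mean-matched location, and the
    between-muscle dependence carries over through the monotone map.
    """
    rho = math.sqrt(tc.cross_muscle_r2)
    w_shared = math.sqrt(rho)
    w_own = math.sqrt(max(0.0, 1.0 - rho))
    z0 = rng.standard_normal(n)
    vals = {}
    for m in ("LTL", "SM"):
        z = w_shared * z0 + w_own * rng.standard_normal(n)
        sd = tc.sd[m]
        if not truncate or sd == 0:
            vals[m] = tc.mean[m] + sd * z
            continue
        loc = _matched_loc(tc.mean[m], sd, tc.lower[m], tc.upper[m])
        a, b = (tc.lower[m] - loc) / sd, (tc.upper[m] - loc) / sd
        u = stats.norm.cdf(z)
        vals[m] = stats.truncnorm.ppf(
            np.clip(u, 1e-12, 1 - 1e-12), a, b, loc=loc, scale=sd
        )
    return vals


def generate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the chemistry table: one row per carcass × muscle.

    Columns: ``carcass_id, muscle`` plus the four chemistry traits.  NIRS
    readings are filled by :func:`generate_nirs`.
    """
    config.validate()
    if rng is None:
        rng = stage_rng(config.seed, "cohort")
    n = config.n_carcasses
    ids = [f"C{i + 1:04d}" for i in range(n)]
    per_muscle = {m: {} for m in ("LTL", "SM")}
    for trait in TRAITS:
        tc = config.traits[trait]
        pair = _draw_trait_pair(tc, n, rng, config.truncate)
        for m in ("LTL", "SM"):
            per_muscle[m][trait] = pair[m]
    frames = []
    for m in ("LTL", "SM"):
        frames.append(
            pd.DataFrame({"carcass_id": ids, "muscle": m, **per_muscle[m]})
        )
    df = pd.concat(frames, ignore_index=True)
    return df.sort_values(["carcass_id", "muscle"], ignore_index=True)


# ---------------------------------------------------------------------------
# NIRS


def generate_nirs(
    cohort: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fill the three device readings per sample from the latent IMF link."""
    if rng is None:
        rng = stage_rng(config.seed, "nirs")
    link = config.nirs
    df = cohort.copy()
    n = len(df)
    latent = (
        link.intercept
        + link.slope * df["imf_pct"].to_numpy()
        + (rng.standard_normal(n) * link.between_sd if link.between_sd else 0.0)
    )
    readings = latent[:, None] + rng.standard_normal((n, 3)) * link.replicate_sd
    # device outputs are positive; redraw the rare non-positive replicate
    for _ in range(100):
        bad = readings <= 0
        if not bad.any():
            break
        readings[bad] = (
            np.broadcast_to(latent[:, None], readings.shape)[bad]
            + rng.standard_normal(int(bad.sum())) * link.replicate_sd
        )
    readings = np.maximum(readings, 1e-6)
    for j in range(3):
        df[f"nirs_{j + 1}"] = readings[:, j]
    return df


# ---------------------------------------------------------------------------
# NMR latent parameters


def link_nmr(
    cohort_ltl: pd.DataFrame,
    config: NmrLinkConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the latent relaxation-parameter vector for each loin sample.

    ``p_2f`` follows the calibrated linear link on centered IMF and pH; the
    two water-pool amplitudes are drawn around their compartment defaults and
    rescaled to fill ``1 − p_2f`` (preserving the calibrated ``p_2f``), and
    the time constants are Gaussian around their defaults.
    """
    config.validate()
    if (cohort_ltl["muscle"] != "LTL").any():
        raise ConfigurationError("relaxometry is measured on the loin (LTL) only")
    n = len(cohort_ltl)
    imf = cohort_ltl["imf_pct"].to_numpy()
    ph = cohort_ltl["pH"].to_numpy()
    p2f = (
        config.p2f_intercept
        + config.coef_imf * (imf - config.imf_center)
        + config.coef_ph * (ph - config.ph_center)
        + rng.standard_normal(n) * config.p2f_sd
    )
    p2f = np.clip(p2f, 1e-6, 0.5)
    p21_raw = np.clip(config.p21_mean + rng.standard_normal(n) * config.p21_sd, 1e-6, None)
    p22_raw = np.clip(config.p22_mean + rng.standard_normal(n) * config.p22_sd, 1e-6, None)
    rescale = (1.0 - p2f) / (p21_raw + p22_raw)
    p21 = p21_raw * rescale
    p22 = p22_raw * rescale
    t21 = config.t21_mean_ms + rng.standard_normal(n) * config.t21_sd_ms
    t22 = config.t22_mean_ms + rng.standard_normal(n) * config.t22_sd_ms
    # keep the compartments ordered and separated from the fixed fast pool
    t21 = np.clip(t21, config.t2f_ms * 1.2, None)
    t22 = np.maximum(t22, t21 * 1.2)
    return pd.DataFrame(
        {
            "carcass_id": cohort_ltl["carcass_id"].to_numpy(),
            "p_2f": p2f,
            "p_21": p21,
            "p_22": p22,
            "t_2f_ms": config.t2f_ms,
            "t_21_ms": t21,
            "t_22_ms": t22,
        }
    )


def nmr_params_from_row(row) -> NmrParams:
    """Build an :class:`NmrParams` from one row of the latent-parameter table."""
    amps = np.array([row["p_2f"], row["p_21"], row["p_22"]], dtype=float)
    amps = amps / amps.sum()
    return NmrParams(
        p_2f=float(amps[0]),
        p_21=float(amps[1]),
        p_22=float(amps[2]),
        t_21_ms=float(row["t_21_ms"]),
        t_22_ms=float(row["t_22_ms"]),
        t_2f_ms=float(row["t_2f_ms"]),
    )


# ---------------------------------------------------------------------------
# echo trains


def _one_scan(
    clean: np.ndarray, acq: AcquisitionConfig, rng: np.random.Generator
) -> np.ndarray:
    """One scan: each echo is the mean of ``points_per_echo`` noisy points."""
    if acq.noise_sd == 0:
        return clean.copy()
    pts = clean[:, None] + rng.standard_normal(
        (clean.size, acq.points_per_echo)
    ) * acq.noise_sd
    return pts.mean(axis=1)


def simulate_echo_train(
    params: NmrParams,
    acq: AcquisitionConfig,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> EchoTrain:
    """Simulate a single-scan CPMG echo train."""
    acq.validate()
    if rng is None:
        rng = stage_rng(0 if seed is None else seed, "echo")
    times = np.arange(1, acq.n_echoes + 1) * acq.echo_spacing_ms
    clean = params.signal(times, scale)
    intensities = _one_scan(clean, acq, rng)
    return EchoTrain(times_ms=times, intensities=intensities, n_scans_averaged=1)


def acquire_with_averaging(
    params: NmrParams,
    acq: AcquisitionConfig,
    scale: float = 1.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> EchoTrain:
    """Signal-average scans until the estimated SNR exceeds the threshold.

    The running average is re-estimated after every scan (noise from tail
    first-differences, t = 0 intensity from a log-linear extrapolation of the
    earliest echoes).  If the threshold is not reached within
    ``acq.max_scans`` the returned train carries ``below_snr_flag=True``.
    """
    acq.validate()
    if rng is None:
        rng = stage_rng(0 if seed is None else seed, "echo")
    times = np.arange(1, acq.n_echoes + 1) * acq.echo_spacing_ms
    clean = params.signal(times, scale)
    running = np.zeros_like(clean)
    snr = 0.0
    sigma = np.inf
    n_scans = 0
    for k in range(1, acq.max_scans + 1):
        running += (_one_scan(clean, acq, rng) - running) / k
        n_scans = k
        train = EchoTrain(times_ms=times, intensities=running, n_scans_averaged=k)
        sigma = relaxfit.estimate_noise(train)
        snr = relaxfit.compute_snr(train, noise_sd=sigma)
        if snr > acq.snr_threshold:
            break
    return EchoTrain(
        times_ms=times,
        intensities=running,
        n_scans_averaged=n_scans,
        noise_sd_estimate=float(sigma),
        snr_estimate=float(snr),
        below_snr_flag=bool(snr <= acq.snr_threshold),
    )


# ---------------------------------------------------------------------------
# sensory panel


def assign_panel(
    samples: pd.DataFrame,
    config: SensoryLinkConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Assign samples to sessions/days and servings to participants.

    Samples are shuffled into sessions of ``samples_per_session``; each
    session has its own pool of participants, each sample is served to
    ``consumers_per_sample`` distinct participants, and servings are dealt
    cyclically so every participant evaluates the same number of samples.
    Serving order within a session is not modelled.
    """
    n = len(samples)
    order = rng.permutation(n)
    per_sess = config.samples_per_session
    n_sessions = math.ceil(n / per_sess)
    sessions_per_day = math.ceil(n_sessions / config.n_days)
    rows = []
    for s in range(n_sessions):
        members = order[s * per_sess : (s + 1) * per_sess]
        session_id = f"S{s + 1:02d}"
        day = s // sessions_per_day + 1
        n_part = config.participants_per_session
        shift = int(rng.integers(0, n_part))
        for j, idx in enumerate(members):
            for k in range(config.consumers_per_sample):
                p = (j * config.consumers_per_sample + k + shift) % n_part
                rows.append(
                    {
                        "sample_index": int(idx),
                        "session_id": session_id,
                        "day": day,
                        "participant_id": f"{session_id}P{p + 1:02d}",
                    }
                )
    return pd.DataFrame(rows)


def generate_sensory(
    samples: pd.DataFrame,
    config: SensoryLinkConfig,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    slopes: dict | None = None,
    intercepts: dict | None = None,
    centers: dict | None = None,
) -> pd.DataFrame:
    """Simulate the consumer panel for the given samples.

    ``samples`` needs ``carcass_id`` and ``muscle`` columns plus every
    predictor column named in the slope configuration.  ``slopes`` /
    ``intercepts`` / ``centers`` override the configured score models (used
    by the single-predictor recovery experiments, e.g. scores driven by a
    relaxation amplitude instead of chemistry).
    """
    config.validate()
    if rng is None:
        rng = stage_rng(0 if seed is None else seed, "sensory")
    slopes = config.slopes if slopes is None else slopes
    intercepts = config.intercepts if intercepts is None else intercepts
    centers = dict(config.centers if centers is None else centers)

    samples = samples.reset_index(drop=True)
    panel = assign_panel(samples, config, rng)
    n_rows = len(panel)

    sessions = panel["session_id"].unique()
    participants = panel["participant_id"].unique()
    carcasses = samples["carcass_id"].unique()
    u_sess = dict(zip(sessions, rng.standard_normal(len(sessions)) * config.sd_session))
    u_part = dict(
        zip(participants, rng.standard_normal(len(participants)) * config.sd_participant)
    )
    u_carc = dict(zip(carcasses, rng.standard_normal(len(carcasses)) * config.sd_carcass))

    samp = samples.loc[panel["sample_index"]].reset_index(drop=True)
    re_sum = (
        panel["session_id"].map(u_sess).to_numpy()
        + panel["participant_id"].map(u_part).to_numpy()
        + samp["carcass_id"].map(u_carc).to_numpy()
    )

    out = pd.DataFrame(
        {
            "participant_id": panel["participant_id"].to_numpy(),
            "session_id": panel["session_id"].to_numpy(),
            "day": panel["day"].to_numpy(),
            "carcass_id": samp["carcass_id"].to_numpy(),
            "muscle": samp["muscle"].to_numpy(),
        }
    )

    for response, resp_slopes in slopes.items():
        mu = samp["muscle"].map(intercepts[response]).to_numpy(dtype=float)
        fixed = mu.copy()
        for pred, coef in resp_slopes.items():
            x = samp[pred].to_numpy(dtype=float)
            center = centers.get(pred, float(np.mean(x)))
            fixed += coef * (x - center)
        score = fixed + re_sum + rng.standard_normal(n_rows) * config.sd_residual
        if config.truncate:
            score = np.clip(score, 0.0, 100.0)
        out[response] = score

    s = config.logit_re_scale
    sd_tot = math.sqrt(
        1.0
        + s**2
        * (config.sd_session**2 + config.sd_participant**2 + config.sd_carcass**2)
    )

    # off-flavor: Bernoulli through an inverse-logit sharing the random effects
    p_off = {m: 1.0 - p for m, p in config.no_off_flavor_prob.items()}
    eta = np.array([logit(p_off[m]) for m in samp["muscle"]]) + s * re_sum
    out["off_flavor"] = (rng.random(n_rows) < expit(eta)).astype(int)

    # ordinal responses: cuts of a latent normal, thresholds placed so the
    # marginal success probabilities hit their configured targets
    for name, probs, n_levels, success_cut_index in (
        ("purchase_intent", config.purchase_success_prob, 5, 2),
        ("quality_grade", config.quality_success_prob, 4, 1),
    ):
        cut = sd_tot * ndtri(1.0 - probs["LTL"])
        delta = {"LTL": 0.0, "SM": cut + sd_tot * ndtri(probs.get("SM", probs["LTL"]))}
        offsets = (np.arange(n_levels - 1) - success_cut_index) * 0.8 * sd_tot
        cuts = cut + offsets
        latent = (
            np.array([delta.get(m, 0.0) for m in samp["muscle"]])
            + s * re_sum
            + rng.standard_normal(n_rows)
        )
        out[name] = np.digitize(latent, cuts) + 1

    return out
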