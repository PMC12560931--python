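"""Configuration objects for the synthetic cohort and acquisition model.

Every tunable of the generator lives here, with defaults reconstructed from
the published study conditions for 60 heavy female pork carcasses:

* trait means come from the per-muscle summary table; SDs are recovered from
  the printed SEMs as ``SD = SEM·√60``; truncation bounds are the printed
  trait ranges;
* cross-muscle dependence per trait is a shared-carcass latent factor whose
  weight reproduces the published between-muscle R²;
* the NIRS device link is calibrated analytically to the pooled
  IMF-vs-mean-output regression caption;
* the relaxation-parameter links are calibrated to the p_2f-vs-IMF and
  p_2f-vs-pH captions, and the residual SDs of p_21/p_22/T_21/T_22 are
  chosen so the single-predictor sensory models reproduce the printed
  standard errors of their slopes;
* sensory fixed effects default to the published slope table; random-effect
  SDs are not published anywhere and the defaults here are declared
  arbitrary (participant 10, session 3, carcass 5, residual 15 on the 0–100
  score scale).

Configs round-trip through plain dicts (and therefore YAML/JSON).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import yaml

from .calibration import RegressionTarget, solve_reverse_link

__all__ = [
    "TraitConfig",
    "CohortConfig",
    "NmrLinkConfig",
    "NirsLinkConfig",
    "AcquisitionConfig",
    "FitOptions",
    "SensoryLinkConfig",
    "PipelineConfig",
    "default_cohort_config",
    "default_sensory_config",
    "load_config",
    "dump_config",
]

_SQRT60 = float(np.sqrt(60.0))

#: Traits of the chemistry table, in canonical column order.
TRAITS = ("pH", "imf_pct", "collagen_mg_g", "collagen_solubility_pct")


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class TraitConfig:
    """Per-muscle distribution of one chemistry trait plus its coupling.

    ``cross_muscle_r2`` is the target squared correlation between the two
    muscles of the same carcass; the generator induces it with a shared
    latent factor of weight ``sqrt(sqrt(r2))`` per muscle, i.e. a bivariate
    normal with correlation ``sqrt(r2)``.
    """

    mean: dict
    sd: dict
    lower: dict
    upper: dict
    cross_muscle_r2: float = 0.0

    def validate(self) -> None:
        for m in self.mean:
            if self.sd[m] < 0 or not np.isfinite(self.sd[m]):
                raise ConfigurationError(f"SD for {m} must be finite and >= 0")
            if not (self.lower[m] <= self.mean[m] <= self.upper[m]):
                raise ConfigurationError(
                    f"range [{self.lower[m]}, {self.upper[m]}] must contain "
                    f"mean {self.mean[m]}"
                )
        if not (0 <= self.cross_muscle_r2 < 1):
            raise ConfigurationError("cross-muscle R² must lie in [0, 1)")


@dataclass
class NmrLinkConfig:
    """Latent links from chemistry to the relaxation parameter vector.

    ``p_2f = p2f_intercept + coef_imf·(IMF − imf_center) +
    coef_ph·(pH − ph_center) + N(0, p2f_sd²)``; the remaining amplitudes are
    drawn around their defaults and rescaled so the three sum to one while
    leaving the calibrated ``p_2f`` untouched.  Time constants are Gaussian
    around their compartment defaults.
    """

    p2f_intercept: float = 0.05
    coef_imf: float = 0.0046792  # R²/slope of the published IMF-vs-p_2f fit
    coef_ph: float = -0.0273333  # R²/slope of the published pH-vs-p_2f fit
    p2f_sd: float = 0.0035
    p21_mean: float = 0.85
    p21_sd: float = 0.05
    p22_mean: float = 0.10
    p22_sd: float = 0.035
    t21_mean_ms: float = 40.0
    t21_sd_ms: float = 1.3
    t22_mean_ms: float = 150.0
    t22_sd_ms: float = 5.8
    t2f_ms: float = 10.0
    imf_center: float = 1.04
    ph_center: float = 5.56

    def validate(self) -> None:
        for name in ("p2f_sd", "p21_sd", "p22_sd", "t21_sd_ms", "t22_sd_ms"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ConfigurationError(f"{name} must be finite and >= 0")
        if not (self.t2f_ms < self.t21_mean_ms < self.t22_mean_ms):
            raise ConfigurationError("need t_2f < t_21 < t_22 on average")


@dataclass
class NirsLinkConfig:
    """Latent link from chemical IMF to the device's predicted-IMF output.

    ``latent = intercept + slope·IMF + N(0, between_sd²)``; each of the three
    replicate readings adds independent N(0, replicate_sd²) noise and is kept
    positive.
    """

    intercept: float = 0.5881
    slope: float = 0.5139
    between_sd: float = 0.4139
    replicate_sd: float = 0.10

    def validate(self) -> None:
        if self.between_sd < 0 or self.replicate_sd < 0:
            raise ConfigurationError("NIRS noise SDs must be >= 0")


@dataclass
class CohortConfig:
    """Everything needed to draw a carcass cohort with both muscles."""

    n_carcasses: int = 60
    traits: dict = field(default_factory=dict)
    nmr: NmrLinkConfig = field(default_factory=NmrLinkConfig)
    nirs: NirsLinkConfig = field(default_factory=NirsLinkConfig)
    truncate: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_carcasses < 2:
            raise ConfigurationError("need at least 2 carcasses")
        for trait, tc in self.traits.items():
            if not isinstance(tc, TraitConfig):
                raise ConfigurationError(f"trait {trait} is not a TraitConfig")
            tc.validate()
        self.nmr.validate()
        self.nirs.validate()


@dataclass
class AcquisitionConfig:
    """CPMG acquisition settings of the benchtop relaxometer model."""

    n_echoes: int = 2000
    echo_spacing_ms: float = 0.3
    polarization_delay_ms: float = 750.0  # informational; not simulated
    points_per_echo: int = 4
    noise_sd: float = 0.04  # per collected point, per scan, intensity units
    snr_threshold: float = 200.0
    max_scans: int = 512

    def validate(self) -> None:
        if self.n_echoes < 1:
            raise ConfigurationError("n_echoes must be >= 1")
        if self.echo_spacing_ms <= 0:
            raise ConfigurationError("echo_spacing_ms must be > 0")
        if self.points_per_echo < 1:
            raise ConfigurationError("points_per_echo must be >= 1")
        if self.noise_sd < 0 or not np.isfinite(self.noise_sd):
            raise ConfigurationError("noise_sd must be finite and >= 0")
        if self.snr_threshold <= 0:
            raise ConfigurationError("snr_threshold must be > 0")
        if self.max_scans < 1:
            raise ConfigurationError("max_scans must be >= 1")


@dataclass
class FitOptions:
    """Options of the tri-exponential decomposition."""

    fixed_t2f_ms: float = 10.0
    t21_bounds_ms: tuple = (10.0, 100.0)  # open at the left end
    t22_bounds_ms: tuple = (100.0, 2000.0)
    n_starts_per_axis: int = 4
    tolerance: float = 1e-12
    max_iterations: int = 200
    start_jitter_seed: int = 0
    degenerate_ratio: float = 1.05  # T_22/T_21 below this flags identifiability loss

    def validate(self) -> None:
        lo1, hi1 = self.t21_bounds_ms
        lo2, hi2 = self.t22_bounds_ms
        if not (self.fixed_t2f_ms <= lo1 < hi1 <= lo2 < hi2):
            raise ConfigurationError(
                "time-constant bound intervals must be disjoint and ordered "
                "above the fixed fast component"
            )
        if self.n_starts_per_axis < 1:
            raise ConfigurationError("need at least one start per axis")


@dataclass
class SensoryLinkConfig:
    """Generative model of the consumer panel.

    Scores are linear in centered chemistry (or any configured predictor
    columns) plus session, participant-within-session and carcass random
    intercepts and a residual, optionally truncated to [0, 100].  Binary and
    ordinal responses ride on latent normals sharing (scaled) random effects.
    """

    intercepts: dict = field(
        default_factory=lambda: {
            "tenderness": {"LTL": 48.8, "SM": 51.7},
            "juiciness": {"LTL": 48.1, "SM": 54.1},
            "flavor": {"LTL": 52.0, "SM": 54.0},
            "overall": {"LTL": 52.0, "SM": 54.7},
        }
    )
    slopes: dict = field(
        default_factory=lambda: {
            "tenderness": {
                "pH": 14.1,
                "collagen_mg_g": -3.86,
                "collagen_solubility_pct": -0.79,
                "imf_pct": 0.40,
            },
            "juiciness": {
                "pH": 12.6,
                "collagen_mg_g": -2.76,
                "collagen_solubility_pct": -0.83,
                "imf_pct": 0.88,
            },
            "flavor": {
                "pH": 11.7,
                "collagen_mg_g": -2.60,
                "collagen_solubility_pct": -0.68,
                "imf_pct": 2.91,
            },
            "overall": {
                "pH": 14.2,
                "collagen_mg_g": -3.42,
                "collagen_solubility_pct": -0.69,
                "imf_pct": 1.58,
            },
        }
    )
    centers: dict = field(
        default_factory=lambda: {
            "pH": 5.605,
            "imf_pct": 1.21,
            "collagen_mg_g": 4.645,
            "collagen_solubility_pct": 9.695,
        }
    )
    sd_session: float = 3.0
    sd_participant: float = 10.0
    sd_carcass: float = 5.0
    sd_residual: float = 15.0
    truncate: bool = True
    no_off_flavor_prob: dict = field(
        default_factory=lambda: {"LTL": 0.996, "SM": 0.992}
    )
    purchase_success_prob: dict = field(
        default_factory=lambda: {"LTL": 0.298, "SM": 0.351}
    )
    quality_success_prob: dict = field(
        default_factory=lambda: {"LTL": 0.284, "SM": 0.318}
    )
    logit_re_scale: float = 0.05  # random effects per score point, logit scale
    consumers_per_sample: int = 10
    samples_per_session: int = 12
    participants_per_session: int = 20
    n_days: int = 3

    def validate(self) -> None:
        for name in ("sd_session", "sd_participant", "sd_carcass", "sd_residual"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for d in (
            self.no_off_flavor_prob,
            self.purchase_success_prob,
            self.quality_success_prob,
        ):
            for m, p in d.items():
                if not (0 < p < 1):
                    raise ConfigurationError(f"probability for {m} must be in (0,1)")
        if self.consumers_per_sample < 1 or self.participants_per_session < 1:
            raise ConfigurationError("panel sizes must be >= 1")
        if self.participants_per_session > 0 and (
            self.samples_per_session * self.consumers_per_sample
        ) % self.participants_per_session:
            raise ConfigurationError(
                "servings per session must divide evenly among participants"
            )


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (see :mod:`meatq.pipeline`)."""

    cohort: CohortConfig = field(default_factory=lambda: default_cohort_config())
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    fit_options: FitOptions = field(default_factory=FitOptions)
    sensory: SensoryLinkConfig = field(default_factory=lambda: default_sensory_config())
    seed: int = 0
    outdir: str = "meatq_out"
    stages: tuple = ("simulate", "fit", "analyze")
    n_replicates: int = 3  # relaxometry measurements per loin sample
    average_trains_before_fit: bool = False

    def validate(self) -> None:
        valid = ("simulate", "fit", "analyze")
        if set(self.stages) - set(valid):
            raise ConfigurationError(f"unknown stages {set(self.stages) - set(valid)}")
        if not self.stages:
            raise ConfigurationError("at least one stage must be enabled")
        # downstream stages need simulated inputs; fitting may be skipped
        # (the analysis then marks its relaxometry tables as skipped)
        if "simulate" not in self.stages:
            raise ConfigurationError("the stage chain must start at 'simulate'")
        self.cohort.validate()
        self.acquisition.validate()
        self.fit_options.validate()
        self.sensory.validate()


def default_cohort_config(n_carcasses: int = 60, seed: int = 0) -> CohortConfig:
    """Cohort configuration at the published study conditions."""
    traits = {
        "pH": TraitConfig(
            mean={"LTL": 5.56, "SM": 5.65},
            sd={"LTL": 0.014 * _SQRT60, "SM": 0.018 * _SQRT60},
            lower={"LTL": 5.33, "SM": 5.46},
            upper={"LTL": 5.88, "SM": 5.99},
            cross_muscle_r2=0.273,
        ),
        "collagen_mg_g": TraitConfig(
            mean={"LTL": 4.56, "SM": 4.73},
            sd={"LTL": 0.073 * _SQRT60, "SM": 0.108 * _SQRT60},
            lower={"LTL": 3.51, "SM": 3.21},
            upper={"LTL": 5.57, "SM": 8.51},
            cross_muscle_r2=0.214,
        ),
        "collagen_solubility_pct": TraitConfig(
            mean={"LTL": 10.2, "SM": 9.19},
            sd={"LTL": 0.258 * _SQRT60, "SM": 0.239 * _SQRT60},
            lower={"LTL": 6.13, "SM": 5.78},
            upper={"LTL": 18.5, "SM": 13.4},
            cross_muscle_r2=0.104,
        ),
        "imf_pct": TraitConfig(
            mean={"LTL": 1.04, "SM": 1.38},
            sd={"LTL": 0.051 * _SQRT60, "SM": 0.065 * _SQRT60},
            lower={"LTL": 0.443, "SM": 0.579},
            upper={"LTL": 2.25, "SM": 2.84},
            cross_muscle_r2=0.044,
        ),
    }
    cfg = CohortConfig(n_carcasses=n_carcasses, traits=traits, seed=seed)
    cfg.validate()
    return cfg


def default_sensory_config() -> SensoryLinkConfig:
    cfg = SensoryLinkConfig()
    cfg.validate()
    return cfg


def nirs_link_from_target(
    target: RegressionTarget,
    imf_mean: float,
    replicate_sd: float = 0.0,
    n_replicates: int = 3,
) -> NirsLinkConfig:
    """Device link whose mean-of-replicates regression reproduces ``target``.

    The replicate noise contributes ``replicate_sd²/n`` to the effective
    predictor noise of the mean reading, so that much is removed from the
    between-sample term.
    """
    link = solve_reverse_link(target)
    var_between = link.noise_sd**2 - replicate_sd**2 / n_replicates
    if var_between < 0:
        raise ConfigurationError("replicate noise exceeds the calibrated total")
    return NirsLinkConfig(
        intercept=imf_mean * (1.0 - link.coef),
        slope=link.coef,
        between_sd=float(np.sqrt(var_between)),
        replicate_sd=replicate_sd,
    )


# ---------------------------------------------------------------------------
# dict / YAML round-tripping


def _as_dict(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _as_dict(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_dict(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_config(config: PipelineConfig, path: str | None = None) -> str:
    """Serialize a pipeline config to YAML (optionally writing ``path``)."""
    text = yaml.safe_dump(_as_dict(config), sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _traits_from_dict(d: dict) -> dict:
    return {name: TraitConfig(**tc) for name, tc in d.items()}


def config_from_dict(d: dict) -> PipelineConfig:
    cohort_d = dict(d.get("cohort", {}))
    if "traits" in cohort_d:
        cohort_d["traits"] = _traits_from_dict(cohort_d["traits"])
    if "nmr" in cohort_d:
        cohort_d["nmr"] = NmrLinkConfig(**cohort_d["nmr"])
    if "nirs" in cohort_d:
        cohort_d["nirs"] = NirsLinkConfig(**cohort_d["nirs"])
    cohort = CohortConfig(**cohort_d) if cohort_d else default_cohort_config()
    fit_d = dict(d.get("fit_options", {}))
    for key in ("t21_bounds_ms", "t22_bounds_ms"):
        if key in fit_d:
            fit_d[key] = tuple(fit_d[key])
    cfg = PipelineConfig(
        cohort=cohort,
        acquisition=AcquisitionConfig(**d.get("acquisition", {})),
        fit_options=FitOptions(**fit_d),
        sensory=SensoryLinkConfig(**d.get("sensory", {})),
        seed=d.get("seed", 0),
        outdir=d.get("outdir", "meatq_out"),
        stages=tuple(d.get("stages", ("simulate", "fit", "analyze"))),
        n_replicates=d.get("n_replicates", 3),
        average_trains_before_fit=d.get("average_trains_before_fit", False),
    )
    cfg.validate()
    return cfg


def load_config(path: str) -> PipelineConfig:
    """Load a pipeline config from a YAML (or JSON, a YAML subset) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)
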