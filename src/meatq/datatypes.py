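"""Core value types shared across the simulation and analysis layers.

Tabular data (cohorts, sensory panels, echo trains on disk) live in pandas
DataFrames; these dataclasses carry the strongly-typed per-object results
(one relaxation measurement, one fit, one regression summary) and enforce
the invariants the rest of the package relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NmrParams",
    "EchoTrain",
    "RelaxFit",
    "RegressionSummary",
    "NirsAggregate",
    "MuscleContrast",
    "SuccessSpec",
    "MUSCLES",
]

#: The two muscles measured: loin (Longissimus thoracis et lumborum) and
#: topside (semimembranosus).
MUSCLES = ("LTL", "SM")


@dataclass(frozen=True)
class NmrParams:
    """Parameters of the tri-exponential transverse-relaxation model.

    The CPMG decay is modelled as three exponentially relaxing proton pools:
    a fast macromolecule/fat-associated pool (``p_2f`` at the fixed time
    constant ``t_2f_ms``), intra-myofibrillar water (``p_21``, ``t_21_ms``)
    and inter-myofibrillar water (``p_22``, ``t_22_ms``).  Amplitudes are
    fractions of the total t = 0 signal and sum to one; an overall intensity
    scale is carried separately wherever it matters.
    """

    p_2f: float
    p_21: float
    p_22: float
    t_21_ms: float
    t_22_ms: float
    t_2f_ms: float = 10.0

    def __post_init__(self) -> None:
        amps = (self.p_2f, self.p_21, self.p_22)
        if any(a < 0 for a in amps):
            raise ValueError(f"amplitudes must be nonnegative, got {amps}")
        total = sum(amps)
        if not np.isclose(total, 1.0, rtol=0, atol=1e-9):
            raise ValueError(f"amplitudes must sum to 1, got {total!r}")
        if not (self.t_2f_ms < self.t_21_ms < self.t_22_ms):
            raise ValueError(
                "time constants must be ordered t_2f < t_21 < t_22, got "
                f"({self.t_2f_ms}, {self.t_21_ms}, {self.t_22_ms})"
            )

    def amplitudes(self) -> np.ndarray:
        return np.array([self.p_2f, self.p_21, self.p_22])

    def time_constants(self) -> np.ndarray:
        return np.array([self.t_2f_ms, self.t_21_ms, self.t_22_ms])

    def signal(self, times_ms: np.ndarray, scale: float = 1.0) -> np.ndarray:
        """Noiseless decay-model intensity at the given echo times."""
        t = np.asarray(times_ms, dtype=float)
        return scale * (
            self.p_2f * np.exp(-t / self.t_2f_ms)
            + self.p_21 * np.exp(-t / self.t_21_ms)
            + self.p_22 * np.exp(-t / self.t_22_ms)
        )


@dataclass
class EchoTrain:
    """A (possibly signal-averaged) CPMG echo decay curve."""

    times_ms: np.ndarray
    intensities: np.ndarray
    n_scans_averaged: int = 1
    noise_sd_estimate: float | None = None
    snr_estimate: float | None = None
    below_snr_flag: bool = False

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times_ms.shape != self.intensities.shape:
            raise ValueError("times and intensities must have equal length")
        if self.times_ms.size and (
            np.any(self.times_ms <= 0) or np.any(np.diff(self.times_ms) <= 0)
        ):
            raise ValueError("echo times must be positive and strictly increasing")

    def __len__(self) -> int:
        return self.times_ms.size


@dataclass
class RelaxFit:
    """Result of one tri-exponential decomposition."""

    params: NmrParams
    scale: float
    residual_rms: float
    converged: bool
    n_starts_used: int = 1
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be nonnegative")
        if self.converged and not np.isfinite(self.residual_rms):
            raise ValueError("a converged fit must have a finite residual_rms")


@dataclass(frozen=True)
class RegressionSummary:
    """Simple-linear-model summary: slope ± SE, R², p, RMSE, n."""

    slope: float
    slope_se: float
    intercept: float
    r2: float
    p_value: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r2 <= 1 + 1e-12):
            raise ValueError(f"r2 out of [0, 1]: {self.r2}")
        if self.rmse < 0:
            raise ValueError("rmse must be nonnegative")
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value out of (0, 1]: {self.p_value}")
        if self.n < 3:
            raise ValueError("need at least 3 observations")


@dataclass(frozen=True)
class NirsAggregate:
    """The three per-sample summaries of the NIRS reading triplet."""

    mean: float
    geometric_mean: float
    highest: float

    def __post_init__(self) -> None:
        if min(self.mean, self.geometric_mean, self.highest) <= 0:
            raise ValueError("aggregates of positive readings must be positive")
        if self.geometric_mean > self.mean * (1 + 1e-12):
            raise ValueError("geometric mean cannot exceed arithmetic mean")
        if self.highest < self.mean * (1 - 1e-12):
            raise ValueError("maximum cannot be below the mean")


@dataclass(frozen=True)
class MuscleContrast:
    """Two-muscle comparison of a trait: per-muscle mean ± SEM and p."""

    trait: str
    means: dict
    sems: dict
    p_value: float

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sems.values()):
            raise ValueError("SEMs must be nonnegative")
        if not (0 < self.p_value <= 1):
            raise ValueError("p_value out of (0, 1]")


@dataclass(frozen=True)
class SuccessSpec:
    """Which ordinal/binary levels of a consumer response count as success."""

    response: str
    success_levels: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.success_levels:
            raise ValueError("success level set must be non-empty")

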