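"""Analytic calibration of the synthetic generator to regression summaries.

The generator has to produce cohorts whose *analysis* reproduces published
simple-regression summaries (slope, R², RMSE) of a response ``y`` on a
predictor ``x``.  For a bivariate-normal pair those three numbers pin down
the full second-moment structure:

    Var(y)   = RMSE² / (1 − R²)            (RMSE = residual SD of y|x)
    Cov(x,y) = R² · Var(y) / slope         (slope = Cov/Var(x), R² = ρ²)
    Var(x)   = Cov(x,y) / slope

From that joint structure either generation direction follows.  The package
generates the *instrument* variable from the *trait* (device output from
intramuscular fat; relaxation amplitude from fat and pH), i.e. the reverse
of the analysed regression, so the reverse-link solution

    x = c + a·(y − E[y]) + u,   a = R²/slope,  Var(u) = a²·Var(y)·(1−R²)/R²

is the one the generator consumes.  All solutions are exact for the
untruncated Gaussian model; truncation to physical ranges attenuates them,
which is why calibration experiments run untruncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegressionTarget",
    "JointMoments",
    "ReverseLink",
    "ForwardLink",
    "solve_joint_moments",
    "solve_reverse_link",
    "solve_forward_link",
    "forward_summary_of_reverse_link",
]


@dataclass(frozen=True)
class RegressionTarget:
    """A published (slope, R², RMSE) triple for a regression of y on x."""

    slope: float
    r2: float
    rmse: float

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("target slope must be nonzero")
        if not (0 < self.r2 < 1):
            raise ValueError(f"target R² must lie in (0, 1), got {self.r2}")
        if self.rmse <= 0:
            raise ValueError("target RMSE must be positive")


@dataclass(frozen=True)
class JointMoments:
    """Second moments of the implied bivariate-normal (x, y) pair."""

    var_x: float
    var_y: float
    cov_xy: float


@dataclass(frozen=True)
class ReverseLink:
    """x generated from y:  x = c + coef·(y − mean_y) + N(0, noise_sd²)."""

    coef: float
    noise_sd: float
    var_y: float


@dataclass(frozen=True)
class ForwardLink:
    """y generated from x:  y = α + slope·x + N(0, resid_sd²)."""

    slope: float
    resid_sd: float
    var_x: float


def solve_joint_moments(target: RegressionTarget) -> JointMoments:
    var_y = target.rmse**2 / (1.0 - target.r2)
    cov = target.r2 * var_y / target.slope
    var_x = cov / target.slope
    if var_x <= 0:
        raise ValueError(f"infeasible target {target}: implied Var(x) <= 0")
    return JointMoments(var_x=var_x, var_y=var_y, cov_xy=cov)


def solve_reverse_link(target: RegressionTarget) -> ReverseLink:
    """Coefficients for generating the predictor from the response."""
    m = solve_joint_moments(target)
    coef = target.r2 / target.slope
    var_u = m.var_x - coef**2 * m.var_y
    if var_u < 0:
        raise ValueError(f"infeasible target {target}: implied noise variance < 0")
    return ReverseLink(coef=coef, noise_sd=float(np.sqrt(var_u)), var_y=m.var_y)


def solve_forward_link(target: RegressionTarget) -> ForwardLink:
    """Coefficients for generating the response directly from the predictor."""
    m = solve_joint_moments(target)
    return ForwardLink(slope=target.slope, resid_sd=target.rmse, var_x=m.var_x)


def forward_summary_of_reverse_link(link: ReverseLink) -> RegressionTarget:
    """Population regression summary of y on x implied by a reverse link.

    Used to verify the closed-form inversion round-trips: feeding the output
    of :func:`solve_reverse_link` through these defining identities must
    return the original target.
    """
    var_x = link.coef**2 * link.var_y + link.noise_sd**2
    cov = link.coef * link.var_y
    slope = cov / var_x
    r2 = cov**2 / (var_x * link.var_y)
    rmse = float(np.sqrt(link.var_y * (1.0 - r2)))
    return RegressionTarget(slope=slope, r2=r2, rmse=rmse)
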