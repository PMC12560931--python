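"""Tri-exponential CPMG decomposition with a fixed fast component.

The decay is modelled as

    I(t) = s · (p_2f · e^{−t/T_2f} + p_21 · e^{−t/T_21} + p_22 · e^{−t/T_22})

with ``T_2f`` held fixed (10 ms by default) to stabilize the fit, amplitudes
nonnegative and summing to one, and ``T_21 < T_22`` constrained to disjoint
bound intervals.  The solver uses variable projection: for any candidate
``(T_21, T_22)`` the absolute amplitudes enter linearly and are solved
exactly by nonnegative least squares, so the outer bounded minimisation runs
over the two log time constants only, multi-started from a log-spaced grid.
Multi-exponential objectives are multimodal; the multi-start is the standard
guard, and variable projection lets degenerate components reach exactly zero
amplitude.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import least_squares, nnls

from .config import FitOptions
from .datatypes import EchoTrain, NmrParams, RelaxFit

__all__ = [
    "fit_triexponential",
    "estimate_noise",
    "compute_snr",
    "average_replicate_fits",
    "AggregationError",
]


class AggregationError(RuntimeError):
    """Raised when replicate fits cannot be aggregated."""


def _basis(times: np.ndarray, t2f: float, t21: float, t22: float) -> np.ndarray:
    return np.exp(-times[:, None] / np.array([t2f, t21, t22]))


def _project(times, y, t2f, t21, t22):
    """Optimal nonnegative amplitudes for fixed time constants."""
    B = _basis(times, t2f, t21, t22)
    amps, _ = nnls(B, y)
    return amps, y - B @ amps


def fit_triexponential(train: EchoTrain, options: FitOptions | None = None) -> RelaxFit:
    """Decompose one echo train; see the module docstring for the model."""
    if options is None:
        options = FitOptions()
    options.validate()
    times = train.times_ms
    y = train.intensities
    if times.size < 6:
        raise ValueError(
            f"need at least 6 echoes to fit 5 free parameters, got {times.size}"
        )

    t2f = options.fixed_t2f_ms
    lo1, hi1 = options.t21_bounds_ms
    lo2, hi2 = options.t22_bounds_ms
    # bound intervals are open at the left end
    lo1, lo2 = lo1 * (1 + 1e-9), lo2 * (1 + 1e-9)
    bounds = (np.log([lo1, lo2]), np.log([hi1, hi2]))

    def residual(x):
        _, r = _project(times, y, t2f, np.exp(x[0]), np.exp(x[1]))
        return r

    k = options.n_starts_per_axis
    g1 = np.log(np.geomspace(lo1 * 1.05, hi1 * 0.95, k))
    g2 = np.log(np.geomspace(lo2 * 1.05, hi2 * 0.95, k))
    jitter_rng = np.random.default_rng(options.start_jitter_seed)

    best = None
    n_starts = 0
    for a in g1:
        for b in g2:
            x0 = np.array([a, b])
            if options.start_jitter_seed:
                x0 = np.clip(
                    x0 + jitter_rng.normal(0, 0.02, 2), bounds[0], bounds[1]
                )
            n_starts += 1
            try:
                res = least_squares(
                    residual,
                    x0,
                    bounds=bounds,
                    xtol=options.tolerance,
                    ftol=options.tolerance,
                    gtol=options.tolerance,
                    max_nfev=options.max_iterations * 4,
                )
            except Exception:  # pragma: no cover - numerical breakdown guard
                continue
            if best is None or res.cost < best.cost:
                best = res

    if best is None:
        params = NmrParams(0.0, 1.0, 0.0, t21_ms=50.0, t22_ms=200.0, t_2f_ms=t2f)
        return RelaxFit(
            params=params,
            scale=float("nan"),
            residual_rms=float("inf"),
            converged=False,
            n_starts_used=n_starts,
        )

    t21, t22 = np.exp(best.x)
    if t21 > t22:  # cannot occur with disjoint bounds, kept as a guard
        t21, t22 = t22, t21
    amps, resid = _project(times, y, t2f, t21, t22)
    scale = float(amps.sum())
    converged = bool(best.status > 0 and scale > 0 and np.isfinite(best.cost))
    if scale > 0:
        fracs = amps / scale
    else:
        fracs = np.array([0.0, 1.0, 0.0])
    degenerate = bool(t22 < options.degenerate_ratio * t21)
    if degenerate:
        # identifiability lost: merge the two slow pools into p_21
        fracs = np.array([fracs[0], fracs[1] + fracs[2], 0.0])
    fracs = fracs / fracs.sum()
    params = NmrParams(
        p_2f=float(fracs[0]),
        p_21=float(fracs[1]),
        p_22=float(fracs[2]),
        t_21_ms=float(t21),
        t_22_ms=float(t22),
        t_2f_ms=t2f,
    )
    return RelaxFit(
        params=params,
        scale=scale,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        converged=converged,
        n_starts_used=n_starts,
        degenerate=degenerate,
    )


def estimate_noise(train: EchoTrain, fit: RelaxFit | None = None) -> float:
    """Noise SD of an echo train.

    With a fit available, the RMS of the fit residuals is the estimate.
    Otherwise the standard deviation of first differences over the last 10%
    of echoes, divided by √2, is used: differencing removes the (locally
    nearly constant) decay signal while noise enters each difference twice.
    """
    if fit is not None:
        return float(fit.residual_rms)
    n = len(train)
    tail = train.intensities[-max(10, n // 10) :]
    if tail.size < 3:
        raise ValueError("too few echoes to estimate noise from the tail")
    d = np.diff(tail)
    return float(np.std(d, ddof=1) / np.sqrt(2.0))


def _extrapolate_t0(train: EchoTrain) -> float:
    """t = 0 intensity from a log-linear fit to the earliest echoes."""
    k = min(10, len(train))
    t = train.times_ms[:k]
    y = train.intensities[:k]
    pos = y > 0
    if pos.sum() < 3:
        return float(abs(y[0])) if len(y) else 0.0
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    return float(np.exp(intercept))


def compute_snr(
    train: EchoTrain,
    fit: RelaxFit | None = None,
    noise_sd: float | None = None,
) -> float:
    """SNR = model intensity extrapolated to t = 0 over the noise SD."""
    s0 = fit.scale if fit is not None else _extrapolate_t0(train)
    sigma = noise_sd if noise_sd is not None else estimate_noise(train, fit)
    if sigma <= 0:
        return float("inf")
    return float(s0 / sigma)


def average_replicate_fits(fits) -> RelaxFit:
    """Average the fitted parameters of the three replicate measurements.

    Each of the five free parameters (and the scale) is the arithmetic mean
    across replicates; the fixed fast time constant is carried through
    unchanged.  Replicate fits that did not converge cannot be averaged.
    """
    fits = list(fits)
    if len(fits) != 3:
        raise AggregationError(f"expected exactly 3 replicate fits, got {len(fits)}")
    for i, f in enumerate(fits):
        if not f.converged:
            raise AggregationError(f"replicate {i} did not converge")
    t2f = fits[0].params.t_2f_ms
    if any(f.params.t_2f_ms != t2f for f in fits):
        raise AggregationError("replicates disagree on the fixed fast time constant")
    amps = np.mean([f.params.amplitudes() for f in fits], axis=0)
    amps = amps / amps.sum()
    params = NmrParams(
        p_2f=float(amps[0]),
        p_21=float(amps[1]),
        p_22=float(amps[2]),
        t_21_ms=float(np.mean([f.params.t_21_ms for f in fits])),
        t_22_ms=float(np.mean([f.params.t_22_ms for f in fits])),
        t_2f_ms=t2f,
    )
    return RelaxFit(
        params=params,
        scale=float(np.mean([f.scale for f in fits])),
        residual_rms=float(np.mean([f.residual_rms for f in fits])),
        converged=True,
        n_starts_used=max(f.n_starts_used for f in fits),
        degenerate=any(f.degenerate for f in fits),
    )
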