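"""Three-parameter logistic psychometric function.

The probability of a rightward choice at (standardized) net motion
strength ``x`` is

    p(x) = gamma + (1 - 2 gamma) / (1 + exp(-beta (x - alpha)))

where ``alpha`` is the bias (midpoint), ``beta`` the slope (log-odds per
unit strength) and ``gamma`` a symmetric lapse rate compressing the curve
away from 0 and 1. Parameters are fit by maximum likelihood under a
Bernoulli choice model; standard errors come from the inverse Hessian of
the negative log-likelihood at the optimum. The 75%-correct threshold is
the analytic inversion of the fitted curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "PsychometricFit",
    "psychometric_p",
    "zscore_strengths",
    "fit_psychometric",
    "threshold75",
]

_EPS = 1e-12


class DegenerateInputError(ValueError):
    """Input lacks the variation required by the operation."""


class FitError(RuntimeError):
    """Maximum-likelihood optimization failed."""


class UndefinedThresholdError(ValueError):
    """The 75% point is unreachable (lapse >= 0.25)."""


@dataclass(frozen=True)
class PsychometricFit:
    alpha: float
    beta: float
    gamma: float
    se_alpha: float
    se_beta: float
    se_gamma: float
    loglik: float
    threshold75: float
    converged: bool = True
    separated: bool = False

    def predict(self, x) -> np.ndarray:
        return psychometric_p(np.asarray(x, dtype=float), self.alpha, self.beta, self.gamma)


def psychometric_p(x: np.ndarray, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Evaluate the lapse-compressed logistic at strength x."""
    return gamma + (1.0 - 2.0 * gamma) / (1.0 + np.exp(-beta * (x - alpha)))


def zscore_strengths(
    net_strengths: Sequence[float],
    subject_ids: Sequence | None = None,
) -> np.ndarray:
    """Standardize net strengths to mean 0, SD 1 (population SD).

    When ``subject_ids`` is given, standardization is applied per subject
    over all of that subject's trials (pooled across sessions), so
    subjects with different stimulus scales are each mapped to a common
    axis.
    """
    x = np.asarray(net_strengths, dtype=float)
    if subject_ids is None:
        sd = x.std()
        if sd == 0 or x.size < 2:
            raise DegenerateInputError("net strengths are constant; cannot z-score")
        return (x - x.mean()) / sd
    subject_ids = np.asarray(subject_ids)
    out = np.empty_like(x)
    for s in np.unique(subject_ids):
        m = subject_ids == s
        sd = x[m].std()
        if sd == 0 or m.sum() < 2:
            raise DegenerateInputError(
                f"net strengths for subject {s!r} are constant; cannot z-score"
            )
        out[m] = (x[m] - x[m].mean()) / sd
    return out


def _nll(params: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    alpha, beta, gamma = params
    p = psychometric_p(x, alpha, beta, gamma)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _nll_transformed(q: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    # gamma = 0.5 * expit(u) keeps the lapse inside (0, 0.5) during search
    alpha, beta, u = q
    gamma = 0.5 / (1.0 + np.exp(-u))
    return _nll(np.array([alpha, beta, gamma]), x, y)


def _numeric_hessian(f, p0: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    n = len(p0)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(p0 + ei + ej)
            fpm = f(p0 + ei - ej)
            fmp = f(p0 - ei + ej)
            fmm = f(p0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H

# Deterministic restart points (alpha, beta, logit-scale lapse): a mild and
# a steep slope, plus a shifted midpoint, guard against local optima.
_STARTS = (
    (0.0, 1.0, -4.0),
    (0.0, 4.0, -2.0),
    (0.5, 0.5, -4.0),
)

_SEPARATION_BETA = 50.0


def fit_psychometric(x: Sequence[float], choices: Sequence[int]) -> PsychometricFit:
    """Maximum-likelihood fit of (alpha, beta, gamma) to binary choices.

    The lapse is optimized on an unbounded scale mapped into [0, 0.5).
    Three deterministic restarts are used; the best optimum is kept.
    Standard errors are sqrt(diag(H^-1)) with H the numerical Hessian of
    the negative log-likelihood in the original parameterization. A fitted
    slope beyond ``50`` log-odds/unit flags (quasi-)separation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(choices, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and choices must have equal length")
    if len(x) < 20:
        raise DegenerateInputError("at least 20 trials are required")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise DegenerateInputError("both choice classes must be present")

    best = None
    for start in _STARTS:
        res = optimize.minimize(
            _nll_transformed,
            np.asarray(start, dtype=float),
            args=(x, y),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError("psychometric optimization did not produce a finite optimum")

    alpha, beta, u = best.x
    gamma = 0.5 / (1.0 + np.exp(-u))
    params = np.array([alpha, beta, gamma])
    loglik = -_nll(params, x, y)

    h = np.array([1e-4, 1e-4, min(1e-5, max(gamma / 10, 1e-8))])
    H = _numeric_hessian(lambda p: _nll(p, x, y), params, h)
    se = np.full(3, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        pass

    separated = bool(abs(beta) > _SEPARATION_BETA)
    try:
        thr = threshold75_params(alpha, beta, gamma)
    except UndefinedThresholdError:
        thr = float("nan")
    return PsychometricFit(
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        se_alpha=float(se[0]),
        se_beta=float(se[1]),
        se_gamma=float(se[2]),
        loglik=float(loglik),
        threshold75=float(thr),
        converged=bool(best.success),
        separated=separated,
    )


def threshold75_params(alpha: float, beta: float, gamma: float) -> float:
    """Strength at which the fitted curve crosses 75% rightward.

    Solves p(x) = 0.75 analytically:
    x = alpha - (1/beta) * ln((0.25 - gamma) / (0.75 - gamma)).
    """
    if gamma >= 0.25:
        raise UndefinedThresholdError(
            f"75% performance unreachable with lapse {gamma:.3f} >= 0.25"
        )
    return alpha - (1.0 / beta) * np.log((0.25 - gamma) / (0.75 - gamma))


def threshold75(fit: PsychometricFit | Mapping | tuple) -> float:
    """Threshold from a fit object, mapping, or (alpha, beta, gamma) tuple."""
    if isinstance(fit, PsychometricFit):
        return threshold75_params(fit.alpha, fit.beta, fit.gamma)
    if isinstance(fit, Mapping):
        return threshold75_params(fit["alpha"], fit["beta"], fit["gamma"])
    alpha, beta, gamma = fit
    return threshold75_params(alpha, beta, gamma)
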