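"""Temporal weighting kernels by ridge-penalized logistic regression.

Choices are regressed on the per-pulse motion strengths to estimate how
much weight each pulse carried in the decision. With Y in {0,1} the
choices, X the n_trials x (n_pulses + 1) design (pulse strengths plus an
intercept column of ones), and w the weights, the penalized log posterior
maximized here is

    L(w) = sum_i [ Y_i w'X_i - log(1 + exp(w'X_i)) ] - lambda * ||w_pulse||^2

i.e. a Bernoulli log-likelihood with a ridge penalty on the pulse weights
only (the bias term is unpenalized). The penalty corresponds to an
independent Gaussian prior N(0, 1/(2 lambda)) on each pulse weight; the
hyperparameter lambda is chosen by evidence optimization — maximizing the
Laplace approximation to the log marginal likelihood over a log-spaced
grid. Estimated kernels are reported normalized to unit Euclidean norm.

Because logistic regression whitens the stimulus covariance, kernels can
be estimated from all trials (including signal trials whose pulses are
temporally correlated through the condition profile), not just zero-mean
trials; ``whitening_check`` verifies this by correlating the two.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .stimulus import TrialRecord

__all__ = [
    "TrialMatrix",
    "KernelFit",
    "build_trial_matrix",
    "fit_kernel_map",
    "estimate_lambda_evidence",
    "fit_kernel",
    "normalize_kernel",
    "whitening_check",
    "DEFAULT_LAMBDA_GRID",
]

# 25 log-spaced ridge values: negligible to total shrinkage at n = 250-5000
DEFAULT_LAMBDA_GRID = np.logspace(-4, 4, 25)


class EstimationError(RuntimeError):
    """Kernel estimation failed (degenerate data or non-finite evidence)."""


class InsufficientDataError(ValueError):
    """Too few trials of the required kind for the requested analysis."""


@dataclass(frozen=True)
class TrialMatrix:
    """Design matrix for kernel regression.

    ``X`` holds pulse strengths in the first ``n_pulses`` columns and an
    intercept column of ones last; ``Y`` is the binary choice vector;
    ``zero_mean_mask`` marks trials drawn from the zero-mean distribution.
    """

    X: np.ndarray
    Y: np.ndarray
    zero_mean_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        if X.ndim != 2 or len(X) != len(Y):
            raise ValueError("X must be 2-D with one row per element of Y")
        if not np.allclose(X[:, -1], 1.0):
            raise ValueError("last column of X must be the intercept (all ones)")
        if not np.isin(Y, (0.0, 1.0)).all():
            raise ValueError("Y must be binary in {0, 1}")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        if self.zero_mean_mask is not None:
            m = np.asarray(self.zero_mean_mask, dtype=bool)
            if len(m) != len(Y):
                raise ValueError("zero_mean_mask length must match Y")
            object.__setattr__(self, "zero_mean_mask", m)

    @property
    def n_pulses(self) -> int:
        return self.X.shape[1] - 1

    def subset(self, mask: np.ndarray) -> "TrialMatrix":
        zm = None if self.zero_mean_mask is None else self.zero_mean_mask[mask]
        return TrialMatrix(self.X[mask], self.Y[mask], zm)


@dataclass(frozen=True)
class KernelFit:
    """MAP kernel estimate: pulse weights, bias, ridge strength."""

    weights: np.ndarray
    bias: float
    lam: float
    weights_normalized: np.ndarray
    log_posterior: float


def build_trial_matrix(trials: Sequence[TrialRecord]) -> TrialMatrix:
    """Assemble the regression design from trials carrying choices."""
    if any(t.choice is None for t in trials):
        raise ValueError("all trials must have choices before kernel estimation")
    P = np.vstack([t.pulse_strengths for t in trials])
    X = np.hstack([P, np.ones((len(trials), 1))])
    Y = np.array([t.choice for t in trials], dtype=float)
    zm = np.array([t.distribution_mu == 0.0 for t in trials], dtype=bool)
    return TrialMatrix(X, Y, zm)


def _penalty_diag(d: int) -> np.ndarray:
    """Ridge indicator: penalize pulse weights, never the bias column."""
    D = np.ones(d)
    D[-1] = 0.0
    return D


def _neg_log_posterior(w, X, Y, lam, D):
    eta = X @ w
    # log(1 + e^eta) computed stably for large |eta|
    ll = float(Y @ eta - np.logaddexp(0.0, eta).sum())
    return -(ll - lam * float(w * D @ w)), ll


def _newton_map(X: np.ndarray, Y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """Damped Newton ascent of the concave penalized log posterior."""
    n, d = X.shape
    D = _penalty_diag(d)
    w = np.zeros(d)
    nlp, _ = _neg_log_posterior(w, X, Y, lam, D)
    for _ in range(100):
        eta = X @ w
        p = expit(eta)
        g = X.T @ (p - Y) + 2.0 * lam * D * w  # gradient of the NEGATIVE posterior
        s = p * (1.0 - p)
        H = X.T @ (X * s[:, None]) + 2.0 * np.diag(lam * D)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as exc:
            raise EstimationError("singular Hessian in kernel MAP") from exc
        # backtracking keeps the objective decreasing even far from optimum
        t = 1.0
        for _ in range(50):
            cand = w - t * step
            nlp_new, _ = _neg_log_posterior(cand, X, Y, lam, D)
            if nlp_new <= nlp:
                break
            t *= 0.5
        w, nlp_prev, nlp = cand, nlp, nlp_new
        if np.max(np.abs(t * step)) < 1e-12 or nlp_prev - nlp < 1e-13:
            break
    return w, nlp


def fit_kernel_map(tm: TrialMatrix, lam: float) -> KernelFit:
    """MAP estimate of the temporal kernel at a fixed ridge strength.

    The objective is strictly concave for ``lam > 0`` (and concave at 0),
    so the optimum is unique; a damped Newton iteration finds it.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    Y = tm.Y
    if not (np.any(Y == 0) and np.any(Y == 1)):
        raise EstimationError("both choice classes must be present")
    w, nlp = _newton_map(tm.X, Y, lam)
    weights = w[:-1]
    return KernelFit(
        weights=weights,
        bias=float(w[-1]),
        lam=float(lam),
        weights_normalized=normalize_kernel(weights),
        log_posterior=float(-nlp),
    )


def _log_evidence(tm: TrialMatrix, lam: float) -> float:
    """Laplace approximation to the log marginal likelihood at one lambda.

    log Z ~ loglik(MAP) + log prior(MAP) + (d+1)/2 log 2pi - 1/2 log|H|,
    with prior N(0, 1/(2 lambda)) per pulse weight and an improper flat
    prior on the bias (whose 2pi terms cancel up to a lambda-free constant).
    """
    X, Y = tm.X, tm.Y
    d = X.shape[1] - 1  # penalized weights only
    D = _penalty_diag(X.shape[1])
    w, _ = _newton_map(X, Y, lam)
    _, ll = _neg_log_posterior(w, X, Y, lam, D)
    log_prior = 0.5 * d * np.log(2.0 * lam / (2.0 * np.pi)) - lam * float(
        w[:-1] @ w[:-1]
    )
    p = expit(X @ w)
    s = p * (1.0 - p)
    H = X.T @ (X * s[:, None]) + 2.0 * np.diag(lam * D)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf
    return ll + log_prior + 0.5 * (d + 1) * np.log(2.0 * np.pi) - 0.5 * logdet


def estimate_lambda_evidence(
    tm: TrialMatrix, grid: np.ndarray | None = None
) -> float:
    """Ridge strength maximizing the Laplace evidence over a log grid.

    Deterministic given the data; raises if the evidence is non-finite
    everywhere on the grid.
    """
    grid = DEFAULT_LAMBDA_GRID if grid is None else np.asarray(grid, dtype=float)
    ev = np.array([_log_evidence(tm, lam) for lam in grid])
    if not np.isfinite(ev).any():
        raise EstimationError("evidence is non-finite across the lambda grid")
    return float(grid[int(np.nanargmax(np.where(np.isfinite(ev), ev, -np.inf)))])


def fit_kernel(tm: TrialMatrix, grid: np.ndarray | None = None) -> KernelFit:
    """Full kernel estimate: evidence-optimized lambda, then the MAP fit."""
    lam = estimate_lambda_evidence(tm, grid)
    return fit_kernel_map(tm, lam)


def normalize_kernel(weights: np.ndarray) -> np.ndarray:
    """Scale the pulse weights to unit Euclidean norm (bias excluded)."""
    w = np.asarray(weights, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise EstimationError("cannot normalize an all-zero kernel")
    return w / norm


def whitening_check(
    trials: Sequence[TrialRecord],
    grid: np.ndarray | None = None,
    min_zero_mean: int = 100,
) -> float:
    """Pearson r between the all-trials and zero-mean-only kernels.

    Fits the kernel twice — on every trial, and on zero-mean trials alone
    (classical noise-based reverse correlation) — and correlates the two
    normalized weight vectors. Agreement confirms that the regression
    whitens the temporal correlations the condition profiles induce on
    signal trials.
    """
    tm = build_trial_matrix(trials)
    n_zero = int(tm.zero_mean_mask.sum())
    if n_zero < min_zero_mean:
        raise InsufficientDataError(
            f"need >= {min_zero_mean} zero-mean trials, found {n_zero}"
        )
    fit_all = fit_kernel(tm, grid)
    fit_zero = fit_kernel(tm.subset(tm.zero_mean_mask), grid)
    r, _ = stats.pearsonr(fit_all.weights_normalized, fit_zero.weights_normalized)
    return float(r)
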