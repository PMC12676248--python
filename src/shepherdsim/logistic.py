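"""Binomial logistic fit of offspring mosaic ratio against parental ratio.

Under random (unmoderated) transmission the offspring ratio would track the
parental ratio one-for-one — the identity line y = x.  A selection process
that herds offspring mosaicism toward lower values bends the retention curve
away from identity.  This module fits

    logit(mu_i) = beta0 + beta1 * x_i

to parent–offspring ratio pairs by maximizing the weighted binomial
log-likelihood  sum_i m_i [ y_i log mu_i + (1 - y_i) log(1 - mu_i) ],
where m_i is the effective number of metaphases behind the reported offspring
percentage, and quantifies the deviation of the fitted curve from y = x with
a case-resampling bootstrap interval.

The optimizer is Newton scoring (IRLS) with step-halving, converged when the
score norm drops below 1e-8.  Observed ratios of exactly 0 or 1 are clamped
to 1/(2m) and 1 - 1/(2m) to keep the likelihood finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "DeviationReport",
    "fit_retention_curve",
    "predict_retention",
    "identity_deviation",
]

_SCORE_TOL = 1e-8
_STEP_TOL = 1e-8  # Newton step below this ≈ score at its rounding floor
_MAX_ITER = 100
_MAX_HALVINGS = 20
DEFAULT_METAPHASES = 30.0  # typical metaphases scored when a source gives only a percent


@dataclass(frozen=True)
class LogisticFit:
    beta0: float
    beta1: float
    se_beta0: float
    se_beta1: float
    loglik: float
    converged: bool
    n_cases: int
    n_iter: int
    # Data retained for bootstrap resampling and diagnostics.
    x: np.ndarray = None
    y: np.ndarray = None
    weights: np.ndarray = None
    loglik_history: tuple[float, ...] = ()


def _loglik(beta: np.ndarray, X: np.ndarray, y: np.ndarray, m: np.ndarray) -> float:
    eta = X @ beta
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    return float(np.sum(m * (y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu))))


def fit_retention_curve(
    x: np.ndarray,
    y: np.ndarray,
    m: np.ndarray | float | None = None,
) -> LogisticFit:
    """Fit the retention curve by Newton scoring with step-halving.

    Parameters
    ----------
    x : parental mosaic fractions in [0, 1]; at least two distinct values.
    y : offspring mosaic fractions in [0, 1].
    m : effective metaphase counts (binomial denominators); scalar or
        per-case; defaults to 30 when unknown.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least two cases")
    if np.ptp(x) == 0.0:
        raise ValueError("all parental ratios identical; slope unidentifiable")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("offspring ratios must lie in [0, 1]")
    if m is None:
        m = DEFAULT_METAPHASES
    m = np.broadcast_to(np.asarray(m, dtype=float), x.shape).copy()
    if np.any(m < 1):
        raise ValueError("weights must be >= 1")

    # Clamp boundary proportions so log-likelihood stays finite.
    y = np.clip(y, 1.0 / (2.0 * m), 1.0 - 1.0 / (2.0 * m))

    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    ll = _loglik(beta, X, y, m)
    history = [ll]
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        mu = expit(X @ beta)
        score = X.T @ (m * (y - mu))
        if np.max(np.abs(score)) < _SCORE_TOL:
            converged = True
            break
        W = m * mu * (1.0 - mu)
        H = X.T @ (W[:, None] * X)
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            break
        if np.max(np.abs(delta)) < _STEP_TOL:
            # Parameter update below float resolution: the score norm has hit
            # its rounding floor (scales with sum of weights), i.e. converged.
            converged = True
            break
        # Step-halving: never accept a step that lowers the likelihood.
        step = 1.0
        for _ in range(_MAX_HALVINGS):
            cand = beta + step * delta
            cand_ll = _loglik(cand, X, y, m)
            if cand_ll >= ll - 1e-12:
                break
            step /= 2.0
        else:
            break
        beta = beta + step * delta
        ll = _loglik(beta, X, y, m)
        history.append(ll)
    else:
        it = _MAX_ITER

    mu = expit(X @ beta)
    score = X.T @ (m * (y - mu))
    if np.max(np.abs(score)) < _SCORE_TOL:
        converged = True
    if not converged:
        warnings.warn(
            "logistic fit did not converge (possible separation)", RuntimeWarning
        )
    W = m * mu * (1.0 - mu)
    H = X.T @ (W[:, None] * X)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])

    return LogisticFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        loglik=ll,
        converged=converged,
        n_cases=len(x),
        n_iter=it,
        x=x,
        y=y,
        weights=m,
        loglik_history=tuple(history),
    )


def predict_retention(fit: LogisticFit, x: float | np.ndarray):
    """Predicted offspring fraction at parental fraction x, strictly in (0,1)."""
    return expit(fit.beta0 + fit.beta1 * np.asarray(x, dtype=float))


@dataclass(frozen=True)
class DeviationReport:
    """Deviation of the fitted retention curve from the identity line y = x."""

    grid: np.ndarray
    fitted: np.ndarray
    mean_abs_deviation_from_identity: float
    bootstrap_ci: tuple[float, float]
    bootstrap_reps: int
    level: float

    def to_dict(self) -> dict:
        return {
            "mean_abs_deviation_from_identity": self.mean_abs_deviation_from_identity,
            "bootstrap_ci": list(self.bootstrap_ci),
            "bootstrap_reps": self.bootstrap_reps,
            "level": self.level,
        }


def _mean_abs_deviation(fit: LogisticFit, grid: np.ndarray) -> float:
    return float(np.mean(np.abs(predict_retention(fit, grid) - grid)))


def identity_deviation(
    fit: LogisticFit,
    grid_size: int = 101,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
) -> DeviationReport:
    """Mean |fitted − identity| over an even grid, with a bootstrap CI.

    The bootstrap resamples cases (parent, offspring, weight triples stored
    on the fit) with replacement, refits, and recomputes the deviation; the
    central interval at ``level`` is reported.  A fixed seed makes the
    interval bit-for-bit reproducible.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if bootstrap_reps < 1:
        raise ValueError("bootstrap_reps must be >= 1")
    if fit.x is None:
        raise ValueError("fit carries no data to resample")
    grid = np.linspace(0.0, 1.0, grid_size)
    point = _mean_abs_deviation(fit, grid)

    rng = np.random.default_rng(seed)
    n = fit.n_cases
    devs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(bootstrap_reps):
            idx = rng.integers(0, n, n)
            xb, yb, mb = fit.x[idx], fit.y[idx], fit.weights[idx]
            if np.ptp(xb) == 0.0:
                continue  # degenerate resample: slope unidentifiable
            fb = fit_retention_curve(xb, yb, mb)
            devs.append(_mean_abs_deviation(fb, grid))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(devs, [alpha, 1.0 - alpha])
    return DeviationReport(
        grid=grid,
        fitted=predict_retention(fit, grid),
        mean_abs_deviation_from_identity=point,
        bootstrap_ci=(float(lo), float(hi)),
        bootstrap_reps=bootstrap_reps,
        level=level,
    )
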