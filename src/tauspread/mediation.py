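"""Bootstrapped causal mediation with a binary mediator.

Treatment X (continuous, standardized), mediator M (binary: APOE e4 carrier
status or amyloid positivity), outcome Y (continuous), with covariate
adjustment on both paths.  The mediator model is a logistic regression of M on
X and covariates; the outcome model is a linear regression of Y on X, M and
covariates (no exposure-mediator interaction).  Under the potential-outcomes
decomposition without interaction:

    ACME = theta_M * [ mean_i P(M=1 | x1, C_i) - mean_i P(M=1 | x0, C_i) ]
    ADE  = theta_X * (x1 - x0)
    total = ACME + ADE  (exact identity)

Uncertainty comes from a nonparametric subject-resampling bootstrap with
percentile confidence intervals and add-one-corrected two-sided p-values.
The logistic fits use Newton-Raphson; quasi-separated fits are refit with a
small ridge penalty and a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError

logger = logging.getLogger(__name__)

DEFAULT_CONTRAST = (0.0, 1.0)  # 1-SD increase on the standardized treatment scale
RIDGE_PENALTY = 1e-2           # per-observation L2 penalty for separated logistic fits


@dataclass
class MediationResult:
    acme: float
    ade: float
    total: float
    prop_mediated: float
    acme_ci: tuple
    ade_ci: tuple
    total_ci: tuple
    acme_p: float
    ade_p: float
    total_p: float
    n_boot: int
    seed: int | None
    contrast: tuple

    def to_dict(self) -> dict:
        return asdict(self)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _logistic_fit(X: np.ndarray, y: np.ndarray, ridge: float = 0.0, max_iter: int = 50,
                  tol: float = 1e-10) -> tuple[np.ndarray, bool]:
    """Newton-Raphson logistic regression.  Returns (coef, converged)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = np.maximum(mu * (1 - mu), 1e-12)
        grad = X.T @ (y - mu) - ridge * n * beta
        H = (X * w[:, None]).T @ X + ridge * n * np.eye(p)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, True
    return beta, False


def _fit_mediator(X: np.ndarray, m: np.ndarray) -> np.ndarray:
    beta, converged = _logistic_fit(X, m)
    if not converged or np.max(np.abs(X @ beta)) > 30:
        logger.warning("logistic mediator fit separated; ridge-stabilized refit")
        beta, _ = _logistic_fit(X, m, ridge=RIDGE_PENALTY)
    return beta


def acme_point(
    mediator_coef: np.ndarray,
    outcome_coef: np.ndarray,
    covariate_rows: np.ndarray | None,
    x0: float,
    x1: float,
    mediator_is_binary: bool = True,
) -> tuple[float, float, float]:
    """Point ACME/ADE/total from fitted coefficients and the treatment contrast.

    Coefficient layout: mediator_coef = [intercept, x, covariates...];
    outcome_coef = [intercept, x, m, covariates...].  ``covariate_rows`` is the
    n x k covariate matrix over which mediator probabilities are averaged.
    With a continuous mediator (linear mediator model) the ACME reduces to the
    product of coefficients.
    """
    theta_x = outcome_coef[1]
    theta_m = outcome_coef[2]
    a1 = mediator_coef[1]
    if mediator_is_binary:
        def mean_p(x):
            eta = mediator_coef[0] + a1 * x
            if covariate_rows is not None and covariate_rows.shape[1]:
                eta = eta + covariate_rows @ mediator_coef[2:]
            return float(np.mean(_sigmoid(np.atleast_1d(eta))))
        acme = theta_m * (mean_p(x1) - mean_p(x0))
    else:
        acme = theta_m * a1 * (x1 - x0)
    ade = theta_x * (x1 - x0)
    return float(acme), float(ade), float(acme + ade)


def _design(x, m, C):
    Xm = np.column_stack([np.ones(len(x)), x] + ([C] if C is not None else []))
    Xy = np.column_stack([np.ones(len(x)), x, m] + ([C] if C is not None else []))
    return Xm, Xy


def mediate(
    x: np.ndarray | pd.Series,
    m: np.ndarray | pd.Series,
    y: np.ndarray | pd.Series,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    contrast: tuple = DEFAULT_CONTRAST,
) -> MediationResult:
    """Bootstrapped mediation of the x -> y relationship through m.

    X is standardized internally (the default contrast (0, 1) is therefore a
    1-SD increase).  The mediator model is logistic when m is binary and
    linear otherwise (in which case the ACME is the coefficient product).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m = np.asarray(m, dtype=float)
    n = len(x)
    if n < 30:
        raise InvalidConfigError(f"mediation requires n >= 30, got {n}")
    if len(m) != n or len(y) != n:
        raise InvalidConfigError("x, m, y must have equal length")
    levels = np.unique(m)
    if len(levels) == 1:
        raise InvalidConfigError("mediator is constant")
    binary = set(levels).issubset({0.0, 1.0})
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        sd = C.std(axis=0)
        C = (C - C.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    if x.std() == 0:
        raise InvalidConfigError("treatment has zero variance")
    xs = (x - x.mean()) / x.std()
    x0, x1 = contrast

    def point(idx: np.ndarray) -> tuple[float, float, float]:
        xi, mi, yi = xs[idx], m[idx], y[idx]
        Ci = C[idx] if C is not None else None
        Xm, Xy = _design(xi, mi, Ci)
        if binary:
            med_coef = _fit_mediator(Xm, mi)
        else:
            med_coef, *_ = np.linalg.lstsq(Xm, mi, rcond=None)
        out_coef, *_ = np.linalg.lstsq(Xy, yi, rcond=None)
        return acme_point(med_coef, out_coef, Ci, x0, x1, mediator_is_binary=binary)

    all_idx = np.arange(n)
    acme, ade, total = point(all_idx)

    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, 3))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        # resamples without both mediator levels cannot support the fit; redraw
        tries = 0
        while binary and len(np.unique(m[idx])) < 2 and tries < 100:
            idx = rng.integers(0, n, size=n)
            tries += 1
        draws[b] = point(idx)

    def summarize(col: int, est: float):
        v = draws[:, col]
        lo, hi = np.percentile(v, [2.5, 97.5])
        p_lo = (1 + np.sum(v <= 0)) / (n_boot + 1)
        p_hi = (1 + np.sum(v >= 0)) / (n_boot + 1)
        p = min(1.0, 2 * min(p_lo, p_hi))
        return (float(lo), float(hi)), float(p)

    acme_ci, acme_p = summarize(0, acme)
    ade_ci, ade_p = summarize(1, ade)
    total_ci, total_p = summarize(2, total)
    prop = acme / total if abs(total) > 1e-12 else float("nan")
    return MediationResult(
        acme=acme, ade=ade, total=total, prop_mediated=prop,
        acme_ci=acme_ci, ade_ci=ade_ci, total_ci=total_ci,
        acme_p=acme_p, ade_p=ade_p, total_p=total_p,
        n_boot=n_boot, seed=seed, contrast=tuple(contrast),
    )
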