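"""Tau-PET epicentre detection via two-component Gaussian mixture scoring.

Baseline tau-PET SUVR in a parcel mixes non-specific binding (low mode) with
specific binding (high mode).  A two-component univariate Gaussian mixture is
fitted per region on the pooled baseline data; the posterior probability of
the high component turns each SUVR into a probabilistic tau-positivity
indicator without a fixed threshold.  Probability-weighted SUVR (SUVR times
that posterior) ranks regions, and the top-k per subject are the individual
epicentres.  Parcels where one and two components fit almost identically
(low-tau regions with no separable high mode) are excluded from selection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .exceptions import ExcludedParcelError, InvalidConfigError

logger = logging.getLogger(__name__)

#: lower bound on component variances, prevents collapse onto a point mass
VARIANCE_FLOOR = 1e-6
#: exclusion rule: BIC(1-component) - BIC(2-component) below this, or component
#: means closer than half the pooled sd, means the high mode is not separable
DELTA_BIC_THRESHOLD = 10.0
SEPARATION_FACTOR = 0.5

ABETA_CUTOFFS = {
    "ADNI_AV45": 1.11,    # global AV45 SUVR
    "ADNI_FBB": 1.08,     # global FBB SUVR
    "HABS_PIB_DVR": 1.2,  # neocortical PiB DVR
}


@dataclass
class GMMFit:
    """Two-component univariate Gaussian mixture fit for one region."""

    mu_low: float
    mu_high: float
    sigma_low: float
    sigma_high: float
    pi_low: float
    pi_high: float
    log_likelihood: float
    delta_bic: float
    excluded: bool


@dataclass
class EpicentreSet:
    """Top-k probability-weighted regions for one subject, scores descending."""

    subject_id: str
    regions: list
    scores: list

    def __post_init__(self):
        if len(self.regions) != len(self.scores):
            raise ValueError("regions and scores must have equal length")


def _loglik(x: np.ndarray, mu, sigma, pi) -> float:
    comp = np.stack(
        [np.log(pi[j]) + norm.logpdf(x, mu[j], sigma[j]) for j in range(2)]
    )
    m = comp.max(axis=0)
    return float(np.sum(m + np.log(np.exp(comp - m).sum(axis=0))))


def _em_once(x: np.ndarray, mu, sigma, pi, tol: float, max_iter: int):
    """One EM run; asserts the log-likelihood never decreases."""
    ll_old = -np.inf
    for _ in range(max_iter):
        # E-step in log space
        log_resp = np.stack(
            [np.log(pi[j]) + norm.logpdf(x, mu[j], sigma[j]) for j in range(2)]
        )
        m = log_resp.max(axis=0)
        log_norm = m + np.log(np.exp(log_resp - m).sum(axis=0))
        resp = np.exp(log_resp - log_norm)
        ll = float(np.sum(log_norm))
        assert ll >= ll_old - 1e-8 * max(1.0, abs(ll_old)), "EM log-likelihood decreased"
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp @ x) / nk
        var = np.maximum(
            np.array([resp[j] @ (x - mu[j]) ** 2 for j in range(2)]) / nk,
            VARIANCE_FLOOR,
        )
        sigma = np.sqrt(var)
        pi = nk / len(x)
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            ll_old = ll
            break
        ll_old = ll
    return mu, sigma, pi, ll_old


def fit_tau_gmm(
    baseline_suvr: np.ndarray,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    delta_bic_threshold: float = DELTA_BIC_THRESHOLD,
    separation_factor: float = SEPARATION_FACTOR,
    seed: int = 0,
) -> GMMFit:
    """EM fit of a two-component univariate Gaussian mixture.

    Initialization: means at the 10th/90th percentiles, shared sd, equal
    weights; ``n_restarts`` jittered restarts keep the best log-likelihood.
    Components are ordered by mean.  The exclusion flag is set when the
    one-component model is nearly as good (delta BIC below threshold) or the
    component means are closer than ``separation_factor`` pooled sd.
    """
    x = np.asarray(baseline_suvr, dtype=float)
    if len(x) < 20:
        raise InvalidConfigError("mixture fit requires >= 20 observations")
    pooled_sd = float(x.std())
    if pooled_sd == 0:
        # degenerate: all observations identical, no mixture separable
        return GMMFit(
            mu_low=float(x[0]), mu_high=float(x[0]),
            sigma_low=math.sqrt(VARIANCE_FLOOR), sigma_high=math.sqrt(VARIANCE_FLOOR),
            pi_low=0.5, pi_high=0.5,
            log_likelihood=np.nan, delta_bic=-np.inf, excluded=True,
        )

    rng = np.random.default_rng(seed)
    base_mu = np.percentile(x, [10, 90]).astype(float)
    best = None
    for i in range(n_restarts):
        mu = base_mu.copy()
        if i > 0:
            mu = mu + rng.normal(0, 0.25 * pooled_sd, size=2)
        sigma = np.full(2, max(pooled_sd, math.sqrt(VARIANCE_FLOOR)))
        pi = np.array([0.5, 0.5])
        mu, sigma, pi, ll = _em_once(x, mu, sigma, pi, tol, max_iter)
        if best is None or ll > best[-1]:
            best = (mu, sigma, pi, ll)
    mu, sigma, pi, ll = best
    order = np.argsort(mu)
    mu, sigma, pi = mu[order], sigma[order], pi[order]

    # BIC comparison against the single-Gaussian model
    n = len(x)
    ll1 = float(np.sum(norm.logpdf(x, x.mean(), max(pooled_sd, math.sqrt(VARIANCE_FLOOR)))))
    bic1 = 2 * math.log(n) - 2 * ll1
    bic2 = 5 * math.log(n) - 2 * ll
    delta_bic = bic1 - bic2
    excluded = (delta_bic < delta_bic_threshold) or (
        (mu[1] - mu[0]) < separation_factor * pooled_sd
    )
    return GMMFit(
        mu_low=float(mu[0]), mu_high=float(mu[1]),
        sigma_low=float(sigma[0]), sigma_high=float(sigma[1]),
        pi_low=float(pi[0]), pi_high=float(pi[1]),
        log_likelihood=ll, delta_bic=float(delta_bic), excluded=bool(excluded),
    )


def tau_probability(fit: GMMFit, suvr) -> np.ndarray | float:
    """Posterior probability that the SUVR belongs to the high-tau component."""
    if fit.excluded:
        raise ExcludedParcelError("tau probability requested from an excluded parcel")
    x = np.asarray(suvr, dtype=float)
    log_low = math.log(fit.pi_low) + norm.logpdf(x, fit.mu_low, fit.sigma_low)
    log_high = math.log(fit.pi_high) + norm.logpdf(x, fit.mu_high, fit.sigma_high)
    m = np.maximum(log_low, log_high)
    p = np.exp(log_high - m) / (np.exp(log_low - m) + np.exp(log_high - m))
    return float(p) if np.isscalar(suvr) else p


def weighted_suvr(suvr, p):
    """Probability-weighted SUVR: the raw SUVR times the high-tau posterior."""
    suvr = np.asarray(suvr, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(suvr <= 0):
        raise InvalidConfigError("suvr must be positive")
    if np.any((p < 0) | (p > 1)):
        raise InvalidConfigError("probability must lie in [0, 1]")
    out = suvr * p
    return float(out) if out.ndim == 0 else out


def select_epicentres(
    weighted_map: pd.Series,
    k: int = 10,
    excluded: set | None = None,
    raw_suvr: pd.Series | None = None,
    subject_id: str = "",
) -> EpicentreSet:
    """The k highest probability-weighted regions, skipping excluded parcels.

    Ties are broken by higher raw SUVR, then lower region index.
    """
    excluded = excluded or set()
    eligible = weighted_map[~weighted_map.index.isin(excluded)]
    if len(eligible) < k:
        raise InvalidConfigError(
            f"only {len(eligible)} eligible regions for k={k} epicentres"
        )
    raw = raw_suvr if raw_suvr is not None else pd.Series(0.0, index=weighted_map.index)
    order = sorted(
        range(len(eligible)),
        key=lambda i: (
            -eligible.iloc[i],
            -float(raw.get(eligible.index[i], 0.0)),
            i,
        ),
    )
    top = [eligible.index[i] for i in order[:k]]
    return EpicentreSet(
        subject_id=subject_id,
        regions=top,
        scores=[float(eligible[r]) for r in top],
    )


def group_epicentres(
    weighted_maps: pd.DataFrame,
    top_frac: float = 0.05,
    excluded: set | None = None,
) -> list:
    """Group-level epicentres: top fraction of regions by mean weighted SUVR."""
    if not 0 < top_frac <= 1:
        raise InvalidConfigError(f"top_frac must be in (0, 1], got {top_frac}")
    excluded = excluded or set()
    means = weighted_maps.mean(axis=0)
    eligible = means[~means.index.isin(excluded)]
    k = int(round(top_frac * len(eligible)))
    k = max(k, 1)
    chosen = select_epicentres(eligible, k=k, excluded=set())
    return chosen.regions


def classify_abeta(global_amyloid: float, convention: str) -> bool:
    """Amyloid positivity by the printed per-tracer cutoff (strict greater-than)."""
    if global_amyloid <= 0:
        raise InvalidConfigError("global amyloid measure must be positive")
    try:
        cutoff = ABETA_CUTOFFS[convention]
    except KeyError:
        raise InvalidConfigError(
            f"unknown convention {convention!r}; one of {sorted(ABETA_CUTOFFS)}"
        ) from None
    return global_amyloid > cutoff


def fit_all_regions(
    baseline: pd.DataFrame,
    seed: int = 0,
    **gmm_kwargs,
) -> tuple[dict, pd.DataFrame, set]:
    """Fit the mixture per region on the pooled baseline matrix (subjects x regions).

    Returns (fits by region, probability-weighted SUVR matrix, excluded region set).
    Weighted scores at excluded parcels are NaN.
    """
    fits = {}
    weighted = pd.DataFrame(index=baseline.index, columns=baseline.columns, dtype=float)
    excluded = set()
    for j, region in enumerate(baseline.columns):
        vals = baseline[region].to_numpy(dtype=float)
        fit = fit_tau_gmm(vals, seed=seed + j, **gmm_kwargs)
        fits[region] = fit
        if fit.excluded:
            excluded.add(region)
            continue
        p = tau_probability(fit, vals)
        weighted[region] = weighted_suvr(vals, p)
    return fits, weighted, excluded
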