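"""Permutation-calibrated Wilcoxon influence maps.

How much does the group-level spreading map (regional beta-values) explain a
subject's FC-to-epicentres profile?  Within each subject, FC to epicentres is
regressed on the group beta map across that subject's eligible non-epicentre
regions, and the residuals are internally studentized.  Because the residuals
are not normal, each region is scored with a Wilcoxon rank-sum statistic of
its residuals (across subjects) against the pooled residuals of all other
regions.  The null distribution comes from repeating the whole procedure with
randomly permuted region labels of the beta map (the same permutation applied
to every subject within an iteration, which preserves subject structure while
breaking map alignment).  Regional z-scores against the permutation null are
thresholded at alpha.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .exceptions import InvalidConfigError

logger = logging.getLogger(__name__)


def subject_residual_map(fc_per_region: pd.Series, group_beta: pd.Series) -> pd.Series:
    """Internally studentized residuals of FC-to-epicentres on the group beta map.

    Simple OLS across the subject's eligible regions; each residual is divided
    by s * sqrt(1 - h) with h the leverage from the hat matrix.
    """
    shared = fc_per_region.index.intersection(group_beta.index)
    y = fc_per_region[shared].to_numpy(dtype=float)
    x = group_beta[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    idx = shared[ok]
    n = len(x)
    if n < 10:
        raise InvalidConfigError(f"need >= 10 regions with both values, got {n}")
    if x.std() == 0:
        raise InvalidConfigError("zero-variance predictor (group beta map)")
    xc = x - x.mean()
    sxx = np.dot(xc, xc)
    slope = np.dot(xc, y) / sxx
    resid = y - y.mean() - slope * xc
    h = 1.0 / n + xc**2 / sxx
    s2 = np.sum(resid**2) / (n - 2)
    # a numerically perfect fit leaves only rounding error: residuals are zero
    if s2 <= 1e-24 * max(1.0, float(np.var(y))):
        return pd.Series(np.zeros(n), index=idx)
    student = resid / np.sqrt(s2 * (1 - h))
    return pd.Series(student, index=idx)


def _rank_sum_z(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized two-sample Wilcoxon rank-sum statistic with tie correction."""
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        return 0.0
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w = ranks[:n1].sum()
    N = n1 + n2
    mean = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1)) if N > 1 else 0.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return 0.0
    return float((w - mean) / math.sqrt(var))


def region_wilcoxon(residual_stack: pd.DataFrame, region) -> float:
    """Rank-sum statistic of one region's residuals versus all other regions pooled.

    Residuals for the region are taken across subjects; the comparison sample
    pools every other region's residuals.  Missing values (a region that is an
    epicentre for a subject) are omitted.  All values tied yields 0 (the
    statistic sits at its expectation).
    """
    vals = residual_stack[region].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 5:
        raise InvalidConfigError(f"region {region!r}: fewer than 5 subjects with residuals")
    others = residual_stack.drop(columns=[region]).to_numpy(dtype=float).ravel()
    others = others[np.isfinite(others)]
    return _rank_sum_z(vals, others)


def _signed_rank_z(vals: np.ndarray) -> float:
    """One-sample Wilcoxon signed-rank statistic vs zero, normal approximation."""
    vals = vals[vals != 0]
    n = len(vals)
    if n == 0:
        return 0.0
    ranks = rankdata(np.abs(vals))
    w_pos = ranks[vals > 0].sum()
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    if var <= 0:
        return 0.0
    return float((w_pos - mean) / math.sqrt(var))


def _residual_stack(fc_maps: pd.DataFrame, beta_values: np.ndarray) -> np.ndarray:
    """Vectorized per-subject studentized residuals.

    ``fc_maps`` is subjects x regions with NaN where a region is ineligible for
    that subject; ``beta_values`` is the (possibly permuted) group beta map in
    column order.  Returns the same-shaped residual array (NaN preserved).
    """
    Y = fc_maps.to_numpy(dtype=float)
    x = np.asarray(beta_values, dtype=float)
    M = np.isfinite(Y) & np.isfinite(x)[None, :]
    n = M.sum(axis=1).astype(float)
    Y0 = np.where(M, Y, 0.0)
    X0 = np.where(M, x[None, :], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        xbar = X0.sum(axis=1) / n
        ybar = Y0.sum(axis=1) / n
        xc = np.where(M, x[None, :] - xbar[:, None], 0.0)
        yc = np.where(M, Y - ybar[:, None], 0.0)
        sxx = (xc**2).sum(axis=1)
        slope = (xc * yc).sum(axis=1) / sxx
        resid = yc - slope[:, None] * xc
        h = 1.0 / n[:, None] + xc**2 / sxx[:, None]
        s2 = (resid**2 * M).sum(axis=1) / (n - 2)
        student = resid / np.sqrt(s2[:, None] * (1 - h))
    student[~M] = np.nan
    # numerically perfect fits leave zero residuals everywhere
    var_y = (yc**2 * M).sum(axis=1) / np.maximum(n, 1)
    perfect = np.isfinite(s2) & (s2 <= 1e-24 * np.maximum(1.0, var_y)) & (sxx > 0)
    if perfect.any():
        student[perfect, :] = np.where(M[perfect, :], 0.0, np.nan)
    # subjects with a degenerate regression are dropped from the maps
    bad = ~np.isfinite(s2) | (s2 < 0) | (sxx <= 0) | (n < 10)
    if bad.any():
        student[bad, :] = np.nan
    return student


def _all_region_stats(student: np.ndarray, variant: str) -> np.ndarray:
    """Per-region rank statistics from the studentized residual stack."""
    S, R = student.shape
    if variant == "signed_rank":
        return np.array(
            [_signed_rank_z(student[np.isfinite(student[:, r]), r]) for r in range(R)]
        )
    finite = np.isfinite(student)
    flat = student[finite]
    if flat.size == 0:
        return np.zeros(R)
    ranks = np.empty_like(student)
    ranks[:] = np.nan
    ranks[finite] = rankdata(flat)
    N = flat.size
    _, counts = np.unique(flat, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (N * (N - 1)) if N > 1 else 0.0
    n1 = finite.sum(axis=0).astype(float)
    n2 = N - n1
    w = np.nansum(ranks, axis=0)
    mean = n1 * (N + 1) / 2.0
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (w - mean) / np.sqrt(var)
    return np.where((var > 0) & (n1 > 0), z, 0.0)


def influence_map(
    fc_maps: pd.DataFrame,
    group_beta: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    variant: str = "rank_sum",
    p_method: str = "permutation",
) -> pd.DataFrame:
    """Permutation-calibrated regional influence map.

    ``fc_maps``: subjects x regions FC-to-epicentres values (NaN at a
    subject's own epicentres or excluded parcels).  ``group_beta``: regional
    group-level beta map.  For each of ``n_perm`` iterations the beta map's
    region labels are shuffled once (identically across subjects) and the
    full residual/rank-sum procedure is recomputed.  Regional z-scores report
    the observed statistic standardized against the permutation null.

    Significance defaults to the exact two-sided permutation p-value
    (add-one corrected): the rank-sum permutation null is visibly non-normal
    at cohort scale, so the exact rank is the calibrated choice; the normal
    approximation to z is available via ``p_method='normal'``.

    Returns a DataFrame indexed by region: observed, null_mean, null_sd, z, p,
    significant; n_perm and seed in ``attrs``.
    """
    if variant not in ("rank_sum", "signed_rank"):
        raise InvalidConfigError(f"unknown wilcoxon variant {variant!r}")
    if p_method not in ("permutation", "normal"):
        raise InvalidConfigError(f"unknown p_method {p_method!r}")
    if len(fc_maps) < 10:
        raise InvalidConfigError("influence map requires >= 10 subjects")
    missing = set(fc_maps.columns) - set(group_beta.index)
    if missing:
        raise InvalidConfigError(f"beta map lacks region(s): {sorted(missing)[:5]}")
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: unstable null distribution", n_perm)

    regions = list(fc_maps.columns)
    beta = group_beta[regions].to_numpy(dtype=float)
    observed = _all_region_stats(_residual_stack(fc_maps, beta), variant)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(regions)))
    for i in range(n_perm):
        perm = rng.permutation(len(regions))
        null[i] = _all_region_stats(_residual_stack(fc_maps, beta[perm]), variant)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (observed - null_mean) / null_sd
    z = np.where(null_sd > 0, z, 0.0)
    if p_method == "normal":
        p = 2 * norm.sf(np.abs(z))
    else:
        p_lo = (1 + (null <= observed[None, :]).sum(axis=0)) / (n_perm + 1)
        p_hi = (1 + (null >= observed[None, :]).sum(axis=0)) / (n_perm + 1)
        p = np.minimum(1.0, 2 * np.minimum(p_lo, p_hi))
    out = pd.DataFrame(
        {
            "observed": observed,
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "p": p,
            "significant": p < alpha,
        },
        index=pd.Index(regions, name="region_id"),
    )
    out.attrs["n_perm"] = n_perm
    out.attrs["seed"] = seed
    out.attrs["alpha"] = alpha
    out.attrs["variant"] = variant
    out.attrs["p_method"] = p_method
    return out
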