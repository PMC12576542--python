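"""Connectivity-distance spreading statistics and association models.

The per-subject spreading statistic (the beta-value) is the standardized
regression coefficient of regional tau accumulation rate on connectivity-based
distance to that subject's epicentres, computed across non-epicentre regions.
For a simple regression on standardized variables this equals the Pearson
correlation, so beta lies in [-1, 1]; more negative values mean stronger
connectivity-mediated spreading.  Group-level regional beta maps and the
covariate-adjusted association/interaction models live here too, as does the
FC-to-epicentres metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .exceptions import InvalidConfigError, RankDeficientError
from .fc_preproc import ConnectivityMatrix, DistanceMatrix
from .epicentres import EpicentreSet

logger = logging.getLogger(__name__)


@dataclass
class BetaValue:
    """Per-subject spreading statistic."""

    subject_id: str
    beta: float           # standardized coefficient == Pearson r
    p_value: float
    n_regions_used: int
    undefined: bool = False


@dataclass
class FCEpicentreMetric:
    """Mean Fisher-z FC between a subject's epicentres and the other regions."""

    subject_id: str
    scalar: float
    per_region: pd.Series  # indexed by non-epicentre region


def distance_to_epicentres(
    d: DistanceMatrix,
    e: EpicentreSet,
    aggregate: str = "mean",
) -> pd.Series:
    """Connectivity-based distance of each non-epicentre region to the epicentre set.

    Aggregation over the set members is the arithmetic mean by default; ``min``
    (distance to the nearest epicentre) is available as an alternative.
    """
    if not e.regions:
        raise InvalidConfigError("empty epicentre set")
    labels = list(d.regions)
    missing = set(e.regions) - set(labels)
    if missing:
        raise InvalidConfigError(f"epicentre region(s) not in matrix: {sorted(missing)}")
    idx = {r: i for i, r in enumerate(labels)}
    epi_idx = [idx[r] for r in e.regions]
    non_epi = [r for r in labels if r not in set(e.regions)]
    block = d.d[np.ix_([idx[r] for r in non_epi], epi_idx)]
    if aggregate == "mean":
        vals = block.mean(axis=1)
    elif aggregate == "min":
        vals = block.min(axis=1)
    else:
        raise InvalidConfigError(f"unknown aggregation {aggregate!r}")
    return pd.Series(vals, index=non_epi, name="distance_to_epicentres")


def subject_beta(
    rates: pd.Series,
    dist: pd.Series,
    subject_id: str = "",
) -> BetaValue:
    """Standardized slope of regional tau rate on distance across shared regions.

    Standardizing both vectors makes the simple-regression slope the Pearson
    correlation; its two-sided p-value is recorded.
    """
    shared = rates.index.intersection(dist.index)
    x = dist[shared].to_numpy(dtype=float)
    y = rates[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise InvalidConfigError(f"need >= 10 paired regions, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        logger.warning("subject %s: zero variance, beta undefined", subject_id)
        return BetaValue(subject_id, np.nan, np.nan, len(x), undefined=True)
    r, p = stats.pearsonr(x, y)
    return BetaValue(subject_id, float(r), float(p), int(len(x)))


def group_beta_map(
    rate_map: pd.DataFrame,
    dist: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Regional standardized distance coefficients across subjects.

    Per region: OLS of that region's tau rate on its connectivity-based
    distance (both standardized across subjects) plus covariates.  Regions
    with fewer than 10 contributing subjects or a failed fit are flagged.
    Returns a DataFrame indexed by region with columns beta/se/p/n/failed.
    """
    rows = {}
    regions = [r for r in rate_map.columns if r in dist.columns]
    for region in regions:
        y = rate_map[region]
        x = dist[region]
        shared = y.index.intersection(x.index)
        yv = y[shared].to_numpy(dtype=float)
        xv = x[shared].to_numpy(dtype=float)
        ok = np.isfinite(yv) & np.isfinite(xv)
        C = None
        if covariates is not None:
            C = covariates.loc[shared].to_numpy(dtype=float)
            ok &= np.all(np.isfinite(C), axis=1)
            C = C[ok]
        yv, xv = yv[ok], xv[ok]
        if len(yv) < 10 or yv.std() == 0 or xv.std() == 0:
            rows[region] = dict(beta=np.nan, se=np.nan, p=np.nan, n=int(len(yv)), failed=True)
            continue
        ys = (yv - yv.mean()) / yv.std()
        xs = (xv - xv.mean()) / xv.std()
        X = [np.ones(len(ys)), xs]
        if C is not None:
            sd = C.std(axis=0)
            Cs = (C - C.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
            X.extend(Cs.T)
        X = np.column_stack(X)
        try:
            fit = sm.OLS(ys, X).fit()
            rows[region] = dict(
                beta=float(fit.params[1]),
                se=float(fit.bse[1]),
                p=float(fit.pvalues[1]),
                n=int(len(ys)),
                failed=False,
            )
        except np.linalg.LinAlgError:
            rows[region] = dict(beta=np.nan, se=np.nan, p=np.nan, n=int(len(ys)), failed=True)
    out = pd.DataFrame.from_dict(rows, orient="index").loc[regions]
    out.index.name = "region_id"
    return out


def fc_to_epicentres(fc: ConnectivityMatrix, e: EpicentreSet) -> FCEpicentreMetric:
    """Mean Fisher-z FC between each non-epicentre region and the epicentre set."""
    if not e.regions:
        raise InvalidConfigError("empty epicentre set")
    labels = list(fc.regions)
    missing = set(e.regions) - set(labels)
    if missing:
        raise InvalidConfigError(f"epicentre region(s) not in matrix: {sorted(missing)}")
    idx = {r: i for i, r in enumerate(labels)}
    non_epi = [r for r in labels if r not in set(e.regions)]
    block = fc.z[np.ix_([idx[r] for r in non_epi], [idx[r] for r in e.regions])]
    per_region = pd.Series(block.mean(axis=1), index=non_epi, name="fc_to_epicentres")
    return FCEpicentreMetric(
        subject_id=e.subject_id,
        scalar=float(per_region.mean()),
        per_region=per_region,
    )


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else v - v.mean()


def association_model(
    y: pd.Series,
    x: pd.Series,
    covariates: pd.DataFrame | None = None,
    moderator: pd.Series | None = None,
) -> pd.DataFrame:
    """Covariate-adjusted OLS of y on x, optionally with a binary moderator.

    Continuous variables are standardized so coefficients are standardized
    betas; the moderator enters as a main effect plus an x-by-moderator
    product term.  Inference is two-sided without multiplicity correction.
    Returns a tidy table (term, estimate, se, t, p).
    """
    data = pd.DataFrame({"y": y, "x": x})
    if moderator is not None:
        data["moderator"] = moderator.astype(float)
    cov_names = []
    if covariates is not None:
        for c in covariates.columns:
            data[c] = covariates[c].astype(float)
            cov_names.append(c)
    data = data.dropna()
    n = len(data)
    k_cov = len(cov_names)
    if n < k_cov + 3:
        raise InvalidConfigError(f"n={n} too small for {k_cov} covariates")

    ys = _standardize(data["y"].to_numpy())
    xs = _standardize(data["x"].to_numpy())
    cols = {"const": np.ones(n), "x": xs}
    if moderator is not None:
        mod = data["moderator"].to_numpy()
        cols["moderator"] = mod
        cols["x:moderator"] = xs * mod
    for c in cov_names:
        v = data[c].to_numpy()
        cols[c] = _standardize(v) if len(np.unique(v)) > 2 else v
    all_terms = list(cols.keys())
    X = np.column_stack([cols[t] for t in all_terms])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via pivoted QR diagnostics
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        aliased = [all_terms[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise RankDeficientError(aliased or ["<unidentified>"])
    fit = sm.OLS(ys, X).fit()
    return pd.DataFrame(
        {
            "term": all_terms,
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    ).reset_index(drop=True)
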