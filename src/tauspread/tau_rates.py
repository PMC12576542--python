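"""Annual tau-PET accumulation rates from longitudinal SUVR.

Each region is fitted with a linear mixed-effects model (random intercept and
random slope per subject, unstructured covariance, REML).  A subject's rate is
the fixed slope plus the subject's predicted random slope (BLUP).  When the
mixed model fails to converge, or the random-slope variance collapses, the
region falls back to per-subject ordinary least-squares slopes and is flagged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .exceptions import SchemaError

logger = logging.getLogger(__name__)

#: random-effect variances below this are treated as singular fits
SINGULAR_VARIANCE = 1e-10
MAX_ITER = 200
CONVERGENCE_TOL = 1e-8


@dataclass
class RateMap:
    """Subject x region slopes (SUVR/year) with per-region fit diagnostics."""

    values: pd.DataFrame       # index subject_id, columns region_id
    diagnostics: pd.DataFrame  # index region_id, columns converged / fallback

    @property
    def subjects(self) -> list:
        return list(self.values.index)

    @property
    def regions(self) -> list:
        return list(self.values.columns)


def _ols_slopes(df: pd.DataFrame) -> tuple[pd.Series, float]:
    """Per-subject least-squares slope of suvr on time, plus the largest
    absolute per-subject fit residual (zero when trajectories are exact lines)."""
    out = {}
    max_resid = 0.0
    for sid, grp in df.groupby("subject_id", sort=False):
        t = grp["time_years"].to_numpy(dtype=float)
        y = grp["suvr"].to_numpy(dtype=float)
        if len(t) < 2 or np.ptp(t) == 0:
            out[sid] = np.nan
        else:
            tc = t - t.mean()
            slope = float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
            out[sid] = slope
            resid = y - y.mean() - slope * tc
            max_resid = max(max_resid, float(np.max(np.abs(resid))))
    return pd.Series(out, dtype=float), max_resid


def fit_region_rates(df: pd.DataFrame) -> tuple[pd.Series, dict]:
    """Per-subject slope for one region's longitudinal records.

    ``df`` has columns subject_id, time_years, suvr.  Subjects with fewer than
    two scans are excluded from the fit (NaN slope, logged warning).  Returns
    (slopes indexed by subject_id, diagnostics dict).
    """
    counts = df.groupby("subject_id")["time_years"].count()
    short = counts[counts < 2].index
    if len(short):
        logger.warning("excluding %d subject(s) with <2 scans from region fit", len(short))
    usable = df[~df["subject_id"].isin(short)]
    diag = {"converged": False, "fallback": True}
    ols, max_resid = _ols_slopes(usable)

    n_subjects = usable["subject_id"].nunique()
    scale = max(1.0, float(usable["suvr"].abs().mean()))
    max_scans = int(usable.groupby("subject_id")["time_years"].count().max() or 0)
    if n_subjects < 3:
        slopes = ols
    elif max_scans >= 3 and max_resid < 1e-9 * scale:
        # exact linear trajectories: per-subject least squares is the
        # maximum-likelihood answer and the mixed model adds nothing
        slopes = ols
        diag = {"converged": True, "fallback": False}
    else:
        slopes = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = smf.mixedlm(
                    "suvr ~ time_years",
                    usable,
                    groups=usable["subject_id"],
                    re_formula="~time_years",
                )
                fit = model.fit(
                    reml=True, maxiter=MAX_ITER, method="lbfgs", full_output=False
                )
                cov_re = np.asarray(fit.cov_re)
                # the optimizer's convergence flag is advisory; the fit is only
                # discarded when the variance components actually degenerate
                singular = (
                    not np.all(np.isfinite(fit.fe_params))
                    or not np.all(np.isfinite(cov_re))
                    or np.any(np.diag(cov_re) < SINGULAR_VARIANCE)
                    or fit.scale < SINGULAR_VARIANCE
                )
                if not singular:
                    fixed = float(fit.fe_params["time_years"])
                    re = fit.random_effects
                    slopes = pd.Series(
                        {sid: fixed + float(re[sid]["time_years"]) for sid in re},
                        dtype=float,
                    )
                    diag = {"converged": bool(fit.converged), "fallback": False}
            except (np.linalg.LinAlgError, ValueError):
                slopes = None
        if slopes is None:
            slopes = ols
    for sid in short:
        slopes[sid] = np.nan
    return slopes, diag


def rate_map(scans: pd.DataFrame) -> RateMap:
    """Fit every region independently and assemble the subject x region RateMap."""
    required = {"subject_id", "time_years", "region_id", "suvr"}
    if not required.issubset(scans.columns):
        raise SchemaError(f"tau scans need columns {sorted(required)}")
    regions = list(pd.unique(scans["region_id"]))
    subjects = list(pd.unique(scans["subject_id"]))
    values = pd.DataFrame(index=subjects, columns=regions, dtype=float)
    diag_rows = {}
    for region, grp in scans.groupby("region_id", sort=False):
        slopes, diag = fit_region_rates(grp)
        values.loc[slopes.index, region] = slopes
        diag_rows[region] = diag
    diagnostics = pd.DataFrame.from_dict(diag_rows, orient="index").loc[regions]
    values.index.name = "subject_id"
    return RateMap(values=values, diagnostics=diagnostics)
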