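"""Readers, writers and schema validation for every artifact the pipeline touches.

All tabular and matrix data are delimited text (CSV/TSV): transparent, diffable
and language-neutral.  Matrices carry a header row and an index column of region
labels and are parsed strictly.  Region order is canonicalized to atlas order
once at load; all downstream indexing is 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import SchemaError

COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "education",
    "mmse",
    "apoe4_carrier",
    "abeta_positive",
    "global_amyloid",
    "group",
]

TAU_COLUMNS = ["subject_id", "time_years", "region_id", "suvr"]

SYMMETRY_TOL = 1e-8


@dataclass(frozen=True)
class AtlasSpec:
    """Region labels and optional centroid coordinates (mm).

    Default naming follows the Schaefer 200-parcel convention used for
    whole-cortex tau-PET and FC parcellation.
    """

    labels: tuple[str, ...]
    coordinates: np.ndarray | None = None

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError("atlas labels must be unique")
        if self.coordinates is not None and len(self.coordinates) != len(self.labels):
            raise SchemaError("coordinate count does not match label count")

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise SchemaError(f"region label {label!r} not in atlas") from None


def default_atlas(n_regions: int = 200, coordinates: np.ndarray | None = None) -> AtlasSpec:
    """Schaefer-style atlas with generated labels."""
    width = len(str(n_regions))
    labels = tuple(f"ROI_{i:0{width}d}" for i in range(n_regions))
    return AtlasSpec(labels=labels, coordinates=coordinates)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Subjects with the APOE ε2/ε4 genotype are not representable here; the
    optional ``apoe24`` marker column, if present, must be all-false (such rows
    are rejected because the protective ε2 allele confounds ε4 carrier status).
    """
    _require_columns(df, COHORT_COLUMNS, "cohort table")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise SchemaError(f"cohort table: duplicate subject_id {dup!r}")
    if not df["sex"].isin(["F", "M"]).all():
        bad = df.loc[~df["sex"].isin(["F", "M"]), "sex"].iloc[0]
        raise SchemaError(f"cohort table: sex must be F or M, got {bad!r}")
    mmse = df["mmse"].to_numpy(dtype=float)
    if np.any(~np.isfinite(mmse)) or mmse.min() < 0 or mmse.max() > 30:
        raise SchemaError("cohort table: mmse must be finite and within [0, 30]")
    if not df["group"].isin(["CN", "MCI"]).all():
        bad = df.loc[~df["group"].isin(["CN", "MCI"]), "group"].iloc[0]
        raise SchemaError(f"cohort table: group must be CN or MCI, got {bad!r}")
    for col in ("age", "education", "global_amyloid"):
        vals = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise SchemaError(f"cohort table: non-finite value in column {col!r}")
    if "apoe24" in df.columns and df["apoe24"].astype(bool).any():
        raise SchemaError("cohort table: APOE e2/e4 genotype rows are not accepted")
    df = df.copy()
    df["apoe4_carrier"] = df["apoe4_carrier"].astype(bool)
    df["abeta_positive"] = df["abeta_positive"].astype(bool)
    return df


def load_cohort(path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path, float_precision="round_trip"))


def write_cohort(df: pd.DataFrame, path) -> None:
    validate_cohort(df).to_csv(path, index=False)


def validate_tau_scans(df: pd.DataFrame, atlas: AtlasSpec) -> pd.DataFrame:
    """Validate long-format longitudinal tau-PET records against the atlas."""
    _require_columns(df, TAU_COLUMNS, "tau scan table")
    labels = set(atlas.labels)
    unknown = set(df["region_id"].unique()) - labels
    if unknown:
        raise SchemaError(f"tau scan table: region label(s) not in atlas: {sorted(unknown)[:5]}")
    suvr = df["suvr"].to_numpy(dtype=float)
    if np.any(~np.isfinite(suvr)) or np.any(suvr <= 0):
        raise SchemaError("tau scan table: suvr must be finite and > 0")
    times = df["time_years"].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)) or np.any(times < 0):
        raise SchemaError("tau scan table: time_years must be finite and >= 0")
    n_scans = df.groupby("subject_id")["time_years"].nunique()
    short = n_scans[n_scans < 2]
    if len(short):
        raise SchemaError(
            f"tau scan table: subject(s) with <2 scans: {list(short.index)[:5]}"
        )
    return df


def load_tau_scans(path, atlas: AtlasSpec) -> pd.DataFrame:
    return validate_tau_scans(pd.read_csv(path, float_precision="round_trip"), atlas)


def write_tau_scans(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def validate_matrix(
    df: pd.DataFrame,
    atlas: AtlasSpec | None = None,
    symmetric: bool = True,
    what: str = "matrix",
) -> pd.DataFrame:
    """Validate a labelled square matrix; reorder rows/columns to atlas order."""
    if list(df.index) != list(df.columns):
        raise SchemaError(f"{what}: row and column labels differ")
    if atlas is not None:
        missing = set(atlas.labels) - set(df.index)
        if missing:
            raise SchemaError(f"{what}: atlas label(s) missing: {sorted(missing)[:5]}")
        df = df.loc[list(atlas.labels), list(atlas.labels)]
    values = df.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise SchemaError(f"{what}: non-finite entries")
    if symmetric and np.max(np.abs(values - values.T)) > SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(np.abs(values - values.T)), values.shape)
        raise SchemaError(
            f"{what}: asymmetric beyond {SYMMETRY_TOL:g} at ({df.index[i]}, {df.columns[j]})"
        )
    return df


def load_matrix(path, atlas: AtlasSpec | None = None, what: str = "matrix") -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return validate_matrix(df, atlas=atlas, what=what)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path)


def load_timeseries(values_path, motion_path=None) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Read a frames×regions TSV and optional motion/nuisance TSV."""
    values = pd.read_csv(values_path, sep="\t", float_precision="round_trip")
    if values.isna().any().any():
        raise SchemaError("timeseries: non-finite values")
    motion = None
    if motion_path is not None:
        motion = pd.read_csv(motion_path, sep="\t", float_precision="round_trip")
    return values, motion


def write_timeseries(values: pd.DataFrame, path) -> None:
    values.to_csv(path, sep="\t", index=False)
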