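"""Parcel-level fMRI QC and connectivity construction.

Implements the resting-state processing chain used to build the normative
functional connectome: framewise-displacement scrubbing, detrending,
band-pass filtering and nuisance regression at the parcel level, Fisher-z
connectivity matrices, density thresholding with subject averaging, and the
conversion of the averaged template into connectivity-based distances where
stronger connectivity means a shorter path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import squareform, pdist

from .exceptions import DisconnectedTemplateError, InvalidConfigError, SchemaError

logger = logging.getLogger(__name__)

#: Sphere radius (mm) used to convert rotational displacement to arc length
#: (Power convention); the head is approximated as a 50 mm sphere.
ROTATION_RADIUS_MM = 50.0

#: Correlations are clipped to +/-(1 - FISHER_CLIP) before atanh so that
#: perfectly correlated series map to a large finite Fisher z.
FISHER_CLIP = 1e-6


@dataclass
class ParcelTimeseries:
    """Parcel-averaged BOLD time-series with motion and nuisance regressors."""

    subject_id: str
    values: np.ndarray            # frames x regions
    tr: float                     # seconds
    motion: np.ndarray | None = None    # frames x 6 (3 translations mm, 3 rotations rad)
    nuisance: np.ndarray | None = None  # frames x k (e.g. mean WM, mean CSF)
    regions: tuple[str, ...] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] < 10:
            raise SchemaError("timeseries must be frames x regions with >= 10 frames")
        if not np.all(np.isfinite(self.values)):
            raise SchemaError("timeseries contains non-finite values")
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.values.shape[0], 6):
                raise SchemaError("motion must have exactly 6 columns, one row per frame")
        if self.nuisance is not None:
            self.nuisance = np.asarray(self.nuisance, dtype=float)
            if self.nuisance.shape[0] != self.values.shape[0]:
                raise SchemaError("nuisance rows must match frame count")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class QCRecord:
    """Motion QC summary for one subject."""

    subject_id: str
    fd: np.ndarray                 # per-frame framewise displacement (mm)
    censored_mask: np.ndarray      # True where the frame is scrubbed
    censored_fraction: float
    excluded: bool


@dataclass
class ConnectivityMatrix:
    """Symmetric Fisher-z connectivity matrix with a zero diagonal."""

    regions: tuple[str, ...]
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.regions)
        if self.z.shape != (n, n):
            raise SchemaError("connectivity matrix shape does not match region labels")
        if not np.all(np.isfinite(self.z)):
            raise SchemaError("connectivity matrix has non-finite entries")
        if np.max(np.abs(self.z - self.z.T)) > 1e-10:
            raise SchemaError("connectivity matrix is not symmetric")
        np.fill_diagonal(self.z, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=list(self.regions), columns=list(self.regions))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConnectivityMatrix":
        return cls(regions=tuple(df.index), z=df.to_numpy(dtype=float))


@dataclass
class DistanceMatrix:
    """Connectivity-based distances: symmetric, zero diagonal, positive off-diagonal."""

    regions: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.regions)
        if self.d.shape != (n, n):
            raise SchemaError("distance matrix shape does not match region labels")
        if not np.all(np.isfinite(self.d)):
            raise SchemaError("distance matrix has non-finite entries")
        off = self.d[~np.eye(n, dtype=bool)]
        if n > 1 and np.any(off <= 0):
            raise SchemaError("distance matrix off-diagonal entries must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=list(self.regions), columns=list(self.regions))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(regions=tuple(df.index), d=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Motion QC
# ---------------------------------------------------------------------------

def framewise_displacement(motion: np.ndarray, radius_mm: float = ROTATION_RADIUS_MM) -> np.ndarray:
    """Power's framewise displacement.

    Sum of absolute frame-to-frame changes in the six rigid-body parameters,
    with the three rotations (radians) converted to arc length on a sphere of
    ``radius_mm``.  The first frame has FD 0 by convention.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise SchemaError("motion must be frames x 6")
    if motion.shape[0] < 2:
        raise SchemaError("framewise displacement requires >= 2 frames")
    diffs = np.abs(np.diff(motion, axis=0))
    fd = diffs[:, :3].sum(axis=1) + radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub(
    ts: ParcelTimeseries,
    fd_threshold: float = 1.0,
    max_censored: float = 0.30,
    radius_mm: float = ROTATION_RADIUS_MM,
) -> tuple[QCRecord, np.ndarray]:
    """Censor high-motion frames and flag subjects with too many of them.

    Frames with FD > ``fd_threshold`` (mm) are censored together with the two
    adjacent volumes (one before, one after).  Subjects whose censored
    fraction exceeds ``max_censored`` are marked excluded; an all-censored
    run is an exclusion, not an exception.

    Returns the QC record and the boolean keep-mask (True = frame survives).
    """
    if ts.motion is None:
        raise SchemaError("scrub requires motion parameters")
    fd = framewise_displacement(ts.motion, radius_mm=radius_mm)
    over = fd > fd_threshold
    censored = over.copy()
    censored[:-1] |= over[1:]   # frame before an offending frame
    censored[1:] |= over[:-1]   # frame after
    frac = float(censored.mean())
    record = QCRecord(
        subject_id=ts.subject_id,
        fd=fd,
        censored_mask=censored,
        censored_fraction=frac,
        excluded=frac > max_censored,
    )
    if record.excluded:
        logger.warning(
            "subject %s excluded: %.1f%% of volumes censored", ts.subject_id, 100 * frac
        )
    return record, ~censored


# ---------------------------------------------------------------------------
# Time-series cleaning
# ---------------------------------------------------------------------------

def _bandpass_segments(values: np.ndarray, keep: np.ndarray, tr: float, band) -> tuple[np.ndarray, np.ndarray]:
    """Band-pass contiguous surviving segments with a 2nd-order Butterworth,
    applied forward-backward.  Segments too short for stable filtering are
    dropped.  Returns (filtered frames, their original indices)."""
    low, high = band
    nyquist = 0.5 / tr
    sos = signal.butter(2, [low / nyquist, high / nyquist], btype="bandpass", output="sos")
    # forward-backward padding needs some run-in; drop segments shorter than this
    min_len = 24
    out_blocks, idx_blocks = [], []
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        return np.empty((0, values.shape[1])), np.empty(0, dtype=int)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, breaks + 1)
    for seg in segments:
        if len(seg) < min_len:
            continue
        filtered = signal.sosfiltfilt(sos, values[seg], axis=0)
        out_blocks.append(filtered)
        idx_blocks.append(seg)
    if not out_blocks:
        return np.empty((0, values.shape[1])), np.empty(0, dtype=int)
    return np.vstack(out_blocks), np.concatenate(idx_blocks)


def clean_timeseries(
    ts: ParcelTimeseries,
    keep_mask: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.08),
    bandpass: bool = True,
) -> ParcelTimeseries:
    """Detrend, regress out nuisance covariates, and band-pass filter.

    Order per region: linear detrend -> regression of motion + nuisance
    columns (themselves detrended) -> band-pass (0.01-0.08 Hz default) on the
    surviving frames, segment-wise across censoring gaps.  Output is zero
    mean per region.
    """
    if ts.tr <= 0:
        raise InvalidConfigError("tr must be positive")
    nyquist = 0.5 / ts.tr
    if bandpass and band[1] >= nyquist:
        raise InvalidConfigError(
            f"band upper edge {band[1]} Hz >= Nyquist {nyquist:.4f} Hz for tr={ts.tr}"
        )
    if keep_mask is None:
        keep_mask = np.ones(ts.n_frames, dtype=bool)
    keep_mask = np.asarray(keep_mask, dtype=bool)
    kept = np.flatnonzero(keep_mask)
    values = ts.values[kept]

    values = signal.detrend(values, axis=0, type="linear")
    regressors = []
    for block in (ts.motion, ts.nuisance):
        if block is not None:
            regressors.append(signal.detrend(block[kept], axis=0, type="linear"))
    if regressors:
        X = np.column_stack([np.ones(len(kept))] + regressors)
        beta, *_ = np.linalg.lstsq(X, values, rcond=None)
        values = values - X @ beta

    if bandpass:
        full = np.zeros((ts.n_frames, ts.n_regions))
        full[kept] = values
        filtered, surviving = _bandpass_segments(full, keep_mask, ts.tr, band)
        values = filtered
    values = values - values.mean(axis=0, keepdims=True) if len(values) else values
    return ParcelTimeseries(
        subject_id=ts.subject_id, values=values, tr=ts.tr, regions=ts.regions
    )


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def fisher_z(r: np.ndarray) -> np.ndarray:
    """Fisher z-transform with clipping of |r| to 1 - 1e-6."""
    return np.arctanh(np.clip(r, -1 + FISHER_CLIP, 1 - FISHER_CLIP))


def connectivity_matrix(
    ts: ParcelTimeseries,
    method: str = "full",
    ridge_factor: float = 0.1,
) -> ConnectivityMatrix:
    """Fisher-z connectivity from cleaned parcel time-series.

    ``full`` is the pairwise Pearson correlation; ``partial`` derives partial
    correlations from the ridge-regularized inverse covariance (ridge =
    ``ridge_factor`` x mean diagonal of the covariance).  Zero-variance
    regions get zero edges with a logged warning.
    """
    values = ts.values
    n_frames, n_regions = values.shape
    if method not in ("full", "partial"):
        raise InvalidConfigError(f"unknown connectivity method {method!r}")
    if method == "full" and n_frames < 10:
        raise SchemaError("full correlation requires >= 10 frames")
    if method == "partial" and n_frames <= n_regions:
        raise SchemaError("partial correlation requires frames > regions")

    sd = values.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "%d zero-variance region(s); their edges set to 0", int(degenerate.sum())
        )
    safe = values.copy()
    safe[:, degenerate] = np.random.default_rng(0).standard_normal((n_frames, degenerate.sum()))

    if method == "full":
        r = np.corrcoef(safe, rowvar=False)
    else:
        cov = np.cov(safe, rowvar=False)
        cov = cov + ridge_factor * np.mean(np.diag(cov)) * np.eye(n_regions)
        prec = np.linalg.inv(cov)
        dd = np.sqrt(np.diag(prec))
        r = -prec / np.outer(dd, dd)
    r = (r + r.T) / 2
    np.fill_diagonal(r, 0.0)
    r[degenerate, :] = 0.0
    r[:, degenerate] = 0.0
    z = fisher_z(r)
    regions = ts.regions or tuple(f"ROI_{i:03d}" for i in range(n_regions))
    return ConnectivityMatrix(regions=tuple(regions), z=z)


def threshold_density(z: np.ndarray, density: float) -> np.ndarray:
    """Keep the round(density * P) strongest positive off-diagonal edges.

    P is the number of unordered region pairs.  Negative edges are zeroed
    first (path lengths require nonnegative weights; the template retains the
    strongest connections only).
    """
    if not 0 < density <= 1:
        raise InvalidConfigError(f"density must be in (0, 1], got {density}")
    n = z.shape[0]
    upper = z[np.triu_indices(n, k=1)].copy()
    upper[upper < 0] = 0.0
    k = int(round(density * len(upper)))
    if k < len(upper):
        order = np.argsort(upper, kind="stable")[::-1]
        cut = np.zeros_like(upper, dtype=bool)
        cut[order[:k]] = True
        upper = np.where(cut, upper, 0.0)
    out = np.zeros_like(z)
    out[np.triu_indices(n, k=1)] = upper
    return out + out.T


def normative_template(
    matrices: list[ConnectivityMatrix], density: float = 0.30
) -> ConnectivityMatrix:
    """Average of per-subject matrices thresholded at the given density."""
    if not matrices:
        raise InvalidConfigError("need at least one connectivity matrix")
    regions = matrices[0].regions
    for m in matrices[1:]:
        if m.regions != regions:
            raise SchemaError("connectivity matrices have differing region sets")
    stack = np.stack([threshold_density(m.z, density) for m in matrices])
    return ConnectivityMatrix(regions=regions, z=stack.mean(axis=0))


def to_distance(
    template: ConnectivityMatrix,
    method: str = "shortest_path",
    coordinates: np.ndarray | None = None,
) -> DistanceMatrix:
    """Convert the template into connectivity-based distances.

    ``shortest_path``: edge length 1/weight on nonzero edges, all-pairs
    weighted shortest paths (Dijkstra); a disconnected template raises.
    ``euclidean``: pairwise distance of supplied region coordinates.
    """
    if method == "euclidean":
        if coordinates is None:
            raise InvalidConfigError("euclidean distances require region coordinates")
        d = squareform(pdist(np.asarray(coordinates, dtype=float)))
        return DistanceMatrix(regions=template.regions, d=d)
    if method != "shortest_path":
        raise InvalidConfigError(f"unknown distance method {method!r}")
    w = template.z
    if np.any(w < 0):
        raise InvalidConfigError("shortest-path conversion requires nonnegative weights")
    n = w.shape[0]
    if n == 1:
        return DistanceMatrix(regions=template.regions, d=np.zeros((1, 1)))
    n_comp, labels = connected_components((w > 0).astype(int), directed=False)
    if n_comp > 1:
        comps = [
            [template.regions[i] for i in np.flatnonzero(labels == c)]
            for c in range(n_comp)
        ]
        raise DisconnectedTemplateError(comps)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = shortest_path(lengths, method="D", directed=False)
    return DistanceMatrix(regions=template.regions, d=d)
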