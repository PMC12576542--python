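"""Forward simulator for cohorts with planted connectivity-mediated tau spreading.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage is testable without any imaging download:

* a modular weighted connectome standing in for the normative functional
  template, with 3-D region coordinates;
* bimodal baseline tau-PET SUVR per region (non-specific vs specific binding),
  with each subject's epicentre set drawn as a medial-temporal-like archetype
  plus small jitter;
* longitudinal tau accumulation seeded at the epicentres:
  rate(s, r) = a_s * exp(-lambda * dist(r, E_s)) + noise, where the coupling
  a_s is raised by APOE e4 carriage and amyloid positivity (mediation chain:
  APOE drawn first, Abeta from a logistic model in APOE, coupling from both);
* subject FC matrices equal to the template plus noise, with
  epicentre<->non-epicentre cells depressed in proportion to a_s
  (tau-dependent functional disconnection);
* covariates (age, sex, education, MMSE) and a Centiloid-like global amyloid
  burden.

A separate triplet generator plants (X, M, Y) mediation structure with a
known ACME, together with a brute-force Monte-Carlo oracle.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .exceptions import InvalidConfigError
from .fc_preproc import ConnectivityMatrix, to_distance
from .io_formats import (
    AtlasSpec,
    default_atlas,
    write_cohort,
    write_matrix,
    write_tau_scans,
)


def _sigmoid(eta):
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Cohort-level quantities mirror the demographics of an elderly
    amyloid/tau-PET sample (ages ~69 +/- 6, 40% APOE e4 carriers, ~55%
    amyloid-positive, 2-4 tau-PET scans over up to four years).
    """

    n_regions: int = 200
    n_modules: int = 7
    n_subjects: int = 200
    n_template_subjects: int = 69
    # tau-PET scan schedule: nominal visit years; each subject gets a scan
    # count drawn uniformly from [min_scans, max_scans] (2-4 per protocol)
    scan_times: tuple = (0.0, 1.0, 2.0, 3.0)
    min_scans: int = 2
    max_scans: int = 4
    scan_time_jitter: float = 0.25       # uniform +/- years around nominal visits
    # baseline SUVR mixture (non-specific low mode vs specific high mode)
    baseline_low_mean: float = 1.2
    baseline_low_sd: float = 0.05
    baseline_high_delta: float = 0.6
    background_high_prob: float = 0.15   # non-specific elevated binding anywhere
    background_high_factor: float = 0.7  # its amplitude relative to epicentre delta
    # spreading: rate = coupling * exp(-lambda * distance-to-epicentres) + noise
    spread_base: float = 0.005           # SUVR/year
    spread_apoe_effect: float = 0.02     # SUVR/year increment for e4 carriers
    spread_abeta_effect: float = 0.03    # SUVR/year increment for Abeta+
    coupling_noise_sd: float = 0.008     # SUVR/year, subject-level
    decay_lambda: float = 0.15           # per connectivity-distance unit
    rate_noise_sd: float = 0.002         # SUVR/year, region-level
    suvr_noise_sd: float = 0.005         # per-scan measurement noise
    # FC: subject matrix = template + noise - gain * coupling on epi<->non-epi cells
    fc_noise_sd: float = 0.05            # Fisher-z units
    disconnection_gain: float = 1.0      # Fisher-z per (SUVR/year) coupling
    # mediation chain
    apoe_prevalence: float = 0.40
    abeta_logit_intercept: float = -0.5
    abeta_apoe_coef: float = 1.5
    # covariates
    age_mean: float = 68.8
    age_sd: float = 6.2
    education_mean: float = 16.3
    education_sd: float = 2.5
    mmse_mean: float = 28.5
    mmse_sd: float = 1.2
    female_prob: float = 0.57
    mci_prob: float = 0.35
    # epicentres
    k_epicentres: int = 10
    epicentre_swap_prob: float = 0.2
    # optional raw time-series emission (exercises the QC stage)
    emit_timeseries: bool = False
    n_frames: int = 240
    tr: float = 3.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        if self.n_regions < 10:
            raise InvalidConfigError("n_regions must be >= 10")
        if self.n_modules < 1 or self.n_modules > self.n_regions:
            raise InvalidConfigError("n_modules must be in [1, n_regions]")
        for name in (
            "baseline_low_sd", "coupling_noise_sd", "rate_noise_sd",
            "suvr_noise_sd", "fc_noise_sd", "age_sd", "education_sd", "mmse_sd",
        ):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        for name in (
            "apoe_prevalence", "female_prob", "mci_prob",
            "background_high_prob", "epicentre_swap_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{name} must be in [0, 1]")
        if not 2 <= len(self.scan_times) or not all(0 <= t <= 4 for t in self.scan_times):
            raise InvalidConfigError("scan_times must be >= 2 visits within [0, 4] years")
        if not (2 <= self.min_scans <= self.max_scans <= 4):
            raise InvalidConfigError("scan counts must satisfy 2 <= min <= max <= 4")
        if self.max_scans > len(self.scan_times):
            raise InvalidConfigError("max_scans exceeds the number of nominal visits")
        if 2 * self.k_epicentres > self.n_regions:
            raise InvalidConfigError("n_regions must be >= 2 * k_epicentres")
        return self


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests."""

    true_epicentres: dict          # subject_id -> list of region labels
    true_rates: pd.DataFrame       # subjects x regions, SUVR/year
    true_spread_coupling: pd.Series
    true_acme: float | None = None


@dataclass
class SimCohort:
    """Everything the downstream pipeline consumes, plus the planted truth."""

    cohort: pd.DataFrame
    scans: pd.DataFrame
    fc: dict                        # subject_id -> ConnectivityMatrix
    template: ConnectivityMatrix    # noise-free template connectome
    coordinates: np.ndarray
    atlas: AtlasSpec
    truth: SimTruth
    timeseries: dict | None = None  # subject_id -> dict(values, motion, nuisance, tr)


def simulate_connectome(
    n_regions: int,
    n_modules: int,
    seed: int,
    length_scale: float = 40.0,
    between_damp: float = 0.6,
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially embedded modular weight matrix in [0, 1] plus 3-D coordinates.

    Modules sit on a ring (radius 60 mm) with regions scattered around their
    module centre; edge weight decays exponentially with Euclidean distance
    (``length_scale`` mm) and between-module edges are damped by
    ``between_damp``, so within-module mean weight exceeds between-module mean
    weight while connectivity-based distances vary smoothly across the cortex
    (near modules are reachable in few strong hops, far modules in many).
    """
    if n_regions < 1 or n_modules < 1:
        raise InvalidConfigError("n_regions and n_modules must be >= 1")
    if n_modules > n_regions:
        raise InvalidConfigError("n_modules may not exceed n_regions")
    rng = np.random.default_rng(seed)
    assignment = module_assignment(n_regions, n_modules)
    angles = 2 * np.pi * np.arange(n_modules) / n_modules
    centers = np.column_stack(
        [60 * np.cos(angles), 60 * np.sin(angles), rng.uniform(-20, 20, n_modules)]
    )
    coords = centers[assignment] + rng.normal(0, 8.0, size=(n_regions, 3))
    if n_regions == 1:
        return np.zeros((1, 1)), coords
    e = squareform(pdist(coords))
    w = np.exp(-e / length_scale)
    same = assignment[:, None] == assignment[None, :]
    w = w * np.where(same, 1.0, between_damp)
    w = w * rng.uniform(0.85, 1.15, size=(n_regions, n_regions))
    w = np.clip((w + w.T) / 2, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return w, coords


def module_assignment(n_regions: int, n_modules: int) -> np.ndarray:
    return (np.arange(n_regions) * n_modules) // n_regions


def _epicentre_pool(dist: np.ndarray, assignment: np.ndarray, k: int) -> tuple[list, list]:
    """Archetype (top-k) and candidate pool (2k) regions nearest the
    designated 'medial temporal' module (module 0)."""
    core = np.flatnonzero(assignment == 0)
    mean_d = dist[:, core].mean(axis=1)
    order = np.argsort(mean_d, kind="stable")
    pool = list(order[: 2 * k])
    archetype = pool[:k]
    return archetype, pool


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate a full synthetic cohort with planted structure (see module docstring)."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ["graph", "cohort", "epicentres", "baseline", "scans", "fc", "timeseries"],
            ss.spawn(7),
        )
    }
    n, k = config.n_regions, config.k_epicentres
    w, coords = simulate_connectome(n, config.n_modules, seed=config.seed)
    atlas = default_atlas(n, coordinates=coords)
    labels = list(atlas.labels)
    template = ConnectivityMatrix(regions=atlas.labels, z=w)
    dist = to_distance(template).d
    assignment = module_assignment(n, config.n_modules)
    archetype, pool = _epicentre_pool(dist, assignment, k)

    rng = rngs["cohort"]
    S = config.n_subjects
    subject_ids = [f"sub-{i:04d}" for i in range(S)]
    apoe = rng.random(S) < config.apoe_prevalence
    p_abeta = _sigmoid(config.abeta_logit_intercept + config.abeta_apoe_coef * apoe)
    abeta = rng.random(S) < p_abeta
    coupling = (
        config.spread_base
        + config.spread_apoe_effect * apoe
        + config.spread_abeta_effect * abeta
        + rng.normal(0, config.coupling_noise_sd, S)
    )
    coupling = np.maximum(coupling, 0.0)

    age = rng.normal(config.age_mean, config.age_sd, S)
    sex = np.where(rng.random(S) < config.female_prob, "F", "M")
    education = np.clip(rng.normal(config.education_mean, config.education_sd, S), 8, 24)
    mmse = np.clip(np.round(rng.normal(config.mmse_mean, config.mmse_sd, S)), 0, 30)
    group = np.where(rng.random(S) < config.mci_prob, "MCI", "CN")
    amyloid = np.where(
        abeta, rng.normal(75, 20, S), rng.normal(18, 10, S)
    )
    amyloid = np.maximum(amyloid, 1.0)

    # per-subject epicentre sets: archetype with jittered swaps within the pool
    erng = rngs["epicentres"]
    non_archetype = [r for r in pool if r not in archetype]
    epicentres: dict[str, list] = {}
    for sid in subject_ids:
        members = list(archetype)
        swaps = np.flatnonzero(erng.random(k) < config.epicentre_swap_prob)
        if len(swaps):
            repl = erng.choice(non_archetype, size=min(len(swaps), len(non_archetype)),
                               replace=False)
            for slot, r in zip(swaps, repl):
                members[slot] = int(r)
        epicentres[sid] = [labels[r] for r in members]

    # planted rates: coupling * exp(-lambda * mean distance to the epicentre set)
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    true_rates = np.empty((S, n))
    dbar = np.empty((S, n))
    for i, sid in enumerate(subject_ids):
        e_idx = [lab_idx[r] for r in epicentres[sid]]
        dbar[i] = dist[:, e_idx].mean(axis=1)
        true_rates[i] = coupling[i] * np.exp(-config.decay_lambda * dbar[i])
    true_rates = true_rates + rngs["scans"].normal(0, config.rate_noise_sd, (S, n))

    # baseline SUVR: low mode everywhere, high mode at epicentres, occasional
    # non-specific elevated binding elsewhere
    brng = rngs["baseline"]
    baseline = config.baseline_low_mean + brng.normal(0, config.baseline_low_sd, (S, n))
    bg = brng.random((S, n)) < config.background_high_prob
    baseline = baseline + bg * config.background_high_factor * config.baseline_high_delta
    for i, sid in enumerate(subject_ids):
        e_idx = [lab_idx[r] for r in epicentres[sid]]
        baseline[i, e_idx] = (
            config.baseline_low_mean
            + config.baseline_high_delta
            + brng.normal(0, config.baseline_low_sd, len(e_idx))
        )

    # longitudinal scans
    srng = rngs["scans"]
    records = []
    nominal = np.asarray(config.scan_times, dtype=float)
    for i, sid in enumerate(subject_ids):
        n_scans = int(srng.integers(config.min_scans, config.max_scans + 1))
        times = nominal[:n_scans].copy()
        if config.scan_time_jitter > 0 and n_scans > 1:
            times[1:] += srng.uniform(
                -config.scan_time_jitter, config.scan_time_jitter, n_scans - 1
            )
        times = np.maximum(times, 0.0)
        for t in times:
            suvr = (
                baseline[i]
                + true_rates[i] * t
                + srng.normal(0, config.suvr_noise_sd, n)
            )
            suvr = np.maximum(suvr, 1e-6)
            records.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "time_years": round(float(t), 6),
                        "region_id": labels,
                        "suvr": suvr,
                    }
                )
            )
    scans = pd.concat(records, ignore_index=True)

    # subject FC: template + noise, epicentre<->non-epicentre cells depressed
    frng = rngs["fc"]
    fc: dict[str, ConnectivityMatrix] = {}
    for i, sid in enumerate(subject_ids):
        noise = frng.normal(0, config.fc_noise_sd, (n, n))
        z = w + (noise + noise.T) / math.sqrt(2.0)
        e_idx = np.array([lab_idx[r] for r in epicentres[sid]])
        mask = np.zeros(n, dtype=bool)
        mask[e_idx] = True
        drop = config.disconnection_gain * coupling[i]
        z[np.ix_(mask, ~mask)] -= drop
        z[np.ix_(~mask, mask)] -= drop
        np.fill_diagonal(z, 0.0)
        fc[sid] = ConnectivityMatrix(regions=atlas.labels, z=z)

    timeseries = None
    if config.emit_timeseries:
        timeseries = {
            sid: generate_timeseries(
                fc[sid].z, config.n_frames, config.tr, rngs["timeseries"]
            )
            for sid in subject_ids
        }

    cohort = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": np.round(age, 1),
            "sex": sex,
            "education": np.round(education, 1),
            "mmse": mmse,
            "apoe4_carrier": apoe,
            "abeta_positive": abeta,
            "global_amyloid": np.round(amyloid, 2),
            "group": group,
        }
    )
    truth = SimTruth(
        true_epicentres=epicentres,
        true_rates=pd.DataFrame(true_rates, index=subject_ids, columns=labels),
        true_spread_coupling=pd.Series(coupling, index=subject_ids, name="coupling"),
    )
    return SimCohort(
        cohort=cohort,
        scans=scans,
        fc=fc,
        template=template,
        coordinates=coords,
        atlas=atlas,
        truth=truth,
        timeseries=timeseries,
    )


def simulate_template_matrices(config: SimConfig, seed: int | None = None) -> list[ConnectivityMatrix]:
    """Healthy-reference FC matrices (template + noise, no disconnection),
    used to build the normative template the way the real analysis does."""
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    w, _ = simulate_connectome(config.n_regions, config.n_modules, seed=config.seed)
    atlas = default_atlas(config.n_regions)
    out = []
    for _ in range(config.n_template_subjects):
        noise = rng.normal(0, config.fc_noise_sd, w.shape)
        z = w + (noise + noise.T) / math.sqrt(2.0)
        np.fill_diagonal(z, 0.0)
        out.append(ConnectivityMatrix(regions=atlas.labels, z=z))
    return out


def generate_timeseries(z: np.ndarray, n_frames: int, tr: float, rng) -> dict:
    """Parcel time-series whose correlation structure approximates tanh(z),
    plus rigid-body motion traces (with occasional spikes) and two nuisance
    regressors, so the QC/cleaning stage can be exercised."""
    n = z.shape[0]
    r = np.tanh(z)
    np.fill_diagonal(r, 1.0)
    vals, vecs = np.linalg.eigh(r)
    vals = np.maximum(vals, 1e-4)
    L = vecs * np.sqrt(vals)
    values = rng.standard_normal((n_frames, n)) @ L.T
    # slow drift: translations in mm, rotations in radians (50 mm arm means
    # rotation steps must be ~100x smaller for comparable displacement)
    motion = np.cumsum(
        rng.normal(0, 1, (n_frames, 6)) * np.array([0.01] * 3 + [1e-4] * 3),
        axis=0,
    )
    spikes = rng.random(n_frames) < 0.02
    motion[spikes, 0] += rng.uniform(1.0, 2.0, spikes.sum())
    nuisance = rng.standard_normal((n_frames, 2))
    return {"values": values, "motion": motion, "nuisance": nuisance, "tr": tr}


# ---------------------------------------------------------------------------
# Mediation triplets with known ACME
# ---------------------------------------------------------------------------

@dataclass
class MediationParams:
    """Generative parameters for (X, M, Y) triplets.

    M ~ Bernoulli(logistic(alpha0 + alpha_x * X + alpha_c . C));
    Y = theta0 + theta_x * X + theta_m * M + theta_c . C + N(0, noise_sd).
    """

    alpha0: float = -0.5
    alpha_x: float = 1.0
    alpha_c: tuple = ()
    theta0: float = 0.0
    theta_x: float = 0.2
    theta_m: float = 0.3
    theta_c: tuple = ()
    noise_sd: float = 1.0

    def validate(self) -> "MediationParams":
        flat = [self.alpha0, self.alpha_x, self.theta0, self.theta_x, self.theta_m,
                self.noise_sd, *self.alpha_c, *self.theta_c]
        if not all(math.isfinite(v) for v in flat):
            raise InvalidConfigError("mediation parameters must be finite")
        if len(self.alpha_c) != len(self.theta_c):
            raise InvalidConfigError("alpha_c and theta_c must have equal length")
        return self

    @property
    def n_covariates(self) -> int:
        return len(self.alpha_c)


def closed_form_acme(params: MediationParams, x0: float = 0.0, x1: float = 1.0) -> float:
    """Exact ACME for the no-covariate case:
    theta_m * (logistic(alpha0 + alpha_x*x1) - logistic(alpha0 + alpha_x*x0))."""
    if params.n_covariates:
        raise InvalidConfigError("closed form only available without covariates")
    return float(
        params.theta_m
        * (_sigmoid(params.alpha0 + params.alpha_x * x1)
           - _sigmoid(params.alpha0 + params.alpha_x * x0))
    )


def simulate_mediation_triplets(
    n: int, params: MediationParams, seed: int
) -> tuple[pd.DataFrame, float]:
    """Draw n triplets (X, M, Y, C...) and return them with the true ACME
    for the default contrast x0=0 -> x1=1."""
    params.validate()
    if n < 10:
        raise InvalidConfigError("n must be >= 10")
    rng = np.random.default_rng(seed)
    k = params.n_covariates
    x = rng.standard_normal(n)
    C = rng.standard_normal((n, k)) if k else np.zeros((n, 0))
    eta = params.alpha0 + params.alpha_x * x + C @ np.asarray(params.alpha_c)
    m = (rng.random(n) < _sigmoid(eta)).astype(float)
    y = (
        params.theta0
        + params.theta_x * x
        + params.theta_m * m
        + C @ np.asarray(params.theta_c)
        + rng.normal(0, params.noise_sd, n)
    )
    df = pd.DataFrame({"x": x, "m": m, "y": y})
    for j in range(k):
        df[f"c{j}"] = C[:, j]
    if params.theta_m == 0 or params.alpha_x == 0:
        true_acme = 0.0
    elif k == 0:
        true_acme = closed_form_acme(params)
    else:
        true_acme, _ = true_acme_oracle(params, 0.0, 1.0, n_mc=200_000, seed=seed + 1)
    return df, true_acme


def true_acme_oracle(
    params: MediationParams, x0: float, x1: float, n_mc: int, seed: int
) -> tuple[float, float]:
    """Brute-force Monte-Carlo ACME under the potential-outcomes definition.

    Draws covariates and the two potential mediators M(x0), M(x1), then
    averages Y(x, M(x1)) - Y(x, M(x0)) with independent outcome noise.
    Returns (estimate, standard error).
    """
    params.validate()
    if n_mc < 10_000:
        raise InvalidConfigError("oracle requires n_mc >= 10^4")
    rng = np.random.default_rng(seed)
    k = params.n_covariates
    C = rng.standard_normal((n_mc, k)) if k else np.zeros((n_mc, 0))
    base = params.alpha0 + C @ np.asarray(params.alpha_c)
    m1 = (rng.random(n_mc) < _sigmoid(base + params.alpha_x * x1)).astype(float)
    m0 = (rng.random(n_mc) < _sigmoid(base + params.alpha_x * x0)).astype(float)
    x = x1  # no exposure-mediator interaction: the ACME is the same at any x

    def outcome(m, noise):
        return (
            params.theta0
            + params.theta_x * x
            + params.theta_m * m
            + C @ np.asarray(params.theta_c)
            + noise
        )

    diff = outcome(m1, rng.normal(0, params.noise_sd, n_mc)) - outcome(
        m0, rng.normal(0, params.noise_sd, n_mc)
    )
    return float(diff.mean()), float(diff.std(ddof=1) / math.sqrt(n_mc))


# ---------------------------------------------------------------------------
# On-disk bundle
# ---------------------------------------------------------------------------

def write_cohort_bundle(sim: SimCohort, outdir) -> dict:
    """Write cohort CSV, long-format tau CSV, per-subject FC matrices and the
    planted truth (JSON) under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    (outdir / "fc").mkdir(parents=True, exist_ok=True)
    write_cohort(sim.cohort, outdir / "cohort.csv")
    write_tau_scans(sim.scans, outdir / "tau_long.csv")
    for sid, mat in sim.fc.items():
        write_matrix(mat.to_frame(), outdir / "fc" / f"{sid}.csv")
    write_matrix(sim.template.to_frame(), outdir / "template_true.csv")
    truth = {
        "true_epicentres": sim.truth.true_epicentres,
        "true_spread_coupling": sim.truth.true_spread_coupling.to_dict(),
        "true_acme": sim.truth.true_acme,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    sim.truth.true_rates.to_csv(outdir / "true_rates.csv")
    manifest = {
        "n_subjects": int(len(sim.cohort)),
        "n_regions": int(sim.atlas.n_regions),
        "files": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
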