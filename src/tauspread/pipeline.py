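"""End-to-end orchestration: simulate -> QC/FC -> rates -> epicentres ->
template/distance -> spreading statistics -> association models -> mediation
-> influence maps, with one config and per-stage sub-seeds derived from a
master seed.  Every results bundle carries a manifest (config echo, seeds,
content hashes) sufficient to reproduce it exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    epicentres as epi,
    fc_preproc as fcp,
    influence_maps as inf,
    io_formats as iof,
    mediation as med,
    spreading as spr,
    tau_rates,
)
from .exceptions import InvalidConfigError
from .synthetic_cohort import (
    SimCohort,
    SimConfig,
    simulate_cohort,
    simulate_template_matrices,
    write_cohort_bundle,
)

logger = logging.getLogger(__name__)

STAGES = [
    "simulate", "qc", "rates", "epicentres", "template",
    "spread", "mediate", "influence",
]


@dataclass
class PipelineConfig:
    """Stage parameters for a full run.  Defaults are the study conditions."""

    outdir: str = "results"
    simulate: bool = True
    input_dir: str | None = None
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    k_epicentres: int = 10
    group_top_frac: float = 0.05
    density: float = 0.30
    fd_threshold: float = 1.0      # mm
    max_censored: float = 0.30
    band: tuple = (0.01, 0.08)     # Hz
    n_boot: int = 1000
    n_perm: int = 1000
    alpha: float = 0.05
    distance_method: str = "shortest_path"
    distance_aggregate: str = "mean"
    wilcoxon_variant: str = "rank_sum"
    mediation_contrast: tuple = (0.0, 1.0)
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not 0 < self.density <= 1:
            raise InvalidConfigError("density must be in (0, 1]")
        if not 0 < self.group_top_frac <= 1:
            raise InvalidConfigError("group_top_frac must be in (0, 1]")
        if not 0 < self.max_censored <= 1:
            raise InvalidConfigError("max_censored must be in (0, 1]")
        if self.fd_threshold <= 0:
            raise InvalidConfigError("fd_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise InvalidConfigError("alpha must be in (0, 1)")
        if self.n_boot < 1 or self.n_perm < 1:
            raise InvalidConfigError("n_boot and n_perm must be >= 1")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for tup in ("band", "mediation_contrast"):
            setattr(cfg, tup, tuple(getattr(cfg, tup)))
        return cfg.validate()

    def sim_config(self) -> SimConfig:
        known = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(self.sim) - known
        if unknown:
            raise InvalidConfigError(f"unknown sim key(s): {sorted(unknown)}")
        kwargs = dict(self.sim)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("k_epicentres", self.k_epicentres)
        return SimConfig(**kwargs).validate()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _covariate_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    cov = pd.DataFrame(index=cohort["subject_id"])
    cov["age"] = cohort.set_index("subject_id")["age"].astype(float)
    cov["sex"] = (cohort.set_index("subject_id")["sex"] == "F").astype(float)
    cov["mmse"] = cohort.set_index("subject_id")["mmse"].astype(float)
    cov["education"] = cohort.set_index("subject_id")["education"].astype(float)
    return cov


def _baseline_matrix(scans: pd.DataFrame) -> pd.DataFrame:
    """Per-subject baseline (earliest-scan) SUVR matrix, subjects x regions."""
    first = scans.loc[scans.groupby("subject_id")["time_years"].transform("min")
                      == scans["time_years"]]
    return first.pivot_table(index="subject_id", columns="region_id", values="suvr")


def _load_inputs(config: PipelineConfig) -> SimCohort:
    if config.input_dir is None:
        raise InvalidConfigError("simulate=false requires input_dir")
    root = Path(config.input_dir)
    for required in ("cohort.csv", "tau_long.csv", "fc", "template_true.csv"):
        if not (root / required).exists():
            raise InvalidConfigError(f"missing input: {root / required}")
    template = fcp.ConnectivityMatrix.from_frame(
        iof.load_matrix(root / "template_true.csv", what="template")
    )
    atlas = iof.AtlasSpec(labels=template.regions)
    cohort = iof.load_cohort(root / "cohort.csv")
    scans = iof.load_tau_scans(root / "tau_long.csv", atlas)
    fc = {
        p.stem: fcp.ConnectivityMatrix.from_frame(iof.load_matrix(p, atlas=atlas))
        for p in sorted((root / "fc").glob("*.csv"))
    }
    from .synthetic_cohort import SimTruth

    truth = SimTruth(
        true_epicentres={},
        true_rates=pd.DataFrame(),
        true_spread_coupling=pd.Series(dtype=float),
    )
    return SimCohort(
        cohort=cohort, scans=scans, fc=fc, template=template,
        coordinates=None, atlas=atlas, truth=truth,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the results bundle; returns the manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(STAGES, ss.spawn(len(STAGES)))
    }

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim_cfg = config.sim_config()
        sim = simulate_cohort(sim_cfg)
        write_cohort_bundle(sim, out / "inputs")
        template_mats = simulate_template_matrices(sim_cfg, seed=stage_seeds["template"])
    else:
        sim = _load_inputs(config)
        template_mats = [sim.template]
    cohort, scans, atlas = sim.cohort, sim.scans, sim.atlas
    subjects = list(cohort["subject_id"])

    # --- QC / FC (only when raw time-series were emitted) ------------------
    fc = dict(sim.fc)
    if sim.timeseries:
        qc_rows = []
        for sid, ts_data in sim.timeseries.items():
            ts = fcp.ParcelTimeseries(
                subject_id=sid, values=ts_data["values"], tr=ts_data["tr"],
                motion=ts_data["motion"], nuisance=ts_data["nuisance"],
                regions=atlas.labels,
            )
            record, keep = fcp.scrub(
                ts, fd_threshold=config.fd_threshold, max_censored=config.max_censored
            )
            qc_rows.append(
                dict(subject_id=sid, censored_fraction=record.censored_fraction,
                     excluded=record.excluded)
            )
            if record.excluded:
                fc.pop(sid, None)
                continue
            cleaned = fcp.clean_timeseries(ts, keep_mask=keep, band=config.band)
            fc[sid] = fcp.connectivity_matrix(cleaned)
        pd.DataFrame(qc_rows).to_csv(out / "qc.csv", index=False)

    # --- normative template and distances ----------------------------------
    template = fcp.normative_template(template_mats, density=config.density)
    iof.write_matrix(template.to_frame(), out / "template.csv")
    dist = fcp.to_distance(
        template, method=config.distance_method,
        coordinates=sim.coordinates,
    )
    iof.write_matrix(dist.to_frame(), out / "distance.csv")

    # --- tau rates ----------------------------------------------------------
    rates = tau_rates.rate_map(scans)
    rates.values.to_csv(out / "rates.csv")
    rates.diagnostics.to_csv(out / "rates_diagnostics.csv")

    # --- epicentres ---------------------------------------------------------
    baseline = _baseline_matrix(scans)
    fits, weighted, excluded = epi.fit_all_regions(
        baseline, seed=stage_seeds["epicentres"]
    )
    pd.DataFrame({r: dataclasses.asdict(f) for r, f in fits.items()}).T.to_csv(
        out / "gmm_params.csv"
    )
    epicentre_sets = {}
    for sid in subjects:
        epicentre_sets[sid] = epi.select_epicentres(
            weighted.loc[sid].dropna(),
            k=config.k_epicentres,
            excluded=excluded,
            raw_suvr=baseline.loc[sid],
            subject_id=sid,
        )
    group_epi = epi.group_epicentres(
        weighted.dropna(axis=1), top_frac=config.group_top_frac, excluded=excluded
    )
    (out / "epicentres.json").write_text(
        json.dumps(
            {
                "individual": {s: e.regions for s, e in epicentre_sets.items()},
                "group": group_epi,
                "excluded_parcels": sorted(excluded),
            },
            indent=1,
        )
    )

    # --- spreading statistics ----------------------------------------------
    beta_rows, fc_rows = [], []
    dist_rows = {}
    fc_region_rows = {}
    for sid in subjects:
        e = epicentre_sets[sid]
        d_vec = spr.distance_to_epicentres(dist, e, aggregate=config.distance_aggregate)
        d_vec = d_vec[~d_vec.index.isin(excluded)]
        r_vec = rates.values.loc[sid]
        r_vec = r_vec[~r_vec.index.isin(excluded)]
        b = spr.subject_beta(r_vec, d_vec, subject_id=sid)
        beta_rows.append(dataclasses.asdict(b))
        dist_rows[sid] = d_vec
        if sid in fc:
            metric = spr.fc_to_epicentres(fc[sid], e)
            fc_rows.append(
                dict(subject_id=sid, fc_to_epicentres=metric.scalar)
            )
            fc_region_rows[sid] = metric.per_region[
                ~metric.per_region.index.isin(excluded)
            ]
    betas = pd.DataFrame(beta_rows).set_index("subject_id")
    betas.to_csv(out / "betas.csv")
    fc_scalar = pd.DataFrame(fc_rows).set_index("subject_id")["fc_to_epicentres"]
    fc_scalar.to_csv(out / "fc_to_epicentres.csv")
    dist_df = pd.DataFrame(dist_rows).T
    fc_region_df = pd.DataFrame(fc_region_rows).T

    covariates = _covariate_frame(cohort)
    gmap = spr.group_beta_map(rates.values, dist_df, covariates=covariates)
    gmap.to_csv(out / "group_beta_map.csv")

    # --- association models --------------------------------------------------
    ct = cohort.set_index("subject_id")
    mean_rate = rates.values.drop(columns=sorted(excluded), errors="ignore").mean(axis=1)
    assoc = {}
    assoc["amyloid_vs_rate"] = spr.association_model(
        mean_rate, ct["global_amyloid"], covariates=covariates
    )
    assoc["amyloid_vs_beta"] = spr.association_model(
        betas["beta"], ct["global_amyloid"], covariates=covariates
    )
    for name, status in (("apoe", "apoe4_carrier"), ("abeta", "abeta_positive")):
        assoc[f"beta_vs_fc_by_{name}"] = spr.association_model(
            betas.loc[fc_scalar.index, "beta"],
            fc_scalar,
            covariates=covariates.loc[fc_scalar.index],
            moderator=ct.loc[fc_scalar.index, status].astype(float),
        )
    for name, table in assoc.items():
        table.to_csv(out / f"association_{name}.csv", index=False)

    # --- mediation ------------------------------------------------------------
    mediation_results = {}
    for name, status, other in (
        ("apoe", "apoe4_carrier", "abeta_positive"),
        ("abeta", "abeta_positive", "apoe4_carrier"),
    ):
        sub = fc_scalar.index
        cov = covariates.loc[sub].copy()
        cov[other] = ct.loc[sub, other].astype(float)
        res = med.mediate(
            x=fc_scalar[sub],
            m=ct.loc[sub, status].astype(float),
            y=betas.loc[sub, "beta"],
            covariates=cov,
            n_boot=config.n_boot,
            seed=stage_seeds["mediate"],
            contrast=config.mediation_contrast,
        )
        mediation_results[name] = res.to_dict()
        (out / f"mediation_{name}.json").write_text(
            json.dumps(res.to_dict(), indent=1)
        )

    # --- influence maps ---------------------------------------------------------
    imap = inf.influence_map(
        fc_region_df,
        gmap["beta"],
        n_perm=config.n_perm,
        alpha=config.alpha,
        seed=stage_seeds["influence"],
        variant=config.wilcoxon_variant,
    )
    imap.to_csv(out / "influence_map.csv")

    # --- manifest -----------------------------------------------------------
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stage_seeds": stage_seeds,
        "hashes": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*.csv")) + sorted(out.rglob("*.json"))
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logger.info("pipeline complete: %s", out)
    return manifest
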