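"""Reproducible file-based runs wiring all stages together.

A RunConfig names an output directory, the study layout, and the global
seed; ``run_pipeline`` executes the requested stages in dependency
order (simulate -> connectome -> similarity -> fit-age -> logan ->
associate), writing plain-text outputs and a manifest with a config
snapshot, per-file checksums and timestamps.  A stage whose outputs
already exist with matching checksums is skipped, so partial runs
resume.  Two runs with the same config (including seed) are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from . import agemodel, crossmodal, logan, pipeline, similarity, synthetic
from .study import StudyConfig, stage_seed, vector_to_matrix

STAGE_ORDER = ("simulate", "connectome", "similarity", "fit-age", "logan", "associate")

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "validate_inputs"]


@dataclass
class RunConfig:
    outdir: str
    study: StudyConfig = field(default_factory=StudyConfig)

    def path(self) -> Path:
        return Path(self.outdir)


@dataclass
class RunManifest:
    config: dict
    stages: dict  # stage -> {files: {name: sha256}, seconds, status}

    def save(self, path: Path) -> None:
        path.write_text(json.dumps({"config": self.config, "stages": self.stages}, indent=1))


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(cfg: RunConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return enc(cfg)


def _stage_fresh(out: Path, manifest: RunManifest, stage: str) -> bool:
    info = manifest.stages.get(stage)
    if not info or info.get("status") != "ok":
        return False
    for name, digest in info["files"].items():
        f = out / name
        if not f.exists() or _sha(f) != digest:
            return False
    return True


def _finish(out: Path, manifest: RunManifest, stage: str, files: list[str], t0: float) -> None:
    manifest.stages[stage] = {
        "status": "ok",
        "seconds": round(time.time() - t0, 3),
        "files": {name: _sha(out / name) for name in files},
    }


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> RunManifest:
    """Execute the requested stages (default: all) into ``config.outdir``."""
    stages = list(stages or STAGE_ORDER)
    for s in stages:
        if s not in STAGE_ORDER:
            raise ValueError(f"unknown stage {s!r}; choose from {STAGE_ORDER}")
    out = config.path()
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        manifest = RunManifest(config=_config_dict(config), stages=prev.get("stages", {}))
        if prev.get("config") != manifest.config:
            manifest.stages = {}  # config changed: nothing is reusable
    else:
        manifest = RunManifest(config=_config_dict(config), stages={})

    cfg = config.study
    labels = [f"roi{j:03d}" for j in range(cfg.n_nodes)]
    stage = "setup"
    try:
        for stage in STAGE_ORDER:
            if stage not in stages:
                continue
            if _stage_fresh(out, manifest, stage):
                continue
            t0 = time.time()
            _require_deps(out, stage)
            files = _run_stage(out, cfg, labels, stage)
            _finish(out, manifest, stage, files, t0)
    except Exception as exc:
        manifest.stages[stage] = {"status": f"failed: {exc}", "files": {}}
        manifest.save(manifest_path)
        raise
    manifest.save(manifest_path)
    return manifest


_DEPS = {
    "simulate": [],
    "connectome": ["subjects.tsv"],
    "similarity": ["subjects_included.tsv"],
    "fit-age": ["subjects_included.tsv"],
    "logan": ["subjects.tsv", "bp_true.tsv"],
    "associate": ["fits_fc.tsv", "fits_bp.tsv", "fits_gmd.tsv"],
}


def _require_deps(out: Path, stage: str) -> None:
    for name in _DEPS[stage]:
        if not (out / name).exists():
            raise FileNotFoundError(
                f"stage {stage!r} requires missing input {name!r}; run earlier stages first"
            )


def _run_stage(out: Path, cfg: StudyConfig, labels: list[str], stage: str) -> list[str]:
    if stage == "simulate":
        return _stage_simulate(out, cfg, labels)
    if stage == "connectome":
        return _stage_connectome(out, cfg, labels)
    if stage == "similarity":
        return _stage_similarity(out, cfg)
    if stage == "fit-age":
        return _stage_fit_age(out, cfg)
    if stage == "logan":
        return _stage_logan(out, cfg, labels)
    return _stage_associate(out, cfg)


def _stage_simulate(out: Path, cfg: StudyConfig, labels: list[str]) -> list[str]:
    cohort = synthetic.make_cohort(
        synthetic.CohortSpec(
            n_young=cfg.n_young, n_old=cfg.n_old, seed=stage_seed(cfg.seed, "cohort")
        )
    )
    truth_rng = np.random.default_rng(stage_seed(cfg.seed, "truth"))
    node_latent = truth_rng.standard_normal(cfg.n_nodes)
    edge_truth = synthetic.sample_edge_truth(
        cfg.n_nodes, cfg.effects, seed=stage_seed(cfg.seed, "truth") + 1, node_latent=node_latent
    )
    node_truth = synthetic.sample_node_truth(
        cfg.n_nodes, cfg.effects, seed=stage_seed(cfg.seed, "truth") + 2, node_latent=node_latent
    )
    files = ["subjects.tsv", "edge_truth.tsv", "bp_true.tsv", "gmd.tsv"]
    fio.write_subject_table(synthetic.cohort_frame(cohort), out / "subjects.tsv")
    fio.write_edge_truth(edge_truth, out / "edge_truth.tsv")
    bp_true = synthetic.simulate_bp_values(cohort, node_truth, seed=stage_seed(cfg.seed, "pet"))
    pd.DataFrame(bp_true, index=[r.subject_id for r in cohort], columns=labels).to_csv(
        out / "bp_true.tsv", sep="\t"
    )
    gmd = synthetic.simulate_gmd(cohort, node_truth, seed=stage_seed(cfg.seed, "gmd"))
    pd.DataFrame(gmd, index=[r.subject_id for r in cohort], columns=labels).to_csv(
        out / "gmd.tsv", sep="\t"
    )
    z_true = synthetic.simulate_edge_values(
        cohort, edge_truth, seed=stage_seed(cfg.seed, "edges"), include_motion=False
    )
    scan_seed = stage_seed(cfg.seed, "scan")
    (out / "scans").mkdir(exist_ok=True)
    for s, rec in enumerate(cohort):
        motion = synthetic.MotionModel(
            mean_fd=rec.motion_trait,
            spike_rate=cfg.young_spike_rate if rec.group == "younger" else cfg.old_spike_rate,
        )
        scan = synthetic.simulate_timeseries(
            vector_to_matrix(z_true[s], cfg.n_nodes),
            cfg.n_volumes,
            tr_seconds=cfg.tr_seconds,
            motion=motion,
            seed=scan_seed + s,
        )
        sid = rec.subject_id
        fio.write_series(scan.series, labels, out / "scans" / f"{sid}_series.tsv")
        fio.write_motion(scan.motion, out / "scans" / f"{sid}_motion.txt")
        fio.write_series(
            np.column_stack([scan.wm, scan.csf]), ["wm", "csf"],
            out / "scans" / f"{sid}_nuisance.tsv",
        )
        files += [
            f"scans/{sid}_series.tsv",
            f"scans/{sid}_motion.txt",
            f"scans/{sid}_nuisance.tsv",
        ]
    return files


def _stage_connectome(out: Path, cfg: StudyConfig, labels: list[str]) -> list[str]:
    subjects = fio.read_subject_table(out / "subjects.tsv")
    (out / "connectomes").mkdir(exist_ok=True)
    reports, files = [], []
    for sid in subjects["subject_id"]:
        series, _ = fio.read_series(out / "scans" / f"{sid}_series.tsv")
        trace = fio.read_motion(out / "scans" / f"{sid}_motion.txt")
        nuis, _ = fio.read_series(out / "scans" / f"{sid}_nuisance.tsv")
        conn, report = pipeline.build_connectome(
            series, trace, nuis[:, 0], nuis[:, 1], cfg.pipeline, labels=labels, subject_id=sid
        )
        reports.append(report)
        if conn is not None:
            fio.write_connectome(conn, out / "connectomes" / f"{sid}.tsv")
            files += [f"connectomes/{sid}.tsv", f"connectomes/{sid}.json"]
    rep = pd.DataFrame(reports)
    rep.to_csv(out / "scrub_report.tsv", sep="\t", index=False)
    merged = subjects.merge(rep[["subject_id", "mean_fd_post", "included"]], on="subject_id")
    fio.write_subject_table(merged[merged["included"]], out / "subjects_included.tsv")
    return files + ["scrub_report.tsv", "subjects_included.tsv"]


def _load_connectomes(out: Path, subjects: pd.DataFrame):
    return [
        fio.read_connectome(out / "connectomes" / f"{sid}.tsv")
        for sid in subjects["subject_id"]
    ]


def _stage_similarity(out: Path, cfg: StudyConfig) -> list[str]:
    subjects = fio.read_subject_table(out / "subjects_included.tsv")
    conns = _load_connectomes(out, subjects)
    sim = similarity.similarity_matrix(conns, subjects)
    pd.DataFrame(sim.matrix, index=sim.subject_ids, columns=sim.subject_ids).to_csv(
        out / "similarity.tsv", sep="\t"
    )
    coords = similarity.classical_mds(sim, n_dims=2)
    pd.DataFrame(coords, index=sim.subject_ids, columns=["dim1", "dim2"]).to_csv(
        out / "mds.tsv", sep="\t"
    )
    summ = similarity.group_similarity_summary(sim)
    (out / "similarity_summary.json").write_text(json.dumps(dataclasses.asdict(summ), indent=1))
    return ["similarity.tsv", "mds.tsv", "similarity_summary.json"]


def _stage_fit_age(out: Path, cfg: StudyConfig) -> list[str]:
    subjects = fio.read_subject_table(out / "subjects_included.tsv")
    conns = _load_connectomes(out, subjects)
    pairs = synthetic.edge_index_pairs(cfg.n_nodes)
    values = np.vstack([c.upper_triangle() for c in conns])
    fits = agemodel.fit_all(
        values,
        subjects["age"].to_numpy(),
        subjects["mean_fd_post"].to_numpy(),
        priors=cfg.priors,
        feature_ids=[f"{i}-{j}" for i, j in pairs],
        seed=stage_seed(cfg.seed, "fit"),
    )
    fits.fits["node_i"] = pairs[:, 0]
    fits.fits["node_j"] = pairs[:, 1]
    fits.fits.to_csv(out / "fits_fc.tsv", sep="\t", index=False)
    # GMD nodal fits ride along: values already on disk from simulate
    gmd = pd.read_csv(out / "gmd.tsv", sep="\t", index_col=0)
    all_subjects = fio.read_subject_table(out / "subjects.tsv")
    gfits = agemodel.fit_all(
        gmd.to_numpy(),
        all_subjects["age"].to_numpy(),
        fd=None,
        priors=cfg.priors,
        feature_ids=list(gmd.columns),
        fixed={"rho": 0.0},
        seed=stage_seed(cfg.seed, "gmd") + 7,
    )
    gfits.fits.to_csv(out / "fits_gmd.tsv", sep="\t", index=False)
    meta = {
        "priors": dataclasses.asdict(cfg.priors),
        "seed": cfg.seed,
        "frac_negative_beta_mu": fits.frac_negative_beta_mu,
        "frac_positive_beta_sigma": fits.frac_positive_beta_sigma,
    }
    (out / "fit_metadata.json").write_text(json.dumps(meta, indent=1))
    return ["fits_fc.tsv", "fits_gmd.tsv", "fit_metadata.json"]


def _stage_logan(out: Path, cfg: StudyConfig, labels: list[str]) -> list[str]:
    subjects = fio.read_subject_table(out / "subjects.tsv")
    bp_true = pd.read_csv(out / "bp_true.tsv", sep="\t", index_col=0)
    schedule = logan.default_schedule()
    pet_seed = stage_seed(cfg.seed, "pet")
    bp_est = np.empty(bp_true.shape)
    for s in range(bp_true.shape[0]):
        for n in range(bp_true.shape[1]):
            tac, ref = synthetic.simulate_tac(
                1.0 + float(bp_true.iloc[s, n]),
                schedule=schedule,
                noise=cfg.pet_noise,
                seed=pet_seed + 1 + s * bp_true.shape[1] + n,
            )
            dvr, _, _ = logan.logan_dvr(tac, ref, window=cfg.logan_window)
            bp_est[s, n] = logan.bp_from_dvr(dvr)
    pd.DataFrame(bp_est, index=bp_true.index, columns=bp_true.columns).to_csv(
        out / "bp_estimated.tsv", sep="\t"
    )
    fits = agemodel.fit_all(
        bp_est,
        subjects["age"].to_numpy(),
        fd=None,
        priors=cfg.priors,
        feature_ids=list(bp_true.columns),
        fixed={"rho": 0.0},
        seed=pet_seed + 7,
    )
    fits.fits.to_csv(out / "fits_bp.tsv", sep="\t", index=False)
    return ["bp_estimated.tsv", "fits_bp.tsv"]


def _stage_associate(out: Path, cfg: StudyConfig) -> list[str]:
    fc = pd.read_csv(out / "fits_fc.tsv", sep="\t")
    bp = pd.read_csv(out / "fits_bp.tsv", sep="\t").set_index("feature")
    gmd = pd.read_csv(out / "fits_gmd.tsv", sep="\t").set_index("feature")
    nodes = sorted(set(fc["node_i"]) | set(fc["node_j"]))
    nodal = crossmodal.average_nodal_beta_table(fc, nodes)
    nodal["roi"] = [f"roi{j:03d}" for j in nodes]
    nodal = nodal.set_index("roi")
    nodal["beta_mu_bp"] = bp["beta_mu"]
    nodal["beta_mu_gmd"] = gmd["beta_mu"]
    nodal["beta_sigma_bp"] = bp["beta_sigma"]
    nodal["beta_sigma_gmd"] = gmd["beta_sigma"]
    nodal.to_csv(out / "nodal_effects.tsv", sep="\t")
    r_bp, p_bp = crossmodal.nodal_correlation(nodal["avg_nodal_beta_mu"], nodal["beta_mu_bp"])
    r_gmd, p_gmd = crossmodal.nodal_correlation(nodal["avg_nodal_beta_mu"], nodal["beta_mu_gmd"])
    joint = crossmodal.joint_regression(
        nodal["avg_nodal_beta_mu"], nodal[["beta_mu_bp", "beta_mu_gmd"]]
    )
    joint.to_csv(out / "joint_regression.tsv", sep="\t", index=False)
    report = {"r_fc_bp": r_bp, "p_fc_bp": p_bp, "r_fc_gmd": r_gmd, "p_fc_gmd": p_gmd}
    (out / "crossmodal.json").write_text(json.dumps(report, indent=1))
    return ["nodal_effects.tsv", "joint_regression.tsv", "crossmodal.json"]


def validate_inputs(config: RunConfig) -> list[str]:
    """Report-only check of every existing input file against its contract."""
    out = config.path()
    problems: list[str] = []
    subj_path = out / "subjects.tsv"
    subjects = None
    if subj_path.exists():
        try:
            subjects = fio.read_subject_table(subj_path)
            if (subjects["age"] <= 0).any():
                problems.append("subjects.tsv: non-positive age")
            if (subjects["mean_fd"] < 0).any():
                problems.append("subjects.tsv: negative mean_fd")
            bad_group = ~subjects["group"].isin(["younger", "older"])
            if bad_group.any():
                problems.append("subjects.tsv: unknown group label")
        except Exception as exc:
            problems.append(f"subjects.tsv: {exc}")
        for sid in subjects["subject_id"] if subjects is not None else []:
            mpath = out / "scans" / f"{sid}_motion.txt"
            if mpath.exists():
                try:
                    fio.read_motion(mpath)
                except Exception as exc:
                    problems.append(f"{mpath.name}: {exc}")
            spath = out / "scans" / f"{sid}_series.tsv"
            if spath.exists() and mpath.exists():
                series, _ = fio.read_series(spath)
                trace = fio.read_motion(mpath)
                if series.shape[0] != trace.shape[0]:
                    problems.append(f"{sid}: series/motion volume count mismatch")
    return problems
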