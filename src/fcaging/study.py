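"""End-to-end synthetic study: simulate, preprocess, fit, associate.

Reproduces the full analysis chain on a synthetic two-age-group cohort:
BOLD time series with motion -> connectomes -> similarity/MDS ->
per-edge heteroscedastic age fits -> edge-removal curves -> SRTM PET
TACs -> Logan BP -> nodal BP/GMD age fits -> cross-modal association.
Everything is deterministic given the study seed; stage seeds are
derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agemodel, crossmodal, logan, pipeline, similarity, synthetic

__all__ = ["StudyConfig", "StudyResult", "stage_seed", "run_synthetic_study"]

_STAGES = (
    "cohort",
    "truth",
    "edges",
    "scan",
    "fit",
    "removal",
    "pet",
    "gmd",
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = _STAGES.index(stage) if stage in _STAGES else 97 + hash(stage) % 100
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


@dataclass
class StudyConfig:
    """Synthetic-study layout.

    Defaults reproduce the emulated design at desk scale: 30 + 30
    subjects, a 60-node connectome (1,770 connections), ~13-min task
    acquisitions at TR 2 s, task-style scrubbing (0.3 mm, >= 300
    volumes), the 18-frame PET schedule and the 18-55 min Logan window.
    """

    n_young: int = 30
    n_old: int = 30
    n_nodes: int = 60
    n_volumes: int = 400
    tr_seconds: float = 2.0
    young_spike_rate: float = 0.01
    old_spike_rate: float = 0.03
    pet_noise: float = 0.02
    effects: synthetic.EffectConfig = field(default_factory=synthetic.EffectConfig)
    pipeline: pipeline.PipelineConfig = field(default_factory=pipeline.PipelineConfig)
    priors: agemodel.AgeModelPriors = field(default_factory=agemodel.AgeModelPriors)
    removal_fractions: tuple[float, ...] = (0.0, 0.05, 0.1, 0.2, 0.4)
    logan_window: tuple[float, float] = (18.0, 55.0)
    seed: int = 0


@dataclass
class StudyResult:
    cohort: list[synthetic.SubjectRecord]
    subjects: pd.DataFrame  # incl. post-scrub mean FD and inclusion flag
    edge_truth: list[synthetic.EdgeTruth]
    node_truth: list[synthetic.NodeTruth]
    connectomes: list[pipeline.Connectome]
    scrub_reports: pd.DataFrame
    sim_matrix: similarity.SimilarityMatrix
    group_summary: similarity.GroupSimilaritySummary
    mds_coords: np.ndarray
    fc_fits: agemodel.AgingEffectTable
    removal_curves: dict[str, pd.DataFrame]  # keys: beta_mu, beta_sigma, random
    bp_values: pd.DataFrame  # subject x node Logan BP estimates
    bp_fits: agemodel.AgingEffectTable
    gmd_values: np.ndarray
    gmd_fits: agemodel.AgingEffectTable
    nodal_table: pd.DataFrame
    crossmodal_stats: dict


def _edge_ids(pairs: np.ndarray) -> list[str]:
    return [f"{i}-{j}" for i, j in pairs]


def vector_to_matrix(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Upper-triangle vector -> symmetric matrix with zero diagonal."""
    mat = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    mat[iu] = vec
    return mat + mat.T


def run_synthetic_study(config: StudyConfig | None = None, progress: bool = False) -> StudyResult:
    cfg = config or StudyConfig()
    n_nodes = cfg.n_nodes
    pairs = synthetic.edge_index_pairs(n_nodes)
    edge_ids = _edge_ids(pairs)
    labels = [f"roi{j:03d}" for j in range(n_nodes)]

    # --- cohort and ground truth -----------------------------------------
    cohort = synthetic.make_cohort(
        synthetic.CohortSpec(
            n_young=cfg.n_young, n_old=cfg.n_old, seed=stage_seed(cfg.seed, "cohort")
        )
    )
    truth_rng = np.random.default_rng(stage_seed(cfg.seed, "truth"))
    node_latent = truth_rng.standard_normal(n_nodes)
    edge_truth = synthetic.sample_edge_truth(
        n_nodes, cfg.effects, seed=stage_seed(cfg.seed, "truth") + 1, node_latent=node_latent
    )
    node_truth = synthetic.sample_node_truth(
        n_nodes, cfg.effects, seed=stage_seed(cfg.seed, "truth") + 2, node_latent=node_latent
    )

    # --- per-subject BOLD series and connectomes -------------------------
    # true z (no motion term: contamination enters through the simulated
    # artifacts instead, and scrubbing/regression must deal with it)
    z_true = synthetic.simulate_edge_values(
        cohort, edge_truth, seed=stage_seed(cfg.seed, "edges"), include_motion=False
    )
    connectomes: list[pipeline.Connectome] = []
    reports = []
    scan_seed = stage_seed(cfg.seed, "scan")
    for s, rec in enumerate(cohort):
        motion = synthetic.MotionModel(
            mean_fd=rec.motion_trait,
            spike_rate=cfg.young_spike_rate if rec.group == "younger" else cfg.old_spike_rate,
        )
        scan = synthetic.simulate_timeseries(
            vector_to_matrix(z_true[s], n_nodes),
            cfg.n_volumes,
            tr_seconds=cfg.tr_seconds,
            motion=motion,
            seed=scan_seed + s,
        )
        conn, report = pipeline.build_connectome(
            scan.series,
            scan.motion,
            scan.wm,
            scan.csf,
            cfg.pipeline,
            labels=labels,
            subject_id=rec.subject_id,
        )
        reports.append(report)
        if conn is not None:
            connectomes.append(conn)
        if progress and (s + 1) % 20 == 0:
            print(f"  simulated {s + 1}/{len(cohort)} subjects")
    scrub_reports = pd.DataFrame(reports)
    subjects = synthetic.cohort_frame(cohort).merge(
        scrub_reports[["subject_id", "mean_fd_post", "included"]], on="subject_id"
    )
    included = subjects[subjects["included"]].reset_index(drop=True)

    # --- similarity and MDS ----------------------------------------------
    sim = similarity.similarity_matrix(connectomes, included)
    summary = similarity.group_similarity_summary(sim)
    coords = similarity.classical_mds(sim, n_dims=2)

    # --- per-edge age fits (FD covariate = post-scrub mean FD) ------------
    by_id = {c.meta["subject_id"]: c for c in connectomes}
    order = included["subject_id"].tolist()
    values = np.vstack([by_id[i].upper_triangle() for i in order])
    ages = included["age"].to_numpy()
    fd = included["mean_fd_post"].to_numpy()
    fc_fits = agemodel.fit_all(
        values,
        ages,
        fd,
        priors=cfg.priors,
        feature_ids=edge_ids,
        seed=stage_seed(cfg.seed, "fit"),
        progress=progress,
    )
    fc_fits.fits["node_i"] = pairs[:, 0]
    fc_fits.fits["node_j"] = pairs[:, 1]

    # --- removal curves ---------------------------------------------------
    rng = np.random.default_rng(stage_seed(cfg.seed, "removal"))
    rankings = {
        "beta_mu": fc_fits.fits["beta_mu"].to_numpy(),
        "beta_sigma": fc_fits.fits["beta_sigma"].to_numpy(),
        "random": rng.random(len(edge_ids)),
    }
    removal = {
        name: similarity.connection_removal_curve(
            connectomes, included, rank, list(cfg.removal_fractions)
        )
        for name, rank in rankings.items()
    }

    # --- PET: SRTM TACs -> Logan BP -> nodal fits -------------------------
    pet_seed = stage_seed(cfg.seed, "pet")
    bp_true = synthetic.simulate_bp_values(cohort, node_truth, seed=pet_seed)
    schedule = logan.default_schedule()
    bp_est = np.empty_like(bp_true)
    for s in range(len(cohort)):
        for n in range(n_nodes):
            tac, ref = synthetic.simulate_tac(
                1.0 + bp_true[s, n],
                schedule=schedule,
                noise=cfg.pet_noise,
                seed=pet_seed + 1 + s * n_nodes + n,
            )
            dvr, _, _ = logan.logan_dvr(tac, ref, window=cfg.logan_window)
            bp_est[s, n] = logan.bp_from_dvr(dvr)
    bp_values = pd.DataFrame(
        bp_est, index=[r.subject_id for r in cohort], columns=labels
    )
    bp_fits = agemodel.fit_all(
        bp_est,
        np.array([r.age for r in cohort]),
        fd=None,
        priors=cfg.priors,
        feature_ids=labels,
        fixed={"rho": 0.0},
        seed=pet_seed + 7,
    )

    # --- GMD nodal fits ---------------------------------------------------
    gmd_seed = stage_seed(cfg.seed, "gmd")
    gmd_values = synthetic.simulate_gmd(cohort, node_truth, seed=gmd_seed)
    gmd_fits = agemodel.fit_all(
        gmd_values,
        np.array([r.age for r in cohort]),
        fd=None,
        priors=cfg.priors,
        feature_ids=labels,
        fixed={"rho": 0.0},
        seed=gmd_seed + 7,
    )

    # --- cross-modal association ------------------------------------------
    nodal = crossmodal.average_nodal_beta_table(fc_fits.fits, list(range(n_nodes)))
    nodal["roi"] = labels
    nodal = nodal.set_index("roi")
    nodal["beta_mu_bp"] = bp_fits.fits.set_index("feature")["beta_mu"]
    nodal["beta_sigma_bp"] = bp_fits.fits.set_index("feature")["beta_sigma"]
    nodal["beta_mu_gmd"] = gmd_fits.fits.set_index("feature")["beta_mu"]
    nodal["beta_sigma_gmd"] = gmd_fits.fits.set_index("feature")["beta_sigma"]

    r_bp, p_bp = crossmodal.nodal_correlation(nodal["avg_nodal_beta_mu"], nodal["beta_mu_bp"])
    r_gmd, p_gmd = crossmodal.nodal_correlation(nodal["avg_nodal_beta_mu"], nodal["beta_mu_gmd"])
    r_sig_gmd, p_sig_gmd = crossmodal.nodal_correlation(
        nodal["avg_nodal_beta_sigma"], nodal["beta_sigma_gmd"]
    )
    joint = crossmodal.joint_regression(
        nodal["avg_nodal_beta_mu"], nodal[["beta_mu_bp", "beta_mu_gmd"]]
    )
    stats = {
        "r_fc_bp": r_bp,
        "p_fc_bp": p_bp,
        "r_fc_gmd": r_gmd,
        "p_fc_gmd": p_gmd,
        "r_sigma_fc_gmd": r_sig_gmd,
        "p_sigma_fc_gmd": p_sig_gmd,
        "joint_regression": joint,
    }

    return StudyResult(
        cohort=cohort,
        subjects=subjects,
        edge_truth=edge_truth,
        node_truth=node_truth,
        connectomes=connectomes,
        scrub_reports=scrub_reports,
        sim_matrix=sim,
        group_summary=summary,
        mds_coords=coords,
        fc_fits=fc_fits,
        removal_curves=removal,
        bp_values=bp_values,
        bp_fits=bp_fits,
        gmd_values=gmd_values,
        gmd_fits=gmd_fits,
        nodal_table=nodal,
        crossmodal_stats=stats,
    )
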