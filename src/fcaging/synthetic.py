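"""Synthetic two-age-group neuroimaging cohorts.

Generates everything the downstream stages need, with known ground
truth: subject demographics and motion traits, per-connection
location-scale parameters for Fisher-z functional connectivity (FC),
ROI BOLD time series with motion contamination, simplified
reference-tissue-model (SRTM) PET time-activity curves with known DVR,
and nodal gray-matter-density (GMD) tables.

The generative model for an imaging value ``y`` of subject ``s`` on
feature ``j`` (an FC edge, or a node for BP/GMD) is

    y_sj = z_sj + rho_j * FD_s
    z_sj ~ Normal(alpha_mu_j + beta_mu_j * a_s,
                  exp(alpha_sigma_j + beta_sigma_j * a_s))

with ``a_s`` the subject's age referenced to 20 years and ``FD_s`` the
subject's mean framewise displacement (mm).  ``beta_mu`` is the per-year
change in the mean, ``beta_sigma`` the per-year change in the log
standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.correlation_tools import corr_clipped, corr_nearest

from .logan import FrameSchedule, TimeActivityCurve

AGE_REFERENCE = 20.0

__all__ = [
    "AGE_REFERENCE",
    "SubjectRecord",
    "CohortSpec",
    "EdgeTruth",
    "NodeTruth",
    "EffectConfig",
    "MotionModel",
    "SimulatedScan",
    "make_cohort",
    "cohort_frame",
    "sample_edge_truth",
    "sample_node_truth",
    "simulate_edge_values",
    "simulate_timeseries",
    "srtm_frame_activity",
    "simulate_tac",
    "simulate_gmd",
    "simulate_bp_values",
    "edge_index_pairs",
]


@dataclass
class SubjectRecord:
    """One participant of the cross-sectional study."""

    subject_id: str
    age: float
    group: str  # "younger" | "older"
    sex: str  # "M" | "F"
    motion_trait: float  # expected mean framewise displacement, mm

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.motion_trait < 0:
            raise ValueError(f"motion_trait must be >= 0, got {self.motion_trait}")
        if self.group not in ("younger", "older"):
            raise ValueError(f"group must be 'younger' or 'older', got {self.group!r}")


@dataclass
class CohortSpec:
    """Two-group cohort layout.

    Defaults follow the study design this package emulates: 30 younger
    subjects (age 24.2 +- 3.4 y) and 30 older (70.8 +- 2.7 y).  Mean-FD
    motion traits are log-normal per group; older adults move more.
    """

    n_young: int = 30
    n_old: int = 30
    young_age_mean: float = 24.2
    young_age_sd: float = 3.4
    old_age_mean: float = 70.8
    old_age_sd: float = 2.7
    young_fd_median: float = 0.08
    old_fd_median: float = 0.14
    fd_log_sd: float = 0.3
    min_age: float = 18.0  # ages truncated below to keep (age - 20) interpretable
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_young", "n_old"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        for name in ("young_age_sd", "old_age_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("young_fd_median", "old_fd_median"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")


@dataclass
class EdgeTruth:
    """Ground-truth location-scale parameters for one connection (i < j)."""

    node_i: int
    node_j: int
    alpha_mu: float  # z units at age 20
    beta_mu: float  # z units / year
    alpha_sigma: float  # log z units at age 20
    beta_sigma: float  # per-year log-SD increment
    rho: float  # z units per mm of mean FD

    def __post_init__(self) -> None:
        if not self.node_i < self.node_j:
            raise ValueError("EdgeTruth requires node_i < node_j")


@dataclass
class NodeTruth:
    """Ground-truth nodal parameters for D1 BP and GMD age models."""

    node: int
    bp_alpha_mu: float
    bp_beta_mu: float
    bp_alpha_sigma: float
    bp_beta_sigma: float
    gmd_alpha_mu: float
    gmd_beta_mu: float
    gmd_alpha_sigma: float
    gmd_beta_sigma: float


@dataclass
class EffectConfig:
    """Distributions for ground-truth effect parameters.

    Edge-level slopes carry a shared per-node latent component
    (``*_coupling``) so that average nodal FC slopes correlate with the
    BP and GMD slopes of the same node, emulating spatially organised
    aging effects.  Defaults give mostly negative ``beta_mu`` (mean FC
    declines with age in most connections) and mostly positive
    ``beta_sigma`` (between-person FC variance grows with age).
    """

    # FC edges (Fisher-z scale)
    alpha_mu_mean: float = 0.3
    alpha_mu_sd: float = 0.25
    beta_mu_mean: float = -0.001
    beta_mu_sd: float = 0.002
    alpha_sigma_mean: float = math.log(0.15)
    alpha_sigma_sd: float = 0.2
    beta_sigma_mean: float = 0.004
    beta_sigma_sd: float = 0.005
    rho_mean: float = 0.0
    rho_sd: float = 0.15
    # per-node latent coupling into edge slopes
    node_coupling_mu: float = 0.0015
    node_coupling_sigma: float = 0.003
    # D1 binding potential (nodes)
    bp_alpha_mu_mean: float = 0.8
    bp_alpha_mu_sd: float = 0.4
    bp_beta_mu_mean: float = -0.005
    bp_beta_mu_sd: float = 0.002
    bp_coupling_mu: float = 0.002
    bp_alpha_sigma_mean: float = math.log(0.12)
    bp_alpha_sigma_sd: float = 0.2
    bp_beta_sigma_mean: float = 0.003
    bp_beta_sigma_sd: float = 0.004
    # gray matter density (nodes)
    gmd_alpha_mu_mean: float = 0.6
    gmd_alpha_mu_sd: float = 0.08
    gmd_beta_mu_mean: float = -0.002
    gmd_beta_mu_sd: float = 0.001
    gmd_coupling_mu: float = -0.0005
    gmd_alpha_sigma_mean: float = math.log(0.03)
    gmd_alpha_sigma_sd: float = 0.2
    gmd_beta_sigma_mean: float = 0.002
    gmd_beta_sigma_sd: float = 0.003


def _truncated_normal(rng: np.random.Generator, mean, sd, low, size) -> np.ndarray:
    """Rejection-sampled normal truncated below at ``low``."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = out <= low
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    raise RuntimeError("truncated-normal sampling failed to converge")


def make_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a two-group cohort. Deterministic given ``spec.seed``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    groups = [
        ("younger", spec.n_young, spec.young_age_mean, spec.young_age_sd, spec.young_fd_median),
        ("older", spec.n_old, spec.old_age_mean, spec.old_age_sd, spec.old_fd_median),
    ]
    idx = 0
    for group, n, age_mean, age_sd, fd_median in groups:
        ages = _truncated_normal(rng, age_mean, age_sd, spec.min_age, n)
        fds = fd_median * np.exp(rng.normal(0.0, spec.fd_log_sd, size=n))
        sexes = rng.choice(["M", "F"], size=n)
        for a, fd, sex in zip(ages, fds, sexes):
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{idx:03d}",
                    age=float(a),
                    group=group,
                    sex=str(sex),
                    motion_trait=float(fd),
                )
            )
            idx += 1
    return records


def cohort_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Subject table with columns subject_id, age, group, sex, mean_fd."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "age": [r.age for r in records],
            "group": [r.group for r in records],
            "sex": [r.sex for r in records],
            "mean_fd": [r.motion_trait for r in records],
        }
    )


def edge_index_pairs(n_nodes: int) -> np.ndarray:
    """(n_edges, 2) array of unordered node pairs i < j in row-major order."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def sample_edge_truth(
    n_nodes: int,
    config: EffectConfig | None = None,
    seed: int = 0,
    node_latent: np.ndarray | None = None,
) -> list[EdgeTruth]:
    """Ground-truth parameters for every unordered node pair.

    ``node_latent`` (one standard-normal value per node) injects the
    shared spatial component into the edge slopes; if omitted it is
    drawn here.  Pass the same latent to :func:`sample_node_truth` to
    couple FC, BP and GMD aging effects.
    """
    if n_nodes < 3:
        raise ValueError(f"n_nodes must be >= 3, got {n_nodes}")
    cfg = config or EffectConfig()
    rng = np.random.default_rng(seed)
    if node_latent is None:
        node_latent = rng.standard_normal(n_nodes)
    if node_latent.shape != (n_nodes,):
        raise ValueError("node_latent must have one entry per node")
    pairs = edge_index_pairs(n_nodes)
    n_edges = pairs.shape[0]
    shared = 0.5 * (node_latent[pairs[:, 0]] + node_latent[pairs[:, 1]])
    alpha_mu = rng.normal(cfg.alpha_mu_mean, cfg.alpha_mu_sd, n_edges)
    beta_mu = (
        cfg.beta_mu_mean
        + cfg.node_coupling_mu * shared
        + rng.normal(0.0, cfg.beta_mu_sd, n_edges)
    )
    alpha_sigma = rng.normal(cfg.alpha_sigma_mean, cfg.alpha_sigma_sd, n_edges)
    beta_sigma = (
        cfg.beta_sigma_mean
        + cfg.node_coupling_sigma * shared
        + rng.normal(0.0, cfg.beta_sigma_sd, n_edges)
    )
    rho = rng.normal(cfg.rho_mean, cfg.rho_sd, n_edges)
    return [
        EdgeTruth(int(i), int(j), float(am), float(bm), float(asg), float(bs), float(r))
        for (i, j), am, bm, asg, bs, r in zip(
            pairs, alpha_mu, beta_mu, alpha_sigma, beta_sigma, rho
        )
    ]


def sample_node_truth(
    n_nodes: int,
    config: EffectConfig | None = None,
    seed: int = 0,
    node_latent: np.ndarray | None = None,
) -> list[NodeTruth]:
    """Ground-truth BP and GMD age-model parameters per node."""
    cfg = config or EffectConfig()
    rng = np.random.default_rng(seed)
    if node_latent is None:
        node_latent = rng.standard_normal(n_nodes)
    bp_alpha_mu = np.clip(
        rng.normal(cfg.bp_alpha_mu_mean, cfg.bp_alpha_mu_sd, n_nodes), 0.1, None
    )
    bp_beta_mu = (
        cfg.bp_beta_mu_mean
        + cfg.bp_coupling_mu * node_latent
        + rng.normal(0.0, cfg.bp_beta_mu_sd, n_nodes)
    )
    bp_alpha_sigma = rng.normal(cfg.bp_alpha_sigma_mean, cfg.bp_alpha_sigma_sd, n_nodes)
    bp_beta_sigma = rng.normal(cfg.bp_beta_sigma_mean, cfg.bp_beta_sigma_sd, n_nodes)
    gmd_alpha_mu = rng.normal(cfg.gmd_alpha_mu_mean, cfg.gmd_alpha_mu_sd, n_nodes)
    gmd_beta_mu = (
        cfg.gmd_beta_mu_mean
        + cfg.gmd_coupling_mu * node_latent
        + rng.normal(0.0, cfg.gmd_beta_mu_sd, n_nodes)
    )
    gmd_alpha_sigma = rng.normal(cfg.gmd_alpha_sigma_mean, cfg.gmd_alpha_sigma_sd, n_nodes)
    gmd_beta_sigma = rng.normal(cfg.gmd_beta_sigma_mean, cfg.gmd_beta_sigma_sd, n_nodes)
    return [
        NodeTruth(
            node=i,
            bp_alpha_mu=float(bp_alpha_mu[i]),
            bp_beta_mu=float(bp_beta_mu[i]),
            bp_alpha_sigma=float(bp_alpha_sigma[i]),
            bp_beta_sigma=float(bp_beta_sigma[i]),
            gmd_alpha_mu=float(gmd_alpha_mu[i]),
            gmd_beta_mu=float(gmd_beta_mu[i]),
            gmd_alpha_sigma=float(gmd_alpha_sigma[i]),
            gmd_beta_sigma=float(gmd_beta_sigma[i]),
        )
        for i in range(n_nodes)
    ]


def simulate_edge_values(
    cohort: list[SubjectRecord],
    edge_truth: list[EdgeTruth],
    seed: int = 0,
    include_motion: bool = True,
) -> np.ndarray:
    """Draw per-subject Fisher-z FC directly from the generative model.

    Returns an (n_subjects, n_edges) array of y = z + rho * FD values,
    subjects in cohort order, edges in ``edge_truth`` order.  With
    ``include_motion=False`` the rho * FD term is omitted and the pure
    z draws are returned (used when motion instead contaminates the
    simulated time series directly).
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    rng = np.random.default_rng(seed)
    ages = np.array([r.age for r in cohort]) - AGE_REFERENCE
    fd = np.array([r.motion_trait for r in cohort])
    am = np.array([e.alpha_mu for e in edge_truth])
    bm = np.array([e.beta_mu for e in edge_truth])
    asg = np.array([e.alpha_sigma for e in edge_truth])
    bs = np.array([e.beta_sigma for e in edge_truth])
    rho = np.array([e.rho for e in edge_truth])
    mu = am[None, :] + bm[None, :] * ages[:, None]
    sd = np.exp(asg[None, :] + bs[None, :] * ages[:, None])
    z = rng.normal(mu, sd)
    if not include_motion:
        return z
    return z + rho[None, :] * fd[:, None]


@dataclass
class MotionModel:
    """Head-motion generator: baseline jitter plus seeded spike events.

    ``mean_fd`` sets the expected baseline framewise displacement per
    volume; spikes add step displacements of ~``spike_amp`` mm at
    Bernoulli(``spike_rate``) volumes and inject a shared artifact
    signal (gain ``artifact_gain``) into every ROI at those volumes.
    """

    mean_fd: float = 0.15
    spike_rate: float = 0.02
    spike_amp: float = 0.8
    artifact_gain: float = 3.0


@dataclass
class SimulatedScan:
    """One subject's simulated acquisition."""

    series: np.ndarray  # (n_volumes, n_rois) BOLD-like signal
    motion: np.ndarray  # (n_volumes, 6): 3 translations mm, 3 rotations rad
    wm: np.ndarray  # white-matter nuisance signal
    csf: np.ndarray  # CSF nuisance signal
    target_correlation: np.ndarray  # population correlation actually sampled
    projection_distance: float  # Frobenius distance moved by the PSD projection


# FD(t) = sum |d translations| + 50 mm * sum |d rotations|; for increments
# N(0, s^2) on each of 6 channels (rotations scaled by the head radius),
# E[FD] = 6 * s * sqrt(2/pi).
_FD_PER_STEP_SD = 6.0 * math.sqrt(2.0 / math.pi)


def simulate_timeseries(
    target_z: np.ndarray,
    n_volumes: int,
    tr_seconds: float = 2.0,
    motion: MotionModel | None = None,
    noise: float = 0.0,
    nuisance_gain: float = 0.3,
    projection: str = "clipped",
    seed: int = 0,
) -> SimulatedScan:
    """Multivariate-normal ROI time series with a target FC structure.

    ``target_z`` is a symmetric matrix of Fisher-z values; the sampled
    series has population correlation equal to the nearest valid
    correlation matrix to tanh(target_z).  Motion spikes add a shared
    artifact to all ROIs, and weak WM/CSF nuisance signals are mixed in
    so confound regression has something real to remove.
    """
    if n_volumes < 50:
        raise ValueError(f"n_volumes must be >= 50, got {n_volumes}")
    target_z = np.asarray(target_z, dtype=float)
    if not np.all(np.isfinite(target_z)):
        raise ValueError("target_z must be finite")
    if target_z.ndim != 2 or target_z.shape[0] != target_z.shape[1]:
        raise ValueError("target_z must be square")
    motion = motion or MotionModel()
    rng = np.random.default_rng(seed)
    n_roi = target_z.shape[0]

    r = np.tanh(target_z)
    np.fill_diagonal(r, 1.0)
    r = 0.5 * (r + r.T)
    # edge-marginal targets need not be jointly realizable; project to a
    # valid correlation matrix ("clipped": one-shot eigenvalue clipping,
    # fast; "nearest": iterative Higham-style projection)
    if projection == "nearest":
        corr = corr_nearest(r, threshold=1e-8, n_fact=100)
    elif projection == "clipped":
        corr = corr_clipped(r, threshold=1e-8)
    else:
        raise ValueError("projection must be 'clipped' or 'nearest'")
    corr = 0.5 * (corr + corr.T)
    proj_dist = float(np.linalg.norm(corr - r, "fro"))
    # small ridge keeps Cholesky stable after the projection
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 1e-8, None)
    root = v * np.sqrt(w)
    series = rng.standard_normal((n_volumes, n_roi)) @ root.T

    # nuisance signals: AR(1) WM and CSF traces leaking into every ROI
    def ar1(phi: float = 0.6) -> np.ndarray:
        x = np.empty(n_volumes)
        x[0] = rng.standard_normal()
        innov = rng.standard_normal(n_volumes) * math.sqrt(1 - phi**2)
        for t in range(1, n_volumes):
            x[t] = phi * x[t - 1] + innov[t]
        return x

    wm = ar1()
    csf = ar1()
    if nuisance_gain > 0:
        series += nuisance_gain * np.outer(wm, rng.normal(0.0, 1.0, n_roi) * 0.5)
        series += nuisance_gain * np.outer(csf, rng.normal(0.0, 1.0, n_roi) * 0.5)

    # motion trace: baseline random-walk jitter calibrated to mean_fd
    step_sd = motion.mean_fd / _FD_PER_STEP_SD
    increments = rng.normal(0.0, step_sd, size=(n_volumes, 6))
    increments[:, 3:] /= 50.0  # rotations in radians on a 50 mm sphere
    increments[0] = 0.0
    trace = np.cumsum(increments, axis=0)
    if motion.spike_rate > 0 and motion.spike_amp > 0:
        spikes = rng.random(n_volumes) < motion.spike_rate
        spikes[0] = False
        for t in np.flatnonzero(spikes):
            amp = motion.spike_amp * (0.5 + rng.random())
            axis = rng.integers(0, 3)
            trace[t:, axis] += amp * rng.choice([-1.0, 1.0])
            series[t] += motion.artifact_gain * amp
    if motion.mean_fd == 0 and motion.spike_rate == 0:
        trace[:] = 0.0
    if noise > 0:
        series += rng.normal(0.0, noise, size=series.shape)
    return SimulatedScan(
        series=series,
        motion=trace,
        wm=wm,
        csf=csf,
        target_correlation=corr,
        projection_distance=proj_dist,
    )


@dataclass
class ReferenceCurve:
    """Bi-exponential bolus input for the reference region:
    C_ref(t) = amplitude * (exp(-washout * t) - exp(-uptake * t))."""

    amplitude: float = 10.0
    uptake: float = 4.0  # 1/min
    washout: float = 0.05  # 1/min


def _exp_frame_means(
    coeffs: np.ndarray, rates: np.ndarray, schedule: FrameSchedule
) -> np.ndarray:
    """Frame averages of sum_i coeffs[i] * exp(-rates[i] * t)."""
    t0 = schedule.start[:, None]
    t1 = schedule.end[:, None]
    k = rates[None, :]
    integral = np.where(
        k == 0, t1 - t0, (np.exp(-k * t0) - np.exp(-k * t1)) / np.where(k == 0, 1.0, k)
    )
    return (integral @ coeffs) / schedule.duration


def srtm_frame_activity(
    dvr_true: float,
    r1: float,
    k2: float,
    reference: ReferenceCurve,
    schedule: FrameSchedule,
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless SRTM target and reference frame activities (closed form).

    The SRTM solution for a reference input C_R is
    C_T(t) = R1*C_R(t) + (k2 - R1*k2a) * (C_R conv exp(-k2a t))(t) with
    k2a = k2 / DVR.  With a bi-exponential C_R every term is a sum of
    exponentials, so frame averages are computed analytically.
    """
    if dvr_true < 1:
        raise ValueError("dvr_true must be >= 1 (specific binding BP >= 0)")
    a, l_up, l_wash = reference.amplitude, reference.uptake, reference.washout
    k2a = k2 / dvr_true
    # guard near-degenerate rate coincidences
    for lam in (l_up, l_wash):
        if abs(k2a - lam) < 1e-9:
            k2a *= 1.0 + 1e-7
    b = (k2 - r1 * k2a) * a
    # C_T = sum of exponentials with rates [washout, uptake, k2a]
    coeffs = np.array(
        [
            r1 * a + b / (k2a - l_wash),
            -r1 * a - b / (k2a - l_up),
            -b / (k2a - l_wash) + b / (k2a - l_up),
        ]
    )
    rates = np.array([l_wash, l_up, k2a])
    target = _exp_frame_means(coeffs, rates, schedule)
    ref_coeffs = np.array([a, -a])
    ref_rates = np.array([l_wash, l_up])
    ref = _exp_frame_means(ref_coeffs, ref_rates, schedule)
    return target, ref


def simulate_tac(
    dvr_true: float,
    r1: float = 1.0,
    k2: float = 0.15,
    reference: ReferenceCurve | None = None,
    schedule: FrameSchedule | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[TimeActivityCurve, TimeActivityCurve]:
    """(target, reference) TACs from SRTM kinetics with known DVR.

    ``noise`` scales count-like Gaussian frame noise with SD
    noise * sqrt(activity / frame duration); 0 gives the exact
    noiseless curves.
    """
    reference = reference or ReferenceCurve()
    schedule = schedule or _default_schedule()
    if schedule.total_minutes <= 18.0:
        raise ValueError("frame schedule must extend past the 18-min Logan window start")
    target, ref = srtm_frame_activity(dvr_true, r1, k2, reference, schedule)
    if noise > 0:
        rng = np.random.default_rng(seed)
        target = target + rng.normal(
            0.0, noise * np.sqrt(np.clip(target, 0, None) / schedule.duration)
        )
        ref = ref + rng.normal(
            0.0, noise * np.sqrt(np.clip(ref, 0, None) / schedule.duration)
        )
    return (
        TimeActivityCurve(schedule, target),
        TimeActivityCurve(schedule, ref),
    )


def _default_schedule() -> FrameSchedule:
    from .logan import default_schedule

    return default_schedule()


def simulate_gmd(
    cohort: list[SubjectRecord],
    node_truth: list[NodeTruth],
    seed: int = 0,
) -> np.ndarray:
    """Subject x ROI gray-matter-density table from the nodal age model."""
    if not cohort:
        raise ValueError("cohort must be nonempty")
    rng = np.random.default_rng(seed)
    ages = np.array([r.age for r in cohort]) - AGE_REFERENCE
    am = np.array([n.gmd_alpha_mu for n in node_truth])
    bm = np.array([n.gmd_beta_mu for n in node_truth])
    asg = np.array([n.gmd_alpha_sigma for n in node_truth])
    bs = np.array([n.gmd_beta_sigma for n in node_truth])
    mu = am[None, :] + bm[None, :] * ages[:, None]
    sd = np.exp(asg[None, :] + bs[None, :] * ages[:, None])
    return rng.normal(mu, sd)


def simulate_bp_values(
    cohort: list[SubjectRecord],
    node_truth: list[NodeTruth],
    seed: int = 0,
) -> np.ndarray:
    """Subject x ROI true binding potentials from the nodal age model.

    Values are clipped at 0 from below (specific binding cannot be
    negative; the defaults make clipping rare).
    """
    if not cohort:
        raise ValueError("cohort must be nonempty")
    rng = np.random.default_rng(seed)
    ages = np.array([r.age for r in cohort]) - AGE_REFERENCE
    am = np.array([n.bp_alpha_mu for n in node_truth])
    bm = np.array([n.bp_beta_mu for n in node_truth])
    asg = np.array([n.bp_alpha_sigma for n in node_truth])
    bs = np.array([n.bp_beta_sigma for n in node_truth])
    mu = am[None, :] + bm[None, :] * ages[:, None]
    sd = np.exp(asg[None, :] + bs[None, :] * ages[:, None])
    return np.clip(rng.normal(mu, sd), 0.0, None)
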