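"""ROI time series -> per-subject Fisher-z connectome.

Implements the denoising chain used for task and resting-state BOLD:
framewise displacement (Power convention, 50 mm head radius), motion
scrubbing with a 1-back/2-forward extension, 24-parameter motion +
WM/CSF (+ optional global signal) confound regression, 0.009-0.1 Hz
band-pass filtering, coverage-based ROI exclusion, and Pearson/Fisher-z
connectome computation on the surviving volumes.

Order of operations: confound regression, then band-pass, then frame
selection (scrubbing) at the correlation step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

Z_CLAMP = 1.0 - 1e-7  # |r| clamp before arctanh keeps z finite

__all__ = [
    "PipelineConfig",
    "Connectome",
    "framewise_displacement",
    "scrub_mask",
    "subject_inclusion",
    "regress_confounds",
    "bandpass",
    "roi_coverage_filter",
    "compute_connectome",
    "build_connectome",
]


@dataclass
class PipelineConfig:
    """Preprocessing constants; defaults are the task-fMRI settings.

    ``min_volumes_strict`` selects the comparison used for subject
    inclusion: task rule "300 or more" is >= (strict=False), the
    resting-state rule "more than 130" is > (strict=True).
    """

    fd_threshold: float = 0.3  # mm; resting-state variant uses 0.4
    min_volumes: int = 300  # resting-state variant uses 130
    min_volumes_strict: bool = False
    scrub_before: int = 1
    scrub_after: int = 2
    bandpass_low: float = 0.009  # Hz
    bandpass_high: float = 0.1  # Hz
    tr_seconds: float = 2.0
    gsr: bool = False
    coverage_threshold: float = 0.5
    head_radius_mm: float = 50.0

    def validate(self) -> None:
        nyquist = 0.5 / self.tr_seconds
        if not (0 < self.bandpass_low < self.bandpass_high <= nyquist):
            raise ValueError(
                f"band ({self.bandpass_low}, {self.bandpass_high}) Hz invalid for "
                f"Nyquist {nyquist} Hz"
            )
        if self.fd_threshold <= 0:
            raise ValueError("fd_threshold must be > 0")


@dataclass
class Connectome:
    """Symmetric Fisher-z FC matrix over retained ROIs for one subject.

    The diagonal is undefined; it is stored as 0 and excluded from every
    downstream analysis.
    """

    labels: list[str]
    matrix: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("connectome matrix must be symmetric")
        off = self.matrix[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off)):
            raise ValueError("off-diagonal entries must be finite")

    def upper_triangle(self) -> np.ndarray:
        """Vector of the n(n-1)/2 unique connections (diagonal excluded)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.matrix[iu]


def framewise_displacement(trace: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Per-volume framewise displacement in mm.

    FD_t = sum |d translations| + head_radius * sum |d rotations|, with
    translations in mm (columns 0-2) and rotations in radians (3-5).
    FD_0 = 0 by convention.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"motion trace must be (n_volumes, 6), got {trace.shape}")
    if trace.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    if not np.all(np.isfinite(trace)):
        raise ValueError("motion trace contains non-finite values")
    diffs = np.abs(np.diff(trace, axis=0))
    fd = diffs[:, :3].sum(axis=1) + head_radius_mm * diffs[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scrub_mask(
    fd: np.ndarray, threshold: float, extend: tuple[int, int] = (1, 2)
) -> np.ndarray:
    """Boolean keep-mask after motion scrubbing.

    A volume is removed iff its FD exceeds ``threshold``, or it lies
    within ``extend[0]`` volumes before or ``extend[1]`` volumes after
    such a flagged volume (window clipped at the series ends).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    fd = np.asarray(fd, dtype=float)
    n = fd.size
    n_before, n_after = extend
    flagged = fd > threshold
    remove = np.zeros(n, dtype=bool)
    for t in np.flatnonzero(flagged):
        remove[max(0, t - n_before) : min(n, t + n_after + 1)] = True
    return ~remove


def subject_inclusion(keep_mask: np.ndarray, min_volumes: int, strict: bool = False) -> bool:
    """Inclusion rule on surviving volume count.

    ``strict=False`` implements "min_volumes or more" (>=, task rule at
    300); ``strict=True`` implements "more than min_volumes" (>, the
    resting-state rule at 130).
    """
    if min_volumes <= 0:
        raise ValueError("min_volumes must be > 0")
    n_kept = int(np.asarray(keep_mask, dtype=bool).sum())
    return n_kept > min_volumes if strict else n_kept >= min_volumes


def _motion_design(trace: np.ndarray) -> np.ndarray:
    """24-parameter motion set: 6 params, backward-difference derivatives
    (first row 0), and the squares of those 12."""
    deriv = np.vstack([np.zeros((1, 6)), np.diff(trace, axis=0)])
    base = np.hstack([trace, deriv])
    return np.hstack([base, base**2])


def regress_confounds(
    series: np.ndarray,
    trace: np.ndarray,
    wm_signal: np.ndarray,
    csf_signal: np.ndarray,
    gsr: bool = False,
) -> np.ndarray:
    """OLS residuals of each ROI series on the nuisance design.

    Design: intercept + 24 motion parameters + WM + CSF, plus the global
    mean signal when ``gsr``.  Collinear columns are dropped with a
    warning rather than failing.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    cols = [np.ones(n), *(c for c in _motion_design(np.asarray(trace, float)).T)]
    cols += [np.asarray(wm_signal, float), np.asarray(csf_signal, float)]
    if gsr:
        cols.append(series.mean(axis=1))
    design = np.column_stack(cols)
    if design.shape[0] != n:
        raise ValueError("confound regressors must match series length")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # drop collinear columns greedily, keeping the earliest of each group
        keep: list[int] = []
        for j in range(design.shape[1]):
            cand = design[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > len(keep):
                keep.append(j)
        warnings.warn(
            f"confound design rank-deficient: dropped {design.shape[1] - len(keep)} "
            "collinear columns"
        )
        log.warning("dropped %d collinear confound columns", design.shape[1] - len(keep))
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, series, rcond=None)
    return series - design @ beta


def bandpass(
    series: np.ndarray,
    low: float = 0.009,
    high: float = 0.1,
    tr_seconds: float = 2.0,
) -> np.ndarray:
    """Zero-phase ideal band-pass via a frequency-domain mask.

    Frequencies strictly inside [low, high] Hz are preserved; all others
    (including DC) are zeroed, so a constant series returns ~0.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[0]
    nyquist = 0.5 / tr_seconds
    if not (0 <= low < high <= nyquist):
        raise ValueError(f"cutoffs ({low}, {high}) invalid for Nyquist {nyquist} Hz")
    freqs = np.fft.rfftfreq(n, d=tr_seconds)
    mask = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(series, axis=0)
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=n, axis=0)


def roi_coverage_filter(
    coverage: np.ndarray, threshold: float = 0.5
) -> np.ndarray:
    """Indices of ROIs whose signal coverage fraction is >= threshold."""
    coverage = np.asarray(coverage, dtype=float)
    if np.any((coverage < 0) | (coverage > 1)):
        raise ValueError("coverage fractions must lie in [0, 1]")
    return np.flatnonzero(coverage >= threshold)


def compute_connectome(
    series: np.ndarray,
    keep_mask: np.ndarray | None = None,
    labels: list[str] | None = None,
    meta: dict | None = None,
) -> Connectome:
    """Pearson/Fisher-z connectome on the surviving volumes.

    r is clamped at +-(1 - 1e-7) before arctanh; the diagonal is stored
    as 0.  A zero-variance ROI is an error naming the ROI.
    """
    series = np.asarray(series, dtype=float)
    n_vol, n_roi = series.shape
    if n_roi < 2:
        raise ValueError("need at least 2 retained ROIs")
    if keep_mask is not None:
        series = series[np.asarray(keep_mask, dtype=bool)]
    if series.shape[0] < 3:
        raise ValueError("need at least 3 surviving volumes")
    labels = labels or [f"roi{j:03d}" for j in range(n_roi)]
    sd = series.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(f"zero-variance ROI(s): {[labels[j] for j in dead]}")
    r = np.corrcoef(series, rowvar=False)
    r = np.clip(r, -Z_CLAMP, Z_CLAMP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = 0.5 * (z + z.T)
    meta = dict(meta or {})
    meta.setdefault("n_volumes_used", int(series.shape[0]))
    return Connectome(labels=labels, matrix=z, meta=meta)


def build_connectome(
    series: np.ndarray,
    trace: np.ndarray,
    wm_signal: np.ndarray,
    csf_signal: np.ndarray,
    config: PipelineConfig,
    labels: list[str] | None = None,
    subject_id: str | None = None,
) -> tuple[Connectome | None, dict]:
    """Full chain for one subject: FD -> confounds -> band-pass -> scrub
    -> inclusion check -> connectome.

    Returns (connectome, report); connectome is None when the subject is
    excluded by the surviving-volume rule.  The report carries FD and
    scrubbing summaries either way.
    """
    config.validate()
    fd = framewise_displacement(trace, config.head_radius_mm)
    keep = scrub_mask(fd, config.fd_threshold, (config.scrub_before, config.scrub_after))
    report = {
        "subject_id": subject_id,
        "n_volumes": int(series.shape[0]),
        "n_volumes_used": int(keep.sum()),
        "mean_fd_pre": float(fd.mean()),
        "mean_fd_post": float(fd[keep].mean()) if keep.any() else float("nan"),
        "gsr": config.gsr,
        "included": subject_inclusion(keep, config.min_volumes, config.min_volumes_strict),
    }
    if not report["included"]:
        return None, report
    resid = regress_confounds(series, trace, wm_signal, csf_signal, gsr=config.gsr)
    filtered = bandpass(resid, config.bandpass_low, config.bandpass_high, config.tr_seconds)
    meta = {
        "subject_id": subject_id,
        "n_volumes_used": report["n_volumes_used"],
        "mean_fd_pre": report["mean_fd_pre"],
        "mean_fd_post": report["mean_fd_post"],
        "gsr": config.gsr,
    }
    conn = compute_connectome(filtered, keep, labels=labels, meta=meta)
    return conn, report
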