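"""Logan graphical analysis of PET time-activity curves.

Distribution volume ratios (DVR) are estimated non-invasively from a
target and a reference-region time-activity curve (TAC) as the slope of
the late-time Logan plot; binding potential is BP = DVR - 1.  The
reference region (cerebellum for dopamine D1 ligands) is assumed devoid
of specific binding, and its ROIs are excluded from downstream tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "BPEstimate",
    "default_schedule",
    "frame_midpoints",
    "cumulative_integral",
    "logan_dvr",
    "bp_from_dvr",
    "roi_bp_table",
]


@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frame timing in minutes."""

    start: np.ndarray  # frame start times, min
    duration: np.ndarray  # frame durations, min

    def __post_init__(self) -> None:
        start = np.asarray(self.start, dtype=float)
        duration = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", duration)
        if start.ndim != 1 or start.shape != duration.shape:
            raise ValueError("start and duration must be 1-D arrays of equal length")
        if start.size == 0:
            raise ValueError("empty frame schedule")
        if start[0] != 0.0:
            raise ValueError("frame schedule must start at t=0")
        if np.any(duration <= 0):
            raise ValueError("frame durations must be positive")
        ends = start + duration
        if not np.allclose(start[1:], ends[:-1]):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def total_minutes(self) -> float:
        return float(self.end[-1])

    def __len__(self) -> int:
        return self.start.size


def default_schedule() -> FrameSchedule:
    """18-frame, 54.6-min dynamic acquisition: 9x2, 3x3, 3x4.2, 3x5 min."""
    durations = np.concatenate(
        [np.full(9, 2.0), np.full(3, 3.0), np.full(3, 4.2), np.full(3, 5.0)]
    )
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return FrameSchedule(starts, durations)


@dataclass
class TimeActivityCurve:
    """Frame-averaged radioactivity for one ROI, decay-corrected to scan start."""

    schedule: FrameSchedule
    activity: np.ndarray  # per-frame mean activity, arbitrary units

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (len(self.schedule),):
            raise ValueError("activity length must match frame schedule")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite")


@dataclass
class BPEstimate:
    roi: str
    dvr: float
    bp: float
    r2: float
    n_points: int
    flagged_negative: bool = field(default=False)


def frame_midpoints(schedule: FrameSchedule) -> np.ndarray:
    """Frame midpoint times (min): start + duration / 2."""
    return schedule.start + schedule.duration / 2.0


def cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Trapezoidal running integral of the activity curve at frame midpoints.

    The piecewise curve is anchored at activity 0 at t=0 and linearly
    interpolated between frame midpoints; the integral to each midpoint
    accumulates the trapezoid areas.
    """
    mid = frame_midpoints(tac.schedule)
    t = np.concatenate([[0.0], mid])
    c = np.concatenate([[0.0], tac.activity])
    areas = 0.5 * (c[1:] + c[:-1]) * np.diff(t)
    return np.cumsum(areas)


def logan_dvr(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    window: tuple[float, float] = (18.0, 55.0),
    k2_ref: float | None = None,
) -> tuple[float, float, int]:
    """Logan-plot DVR from target and reference TACs.

    Returns (dvr, r2, n_points): the OLS slope of
    y = Int_0^t C_T / C_T(t)  against  x = Int_0^t C_ref / C_T(t)
    over frames whose midpoints fall inside ``window`` (minutes).
    By default no k2'-intercept correction is applied; passing the
    reference-region efflux constant ``k2_ref`` (1/min) switches to the
    corrected abscissa x = (Int_0^t C_ref + C_ref(t)/k2') / C_T(t), for
    sensitivity analyses.
    """
    if target.schedule is not reference.schedule and not (
        np.array_equal(target.schedule.start, reference.schedule.start)
        and np.array_equal(target.schedule.duration, reference.schedule.duration)
    ):
        raise ValueError("target and reference must share a frame schedule")
    mid = frame_midpoints(target.schedule)
    in_win = (mid >= window[0]) & (mid <= window[1])
    if in_win.sum() < 3:
        raise ValueError(
            f"need >= 3 frame midpoints in window {window}, got {int(in_win.sum())}"
        )
    ct = target.activity[in_win]
    if np.any(ct == 0):
        raise ValueError("target activity is zero inside the Logan window")
    int_t = cumulative_integral(target)[in_win]
    int_r = cumulative_integral(reference)[in_win]
    if k2_ref is not None:
        if k2_ref <= 0:
            raise ValueError("k2_ref must be positive")
        int_r = int_r + reference.activity[in_win] / k2_ref
    y = int_t / ct
    x = int_r / ct
    x_c = x - x.mean()
    sxx = float(x_c @ x_c)
    if sxx <= 0 or not np.isfinite(sxx):
        raise ValueError("degenerate Logan abscissa (zero variance)")
    slope = float(x_c @ (y - y.mean())) / sxx
    resid = y - y.mean() - slope * x_c
    syy = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 1.0
    return slope, r2, int(in_win.sum())


def bp_from_dvr(dvr: float) -> float:
    """Binding potential from distribution volume ratio: BP = DVR - 1."""
    if not np.isfinite(dvr):
        raise ValueError("dvr must be finite")
    return dvr - 1.0


def roi_bp_table(
    tacs: dict[str, TimeActivityCurve],
    reference: TimeActivityCurve,
    cerebellar_rois: list[str] | None = None,
    window: tuple[float, float] = (18.0, 55.0),
) -> pd.DataFrame:
    """BP per non-cerebellar ROI.

    ROIs listed in ``cerebellar_rois`` are dropped: the cerebellum serves
    as the reference region and must not appear in its own output.
    Negative BP values (possible under noise) are kept but flagged.
    """
    cerebellar = set(cerebellar_rois or [])
    rows = []
    for roi in tacs:
        if roi in cerebellar:
            continue
        dvr, r2, n = logan_dvr(tacs[roi], reference, window=window)
        bp = bp_from_dvr(dvr)
        rows.append(
            {
                "roi": roi,
                "dvr": dvr,
                "bp": bp,
                "r2": r2,
                "n_points": n,
                "flagged_negative": bp < 0,
            }
        )
    return pd.DataFrame(rows, columns=["roi", "dvr", "bp", "r2", "n_points", "flagged_negative"])
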