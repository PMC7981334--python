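"""Plain-text readers and writers for the pipeline's file formats.

All formats are TSV or whitespace-delimited text: subject tables, ROI
time series (rows = volumes, columns = ROI labels), 6-column motion
traces (3 translations in mm, 3 rotations in radians), square
connectome matrices with ROI-label header row/column plus a JSON
metadata sidecar, long-format ground-truth and fit tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import Connectome
from .synthetic import EdgeTruth

__all__ = [
    "write_subject_table",
    "read_subject_table",
    "write_series",
    "read_series",
    "write_motion",
    "read_motion",
    "write_connectome",
    "read_connectome",
    "write_edge_truth",
    "read_edge_truth",
]


def write_subject_table(subjects: pd.DataFrame, path: str | Path) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def read_subject_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"subject_id", "age", "group", "sex", "mean_fd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    return df


def write_series(series: np.ndarray, labels: list[str], path: str | Path) -> None:
    pd.DataFrame(series, columns=labels).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_series(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_motion(trace: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(trace, float), fmt="%.8g")


def read_motion(path: str | Path) -> np.ndarray:
    trace = np.loadtxt(path)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(f"motion file must have 6 columns, got shape {trace.shape}")
    return trace


def write_connectome(conn: Connectome, path: str | Path) -> None:
    """Square TSV with label header/index plus a .json metadata sidecar."""
    path = Path(path)
    pd.DataFrame(conn.matrix, index=conn.labels, columns=conn.labels).to_csv(
        path, sep="\t", float_format="%.8g"
    )
    path.with_suffix(".json").write_text(json.dumps(conn.meta, indent=1))


def read_connectome(path: str | Path) -> Connectome:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    mat = df.to_numpy(dtype=float)
    return Connectome(labels=list(df.columns), matrix=0.5 * (mat + mat.T), meta=meta)


def write_edge_truth(truth: list[EdgeTruth], path: str | Path) -> None:
    pd.DataFrame(
        {
            "node_i": [e.node_i for e in truth],
            "node_j": [e.node_j for e in truth],
            "alpha_mu": [e.alpha_mu for e in truth],
            "beta_mu": [e.beta_mu for e in truth],
            "alpha_sigma": [e.alpha_sigma for e in truth],
            "beta_sigma": [e.beta_sigma for e in truth],
            "rho": [e.rho for e in truth],
        }
    ).to_csv(path, sep="\t", index=False)


def read_edge_truth(path: str | Path) -> list[EdgeTruth]:
    df = pd.read_csv(path, sep="\t")
    return [
        EdgeTruth(
            int(r.node_i), int(r.node_j), r.alpha_mu, r.beta_mu,
            r.alpha_sigma, r.beta_sigma, r.rho,
        )
        for r in df.itertuples()
    ]
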