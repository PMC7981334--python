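"""Connectome similarity, group summaries, MDS, and edge-removal curves.

Similarity between two subjects' connectomes is the Pearson correlation
of their upper-triangle Fisher-z vectors (diagonal excluded).  Pairwise
similarities are arranged subject x subject ordered by age; aging shows
up as lower within-old and between-group similarity.  Classical
(Torgerson) multidimensional scaling embeds subjects in the plane from
dissimilarities 1 - similarity.  The removal analysis deletes the
connections with the largest aging effects and tracks how the group
similarity structure collapses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import Connectome

__all__ = [
    "SimilarityMatrix",
    "GroupSimilaritySummary",
    "connectome_similarity",
    "similarity_matrix",
    "group_similarity_summary",
    "classical_mds",
    "connection_removal_curve",
]


@dataclass
class SimilarityMatrix:
    """Pairwise connectome similarities, subjects sorted by age."""

    subject_ids: list[str]
    ages: np.ndarray
    groups: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.subject_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")


@dataclass
class GroupSimilaritySummary:
    """Mean pair similarities within and between age groups.

    ``t_yy_oo``/``p_yy_oo`` compare the within-young and within-old pair
    sets, ``t_oo_yo``/``p_oo_yo`` the within-old and between-group sets
    (Welch two-sample t tests on pair similarities; pairs sharing a
    subject are not independent, so the p values are descriptive, as in
    the procedure this mirrors).
    """

    mean_yy: float
    mean_oo: float
    mean_yo: float
    diff_yy_oo: float
    diff_oo_yo: float
    t_yy_oo: float
    p_yy_oo: float
    t_oo_yo: float
    p_oo_yo: float
    n_yy: int
    n_oo: int
    n_yo: int


def _upper(matrix: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]


def connectome_similarity(c1: Connectome, c2: Connectome) -> float:
    """Pearson correlation over the unique-connection vectors of two subjects."""
    if c1.labels != c2.labels:
        raise ValueError("connectomes must share an identical ROI label list")
    return float(np.corrcoef(c1.upper_triangle(), c2.upper_triangle())[0, 1])


def similarity_matrix(
    connectomes: list[Connectome],
    subjects: pd.DataFrame,
) -> SimilarityMatrix:
    """All-pairs similarity, subjects sorted ascending by age.

    ``subjects`` needs columns subject_id, age, group and one row per
    connectome (matched on the connectome's subject_id metadata).
    """
    if len(connectomes) < 2:
        raise ValueError("need at least 2 subjects")
    by_id = {c.meta.get("subject_id"): c for c in connectomes}
    sub = subjects[subjects["subject_id"].isin(by_id)].sort_values("age", kind="stable")
    ids = sub["subject_id"].tolist()
    vecs = np.vstack([by_id[i].upper_triangle() for i in ids])
    mat = np.corrcoef(vecs)
    mat = 0.5 * (mat + mat.T)
    np.fill_diagonal(mat, 1.0)
    return SimilarityMatrix(
        subject_ids=ids,
        ages=sub["age"].to_numpy(),
        groups=sub["group"].tolist(),
        matrix=mat,
    )


def _pair_sets(groups: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    g = np.asarray(groups)
    iu = np.triu_indices(g.size, k=1)
    young = g == "younger"
    yy = young[iu[0]] & young[iu[1]]
    oo = ~young[iu[0]] & ~young[iu[1]]
    yo = ~(yy | oo)
    return yy, oo, yo


def group_similarity_summary(
    sim: SimilarityMatrix, groups: list[str] | None = None
) -> GroupSimilaritySummary:
    """Within-young, within-old and between-group mean pair similarities,
    with Welch t tests on the YY-vs-OO and OO-vs-YO pair sets."""
    groups = groups if groups is not None else sim.groups
    g = np.asarray(groups)
    for name in ("younger", "older"):
        if (g == name).sum() < 2:
            raise ValueError(f"group {name!r} needs >= 2 members for within-group pairs")
    vals = _upper(sim.matrix)
    yy, oo, yo = _pair_sets(list(g))
    s_yy, s_oo, s_yo = vals[yy], vals[oo], vals[yo]
    t1, p1 = stats.ttest_ind(s_yy, s_oo, equal_var=False)
    t2, p2 = stats.ttest_ind(s_oo, s_yo, equal_var=False)
    return GroupSimilaritySummary(
        mean_yy=float(s_yy.mean()),
        mean_oo=float(s_oo.mean()),
        mean_yo=float(s_yo.mean()),
        diff_yy_oo=float(s_yy.mean() - s_oo.mean()),
        diff_oo_yo=float(s_oo.mean() - s_yo.mean()),
        t_yy_oo=float(t1),
        p_yy_oo=float(p1),
        t_oo_yo=float(t2),
        p_oo_yo=float(p2),
        n_yy=int(yy.sum()),
        n_oo=int(oo.sum()),
        n_yo=int(yo.sum()),
    )


def classical_mds(
    sim: SimilarityMatrix | np.ndarray, n_dims: int = 2
) -> np.ndarray:
    """Torgerson classical MDS coordinates.

    A SimilarityMatrix is converted to dissimilarities d = 1 - s; a
    plain array is taken as dissimilarities directly.  Coordinates are
    the top-``n_dims`` eigenvectors of the double-centered squared
    dissimilarity matrix scaled by sqrt(eigenvalue); negative
    eigenvalues are truncated to 0.
    """
    if isinstance(sim, SimilarityMatrix):
        d = 1.0 - sim.matrix
    else:
        d = np.asarray(sim, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 subjects for MDS")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = 0.5 * (b + b.T)
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    n_pos = int((w > 1e-12).sum())
    if n_pos < n_dims:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} dimensions"
        )
    k = min(n_dims, max(n_pos, 0))
    return v[:, :k] * np.sqrt(np.clip(w[:k], 0.0, None))


def connection_removal_curve(
    connectomes: list[Connectome],
    subjects: pd.DataFrame,
    ranking: np.ndarray,
    fractions: list[float],
    rank_abs: bool = True,
) -> pd.DataFrame:
    """Group similarity after deleting the top-ranked connections.

    ``ranking`` holds one value per unique connection (upper-triangle
    order); for each fraction f the top f of connections by |ranking|
    (or raw ranking when ``rank_abs=False``) are removed, ties broken by
    edge index, and the group similarity summary is recomputed on the
    remaining connections.  f = 1 is rejected (no edges would remain).
    """
    ranking = np.asarray(ranking, dtype=float)
    by_id = {c.meta.get("subject_id"): c for c in connectomes}
    sub = subjects[subjects["subject_id"].isin(by_id)].sort_values("age", kind="stable")
    ids = sub["subject_id"].tolist()
    vecs = np.vstack([by_id[i].upper_triangle() for i in ids])
    n_edges = vecs.shape[1]
    if ranking.shape != (n_edges,):
        raise ValueError("ranking must cover every connection")
    key = np.abs(ranking) if rank_abs else ranking
    # descending by key, ties by edge index: stable sort on negated key
    order = np.argsort(-key, kind="stable")
    rows = []
    for f in fractions:
        if not (0 <= f < 1):
            raise ValueError(f"fraction must be in [0, 1), got {f}")
        n_remove = int(round(f * n_edges))
        keep = np.ones(n_edges, dtype=bool)
        keep[order[:n_remove]] = False
        sub_vecs = vecs[:, keep]
        mat = np.corrcoef(sub_vecs)
        np.fill_diagonal(mat, 1.0)
        sm = SimilarityMatrix(
            subject_ids=ids,
            ages=sub["age"].to_numpy(),
            groups=sub["group"].tolist(),
            matrix=0.5 * (mat + mat.T),
        )
        summ = group_similarity_summary(sm)
        rows.append(
            {
                "fraction_removed": f,
                "n_edges_left": int(keep.sum()),
                "mean_yy": summ.mean_yy,
                "mean_oo": summ.mean_oo,
                "mean_yo": summ.mean_yo,
                "diff_yy_oo": summ.diff_yy_oo,
                "diff_yy_yo": summ.mean_yy - summ.mean_yo,
            }
        )
    return pd.DataFrame(rows)
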