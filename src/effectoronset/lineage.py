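"""Lineage-restriction calling from cluster-averaged single-cell expression.

At the early gastrula stage the sea urchin embryo comprises seven cell
lineages: apical ectoderm, nonapical ectoderm, Veg1 ectoderm, Veg1/2
endoderm, nonskeletogenic mesoderm (NSM), skeletogenic cells and germline
(Veg1 and Veg2 endoderm are not separable in the single-cell data and are
treated as one lineage). A gene counts as expressed in a lineage when the
average normalized expression of that lineage's *representative* cluster —
the member cluster with the highest average — strictly exceeds a cutoff
(default 0.3). Genes expressed in 0 lineages are *undetected*, in all 7
*ubiquitous* (housekeeping-like), and in 1–6 *restricted*: the restricted
set is the tissue-specific effector candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Canonical order of the seven early-gastrula cell lineages.
LINEAGES: tuple[str, ...] = (
    "apical_ectoderm",
    "nonapical_ectoderm",
    "veg1_ectoderm",
    "veg12_endoderm",
    "NSM",
    "skeletogenic",
    "germline",
)

#: Default early-gastrula cluster -> lineage assignment (15 clusters).
DEFAULT_EG_CLUSTER_LINEAGES: dict[str, str] = {
    "0": "veg1_ectoderm",
    "1": "veg1_ectoderm",
    "5": "veg1_ectoderm",
    "6": "veg1_ectoderm",
    "2": "nonapical_ectoderm",
    "3": "nonapical_ectoderm",
    "8": "nonapical_ectoderm",
    "9": "nonapical_ectoderm",
    "4": "veg12_endoderm",
    "7": "veg12_endoderm",
    "10": "NSM",
    "14": "NSM",
    "11": "apical_ectoderm",
    "12": "skeletogenic",
    "13": "germline",
}

LINEAGE_CALL_CATEGORIES = ("undetected", "restricted", "ubiquitous")


@dataclass(frozen=True)
class LineageMap:
    """cluster id -> lineage, with optional clusters excluded from calling."""

    mapping: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_EG_CLUSTER_LINEAGES)
    )
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = {lin for lin in self.mapping.values() if lin not in LINEAGES}
        if bad:
            raise ValueError(f"unknown lineages in map: {sorted(bad)}; allowed: {LINEAGES}")

    def clusters_of(self, lineage: str) -> list[str]:
        return sorted(
            (c for c, lin in self.mapping.items() if lin == lineage),
            key=_cluster_sort_key,
        )

    @property
    def lineages_present(self) -> tuple[str, ...]:
        present = set(self.mapping.values())
        return tuple(lin for lin in LINEAGES if lin in present)


def _cluster_sort_key(cluster_id: str):
    """Numeric-first ordering so 'lowest cluster id' means 2 < 10, not '10' < '2'."""
    s = str(cluster_id)
    return (0, int(s), s) if s.isdigit() else (1, 0, s)


def average_by_cluster(
    cells: pd.DataFrame, assignments: pd.Series
) -> pd.DataFrame:
    """Average a genes x cells matrix within clusters -> genes x clusters.

    Parameters
    ----------
    cells
        Normalized expression, genes as index, cell ids as columns.
    assignments
        cell id -> cluster id; must cover every column of ``cells`` and every
        cluster must contain at least one cell of the matrix.
    """
    missing = [c for c in cells.columns if c not in assignments.index]
    if missing:
        raise ValueError(f"{len(missing)} cells lack a cluster assignment: {missing[:10]}")
    assign = assignments.loc[cells.columns].astype(str)
    empty = sorted(set(assignments.astype(str)) - set(assign), key=_cluster_sort_key)
    if empty:
        raise ValueError(f"empty cluster(s) with no cells in the matrix: {empty}")
    averages = cells.T.groupby(assign).mean().T
    averages.columns = [str(c) for c in averages.columns]
    averages.index.name = cells.index.name or "gene_id"
    return averages


def call_lineages(
    matrix: pd.DataFrame,
    lmap: LineageMap | None = None,
    threshold: float = 0.3,
) -> pd.DataFrame:
    """Per-gene lineage-expression calls from cluster averages.

    For each lineage the representative cluster is the member with the highest
    average for that gene (ties go to the lowest cluster id); the lineage is
    flagged expressed iff the representative average is strictly greater than
    ``threshold``.

    Returns a frame indexed by gene with, per lineage, ``expressed_<lineage>``
    (bool) and ``rep_cluster_<lineage>``, plus ``n_lineages``, ``category``
    (undetected / restricted / ubiquitous) and ``lineage_set`` (pipe-joined in
    canonical lineage order; empty string when undetected).
    """
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    lmap = lmap or LineageMap()
    known = set(lmap.mapping) | set(lmap.excluded)
    stray = sorted(set(map(str, matrix.columns)) - known, key=_cluster_sort_key)
    if stray:
        raise ValueError(f"matrix clusters not in the lineage map: {stray}")

    mat = matrix.copy()
    mat.columns = [str(c) for c in mat.columns]
    lineages = lmap.lineages_present
    out = pd.DataFrame(index=mat.index)
    expressed_cols = []
    for lin in lineages:
        clusters = [c for c in lmap.clusters_of(lin) if c in mat.columns]
        if not clusters:
            out[f"expressed_{lin}"] = False
            out[f"rep_cluster_{lin}"] = ""
            continue
        sub = mat[clusters]
        # idxmax on the numeric-sorted column order implements the tie rule
        rep = sub.idxmax(axis=1)
        rep_value = sub.max(axis=1)
        out[f"expressed_{lin}"] = rep_value > threshold
        out[f"rep_cluster_{lin}"] = rep
        expressed_cols.append(f"expressed_{lin}")

    flags = out[expressed_cols] if expressed_cols else pd.DataFrame(index=mat.index)
    n_total = len(LINEAGES)
    out["n_lineages"] = flags.sum(axis=1).astype(int) if expressed_cols else 0
    out["category"] = np.select(
        [out["n_lineages"] == 0, out["n_lineages"] == n_total],
        ["undetected", "ubiquitous"],
        default="restricted",
    )
    out["lineage_set"] = [
        "|".join(lin for lin in lineages if row.get(f"expressed_{lin}", False))
        for _, row in out.iterrows()
    ]
    out.index.name = matrix.index.name or "gene_id"
    return out


def lineage_set_of(calls: pd.DataFrame, gene_id: str) -> frozenset[str]:
    """The set of lineages a gene was called expressed in."""
    raw = calls.loc[gene_id, "lineage_set"]
    return frozenset(raw.split("|")) if raw else frozenset()


def summarize_distribution(matrix: pd.DataFrame) -> pd.DataFrame:
    """Median and third quartile of gene-wise averages, per cluster.

    Quartiles use linear interpolation, so e.g. values {1,2,3,4} give
    median 2.5 and Q3 3.25.
    """
    if matrix.shape[0] < 1:
        raise ValueError("need at least one gene to summarize")
    med = matrix.quantile(0.5, axis=0, interpolation="linear")
    q3 = matrix.quantile(0.75, axis=0, interpolation="linear")
    out = pd.DataFrame({"median": med, "q3": q3})
    out.index = [str(c) for c in out.index]
    out.index.name = "cluster_id"
    return out
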