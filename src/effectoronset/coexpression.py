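"""Cell-level coexpression of effector-gene pairs in shared precursor clusters.

Effector genes of two different lineages (e.g. Veg2 endoderm and NSM) can
already be co-active in the common precursor cells (Veg2 blastomeres) at the
earlier, early-blastula stage — before the lineages segregate. This module
quantifies that with an explicit count: within a precursor cluster, the
fraction of cells whose normalized expression of *both* genes exceeds a
threshold (default 0, i.e. any detected expression).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class CoexpressionResult:
    gene_a: str
    gene_b: str
    precursor_cluster: str
    n_cells: int
    n_expressing_a: int
    n_expressing_b: int
    n_coexpressing: int
    fraction_coexpressing: float


def coexpression_in_cluster(
    cells: pd.DataFrame,
    assignments: pd.Series,
    gene_a: str,
    gene_b: str,
    cluster: str,
    expressed_min: float = 0.0,
) -> CoexpressionResult:
    """Count cells of one cluster expressing gene_a, gene_b and both.

    A cell expresses a gene iff its normalized value is strictly greater than
    ``expressed_min``. ``cells`` is genes x cells; ``assignments`` maps cell id
    to cluster id.
    """
    for g in (gene_a, gene_b):
        if g not in cells.index:
            raise KeyError(f"gene {g!r} not in the expression matrix")
    members = assignments.index[assignments.astype(str) == str(cluster)]
    members = [c for c in members if c in cells.columns]
    if not members:
        raise KeyError(f"cluster {cluster!r} has no cells in the matrix")
    a = cells.loc[gene_a, members].astype(float) > expressed_min
    b = cells.loc[gene_b, members].astype(float) > expressed_min
    n_co = int((a & b).sum())
    return CoexpressionResult(
        gene_a=gene_a,
        gene_b=gene_b,
        precursor_cluster=str(cluster),
        n_cells=len(members),
        n_expressing_a=int(a.sum()),
        n_expressing_b=int(b.sum()),
        n_coexpressing=n_co,
        fraction_coexpressing=n_co / len(members),
    )


def screen_precursor_coexpression(
    cells_early: pd.DataFrame,
    assignments: pd.Series,
    lineage_calls: pd.DataFrame,
    precursor_map: Mapping[tuple[str, str], Sequence[str]],
    expressed_min: float = 0.0,
) -> pd.DataFrame:
    """Coexpression of all single-lineage effector pairs sharing a precursor.

    ``lineage_calls`` is the later-stage call table (see
    :func:`effectoronset.lineage.call_lineages`); only genes restricted to a
    single lineage are paired. ``precursor_map`` assigns to an unordered
    lineage pair the precursor cluster id(s) at the earlier stage, e.g.
    ``{("veg12_endoderm", "NSM"): ["7"]}``. Genes absent from the early-stage
    matrix are skipped. Pairs are enumerated with ``gene_a < gene_b``; the
    result has one row per (pair, precursor cluster), sorted by descending
    coexpression fraction (ties by gene ids for determinism).
    """
    singles = lineage_calls[lineage_calls["n_lineages"] == 1]
    by_lineage: dict[str, list[str]] = {}
    for g, lin in singles["lineage_set"].items():
        if g in cells_early.index:
            by_lineage.setdefault(lin, []).append(g)

    norm_map = {frozenset(pair): list(clusters) for pair, clusters in precursor_map.items()}
    rows: list[CoexpressionResult] = []
    for pair_key, clusters in norm_map.items():
        lin_a, lin_b = sorted(pair_key)
        genes_a = by_lineage.get(lin_a, [])
        genes_b = by_lineage.get(lin_b, [])
        for ga, gb in ((x, y) for x in genes_a for y in genes_b):
            a, b = sorted((ga, gb))
            for cluster in clusters:
                rows.append(
                    coexpression_in_cluster(
                        cells_early, assignments, a, b, cluster, expressed_min
                    )
                )
    out = pd.DataFrame([asdict(r) for r in rows]) if rows else pd.DataFrame(
        columns=[f.name for f in CoexpressionResult.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    )
    if len(out):
        out = out.sort_values(
            ["fraction_coexpressing", "gene_a", "gene_b", "precursor_cluster"],
            ascending=[False, True, True, True],
            ignore_index=True,
        )
    return out
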