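"""Domain-based regulatory/effector partitioning and reciprocal-best-hit orthology.

The first two stages of the screening cascade:

1. Partition a gene catalog into *regulatory* genes (any significant hit to a
   curated TF or signaling Pfam accession) and *candidate effector* genes.
2. Build a cross-species ortholog map from two directional protein hit tables
   (BLAST tabular style) by reciprocal best hits (RBH), and restrict the
   candidate pool to genes with an ortholog.

Hit tables are plain :class:`pandas.DataFrame` objects; see :mod:`effectoronset.io`
for the file readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .domains import RegulatoryDomainList, strip_accession_version

DOMAIN_HIT_COLUMNS = ("gene_id", "domain_accession", "evalue", "score")
PAIRWISE_HIT_COLUMNS = ("query_id", "subject_id", "bitscore", "evalue")


@dataclass(frozen=True)
class GeneCatalog:
    """An ordered catalog of gene-model identifiers for one species."""

    species: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dups = sorted({g for g in self.gene_ids if g in seen or seen.add(g)})
            raise ValueError(f"duplicate gene ids in {self.species} catalog: {dups[:10]}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene_id: object) -> bool:
        return gene_id in set(self.gene_ids)


@dataclass(frozen=True)
class RegulatoryPartition:
    """Exhaustive, disjoint split of a catalog into regulatory vs candidates."""

    regulatory_ids: tuple[str, ...]
    candidate_ids: tuple[str, ...]
    reasons: Mapping[str, str]  # gene_id -> tf | signaling | both | none

    def reason_of(self, gene_id: str) -> str:
        return self.reasons[gene_id]


def classify_regulatory(
    catalog: GeneCatalog,
    hits: pd.DataFrame,
    domains: RegulatoryDomainList | None = None,
    evalue_max: float = 1e-5,
) -> RegulatoryPartition:
    """Flag genes with a significant hit to a listed TF/signaling domain.

    A gene is *regulatory* iff it has at least one domain hit whose accession
    (version-stripped) is on either curated list and whose E-value is
    ``<= evalue_max``. Both output id tuples preserve catalog order, and
    every catalog gene appears in exactly one of them.

    Raises
    ------
    ValueError
        If ``evalue_max`` is not positive, or the hit table references gene
        ids absent from the catalog (all offenders are listed).
    """
    if evalue_max <= 0:
        raise ValueError(f"evalue_max must be > 0, got {evalue_max}")
    domains = domains or RegulatoryDomainList()

    hits = _normalize_columns(hits, DOMAIN_HIT_COLUMNS)
    known = set(catalog.gene_ids)
    unknown = sorted(set(hits["gene_id"]) - known)
    if unknown:
        raise ValueError(
            f"domain hits reference {len(unknown)} gene ids not in the "
            f"{catalog.species} catalog: {unknown[:20]}"
        )

    sig_hits = hits[hits["evalue"].astype(float) <= evalue_max]
    bare = sig_hits["domain_accession"].map(strip_accession_version)
    tf_genes = set(sig_hits.loc[bare.isin(domains.tf_bare), "gene_id"])
    sig_genes = set(sig_hits.loc[bare.isin(domains.signaling_bare), "gene_id"])

    reasons: dict[str, str] = {}
    regulatory: list[str] = []
    candidates: list[str] = []
    for g in catalog.gene_ids:
        in_tf, in_sig = g in tf_genes, g in sig_genes
        if in_tf and in_sig:
            reasons[g] = "both"
        elif in_tf:
            reasons[g] = "tf"
        elif in_sig:
            reasons[g] = "signaling"
        else:
            reasons[g] = "none"
        (regulatory if in_tf or in_sig else candidates).append(g)
    return RegulatoryPartition(tuple(regulatory), tuple(candidates), reasons)


def best_hits(hits: pd.DataFrame) -> pd.Series:
    """Best subject per query: max bitscore, then min E-value, then smallest id.

    Multiple rows for one (query, subject) pair — e.g. several HSPs — are first
    reduced to the single best row under the same ordering, so duplicate HSPs
    can never outvote a stronger hit.
    """
    hits = _normalize_columns(hits, PAIRWISE_HIT_COLUMNS)
    if hits.empty:
        return pd.Series(dtype=object, name="subject_id")
    ordered = hits.sort_values(
        ["query_id", "bitscore", "evalue", "subject_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    # pair-level reduction then query-level selection collapse to the same
    # first row per query under this lexicographic ordering
    top = ordered.drop_duplicates("query_id", keep="first")
    return top.set_index("query_id")["subject_id"]


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> pd.DataFrame:
    """Ortholog pairs (a, b) where each is the other's top-scoring hit.

    Returns a two-column frame ``(species_a_id, species_b_id)`` sorted by
    ``species_a_id``. The result is a matching: no id occurs twice, because
    each query has exactly one best hit. Row order of the inputs is irrelevant.
    """
    best_ab = best_hits(hits_ab)
    best_ba = best_hits(hits_ba)
    pairs = [
        (a, b)
        for a, b in best_ab.items()
        if best_ba.get(b) == a
    ]
    out = pd.DataFrame(pairs, columns=["species_a_id", "species_b_id"])
    return out.sort_values("species_a_id", ignore_index=True)


def ortholog_dict(ortholog_map: pd.DataFrame, direction: str = "ab") -> dict[str, str]:
    """Mapping view of an RBH table; ``direction`` is ``"ab"`` or ``"ba"``."""
    if direction == "ab":
        return dict(zip(ortholog_map["species_a_id"], ortholog_map["species_b_id"]))
    if direction == "ba":
        return dict(zip(ortholog_map["species_b_id"], ortholog_map["species_a_id"]))
    raise ValueError(f"direction must be 'ab' or 'ba', got {direction!r}")


def restrict_to_orthologs(
    candidate_ids: Sequence[str], ortholog_map: pd.DataFrame
) -> list[str]:
    """Keep only candidates that have an ortholog partner, preserving order."""
    mapped = set(ortholog_map["species_a_id"])
    return [g for g in candidate_ids if g in mapped]


def _normalize_columns(df: pd.DataFrame, required: Iterable[str]) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"hit table is missing columns {missing}; has {list(df.columns)}")
    return df
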