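"""Readers and writers for the pipeline's plain-text interchange formats.

Everything is tab-separated text or JSON/YAML:

* gene catalogs — one id per line, or FASTA (ids taken from record headers);
* pairwise protein hits — BLAST tabular (``-outfmt 6``) with the standard
  12 columns;
* domain hits — 4-column TSV ``gene_id, domain_accession, evalue, score``,
  or HMMER ``--tblout`` via ``dialect="tblout"``;
* expression matrices — TSV with ``gene_id`` first column; temporal matrices
  use hour-labelled columns ``h0, h6, ..., h30``; the cell-level matrix can
  also round-trip through MatrixMarket with sidecar row/column files;
* lineage maps — YAML mapping or 2-column TSV ``cluster_id, lineage``.
"""

from __future__ import annotations

import json
from pathlib import Path
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .lineage import LineageMap
from .screen import GeneCatalog

BLAST6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------- catalogs

def read_gene_catalog(path: str | Path, species: str = "") -> GeneCatalog:
    """Read gene ids from a one-id-per-line text file or a FASTA file."""
    path = Path(path)
    species = species or path.stem
    if path.suffix.lower() in {".fa", ".fasta", ".faa"}:
        from Bio import SeqIO

        ids = [rec.id for rec in SeqIO.parse(str(path), "fasta")]
    else:
        ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return GeneCatalog(species=species, gene_ids=tuple(ids))


def write_gene_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in catalog.gene_ids))


# ------------------------------------------------------------- hit tables

def read_blast6(path: str | Path) -> pd.DataFrame:
    """BLAST ``-outfmt 6`` TSV -> pairwise hit frame (query/subject/bitscore/evalue)."""
    raw = pd.read_csv(path, sep="\t", header=None, names=BLAST6_COLUMNS, comment="#")
    return pd.DataFrame(
        {
            "query_id": raw["qseqid"].astype(str),
            "subject_id": raw["sseqid"].astype(str),
            "bitscore": raw["bitscore"].astype(float),
            "evalue": raw["evalue"].astype(float),
        }
    )


def write_blast6(hits: pd.DataFrame, path: str | Path) -> None:
    """Write a pairwise hit frame as 12-column BLAST tabular (dummy alignment columns)."""
    n = len(hits)
    full = pd.DataFrame(
        {
            "qseqid": hits["query_id"].to_numpy(),
            "sseqid": hits["subject_id"].to_numpy(),
            "pident": [100.0] * n,
            "length": [100] * n,
            "mismatch": [0] * n,
            "gapopen": [0] * n,
            "qstart": [1] * n,
            "qend": [100] * n,
            "sstart": [1] * n,
            "send": [100] * n,
            "evalue": hits["evalue"].to_numpy(),
            "bitscore": hits["bitscore"].to_numpy(),
        }
    )
    full.to_csv(path, sep="\t", header=False, index=False, float_format=FLOAT_FORMAT)


def read_domain_hits(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Domain hit table; ``dialect="tblout"`` accepts HMMER per-target output.

    In ``--tblout`` the target is the sequence (gene) and the query is the
    profile, with full-sequence E-value and score in columns 5-6.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "domain_accession", "evalue", "score"}
        if not required <= set(df.columns):
            raise ValueError(f"domain-hit TSV must have columns {sorted(required)}")
        return df[["gene_id", "domain_accession", "evalue", "score"]].astype(
            {"gene_id": str, "domain_accession": str, "evalue": float, "score": float}
        )
    if dialect == "tblout":
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            rows.append(
                {
                    "gene_id": parts[0],
                    "domain_accession": parts[3],
                    "evalue": float(parts[4]),
                    "score": float(parts[5]),
                }
            )
        return pd.DataFrame(rows, columns=["gene_id", "domain_accession", "evalue", "score"])
    raise ValueError(f"unknown domain-hit dialect {dialect!r}")


def write_domain_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ------------------------------------------------------ expression matrices

def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x columns TSV, first column ``gene_id``; column labels kept as str."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = [str(c) for c in df.columns]
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_temporal_matrix(path: str | Path) -> pd.DataFrame:
    """Temporal FPKM TSV with columns ``h0, h6, ...`` -> integer-hour columns."""
    df = read_expression_matrix(path)
    try:
        df.columns = [int(str(c).lstrip("hH")) for c in df.columns]
    except ValueError as err:
        raise ValueError(f"temporal columns must look like 'h0', 'h6', ...: {err}") from err
    return df


def write_temporal_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.columns = [f"h{int(c)}" for c in out.columns]
    write_expression_matrix(out, path)


def write_cell_matrix_mtx(
    cells: pd.DataFrame, prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write a genes x cells matrix as MatrixMarket + row/column sidecars.

    Produces ``<prefix>.mtx``, ``<prefix>.genes.txt`` and ``<prefix>.cells.txt``.
    """
    prefix = Path(prefix)
    mtx = prefix.with_suffix(".mtx")
    genes = prefix.parent / f"{prefix.name}.genes.txt"
    cellf = prefix.parent / f"{prefix.name}.cells.txt"
    spio.mmwrite(str(mtx), sparse.csr_matrix(cells.to_numpy(dtype=float)))
    genes.write_text("".join(f"{g}\n" for g in cells.index))
    cellf.write_text("".join(f"{c}\n" for c in cells.columns))
    return mtx, genes, cellf


def read_cell_matrix_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx"))).toarray()
    genes = (prefix.parent / f"{prefix.name}.genes.txt").read_text().split()
    cells = (prefix.parent / f"{prefix.name}.cells.txt").read_text().split()
    df = pd.DataFrame(mat, index=genes, columns=cells)
    df.index.name = "gene_id"
    return df


def read_cluster_assignments(path: str | Path) -> pd.Series:
    """2-column TSV ``cell_id, cluster_id`` -> Series cell -> cluster (str)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("cluster assignment TSV needs columns cell_id, cluster_id")
    return df.set_index(df.columns[0])[df.columns[1]].astype(str)


def write_cluster_assignments(assignments: pd.Series, path: str | Path) -> None:
    df = assignments.rename("cluster_id").rename_axis("cell_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ lineage maps

def read_lineage_map(path: str | Path) -> LineageMap:
    """Lineage map from YAML (``mapping:``/``excluded:`` or flat dict) or TSV."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(path.read_text())
        if "mapping" in data:
            return LineageMap(
                mapping={str(k): v for k, v in data["mapping"].items()},
                excluded=frozenset(str(c) for c in data.get("excluded", [])),
            )
        return LineageMap(mapping={str(k): v for k, v in data.items()})
    df = pd.read_csv(path, sep="\t", dtype=str)
    return LineageMap(mapping=dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


def write_lineage_map(lmap: LineageMap, path: str | Path) -> None:
    path = Path(path)
    payload = {"mapping": dict(lmap.mapping), "excluded": sorted(lmap.excluded)}
    path.write_text(yaml.safe_dump(payload, sort_keys=True))


# ------------------------------------------------------------------- JSON

def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
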