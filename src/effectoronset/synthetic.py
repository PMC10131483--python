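"""Synthetic five-part input bundles with planted ground truth.

The generator emulates every input the screening cascade consumes — two gene
catalogs, a domain-hit table, two directional protein hit tables, cluster- and
cell-level single-cell expression at two stages, and replicate-level temporal
FPKM matrices — for a population of genes with *known* classes:

* spatial: housekeeping (all 7 lineages), lineage-restricted (1-6 lineages),
  or undetected at the early-gastrula stage;
* temporal: maternal-only, zygotic-clear (onset at a planted grid hour),
  maternal with a dip-then-rise, ambiguous at 0 hpf, or never expressed;
* orthology: most genes form reciprocal best-hit pairs across the two
  species; a configured fraction are decoys with only one-directional top
  hits, and paralog rows at 90% of the true pair's bitscore exercise the
  non-reciprocal path;
* regulation: a configured fraction carry a significant hit to a curated
  TF/signaling Pfam accession.

Cluster-average and FPKM noise is multiplicative lognormal (strictly
nonnegative and right-skewed, like real normalized expression); with
``noise_sd = 0`` every value equals its class mean exactly and all downstream
calls recover the truth with zero errors.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .domains import DEFAULT_SIGNALING_ACCESSIONS, DEFAULT_TF_ACCESSIONS
from .lineage import DEFAULT_EG_CLUSTER_LINEAGES, LINEAGES, LineageMap, average_by_cluster
from .onset import TIME_GRID
from . import io as eio

TEMPORAL_CLASSES = (
    "maternal_only",
    "zygotic_clear",
    "maternal_dip_rise",
    "ambiguous_t0",
    "never_expressed",
)

SPATIAL_CLASSES = ("housekeeping", "restricted", "undetected")

#: Early-blastula precursor clusters used for planted coexpression.
EB_CLUSTERS: tuple[str, ...] = tuple(str(i) for i in range(10))
VEG1_PRECURSOR_CLUSTER = "5"
VEG2_PRECURSOR_CLUSTER = "7"

DEFAULT_PRECURSOR_MAP: dict[tuple[str, str], tuple[str, ...]] = {
    ("veg12_endoderm", "NSM"): (VEG2_PRECURSOR_CLUSTER,),
    ("veg1_ectoderm", "veg12_endoderm"): (VEG1_PRECURSOR_CLUSTER,),
}


def _normalized(weights: Sequence[float], what: str) -> np.ndarray:
    arr = np.asarray(weights, dtype=float)
    if (arr < 0).any():
        raise ValueError(f"{what} weights must be nonnegative")
    total = arr.sum()
    if total <= 0:
        raise ValueError(f"{what} weights sum to zero")
    return arr / total


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; defaults mirror the screened gene population.

    The spatial-class proportions default to the observed shares of
    undetected / housekeeping / restricted genes among analyzable genes
    (~0.56 / 0.16 / 0.28), the lineage-count weights to the observed
    1-to-6-lineage counts, and the temporal-class weights to the observed
    maternal / zygotic-clear / ambiguous / undetected split with a small
    dip-rise slice carved out of the maternal share.
    """

    n_genes: int = 2000
    fraction_regulatory: float = 0.03
    fraction_housekeeping: float = 0.16
    fraction_restricted: float = 0.28
    fraction_undetected: float = 0.56
    lineage_count_weights: tuple[float, ...] = (1058, 507, 494, 329, 348, 327)
    class_weights_temporal: tuple[float, ...] = (0.55, 0.17, 0.05, 0.13, 0.10)
    expressed_mean: float = 1.0
    background_mean: float = 0.05
    noise_sd: float = 0.2
    fpkm_high: float = 20.0
    fpkm_low: float = 0.1
    dip_rise_t0_fpkm: float = 6.0
    ambiguous_t0_fpkm: float = 2.0
    maternal_decay_rate: float = 0.1   # 1/h, maternal-only exponential decay
    dip_decay_rate: float = 0.25       # 1/h, faster decay for dip-rise genes
    fraction_unmapped: float = 0.10
    fraction_paralog_decoy: float = 0.15
    fraction_offlist_domain: float = 0.08
    fraction_weak_domain: float = 0.04
    n_replicates: int = 3
    n_cells_per_cluster: int = 40
    precursor_express_fraction: float = 0.8
    precursor_offset_fraction: float = 0.2
    onset_grid: tuple[int, ...] = TIME_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        spatial_sum = (
            self.fraction_housekeeping + self.fraction_restricted + self.fraction_undetected
        )
        if abs(spatial_sum - 1.0) > 1e-9:
            raise ValueError(
                f"spatial class proportions must sum to 1, got {spatial_sum!r}"
            )
        temporal = np.asarray(self.class_weights_temporal, dtype=float)
        if len(temporal) != len(TEMPORAL_CLASSES):
            raise ValueError(
                f"class_weights_temporal needs {len(TEMPORAL_CLASSES)} entries "
                f"(order {TEMPORAL_CLASSES})"
            )
        if abs(temporal.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"temporal class proportions must sum to 1, got {temporal.sum()!r}"
            )
        if not 0 <= self.fraction_regulatory <= 1:
            raise ValueError("fraction_regulatory must lie in [0, 1]")
        if len(self.lineage_count_weights) != 6:
            raise ValueError("lineage_count_weights needs 6 entries (1-6 lineages)")
        if self.noise_sd < 0 or self.background_mean < 0 or self.fpkm_low < 0:
            raise ValueError("noise_sd, background_mean and fpkm_low must be >= 0")
        if self.expressed_mean <= 0 or self.fpkm_high <= 0:
            raise ValueError("expressed_mean and fpkm_high must be > 0")
        grid = tuple(int(h) for h in self.onset_grid)
        if list(grid) != sorted(set(grid)) or 0 not in grid or len(grid) < 3:
            raise ValueError("onset_grid must be strictly increasing and contain 0")
        n_planted = (
            sum(w > 0 for w in (self.fraction_housekeeping, self.fraction_restricted,
                                self.fraction_undetected))
            + sum(w > 0 for w in temporal)
        )
        if self.n_genes < n_planted:
            raise ValueError(
                f"n_genes = {self.n_genes} is smaller than the number of planted "
                f"gene classes ({n_planted})"
            )


@dataclass
class SyntheticBundle:
    """Everything :func:`simulate_dataset` produces, in memory."""

    config: SimulationConfig
    truth: pd.DataFrame
    catalog_a: "GeneCatalog"
    catalog_b: "GeneCatalog"
    domain_hits: pd.DataFrame
    hits_ab: pd.DataFrame
    hits_ba: pd.DataFrame
    eg_cluster_averages: pd.DataFrame
    eb_cluster_averages: pd.DataFrame
    eb_cells: pd.DataFrame
    eb_cell_clusters: pd.Series
    lineage_map: LineageMap
    precursor_map: Mapping[tuple[str, str], tuple[str, ...]]
    fpkm_replicates: list[pd.DataFrame]


def _lognoise(rng: np.random.Generator, sd: float, shape) -> np.ndarray:
    if sd == 0:
        return np.ones(shape)
    return np.exp(rng.normal(0.0, sd, size=shape))


def _simulate_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_genes
    gene_a = [f"HpGene_{i:05d}" for i in range(n)]
    gene_b = [f"SpGene_{i:05d}" for i in range(n)]

    is_regulatory = rng.random(n) < config.fraction_regulatory
    spatial = rng.choice(
        SPATIAL_CLASSES,
        size=n,
        p=[config.fraction_housekeeping, config.fraction_restricted, config.fraction_undetected],
    )
    lin_weights = _normalized(config.lineage_count_weights, "lineage_count")
    temporal = rng.choice(
        TEMPORAL_CLASSES, size=n, p=_normalized(config.class_weights_temporal, "temporal")
    )
    mapped = rng.random(n) >= config.fraction_unmapped

    grid = tuple(int(h) for h in config.onset_grid)
    zygotic_hours = [h for h in grid if h > 0]
    # a dip inside the 6-10 hpf window needs the rise to land after it
    dip_hours = [h for h in grid if h >= 10] or zygotic_hours[-1:]

    lineage_sets: list[str] = []
    onsets = np.full(n, np.nan)
    for i in range(n):
        if spatial[i] == "housekeeping":
            lineage_sets.append("|".join(LINEAGES))
        elif spatial[i] == "undetected":
            lineage_sets.append("")
        else:
            k = int(rng.choice(np.arange(1, 7), p=lin_weights))
            chosen = rng.choice(len(LINEAGES), size=k, replace=False)
            lineage_sets.append("|".join(lin for j, lin in enumerate(LINEAGES) if j in set(chosen)))
        if temporal[i] == "zygotic_clear" or temporal[i] == "ambiguous_t0":
            onsets[i] = rng.choice(zygotic_hours)
        elif temporal[i] == "maternal_dip_rise":
            onsets[i] = rng.choice(dip_hours)

    truth = pd.DataFrame(
        {
            "gene_id": gene_a,
            "is_regulatory": is_regulatory,
            "ortholog_partner": [b if m else "" for b, m in zip(gene_b, mapped)],
            "spatial_class": spatial,
            "lineage_set": lineage_sets,
            "temporal_class": temporal,
            "true_onset_hpf": onsets,
        }
    ).set_index("gene_id")
    return truth


def _simulate_domain_hits(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    on_list = sorted(DEFAULT_TF_ACCESSIONS | DEFAULT_SIGNALING_ACCESSIONS)
    rows = []
    for g, reg in truth["is_regulatory"].items():
        if reg:
            for _ in range(int(rng.integers(1, 3))):
                rows.append(
                    {
                        "gene_id": g,
                        "domain_accession": str(rng.choice(on_list)),
                        "evalue": 10.0 ** -rng.uniform(10, 50),
                        "score": float(np.round(rng.uniform(50, 300), 1)),
                    }
                )
        else:
            u = rng.random()
            if u < config.fraction_offlist_domain:
                # metabolic/structural domain not on the regulatory lists
                rows.append(
                    {
                        "gene_id": g,
                        "domain_accession": str(rng.choice(["PF99001.1", "PF99002.1", "PF99003.1"])),
                        "evalue": 10.0 ** -rng.uniform(5, 30),
                        "score": float(np.round(rng.uniform(30, 200), 1)),
                    }
                )
            elif u < config.fraction_offlist_domain + config.fraction_weak_domain:
                # marginal hit to a listed domain, above any sane cutoff
                rows.append(
                    {
                        "gene_id": g,
                        "domain_accession": str(rng.choice(on_list)),
                        "evalue": 10.0 ** -rng.uniform(0, 4),
                        "score": float(np.round(rng.uniform(5, 20), 1)),
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "domain_accession", "evalue", "score"])


def _simulate_hit_tables(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    gene_a = list(truth.index)
    partners = truth["ortholog_partner"]
    mapped_idx = [i for i, g in enumerate(gene_a) if partners.iloc[i]]
    ab_rows, ba_rows = [], []
    base_scores = np.round(rng.uniform(200, 600, size=len(gene_a)), 1)
    for i, g in enumerate(gene_a):
        b = partners.iloc[i]
        if b:
            score = float(base_scores[i])
            ab_rows.append({"query_id": g, "subject_id": b, "bitscore": score, "evalue": 1e-50})
            ba_rows.append({"query_id": b, "subject_id": g, "bitscore": score, "evalue": 1e-50})
            if mapped_idx and rng.random() < config.fraction_paralog_decoy:
                j = int(rng.choice(mapped_idx))
                if j != i:
                    decoy = float(np.round(0.9 * score, 1))
                    ab_rows.append(
                        {"query_id": g, "subject_id": partners.iloc[j],
                         "bitscore": decoy, "evalue": 1e-40}
                    )
                    ba_rows.append(
                        {"query_id": b, "subject_id": gene_a[j],
                         "bitscore": decoy, "evalue": 1e-40}
                    )
        elif mapped_idx:
            # decoy: top hit exists but is another gene's reciprocal partner
            j = int(rng.choice(mapped_idx))
            score = float(np.round(rng.uniform(100, 190), 1))
            ab_rows.append(
                {"query_id": g, "subject_id": partners.iloc[j], "bitscore": score, "evalue": 1e-20}
            )
            ba_rows.append(
                {"query_id": f"SpGene_{i:05d}", "subject_id": gene_a[j],
                 "bitscore": score, "evalue": 1e-20}
            )
    cols = ["query_id", "subject_id", "bitscore", "evalue"]
    return pd.DataFrame(ab_rows, columns=cols), pd.DataFrame(ba_rows, columns=cols)


def _simulate_eg_averages(
    config: SimulationConfig, truth: pd.DataFrame, lmap: LineageMap, rng: np.random.Generator
) -> pd.DataFrame:
    clusters = sorted(lmap.mapping, key=lambda c: int(c))
    gene_b = [f"SpGene_{i:05d}" for i in range(config.n_genes)]
    partner_of = {b: a for a, b in truth["ortholog_partner"].items() if b}
    means = np.full((config.n_genes, len(clusters)), config.background_mean)
    for r, b in enumerate(gene_b):
        a = partner_of.get(b)
        if a is None:
            continue
        lset = set(truth.loc[a, "lineage_set"].split("|")) - {""}
        for c_idx, c in enumerate(clusters):
            if lmap.mapping[c] in lset:
                means[r, c_idx] = config.expressed_mean
    values = means * _lognoise(rng, config.noise_sd, means.shape)
    out = pd.DataFrame(values, index=gene_b, columns=clusters)
    out.index.name = "gene_id"
    return out


def _simulate_eb_cells(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series]:
    n_per = config.n_cells_per_cluster
    cells = [f"EBcell_{i:05d}" for i in range(n_per * len(EB_CLUSTERS))]
    assignment = pd.Series(
        {cells[k * n_per + j]: EB_CLUSTERS[k] for k in range(len(EB_CLUSTERS)) for j in range(n_per)}
    )
    gene_b = [f"SpGene_{i:05d}" for i in range(config.n_genes)]
    mat = np.zeros((config.n_genes, len(cells)))

    express = int(round(config.precursor_express_fraction * n_per))
    offset = int(round(config.precursor_offset_fraction * n_per))
    veg2_start = EB_CLUSTERS.index(VEG2_PRECURSOR_CLUSTER) * n_per
    veg1_start = EB_CLUSTERS.index(VEG1_PRECURSOR_CLUSTER) * n_per

    partner_of = {b: a for a, b in truth["ortholog_partner"].items() if b}
    for r, b in enumerate(gene_b):
        a = partner_of.get(b)
        if a is None:
            continue
        row = truth.loc[a]
        lset = set(row["lineage_set"].split("|")) - {""}
        if row["spatial_class"] == "housekeeping":
            mat[r, :] = config.expressed_mean
        elif lset == {"veg12_endoderm"}:
            mat[r, veg2_start:veg2_start + express] = config.expressed_mean
            mat[r, veg1_start + offset:veg1_start + offset + express] = config.expressed_mean
        elif lset == {"NSM"}:
            mat[r, veg2_start + offset:veg2_start + offset + express] = config.expressed_mean
        elif lset == {"veg1_ectoderm"}:
            mat[r, veg1_start:veg1_start + express] = config.expressed_mean
    mat = mat * _lognoise(rng, config.noise_sd, mat.shape)
    out = pd.DataFrame(mat, index=gene_b, columns=cells)
    out.index.name = "gene_id"
    return out, assignment


def temporal_mean_curve(
    config: SimulationConfig, temporal_class: str, onset: float | None
) -> np.ndarray:
    """Noise-free FPKM trajectory of one gene class on the config grid."""
    t = np.asarray(config.onset_grid, dtype=float)
    if temporal_class == "never_expressed":
        return np.full_like(t, config.fpkm_low)
    if temporal_class == "maternal_only":
        return config.fpkm_high * np.exp(-config.maternal_decay_rate * t)
    if temporal_class == "zygotic_clear":
        return np.where(t >= onset, config.fpkm_high, config.fpkm_low)
    if temporal_class == "maternal_dip_rise":
        maternal = config.dip_rise_t0_fpkm * np.exp(-config.dip_decay_rate * t)
        return maternal + np.where(t >= onset, config.fpkm_high, 0.0)
    if temporal_class == "ambiguous_t0":
        return np.where(t >= onset, config.fpkm_high, config.ambiguous_t0_fpkm)
    raise ValueError(f"unknown temporal class {temporal_class!r}")


def _simulate_fpkm(
    config: SimulationConfig, truth: pd.DataFrame, rng: np.random.Generator
) -> list[pd.DataFrame]:
    grid = [int(h) for h in config.onset_grid]
    curves = np.vstack(
        [
            temporal_mean_curve(config, row["temporal_class"], row["true_onset_hpf"])
            for _, row in truth.iterrows()
        ]
    )
    reps = []
    for _ in range(config.n_replicates):
        values = curves * _lognoise(rng, config.noise_sd, curves.shape)
        rep = pd.DataFrame(values, index=truth.index, columns=grid)
        rep.index.name = "gene_id"
        reps.append(rep)
    return reps


def simulate_dataset(config: SimulationConfig) -> SyntheticBundle:
    """Generate a complete input bundle with planted truth; deterministic per seed."""
    from .screen import GeneCatalog

    rng = np.random.default_rng(config.seed)
    truth = _simulate_truth(config, rng)
    domain_hits = _simulate_domain_hits(config, truth, rng)
    hits_ab, hits_ba = _simulate_hit_tables(config, truth, rng)
    lmap = LineageMap(mapping=dict(DEFAULT_EG_CLUSTER_LINEAGES))
    eg = _simulate_eg_averages(config, truth, lmap, rng)
    eb_cells, eb_assign = _simulate_eb_cells(config, truth, rng)
    eb_avg = average_by_cluster(eb_cells, eb_assign)
    fpkm = _simulate_fpkm(config, truth, rng)
    return SyntheticBundle(
        config=config,
        truth=truth,
        catalog_a=GeneCatalog("HpSim", tuple(truth.index)),
        catalog_b=GeneCatalog("SpSim", tuple(f"SpGene_{i:05d}" for i in range(config.n_genes))),
        domain_hits=domain_hits,
        hits_ab=hits_ab,
        hits_ba=hits_ba,
        eg_cluster_averages=eg,
        eb_cluster_averages=eb_avg,
        eb_cells=eb_cells,
        eb_cell_clusters=eb_assign,
        lineage_map=lmap,
        precursor_map=dict(DEFAULT_PRECURSOR_MAP),
        fpkm_replicates=fpkm,
    )


def empty_bundle(config: SimulationConfig | None = None) -> SyntheticBundle:
    """A structurally complete bundle with zero genes (for I/O edge cases)."""
    from .screen import GeneCatalog

    config = config or SimulationConfig()
    grid = [int(h) for h in config.onset_grid]
    truth = pd.DataFrame(
        columns=[
            "is_regulatory", "ortholog_partner", "spatial_class",
            "lineage_set", "temporal_class", "true_onset_hpf",
        ],
        index=pd.Index([], name="gene_id"),
    )
    hit_cols = ["query_id", "subject_id", "bitscore", "evalue"]
    lmap = LineageMap(mapping=dict(DEFAULT_EG_CLUSTER_LINEAGES))
    clusters = sorted(lmap.mapping, key=lambda c: int(c))
    cells = [f"EBcell_{i:05d}" for i in range(len(EB_CLUSTERS))]
    assignment = pd.Series(dict(zip(cells, EB_CLUSTERS)))
    empty_mat = lambda cols: pd.DataFrame(  # noqa: E731
        columns=cols, index=pd.Index([], name="gene_id"), dtype=float
    )
    return SyntheticBundle(
        config=config,
        truth=truth,
        catalog_a=GeneCatalog("HpSim", ()),
        catalog_b=GeneCatalog("SpSim", ()),
        domain_hits=pd.DataFrame(columns=["gene_id", "domain_accession", "evalue", "score"]),
        hits_ab=pd.DataFrame(columns=hit_cols),
        hits_ba=pd.DataFrame(columns=hit_cols),
        eg_cluster_averages=empty_mat(clusters),
        eb_cluster_averages=empty_mat(list(EB_CLUSTERS)),
        eb_cells=empty_mat(cells),
        eb_cell_clusters=assignment,
        lineage_map=lmap,
        precursor_map=dict(DEFAULT_PRECURSOR_MAP),
        fpkm_replicates=[empty_mat(grid) for _ in range(config.n_replicates)],
    )


def write_bundle(
    bundle: SyntheticBundle, directory: str | Path, cell_matrix_format: str = "tsv"
) -> dict:
    """Write every table of a bundle as plain text; returns (and writes) a manifest.

    The manifest maps each file name to its data row count plus an sha256 of
    the file contents, so re-runs can be compared byte-for-byte.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    eio.write_gene_catalog(bundle.catalog_a, directory / "catalog_a.txt")
    eio.write_gene_catalog(bundle.catalog_b, directory / "catalog_b.txt")
    eio.write_domain_hits(bundle.domain_hits, directory / "domain_hits.tsv")
    eio.write_blast6(bundle.hits_ab, directory / "hits_ab.tsv")
    eio.write_blast6(bundle.hits_ba, directory / "hits_ba.tsv")
    eio.write_expression_matrix(bundle.eg_cluster_averages, directory / "eg_cluster_averages.tsv")
    eio.write_expression_matrix(bundle.eb_cluster_averages, directory / "eb_cluster_averages.tsv")
    if cell_matrix_format == "mtx":
        eio.write_cell_matrix_mtx(bundle.eb_cells, directory / "eb_cells")
    else:
        eio.write_expression_matrix(bundle.eb_cells, directory / "eb_cells.tsv")
    eio.write_cluster_assignments(bundle.eb_cell_clusters, directory / "eb_cell_clusters.tsv")
    eio.write_lineage_map(bundle.lineage_map, directory / "lineage_map.yaml")
    eio.write_json(
        {"|".join(sorted(pair)): list(clusters) for pair, clusters in bundle.precursor_map.items()},
        directory / "precursor_map.json",
    )
    for i, rep in enumerate(bundle.fpkm_replicates, start=1):
        eio.write_temporal_matrix(rep, directory / f"fpkm_rep{i}.tsv")

    truth_out = bundle.truth.reset_index().to_dict(orient="records")
    for rec in truth_out:
        onset = rec["true_onset_hpf"]
        rec["true_onset_hpf"] = None if pd.isna(onset) else float(onset)
        rec["is_regulatory"] = bool(rec["is_regulatory"])
    eio.write_json({"config": asdict(bundle.config), "genes": truth_out}, directory / "truth.json")

    row_counts = {
        "catalog_a.txt": len(bundle.catalog_a),
        "catalog_b.txt": len(bundle.catalog_b),
        "domain_hits.tsv": len(bundle.domain_hits),
        "hits_ab.tsv": len(bundle.hits_ab),
        "hits_ba.tsv": len(bundle.hits_ba),
        "eg_cluster_averages.tsv": len(bundle.eg_cluster_averages),
        "eb_cluster_averages.tsv": len(bundle.eb_cluster_averages),
        "eb_cell_clusters.tsv": len(bundle.eb_cell_clusters),
        "lineage_map.yaml": len(bundle.lineage_map.mapping),
        "precursor_map.json": len(bundle.precursor_map),
        "truth.json": len(bundle.truth),
    }
    if cell_matrix_format == "mtx":
        row_counts["eb_cells.mtx"] = bundle.eb_cells.shape[0]
    else:
        row_counts["eb_cells.tsv"] = len(bundle.eb_cells)
    for i, rep in enumerate(bundle.fpkm_replicates, start=1):
        row_counts[f"fpkm_rep{i}.tsv"] = len(rep)

    manifest = {
        "seed": bundle.config.seed,
        "n_genes": bundle.config.n_genes,
        "files": {
            name: {
                "rows": rows,
                "sha256": hashlib.sha256((directory / name).read_bytes()).hexdigest(),
            }
            for name, rows in sorted(row_counts.items())
        },
    }
    eio.write_json(manifest, directory / "manifest.json")
    return manifest


def read_truth(directory: str | Path) -> pd.DataFrame:
    """Load the planted truth table written by :func:`write_bundle`."""
    payload = eio.read_json(Path(directory) / "truth.json")
    columns = [
        "is_regulatory", "ortholog_partner", "spatial_class",
        "lineage_set", "temporal_class", "true_onset_hpf",
    ]
    truth = pd.DataFrame(payload["genes"]).set_index("gene_id")[columns]
    truth["true_onset_hpf"] = truth["true_onset_hpf"].astype(float)
    return truth
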