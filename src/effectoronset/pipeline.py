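"""Orchestration of the effector-gene screening cascade and its reports.

Stages, in order:

1. ``domain_filter``      — remove regulatory genes (TF/signaling domains);
2. ``reciprocal_best_hit``— keep candidates with a cross-species ortholog;
3. ``lineage_restriction``— keep genes expressed in 1-6 of the 7 lineages
   (drop undetected and ubiquitous genes);
4. ``onset_classification``— keep clearly zygotic genes (FPKM(0) < 1, onset on
   the grid); maternal and ambiguous-at-0-hpf genes leave the funnel in named
   buckets, with dip-rise onsets inferred for the maternal ones as a side
   report;
5. ``manual_exclusion``   — apply a user-supplied post-hoc exclusion list
   (annotation review cannot be automated).

Every stage asserts conservation (``n_in = n_out + n_removed``) and chains
into the next, so the funnel report is auditable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as eio
from .domains import RegulatoryDomainList
from .lineage import LineageMap, call_lineages
from .onset import (
    DEFAULT_EARLY_WINDOW,
    annotate_dip_rise,
    average_replicates,
    call_onset,
)
from .screen import (
    GeneCatalog,
    classify_regulatory,
    ortholog_dict,
    reciprocal_best_hits,
    restrict_to_orthologs,
)


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the cascade, with the screen's standard defaults."""

    evalue_max: float = 1e-5
    lineage_threshold: float = 0.3
    expr_threshold: float = 3.0
    maternal_threshold: float = 3.0
    zygotic_t0_max: float = 1.0
    early_window: tuple[int, ...] = DEFAULT_EARLY_WINDOW
    exclusion_list: tuple[str, ...] = ()


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    n_removed: int
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_in != self.n_out + self.n_removed:
            raise ValueError(
                f"funnel conservation violated at {self.name}: "
                f"{self.n_in} != {self.n_out} + {self.n_removed}"
            )


@dataclass
class FunnelReport:
    stages: list[FunnelStage]
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise ValueError(
                    f"funnel stages do not chain: {prev.name}.n_out = {prev.n_out} "
                    f"but {nxt.name}.n_in = {nxt.n_in}"
                )

    @property
    def final_count(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "n_in": s.n_in,
                    "n_out": s.n_out,
                    "n_removed": s.n_removed,
                    "detail": dict(s.detail),
                }
                for s in self.stages
            ],
            "extras": dict(self.extras),
        }


@dataclass
class PipelineResult:
    records: pd.DataFrame
    funnel: FunnelReport
    lineage_calls: pd.DataFrame
    onset_calls: pd.DataFrame
    ortholog_map: pd.DataFrame


def run_pipeline(
    catalog_a: GeneCatalog,
    domain_hits: pd.DataFrame,
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    cluster_matrix: pd.DataFrame,
    fpkm: Sequence[pd.DataFrame] | pd.DataFrame,
    lineage_map: LineageMap | None = None,
    domains: RegulatoryDomainList | None = None,
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the whole cascade on in-memory inputs.

    ``cluster_matrix`` is indexed by the *other* species' gene ids (the
    single-cell data); the ortholog map joins the two namespaces.  ``fpkm``
    is either a list of replicate matrices (averaged here) or one
    already-averaged matrix, indexed by the catalog species' ids.
    """
    params = params or PipelineParams()
    lineage_map = lineage_map or LineageMap()

    # stage 1 — domain filter
    partition = classify_regulatory(catalog_a, domain_hits, domains, params.evalue_max)
    n0 = len(catalog_a)
    stage1 = FunnelStage(
        "domain_filter",
        n_in=n0,
        n_out=len(partition.candidate_ids),
        n_removed=len(partition.regulatory_ids),
        detail={
            "tf": sum(1 for r in partition.reasons.values() if r == "tf"),
            "signaling": sum(1 for r in partition.reasons.values() if r == "signaling"),
            "both": sum(1 for r in partition.reasons.values() if r == "both"),
        },
    )

    # stage 2 — reciprocal best hits
    omap = reciprocal_best_hits(hits_ab, hits_ba)
    mapped = restrict_to_orthologs(partition.candidate_ids, omap)
    stage2 = FunnelStage(
        "reciprocal_best_hit",
        n_in=len(partition.candidate_ids),
        n_out=len(mapped),
        n_removed=len(partition.candidate_ids) - len(mapped),
        detail={"rbh_pairs_total": len(omap), "candidates_with_rbh": len(mapped)},
    )

    # stage 3 — lineage restriction (on the partner species' single-cell data)
    lineage_calls = call_lineages(cluster_matrix, lineage_map, params.lineage_threshold)
    a_to_b = ortholog_dict(omap, "ab")
    categories = {}
    for a in mapped:
        b = a_to_b[a]
        categories[a] = (
            lineage_calls.loc[b, "category"] if b in lineage_calls.index else "undetected"
        )
    restricted = [a for a in mapped if categories[a] == "restricted"]
    n_undet = sum(1 for a in mapped if categories[a] == "undetected")
    n_ubiq = sum(1 for a in mapped if categories[a] == "ubiquitous")
    stage3 = FunnelStage(
        "lineage_restriction",
        n_in=len(mapped),
        n_out=len(restricted),
        n_removed=n_undet + n_ubiq,
        detail={"undetected": n_undet, "ubiquitous": n_ubiq},
    )

    # stage 4 — transcript origin and onset
    avg = average_replicates(list(fpkm)) if isinstance(fpkm, (list, tuple)) else fpkm
    onset_calls = call_onset(
        avg,
        expr_threshold=params.expr_threshold,
        maternal_threshold=params.maternal_threshold,
        zygotic_t0_max=params.zygotic_t0_max,
    )
    restricted_in_fpkm = [a for a in restricted if a in onset_calls.index]
    onset_sub = annotate_dip_rise(
        avg.loc[restricted_in_fpkm],
        onset_calls.loc[restricted_in_fpkm],
        early_window=params.early_window,
        expr_threshold=params.expr_threshold,
        maternal_threshold=params.maternal_threshold,
    )
    origin_of = {
        a: (onset_sub.loc[a, "origin"] if a in onset_sub.index else "undetected")
        for a in restricted
    }
    zygotic = [a for a in restricted if origin_of[a] == "zygotic_clear"]
    buckets = {
        "undetected_temporal": sum(1 for a in restricted if origin_of[a] == "undetected"),
        "maternal": sum(1 for a in restricted if origin_of[a] == "maternal"),
        "ambiguous_t0": sum(1 for a in restricted if origin_of[a] == "ambiguous_t0"),
    }
    stage4 = FunnelStage(
        "onset_classification",
        n_in=len(restricted),
        n_out=len(zygotic),
        n_removed=sum(buckets.values()),
        detail=buckets,
    )

    # stage 5 — post-hoc annotation-based exclusion
    excluded = [g for g in zygotic if g in set(params.exclusion_list)]
    final = [g for g in zygotic if g not in set(params.exclusion_list)]
    stage5 = FunnelStage(
        "manual_exclusion",
        n_in=len(zygotic),
        n_out=len(final),
        n_removed=len(excluded),
        detail={"excluded_ids": sorted(excluded)},
    )

    funnel = FunnelReport(
        stages=[stage1, stage2, stage3, stage4, stage5],
        extras={
            "catalog_size": n0,
            "rbh_pairs_total": len(omap),
            "candidates_with_rbh": len(mapped),
            "maternal_with_dip_rise_onset": int(
                onset_sub["dip_rise_onset_hpf"].notna().sum()
            ),
        },
    )

    records = _build_records(
        catalog_a, partition, a_to_b, lineage_calls, onset_calls, onset_sub,
        set(final), set(params.exclusion_list),
    )
    return PipelineResult(
        records=records,
        funnel=funnel,
        lineage_calls=lineage_calls,
        onset_calls=onset_sub,
        ortholog_map=omap,
    )


def _build_records(
    catalog_a, partition, a_to_b, lineage_calls, onset_calls, onset_sub,
    final_set: set, exclusion: set,
) -> pd.DataFrame:
    rows = []
    for g in catalog_a.gene_ids:
        b = a_to_b.get(g, "")
        lrow = lineage_calls.loc[b] if b and b in lineage_calls.index else None
        if g in onset_sub.index:
            orow = onset_sub.loc[g]
            dip = orow["dip_rise_onset_hpf"]
        elif g in onset_calls.index:
            orow = onset_calls.loc[g]
            dip = np.nan
        else:
            orow, dip = None, np.nan
        rows.append(
            {
                "gene_id": g,
                "ortholog_id": b,
                "regulatory_reason": partition.reasons[g],
                "lineage_set": lrow["lineage_set"] if lrow is not None else "",
                "n_lineages": int(lrow["n_lineages"]) if lrow is not None else -1,
                "category": lrow["category"] if lrow is not None else "",
                "origin": orow["origin"] if orow is not None else "",
                "onset_hpf": float(orow["onset_hpf"]) if orow is not None else np.nan,
                "method": orow["method"] if orow is not None else "",
                "dip_rise_onset_hpf": dip,
                "post_hoc_flag": g in exclusion,
                "final_effector": g in final_set,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def onset_histogram(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulations of final effector genes with a resolved onset.

    Returns two tidy frames: counts by ``(onset_hpf, n_lineages)`` and, for
    single-lineage genes only, counts by ``(onset_hpf, lineage)``.
    """
    resolved = records[records["final_effector"] & records["onset_hpf"].notna()]
    by_n = (
        resolved.groupby(["onset_hpf", "n_lineages"]).size().rename("count").reset_index()
    )
    singles = resolved[resolved["n_lineages"] == 1].rename(columns={"lineage_set": "lineage"})
    by_lin = (
        singles.groupby(["onset_hpf", "lineage"]).size().rename("count").reset_index()
    )
    return by_n, by_lin


def write_pipeline_outputs(result: PipelineResult, directory: str | Path) -> dict:
    """Write all result tables + the funnel JSON; returns the file map."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {}

    def _tsv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        df.to_csv(directory / name, sep="\t", index=index, float_format="%.10g")
        files[name] = str(directory / name)

    _tsv(result.records, "records.tsv")
    _tsv(result.lineage_calls, "lineage_calls.tsv")
    _tsv(result.onset_calls, "onset_calls.tsv")
    _tsv(result.ortholog_map, "ortholog_map.tsv", index=False)
    by_n, by_lin = onset_histogram(result.records)
    _tsv(by_n, "onset_by_n_lineages.tsv", index=False)
    _tsv(by_lin, "onset_by_lineage.tsv", index=False)
    eio.write_json(result.funnel.to_dict(), directory / "funnel.json")
    files["funnel.json"] = str(directory / "funnel.json")
    return files


def run_pipeline_from_config(config_path: str | Path) -> PipelineResult:
    """Run the cascade from a YAML config of input paths and thresholds."""
    import yaml

    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    base = config_path.parent

    def _p(rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else base / p

    inputs = cfg["inputs"]
    catalog = eio.read_gene_catalog(_p(inputs["catalog_a"]), species=cfg.get("species_a", "A"))
    domain_hits = eio.read_domain_hits(
        _p(inputs["domain_hits"]), dialect=inputs.get("domain_dialect", "tsv")
    )
    hits_ab = eio.read_blast6(_p(inputs["hits_ab"]))
    hits_ba = eio.read_blast6(_p(inputs["hits_ba"]))
    cluster_matrix = eio.read_expression_matrix(_p(inputs["cluster_matrix"]))
    if "fpkm_replicates" in inputs:
        fpkm = [eio.read_temporal_matrix(_p(p)) for p in inputs["fpkm_replicates"]]
    else:
        fpkm = eio.read_temporal_matrix(_p(inputs["fpkm_average"]))
    lmap = eio.read_lineage_map(_p(inputs["lineage_map"])) if "lineage_map" in inputs else None

    p = cfg.get("params", {})
    params = PipelineParams(
        evalue_max=float(p.get("evalue_max", 1e-5)),
        lineage_threshold=float(p.get("lineage_threshold", 0.3)),
        expr_threshold=float(p.get("expr_threshold", 3.0)),
        maternal_threshold=float(p.get("maternal_threshold", 3.0)),
        zygotic_t0_max=float(p.get("zygotic_t0_max", 1.0)),
        early_window=tuple(p.get("early_window", DEFAULT_EARLY_WINDOW)),
        exclusion_list=tuple(cfg.get("exclusion_list", [])),
    )
    return run_pipeline(
        catalog, domain_hits, hits_ab, hits_ba, cluster_matrix, fpkm,
        lineage_map=lmap, params=params,
    )


def run_pipeline_on_bundle(bundle, params: PipelineParams | None = None) -> PipelineResult:
    """Convenience: run the cascade directly on a synthetic bundle."""
    return run_pipeline(
        bundle.catalog_a,
        bundle.domain_hits,
        bundle.hits_ab,
        bundle.hits_ba,
        bundle.eg_cluster_averages,
        bundle.fpkm_replicates,
        lineage_map=bundle.lineage_map,
        params=params,
    )
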