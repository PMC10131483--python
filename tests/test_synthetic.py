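"""Synthetic bundle generation: validation, determinism, truth structure, round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from effectoronset import (
    SimulationConfig,
    empty_bundle,
    read_truth,
    simulate_dataset,
    temporal_mean_curve,
    write_bundle,
)
from effectoronset import io as eio
from effectoronset.synthetic import SPATIAL_CLASSES, TEMPORAL_CLASSES


class TestConfigValidation:
    def test_spatial_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(fraction_housekeeping=0.5, fraction_restricted=0.5,
                             fraction_undetected=0.5)

    def test_temporal_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SimulationConfig(class_weights_temporal=(0.5, 0.5, 0.5, 0.0, 0.0))

    def test_too_few_genes_for_planted_classes(self):
        with pytest.raises(ValueError, match="planted"):
            SimulationConfig(n_genes=3)

    def test_grid_must_contain_zero(self):
        with pytest.raises(ValueError, match="onset_grid"):
            SimulationConfig(onset_grid=(6, 8, 10, 12))


class TestTruthStructure:
    def test_onset_defined_exactly_for_onset_classes(self, small_bundle):
        truth = small_bundle.truth
        has_onset = truth["true_onset_hpf"].notna()
        onset_classes = truth["temporal_class"].isin(
            ["zygotic_clear", "maternal_dip_rise", "ambiguous_t0"]
        )
        assert (has_onset == onset_classes).all()
        grid = set(small_bundle.config.onset_grid) - {0}
        assert set(truth.loc[has_onset, "true_onset_hpf"]) <= grid

    def test_dip_rise_onsets_leave_room_for_the_early_dip(self, small_bundle):
        dips = small_bundle.truth.query("temporal_class == 'maternal_dip_rise'")
        assert (dips["true_onset_hpf"] >= 10).all()

    def test_ortholog_partners_are_unique(self, small_bundle):
        partners = small_bundle.truth["ortholog_partner"]
        mapped = partners[partners != ""]
        assert mapped.is_unique

    def test_class_counts_consistent_with_configured_proportions(self):
        # pooled over 20 seeds, a chi-square goodness-of-fit should not reject
        counts_spatial = dict.fromkeys(SPATIAL_CLASSES, 0)
        counts_temporal = dict.fromkeys(TEMPORAL_CLASSES, 0)
        config = SimulationConfig(n_genes=200)
        for seed in range(20):
            truth = simulate_dataset(
                SimulationConfig(n_genes=200, seed=seed)
            ).truth
            for cls, n in truth["spatial_class"].value_counts().items():
                counts_spatial[cls] += n
            for cls, n in truth["temporal_class"].value_counts().items():
                counts_temporal[cls] += n
        total = 20 * 200
        p_spatial = [config.fraction_housekeeping, config.fraction_restricted,
                     config.fraction_undetected]
        observed = [counts_spatial[c] for c in ("housekeeping", "restricted", "undetected")]
        assert stats.chisquare(observed, [p * total for p in p_spatial]).pvalue > 0.001
        observed_t = [counts_temporal[c] for c in TEMPORAL_CLASSES]
        expected_t = [w * total for w in config.class_weights_temporal]
        assert stats.chisquare(observed_t, expected_t).pvalue > 0.001


class TestZeroNoise:
    def test_cluster_averages_equal_class_means_exactly(self, zero_noise_bundle):
        b = zero_noise_bundle
        values = set(np.unique(b.eg_cluster_averages.to_numpy()))
        assert values <= {b.config.background_mean, b.config.expressed_mean}

    def test_fpkm_replicates_equal_mean_curves_exactly(self, zero_noise_bundle):
        b = zero_noise_bundle
        for rep in b.fpkm_replicates:
            for g, row in b.truth.iterrows():
                expected = temporal_mean_curve(
                    b.config, row["temporal_class"], row["true_onset_hpf"]
                )
                np.testing.assert_array_equal(rep.loc[g].to_numpy(), expected)


class TestDeterminism:
    def test_same_seed_reproduces_every_table(self):
        config = SimulationConfig(n_genes=80, seed=13)
        b1, b2 = simulate_dataset(config), simulate_dataset(config)
        pd.testing.assert_frame_equal(b1.truth, b2.truth)
        pd.testing.assert_frame_equal(b1.hits_ab, b2.hits_ab)
        pd.testing.assert_frame_equal(b1.eg_cluster_averages, b2.eg_cluster_averages)
        pd.testing.assert_frame_equal(b1.fpkm_replicates[2], b2.fpkm_replicates[2])

    def test_written_bundles_are_byte_identical(self, tmp_path):
        config = SimulationConfig(n_genes=40, seed=13)
        m1 = write_bundle(simulate_dataset(config), tmp_path / "run1")
        m2 = write_bundle(simulate_dataset(config), tmp_path / "run2")
        assert {k: v["sha256"] for k, v in m1["files"].items()} == {
            k: v["sha256"] for k, v in m2["files"].items()
        }

    def test_different_seeds_differ(self):
        a = simulate_dataset(SimulationConfig(n_genes=40, seed=1))
        b = simulate_dataset(SimulationConfig(n_genes=40, seed=2))
        assert not a.eg_cluster_averages.equals(b.eg_cluster_averages)


class TestWriteBundle:
    def test_manifest_row_counts_match_table_lengths(self, tmp_path):
        bundle = simulate_dataset(SimulationConfig(n_genes=100, seed=5))
        manifest = write_bundle(bundle, tmp_path)
        files = manifest["files"]
        assert files["catalog_a.txt"]["rows"] == 100
        assert files["domain_hits.tsv"]["rows"] == len(bundle.domain_hits)
        assert files["hits_ab.tsv"]["rows"] == len(bundle.hits_ab)
        assert files["eg_cluster_averages.tsv"]["rows"] == 100
        assert files["fpkm_rep1.tsv"]["rows"] == 100
        # and the files really have that many data rows
        assert len((tmp_path / "catalog_a.txt").read_text().splitlines()) == 100
        n_lines = len((tmp_path / "eg_cluster_averages.tsv").read_text().splitlines())
        assert n_lines == 101  # header + genes

    def test_empty_bundle_writes_all_files_with_zero_gene_rows(self, tmp_path):
        manifest = write_bundle(empty_bundle(), tmp_path)
        for name in ("catalog_a.txt", "domain_hits.tsv", "hits_ab.tsv",
                     "eg_cluster_averages.tsv", "fpkm_rep1.tsv", "truth.json"):
            assert manifest["files"][name]["rows"] == 0
            assert (tmp_path / name).exists()

    def test_round_trip_reconstructs_matrices(self, tmp_path, small_bundle):
        write_bundle(small_bundle, tmp_path)
        eg = eio.read_expression_matrix(tmp_path / "eg_cluster_averages.tsv")
        pd.testing.assert_frame_equal(eg, small_bundle.eg_cluster_averages, rtol=1e-9)
        rep1 = eio.read_temporal_matrix(tmp_path / "fpkm_rep1.tsv")
        pd.testing.assert_frame_equal(rep1, small_bundle.fpkm_replicates[0], rtol=1e-9)
        hits = eio.read_blast6(tmp_path / "hits_ab.tsv")
        pd.testing.assert_frame_equal(hits, small_bundle.hits_ab, rtol=1e-9)
        truth = read_truth(tmp_path)
        pd.testing.assert_frame_equal(truth, small_bundle.truth)
        lmap = eio.read_lineage_map(tmp_path / "lineage_map.yaml")
        assert dict(lmap.mapping) == dict(small_bundle.lineage_map.mapping)

    def test_cell_matrix_matrixmarket_round_trip(self, tmp_path):
        bundle = simulate_dataset(SimulationConfig(n_genes=30, seed=2))
        write_bundle(bundle, tmp_path, cell_matrix_format="mtx")
        cells = eio.read_cell_matrix_mtx(tmp_path / "eb_cells")
        pd.testing.assert_frame_equal(cells, bundle.eb_cells, rtol=1e-9)
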