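"""Replicate averaging, origin classification and onset calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from effectoronset import (
    TIME_GRID,
    annotate_dip_rise,
    average_replicates,
    call_onset,
    infer_dip_rise_onset,
)
from conftest import random_temporal_matrix
from oracles import oracle_call_onset, oracle_dip_rise


def trajectory(values: dict[int, float]) -> pd.Series:
    full = {h: values.get(h, 0.0) for h in TIME_GRID}
    return pd.Series(full)


def one_gene_matrix(values: dict[int, float], gene: str = "g1") -> pd.DataFrame:
    return pd.DataFrame([trajectory(values)], index=[gene])


class TestAverageReplicates:
    def test_identical_replicates_average_to_themselves(self):
        rep = one_gene_matrix({0: 4.0, 10: 8.0})
        pd.testing.assert_frame_equal(average_replicates([rep, rep, rep]), rep, check_dtype=False)

    def test_elementwise_mean(self):
        reps = [one_gene_matrix({6: v}) for v in (0.0, 3.0, 6.0)]
        assert average_replicates(reps).loc["g1", 6] == 3.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        reps = [random_temporal_matrix(rng, n_genes=10) for _ in range(3)]
        avg = average_replicates(reps)
        for g in reps[0].index:
            for h in TIME_GRID:
                expected = (reps[0].loc[g, h] + reps[1].loc[g, h] + reps[2].loc[g, h]) / 3
                assert avg.loc[g, h] == pytest.approx(expected, rel=1e-12)

    def test_mismatched_genes_rejected(self):
        a = one_gene_matrix({0: 1.0}, gene="g1")
        b = one_gene_matrix({0: 1.0}, gene="g2")
        with pytest.raises(ValueError, match="gene"):
            average_replicates([a, b])


class TestCallOnset:
    def test_all_zero_trajectory_is_undetected(self):
        calls = call_onset(one_gene_matrix({}))
        row = calls.loc["g1"]
        assert not row["detected"]
        assert row["origin"] == "undetected"
        assert np.isnan(row["onset_hpf"])

    def test_clean_zygotic_gene_gets_first_crossing_onset(self):
        calls = call_onset(one_gene_matrix({6: 5.0, 8: 5.0, 10: 6.0}))
        row = calls.loc["g1"]
        assert row["origin"] == "zygotic_clear"
        assert row["onset_hpf"] == 6.0
        assert row["method"] == "first_crossing"

    def test_intermediate_t0_band_is_ambiguous_without_onset(self):
        calls = call_onset(one_gene_matrix({0: 2.0, 20: 10.0}))
        row = calls.loc["g1"]
        assert row["origin"] == "ambiguous_t0"
        assert np.isnan(row["onset_hpf"])

    def test_flat_maternal_gene_has_no_onset(self):
        calls = call_onset(one_gene_matrix(dict.fromkeys(TIME_GRID, 4.0)))
        row = calls.loc["g1"]
        assert row["origin"] == "maternal"
        assert np.isnan(row["onset_hpf"])
        assert row["method"] == "undefined"

    def test_t0_boundaries_are_strict(self):
        # FPKM(0) exactly 3 is not maternal; exactly 1 is not clearly zygotic
        at_three = call_onset(one_gene_matrix({0: 3.0, 10: 9.0})).loc["g1"]
        at_one = call_onset(one_gene_matrix({0: 1.0, 10: 9.0})).loc["g1"]
        assert at_three["origin"] == "ambiguous_t0"
        assert at_one["origin"] == "ambiguous_t0"

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scripted_per_gene_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = random_temporal_matrix(rng, n_genes=100)
        calls = call_onset(mat)
        for g in mat.index:
            origin, onset = oracle_call_onset(
                dict(mat.loc[g]), list(TIME_GRID), 3.0, 3.0, 1.0
            )
            assert calls.loc[g, "origin"] == origin, g
            got = calls.loc[g, "onset_hpf"]
            assert (np.isnan(got) and onset is None) or got == onset

    def test_onset_monotone_nondecreasing_in_expr_threshold(self):
        rng = np.random.default_rng(99)
        mat = random_temporal_matrix(rng, n_genes=80)
        previous = None
        for thr in (0.5, 1.0, 3.0, 5.0, 9.0):
            onset = call_onset(mat, expr_threshold=thr, zygotic_t0_max=min(1.0, thr))["onset_hpf"]
            if previous is not None:
                both = previous.notna() & onset.notna()
                assert (onset[both] >= previous[both]).all()
            previous = onset

    def test_undetected_genes_never_carry_an_onset(self):
        mat = random_temporal_matrix(np.random.default_rng(3), n_genes=60)
        calls = call_onset(mat)
        assert calls.loc[~calls["detected"], "onset_hpf"].isna().all()
        # origin classes partition detected genes
        detected = calls[calls["detected"]]
        assert set(detected["origin"]) <= {"maternal", "zygotic_clear", "ambiguous_t0"}

    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(ValueError):
            call_onset(one_gene_matrix({}), expr_threshold=1.0, zygotic_t0_max=2.0)


class TestDipRise:
    def test_printed_maternal_dip_rise_example_gives_10_hpf(self):
        # FPKM 3.23 at fertilization, early minimum 1.86 at 8 hpf, 4.93 at the
        # next grid point and above threshold afterwards
        traj = trajectory(
            {0: 3.23, 6: 2.5, 8: 1.86, 10: 4.93, 12: 5.0, 14: 5.5, 16: 5.8,
             18: 6.0, 20: 6.1, 22: 6.2, 24: 6.3, 26: 6.4, 28: 6.4, 30: 6.5}
        )
        assert infer_dip_rise_onset(traj) == 10.0

    def test_monotone_maternal_decay_yields_none(self):
        values = {h: 10.0 * np.exp(-0.1 * h) for h in TIME_GRID}
        assert infer_dip_rise_onset(trajectory(values)) is None

    def test_rise_must_clear_both_minimum_and_threshold(self):
        # dip to 2.0 at 10 hpf; 2.5 and 2.9 rise above the minimum but not the
        # threshold; 3.5 at 16 hpf is the first point clearing both
        traj = trajectory({0: 5.0, 6: 4.0, 8: 3.0, 10: 2.0, 12: 2.5, 14: 2.9, 16: 3.5})
        assert infer_dip_rise_onset(traj) == 16.0

    def test_no_dip_below_t0_level_yields_none(self):
        traj = trajectory(dict.fromkeys(TIME_GRID, 4.0))
        assert infer_dip_rise_onset(traj) is None

    def test_non_maternal_trajectory_violates_contract(self):
        with pytest.raises(ValueError, match="maternal"):
            infer_dip_rise_onset(trajectory({0: 1.0, 10: 8.0}))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_hand_rule_oracle_on_random_maternal_trajectories(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            values = {0: float(rng.uniform(3.1, 12.0))}
            for h in TIME_GRID[1:]:
                values[h] = float(rng.choice([0.5, 1.5, 2.5, 3.5, 5.0, 8.0]))
            got = infer_dip_rise_onset(trajectory(values))
            want = oracle_dip_rise(values, list(TIME_GRID), (6, 8, 10), 3.0)
            assert got == want

    def test_annotate_adds_onsets_only_for_maternal_genes(self):
        mat = pd.concat(
            [
                one_gene_matrix({0: 5.0, 6: 2.0, 8: 1.5, 10: 6.0, 12: 6.0}, "mat_dip"),
                one_gene_matrix({0: 8.0, 6: 7.0, 8: 6.0, 10: 5.0}, "mat_flat"),
                one_gene_matrix({6: 5.0, 8: 5.0}, "zyg"),
            ]
        )
        calls = annotate_dip_rise(mat, call_onset(mat))
        assert calls.loc["mat_dip", "dip_rise_onset_hpf"] == 10.0
        assert calls.loc["mat_dip", "method"] == "dip_rise"
        assert np.isnan(calls.loc["mat_flat", "dip_rise_onset_hpf"])
        assert np.isnan(calls.loc["zyg", "dip_rise_onset_hpf"])
        assert calls.loc["zyg", "method"] == "first_crossing"
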