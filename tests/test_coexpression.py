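"""Binarization, per-cell histograms, markers, coexpression percentages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cteninx.coexpression import (
    binarize,
    coexpression_pairs,
    expression_ratio,
    innexin_count_histogram,
    metacell_markers,
    pairwise_coexpression,
)
from cteninx.simulate import PlantedPair, UMISimParams, simulate_umi

from .oracles import histogram_fractions, pair_percent


def umi_frame(arr, genes=None, cells=None):
    arr = np.asarray(arr)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = cells or [f"c{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=genes, columns=cells)


class TestBinarize:
    def test_default_threshold_is_one_umi(self):
        mask = binarize(umi_frame([[0, 1, 5]]))
        assert mask.mask.to_numpy().tolist() == [[False, True, True]]
        assert mask.min_umi == 1

    def test_higher_threshold(self):
        mask = binarize(umi_frame([[0, 1, 2]]), min_umi=2)
        assert mask.mask.to_numpy().tolist() == [[False, False, True]]

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            binarize(umi_frame(np.array([[0.5, 1.0]])))

    @given(st.integers(0, 2**31 - 1))
    def test_matches_elementwise_comparison(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(1.0, size=(20, 50))
        mask = binarize(umi_frame(counts), min_umi=2)
        assert (mask.mask.to_numpy() == (counts >= 2)).all()


class TestHistogram:
    def test_all_zero_matrix(self):
        mask = binarize(umi_frame(np.zeros((4, 6), dtype=int) + 0))
        # all-zero counts: every cell expresses nothing
        hist = innexin_count_histogram(mask, ["g0", "g1", "g2", "g3"])
        assert hist.fractions == (1.0, 0.0, 0.0, 0.0)

    def test_hand_built_counts_and_max(self):
        # per-cell expressed-target counts {0,0,1,1,1,2,2,3,5,9}
        per_cell = [0, 0, 1, 1, 1, 2, 2, 3, 5, 9]
        arr = np.zeros((9, 10), dtype=int)
        for j, k in enumerate(per_cell):
            arr[:k, j] = 1
        mask = binarize(umi_frame(arr))
        hist = innexin_count_histogram(mask, [f"g{i}" for i in range(9)])
        assert hist.fractions == (0.2, 0.3, 0.2, 0.3)
        assert hist.max_per_cell == 9

    def test_every_cell_expresses_exactly_one(self):
        arr = np.eye(5, dtype=int)
        mask = binarize(umi_frame(arr))
        hist = innexin_count_histogram(mask, [f"g{i}" for i in range(5)])
        assert hist.fractions == (0.0, 1.0, 0.0, 0.0)

    def test_alternative_gt3_bucketing_still_sums_to_one(self):
        per_cell = [0, 1, 2, 3, 4]
        arr = np.zeros((4, 5), dtype=int)
        for j, k in enumerate(per_cell):
            arr[:k, j] = 1
        mask = binarize(umi_frame(arr))
        ge3 = innexin_count_histogram(mask, [f"g{i}" for i in range(4)])
        gt3 = innexin_count_histogram(
            mask, [f"g{i}" for i in range(4)], top_bucket="gt3"
        )
        assert ge3.fractions == (0.2, 0.2, 0.2, 0.4)
        assert gt3.fractions == (0.2, 0.2, 0.4, 0.2)
        assert abs(sum(gt3.fractions) - 1) < 1e-12

    def test_empty_targets_error(self):
        mask = binarize(umi_frame([[1]]))
        with pytest.raises(ValueError):
            innexin_count_histogram(mask, [])

    @given(st.integers(0, 2**31 - 1))
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(0.7, size=(10, 40))
        mask = binarize(umi_frame(counts))
        hist = innexin_count_histogram(mask, [f"g{i}" for i in range(10)])
        assert abs(sum(hist.fractions) - 1.0) < 1e-12
        assert hist.fractions == histogram_fractions(
            mask.mask, [f"g{i}" for i in range(10)]
        )


class TestMarkers:
    def make(self, per_gene_cells, n_cells, metacell="M1"):
        arr = np.zeros((1, n_cells), dtype=int)
        arr[0, :per_gene_cells] = 1
        mask = binarize(umi_frame(arr, genes=["g0"]))
        mc = {f"c{j}": metacell for j in range(n_cells)}
        return metacell_markers(mask, mc)

    def test_three_of_five_is_marker(self):
        row = self.make(3, 5).iloc[0]
        assert row["fraction"] == 0.6 and row["is_marker"]

    def test_exact_half_boundary_inclusive(self):
        row = self.make(2, 4).iloc[0]
        assert row["fraction"] == 0.5 and row["is_marker"]

    def test_zero_of_five_not_marker(self):
        row = self.make(0, 5).iloc[0]
        assert not row["is_marker"]

    def test_unknown_cell_in_map_errors(self):
        mask = binarize(umi_frame([[1]]))
        with pytest.raises(ValueError):
            metacell_markers(mask, {"nope": "M1"})


class TestPairwiseCoexpression:
    def test_identical_sets_give_hundred_percent(self):
        arr = np.array([[1, 1, 0, 0], [1, 1, 0, 0]])
        cm = pairwise_coexpression(binarize(umi_frame(arr)), ["g0", "g1"])
        assert cm.percent.loc["g0", "g1"] == 100.0

    def test_disjoint_sets_give_zero_percent(self):
        arr = np.array([[1, 1, 0, 0], [0, 0, 1, 1]])
        cm = pairwise_coexpression(binarize(umi_frame(arr)), ["g0", "g1"])
        assert cm.percent.loc["g0", "g1"] == 0.0

    def test_partial_overlap_uses_min_denominator(self):
        # A in cells 1-5, B in cells 4-7 of an 8-cell mask
        arr = np.zeros((2, 8), dtype=int)
        arr[0, 0:5] = 1
        arr[1, 3:7] = 1
        cm = pairwise_coexpression(binarize(umi_frame(arr)), ["g0", "g1"])
        assert cm.n_both.loc["g0", "g1"] == 2
        assert cm.percent.loc["g0", "g1"] == 50.0

    def test_silent_gene_percent_is_missing_not_zero(self):
        arr = np.array([[1, 1], [0, 0]])
        cm = pairwise_coexpression(binarize(umi_frame(arr)), ["g0", "g1"])
        assert np.isnan(cm.percent.loc["g0", "g1"])
        assert cm.percent.loc["g0", "g0"] == 100.0

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_and_order_invariant(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(0.8, size=(8, 60))
        frame = umi_frame(counts)
        genes = list(frame.index)
        cm = pairwise_coexpression(binarize(frame), genes)
        assert np.allclose(
            cm.percent.to_numpy(), cm.percent.to_numpy().T, equal_nan=True
        )
        shuffled = frame.sample(frac=1, axis=1, random_state=1)
        cm2 = pairwise_coexpression(binarize(shuffled), genes)
        assert np.allclose(
            cm.percent.to_numpy(), cm2.percent.to_numpy(), equal_nan=True
        )
        for a in genes[:3]:
            for b in genes[:3]:
                expect = pair_percent(binarize(frame).mask, a, b)
                got = cm.percent.loc[a, b]
                if expect is None:
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expect)


class TestCoexpressionPairs:
    def test_single_pair_above_threshold(self):
        arr = np.array([[1, 1, 1, 0], [1, 1, 0, 1], [0, 0, 1, 1]])
        cm = pairwise_coexpression(
            binarize(umi_frame(arr)), ["g0", "g1", "g2"]
        )
        pairs = coexpression_pairs(cm, threshold=60.0)
        assert len(pairs) == 1
        assert {pairs.iloc[0]["gene_a"], pairs.iloc[0]["gene_b"]} == \
            {"g0", "g1"}

    def test_no_pairs_when_all_below_threshold(self):
        arr = np.array([[1, 0], [0, 1]])
        cm = pairwise_coexpression(binarize(umi_frame(arr)), ["g0", "g1"])
        assert coexpression_pairs(cm, 50.0).empty

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(0.6, size=(10, 80))
        frame = umi_frame(counts)
        genes = list(frame.index)
        cm = pairwise_coexpression(binarize(frame), genes)
        pairs = coexpression_pairs(cm, 50.0)
        expected = set()
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                pct = pair_percent(binarize(frame).mask, a, b)
                if pct is not None and pct >= 50.0:
                    expected.add(frozenset((a, b)))
        got = {
            frozenset((r["gene_a"], r["gene_b"]))
            for _, r in pairs.iterrows()
        }
        assert got == expected


class TestExpressionRatio:
    def test_constant_two_to_one_ratio(self):
        tpm = pd.DataFrame(
            [[4.0, 6.0, 8.0], [2.0, 3.0, 4.0]], index=["INXB", "INXD"]
        )
        ratios, med, mad = expression_ratio(tpm, "INXB", "INXD")
        assert list(ratios) == [2.0, 2.0, 2.0]
        assert med == 2.0 and mad == 0.0

    def test_equal_genes_give_unit_ratio(self):
        tpm = pd.DataFrame([[3.0, 5.0], [3.0, 5.0]], index=["a", "b"])
        _, med, _ = expression_ratio(tpm, "a", "b")
        assert med == 1.0

    def test_all_zero_denominator_errors(self):
        tpm = pd.DataFrame([[1.0], [0.0]], index=["a", "b"])
        with pytest.raises(ValueError):
            expression_ratio(tpm, "a", "b")

    def test_random_tables_match_elementwise_division(self):
        rng = np.random.default_rng(3)
        tpm = pd.DataFrame(rng.uniform(0.5, 10, size=(2, 9)),
                           index=["a", "b"])
        ratios, med, _ = expression_ratio(tpm, "a", "b")
        assert np.allclose(ratios, tpm.loc["a"] / tpm.loc["b"])
        assert med == pytest.approx(np.median(tpm.loc["a"] / tpm.loc["b"]))


class TestPlantedCoexpression:
    def test_planted_pair_percent_near_analytic_expectation(self):
        params = UMISimParams(
            metacell_sizes=(1000, 1000, 1000, 1000, 1000),
            planted_pairs=(PlantedPair("G000", "G001", 0.3),),
            seed=42,
        )
        sim = simulate_umi(params)
        cm = pairwise_coexpression(binarize(sim.umi), ["G000", "G001"])
        expected = sim.truth["pairs"][("G000", "G001")]["expected_percent"]
        assert cm.percent.loc["G000", "G001"] == pytest.approx(
            expected, abs=3.0
        )

    def test_full_program_fraction_and_depth_saturates(self):
        params = UMISimParams(
            metacell_sizes=(500,),
            mean_depth=60.0,
            dispersion=10.0,
            planted_pairs=(PlantedPair("G000", "G001", 1.0),),
            seed=7,
        )
        sim = simulate_umi(params)
        cm = pairwise_coexpression(binarize(sim.umi), ["G000", "G001"])
        assert cm.percent.loc["G000", "G001"] > 99.0
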