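"""Density thresholding, block counting, permutation inference, FDR."""

import numpy as np
import pandas as pd
import pytest

from mcnkit import (
    AssociationMatrix,
    build_mcn,
    count_connections,
    coupling_delta,
    default_density_grid,
    density_sweep_report,
    fdr_adjust,
    m_from_density,
    permutation_test,
    threshold_binarize,
)
from mcnkit.atlas import BLOCKS, block_sizes
from mcnkit.errors import ValidationError

from conftest import make_toy_atlas
from test_covariance import random_rates


def assoc_from_weights(W, rois, group="g", n=20):
    W = np.asarray(W, dtype=float)
    np.fill_diagonal(W, 0.0)
    return AssociationMatrix(
        r=W, z=np.arctanh(np.clip(W, -0.999999, 0.999999)), rois=tuple(rois),
        group=group, n_subjects=n,
    )


class TestThreshold:
    def test_m_rounding(self):
        assert m_from_density(0.20, 496) == 99  # 99.2 rounds half-up to 99
        assert m_from_density(1.0, 496) == 496
        assert m_from_density(0.25, 10) == 3  # 2.5 rounds half-up to 3
        with pytest.raises(ValidationError):
            m_from_density(0.0, 496)

    def test_keeps_exactly_the_strongest_edges(self):
        rois = ("a", "b", "c", "d")
        W = np.array(
            [
                [0.0, 0.9, 0.1, 0.5],
                [0.9, 0.0, 0.7, -0.2],
                [0.1, 0.7, 0.0, 0.3],
                [0.5, -0.2, 0.3, 0.0],
            ]
        )
        net = threshold_binarize(assoc_from_weights(W, rois), K=0.5)  # m = 3 of 6
        assert net.m == 3
        expected = {("a", "b"), ("b", "c"), ("a", "d")}
        kept = {
            (rois[i], rois[j])
            for i, j in zip(*np.triu_indices(4, 1))
            if net.adjacency[i, j]
        }
        assert kept == expected

    def test_full_density_complete_graph(self, atlas):
        rates = random_rates(30, 32, seed=0, columns=list(atlas.rois))
        net = threshold_binarize(build_mcn(rates), K=1.0)
        assert net.m == 496
        counts = count_connections(net, atlas)
        assert counts.counts == block_sizes(atlas)

    def test_signed_ranking_prefers_positive(self):
        rois = ("a", "b", "c", "d")
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = -0.95  # strong negative must NOT be retained
        W[2, 3] = W[3, 2] = 0.05
        W[0, 2] = W[2, 0] = 0.10
        net = threshold_binarize(assoc_from_weights(W, rois), K=2 / 6)
        assert net.adjacency[0, 1] == 0
        assert net.adjacency[2, 3] == 1 and net.adjacency[0, 2] == 1


class TestCounts:
    def test_hand_counted_toy(self):
        atlas = make_toy_atlas({"SN": 2, "DMN": 2})  # X = {A,B}, Y = {C,D}
        W = np.zeros((4, 4))
        for i, j, w in [(0, 1, 0.9), (2, 3, 0.8), (0, 2, 0.7)]:
            W[i, j] = W[j, i] = w
        net = threshold_binarize(assoc_from_weights(W, atlas.rois), K=0.5)
        counts = count_connections(net, atlas).counts
        assert counts["within_SN"] == 1 and counts["within_DMN"] == 1
        assert counts["SN_DMN"] == 1 and sum(counts.values()) == 3

    def test_empty_graph_all_zero(self, atlas):
        rates = random_rates(30, 32, seed=1, columns=list(atlas.rois))
        net = threshold_binarize(build_mcn(rates), K=1e-4)  # m = 0
        counts = count_connections(net, atlas)
        assert counts.m == 0 and all(v == 0 for v in counts.counts.values())

    @pytest.mark.parametrize("K", [0.05, 0.10, 0.20, 0.30, 0.77])
    def test_partition_sums_to_m(self, atlas, K):
        rates = random_rates(40, 32, seed=2, columns=list(atlas.rois))
        net = threshold_binarize(build_mcn(rates), K=K)
        counts = count_connections(net, atlas)
        assert sum(counts.counts.values()) == net.m == m_from_density(K, 496)


class TestCouplingDelta:
    def test_identical_groups_give_zero(self, atlas):
        half = random_rates(20, 32, seed=3, columns=list(atlas.rois))
        dup = half.copy()
        dup.index = [f"T{i:03d}" for i in range(20)]
        rates = pd.concat([half, dup])
        labels = pd.Series(["low"] * 20 + ["high"] * 20, index=rates.index)
        delta = coupling_delta(rates, labels, K=0.20, atlas=atlas)
        assert (delta == 0).all()

    def test_swapping_labels_negates_delta(self, atlas):
        rates = random_rates(40, 32, seed=4, columns=list(atlas.rois))
        labels = pd.Series(["low"] * 20 + ["high"] * 20, index=rates.index)
        swapped = labels.map({"low": "high", "high": "low"})
        d1 = coupling_delta(rates, labels, K=0.20, atlas=atlas)
        d2 = coupling_delta(rates, swapped, K=0.20, atlas=atlas)
        assert (d1 == -d2).all()

    def test_block_deltas_sum_to_zero(self, atlas):
        rates = random_rates(50, 32, seed=5, columns=list(atlas.rois))
        labels = pd.Series(["low"] * 25 + ["high"] * 25, index=rates.index)
        for K in (0.10, 0.20, 0.30):
            assert coupling_delta(rates, labels, K=K, atlas=atlas).sum() == 0


class TestPermutationTest:
    def test_p_values_on_smoothed_grid_and_deterministic(self, toy_atlas6):
        rates = random_rates(16, 6, seed=6, columns=list(toy_atlas6.rois))
        labels = pd.Series(["low"] * 8 + ["high"] * 8, index=rates.index)
        res1 = permutation_test(rates, labels, K_values=[0.2, 0.4], n_perm=100,
                                seed=11, atlas=toy_atlas6)
        res2 = permutation_test(rates, labels, K_values=[0.2, 0.4], n_perm=100,
                                seed=11, atlas=toy_atlas6)
        pd.testing.assert_frame_equal(res1, res2)
        # add-one smoothing: every p is (1 + c) / (1 + n_perm)
        counts = res1["p"] * 101 - 1
        np.testing.assert_allclose(counts, np.round(counts), atol=1e-9)
        assert ((res1["p"] > 0) & (res1["p"] <= 1)).all()
        assert (res1["q"] >= res1["p"] - 1e-12).all()

    def test_seed_sensitivity_is_monte_carlo_bounded(self, toy_atlas6):
        rates = random_rates(24, 6, seed=7, columns=list(toy_atlas6.rois))
        labels = pd.Series(["low"] * 12 + ["high"] * 12, index=rates.index)
        kw = dict(K_values=[0.3], n_perm=2000, atlas=toy_atlas6)
        pa = permutation_test(rates, labels, seed=1, **kw).set_index("block")["p"]
        pb = permutation_test(rates, labels, seed=2, **kw).set_index("block")["p"]
        bound = 4 * np.sqrt(pa * (1 - pa) / 2000) + 2 / 2001
        assert (np.abs(pa - pb) <= bound).all()

    def test_requires_enough_permutations(self, toy_atlas6):
        rates = random_rates(16, 6, seed=8, columns=list(toy_atlas6.rois))
        labels = pd.Series(["low"] * 8 + ["high"] * 8, index=rates.index)
        with pytest.raises(ValidationError, match="n_perm"):
            permutation_test(rates, labels, K_values=[0.2], n_perm=50, atlas=toy_atlas6)


def bh_stepup_oracle(p):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestFdr:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(fdr_adjust([0.42]), [0.42])
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValidationError):
            fdr_adjust([0.0, 0.5])

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_adjust(p), bh_stepup_oracle(p), atol=1e-12)


class TestDensitySweep:
    def test_default_grid_dimensions(self, atlas):
        grid = default_density_grid()
        assert len(grid) == 21
        rates = random_rates(40, 32, seed=9, columns=list(atlas.rois))
        labels = pd.Series(["low"] * 20 + ["high"] * 20, index=rates.index)
        res = permutation_test(rates, labels, K_values=grid, n_perm=100, seed=3, atlas=atlas)
        assert len(res) == 21 * 6
        report = density_sweep_report(res, report_K=0.20)
        assert report["is_report_density"].sum() == 6

    def test_single_density_consistency_is_one(self, toy_atlas6):
        rates = random_rates(16, 6, seed=10, columns=list(toy_atlas6.rois))
        labels = pd.Series(["low"] * 8 + ["high"] * 8, index=rates.index)
        res = permutation_test(rates, labels, K_values=[0.2], n_perm=100, seed=5,
                               atlas=toy_atlas6)
        report = density_sweep_report(res, report_K=0.2)
        assert (report["consistency"] == 1.0).all()

    def test_missing_report_density_raises(self, toy_atlas6):
        rates = random_rates(16, 6, seed=12, columns=list(toy_atlas6.rois))
        labels = pd.Series(["low"] * 8 + ["high"] * 8, index=rates.index)
        res = permutation_test(rates, labels, K_values=[0.2], n_perm=100, seed=5,
                               atlas=toy_atlas6)
        with pytest.raises(ValidationError):
            density_sweep_report(res, report_K=0.25)
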