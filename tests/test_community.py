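import numpy as np
import pandas as pd
import pytest
import skbio
from skbio.stats.distance import permanova as skbio_permanova

from micage import (
    FeatureTable,
    alpha_diversity,
    beta_diversity,
    chao1,
    collapse_taxonomy,
    fb_ratio,
    pcoa,
    permanova,
    rarefy,
    relative_abundance,
    shannon,
    simpson,
    sim_community,
    sim_tree,
    CommunitySimSpec,
)
from conftest import (
    brute_force_bray_curtis,
    brute_force_jaccard,
    brute_force_unweighted_unifrac,
    brute_force_weighted_unifrac,
)


class TestAlphaDiversity:
    def test_uniform_counts(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(np.log(4))
        assert simpson([1, 1, 1, 1]) == pytest.approx(0.75)

    def test_simpson_hand_computed(self):
        # p = (0.5, 0.3, 0.2) -> 1 - (0.25 + 0.09 + 0.04)
        assert simpson([5, 3, 2]) == pytest.approx(0.62)

    @pytest.mark.parametrize("counts,expected", [
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
        ([1] * 4 + [2] * 2 + [5] * 4, 12.0),
        # no singletons -> chao1 = S_obs
        ([2, 2, 3, 5], 4.0),
    ])
    def test_chao1(self, counts, expected):
        assert chao1(np.array(counts)) == pytest.approx(expected)

    def test_all_zero_sample_rejected(self, small_table):
        bad = small_table.data.copy()
        bad.iloc[0] = 0
        table = FeatureTable(bad, small_table.groups)
        with pytest.raises(ValueError):
            alpha_diversity(table)

    def test_invariant_to_feature_order(self, small_table):
        res = alpha_diversity(small_table)
        shuffled = FeatureTable(
            small_table.data[small_table.data.columns[::-1]],
            small_table.groups)
        res2 = alpha_diversity(shuffled)
        pd.testing.assert_series_equal(res.shannon, res2.shannon)
        pd.testing.assert_series_equal(res.chao1, res2.chao1)


class TestRarefy:
    def test_row_sums_equal_depth(self, small_table):
        out = rarefy(small_table, depth=50, seed=0)
        assert (out.data.sum(axis=1) == 50).all()

    def test_depth_at_total_preserves_sample(self, small_table):
        totals = small_table.data.sum(axis=1)
        depth = int(totals.min())
        out = rarefy(small_table, depth=depth, seed=0)
        smallest = totals.idxmin()
        pd.testing.assert_series_equal(out.data.loc[smallest],
                                       small_table.data.loc[smallest])

    def test_deterministic(self, small_table):
        a = rarefy(small_table, depth=40, seed=3)
        b = rarefy(small_table, depth=40, seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_depth_exceeding_all_samples_errors(self, small_table):
        with pytest.raises(ValueError):
            rarefy(small_table, depth=10 ** 9)


class TestBetaDiversity:
    def test_identical_samples_distance_zero(self, toy_tree):
        data = pd.DataFrame([[3, 1, 0, 2]] * 2, index=["x", "y"],
                            columns=list("ABCD"))
        table = FeatureTable(data, pd.Series(["a", "b"], index=["x", "y"]))
        for metric in ("bray_curtis", "jaccard", "unweighted_unifrac",
                       "weighted_unifrac"):
            dm = beta_diversity(table, metric, tree=toy_tree)
            assert dm["x", "y"] == pytest.approx(0.0, abs=1e-12)

    def test_bray_curtis_hand_computed(self):
        data = pd.DataFrame([[2, 0, 1], [0, 2, 1]], index=["x", "y"],
                            columns=["t0", "t1", "t2"])
        table = FeatureTable(data, pd.Series(["a", "b"], index=["x", "y"]))
        dm = beta_diversity(table, "bray_curtis")
        assert dm["x", "y"] == pytest.approx(4 / 6)

    def test_unifrac_on_toy_tree(self, toy_tree):
        # disjoint single-leaf samples on symmetric cherries
        data = pd.DataFrame([[1, 0, 0, 0], [0, 0, 1, 0]], index=["x", "y"],
                            columns=list("ABCD"))
        table = FeatureTable(data, pd.Series(["a", "b"], index=["x", "y"]))
        dm = beta_diversity(table, "weighted_unifrac", tree=toy_tree)
        assert dm["x", "y"] == pytest.approx(1.0)
        data2 = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["x", "y"],
                             columns=list("ABCD"))
        table2 = FeatureTable(data2, pd.Series(["a", "b"], index=["x", "y"]))
        dm2 = beta_diversity(table2, "unweighted_unifrac", tree=toy_tree)
        assert dm2["x", "y"] == pytest.approx(1.0)

    def test_all_metrics_match_brute_force(self):
        rng = np.random.default_rng(11)
        data = pd.DataFrame(rng.integers(0, 30, size=(5, 8)),
                            index=[f"s{i}" for i in range(5)],
                            columns=[f"t{i:02d}" for i in range(8)])
        data.iloc[0, :4] = 0  # exercise absences
        table = FeatureTable(data, pd.Series(["a"] * 3 + ["b"] * 2,
                                             index=data.index))
        tree = sim_tree(8, seed=5)
        tree_ids = sorted(t.name for t in tree.tips())
        tree = skbio.TreeNode.read(
            [str(tree).replace("taxon_0", "t")])  # relabel to t00..t07
        oracles = {
            "bray_curtis": lambda x, y: brute_force_bray_curtis(x, y),
            "jaccard": lambda x, y: brute_force_jaccard(x, y),
            "unweighted_unifrac": lambda x, y:
                brute_force_unweighted_unifrac(x, y, tree, list(data.columns)),
            "weighted_unifrac": lambda x, y:
                brute_force_weighted_unifrac(x, y, tree, list(data.columns)),
        }
        for metric, oracle in oracles.items():
            dm = beta_diversity(table, metric, tree=tree)
            for i in range(5):
                for j in range(i + 1, 5):
                    expect = oracle(data.iloc[i].values, data.iloc[j].values)
                    assert dm[data.index[i], data.index[j]] == \
                        pytest.approx(expect, abs=1e-12), metric

    def test_weighted_unifrac_sample_scale_invariance(self, toy_tree):
        data = pd.DataFrame([[3, 1, 2, 0], [1, 0, 4, 2]], index=["x", "y"],
                            columns=list("ABCD"))
        table = FeatureTable(data, pd.Series(["a", "b"], index=["x", "y"]))
        scaled = FeatureTable(data.mul([1.0, 7.0], axis=0),
                              pd.Series(["a", "b"], index=["x", "y"]))
        d1 = beta_diversity(table, "weighted_unifrac", tree=toy_tree)
        d2 = beta_diversity(scaled, "weighted_unifrac", tree=toy_tree)
        assert d1["x", "y"] == pytest.approx(d2["x", "y"], abs=1e-12)

    def test_missing_tree_leaf_refused(self, toy_tree):
        data = pd.DataFrame([[1, 2], [2, 1]], index=["x", "y"],
                            columns=["A", "Z"])
        table = FeatureTable(data, pd.Series(["a", "b"], index=["x", "y"]))
        with pytest.raises(ValueError, match="missing"):
            beta_diversity(table, "unweighted_unifrac", tree=toy_tree)


class TestPermanova:
    def _dm(self, n, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 4))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        return skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])

    def test_exhaustive_two_vs_two_lattice(self):
        dm = self._dm(4, 0)
        groups = pd.Series(["a", "a", "b", "b"], index=dm.ids)
        res = permanova(dm, groups, n_perm=999, seed=0)
        assert res.exhaustive and res.n_permutations == 6
        assert (res.p_value * 6) == pytest.approx(round(res.p_value * 6))

    def test_minimum_p_with_999_permutations(self):
        # Monte-Carlo p = (1 + hits) / (1 + 999) >= 0.001
        dm = self._dm(16, 1)
        groups = pd.Series(["a"] * 8 + ["b"] * 8, index=dm.ids)
        res = permanova(dm, groups, n_perm=999, seed=0)
        assert res.p_value >= 1 / 1000

    def test_matches_skbio_pseudo_f(self):
        dm = self._dm(12, 2)
        groups = ["a"] * 6 + ["b"] * 6
        res = permanova(dm, pd.Series(groups, index=dm.ids), n_perm=99, seed=0)
        ref = skbio_permanova(dm, grouping=list(groups), permutations=99)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_group_of_one_rejected(self):
        dm = self._dm(4, 3)
        groups = pd.Series(["a", "b", "b", "b"], index=dm.ids)
        with pytest.raises(ValueError):
            permanova(dm, groups)


class TestPcoa:
    def test_equilateral_configuration(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = skbio.DistanceMatrix(d, ids=list("xyz"))
        res = pcoa(dm)
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1])
        assert res.eigenvalues[0] > 0

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = skbio.DistanceMatrix(d, ids=[f"s{i}" for i in range(6)])
        res = pcoa(dm)
        coords = res.coordinates.values
        d2 = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
        assert np.allclose(d, d2, atol=1e-9)

    def test_duplicate_sample_coincident(self):
        x = np.array([[0.0, 0], [1, 0], [1, 0], [0, 2]])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        dm = skbio.DistanceMatrix(d, ids=list("abcd"))
        res = pcoa(dm)
        assert np.allclose(res.coordinates.loc["b"], res.coordinates.loc["c"],
                           atol=1e-9)


class TestComposition:
    taxonomy = {"t0": "Firmicutes;F1;G1", "t1": "Firmicutes;F1;G2",
                "t2": "Bacteroidetes;B1;G3", "t3": "Proteobacteria;P1;G4"}

    def _table(self, rows):
        data = pd.DataFrame(rows, index=[f"s{i}" for i in range(len(rows))],
                            columns=["t0", "t1", "t2", "t3"])
        return FeatureTable(data, pd.Series("a", index=data.index))

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(9)
        table = self._table(rng.integers(1, 50, size=(4, 4)))
        rel = relative_abundance(table)
        assert np.allclose(rel.data.sum(axis=1), 1.0, atol=1e-12)

    def test_single_phylum_is_all(self):
        table = self._table([[5, 5, 0, 0]])
        phylum = collapse_taxonomy(table, self.taxonomy, level=0)
        rel = relative_abundance(phylum)
        assert rel.data.loc["s0", "Firmicutes"] == pytest.approx(1.0)

    def test_fb_ratio_hand_computed(self):
        # Firmicutes 60, Bacteroidetes 30, other 10 -> 2.0
        table = self._table([[40, 20, 30, 10]])
        assert fb_ratio(table, self.taxonomy)["s0"] == pytest.approx(2.0)

    def test_fb_ratio_undefined_without_bacteroidetes(self):
        table = self._table([[40, 20, 0, 10]])
        assert np.isnan(fb_ratio(table, self.taxonomy)["s0"])


class TestNullCalibration:
    def test_permanova_rejection_rate_on_exchangeable_data(self):
        """Type-I error of PERMANOVA at alpha=0.05 on exchangeable tables."""
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            tbl, _ = sim_community(CommunitySimSpec(
                n_taxa=20, n_per_group=6, sequencing_depth=1000, seed=rep))
            dm = beta_diversity(tbl, "bray_curtis")
            res = permanova(dm, tbl.groups, n_perm=199, seed=700_000 + rep)
            rej += res.p_value <= 0.05
        assert 0.02 <= rej / n_rep <= 0.09
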