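import math

import numpy as np
import pandas as pd
import pytest

import lea

from . import oracles


@pytest.fixture(scope="module")
def donor_series(small_dataset):
    return small_dataset["cells"].column("donor_id")


class TestGeneAssociation:
    def test_collinear_gene_equals_age_lea(self, small_index, small_dataset, donor_series):
        """A gene exactly affine in donor age gives the identical per-cell result."""
        age = small_dataset["donor_meta"].set_index("donor_id")["age"]
        expr = lea.ExpressionTable(
            pd.DataFrame({"fake": 0.5 * age + 3.0}).T.rename_axis("gene_id")
        )
        by_gene = lea.gene_association(small_index, donor_series, expr, "fake")
        by_age = lea.lea_continuous(small_index, donor_series, age)
        np.testing.assert_allclose(by_gene.p, by_age.p, atol=1e-12)
        np.testing.assert_allclose(by_gene.signed_score, by_age.signed_score, atol=1e-12)

    def test_constant_gene_gives_null_scores(self, small_index, donor_series, small_dataset):
        donors = small_dataset["expression"].donors
        expr = lea.ExpressionTable(
            pd.DataFrame([[2.0] * len(donors)], index=["flat"], columns=donors)
        )
        res = lea.gene_association(small_index, donor_series, expr, "flat")
        assert np.all(res.p == 1.0)
        assert np.all(res.signed_score == 0.0)

    def test_negated_gene_negates_scores(self, small_index, small_dataset, donor_series):
        et = small_dataset["expression"]
        gene = et.df.index[0]
        flipped = lea.ExpressionTable((et.df.max().max() - et.df).rename_axis("gene_id"))
        a = lea.gene_association(small_index, donor_series, et, gene)
        b = lea.gene_association(small_index, donor_series, flipped, gene)
        np.testing.assert_allclose(a.signed_score, -b.signed_score, atol=1e-12)

    def test_missing_gene_raises(self, small_index, small_dataset, donor_series):
        with pytest.raises(KeyError):
            lea.gene_association(small_index, donor_series, small_dataset["expression"], "nope")

    def test_signal_gene_recovers_planted_cluster(self, small_index, small_dataset, donor_series):
        truth = small_dataset["truth"]
        signal = truth.genes.loc[truth.genes["is_signal"], "gene_id"].iloc[0]
        res = lea.gene_association(small_index, donor_series, small_dataset["expression"], signal)
        in_cluster = truth.cells["cluster"].to_numpy() == 0
        assert lea.benchmark_aroc(res.signed_score, in_cluster) >= 0.9


class TestPathwayTtest:
    def test_identical_scores_give_p_one_direction_zero(self):
        scores = pd.DataFrame(np.full((3, 6), 1.5), columns=[f"g{i}" for i in range(6)])
        ann = lea.PathwayAnnotation({"pw": {"g0", "g1", "g2"}})
        res = lea.pathway_ttest(scores, ann)
        assert np.all(res.p["pw"] == 1.0)
        assert np.all(res.direction["pw"] == 0.0)

    def test_shift_sets_direction_and_monotone_p(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(1, 20))
        genes = [f"g{i}" for i in range(20)]
        ann = lea.PathwayAnnotation({"pw": set(genes[:8])})
        ps = []
        for delta in (0.5, 1.5, 3.0):
            x = base.copy()
            x[0, :8] += delta
            res = lea.pathway_ttest(pd.DataFrame(x, columns=genes), ann)
            assert res.direction["pw"].iloc[0] == 1.0
            ps.append(res.p["pw"].iloc[0])
        assert ps[0] > ps[1] > ps[2]

    def test_matches_welch_oracle(self):
        pathway_scores = [2, 2, 3, 3, 2.5]
        background = [0, 0.5, -0.5, 0, 0.2]
        genes = [f"g{i}" for i in range(10)]
        scores = pd.DataFrame([pathway_scores + background], columns=genes)
        ann = lea.PathwayAnnotation({"pw": set(genes[:5])})
        res = lea.pathway_ttest(scores, ann)
        expected = oracles.welch_t_p(np.array(pathway_scores), np.array(background))
        assert res.p["pw"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_pooled_variance_matches_scipy(self):
        from scipy import stats as ss

        rng = np.random.default_rng(3)
        x = rng.normal(size=(4, 15))
        genes = [f"g{i}" for i in range(15)]
        ann = lea.PathwayAnnotation({"pw": set(genes[:6])})
        res = lea.pathway_ttest(pd.DataFrame(x, columns=genes), ann, equal_var=True)
        for row in range(4):
            ref = ss.ttest_ind(x[row, :6], x[row, 6:], equal_var=True)
            assert res.p["pw"].iloc[row] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_small_pathway_skipped_with_warning(self):
        scores = pd.DataFrame(np.ones((2, 5)), columns=[f"g{i}" for i in range(5)])
        ann = lea.PathwayAnnotation({"small": {"g0"}, "ok": {"g0", "g1"}})
        with pytest.warns(UserWarning, match="skipped"):
            res = lea.pathway_ttest(scores, ann)
        assert res.skipped == ["small"]
        assert list(res.p.columns) == ["ok"]


class TestPathwayHypergeom:
    def test_disjoint_pathway_p_one(self):
        scores = pd.Series(
            np.linspace(0.1, 2.0, 20), index=[f"g{i}" for i in range(20)]
        )
        ann = lea.PathwayAnnotation({"pw": {"g0", "g1"}})  # lowest scores
        res = lea.pathway_hypergeom(scores, ann, percentile=0.9)
        assert res.loc[res.pathway_id == "pw", "p"].iloc[0] == 1.0

    def test_pathway_equal_to_top_set(self):
        genes = [f"g{i}" for i in range(100)]
        scores = pd.Series(np.arange(1.0, 101.0), index=genes)
        ann = lea.PathwayAnnotation({"top5": set(genes[-5:])})
        res = lea.pathway_hypergeom(scores, ann, percentile=0.95)
        expected = 1 / math.comb(100, 5)
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-12)
        assert res["overlap"].iloc[0] == 5

    def test_matches_enumeration_small_universe(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(12)]
        scores = pd.Series(rng.permutation(np.arange(1.0, 13.0)), index=genes)
        ann = lea.PathwayAnnotation({"pw": set(genes[:4])})
        res = lea.pathway_hypergeom(scores, ann, percentile=0.7)
        thr = np.quantile(scores[scores > 0].to_numpy(), 0.7)
        top = set(scores.index[scores > thr])
        expected = oracles.top_set_overlap_p(12, top, set(genes[:4]), genes)
        assert res["p"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_empty_top_set_all_p_one(self):
        scores = pd.Series([-1.0, -2.0, -0.5], index=["a", "b", "c"])
        ann = lea.PathwayAnnotation({"pw": {"a", "b"}})
        res = lea.pathway_hypergeom(scores, ann)
        assert (res["p"] == 1.0).all()

    def test_bad_percentile_raises(self):
        scores = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError):
            lea.pathway_hypergeom(scores, lea.PathwayAnnotation({"pw": {"a"}}), percentile=1.5)


class TestAroc:
    def test_perfect_separation(self):
        assert lea.benchmark_aroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_one_swap_gives_three_quarters(self):
        assert lea.benchmark_aroc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == 0.75

    def test_chance_level_for_independent_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        truth = rng.random(4000) < 0.5
        assert lea.benchmark_aroc(scores, truth) == pytest.approx(0.5, abs=0.03)

    def test_matches_pair_counting_oracle_with_ties(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 5, size=40).astype(float)  # plenty of ties
        truth = rng.random(40) < 0.4
        expected = oracles.aroc_pair_count(scores, truth)
        assert lea.benchmark_aroc(scores, truth) == pytest.approx(expected, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=100)
        truth = rng.random(100) < 0.5
        a = lea.benchmark_aroc(scores, truth)
        b = lea.benchmark_aroc(np.exp(3 * scores), truth)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            lea.benchmark_aroc([0.1, 0.9], [1, 1])


class TestSignedGroupDifference:
    def test_identical_groups_score_zero(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        score, p = lea.signed_group_difference(x, [0, 1, 2], [3, 4, 5])
        assert score == 0.0 and p == 1.0

    def test_sign_convention_pos_below_neg(self):
        # positive group median below negative group median -> positive score
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(1.0, 0.5, 200), rng.normal(2.0, 0.5, 200)])
        score, p = lea.signed_group_difference(x, np.arange(200), np.arange(200, 400))
        assert score > 0 and p < 1e-10

    def test_p_matches_welch_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.normal(1.0, 1.0, 200)
        b = rng.normal(0.0, 1.0, 200)
        x = np.concatenate([a, b])
        _, p = lea.signed_group_difference(x, np.arange(200), np.arange(200, 400))
        assert p == pytest.approx(oracles.welch_t_p(a, b), rel=1e-10)

    def test_zero_negative_median_raises(self):
        x = np.array([1.0, 2.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="median"):
            lea.signed_group_difference(x, [0, 1], [2, 3, 4])

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            lea.signed_group_difference(np.ones(3), [], [0, 1, 2])


class TestBinnedAssociation:
    @staticmethod
    def _wells(n_wells=6, cells_per_well=200, slope=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for w in range(n_wells):
            bf = rng.uniform(0, 1, cells_per_well)
            resp = 10.0 - slope * bf + rng.normal(0, 0.2, cells_per_well)
            rows.append(pd.DataFrame({"well_id": f"W{w}", "bright_field": bf, "mito": resp}))
        return pd.concat(rows, ignore_index=True)

    def test_equal_bin_occupancy_within_well(self):
        cells = self._wells(n_wells=2, cells_per_well=200)
        res = lea.binned_feature_association(cells, "bright_field", "mito")
        # every bin mean defined in every well (20 cells per bin expected)
        assert not res.well_means.isna().any().any()

    def test_null_response_not_significant(self):
        cells = self._wells(slope=0.0, seed=1)
        res = lea.binned_feature_association(cells, "bright_field", "mito")
        adjusted = lea.adjust_pvalues(res.bins["p"].to_numpy()[:-1], 9)
        assert (adjusted > 0.05).all()

    def test_monotone_response_detected(self):
        cells = self._wells(slope=5.0, seed=2)
        res = lea.binned_feature_association(cells, "bright_field", "mito")
        means = res.bins["mean"].to_numpy()
        assert np.all(np.diff(means) < 0)  # strictly decreasing in bin feature
        assert (res.bins["p"].to_numpy()[:5] < 1e-4).all()
        assert res.bins["p"].iloc[-1] == 1.0  # reference bin vs itself

    def test_small_well_skipped_with_warning(self):
        cells = self._wells(n_wells=3, cells_per_well=50)
        tiny = pd.DataFrame({"well_id": "Wtiny", "bright_field": [0.5] * 4, "mito": [1.0] * 4})
        with pytest.warns(UserWarning, match="skipped"):
            res = lea.binned_feature_association(
                pd.concat([cells, tiny], ignore_index=True), "bright_field", "mito"
            )
        assert res.skipped_wells == ["Wtiny"]

    def test_needs_two_wells(self):
        cells = self._wells(n_wells=1)
        with pytest.raises(ValueError):
            lea.binned_feature_association(cells, "bright_field", "mito")
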