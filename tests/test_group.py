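"""Two-group learning, the weight table, and the permutation test."""

import numpy as np
import pandas as pd
import pytest

import graybn as gb

from conftest import cohort_from_matrix, two_group_cohort


def skeleton_pr(learned, true_dag):
    ls, ts = learned.skeleton(), true_dag.skeleton()
    tp = len(ls & ts)
    return tp / max(len(ls), 1), tp / len(ts)


#: Analysis configuration for full-cohort structure learning: seeded random
#: restarts guard against greedy local optima (see docs/methods.md).
ANALYSIS_CONFIG = gb.SearchConfig(restarts=20, seed=202)


class TestLearnGroupModels:
    def test_generators_recovered_per_group(self, young_model, old_model):
        cohort = two_group_cohort(young_model, old_model, 2000, 2000, seed=1)
        models = gb.learn_group_models(cohort, ANALYSIS_CONFIG)
        p_y, r_y = skeleton_pr(models.model_a.dag, young_model.dag)
        p_o, r_o = skeleton_pr(models.model_b.dag, old_model.dag)
        assert min(p_y, r_y) >= 0.8
        assert min(p_o, r_o) >= 0.8

    def test_shared_generator_gives_shared_union(self, young_model):
        """Both groups drawn from one model: every true adjacency lands in
        the edge union and each learned model stays precise (the union
        itself accumulates both models' few extras)."""
        cohort = two_group_cohort(young_model, young_model, 2000, 2000, seed=2)
        models = gb.learn_group_models(cohort, ANALYSIS_CONFIG)
        union_skel = {frozenset(e) for e in models.edge_union}
        true_skel = set(young_model.dag.skeleton())
        assert len(union_skel & true_skel) / len(true_skel) >= 0.8
        for res in (models.model_a, models.model_b):
            p, _ = skeleton_pr(res.dag, young_model.dag)
            assert p >= 0.8

    def test_three_groups_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        cohort = cohort_from_matrix(X, ["A", "B"], ["g1"] * 10 + ["g2"] * 10 + ["g3"] * 10)
        with pytest.raises(ValueError, match="two group"):
            gb.learn_group_models(cohort)

    def test_small_group_rejected(self):
        X = np.random.default_rng(0).normal(size=(12, 3))
        cohort = cohort_from_matrix(X, ["A", "B", "C"], ["g1"] * 8 + ["g2"] * 4)
        with pytest.raises(ValueError, match="too small"):
            gb.learn_group_models(cohort)


class TestWeightTable:
    def test_empty_models(self):
        net = gb.make_group_model(gb.GroupSpec(label="g", n=5), roi_names=("A", "B"))
        models = gb.GroupModels(
            labels=("a", "b"),
            results={
                "a": gb.GaussianBNResults(None, net),
                "b": gb.GaussianBNResults(None, net),
            },
        )
        assert len(gb.weight_table(models)) == 0

    def test_reversed_edge_is_category_iv(self):
        net_a = gb.make_group_model(
            gb.GroupSpec(label="a", n=5, edges={("X", "Y"): 0.5}), ("X", "Y")
        )
        net_b = gb.make_group_model(
            gb.GroupSpec(label="b", n=5, edges={("Y", "X"): 0.5}), ("X", "Y")
        )
        models = gb.GroupModels(
            labels=("a", "b"),
            results={
                "a": gb.GaussianBNResults(None, net_a),
                "b": gb.GaussianBNResults(None, net_b),
            },
        )
        wt = gb.weight_table(models)
        assert list(wt["category"]) == ["IV", "IV"]

    def test_published_partition_reproduced(self, generator_group_models):
        """Models parameterised with the published young/old structures and
        weights tabulate into the published category partition."""
        wt = gb.weight_table(generator_group_models).set_index(["parent", "child"])
        expected = {
            ("lHP", "mPFC"): "I",
            ("rITC", "lITC"): "I",
            ("rITC", "mPFC"): "I",
            ("rHP", "rITC"): "II",
            ("PCC", "lIPC"): "II",
            ("mPFC", "PCC"): "II",
            ("mPFC", "lIPC"): "II",
            ("lITC", "lHP"): "III",
            ("rIPC", "rITC"): "III",
            ("PCC", "rIPC"): "III",
            ("rHP", "lHP"): "IV",
            ("lHP", "rHP"): "IV",
            ("rIPC", "lIPC"): "IV",
            ("lIPC", "rIPC"): "IV",
        }
        assert len(wt) == len(expected)
        for edge, cat in expected.items():
            assert wt.loc[edge, "category"] == cat
        # the tabulated weights are the generating coefficients
        assert wt.loc[("rHP", "lHP"), "weight_a"] == pytest.approx(0.921)
        assert wt.loc[("lHP", "rHP"), "weight_b"] == pytest.approx(0.773)


class TestPermutationTest:
    def make_null_cohort(self, seed=0, n=60):
        net = gb.make_group_model(
            gb.GroupSpec(label="g", n=n, edges={("A", "B"): 0.6}), ("A", "B", "C")
        )
        return two_group_cohort(net, net, n, n, labels=("a", "b"), seed=seed)

    def test_reproducible_given_seed(self):
        cohort = self.make_null_cohort(seed=3)
        models = gb.learn_group_models(cohort)
        r1 = gb.permutation_test(cohort, models, n_perm=100, seed=5)
        r2 = gb.permutation_test(cohort, models, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_one_sided_p_values_sum_above_one(self):
        """With plain-proportion p values and tie counting,
        p_a_greater + p_b_greater >= 1 for every edge."""
        cohort = self.make_null_cohort(seed=4)
        models = gb.learn_group_models(cohort)
        res = gb.permutation_test(cohort, models, n_perm=200, seed=6)
        s = res.table["p_a_greater"] + res.table["p_b_greater"]
        assert (s >= 1 - 1e-12).all()
        assert res.table[["p_a_greater", "p_b_greater"]].min().min() >= 0
        assert res.table[["p_a_greater", "p_b_greater"]].max().max() <= 1

    def test_strong_group_difference_detected(self, ):
        """Edge coefficient 0.9 in group a vs 0 in group b at n=500/group is
        detected with p_a_greater <= 0.01 (fixed-structure fast mode)."""
        net_a = gb.make_group_model(
            gb.GroupSpec(label="a", n=500, edges={("A", "B"): 0.9}), ("A", "B")
        )
        net_b = gb.make_group_model(gb.GroupSpec(label="b", n=500), ("A", "B"))
        cohort = two_group_cohort(net_a, net_b, 500, 500, labels=("a", "b"), seed=7)
        models = gb.learn_group_models(cohort)
        res = gb.permutation_test(
            cohort, models, n_perm=500, seed=8, relearn_structure=False
        )
        t = res.table.set_index(["parent", "child"])
        # the strong edge is in the union in one orientation or the other
        p = None
        for e in [("A", "B"), ("B", "A")]:
            if e in t.index:
                p = t.loc[e, "p_a_greater"]
        assert p is not None and p <= 0.01

    def test_label_swap_symmetry(self):
        """Relabelling which group is 'a' negates the differences and swaps
        the two one-sided p values (same seed, fixed structures)."""
        cohort = self.make_null_cohort(seed=9)
        models = gb.learn_group_models(cohort)
        swapped = gb.GroupModels(
            labels=(models.labels[1], models.labels[0]), results=models.results
        )
        r = gb.permutation_test(cohort, models, n_perm=150, seed=10,
                                relearn_structure=False)
        rs = gb.permutation_test(cohort, swapped, n_perm=150, seed=10,
                                 relearn_structure=False)
        a = r.table.set_index(["parent", "child"]).sort_index()
        b = rs.table.set_index(["parent", "child"]).sort_index()
        np.testing.assert_allclose(a["observed_diff"], -b["observed_diff"], atol=1e-12)

    def test_too_few_permutations_rejected(self):
        cohort = self.make_null_cohort(seed=11)
        models = gb.learn_group_models(cohort)
        with pytest.raises(ValueError, match="n_perm"):
            gb.permutation_test(cohort, models, n_perm=50)


class TestFlagSignificant:
    def make_result(self, p_a):
        table = pd.DataFrame(
            {
                "parent": ["A"],
                "child": ["B"],
                "observed_diff": [0.3],
                "p_a_greater": [p_a],
                "p_b_greater": [1 - p_a],
            }
        )
        return gb.PermutationTestResult(table, ("a", "b"), 1000, 0)

    def test_inclusive_comparator_flags_boundary(self):
        """p = 0.050 is flagged at alpha 0.05 under the default inclusive
        comparator, not under the strict one."""
        res = self.make_result(0.050)
        assert gb.flag_significant(res)["a_greater"] == [("A", "B")]
        assert gb.flag_significant(res, inclusive=False)["a_greater"] == []

    def test_p_below_alpha_flagged(self):
        res = self.make_result(0.041)
        assert gb.flag_significant(res)["a_greater"] == [("A", "B")]

    def test_empty_results_and_bad_alpha(self):
        empty = gb.PermutationTestResult(
            pd.DataFrame(columns=["parent", "child", "observed_diff",
                                  "p_a_greater", "p_b_greater"]),
            ("a", "b"), 1000, 0,
        )
        flags = gb.flag_significant(empty)
        assert flags == {"a_greater": [], "b_greater": []}
        with pytest.raises(ValueError, match="alpha"):
            gb.flag_significant(empty, alpha=1.5)


class TestGroupComparisonObjects:
    def test_fit_returns_results_with_summary(self, young_model, old_model):
        cohort = two_group_cohort(young_model, old_model, 120, 100, seed=12)
        res = gb.GroupComparison(cohort).fit()
        text = res.summary()
        assert "young" in text and "old" in text
        assert isinstance(res.weight_table, pd.DataFrame)
        perm = res.permutation_test(n_perm=100, seed=1, relearn_structure=False)
        assert perm.n_permutations == 100
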