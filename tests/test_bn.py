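"""Linear-Gaussian network numerics: standardization, MLE, likelihood, BIC,
joint density, sampling, serialization."""

import json

import numpy as np
import pytest
from scipy import stats

import graybn as gb
from graybn.bn import FamilyScorer, Standardization

LOG_ROOT_2PI = 0.5 * np.log(2 * np.pi)


def chain_model(beta=0.8, d=3):
    """X0 -> X1 -> ... with equal coefficients and unit-variance roots."""
    names = tuple(f"X{i}" for i in range(d))
    edges = {(names[i], names[i + 1]): beta for i in range(d - 1)}
    return gb.make_group_model(
        gb.GroupSpec(label="g", n=10, edges=edges), roi_names=names
    )


class TestStandardize:
    def test_three_point_column(self):
        Z, std = gb.standardize(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(Z[:, 0], [-1, 0, 1])
        assert std.means[0] == 2 and std.sds[0] == 1

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        Z, _ = gb.standardize(rng.normal(size=(40, 3)))
        Z2, _ = gb.standardize(Z)
        np.testing.assert_allclose(Z, Z2, atol=1e-12)

    def test_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(1)
        Z, std = gb.standardize(rng.uniform(0, 5, size=(50, 8)))
        np.testing.assert_allclose(Z.mean(0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(0, ddof=1), 1, atol=1e-12)
        back = std.inverse(Z)
        np.testing.assert_allclose(gb.standardize(back)[0], Z, atol=1e-10)

    def test_zero_variance_column_named(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="flat"):
            gb.standardize(X, columns=["ok", "flat"])


class TestFitMle:
    def test_two_node_hand_example(self):
        """Child on parent least squares: beta = Sxy/Sxx = 1.5, MLE variance
        RSS/n = 0.5."""
        dag = gb.DAG(["X", "Y"], [("X", "Y")])
        net = gb.fit_mle(dag, np.array([[-1, -2], [0, 1], [1, 1]], float))
        cpd = net.cpds["Y"]
        assert cpd.coefficients[0] == pytest.approx(1.5)
        assert cpd.intercept == pytest.approx(0.0, abs=1e-12)
        assert cpd.residual_variance == pytest.approx(0.5)

    def test_parentless_node_is_sample_mean_and_mle_variance(self):
        dag = gb.DAG(["X"])
        net = gb.fit_mle(dag, np.array([[-1.0], [1.0], [-1.0], [1.0]]))
        assert net.cpds["X"].intercept == pytest.approx(0.0)
        assert net.cpds["X"].residual_variance == pytest.approx(1.0)

    def test_empty_graph_equals_univariate_fits(self):
        rng = np.random.default_rng(3)
        X = rng.normal(2, 3, size=(60, 8))
        dag = gb.DAG([f"X{i}" for i in range(8)])
        net = gb.fit_mle(dag, X)
        total = sum(net.node_log_likelihood(X, n) for n in dag.nodes)
        expected = sum(
            stats.norm.logpdf(X[:, j], X[:, j].mean(), X[:, j].std(ddof=0)).sum()
            for j in range(8)
        )
        assert total == pytest.approx(expected, rel=1e-10)

    def test_collinear_parents_error_names_node(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        X = np.column_stack([x, x, rng.normal(size=50)])
        dag = gb.DAG(["A", "B", "C"], [("A", "C"), ("B", "C")])
        with pytest.raises(np.linalg.LinAlgError, match="C"):
            gb.fit_mle(dag, X)

    def test_single_parent_weight_is_pearson_correlation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = 0.6 * x + rng.normal(size=200)
        Z, _ = gb.standardize(np.column_stack([x, y]))
        net = gb.fit_mle(gb.DAG(["X", "Y"], [("X", "Y")]), Z)
        r = stats.pearsonr(x, y).statistic
        assert net.edge_weight("X", "Y") == pytest.approx(r, abs=1e-9)

    def test_null_coefficient_is_small(self):
        rng = np.random.default_rng(6)
        Z, _ = gb.standardize(rng.normal(size=(2000, 2)))
        net = gb.fit_mle(gb.DAG(["X", "Y"], [("X", "Y")]), Z)
        assert abs(net.edge_weight("X", "Y")) < 0.08

    def test_near_deterministic_edge_weight_near_one(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=500)
        y = x + 1e-3 * rng.normal(size=500)
        Z, _ = gb.standardize(np.column_stack([x, y]))
        net = gb.fit_mle(gb.DAG(["X", "Y"], [("X", "Y")]), Z)
        assert net.edge_weight("X", "Y") == pytest.approx(1.0, abs=0.05)

    def test_absent_edge_weight_rejected(self):
        net = chain_model()
        with pytest.raises(ValueError, match="not in the model"):
            net.edge_weight("X2", "X0")


class TestLikelihoodAndBic:
    def test_standard_normal_point_density(self):
        dag = gb.DAG(["X"])
        net = gb.fit_mle(dag, np.array([[-1.0], [1.0], [-1.0], [1.0]]))
        assert net.logpdf(np.array([0.0]), use_standardization=False) == pytest.approx(
            -LOG_ROOT_2PI
        )

    def test_four_point_node_log_likelihood(self):
        dag = gb.DAG(["X"])
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        net = gb.fit_mle(dag, X)
        assert net.node_log_likelihood(X, "X") == pytest.approx(
            4 * (-LOG_ROOT_2PI - 0.5)
        )

    def test_bic_single_node_hand_value(self):
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        got = gb.bic_score(gb.DAG(["X"]), X)
        assert got == pytest.approx(4 * (-LOG_ROOT_2PI - 0.5) - np.log(4))
        assert got == pytest.approx(-7.062048, abs=1e-6)

    def test_bic_decomposes_over_families(self):
        """Score of a DAG equals the sum of its per-family scores."""
        rng = np.random.default_rng(8)
        names = ["A", "B", "C", "D", "E"]
        X = rng.normal(size=(80, 5))
        for _ in range(5):
            # random DAG via random order + random edges
            order = rng.permutation(5)
            edges = [
                (names[order[i]], names[order[j]])
                for i in range(5)
                for j in range(i + 1, 5)
                if rng.random() < 0.4
            ]
            dag = gb.DAG(names, edges)
            scorer = FamilyScorer(X, names)
            per_family = sum(
                scorer.family_score(
                    names.index(n), [names.index(p) for p in dag.parents(n)]
                )
                for n in names
            )
            assert gb.bic_score(dag, X) == pytest.approx(per_family, rel=1e-12)

    def test_score_equivalence_two_node(self):
        """BIC cannot distinguish X->Y from Y->X (same equivalence class)."""
        rng = np.random.default_rng(9)
        x = rng.normal(size=1000)
        y = 0.9 * x + rng.normal(size=1000) * 0.44
        Z, _ = gb.standardize(np.column_stack([x, y]))
        names = ["X", "Y"]
        b_xy = gb.bic_score(gb.DAG(names, [("X", "Y")]), Z)
        b_yx = gb.bic_score(gb.DAG(names, [("Y", "X")]), Z)
        b_empty = gb.bic_score(gb.DAG(names), Z)
        assert b_xy == pytest.approx(b_yx, abs=1e-6)
        assert b_xy > b_empty

    def test_joint_density_sums_node_log_likelihoods(self):
        net = chain_model(0.7)
        X = net.sample(25, seed=0)
        total_nodes = sum(net.node_log_likelihood(X, n) for n in net.nodes)
        total_joint = np.sum(net.logpdf(X, use_standardization=False))
        assert total_joint == pytest.approx(total_nodes, abs=1e-9)

    def test_joint_density_matches_implied_multivariate_gaussian(self):
        """A chain's factorised density equals the closed-form density of the
        trivariate Gaussian implied by the structural equations."""
        net = chain_model(0.8)
        mu, Sigma = net.implied_moments()
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(20, 3))
        mv = stats.multivariate_normal(mean=mu, cov=Sigma)
        np.testing.assert_allclose(
            net.logpdf(pts, use_standardization=False), mv.logpdf(pts), atol=1e-8
        )

    def test_density_maximised_at_fitted_mean(self):
        """Sliding any single coordinate away from the implied mean can only
        lower the joint density."""
        net = chain_model(0.6)
        mu, _ = net.implied_moments()
        at_mean = net.logpdf(mu, use_standardization=False)
        for j in range(3):
            for delta in np.linspace(-2, 2, 9):
                if delta == 0:
                    continue
                x = mu.copy()
                x[j] += delta
                assert net.logpdf(x, use_standardization=False) < at_mean

    def test_raw_scale_density_includes_jacobian(self):
        """Raw-scale logpdf = standardized-scale logpdf - sum(log sd), so it
        integrates to one on the volume scale."""
        net = gb.make_group_model(
            gb.GroupSpec(label="g", n=5, edges={("A", "B"): 0.5}, means=0.5, sds=0.05),
            roi_names=("A", "B"),
        )
        mu, Sigma = net.implied_moments(raw=True)
        mv = stats.multivariate_normal(mean=mu, cov=Sigma)
        x = np.array([0.52, 0.47])
        assert net.logpdf(x) == pytest.approx(mv.logpdf(x), abs=1e-8)

    def test_zero_variance_density_undefined(self):
        cpd = gb.LinearGaussianCPD("X", (), 0.0, np.empty(0), 0.0)
        with pytest.raises(ValueError, match="variance"):
            cpd.logpdf(np.array([0.0]), np.empty((1, 0)))


class TestSampling:
    def test_parentless_moments(self):
        net = gb.LinearGaussianBN(
            gb.DAG(["X"]),
            {"X": gb.LinearGaussianCPD("X", (), 5.0, np.empty(0), 4.0)},
        )
        X = net.sample(10000, seed=1)
        assert X[:, 0].mean() == pytest.approx(5.0, abs=0.08)
        assert X[:, 0].var() == pytest.approx(4.0, abs=0.25)

    def test_chain_covariance(self):
        net = chain_model(0.8, d=2)
        X = net.sample(20000, seed=2)
        cov = np.cov(X.T)
        assert cov[0, 1] == pytest.approx(0.8 * cov[0, 0], abs=0.03)

    def test_same_seed_identical(self):
        net = chain_model(0.5)
        np.testing.assert_array_equal(net.sample(50, seed=9), net.sample(50, seed=9))

    def test_fit_recovers_generating_coefficients(self):
        net = chain_model(0.65)
        Z = net.sample(5000, seed=3)
        fitted = gb.fit_mle(net.dag, Z)
        for (p, c), w in net.edge_weights.items():
            assert fitted.edge_weight(p, c) == pytest.approx(w, abs=0.05)


class TestModelResults:
    def test_results_bic_matches_score_function(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 4))
        res = gb.GaussianBN(X).fit()
        Z, _ = gb.standardize(X)
        assert res.bic == pytest.approx(gb.bic_score(res.dag, Z), rel=1e-9)

    def test_summary_mentions_edges_and_n(self):
        net = chain_model(0.7)
        Z = net.sample(200, seed=4)
        res = gb.GaussianBN(Z, dag=net.dag, standardize=False).fit()
        text = res.summary()
        assert "X0->X1" in text and "n: 200" in text

    def test_json_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(150, 5))
        net = gb.GaussianBN(X).fit(gb.SearchConfig()).network
        path = tmp_path / "model.json"
        net.to_json(path)
        back = gb.LinearGaussianBN.from_json(path)
        assert back.dag == net.dag
        assert back.n == net.n
        for node in net.nodes:
            a, b = net.cpds[node], back.cpds[node]
            assert a.parents == b.parents
            assert a.intercept == b.intercept
            assert a.residual_variance == b.residual_variance
            np.testing.assert_array_equal(a.coefficients, b.coefficients)
        np.testing.assert_array_equal(
            back.standardization.means, net.standardization.means
        )

    def test_insufficient_sample_for_learning(self):
        X = np.random.default_rng(0).normal(size=(5, 8))
        with pytest.raises(ValueError, match="insufficient sample"):
            gb.GaussianBN(X).fit()
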