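"""Linear-Gaussian Bayesian networks: parameters, likelihood, BIC, sampling.

The network over d continuous variables (here: regional mean gray-matter
volumes) factorises the joint density as

    p(x) = prod_j N(x_j | b0_j + b_j' x_{pi_j}, sigma2_j)

where pi_j is node j's parent set in a :class:`~graybn.dag.DAG`.  Parameters
are estimated per node by least squares (the maximum-likelihood solution),
with the residual variance using the MLE denominator n.  The decomposable
BIC score of a structure is

    BIC = sum_j [ L_j(theta_hat) - (k_j / 2) log n ],   k_j = |pi_j| + 2,

with L_j the maximised Gaussian log-likelihood of node j given its parents
and k_j counting intercept, parent coefficients and residual variance.
Counting the variance keeps k_j symmetric under edge reversal, so Markov
equivalent structures score identically.

Data are z-scored per variable before fitting by default, so fitted edge
coefficients are standardized weights (a single-parent weight equals the
Pearson correlation between parent and child).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dag import DAG

__all__ = [
    "LOG_2PI",
    "VARIANCE_FLOOR",
    "Standardization",
    "standardize",
    "LinearGaussianCPD",
    "LinearGaussianBN",
    "FamilyScorer",
    "GaussianBN",
    "GaussianBNResults",
    "fit_mle",
    "bic_score",
    "node_log_likelihood",
    "log_joint_density",
    "edge_weight",
    "sample",
]

LOG_2PI = float(np.log(2.0 * np.pi))

#: Residual variances below this are clamped (with a warning) when fitting
#: and rejected when evaluating densities — a zero variance makes the
#: Gaussian density undefined.
VARIANCE_FLOOR = 1e-10


class CollinearParentsError(np.linalg.LinAlgError):
    """Parent design matrix is singular (collinear parents)."""


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Standardization:
    """Per-variable affine transform ``z = (x - mean) / sd`` and its inverse."""

    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "means", np.asarray(self.means, dtype=float))
        object.__setattr__(self, "sds", np.asarray(self.sds, dtype=float))
        if np.any(self.sds <= 0):
            raise ValueError("standard deviations must be positive")

    @classmethod
    def identity(cls, d: int) -> "Standardization":
        return cls(np.zeros(d), np.ones(d))

    @property
    def is_identity(self) -> bool:
        return bool(np.all(self.means == 0.0) and np.all(self.sds == 1.0))

    @property
    def log_jacobian(self) -> float:
        """log |d z / d x| = -sum log sd; converts standardized-scale
        log-densities into raw-scale log-densities."""
        return float(-np.sum(np.log(self.sds)))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.means) / self.sds

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sds + self.means


def standardize(
    data: np.ndarray, columns: Sequence[str] | None = None
) -> tuple[np.ndarray, Standardization]:
    """Z-score each column (mean 0, sd 1 with the n-1 denominator).

    Parameters
    ----------
    data : (n, d) array
    columns : optional names used in the zero-variance error message.

    Returns
    -------
    (standardized matrix, recorded :class:`Standardization`)
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be a 2-D (subjects x variables) matrix")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(~(sds > 0))
    if bad.size:
        names = (
            [columns[i] for i in bad] if columns is not None else list(bad)
        )
        raise ValueError(f"zero-variance column(s): {names}")
    std = Standardization(means, sds)
    return (X - means) / sds, std


# ---------------------------------------------------------------------------
# conditional densities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearGaussianCPD:
    """Gaussian density of one node given its parents.

    mean = intercept + coefficients . parent values; constant residual
    variance.  ``coefficient_se``/``intercept_se`` are conventional OLS
    standard errors (unbiased variance denominator), populated when the CPD
    was fitted from data.
    """

    node: str
    parents: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    residual_variance: float
    intercept_se: float | None = None
    coefficient_se: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(
            self, "coefficients", np.atleast_1d(np.asarray(self.coefficients, float))
        )
        object.__setattr__(self, "parents", tuple(self.parents))
        if len(self.coefficients) != len(self.parents):
            raise ValueError(
                f"node {self.node!r}: {len(self.coefficients)} coefficients "
                f"for {len(self.parents)} parents"
            )
        if self.residual_variance < 0:
            raise ValueError(f"node {self.node!r}: negative residual variance")

    @property
    def n_parameters(self) -> int:
        """Free parameters: intercept + one coefficient per parent + variance."""
        return len(self.parents) + 2

    def conditional_mean(self, parent_values: np.ndarray) -> np.ndarray:
        """Mean given an (n, |parents|) array of parent values."""
        pv = np.asarray(parent_values, dtype=float)
        if len(self.parents) == 0:
            n = 1 if pv.ndim < 2 else pv.shape[0]
            return np.full(n, self.intercept)
        pv = np.atleast_2d(pv)
        return self.intercept + pv @ self.coefficients

    def logpdf(self, values: np.ndarray, parent_values: np.ndarray) -> np.ndarray:
        """Per-observation log density of the node given its parents."""
        if self.residual_variance < VARIANCE_FLOOR:
            raise ValueError(
                f"node {self.node!r}: residual variance below floor, "
                "density undefined"
            )
        v = np.atleast_1d(np.asarray(values, dtype=float))
        mu = self.conditional_mean(parent_values)
        return -0.5 * (
            LOG_2PI
            + np.log(self.residual_variance)
            + (v - mu) ** 2 / self.residual_variance
        )


# ---------------------------------------------------------------------------
# family scoring (the hill-climb hot path)
# ---------------------------------------------------------------------------


class FamilyScorer:
    """Per-family MLE fits and BIC scores from a centred Gram matrix.

    Centring the data once makes every family regression a small solve
    against the cross-product matrix, so scoring a candidate parent set is
    O(k^3) with k = |parents| regardless of sample size.
    """

    def __init__(self, data: np.ndarray, node_names: Sequence[str] | None = None):
        X = np.asarray(data, dtype=float)
        if X.ndim != 2:
            raise ValueError("data must be 2-D")
        self.n, self.d = X.shape
        self.node_names = (
            tuple(node_names) if node_names is not None
            else tuple(f"X{i}" for i in range(self.d))
        )
        self.means = X.mean(axis=0)
        Xc = X - self.means
        self.S = Xc.T @ Xc  # centred cross-products
        self._log_n = float(np.log(self.n))

    def family_mle(
        self, child: int, parents: Sequence[int]
    ) -> tuple[float, np.ndarray, float]:
        """(intercept, coefficients, MLE residual variance) for one family."""
        parents = list(parents)
        Scc = self.S[child, child]
        if not parents:
            sigma2 = Scc / self.n
            beta = np.empty(0)
            intercept = self.means[child]
        else:
            Spp = self.S[np.ix_(parents, parents)]
            Spc = self.S[parents, child]
            try:
                L = np.linalg.cholesky(Spp)
                # cholesky can pass on a numerically singular Gram matrix;
                # a near-zero pivot relative to scale still means collinear
                if np.min(np.diag(L)) ** 2 < 1e-12 * np.max(np.diag(Spp)):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                raise CollinearParentsError(
                    f"singular parent design for node "
                    f"{self.node_names[child]!r} (collinear parents "
                    f"{[self.node_names[p] for p in parents]})"
                ) from None
            beta = np.linalg.solve(L.T, np.linalg.solve(L, Spc))
            rss = max(Scc - Spc @ beta, 0.0)
            sigma2 = rss / self.n
            intercept = self.means[child] - beta @ self.means[parents]
        if sigma2 < VARIANCE_FLOOR:
            warnings.warn(
                f"node {self.node_names[child]!r}: residual variance "
                f"{sigma2:.3g} clamped to floor {VARIANCE_FLOOR}",
                RuntimeWarning,
                stacklevel=2,
            )
            sigma2 = VARIANCE_FLOOR
        return intercept, beta, sigma2

    def family_loglik(self, child: int, parents: Sequence[int]) -> float:
        """Maximised Gaussian log-likelihood of one node-family."""
        _, _, sigma2 = self.family_mle(child, parents)
        return -0.5 * self.n * (LOG_2PI + np.log(sigma2) + 1.0)

    def family_score(self, child: int, parents: Sequence[int]) -> float:
        """BIC contribution: maximised log-likelihood minus (k/2) log n."""
        k = len(parents) + 2
        return self.family_loglik(child, parents) - 0.5 * k * self._log_n

    def fit_cpd(self, child: int, parents: Sequence[int]) -> LinearGaussianCPD:
        """Full CPD with OLS standard errors for reporting."""
        parents = list(parents)
        intercept, beta, sigma2 = self.family_mle(child, parents)
        k = len(parents)
        dof = self.n - k - 1
        s2_unbiased = sigma2 * self.n / dof if dof > 0 else np.nan
        if parents:
            cov = s2_unbiased * np.linalg.inv(self.S[np.ix_(parents, parents)])
            coef_se = np.sqrt(np.diag(cov))
        else:
            coef_se = np.empty(0)
        intercept_se = float(np.sqrt(s2_unbiased / self.n)) if dof > 0 else None
        return LinearGaussianCPD(
            node=self.node_names[child],
            parents=tuple(self.node_names[p] for p in parents),
            intercept=float(intercept),
            coefficients=beta,
            residual_variance=float(sigma2),
            intercept_se=intercept_se,
            coefficient_se=coef_se,
        )


# ---------------------------------------------------------------------------
# the parameterised network
# ---------------------------------------------------------------------------


class LinearGaussianBN:
    """A DAG plus one linear-Gaussian CPD per node.

    Carries the per-variable standardization used before fitting (identity
    when the network was built on the raw scale) and, when fitted, the
    sample size n.  Evaluation, sampling and serialization live here;
    structure learning lives in :mod:`graybn.search`.
    """

    def __init__(
        self,
        dag: DAG,
        cpds: Mapping[str, LinearGaussianCPD] | Sequence[LinearGaussianCPD],
        standardization: Standardization | None = None,
        n: int | None = None,
    ):
        if not isinstance(cpds, Mapping):
            cpds = {c.node: c for c in cpds}
        if set(cpds) != set(dag.nodes):
            raise ValueError("CPD set must cover exactly the DAG's nodes")
        for node in dag.nodes:
            if tuple(cpds[node].parents) != dag.parents(node):
                raise ValueError(
                    f"CPD parents for {node!r} do not match the DAG"
                )
        self.dag = dag
        self.cpds = {n_: cpds[n_] for n_ in dag.nodes}
        self.standardization = (
            standardization
            if standardization is not None
            else Standardization.identity(dag.n_nodes)
        )
        self.n = n
        self._index = {name: i for i, name in enumerate(dag.nodes)}

    # -- accessors ---------------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    @property
    def n_parameters(self) -> int:
        return sum(c.n_parameters for c in self.cpds.values())

    def edge_weight(self, parent: str, child: str) -> float:
        """Fitted coefficient of *parent* in *child*'s CPD (the connection
        weight; a standardized coefficient when data were z-scored)."""
        if not self.dag.has_edge(parent, child):
            raise ValueError(f"edge ({parent!r}, {child!r}) not in the model")
        cpd = self.cpds[child]
        return float(cpd.coefficients[cpd.parents.index(parent)])

    @property
    def edge_weights(self) -> dict[tuple[str, str], float]:
        return {
            (p, c): self.edge_weight(p, c) for (p, c) in sorted(self.dag.edges)
        }

    # -- likelihood --------------------------------------------------------

    def _columns(self, data: np.ndarray, names: Sequence[str]) -> np.ndarray:
        idx = [self._index[n_] for n_ in names]
        return data[:, idx]

    def node_log_likelihood(self, data: np.ndarray, node: str) -> float:
        """Sum over rows of the log density of *node* given its parents.

        *data* is on the model's internal (standardized) scale, columns in
        node order.
        """
        X = np.atleast_2d(np.asarray(data, dtype=float))
        cpd = self.cpds[node]
        vals = X[:, self._index[node]]
        pv = self._columns(X, cpd.parents) if cpd.parents else np.empty((len(X), 0))
        return float(cpd.logpdf(vals, pv).sum())

    def logpdf(self, x: np.ndarray, use_standardization: bool = True) -> float | np.ndarray:
        """Log joint density sum_j log p(x_j | x_{pi_j}).

        With ``use_standardization`` (default) *x* is on the raw scale: it is
        transformed by the stored standardization and the Jacobian term
        -sum log sd is added, so the result is the density of the raw
        vector.  With the flag off *x* is taken to be on the model's
        internal scale already.
        """
        x = np.asarray(x, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input vector")
        single = x.ndim == 1
        X = np.atleast_2d(x)
        if X.shape[1] != self.dag.n_nodes:
            raise ValueError(
                f"expected vectors of length {self.dag.n_nodes}, got {X.shape[1]}"
            )
        jac = 0.0
        if use_standardization:
            X = (X - self.standardization.means) / self.standardization.sds
            jac = self.standardization.log_jacobian
        total = np.zeros(len(X))
        for node, cpd in self.cpds.items():
            vals = X[:, self._index[node]]
            pv = (
                self._columns(X, cpd.parents)
                if cpd.parents
                else np.empty((len(X), 0))
            )
            total += cpd.logpdf(vals, pv)
        total += jac
        return float(total[0]) if single else total

    # -- sampling and implied joint ---------------------------------------

    def sample(
        self, n: int, seed: int | np.random.Generator | None = None, raw: bool = False
    ) -> np.ndarray:
        """Ancestral sampling: draw *n* vectors in topological order.

        Each node is intercept + coefficients . sampled parents + Gaussian
        noise with the node's residual variance.  ``raw=True`` maps samples
        back through the stored standardization.  Reproducible given *seed*.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        Z = np.zeros((n, self.dag.n_nodes))
        for node in self.dag.topological_order():
            cpd = self.cpds[node]
            j = self._index[node]
            mu = (
                cpd.conditional_mean(self._columns(Z, cpd.parents))
                if cpd.parents
                else np.full(n, cpd.intercept)
            )
            Z[:, j] = mu + rng.normal(0.0, np.sqrt(cpd.residual_variance), size=n)
        return self.standardization.inverse(Z) if raw else Z

    def implied_moments(self, raw: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Mean vector and covariance of the joint Gaussian the structural
        equations imply: with coefficient matrix B (B[p, c] = weight of p in
        c's CPD), M = (I - B')^{-1}, mu = M c and Sigma = M D M' where D is
        the diagonal of residual variances."""
        d = self.dag.n_nodes
        B = np.zeros((d, d))
        c = np.zeros(d)
        Dv = np.zeros(d)
        for node, cpd in self.cpds.items():
            j = self._index[node]
            c[j] = cpd.intercept
            Dv[j] = cpd.residual_variance
            for p, b in zip(cpd.parents, cpd.coefficients):
                B[self._index[p], j] = b
        M = np.linalg.inv(np.eye(d) - B.T)
        mu = M @ c
        Sigma = M @ np.diag(Dv) @ M.T
        if raw:
            s = self.standardization.sds
            mu = self.standardization.inverse(mu)
            Sigma = Sigma * np.outer(s, s)
        return mu, Sigma

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": list(self.dag.nodes),
            "edges": sorted(list(e) for e in self.dag.edges),
            "cpds": {
                node: {
                    "parents": list(cpd.parents),
                    "intercept": cpd.intercept,
                    "coefficients": cpd.coefficients.tolist(),
                    "residual_variance": cpd.residual_variance,
                }
                for node, cpd in self.cpds.items()
            },
            "n": self.n,
            "standardization": {
                "means": self.standardization.means.tolist(),
                "sds": self.standardization.sds.tolist(),
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearGaussianBN":
        dag = DAG(d["nodes"], [tuple(e) for e in d["edges"]])
        cpds = {}
        for node, spec in d["cpds"].items():
            # DAG sorts parent tuples; re-order coefficients to match
            order = sorted(range(len(spec["parents"])), key=lambda i: spec["parents"][i])
            cpds[node] = LinearGaussianCPD(
                node=node,
                parents=tuple(spec["parents"][i] for i in order),
                intercept=spec["intercept"],
                coefficients=np.array([spec["coefficients"][i] for i in order]),
                residual_variance=spec["residual_variance"],
            )
        std = Standardization(
            np.array(d["standardization"]["means"]),
            np.array(d["standardization"]["sds"]),
        )
        return cls(dag, cpds, standardization=std, n=d["n"])

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "LinearGaussianBN":
        try:
            d = json.loads(source)
        except (json.JSONDecodeError, TypeError):
            with open(source) as fh:
                d = json.load(fh)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# statsmodels-style model / results pair
# ---------------------------------------------------------------------------


class GaussianBN:
    """Model object: data plus (optionally) a fixed structure.

    ``fit()`` learns the structure by BIC hill climbing when no DAG is
    given, then estimates all CPDs by maximum likelihood, and returns a
    :class:`GaussianBNResults`.

    Parameters
    ----------
    data
        (n, d) array or DataFrame of continuous variables.
    dag
        Optional fixed :class:`~graybn.dag.DAG`; when omitted the structure
        is learned.
    node_names
        Required for array input; taken from columns for DataFrame input.
    standardize
        Z-score each variable before fitting (default).  Keeps edge weights
        on the standardized-coefficient scale.
    """

    def __init__(
        self,
        data,
        dag: DAG | None = None,
        node_names: Sequence[str] | None = None,
        standardize: bool = True,
    ):
        if isinstance(data, pd.DataFrame):
            node_names = list(data.columns) if node_names is None else list(node_names)
            data = data[node_names].to_numpy(dtype=float)
        X = np.asarray(data, dtype=float)
        if X.ndim != 2:
            raise ValueError("data must be 2-D (subjects x variables)")
        if node_names is None:
            node_names = [f"X{i}" for i in range(X.shape[1])]
        if not np.all(np.isfinite(X)):
            raise ValueError("data contains non-finite values")
        if dag is not None and tuple(dag.nodes) != tuple(node_names):
            raise ValueError("dag nodes must match data columns (same order)")
        self.endog = X
        self.node_names = tuple(node_names)
        self.dag = dag
        self.should_standardize = standardize
        self.nobs = X.shape[0]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, columns: Sequence[str] | None = None, **kw
    ) -> "GaussianBN":
        cols = list(columns) if columns is not None else list(df.columns)
        return cls(df[cols], node_names=cols, **kw)

    def fit(self, config=None) -> "GaussianBNResults":
        d = len(self.node_names)
        if self.dag is None and self.nobs < d + 2:
            raise ValueError(
                f"insufficient sample: n={self.nobs} < d+2={d + 2} "
                f"for {d} variables"
            )
        if self.dag is not None:
            largest = max(
                (len(self.dag.parents(n_)) for n_ in self.node_names), default=0
            )
            if self.nobs < largest + 2:
                raise ValueError(
                    f"insufficient sample: n={self.nobs} for a node with "
                    f"{largest} parents (need >= {largest + 2})"
                )
        if self.should_standardize:
            Z, std = standardize(self.endog, self.node_names)
        else:
            Z, std = self.endog, Standardization.identity(d)
        trace = None
        dag = self.dag
        if dag is None:
            from .search import hill_climb

            dag, trace = hill_climb(Z, config=config, node_names=self.node_names)
        scorer = FamilyScorer(Z, self.node_names)
        idx = {n_: i for i, n_ in enumerate(self.node_names)}
        cpds = {
            node: scorer.fit_cpd(idx[node], [idx[p] for p in dag.parents(node)])
            for node in dag.nodes
        }
        net = LinearGaussianBN(dag, cpds, standardization=std, n=self.nobs)
        return GaussianBNResults(self, net, Z, score_trace=trace)


class GaussianBNResults:
    """Fitted network: structure, CPDs, score, and reporting.

    Delegates evaluation/sampling to the wrapped :class:`LinearGaussianBN`
    (available as ``.network``).
    """

    def __init__(
        self,
        model: GaussianBN | None,
        network: LinearGaussianBN,
        fitted_data: np.ndarray | None = None,
        score_trace: list[float] | None = None,
    ):
        self.model = model
        self.network = network
        self._fitted_data = fitted_data
        self.score_trace = score_trace

    # delegation ----------------------------------------------------------

    def __getattr__(self, name):
        return getattr(self.network, name)

    @property
    def dag(self) -> DAG:
        return self.network.dag

    @property
    def llf(self) -> float:
        """Maximised log-likelihood on the fitting data."""
        if self._fitted_data is None:
            raise ValueError("no fitting data attached")
        return sum(
            self.network.node_log_likelihood(self._fitted_data, node)
            for node in self.network.nodes
        )

    @property
    def bic(self) -> float:
        """Decomposable BIC: llf - (total free parameters / 2) log n."""
        return self.llf - 0.5 * self.network.n_parameters * np.log(self.network.n)

    @property
    def params(self) -> pd.Series:
        """Edge weights indexed 'parent->child'."""
        w = self.network.edge_weights
        return pd.Series(
            {f"{p}->{c}": v for (p, c), v in w.items()}, dtype=float
        )

    @property
    def bse(self) -> pd.Series:
        """OLS standard errors of the edge weights."""
        out = {}
        for (p, c) in sorted(self.network.dag.edges):
            cpd = self.network.cpds[c]
            se = (
                cpd.coefficient_se[cpd.parents.index(p)]
                if cpd.coefficient_se is not None
                else np.nan
            )
            out[f"{p}->{c}"] = se
        return pd.Series(out, dtype=float)

    def summary(self) -> str:
        net = self.network
        lines = [
            "Linear-Gaussian Bayesian Network",
            "=" * 54,
            f"Nodes: {len(net.nodes)}   Edges: {len(net.dag.edges)}   "
            f"n: {net.n}",
        ]
        if self._fitted_data is not None:
            lines.append(
                f"Log-likelihood: {self.llf:.3f}   BIC: {self.bic:.3f}   "
                f"Parameters: {net.n_parameters}"
            )
        lines.append("-" * 54)
        lines.append(f"{'edge':<24}{'weight':>10}{'std err':>10}")
        params, bse = self.params, self.bse
        for name in params.index:
            se = bse[name]
            se_s = f"{se:.3f}" if np.isfinite(se) else "--"
            lines.append(f"{name:<24}{params[name]:>10.3f}{se_s:>10}")
        if len(params) == 0:
            lines.append("(empty graph)")
        lines.append("-" * 54)
        lines.append("Residual variances:")
        for node in net.nodes:
            lines.append(f"  {node:<8}{net.cpds[node].residual_variance:>10.3f}")
        return "\n".join(lines)

    def plot_dag(self, ax=None):  # pragma: no cover - thin plotting helper
        """Draw the learned graph with edge labels = weights (matplotlib)."""
        import matplotlib.pyplot as plt
        import networkx as nx

        g = self.network.dag.to_networkx()
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 6))
        pos = nx.circular_layout(g)
        nx.draw_networkx(g, pos, ax=ax, node_color="#c6dbef", node_size=1400)
        labels = {e: f"{w:.2f}" for e, w in self.network.edge_weights.items()}
        nx.draw_networkx_edge_labels(g, pos, edge_labels=labels, ax=ax)
        ax.set_axis_off()
        return ax


# ---------------------------------------------------------------------------
# functional wrappers (operation-style surface)
# ---------------------------------------------------------------------------


def fit_mle(
    dag: DAG,
    data: np.ndarray,
    standardization: Standardization | None = None,
) -> LinearGaussianBN:
    """Maximum-likelihood fit of all CPDs for a fixed structure.

    *data* is taken as already on the fitting scale (standardize first if
    standardized weights are wanted); the optional *standardization* is
    stored on the returned network for later raw-scale evaluation.
    """
    res = GaussianBN(
        data, dag=dag, node_names=dag.nodes, standardize=False
    ).fit()
    net = res.network
    if standardization is not None:
        net = LinearGaussianBN(
            net.dag, net.cpds, standardization=standardization, n=net.n
        )
    return net


def bic_score(dag: DAG, data: np.ndarray) -> float:
    """BIC of *dag* on *data*: sum of per-family maximised log-likelihoods
    minus (k_j/2) log n, k_j = |parents| + 2."""
    scorer = FamilyScorer(np.asarray(data, float), dag.nodes)
    idx = {n_: i for i, n_ in enumerate(dag.nodes)}
    return sum(
        scorer.family_score(idx[node], [idx[p] for p in dag.parents(node)])
        for node in dag.nodes
    )


def node_log_likelihood(model: LinearGaussianBN, data, node: str) -> float:
    return model.node_log_likelihood(data, node)


def log_joint_density(
    model: LinearGaussianBN, x, standardize_with_model: bool = True
):
    return model.logpdf(x, use_standardization=standardize_with_model)


def edge_weight(model: LinearGaussianBN, edge: tuple[str, str]) -> float:
    return model.edge_weight(*edge)


def sample(model: LinearGaussianBN, n: int, seed=None, raw: bool = False):
    return model.sample(n, seed=seed, raw=raw)
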