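"""Two-group network comparison.

One network is learned per group (z-scored within group, BIC hill climb,
maximum-likelihood fit).  Edge weights over the union of the two learned
edge sets are tabulated into four categories:

    I   same directed edge present in both groups
    II  edge present only in group a
    III edge present only in group b
    IV  edge present in both skeletons but with opposite orientation

Between-group weight differences are tested by a label-permutation test:
group labels are shuffled (group sizes preserved exactly), the full
per-group procedure — standardize, re-learn the structure, fit — is re-run,
and for every union edge the permuted weight difference is recorded (an
edge absent from a permuted model contributes weight 0, "no association").
Two one-sided type-I error probabilities are reported per edge as plain
proportions over the permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .bn import FamilyScorer, GaussianBN, GaussianBNResults
from .cohort import CohortTable
from .search import SearchConfig, hill_climb

__all__ = [
    "GroupModels",
    "PermutationTestResult",
    "GroupComparison",
    "GroupComparisonResults",
    "learn_group_models",
    "weight_table",
    "permutation_test",
    "flag_significant",
]


@dataclass
class GroupModels:
    """Fitted networks for the two groups, over an identical node list."""

    labels: tuple[str, str]
    results: dict[str, GaussianBNResults]

    def __post_init__(self):
        a, b = self.labels
        if self.results[a].network.nodes != self.results[b].network.nodes:
            raise ValueError("both models must share the same node list")

    @property
    def model_a(self) -> GaussianBNResults:
        return self.results[self.labels[0]]

    @property
    def model_b(self) -> GaussianBNResults:
        return self.results[self.labels[1]]

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.model_a.network.nodes

    @property
    def edge_union(self) -> list[tuple[str, str]]:
        """All directed edges present in either learned DAG, sorted."""
        return sorted(self.model_a.dag.edges | self.model_b.dag.edges)

    def weight(self, label: str, parent: str, child: str) -> float:
        """Edge weight in one group's model; 0.0 when the edge is absent."""
        net = self.results[label].network
        if net.dag.has_edge(parent, child):
            return net.edge_weight(parent, child)
        return 0.0

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "models": {g: r.network.to_dict() for g, r in self.results.items()},
        }


def learn_group_models(
    cohort: CohortTable,
    config: SearchConfig | None = None,
    groups: tuple[str, str] | None = None,
) -> GroupModels:
    """Standardize within group, hill-climb a structure, and fit, per group.

    *groups* fixes the (a, b) label order; default is order of first
    appearance in the cohort.  Each group needs n >= d + 2 subjects.
    """
    if groups is None:
        groups = cohort.require_two_groups()
    else:
        groups = tuple(groups)
        present = set(cohort.groups)
        if len(groups) != 2 or set(groups) - present:
            raise ValueError(f"groups {groups} not both present in cohort {sorted(present)}")
    d = len(cohort.roi_names)
    results = {}
    for g in groups:
        X = cohort.group_volumes(g)
        if X.shape[0] < d + 2:
            raise ValueError(
                f"group {g!r} too small: n={X.shape[0]}, need >= {d + 2}"
            )
        results[g] = GaussianBN(
            X, node_names=cohort.roi_names, standardize=True
        ).fit(config)
    return GroupModels(labels=groups, results=results)


def weight_table(models: GroupModels) -> pd.DataFrame:
    """One row per union edge with both groups' weights and a category.

    Columns: parent, child, weight_a, weight_b, category; the weight is NaN
    in a group where the (directed) edge is absent.  Rows sorted by
    (category, parent, child).
    """
    a, b = models.labels
    dag_a, dag_b = models.model_a.dag, models.model_b.dag
    rows = []
    for p, c in models.edge_union:
        in_a, in_b = dag_a.has_edge(p, c), dag_b.has_edge(p, c)
        if in_a and in_b:
            cat = "I"
        elif in_a:
            cat = "IV" if dag_b.has_edge(c, p) else "II"
        else:
            cat = "IV" if dag_a.has_edge(c, p) else "III"
        rows.append(
            {
                "parent": p,
                "child": c,
                "weight_a": models.weight(a, p, c) if in_a else np.nan,
                "weight_b": models.weight(b, p, c) if in_b else np.nan,
                "category": cat,
            }
        )
    df = pd.DataFrame(
        rows, columns=["parent", "child", "weight_a", "weight_b", "category"]
    )
    if len(df):
        df = df.sort_values(["category", "parent", "child"], ignore_index=True)
    df.attrs["labels"] = models.labels
    return df


@dataclass
class PermutationTestResult:
    """Per-edge observed weight differences and one-sided p values."""

    table: pd.DataFrame  # parent, child, observed_diff, p_a_greater, p_b_greater
    labels: tuple[str, str]
    n_permutations: int
    seed: int | None

    def flag_significant(self, alpha: float = 0.05, inclusive: bool = True) -> dict:
        return flag_significant(self, alpha=alpha, inclusive=inclusive)


def _group_weights(
    X: np.ndarray,
    node_names: Sequence[str],
    union_edges: Sequence[tuple[str, str]],
    config: SearchConfig,
    fixed_parents: dict[str, tuple[str, ...]] | None,
) -> np.ndarray:
    """Standardized edge weights for one (possibly permuted) group.

    Re-learns the structure unless *fixed_parents* pins it; returns the
    weight of each union edge (0 where absent from this group's DAG).
    """
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    idx = {n_: i for i, n_ in enumerate(node_names)}
    if fixed_parents is None:
        dag, _ = hill_climb(Xs, config=config, node_names=node_names)
        parents = {n_: dag.parents(n_) for n_ in node_names}
    else:
        parents = fixed_parents
    scorer = FamilyScorer(Xs, node_names)
    coef_by_child: dict[str, dict[str, float]] = {}
    out = np.zeros(len(union_edges))
    for k, (p, c) in enumerate(union_edges):
        ps = parents[c]
        if p not in ps:
            continue
        if c not in coef_by_child:
            _, beta, _ = scorer.family_mle(idx[c], [idx[q] for q in ps])
            coef_by_child[c] = dict(zip(ps, beta))
        out[k] = coef_by_child[c][p]
    return out


def permutation_test(
    cohort: CohortTable,
    models: GroupModels,
    n_perm: int = 5000,
    seed: int | None = None,
    config: SearchConfig | None = None,
    relearn_structure: bool = True,
    add_one: bool = False,
) -> PermutationTestResult:
    """Label-permutation test of between-group differences in edge weights.

    For each of *n_perm* shuffles of the group labels (group sizes
    preserved), the per-group pipeline is re-run and each observed-union
    edge gets a permuted difference ``weight_a - weight_b`` (0 for an edge
    absent from a permuted model).  ``p_a_greater`` is the proportion of
    permuted differences >= the observed one, ``p_b_greater`` the
    proportion <=.  ``relearn_structure=False`` keeps the two observed
    structures fixed and only re-estimates weights (fast mode, for tests).
    ``add_one`` switches to the (+1)-smoothed estimator.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 (p resolution too coarse)")
    config = config or SearchConfig()
    a, b = models.labels
    union = models.edge_union
    observed = np.array(
        [models.weight(a, p, c) - models.weight(b, p, c) for p, c in union]
    )
    X = cohort.volumes
    grp = cohort.df["group"].to_numpy()
    idx_a = np.flatnonzero(grp == a)
    idx_b = np.flatnonzero(grp == b)
    n_a = len(idx_a)
    all_idx = np.concatenate([idx_a, idx_b])
    names = cohort.roi_names
    fixed_a = fixed_b = None
    if not relearn_structure:
        fixed_a = {n_: models.model_a.dag.parents(n_) for n_ in names}
        fixed_b = {n_: models.model_b.dag.parents(n_) for n_ in names}

    rng = np.random.default_rng(seed)
    ge = np.zeros(len(union))
    le = np.zeros(len(union))
    for _ in range(n_perm):
        perm = rng.permutation(all_idx)
        w_a = _group_weights(X[perm[:n_a]], names, union, config, fixed_a)
        w_b = _group_weights(X[perm[n_a:]], names, union, config, fixed_b)
        diff = w_a - w_b
        ge += diff >= observed
        le += diff <= observed
    denom = n_perm + 1 if add_one else n_perm
    num = 1 if add_one else 0
    table = pd.DataFrame(
        {
            "parent": [p for p, _ in union],
            "child": [c for _, c in union],
            "observed_diff": observed,
            "p_a_greater": (ge + num) / denom,
            "p_b_greater": (le + num) / denom,
        }
    )
    return PermutationTestResult(
        table=table, labels=(a, b), n_permutations=n_perm, seed=seed
    )


def flag_significant(
    results: PermutationTestResult, alpha: float = 0.05, inclusive: bool = True
) -> dict[str, list[tuple[str, str]]]:
    """Edges significant in each direction, uncorrected for multiplicity.

    The default comparator is inclusive (p <= alpha); ``inclusive=False``
    uses strict <.  Keys: ``"a_greater"`` and ``"b_greater"``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    t = results.table

    def hit(p):
        return p <= alpha if inclusive else p < alpha

    return {
        "a_greater": [
            (r.parent, r.child) for r in t.itertuples() if hit(r.p_a_greater)
        ],
        "b_greater": [
            (r.parent, r.child) for r in t.itertuples() if hit(r.p_b_greater)
        ],
    }


# ---------------------------------------------------------------------------
# model/results pair over the whole comparison
# ---------------------------------------------------------------------------


class GroupComparison:
    """Model object for the full two-group analysis.

    ``fit()`` learns one network per group and returns a
    :class:`GroupComparisonResults` from which the weight table, the
    permutation test and the classifier are reachable.
    """

    def __init__(
        self,
        cohort: CohortTable,
        config: SearchConfig | None = None,
        groups: tuple[str, str] | None = None,
    ):
        self.cohort = cohort
        self.config = config
        self.groups = groups

    def fit(self) -> "GroupComparisonResults":
        models = learn_group_models(self.cohort, self.config, self.groups)
        return GroupComparisonResults(self, models)


class GroupComparisonResults:
    def __init__(self, model: GroupComparison, models: GroupModels):
        self.model = model
        self.models = models

    @property
    def weight_table(self) -> pd.DataFrame:
        return weight_table(self.models)

    def permutation_test(self, n_perm: int = 5000, seed=None, **kw) -> PermutationTestResult:
        return permutation_test(
            self.model.cohort, self.models, n_perm=n_perm, seed=seed,
            config=self.model.config, **kw
        )

    def classify(self, mode: str = "post_hoc", **kw):
        from .classify import classify_cohort

        return classify_cohort(self.models, self.model.cohort, mode=mode, **kw)

    def summary(self) -> str:
        a, b = self.models.labels
        wt = self.weight_table
        lines = [
            "Two-group Bayesian network comparison",
            "=" * 60,
            f"Groups: a={a!r} (n={self.models.model_a.network.n}), "
            f"b={b!r} (n={self.models.model_b.network.n})",
            f"Edges: {len(self.models.model_a.dag.edges)} (a), "
            f"{len(self.models.model_b.dag.edges)} (b), "
            f"union {len(self.models.edge_union)}",
            "-" * 60,
            f"{'edge':<18}{'cat':>4}{'w_' + a:>12}{'w_' + b:>12}",
        ]
        for r in wt.itertuples():
            wa = f"{r.weight_a:.3f}" if np.isfinite(r.weight_a) else "--"
            wb = f"{r.weight_b:.3f}" if np.isfinite(r.weight_b) else "--"
            lines.append(f"{r.parent + '->' + r.child:<18}{r.category:>4}{wa:>12}{wb:>12}")
        return "\n".join(lines)
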