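"""Score-based DAG learning: greedy BIC hill climbing plus a brute-force
exhaustive search usable as an oracle at small node counts.

The climber starts from the empty graph and repeatedly applies the single
acyclicity-preserving move (edge addition or removal; reversal optional)
that most improves the decomposable BIC, stopping when no move improves the
score by more than a small tolerance.  Because the score decomposes over
node families, each move is evaluated by re-scoring only the affected
child's family, and family scores are cached by (child, parent set).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bn import FamilyScorer
from .dag import DAG, enumerate_dags

__all__ = ["SearchConfig", "hill_climb", "exhaustive_best_dag"]

_MOVE_ORDER = {"add": 0, "remove": 1, "reverse": 2}


@dataclass(frozen=True)
class SearchConfig:
    """Hill-climb settings.

    moves
        Subset of {"add", "remove", "reverse"}; reversal is off by default.
    max_iterations
        Hard cap on greedy steps; hitting it returns the current graph with
        a warning.
    tol
        Minimum score improvement to accept a move (guards float noise).
    restarts / seed
        Optional random restarts from seeded random DAGs; the best-scoring
        run wins.  ``restarts=0`` (default) is fully deterministic.
    score_cache
        Cache family scores by (child, parent set); results are bit-identical
        with the cache on or off.
    """

    moves: tuple[str, ...] = ("add", "remove")
    max_iterations: int = 1000
    tol: float = 1e-9
    restarts: int = 0
    seed: int | None = None
    score_cache: bool = True

    def __post_init__(self):
        object.__setattr__(self, "moves", tuple(self.moves))
        if not self.moves:
            raise ValueError("moves must be non-empty")
        bad = set(self.moves) - set(_MOVE_ORDER)
        if bad:
            raise ValueError(f"unknown moves: {sorted(bad)}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def _reaches(children: list[set[int]], start: int, target: int) -> bool:
    """True if a directed path start -> ... -> target exists."""
    if start == target:
        return True
    stack = [start]
    seen = {start}
    while stack:
        u = stack.pop()
        for v in children[u]:
            if v == target:
                return True
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return False


class _Climber:
    """One greedy run over index-based parent sets."""

    def __init__(self, scorer: FamilyScorer, config: SearchConfig, name_order: list[int]):
        self.scorer = scorer
        self.config = config
        self.d = scorer.d
        # pairs in lexicographic (parent name, child name) order — the
        # documented tie-break: first strictly better move in this order wins
        self.pairs = [
            (p, c) for p in name_order for c in name_order if p != c
        ]
        self.cache: dict[tuple[int, frozenset[int]], float] = {}

    def family(self, child: int, parents: frozenset[int]) -> float:
        if not self.config.score_cache:
            return self.scorer.family_score(child, sorted(parents))
        key = (child, parents)
        if key not in self.cache:
            self.cache[key] = self.scorer.family_score(child, sorted(parents))
        return self.cache[key]

    def run(self, parents: list[frozenset[int]]) -> tuple[list[frozenset[int]], list[float]]:
        cfg = self.config
        d = self.d
        children: list[set[int]] = [set() for _ in range(d)]
        for c in range(d):
            for p in parents[c]:
                children[p].add(c)
        fam = [self.family(j, parents[j]) for j in range(d)]
        trace = [sum(fam)]
        # deltas within tol of each other count as ties, broken by canonical
        # move order: analytically equal improvements (e.g. the two
        # orientations of a fresh edge, equal by score equivalence) differ
        # only by float noise, and noise must not decide the orientation
        tol = cfg.tol
        for _ in range(cfg.max_iterations):
            best_delta = tol
            best_move = None
            if "add" in cfg.moves:
                for p, c in self.pairs:
                    if p in parents[c] or _reaches(children, c, p):
                        continue
                    delta = self.family(c, parents[c] | {p}) - fam[c]
                    if delta > best_delta + tol:
                        best_delta, best_move = delta, ("add", p, c)
            if "remove" in cfg.moves:
                for p, c in self.pairs:
                    if p not in parents[c]:
                        continue
                    delta = self.family(c, parents[c] - {p}) - fam[c]
                    if delta > best_delta + tol:
                        best_delta, best_move = delta, ("remove", p, c)
            if "reverse" in cfg.moves:
                for p, c in self.pairs:
                    if p not in parents[c]:
                        continue
                    children[p].discard(c)
                    cyclic = _reaches(children, p, c)
                    children[p].add(c)
                    if cyclic:
                        continue
                    delta = (
                        self.family(c, parents[c] - {p})
                        - fam[c]
                        + self.family(p, parents[p] | {c})
                        - fam[p]
                    )
                    if delta > best_delta + tol:
                        best_delta, best_move = delta, ("reverse", p, c)
            if best_move is None:
                break
            kind, p, c = best_move
            if kind == "add":
                parents[c] = parents[c] | {p}
                children[p].add(c)
            elif kind == "remove":
                parents[c] = parents[c] - {p}
                children[p].discard(c)
            else:
                parents[c] = parents[c] - {p}
                children[p].discard(c)
                parents[p] = parents[p] | {c}
                children[c].add(p)
                fam[p] = self.family(p, parents[p])
            fam[c] = self.family(c, parents[c])
            trace.append(sum(fam))
        else:
            warnings.warn(
                "hill_climb: iteration cap reached before convergence",
                RuntimeWarning,
                stacklevel=3,
            )
        return parents, trace


def hill_climb(
    data: np.ndarray,
    config: SearchConfig | None = None,
    node_names: Sequence[str] | None = None,
) -> tuple[DAG, list[float]]:
    """Greedy BIC hill climb from the empty graph.

    Parameters
    ----------
    data : (n, d) matrix (standardize beforehand for standardized weights;
        scoring centres internally either way).
    config : :class:`SearchConfig`
    node_names : column names; defaults to X0..X{d-1}.

    Returns
    -------
    (learned :class:`~graybn.dag.DAG`, monotone BIC trace)

    The result is deterministic given (data, config with restarts=0): ties
    between equally improving moves are broken by move type
    (add < remove < reverse) then by the lexicographically smallest
    (parent, child) name pair.
    """
    config = config or SearchConfig()
    X = np.asarray(data, dtype=float)
    scorer = FamilyScorer(X, node_names)
    names = scorer.node_names
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError(
            f"insufficient sample: n={X.shape[0]} < d+2={X.shape[1] + 2}"
        )
    name_order = sorted(range(len(names)), key=lambda i: names[i])
    climber = _Climber(scorer, config, name_order)

    d = scorer.d
    runs: list[tuple[list[frozenset[int]], list[float]]] = []
    parents0: list[frozenset[int]] = [frozenset() for _ in range(d)]
    runs.append(climber.run(parents0))
    if config.restarts > 0:
        rng = np.random.default_rng(config.seed)
        for _ in range(config.restarts):
            order = rng.permutation(d)
            rnd: list[frozenset[int]] = [frozenset() for _ in range(d)]
            for i in range(d):
                for j in range(i + 1, d):
                    if rng.random() < 0.25:
                        rnd[order[j]] = rnd[order[j]] | {int(order[i])}
            runs.append(climber.run(rnd))
    parents, trace = max(enumerate(runs), key=lambda kv: (kv[1][1][-1], -kv[0]))[1]
    edges = [
        (names[p], names[c]) for c in range(d) for p in parents[c]
    ]
    return DAG(names, edges), trace


def exhaustive_best_dag(
    data: np.ndarray, node_names: Sequence[str] | None = None
) -> tuple[DAG, float]:
    """Enumerate every labelled DAG (d <= 4 only) and return the BIC argmax.

    Ties are broken toward fewer edges, then the lexicographically smallest
    sorted edge list.  This is the literal "assess all possible DAGs"
    reading, retained as an oracle for the greedy search.
    """
    X = np.asarray(data, dtype=float)
    d = X.shape[1]
    if d > 4:
        raise ValueError(
            f"exhaustive enumeration refused for d={d} > 4 "
            "(combinatorial explosion)"
        )
    scorer = FamilyScorer(X, node_names)
    names = scorer.node_names
    idx = {n_: i for i, n_ in enumerate(names)}
    cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family(child: int, parents: tuple[int, ...]) -> float:
        key = (child, parents)
        if key not in cache:
            cache[key] = scorer.family_score(child, list(parents))
        return cache[key]

    best_dag: DAG | None = None
    best_score = -np.inf
    best_key: tuple | None = None
    for dag in enumerate_dags(names):
        score = sum(
            family(idx[node], tuple(idx[p] for p in dag.parents(node)))
            for node in names
        )
        key = (len(dag.edges), sorted(dag.edges))
        if (
            best_dag is None
            or score > best_score
            or (score == best_score and key < best_key)
        ):
            best_dag, best_score, best_key = dag, score, key
    assert best_dag is not None
    return best_dag, best_score
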