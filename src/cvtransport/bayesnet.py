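"""Discrete Bayesian networks for cohort-membership modelling.

A compact implementation of score-based structure learning (greedy
hill-climbing over DAGs with the BIC score, seeded random restarts) and
exact posterior inference for a single node given full evidence on the
rest — all that the non-parametric membership model of the transposition
analysis needs. Continuous covariates enter after quantile discretization.

The network is learned on the stacked trial + target sample with the
source indicator included as an ordinary node; the membership probability
P(source = trial | X = x) then follows from the indicator's Markov
blanket, so only the indicator's own conditional probability table and
those of its children are touched at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Discretizer:
    """Quantile-bin map for continuous covariates (binary pass through)."""

    edges: dict[str, np.ndarray]  # inner edges per continuous covariate

    @classmethod
    def fit(cls, df: pd.DataFrame, continuous: list[str], bins: int = 5) -> "Discretizer":
        edges = {}
        for name in continuous:
            qs = np.quantile(df[name].to_numpy(dtype=float), np.linspace(0, 1, bins + 1)[1:-1])
            edges[name] = np.unique(qs)
        return cls(edges)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for col in df.columns:
            x = df[col].to_numpy(dtype=float)
            if col in self.edges:
                out[col] = np.digitize(x, self.edges[col])
            else:
                out[col] = x.astype(int)
        return pd.DataFrame(out, index=df.index)


# ---------------------------------------------------------------------------
# BIC scoring with caching
# ---------------------------------------------------------------------------


class _BicScorer:
    def __init__(self, data: np.ndarray, levels: np.ndarray):
        self.data = data  # (n, p) int-coded
        self.levels = levels
        self.n = data.shape[0]
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, v: int, parents: tuple[int, ...]) -> float:
        key = (v, parents)
        if key in self._cache:
            return self._cache[key]
        r = int(self.levels[v])
        cols = (v,) + parents
        dims = tuple(int(self.levels[c]) for c in cols)
        flat = np.ravel_multi_index(tuple(self.data[:, c] for c in cols), dims)
        counts = np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims)
        nij = counts.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = np.where(counts > 0, counts * np.log(counts / nij), 0.0).sum()
        q = int(np.prod(dims[1:])) if parents else 1
        penalty = 0.5 * np.log(self.n) * (r - 1) * q
        score = float(ll - penalty)
        self._cache[key] = score
        return score


# ---------------------------------------------------------------------------
# structure learning
# ---------------------------------------------------------------------------


def _has_path(adj: dict[int, set[int]], a: int, b: int) -> bool:
    """True if a directed path a -> ... -> b exists."""
    stack, seen = [a], set()
    while stack:
        v = stack.pop()
        if v == b:
            return True
        if v in seen:
            continue
        seen.add(v)
        stack.extend(adj[v])
    return False


@dataclass
class DiscreteBayesianNetwork:
    """Fitted discrete Bayesian network.

    ``cpts[v]`` is a table with the node's own state on the first axis and
    one axis per parent (in ``parents[v]`` order), holding conditional
    probabilities smoothed with a small Dirichlet pseudocount.
    """

    nodes: list[str]
    parents: dict[str, tuple[str, ...]]
    cpts: dict[str, np.ndarray]
    levels: dict[str, int]
    score: float
    discretizer: Discretizer | None = None

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c, ps in self.parents.items() for p in ps)

    def posterior(self, node: str, evidence: pd.DataFrame) -> np.ndarray:
        """P(node = s | all other nodes) for each row; shape (n, levels)."""
        others = [c for c in self.nodes if c != node]
        ev = evidence[others]
        if self.discretizer is not None:
            ev = self.discretizer.transform(ev)
        n = len(ev)
        K = self.levels[node]
        logp = np.zeros((n, K))
        for s in range(K):
            # node's own CPT
            idx = (np.full(n, s),) + tuple(
                ev[p].to_numpy() for p in self.parents[node]
            )
            logp[:, s] += np.log(self.cpts[node][idx])
            # children whose parent set contains `node`
            for c in self.nodes:
                if c == node or node not in self.parents[c]:
                    continue
                idx_c = (ev[c].to_numpy(),) + tuple(
                    np.full(n, s) if p == node else ev[p].to_numpy()
                    for p in self.parents[c]
                )
                logp[:, s] += np.log(self.cpts[c][idx_c])
        logp -= logp.max(axis=1, keepdims=True)
        post = np.exp(logp)
        return post / post.sum(axis=1, keepdims=True)


def learn_structure(
    coded: pd.DataFrame,
    max_indegree: int = 3,
    restarts: int = 5,
    seed: int = 0,
    require_connected: str | None = None,
    pseudocount: float = 0.5,
) -> DiscreteBayesianNetwork:
    """Hill-climbing BIC structure search on integer-coded data.

    `restarts` seeded random restarts perturb the empty starting graph;
    the highest-scoring DAG wins (ties broken by the earlier restart, so
    the result is deterministic given seed and settings). If
    `require_connected` names a node that ends up isolated, the single
    best-scoring edge touching it is added.
    """
    nodes = list(coded.columns)
    p = len(nodes)
    data = coded.to_numpy(dtype=int)
    levels = np.array([int(data[:, j].max()) + 1 for j in range(p)])
    for j, name in enumerate(nodes):
        if levels[j] < 2:
            raise ValueError(f"node {name!r} has a single observed level")
    scorer = _BicScorer(data, levels)
    rng = np.random.default_rng(seed)

    def climb(parent_sets: list[set[int]]) -> tuple[list[set[int]], float]:
        local = [scorer.local(v, tuple(sorted(parent_sets[v]))) for v in range(p)]
        children = [set() for _ in range(p)]
        for v in range(p):
            for u in parent_sets[v]:
                children[u].add(v)
        while True:
            best_delta, best_move = 1e-10, None
            for u in range(p):
                for v in range(p):
                    if u == v:
                        continue
                    if u in parent_sets[v]:
                        # delete u -> v
                        new = tuple(sorted(parent_sets[v] - {u}))
                        delta = scorer.local(v, new) - local[v]
                        if delta > best_delta:
                            best_delta, best_move = delta, ("del", u, v)
                        # reverse u -> v (becomes v -> u)
                        if len(parent_sets[u]) < max_indegree:
                            adj = {
                                i: children[i] - ({v} if i == u else set())
                                for i in range(p)
                            }
                            if not _has_path(adj, u, v):
                                d2 = (
                                    scorer.local(v, new)
                                    - local[v]
                                    + scorer.local(u, tuple(sorted(parent_sets[u] | {v})))
                                    - local[u]
                                )
                                if d2 > best_delta:
                                    best_delta, best_move = d2, ("rev", u, v)
                    elif v not in parent_sets[u] and len(parent_sets[v]) < max_indegree:
                        # add u -> v unless it creates a cycle
                        if not _has_path({i: children[i] for i in range(p)}, v, u):
                            new = tuple(sorted(parent_sets[v] | {u}))
                            delta = scorer.local(v, new) - local[v]
                            if delta > best_delta:
                                best_delta, best_move = delta, ("add", u, v)
            if best_move is None:
                break
            op, u, v = best_move
            if op == "add":
                parent_sets[v].add(u)
                children[u].add(v)
            elif op == "del":
                parent_sets[v].discard(u)
                children[u].discard(v)
            else:
                parent_sets[v].discard(u)
                children[u].discard(v)
                parent_sets[u].add(v)
                children[v].add(u)
            local[v] = scorer.local(v, tuple(sorted(parent_sets[v])))
            local[u] = scorer.local(u, tuple(sorted(parent_sets[u])))
        return parent_sets, float(sum(local))

    best_sets, best_score = climb([set() for _ in range(p)])
    for _ in range(max(0, restarts - 1)):
        start = [set() for _ in range(p)]
        # random acyclic perturbation: a few edges along a random order
        order = rng.permutation(p)
        for _ in range(p):
            i, j = rng.integers(0, p, size=2)
            u, v = (order[i], order[j]) if i < j else (order[j], order[i])
            if u != v and len(start[v]) < max_indegree:
                start[v].add(u)
        sets_r, score_r = climb(start)
        if score_r > best_score + 1e-9:
            best_sets, best_score = sets_r, score_r

    if require_connected is not None:
        v = nodes.index(require_connected)
        isolated = not best_sets[v] and all(v not in s for s in best_sets)
        if isolated:
            cands = []
            for u in range(p):
                if u == v:
                    continue
                d_in = scorer.local(v, (u,)) - scorer.local(v, ())
                cands.append((d_in, "in", u))
                if len(best_sets[u]) < max_indegree:
                    d_out = scorer.local(u, tuple(sorted(best_sets[u] | {v}))) - scorer.local(
                        u, tuple(sorted(best_sets[u]))
                    )
                    cands.append((d_out, "out", u))
            d, kind, u = max(cands, key=lambda c: (c[0], c[1], -c[2]))
            if kind == "in":
                best_sets[v].add(u)
            else:
                best_sets[u].add(v)
            best_score += d

    # CPT estimation with Dirichlet smoothing
    parents = {nodes[v]: tuple(nodes[u] for u in sorted(best_sets[v])) for v in range(p)}
    cpts: dict[str, np.ndarray] = {}
    for v in range(p):
        ps = tuple(sorted(best_sets[v]))
        cols = (v,) + ps
        dims = tuple(int(levels[c]) for c in cols)
        flat = np.ravel_multi_index(tuple(data[:, c] for c in cols), dims)
        counts = np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims).astype(float)
        counts += pseudocount
        cpts[nodes[v]] = counts / counts.sum(axis=0, keepdims=True)

    return DiscreteBayesianNetwork(
        nodes=nodes,
        parents=parents,
        cpts=cpts,
        levels={nodes[j]: int(levels[j]) for j in range(p)},
        score=best_score,
    )
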