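"""Exact score-based Bayesian-network structure learning on binary data.

Families are scored with the BDeu (Bayesian Dirichlet equivalent uniform)
marginal likelihood; the globally optimal DAG is found by dynamic
programming over variable subsets (best-parent-set tables, then the optimal
sink ordering), which is exact and cheap for the handful of molecular
variables analysed here.  The reported object is the Markov-equivalence
skeleton with a sign per edge (the direction of the conditional
association), plus all chordless undirected cycles ("association loops").
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "DagStructure", "SignedSkeleton", "AssociationLoop",
    "family_score", "learn_dag", "annotate_signs", "find_loops",
]

MAX_EXACT_VARIABLES = 15


@dataclasses.dataclass
class DagStructure:
    variables: tuple[str, ...]
    parents: dict[str, tuple[str, ...]]
    score: float
    order: tuple[str, ...]          # topological order witness

    def skeleton_edges(self) -> set[frozenset]:
        return {frozenset((c, p)) for c, ps in self.parents.items() for p in ps}

    def validate(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        for c, ps in self.parents.items():
            for p in ps:
                if p == c:
                    raise ValueError(f"self-loop at {c}")
                g.add_edge(p, c)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent sets form a cycle")


@dataclasses.dataclass
class SignedSkeleton:
    edges: dict[frozenset, tuple[str, float]]   # edge -> (sign, cond. log-OR)

    def edge_signs(self) -> dict[frozenset, str]:
        return {e: s for e, (s, _m) in self.edges.items()}


@dataclasses.dataclass
class AssociationLoop:
    cycle: tuple[str, ...]          # closed walk, first == last
    net_sign: str                   # product of edge signs: + or -


def _as_matrix(data) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(data, pd.DataFrame):
        if data.isna().any().any():
            raise ValueError("data must be complete cases (no missing calls)")
        return data.to_numpy(dtype=int), tuple(data.columns)
    arr = np.asarray(data, dtype=int)
    return arr, tuple(f"x{i}" for i in range(arr.shape[1]))


def _cell_counts(matrix: np.ndarray) -> np.ndarray:
    """Counts over all 2^k binary configurations (variable i ↔ bit i)."""
    k = matrix.shape[1]
    codes = matrix @ (1 << np.arange(k))
    return np.bincount(codes, minlength=2 ** k)


def _marginal_counts(cells: np.ndarray, keep: tuple[int, ...], k: int) -> np.ndarray:
    """Marginalize the 2^k cell-count vector onto the variables in ``keep``."""
    t = cells.reshape((2,) * k, order="F")  # axis i = variable i
    drop = tuple(i for i in range(k) if i not in keep)
    t = t.sum(axis=drop, keepdims=False)
    # axes are now the kept variables in index order; reorder to `keep` order
    order = np.argsort(np.argsort(keep))
    t = np.transpose(t, axes=order) if t.ndim > 1 else t
    return t


def _bdeu_family(cells: np.ndarray, k: int, child: int,
                 parents: tuple[int, ...], ess: float) -> float:
    """BDeu log marginal likelihood of one (child | parents) family.

    q parent configurations, r = 2 child states; Dirichlet hyperparameters
    ess/q per configuration, ess/(2q) per cell.
    """
    fam = tuple(sorted(parents)) + (child,)
    t = _marginal_counts(cells, fam, k)
    t = t.reshape(-1, 2)            # rows = parent configs, cols = child state
    q = t.shape[0]
    a_j = ess / q
    a_jk = ess / (2 * q)
    n_j = t.sum(axis=1)
    return float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j))
        + np.sum(gammaln(a_jk + t) - gammaln(a_jk))
    )


def family_score(data, child: str, parents, ess: float = 1.0) -> float:
    """BDeu score of one family on a complete-case binary matrix.

    Depends on the data only through its contingency counts (hence invariant
    to row permutation); decomposable across families.
    """
    matrix, names = _as_matrix(data)
    if matrix.shape[0] == 0:
        raise ValueError("empty data")
    if ess <= 0:
        raise ValueError("ess must be positive")
    ci = names.index(child)
    pidx = tuple(names.index(p) for p in parents)
    if ci in pidx:
        raise ValueError("child cannot be its own parent")
    cells = _cell_counts(matrix)
    return _bdeu_family(cells, len(names), ci, pidx, ess)


def learn_dag(data, ess: float = 1.0, max_parents: int = 4) -> DagStructure:
    """Globally optimal DAG by exact dynamic programming.

    Phase 1 scores every (child, parent set) family with |parents| ≤
    ``max_parents``; phase 2 propagates best-parent-sets over candidate
    subsets; phase 3 finds the optimal ordering by DP over subsets.  Ties
    are broken toward lexicographically smaller parent sets / sink choices,
    so the result is deterministic.
    """
    matrix, names = _as_matrix(data)
    k = len(names)
    if k > MAX_EXACT_VARIABLES:
        raise ValueError(
            f"{k} variables exceed the exact-search guard ({MAX_EXACT_VARIABLES})")
    if matrix.shape[0] == 0:
        raise ValueError("empty data")
    cells = _cell_counts(matrix)
    full = (1 << k) - 1

    # phase 1: raw family scores, keyed (child, parent bitmask)
    raw: list[dict[int, float]] = [dict() for _ in range(k)]
    for child in range(k):
        others = [i for i in range(k) if i != child]
        for size in range(0, max_parents + 1):
            for combo in itertools.combinations(others, size):
                mask = sum(1 << i for i in combo)
                raw[child][mask] = _bdeu_family(cells, k, child, combo, ess)

    # phase 2: best parent set within each candidate set
    # bps[child][S] = (score, parent mask); prefer lexicographically smaller
    # masks on ties (a smaller bitmask == lexicographically earlier set here)
    bps: list[dict[int, tuple[float, int]]] = [dict() for _ in range(k)]
    for child in range(k):
        cand_all = full & ~(1 << child)
        subsets = [0]
        bps[child][0] = (raw[child][0], 0)
        # iterate subsets of cand_all in increasing popcount order
        masks = sorted((m for m in range(cand_all + 1) if m & cand_all == m),
                       key=lambda m: (bin(m).count("1"), m))
        for m in masks:
            if m == 0:
                continue
            best = None
            if m in raw[child]:
                best = (raw[child][m], m)
            for b in range(k):
                if m & (1 << b):
                    sub = bps[child][m & ~(1 << b)]
                    if best is None or sub[0] > best[0] or (
                            sub[0] == best[0] and sub[1] < best[1]):
                        best = sub
            bps[child][m] = best
        del subsets

    # phase 3: optimal ordering over subsets; M[S] = best score of a network
    # on variable set S (predecessors of each sink drawn from within S)
    M = {0: 0.0}
    choice: dict[int, int] = {}
    for S in sorted(range(1, full + 1), key=lambda m: (bin(m).count("1"), m)):
        best_score, best_sink = -math.inf, -1
        for sink in range(k):
            if not S & (1 << sink):
                continue
            rest = S & ~(1 << sink)
            sc = M[rest] + bps[sink][rest][0]
            if sc > best_score or (sc == best_score and sink < best_sink):
                best_score, best_sink = sc, sink
        M[S] = best_score
        choice[S] = best_sink

    # reconstruct
    order_idx: list[int] = []
    S = full
    while S:
        sink = choice[S]
        order_idx.append(sink)
        S &= ~(1 << sink)
    order_idx.reverse()
    parents: dict[str, tuple[str, ...]] = {}
    placed = 0
    for sink in order_idx:
        pmask = bps[sink][placed][1]
        parents[names[sink]] = tuple(names[i] for i in range(k) if pmask & (1 << i))
        placed |= 1 << sink
    dag = DagStructure(variables=names, parents=parents, score=M[full],
                       order=tuple(names[i] for i in order_idx))
    dag.validate()
    total = sum(family_score(pd.DataFrame(matrix, columns=names), c, ps, ess)
                for c, ps in parents.items())
    assert abs(total - dag.score) < 1e-6, "score decomposability violated"
    return dag


def _stratified_log_or(matrix: np.ndarray, names: tuple[str, ...],
                       a: str, b: str, conditioning: tuple[str, ...]) -> float:
    """Mantel–Haenszel-style conditional log-OR of (a, b) across strata of
    the conditioning variables, with the 0.5 correction for empty cells."""
    ia, ib = names.index(a), names.index(b)
    ic = [names.index(c) for c in conditioning]
    if ic:
        strata_codes = matrix[:, ic] @ (1 << np.arange(len(ic)))
    else:
        strata_codes = np.zeros(len(matrix), dtype=int)
    num, den = 0.0, 0.0
    for s in np.unique(strata_codes):
        sub = matrix[strata_codes == s]
        x, y = sub[:, ia], sub[:, ib]
        t11 = np.sum((x == 1) & (y == 1)) + 0.0
        t10 = np.sum((x == 1) & (y == 0)) + 0.0
        t01 = np.sum((x == 0) & (y == 1)) + 0.0
        t00 = np.sum((x == 0) & (y == 0)) + 0.0
        if min(t11, t10, t01, t00) == 0:
            t11, t10, t01, t00 = t11 + 0.5, t10 + 0.5, t01 + 0.5, t00 + 0.5
        n = t11 + t10 + t01 + t00
        num += t11 * t00 / n
        den += t10 * t01 / n
    return math.log(num / den)


def annotate_signs(dag: DagStructure, data) -> SignedSkeleton:
    """Sign each skeleton edge by its conditional log-OR.

    For edge (u, v) the conditioning set is the union of the two variables'
    other parents; the conditional OR is pooled over strata of that set
    (0.5 correction in empty cells).
    """
    matrix, names = _as_matrix(data)
    edges: dict[frozenset, tuple[str, float]] = {}
    for e in dag.skeleton_edges():
        u, v = sorted(e)
        cond = tuple(sorted((set(dag.parents[u]) | set(dag.parents[v])) - {u, v}))
        lor = _stratified_log_or(matrix, names, u, v, cond)
        edges[e] = ("+" if lor > 0 else "-", lor)
    return SignedSkeleton(edges=edges)


def find_loops(skeleton: SignedSkeleton) -> list[AssociationLoop]:
    """All chordless undirected cycles, each with its net sign (product of
    edge signs); empty for forests."""
    g = nx.Graph()
    for e in skeleton.edges:
        u, v = sorted(e)
        g.add_edge(u, v)
    loops = []
    for cyc in nx.chordless_cycles(g):
        if len(cyc) < 3:
            continue
        # canonical rotation for determinism
        i = cyc.index(min(cyc))
        rot = cyc[i:] + cyc[:i]
        if len(rot) > 2 and rot[1] > rot[-1]:
            rot = [rot[0]] + rot[:0:-1]
        closed = tuple(rot) + (rot[0],)
        neg = sum(
            1 for a, b in zip(closed[:-1], closed[1:])
            if skeleton.edges[frozenset((a, b))][0] == "-"
        )
        loops.append(AssociationLoop(cycle=closed, net_sign="-" if neg % 2 else "+"))
    return sorted(loops, key=lambda l: (len(l.cycle), l.cycle))
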