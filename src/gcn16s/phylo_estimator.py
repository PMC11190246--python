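"""Phylogeny-based hidden-state prediction of 16S copy numbers.

Five classical estimators infer an unobserved tip trait on a Newick tree from
labeled tips:

- subtree averaging (SA): nearest ancestor's mean of known descendants;
- empirical probabilities (EP): nearest informative ancestor's state
  frequency vector, summarized by its expectation;
- Sankoff maximum parsimony (MPR): minimal-total-transition-cost states by
  dynamic programming, ties averaged;
- weighted squared-change parsimony (WSCP): values minimizing
  sum((dx)^2 / branch_length), a sparse linear system;
- phylogenetic independent contrasts (PIC): Felsenstein's pruning pass,
  equivalent to the Brownian-motion ML ancestral estimate.

Continuous methods treat the tree as unrooted (predictions are re-rooting
invariant); zero-length branches are collapsed into polytomies by default.
"""

from __future__ import annotations

import io
import sys
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths, wrapping a dendropy Tree."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def write_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; missing branch lengths default to 0 (warned)."""
    try:
        tree = dendropy.Tree.get(data=text, schema="newick")
    except Exception as exc:
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing += 1
        elif edge.length < 0:
            raise ValueError("negative branch length")
    if missing:
        warnings.warn(f"{missing} branches without lengths; defaulted to 0")
    return PhyloTree(tree)


def _check_inputs(ptree: PhyloTree, known: Mapping[str, float], queries: Sequence[str]):
    if not known:
        raise ValueError("need at least one known tip")
    tips = set(ptree.tip_labels)
    absent = [q for q in list(queries) + list(known) if q not in tips]
    if absent:
        raise ValueError(f"labels not in tree: {absent[:5]}")


# ---------------------------------------------------------------------------
# SA / EP (rooted, ancestor-based)

def hsp_subtree_averaging(
    ptree: PhyloTree, known: Mapping[str, float], queries: Sequence[str]
) -> dict[str, float]:
    """Each query takes the mean known-tip value of its nearest informative
    ancestor's subtree."""
    _check_inputs(ptree, known, queries)
    tree = ptree.tree
    subtree_sum: dict[int, float] = {}
    subtree_n: dict[int, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            v = known.get(node.taxon.label)
            subtree_sum[id(node)] = 0.0 if v is None else float(v)
            subtree_n[id(node)] = 0 if v is None else 1
        else:
            subtree_sum[id(node)] = sum(subtree_sum[id(c)] for c in node.child_nodes())
            subtree_n[id(node)] = sum(subtree_n[id(c)] for c in node.child_nodes())
    out: dict[str, float] = {}
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    for q in queries:
        node = leaf_by_label[q]
        while subtree_n[id(node)] == 0:
            node = node.parent_node
        out[q] = subtree_sum[id(node)] / subtree_n[id(node)]
    return out


def hsp_empirical_probabilities(
    ptree: PhyloTree,
    known: Mapping[str, int],
    queries: Sequence[str],
    s_max: Optional[int] = None,
    point: str = "expectation",
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-query empirical state distribution (states 1..s_max) + scalar.

    The distribution is the state frequency vector of the known tips under
    the query's nearest informative ancestor; the scalar summary is its
    expectation (or argmax with ``point='argmax'``, lowest state on ties).
    """
    _check_inputs(ptree, known, queries)
    states = {t: int(v) for t, v in known.items()}
    if any(v < 1 for v in states.values()):
        raise ValueError("states must be >= 1")
    S = s_max or max(states.values())
    tree = ptree.tree
    freq: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        vec = np.zeros(S)
        if node.is_leaf():
            s = states.get(node.taxon.label)
            if s is not None:
                vec[s - 1] = 1.0
        else:
            for c in node.child_nodes():
                vec += freq[id(c)]
        freq[id(node)] = vec
    dists: dict[str, np.ndarray] = {}
    points: dict[str, float] = {}
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    values = np.arange(1, S + 1)
    for q in queries:
        node = leaf_by_label[q]
        while freq[id(node)].sum() == 0:
            node = node.parent_node
        d = freq[id(node)] / freq[id(node)].sum()
        dists[q] = d
        if point == "argmax":
            points[q] = float(values[int(np.argmax(d))])
        else:
            points[q] = float(d @ values)
    return dists, points


# ---------------------------------------------------------------------------
# Sankoff maximum parsimony

def _sankoff_messages(ptree: PhyloTree, base: dict[int, np.ndarray], cost: np.ndarray):
    """Undirected min-sum message passing; msg[(u,v)] is the cost vector the
    component behind u contributes, seen from v, minimized over u's state."""
    tree = ptree.tree
    nbrs: dict[int, list] = {}
    nodes = list(tree.preorder_node_iter())
    for node in nodes:
        lst = list(node.child_nodes())
        if node.parent_node is not None:
            lst.append(node.parent_node)
        nbrs[id(node)] = lst
    msg: dict[tuple[int, int], np.ndarray] = {}

    def compute(u, v):  # message u -> v
        key = (id(u), id(v))
        if key in msg:
            return msg[key]
        total = base[id(u)].copy()
        for w in nbrs[id(u)]:
            if w is not v:
                total = total + compute(w, u)
        out = np.min(cost + total[None, :], axis=1)  # min over u's state s'
        msg[key] = out
        return out

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(nodes) + 1000))
    try:
        # force computation of all messages
        for u in nodes:
            for v in nbrs[id(u)]:
                compute(u, v)
    finally:
        sys.setrecursionlimit(old)
    return msg, nbrs


def hsp_sankoff_mpr(
    ptree: PhyloTree,
    known: Mapping[str, int],
    queries: Sequence[str],
    s_max: Optional[int] = None,
    cost_matrix: Optional[np.ndarray] = None,
    point: str = "expectation",
) -> tuple[dict[str, float], float]:
    """Sankoff dynamic program; returns ({query: prediction}, minimal cost).

    Known tips cost 0 in their observed state and infinity elsewhere; query
    tips are free. Each query's cost vector is evaluated with the tree
    re-rooted at the query (via message passing); the prediction averages the
    states attaining the minimum (or takes the lowest, ``point='argmax'``).
    """
    _check_inputs(ptree, known, queries)
    states = {t: int(v) for t, v in known.items()}
    S = s_max or max(states.values())
    if cost_matrix is None:
        cost = 1.0 - np.eye(S)
    else:
        cost = np.asarray(cost_matrix, dtype=float)
        if cost.shape != (S, S) or np.any(cost < 0) or np.any(np.diag(cost) != 0):
            raise ValueError("cost matrix must be SxS, non-negative, zero diagonal")
    INF = np.inf
    base: dict[int, np.ndarray] = {}
    tree = ptree.tree
    for node in tree.preorder_node_iter():
        vec = np.zeros(S)
        if node.is_leaf():
            s = states.get(node.taxon.label)
            if s is not None:
                vec = np.full(S, INF)
                vec[s - 1] = 0.0
        base[id(node)] = vec

    msg, nbrs = _sankoff_messages(ptree, base, cost)

    root = tree.seed_node
    root_cost = base[id(root)].copy()
    for c in nbrs[id(root)]:
        root_cost = root_cost + msg[(id(c), id(root))]
    total_min = float(np.min(root_cost))

    values = np.arange(1, S + 1)
    out: dict[str, float] = {}
    leaf_by_label = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    for q in queries:
        node = leaf_by_label[q]
        vec = base[id(node)].copy()
        for w in nbrs[id(node)]:
            vec = vec + msg[(id(w), id(node))]
        best = np.min(vec)
        tied = values[np.isclose(vec, best)]
        out[q] = float(tied[0]) if point == "argmax" else float(np.mean(tied))
    return out, total_min


# ---------------------------------------------------------------------------
# collapsed undirected graph for the continuous methods

def _collapsed_graph(
    ptree: PhyloTree,
    known: Mapping[str, float],
    zero_mode: str = "collapse",
    epsilon: float = 1e-9,
):
    """Union zero-length edges into single vertices (or floor them).

    Returns (n_groups, edges [(g1, g2, length)], group_known {g: [values]},
    tip_group {label: g}).
    """
    tree = ptree.tree
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = list(range(len(nodes)))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    edges_raw = []
    for node in nodes:
        if node.parent_node is None:
            continue
        length = float(node.edge.length or 0.0)
        a, b = index[id(node)], index[id(node.parent_node)]
        if length <= 0:
            if zero_mode == "collapse":
                union(a, b)
            else:
                edges_raw.append((a, b, epsilon))
        else:
            edges_raw.append((a, b, length))

    groups = sorted({find(i) for i in range(len(nodes))})
    gid = {g: k for k, g in enumerate(groups)}
    edges = []
    for a, b, length in edges_raw:
        ga, gb = gid[find(a)], gid[find(b)]
        if ga != gb:
            edges.append((ga, gb, length))
    group_known: dict[int, list[float]] = {}
    tip_group: dict[str, int] = {}
    for lf in tree.leaf_node_iter():
        g = gid[find(index[id(lf)])]
        tip_group[lf.taxon.label] = g
        v = known.get(lf.taxon.label)
        if v is not None:
            group_known.setdefault(g, []).append(float(v))
    return len(groups), edges, group_known, tip_group


def hsp_wscp(
    ptree: PhyloTree,
    known: Mapping[str, float],
    queries: Sequence[str],
    zero_mode: str = "collapse",
) -> dict[str, float]:
    """Weighted squared-change parsimony.

    Minimizes sum over edges of (value change)^2 / branch length with known
    tips fixed; every unknown node's optimum is the inverse-branch-length
    weighted mean of its neighbors, a sparse linear system.
    """
    _check_inputs(ptree, known, queries)
    n, edges, group_known, tip_group = _collapsed_graph(ptree, known, zero_mode)
    fixed = {g: float(np.mean(v)) for g, v in group_known.items()}
    free = [g for g in range(n) if g not in fixed]
    # drop free groups with no path to data (possible only on degenerate input)
    pos = {g: i for i, g in enumerate(free)}
    A = sp.lil_matrix((len(free), len(free)))
    rhs = np.zeros(len(free))
    diag = np.zeros(len(free))
    for a, b, length in edges:
        w = 1.0 / length
        for u, v in ((a, b), (b, a)):
            if u in pos:
                diag[pos[u]] += w
                if v in pos:
                    A[pos[u], pos[v]] -= w
                else:
                    rhs[pos[u]] += w * fixed[v]
    A.setdiag(diag)
    if len(free):
        if np.any(diag == 0):
            raise ValueError("unknown node disconnected from data")
        sol = spla.spsolve(A.tocsr(), rhs)
    else:
        sol = np.zeros(0)
    values = dict(fixed)
    for g, i in pos.items():
        values[g] = float(sol[i])
    return {q: values[tip_group[q]] for q in queries}


def hsp_pic(
    ptree: PhyloTree,
    known: Mapping[str, float],
    queries: Sequence[str],
    zero_mode: str = "collapse",
) -> dict[str, float]:
    """Phylogenetic independent contrasts / Brownian-motion ML estimate.

    Felsenstein's pruning pass run toward each query: combining the messages
    (x_hat, effective length) of the query's neighborhood gives the ML
    estimate at its attachment point. Other queries carry no information and
    are pruned.
    """
    _check_inputs(ptree, known, queries)
    n, edges, group_known, tip_group = _collapsed_graph(ptree, known, zero_mode)
    nbrs: dict[int, list[tuple[int, float]]] = {g: [] for g in range(n)}
    for a, b, length in edges:
        nbrs[a].append((b, length))
        nbrs[b].append((a, length))
    fixed = {g: float(np.mean(v)) for g, v in group_known.items()}

    msg: dict[tuple[int, int], Optional[tuple[float, float]]] = {}

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * n + 1000))

    def compute(u: int, v: int, length: float):
        """Message u -> v over an edge of ``length``: (mean, total length)."""
        key = (u, v)
        if key in msg:
            return msg[key]
        if u in fixed:
            out = (fixed[u], length)
        else:
            parts = [compute(w, u, l) for (w, l) in nbrs[u] if w != v]
            parts = [p for p in parts if p is not None]
            if not parts:
                out = None
            else:
                prec = [1.0 / p[1] if p[1] > 0 else np.inf for p in parts]
                if np.any(np.isinf(prec)):
                    exact = [p[0] for p, pr in zip(parts, prec) if np.isinf(pr)]
                    out = (float(np.mean(exact)), length)
                else:
                    total_prec = sum(prec)
                    mean = sum(p[0] * pr for p, pr in zip(parts, prec)) / total_prec
                    out = (mean, length + 1.0 / total_prec)
        msg[key] = out
        return out

    try:
        result: dict[str, float] = {}
        for q in queries:
            g = tip_group[q]
            if g in fixed:  # query collapsed onto a known tip
                result[q] = fixed[g]
                continue
            parts = [compute(w, g, l) for (w, l) in nbrs[g]]
            parts = [p for p in parts if p is not None]
            if not parts:
                raise ValueError(f"query {q!r} disconnected from any known tip")
            prec = [1.0 / p[1] if p[1] > 0 else np.inf for p in parts]
            if np.any(np.isinf(prec)):
                exact = [p[0] for p, pr in zip(parts, prec) if np.isinf(pr)]
                result[q] = float(np.mean(exact))
            else:
                total_prec = sum(prec)
                result[q] = float(
                    sum(p[0] * pr for p, pr in zip(parts, prec)) / total_prec
                )
    finally:
        sys.setrecursionlimit(old)
    return result


METHODS = {
    "sa": hsp_subtree_averaging,
    "wscp": hsp_wscp,
    "pic": hsp_pic,
}


def predict(
    method: str,
    ptree: PhyloTree,
    known: Mapping[str, float],
    queries: Sequence[str],
    **kwargs,
) -> dict[str, float]:
    """Uniform scalar-prediction front-end over the five HSP methods."""
    method = method.lower()
    if method in METHODS:
        return METHODS[method](ptree, known, queries, **kwargs)
    if method == "ep":
        known_int = {t: int(round(v)) for t, v in known.items()}
        _, points = hsp_empirical_probabilities(ptree, known_int, queries, **kwargs)
        return points
    if method == "mpr":
        known_int = {t: int(round(v)) for t, v in known.items()}
        points, _ = hsp_sankoff_mpr(ptree, known_int, queries, **kwargs)
        return points
    raise ValueError(f"unknown method {method!r}; expected ep|sa|pic|mpr|wscp")
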