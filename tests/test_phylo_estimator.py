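from itertools import product

import dendropy
import numpy as np
import pytest

from gcn16s.phylo_estimator import (
    PhyloTree,
    hsp_empirical_probabilities,
    hsp_pic,
    hsp_sankoff_mpr,
    hsp_subtree_averaging,
    hsp_wscp,
    parse_newick,
)
from gcn16s.synthetic_data import SimulationConfig, simulate_tree

# ---------------------------------------------------------------------------
# helpers / oracles


def random_tree(n_tips: int, seed: int) -> PhyloTree:
    cfg = SimulationConfig(n_tips=n_tips, seed=seed)
    tree = simulate_tree(cfg)
    # perturb branch lengths away from ultrametricity
    rng = np.random.Generator(np.random.PCG64(seed + 1000))
    for edge in tree.tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(edge.length) * rng.uniform(0.5, 1.5) + 0.05
    return tree


def gls_bm_estimate(ptree: PhyloTree, known: dict, query: str) -> float:
    """Brownian-motion GLS oracle: the conditional mean of the query tip given
    the known tips under BM with the REML mean, computed from the full tip
    covariance (shared root-to-MRCA path lengths)."""
    tree = ptree.tree
    depth = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        depth[id(node)] = (0.0 if parent is None
                           else depth[id(parent)] + float(node.edge.length or 0.0))
    tips = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    labels = list(known) + [query]
    pdm = tree.phylogenetic_distance_matrix()

    def mrca_depth(a, b):
        if a == b:
            return depth[id(tips[a])]
        m = pdm.mrca(tips[a].taxon, tips[b].taxon)
        return depth[id(m)]

    n = len(known)
    C = np.array([[mrca_depth(a, b) for b in labels] for a in labels])
    Ck = C[:n, :n]
    c = C[:n, n]
    y = np.array([known[t] for t in known])
    Cinv = np.linalg.inv(Ck)
    ones = np.ones(n)
    mu = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
    return float(mu + c @ Cinv @ (y - mu * ones))


def sankoff_brute_force(ptree: PhyloTree, known: dict, s_max: int):
    """Minimal total transition cost by exhaustive enumeration over the
    states of every internal node and every unlabeled tip."""
    tree = ptree.tree
    nodes = list(tree.preorder_node_iter())
    fixed = {}
    free = []
    for node in nodes:
        if node.is_leaf() and node.taxon.label in known:
            fixed[id(node)] = known[node.taxon.label]
        else:
            free.append(id(node))
    best = np.inf
    for assignment in product(range(1, s_max + 1), repeat=len(free)):
        state = dict(fixed)
        state.update(dict(zip(free, assignment)))
        cost = 0
        for node in nodes:
            if node.parent_node is not None:
                cost += int(state[id(node)] != state[id(node.parent_node)])
        best = min(best, cost)
    return best


# ---------------------------------------------------------------------------
# parsing

class TestNewick:
    def test_basic_topology(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert len(t.tree.internal_nodes()) == 2

    def test_missing_branch_length_defaults_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            t = parse_newick("((A:1,B),C:2);")
        edge = [lf for lf in t.tree.leaf_node_iter() if lf.taxon.label == "B"][0].edge
        assert edge.length == 0.0

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((A:1,A:1):1,C:2);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            parse_newick("((A:1,B:1):1,C:2;")

    @pytest.mark.parametrize("seed", range(5))
    def test_write_parse_round_trip(self, seed):
        t = random_tree(8, seed)
        text = t.write_newick()
        t2 = parse_newick(text)
        assert sorted(t2.tip_labels) == sorted(t.tip_labels)
        # identical pairwise distances => isomorphic weighted trees
        def dists(pt):
            pdm = pt.tree.phylogenetic_distance_matrix()
            taxa = sorted(pt.tree.taxon_namespace, key=lambda x: x.label)
            return np.array([[pdm.patristic_distance(a, b) for b in taxa] for a in taxa])
        assert np.allclose(dists(t), dists(t2), atol=1e-9)


# ---------------------------------------------------------------------------
# subtree averaging / empirical probabilities

class TestSubtreeAveraging:
    def test_star_tree_mean(self):
        t = parse_newick("(A:1,B:1,Q:1);")
        assert hsp_subtree_averaging(t, {"A": 2.0, "B": 4.0}, ["Q"])["Q"] == 3.0

    def test_query_sister_to_single_known_tip(self):
        t = parse_newick("((K:1,Q:1):1,(X:1,Y:1):1);")
        out = hsp_subtree_averaging(t, {"K": 7.0, "X": 1.0, "Y": 1.0}, ["Q"])
        assert out["Q"] == 7.0

    def test_no_known_tips_rejected(self):
        t = parse_newick("(A:1,Q:1);")
        with pytest.raises(ValueError):
            hsp_subtree_averaging(t, {}, ["Q"])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_descendant_enumeration_oracle(self, seed):
        t = random_tree(10, seed)
        rng = np.random.Generator(np.random.PCG64(seed))
        tips = t.tip_labels
        queries = list(rng.choice(tips, size=3, replace=False))
        known = {tip: float(rng.integers(1, 10)) for tip in tips if tip not in queries}
        got = hsp_subtree_averaging(t, known, queries)
        for q in queries:
            node = [lf for lf in t.tree.leaf_node_iter() if lf.taxon.label == q][0]
            while True:
                vals = [known[lf.taxon.label] for lf in node.leaf_iter()
                        if lf.taxon.label in known]
                if vals:
                    break
                node = node.parent_node
            assert got[q] == pytest.approx(np.mean(vals), abs=1e-12)


class TestEmpiricalProbabilities:
    def test_star_tree_counting(self):
        t = parse_newick("(A:1,B:1,C:1,Q:1);")
        dists, points = hsp_empirical_probabilities(
            t, {"A": 2, "B": 2, "C": 4}, ["Q"])
        assert dists["Q"][1] == pytest.approx(2 / 3)
        assert dists["Q"][3] == pytest.approx(1 / 3)
        assert points["Q"] == pytest.approx(8 / 3)

    def test_unanimous_states(self):
        t = parse_newick("((A:1,B:1):1,Q:1);")
        dists, points = hsp_empirical_probabilities(t, {"A": 5, "B": 5}, ["Q"])
        assert points["Q"] == 5.0
        assert dists["Q"][4] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_distributions_normalized(self, seed):
        t = random_tree(12, seed)
        rng = np.random.Generator(np.random.PCG64(seed))
        tips = t.tip_labels
        queries = list(rng.choice(tips, size=3, replace=False))
        known = {tip: int(rng.integers(1, 6)) for tip in tips if tip not in queries}
        dists, _ = hsp_empirical_probabilities(t, known, queries)
        for d in dists.values():
            assert d.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Sankoff parsimony

class TestSankoffMPR:
    def test_unanimous_tips_cost_zero(self):
        t = parse_newick("((A:1,B:1):1,(C:1,Q:1):1);")
        preds, cost = hsp_sankoff_mpr(t, {"A": 5, "B": 5, "C": 5}, ["Q"])
        assert preds["Q"] == 5.0 and cost == 0.0

    def test_two_state_cherry_tie_averages(self):
        t = parse_newick("((A:1,B:1):1,Q:1);")
        preds, cost = hsp_sankoff_mpr(t, {"A": 1, "B": 2}, ["Q"])
        assert cost == 1.0
        assert preds["Q"] == pytest.approx(1.5)

    def test_negative_costs_rejected(self):
        t = parse_newick("(A:1,Q:1);")
        with pytest.raises(ValueError):
            hsp_sankoff_mpr(t, {"A": 2}, ["Q"],
                            cost_matrix=np.array([[0, -1], [1, 0.0]]))

    @pytest.mark.parametrize("seed", range(30))
    def test_minimal_cost_matches_exhaustive_enumeration(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        n_tips = int(rng.integers(4, 8))
        s_max = int(rng.integers(2, 5))
        t = random_tree(n_tips, seed)
        tips = t.tip_labels
        n_queries = int(rng.integers(1, 3))
        queries = list(rng.choice(tips, size=n_queries, replace=False))
        known = {tip: int(rng.integers(1, s_max + 1)) for tip in tips
                 if tip not in queries}
        if not known:
            known = {tips[0]: 1}
            queries = [q for q in queries if q != tips[0]]
        _, cost = hsp_sankoff_mpr(t, known, queries, s_max=s_max)
        assert cost == sankoff_brute_force(t, known, s_max)


# ---------------------------------------------------------------------------
# WSCP / PIC

class TestWSCP:
    def test_star_tree_symmetry(self):
        t = parse_newick("(A:1,B:1,Q:1);")
        assert hsp_wscp(t, {"A": 1.0, "B": 5.0}, ["Q"])["Q"] == pytest.approx(3.0)

    def test_two_tip_weighted_solution_by_hand(self):
        # unknown node u connects to tips 0 (len 1) and 4 (len 3):
        # u = (0/1 + 4/3) / (1/1 + 1/3) = 1.0
        t = parse_newick("((A:1,B:3):1,Q:1);")
        assert hsp_wscp(t, {"A": 0.0, "B": 4.0}, ["Q"])["Q"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_matches_scipy_minimizer(self, seed):
        from scipy.optimize import minimize

        t = random_tree(8, seed)
        rng = np.random.Generator(np.random.PCG64(seed))
        tips = t.tip_labels
        queries = list(rng.choice(tips, size=2, replace=False))
        known = {tip: float(rng.uniform(1, 10)) for tip in tips if tip not in queries}
        got = hsp_wscp(t, known, queries)

        nodes = list(t.tree.preorder_node_iter())
        unknown = [n for n in nodes
                   if not (n.is_leaf() and n.taxon.label in known)]
        idx = {id(n): i for i, n in enumerate(unknown)}

        def value(node, x):
            if id(node) in idx:
                return x[idx[id(node)]]
            return known[node.taxon.label]

        def objective(x):
            total = 0.0
            for node in nodes:
                if node.parent_node is None:
                    continue
                d = value(node, x) - value(node.parent_node, x)
                total += d * d / float(node.edge.length)
            return total

        res = minimize(objective, np.full(len(unknown), np.mean(list(known.values()))),
                       method="BFGS", options={"gtol": 1e-12, "maxiter": 5000})
        for q in queries:
            node = [lf for lf in t.tree.leaf_node_iter() if lf.taxon.label == q][0]
            assert got[q] == pytest.approx(res.x[idx[id(node)]], abs=1e-5)

    def test_zero_length_branch_collapses_to_known_value(self):
        t = parse_newick("((K:0.0,Q:0.0):1,(X:1,Y:1):1);")
        out = hsp_wscp(t, {"K": 9.0, "X": 1.0, "Y": 1.0}, ["Q"])
        assert out["Q"] == 9.0


class TestPIC:
    def test_ultrametric_symmetric_tree_is_tip_mean(self):
        t = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,Q:3);")
        known = {"A": 2.0, "B": 4.0, "C": 6.0, "D": 8.0}
        assert hsp_pic(t, known, ["Q"])["Q"] == pytest.approx(5.0)

    def test_two_tip_case_equals_wscp(self):
        t = parse_newick("((A:1,B:3):1,Q:1);")
        known = {"A": 0.0, "B": 4.0}
        assert hsp_pic(t, known, ["Q"])["Q"] == pytest.approx(
            hsp_wscp(t, known, ["Q"])["Q"])

    def test_exact_interpolation_at_zero_distance(self):
        t = parse_newick("((K:0.0,Q:0.0):1,(X:1,Y:1):2);")
        out = hsp_pic(t, {"K": 9.0, "X": 1.0, "Y": 2.0}, ["Q"])
        assert out["Q"] == pytest.approx(9.0, abs=1e-9)


class TestContinuousMethodProperties:
    @pytest.mark.parametrize("method", [hsp_wscp, hsp_pic, hsp_subtree_averaging])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_predictions_within_known_range(self, method, seed):
        t = random_tree(12, seed)
        rng = np.random.Generator(np.random.PCG64(seed))
        tips = t.tip_labels
        queries = list(rng.choice(tips, size=3, replace=False))
        known = {tip: float(rng.uniform(1, 21)) for tip in tips if tip not in queries}
        out = method(t, known, queries)
        lo, hi = min(known.values()), max(known.values())
        for v in out.values():
            assert lo - 1e-9 <= v <= hi + 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rerooting_invariance_of_wscp_and_pic(self, seed):
        t = random_tree(8, seed)
        rng = np.random.Generator(np.random.PCG64(seed))
        tips = t.tip_labels
        q = tips[0]
        known = {tip: float(rng.uniform(1, 10)) for tip in tips[1:]}
        before_w = hsp_wscp(t, known, [q])[q]
        before_p = hsp_pic(t, known, [q])[q]
        t2 = parse_newick(t.write_newick())
        node = t2.tree.internal_nodes()[-1]
        t2.tree.reroot_at_node(node, update_bipartitions=False)
        assert hsp_wscp(t2, known, [q])[q] == pytest.approx(before_w, abs=1e-8)
        assert hsp_pic(t2, known, [q])[q] == pytest.approx(before_p, abs=1e-8)
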