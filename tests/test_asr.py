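"""Parsimony and likelihood ancestral reconstruction against oracles."""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np
import pytest

from phyloniche.asr import (
    fitch_reconstruct,
    mk2_fit,
    mk2_loglik,
    mk2_marginal,
    NodeReconstruction,
    smooth_niche,
    states_from_reconstruction,
)
from phyloniche.data_io import Phylo, read_newick

S0, S1, SU = frozenset({0}), frozenset({1}), frozenset({0, 1})


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def enumerate_parsimony(phylo: Phylo, tips):
    """Exhaustive minimum over all labelings consistent with tip sets."""
    nodes = phylo.postorder()
    allowed = [sorted(tips[n.taxon.label]) if n.is_leaf() else [0, 1] for n in nodes]
    edges = [
        (i, next(j for j, m in enumerate(nodes) if m is n.parent_node))
        for i, n in enumerate(nodes)
        if n.parent_node is not None
    ]
    best = None
    per_state = [{0: np.inf, 1: np.inf} for _ in nodes]
    for combo in itertools.product(*allowed):
        cost = sum(combo[a] != combo[b] for a, b in edges)
        for i, s in enumerate(combo):
            per_state[i][s] = min(per_state[i][s], cost)
        best = cost if best is None else min(best, cost)
    sets = {
        nodes[i].node_id: frozenset(s for s in (0, 1) if per_state[i][s] == best)
        for i in range(len(nodes))
    }
    return sets, best


def enumerate_likelihood(phylo: Phylo, tips, q):
    """Sum over all joint internal+tip labelings of the joint probability."""
    nodes = phylo.postorder()
    allowed = [sorted(tips[n.taxon.label]) if n.is_leaf() else [0, 1] for n in nodes]
    total = 0.0
    marg = {n.node_id: np.zeros(2) for n in nodes}
    for combo in itertools.product(*allowed):
        assign = {n.node_id: s for n, s in zip(nodes, combo)}
        p = 0.5  # uniform root prior
        for n in nodes:
            if n.parent_node is None:
                continue
            t = n.edge.length or 0.0
            stay = 0.5 * (1.0 + np.exp(-2.0 * q * t))
            p *= stay if assign[n.node_id] == assign[n.parent_node.node_id] else 1.0 - stay
        total += p
        for nid, s in assign.items():
            marg[nid][s] += p
    return total, {nid: v / total for nid, v in marg.items()}


def random_phylo(rng: random.Random, n_tips: int) -> Phylo:
    labels = [f"t{i}" for i in range(n_tips)]
    nodes = [f"{l}:{rng.uniform(0.1, 3.0):.3f}" for l in labels]
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        nodes.append(f"({a},{b}):{rng.uniform(0.1, 3.0):.3f}")
    tree = dendropy.Tree.get(
        data=nodes[0] + ";", schema="newick",
        preserve_underscores=True, rooting="force-rooted",
    )
    return Phylo(tree)


def random_tips(rng: random.Random, phylo: Phylo, with_unknown=True):
    choices = [S0, S1, SU] if with_unknown else [S0, S1]
    return {lab: rng.choice(choices) for lab in phylo.tip_labels}


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

class TestFitch:
    def test_identical_cherry(self, cherry):
        sets, score = fitch_reconstruct(cherry, {"A": S1, "B": S1})
        assert score == 0
        assert sets[cherry.root.node_id] == S1

    def test_conflicting_cherry(self, cherry):
        sets, score = fitch_reconstruct(cherry, {"A": S1, "B": S0})
        assert score == 1
        assert sets[cherry.root.node_id] == SU

    def test_unknown_tip_never_forces_change(self, cherry):
        sets, score = fitch_reconstruct(cherry, {"A": S1, "B": SU})
        assert score == 0
        assert sets[cherry.root.node_id] == S1

    def test_two_cherries_single_change(self, quartet):
        tips = {"A": S1, "B": S1, "C": S0, "D": S0}
        sets, score = fitch_reconstruct(quartet, tips)
        assert score == 1
        internal = [n for n in quartet.postorder() if not n.is_leaf()]
        by_desc = {
            frozenset(l.taxon.label for l in n.leaf_iter()): sets[n.node_id]
            for n in internal
        }
        assert by_desc[frozenset("AB")] == S1
        assert by_desc[frozenset("CD")] == S0
        assert by_desc[frozenset("ABCD")] == SU

    def test_missing_tip_character_is_error(self, cherry):
        with pytest.raises(KeyError, match="B"):
            fitch_reconstruct(cherry, {"A": S1})

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_exhaustive_enumeration(self, trial):
        rng = random.Random(trial)
        ph = random_phylo(rng, rng.randint(2, 6))
        tips = random_tips(rng, ph)
        sets, score = fitch_reconstruct(ph, tips)
        exp_sets, exp_score = enumerate_parsimony(ph, tips)
        assert score == exp_score
        assert sets == exp_sets

    def test_all_present_tips_give_all_present_nodes(self):
        rng = random.Random(99)
        ph = random_phylo(rng, 6)
        sets, score = fitch_reconstruct(ph, {lab: S1 for lab in ph.tip_labels})
        assert score == 0
        assert all(s == S1 for s in sets.values())

    def test_polytomy_handled_exactly(self, newick_file):
        ph = read_newick(newick_file("(A:1,B:1,C:1,D:1):0;"))
        tips = {"A": S1, "B": S1, "C": S0, "D": S0}
        sets, score = fitch_reconstruct(ph, tips)
        exp_sets, exp_score = enumerate_parsimony(ph, tips)
        assert score == exp_score == 2
        assert sets == exp_sets


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

class TestMk2Loglik:
    def test_two_tip_closed_form(self, cherry):
        # both tips state 1, branch lengths 1 each: path 2t between the tips
        q = 0.37
        ll = mk2_loglik(cherry, {"A": S1, "B": S1}, q)
        stay = 0.5 * (1 + np.exp(-2 * q * 2.0))
        assert ll == pytest.approx(np.log(0.5 * stay), abs=1e-12)

    def test_small_rate_limit(self, cherry):
        same = mk2_loglik(cherry, {"A": S1, "B": S1}, 1e-9)
        assert same == pytest.approx(np.log(0.5), abs=1e-6)
        conflicting = [
            mk2_loglik(cherry, {"A": S1, "B": S0}, q) for q in (1e-2, 1e-4, 1e-6)
        ]
        assert conflicting[0] > conflicting[1] > conflicting[2]  # monotone to -inf

    def test_all_unknown_invariant_to_rate(self, quartet):
        tips = {lab: SU for lab in quartet.tip_labels}
        lls = {mk2_loglik(quartet, tips, q) for q in (1e-4, 0.1, 2.0)}
        assert all(abs(ll - np.log(1.0)) < 1e-12 for ll in lls)

    def test_non_positive_rate_rejected(self, cherry):
        with pytest.raises(ValueError):
            mk2_loglik(cherry, {"A": S1, "B": S1}, 0.0)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_joint_enumeration(self, trial):
        rng = random.Random(1000 + trial)
        ph = random_phylo(rng, rng.randint(2, 6))
        tips = random_tips(rng, ph)
        q = rng.uniform(0.05, 1.5)
        expected, _ = enumerate_likelihood(ph, tips, q)
        assert mk2_loglik(ph, tips, q) == pytest.approx(np.log(expected), abs=1e-10)

    @pytest.mark.parametrize("trial", range(10))
    def test_invariant_to_rerooting(self, trial):
        rng = random.Random(2000 + trial)
        ph = random_phylo(rng, rng.randint(3, 6))
        tips = random_tips(rng, ph)
        q = rng.uniform(0.05, 1.0)
        ll = mk2_loglik(ph, tips, q)
        clone = ph.tree.clone(depth=1)
        internals = [
            n for n in clone.preorder_node_iter()
            if not n.is_leaf() and n.parent_node is not None
        ]
        if not internals:
            pytest.skip("no alternative root position on this topology")
        clone.reroot_at_node(rng.choice(internals), update_bipartitions=False)
        ll2 = mk2_loglik(Phylo(clone), tips, q)
        assert ll2 == pytest.approx(ll, abs=1e-10)


class TestMk2Marginal:
    @pytest.mark.parametrize("trial", range(15))
    def test_matches_joint_enumeration(self, trial):
        rng = random.Random(3000 + trial)
        ph = random_phylo(rng, rng.randint(2, 5))
        tips = random_tips(rng, ph)
        q = rng.uniform(0.05, 1.5)
        _, exp_marg = enumerate_likelihood(ph, tips, q)
        got = mk2_marginal(ph, tips, q)
        for nid, p1 in got.items():
            assert p1 == pytest.approx(exp_marg[nid][1], abs=1e-10)

    def test_probabilities_sum_to_one(self):
        rng = random.Random(7)
        ph = random_phylo(rng, 6)
        tips = random_tips(rng, ph)
        got = mk2_marginal(ph, tips, 0.3)
        for p1 in got.values():
            assert 0.0 <= p1 <= 1.0  # complementary prob is 1 - p1 by construction

    def test_zero_length_branch_pins_adjacent_node(self, newick_file):
        ph = read_newick(newick_file("((A:0,B:2):1,C:3):0;"))
        got = mk2_marginal(ph, {"A": S1, "B": S0, "C": S0}, 0.2)
        parent_of_a = next(
            n for n in ph.postorder()
            if not n.is_leaf() and "A" in {l.taxon.label for l in n.leaf_iter()}
            and len(list(n.leaf_iter())) == 2
        )
        assert got[parent_of_a.node_id] == pytest.approx(1.0, abs=1e-12)

    def test_uniform_present_tips_lean_present_everywhere(self):
        rng = random.Random(11)
        ph = random_phylo(rng, 6)
        got = mk2_marginal(ph, {lab: S1 for lab in ph.tip_labels}, 0.4)
        assert all(p >= 0.5 - 1e-12 for p in got.values())

    def test_unknown_tip_on_zero_branch_is_inert(self, newick_file):
        base = read_newick(newick_file("((A:1,B:1):1,C:2):0;"))
        tips = {"A": S1, "B": S0, "C": S1}
        before = mk2_marginal(base, tips, 0.3)
        desc_before = {
            frozenset(l.taxon.label for l in n.leaf_iter()): before[n.node_id]
            for n in base.postorder()
        }
        grown = read_newick(newick_file("(((A:1,B:1):1,C:2):0,X:0):0;"))
        after = mk2_marginal(grown, {**tips, "X": SU}, 0.3)
        desc_after = {
            frozenset(l.taxon.label for l in n.leaf_iter()): after[n.node_id]
            for n in grown.postorder()
        }
        for key, p in desc_before.items():
            assert desc_after[key] == pytest.approx(p, abs=1e-10)


def simulate_mk2_tips(phylo: Phylo, q: float, rng: np.random.Generator):
    """Forward simulation under the symmetric model — fitting oracle."""
    state = {phylo.root.node_id: int(rng.integers(2))}
    for node in phylo.preorder():
        if node.parent_node is not None:
            stay = 0.5 * (1 + np.exp(-2 * q * (node.edge.length or 0.0)))
            s = state[node.parent_node.node_id]
            state[node.node_id] = s if rng.random() < stay else 1 - s
    return {
        n.taxon.label: frozenset({state[n.node_id]})
        for n in phylo.postorder() if n.is_leaf()
    }


class TestMk2Fit:
    def test_uninformative_character_hits_lower_bound(self, quartet):
        fit = mk2_fit(quartet, {lab: S1 for lab in quartet.tip_labels})
        assert fit.at_lower_bound

    def test_single_tip_tree_rejected(self, newick_file):
        ph = read_newick(newick_file("(A:1):0;"))
        with pytest.raises(ValueError):
            mk2_fit(ph, {"A": S1})

    def test_recovers_simulated_rate_within_factor_two(self):
        from phyloniche.synthetic_data import simulate_tree

        ph = simulate_tree(32, root_age=10.0, seed=4)
        rng = np.random.default_rng(4)
        q_true = 0.08
        chars = [simulate_mk2_tips(ph, q_true, rng) for _ in range(200)]
        fit = mk2_fit(ph, chars)
        assert q_true / 2 <= fit.q <= q_true * 2


# ---------------------------------------------------------------------------
# discretization and smoothing
# ---------------------------------------------------------------------------

class TestStatesFromReconstruction:
    def test_ml_thresholding(self):
        rec = NodeReconstruction(0, ml_prob_present=np.array([0.97, 0.5, 0.02]))
        states = states_from_reconstruction(rec, "likelihood", ml_threshold=0.95)
        assert list(states) == ["1", "?", "0"]

    def test_parsimony_sets(self):
        rec = NodeReconstruction(0, parsimony_sets=[S1, S0, SU])
        assert list(states_from_reconstruction(rec, "parsimony")) == ["1", "0", "?"]

    def test_bad_threshold_rejected(self):
        rec = NodeReconstruction(0, ml_prob_present=np.array([0.9]))
        with pytest.raises(ValueError):
            states_from_reconstruction(rec, "likelihood", ml_threshold=0.4)


class TestSmoothNiche:
    def test_interior_gap_filled_and_flagged(self):
        nv = smooth_niche(list("01010"))
        assert "".join(nv.states) == "01110"
        assert nv.filled.tolist() == [False, False, True, False, False]
        assert nv.interval == (1, 3)

    def test_contiguous_input_unchanged(self):
        nv = smooth_niche(list("01110"))
        assert "".join(nv.states) == "01110"
        assert not nv.filled.any()

    def test_edge_unknowns_left_alone(self):
        nv = smooth_niche(list("?110"))
        assert "".join(nv.states) == "?110"

    def test_interior_uncertain_filled(self):
        nv = smooth_niche(list("1?1"))
        assert "".join(nv.states) == "111"
        assert nv.filled[1]

    def test_empty_niche_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            nv = smooth_niche(list("00?"))
        assert nv.interval is None
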