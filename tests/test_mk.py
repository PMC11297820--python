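"""Mk-n pruning likelihood, fitting, AICc, marginal ASR and transition tally."""

import itertools
import math

import numpy as np
import pytest
import scipy.linalg

from stylotrace import trees as T
from stylotrace.characters import CharacterMatrix
from stylotrace.mk import (
    ASRResult,
    FitResult,
    MkModelSpec,
    aicc,
    asr_marginal,
    compare_models,
    fit_mk,
    mk_loglik,
    tally_transitions,
)

# ---------------------------------------------------------------------------
# independent enumeration oracle


def all_rooted_topologies(labels):
    """All rooted binary topologies (as nested tuples) over the labels."""
    if len(labels) == 1:
        return [labels[0]]
    out = []
    first, rest = labels[0], labels[1:]
    for k in range(len(rest) + 1):
        for left_rest in itertools.combinations(rest, k):
            right = [x for x in rest if x not in left_rest]
            if not right:
                continue
            for lt in all_rooted_topologies([first] + list(left_rest)):
                for rt in all_rooted_topologies(right):
                    out.append((lt, rt))
    # deduplicate by canonical form (left/right order is irrelevant)
    seen = {}
    for t in out:
        seen[canonical(t)] = t
    return list(seen.values())


def canonical(t):
    if isinstance(t, str):
        return t
    a, b = canonical(t[0]), canonical(t[1])
    return (a, b) if str(a) < str(b) else (b, a)


def to_newick(t, rng):
    def rec(node):
        if isinstance(node, str):
            return f"{node}:{rng.uniform(0.1, 2.0):.6f}"
        return f"({rec(node[0])},{rec(node[1])}):{rng.uniform(0.1, 2.0):.6f}"

    return f"({rec(t[0])},{rec(t[1])});"


def enumeration_loglik(tree, chars, Q, root_mode):
    """Exhaustive sum over internal-node state assignments."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    n_states = Q.shape[0]
    P = {
        id(n): scipy.linalg.expm(Q * n.edge.length)
        for n in nodes
        if n.parent_node is not None
    }
    root = tree.seed_node
    per_root_state = np.zeros(n_states)
    for assign in itertools.product(range(n_states), repeat=len(internal)):
        states = {id(n): s for n, s in zip(internal, assign)}
        for n in nodes:
            if n.is_leaf():
                states[id(n)] = chars.state_index(n.taxon.label)
        lik = 1.0
        for n in nodes:
            if n.parent_node is None:
                continue
            sp = states[id(n.parent_node)]
            sc = states[id(n)]
            if sc is None:  # missing tip: sum over states = row sum = 1
                continue
            lik *= P[id(n)][sp, sc]
        per_root_state[states[id(root)]] += lik
    if root_mode == "flat":
        L = per_root_state.mean()
    elif root_mode == "weighted":
        L = (per_root_state**2).sum() / per_root_state.sum()
    else:
        L = per_root_state[int(root_mode.split(":")[1] == "s1")]
    return math.log(L), per_root_state


class TestMkLoglikOracle:
    @pytest.mark.parametrize("n_tips,n_states", [(2, 2), (3, 2), (3, 3), (4, 3), (5, 3)])
    @pytest.mark.parametrize("root_mode", ["weighted", "flat"])
    def test_matches_enumeration_all_topologies(self, n_tips, n_states, root_mode):
        """Pruning equals brute-force enumeration on every rooted topology."""
        rng = np.random.default_rng(n_tips * 10 + n_states)
        labels = [chr(65 + i) for i in range(n_tips)]
        states = tuple(f"s{i}" for i in range(n_states))
        for topo in all_rooted_topologies(labels):
            tree = T.tree_from_string(to_newick(topo, rng))
            data = {lab: states[rng.integers(n_states)] for lab in labels}
            chars = CharacterMatrix(states, data)
            model = MkModelSpec(n_states, "ARD")
            theta = rng.uniform(0.05, 1.5, size=model.n_params)
            got = mk_loglik(tree, chars, model, theta, root_mode)
            expected, _ = enumeration_loglik(tree, chars, model.build_q(theta), root_mode)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_missing_data_tip(self, three_tip_tree):
        chars = CharacterMatrix(("s0", "s1"), {"A": "s0", "B": None, "C": "s1"})
        model = MkModelSpec(2, "ER")
        got = mk_loglik(three_tip_tree, chars, model, [0.4], "flat")
        expected, _ = enumeration_loglik(three_tip_tree, chars, model.build_q([0.4]), "flat")
        assert got == pytest.approx(expected, abs=1e-8)

    def test_zero_rate_flat_root(self, three_tip_tree):
        chars = CharacterMatrix(("s0", "s1"), {"A": "s0", "B": "s0", "C": "s0"})
        got = mk_loglik(three_tip_tree, chars, MkModelSpec(2, "ER"), [1e-13], "flat")
        assert got == pytest.approx(math.log(0.5), abs=1e-9)

    def test_weighted_root_is_convex_combination(self, three_tip_tree, three_tip_chars):
        model = MkModelSpec(2, "ER")
        for theta in ([0.1], [0.7], [2.0]):
            lw = mk_loglik(three_tip_tree, three_tip_chars, model, theta, "weighted")
            fixed = [
                mk_loglik(three_tip_tree, three_tip_chars, model, theta, f"fixed:s{i}")
                for i in range(2)
            ]
            assert min(fixed) - 1e-12 <= lw <= max(fixed) + 1e-12

    def test_scaling_invariance(self, bd_tree_10):
        """lnL is invariant under tree x c, rates / c."""
        from stylotrace import simulate as sim
        from stylotrace.characters import BINARY_STATES

        model = MkModelSpec(2, "SYM")
        chars = sim.simulate_mk(bd_tree_10, model, [0.8], BINARY_STATES, seed=2)
        theta = np.array([0.8])
        l1 = mk_loglik(bd_tree_10, chars, model, theta, "weighted")
        scaled = T.rescale_root_height(bd_tree_10, 4.0)
        l2 = mk_loglik(scaled, chars, model, theta / 4.0, "weighted")
        assert l1 == pytest.approx(l2, abs=1e-8)

    def test_state_outside_space_errors(self, three_tip_tree):
        with pytest.raises(ValueError):
            CharacterMatrix(("s0", "s1"), {"A": "s2", "B": "s0", "C": "s0"})


class TestAicc:
    def test_arithmetic(self):
        assert aicc(0.0, 1, 35) == pytest.approx(2 + 4 / 33)
        assert aicc(-10.0, 2, 10) == pytest.approx(20 + 4 + 12 / 7)

    def test_undefined_for_small_n(self):
        with pytest.raises(ValueError):
            aicc(0.0, 5, 6)


class TestFitMk:
    def test_monomorphic_rate_at_lower_bound(self, three_tip_tree):
        chars = CharacterMatrix(("s0", "s1"), {"A": "s0", "B": "s0", "C": "s0"})
        fit = fit_mk(three_tip_tree, chars, MkModelSpec(2, "ER"), "flat", n_starts=2, seed=0)
        assert fit.theta[0] < 1e-5  # driven to the lower boundary
        assert fit.lnl == pytest.approx(math.log(0.5), abs=1e-4)

    def test_matches_grid_search(self, three_tip_tree, three_tip_chars):
        model = MkModelSpec(2, "ER")
        fit = fit_mk(three_tip_tree, three_tip_chars, model, "weighted", n_starts=3, seed=1)
        grid = np.arange(1e-4, 2.0, 1e-4)
        lls = [mk_loglik(three_tip_tree, three_tip_chars, model, [g], "weighted")
               for g in grid]
        assert fit.theta[0] == pytest.approx(grid[int(np.argmax(lls))], abs=1e-4)

    def test_scheme_nesting(self, study_fixture):
        fits = {
            s: fit_mk(study_fixture.tree, study_fixture.chars5, MkModelSpec(5, s),
                      n_starts=2, seed=3)
            for s in ("ER", "SYM", "ARD")
        }
        assert fits["ARD"].lnl >= fits["SYM"].lnl - 1e-6
        assert fits["SYM"].lnl >= fits["ER"].lnl - 1e-6
        assert fits["ER"].n == 34  # tips with data

    def test_k_by_scheme(self):
        assert MkModelSpec(5, "ER").n_params == 1
        assert MkModelSpec(5, "SYM").n_params == 10
        assert MkModelSpec(5, "ARD").n_params == 20


class TestCompareModels:
    def test_single_fit(self):
        f = FitResult("m", -10.0, np.array([1.0]), 1, 20, aicc(-10, 1, 20), True)
        table = compare_models([f])
        assert table["delta_AICc"].iloc[0] == 0.0

    def test_ranking_matches_independent_sort(self):
        rng = np.random.default_rng(4)
        fits = []
        for i in range(6):
            lnl = -rng.uniform(5, 80)
            k = int(rng.integers(1, 5))
            fits.append(FitResult(f"m{i}", lnl, np.ones(k), k, 30, aicc(lnl, k, 30), True))
        table = compare_models(fits)
        assert list(table["AICc"]) == sorted(f.aicc for f in fits)
        assert table["best"].iloc[0] and not table["best"].iloc[1:].any()

    def test_mixed_data_rejected(self):
        f1 = FitResult("a", -1, np.ones(1), 1, 20, aicc(-1, 1, 20), True,
                       data_key=("x",))
        f2 = FitResult("b", -2, np.ones(1), 1, 20, aicc(-2, 1, 20), True,
                       data_key=("y",))
        with pytest.raises(ValueError):
            compare_models([f1, f2])


class TestASRMarginal:
    def test_zero_rate_monomorphic(self, three_tip_tree):
        chars = CharacterMatrix(("s0", "s1"), {"A": "s0", "B": "s0", "C": "s0"})
        asr = asr_marginal(three_tip_tree, chars, MkModelSpec(2, "ER"), [1e-12], "flat")
        for p in asr.probs.values():
            assert p[0] == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("root_mode", ["weighted", "flat", "fixed:s1"])
    def test_matches_enumeration(self, three_tip_tree, three_tip_chars, root_mode):
        model = MkModelSpec(2, "ER")
        theta = [0.5]
        asr = asr_marginal(three_tip_tree, three_tip_chars, model, theta, root_mode)
        # enumerate marginals at the (A,B) node under the same root prior
        Q = model.build_q(theta)
        P1 = scipy.linalg.expm(Q)
        P2 = scipy.linalg.expm(2 * Q)
        prior = {"weighted": [0.5, 0.5], "flat": [0.5, 0.5], "fixed:s1": [0.0, 1.0]}[root_mode]
        num_x = np.zeros(2)
        num_r = np.zeros(2)
        for r in range(2):
            for x in range(2):
                term = prior[r] * P1[r, x] * P1[x, 0] * P1[x, 0] * P2[r, 1]
                num_x[x] += term
                num_r[r] += term
        np.testing.assert_allclose(asr.probs[frozenset({"A", "B"})], num_x / num_x.sum(),
                                   atol=1e-10)
        np.testing.assert_allclose(asr.probs[frozenset({"A", "B", "C"})],
                                   num_r / num_r.sum(), atol=1e-10)

    def test_vectors_sum_to_one(self, study_fixture):
        model = MkModelSpec(5, "ER")
        asr = asr_marginal(study_fixture.tree, study_fixture.chars5, model, [2.0],
                           "weighted")
        for p in asr.probs.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert ((0 <= p) & (p <= 1)).all()

    def test_weighted_root_marginal_is_normalized_profile(self, three_tip_tree,
                                                          three_tip_chars):
        """At the root, the weighted-mode marginal equals the normalized
        fixed-root likelihood profile."""
        model = MkModelSpec(2, "ER")
        theta = [0.5]
        asr = asr_marginal(three_tip_tree, three_tip_chars, model, theta, "weighted")
        profile = np.array([
            math.exp(mk_loglik(three_tip_tree, three_tip_chars, model, theta, f"fixed:s{i}"))
            for i in range(2)
        ])
        np.testing.assert_allclose(asr.probs[frozenset({"A", "B", "C"})],
                                   profile / profile.sum(), atol=1e-9)

    def test_fixed_root_gets_probability_one(self, three_tip_tree, three_tip_chars):
        asr = asr_marginal(three_tip_tree, three_tip_chars, MkModelSpec(2, "ER"),
                           [0.5], "fixed:s1")
        assert asr.probs[frozenset({"A", "B", "C"})][1] == pytest.approx(1.0)


class TestTallyTransitions:
    def test_uniform_states_no_transitions(self, three_tip_tree):
        chars = CharacterMatrix(("s0", "s1"), {"A": "s0", "B": "s0", "C": "s0"})
        asr = asr_marginal(three_tip_tree, chars, MkModelSpec(2, "ER"), [1e-10], "flat")
        total, pairs = tally_transitions(three_tip_tree, chars, asr)
        assert total == 0 and pairs == {}

    def test_hand_counted_four_tip_tree(self):
        tree = T.tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
        chars = CharacterMatrix(("s0", "s1"), {"A": "s0", "B": "s0", "C": "s1", "D": "s1"})
        # hand-assigned internal states: AB node -> s0, CD node -> s1, root -> s0
        probs = {
            frozenset({"A", "B"}): np.array([1.0, 0.0]),
            frozenset({"C", "D"}): np.array([0.0, 1.0]),
            frozenset({"A", "B", "C", "D"}): np.array([1.0, 0.0]),
        }
        asr = ASRResult(("s0", "s1"), probs, "flat")
        total, pairs = tally_transitions(tree, chars, asr)
        assert total == 1  # only root -> CD-node changes
        assert pairs == {("s0", "s1"): 1}

    def test_missing_tip_edges_excluded(self, three_tip_tree):
        chars = CharacterMatrix(("s0", "s1"), {"A": "s0", "B": "s0", "C": None})
        asr = asr_marginal(three_tip_tree, chars, MkModelSpec(2, "ER"), [0.3], "flat")
        total, _ = tally_transitions(three_tip_tree, chars, asr)
        assert total == 0

    def test_argmax_tie_goes_to_lowest_index(self):
        probs = {frozenset({"A", "B"}): np.array([0.5, 0.5])}
        asr = ASRResult(("s0", "s1"), probs, "flat")
        assert asr.argmax(frozenset({"A", "B"})) == 0
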