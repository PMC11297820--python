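"""Synthetic-data generators with the statistical structure of the analyses.

Every stage of the pipeline can be exercised without downloads: ultrametric
trees from (state-dependent) birth-death processes with incomplete sampling,
discrete characters from Mk jump processes, pseudo-posterior tree samples
from branch-length jitter, and a study-shaped fixture that attaches the real
35-taxon character table to a simulated tree.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import math

import dendropy
import numpy as np

from .bisse import BisseParams
from .characters import BINARY_STATES, CharacterMatrix
from .mk import MkModelSpec
from .trees import node_ages, rescale_root_height, root_height

RETRY_CAP = 100


@dataclass
class SimConfig:
    """Bundle of generator settings (defaults mirror the study conditions)."""

    seed: int = 1
    n_tips: int = 35
    tree_height: float = 1.0
    birth: float = 1.0
    death: float = 0.25
    mk_scheme: str = "ER"
    mk_rate: float = 3.0
    bisse: BisseParams = field(
        default_factory=lambda: BisseParams(
            lam0=3.95, lam1=7.07, mu0=0.0, mu1=0.0, q01=1.78, q10=1.78, rho=0.16
        )
    )
    n_posterior: int = 100
    jitter_sigma: float = 0.1


# ---------------------------------------------------------------------------
# forward birth-death machinery


class _Lineage:
    __slots__ = ("idx", "parent", "birth_time", "death_time", "state", "children")

    def __init__(self, idx: int, parent: Optional[int], birth_time: float, state: int):
        self.idx = idx
        self.parent = parent
        self.birth_time = birth_time
        self.death_time: Optional[float] = None
        self.state = state
        self.children: list[int] = []


def _forward_bd(
    rng: np.random.Generator,
    lam: Sequence[float],
    mu: Sequence[float],
    q: Sequence[Sequence[float]],
    start_state: int,
    n_extant: Optional[int],
    max_time: Optional[float],
) -> tuple[list[_Lineage], float]:
    """Gillespie simulation from a single lineage.

    Stops when the extant count first reaches ``n_extant`` (the clock is then
    advanced to the next would-be event so the youngest tips have positive
    pendant branches) or when ``max_time`` is reached.  Returns all lineages
    and the stop time; raises if the clade dies out.
    """
    if n_extant is None and max_time is None:
        raise ValueError("need a stopping rule")
    n_states = len(lam)
    lineages = [_Lineage(0, None, 0.0, start_state)]
    active: list[int] = [0]
    t = 0.0
    while True:
        if not active:
            raise _Extinct()
        rates = np.array(
            [lam[lineages[i].state] + mu[lineages[i].state]
             + sum(q[lineages[i].state][j] for j in range(n_states) if j != lineages[i].state)
             for i in active]
        )
        total = rates.sum()
        if total <= 0:
            if max_time is not None:
                t = max_time
                break
            raise _Extinct()
        wait = rng.exponential(1.0 / total)
        if n_extant is not None and len(active) >= n_extant:
            t += wait if np.isfinite(wait) else 0.0
            break
        if max_time is not None and t + wait >= max_time:
            t = max_time
            break
        t += wait
        i = active[rng.choice(len(active), p=rates / total)]
        lin = lineages[i]
        s = lin.state
        q_out = [q[s][j] if j != s else 0.0 for j in range(n_states)]
        ev = rng.random() * (lam[s] + mu[s] + sum(q_out))
        if ev < lam[s]:
            for _ in range(2):
                child = _Lineage(len(lineages), i, t, s)
                lin.children.append(child.idx)
                lineages.append(child)
            lin.death_time = t
            active.remove(i)
            active.extend([c for c in lin.children])
        elif ev < lam[s] + mu[s]:
            lin.death_time = t
            active.remove(i)
        else:
            ev -= lam[s] + mu[s]
            for j in range(n_states):
                if ev < q_out[j]:
                    lin.state = j
                    break
                ev -= q_out[j]
    for i in active:
        lineages[i].death_time = t
    return lineages, t


class _Extinct(Exception):
    pass


def _build_tree(
    lineages: list[_Lineage], t_end: float, keep: set[int], labels: Sequence[str]
) -> tuple[dendropy.Tree, dict[str, int]]:
    """Assemble a dendropy tree over the kept extant lineages.

    Extinct and unsampled lineages are pruned and unifurcations suppressed
    with branch lengths summed.  Returns the tree and tip label -> state.
    """
    # which internal lineages have sampled descendants
    has_sampled = {i: (i in keep) for i in range(len(lineages))}
    for lin in reversed(lineages):  # children have higher indices than parents
        for c in lin.children:
            if has_sampled[c]:
                has_sampled[lin.idx] = True

    label_iter = iter(labels)
    states: dict[str, int] = {}

    def grow(idx: int, parent_node: Optional[dendropy.Node], extra: float,
             tree: dendropy.Tree) -> None:
        lin = lineages[idx]
        length = (lin.death_time - lin.birth_time) + extra
        kids = [c for c in lin.children if has_sampled[c]]
        if not kids and idx in keep:
            node = dendropy.Node()
            node.edge.length = length
            label = next(label_iter)
            node.taxon = tree.taxon_namespace.require_taxon(label=label)
            states[label] = lin.state
            parent_node.add_child(node)
        elif len(kids) == 1:
            grow(kids[0], parent_node, length, tree)
        elif len(kids) == 2:
            node = dendropy.Node()
            node.edge.length = length
            parent_node.add_child(node)
            grow(kids[0], node, 0.0, tree)
            grow(kids[1], node, 0.0, tree)

    # find the MRCA of sampled tips: walk from the origin lineage while only
    # one child subtree is sampled
    root_idx = 0
    while True:
        kids = [c for c in lineages[root_idx].children if has_sampled[c]]
        if len(kids) == 1:
            root_idx = kids[0]
        else:
            break
    tree = dendropy.Tree()
    if not [c for c in lineages[root_idx].children if has_sampled[c]]:
        raise _Extinct()
    kids = [c for c in lineages[root_idx].children if has_sampled[c]]
    tree.seed_node.edge.length = None
    grow(kids[0], tree.seed_node, 0.0, tree)
    grow(kids[1], tree.seed_node, 0.0, tree)
    return tree, states


def _default_labels(n: int) -> list[str]:
    return [f"t{i+1}" for i in range(n)]


def simulate_bd_tree(
    n_tips: int,
    birth: float = 1.0,
    death: float = 0.0,
    seed: int = 0,
    root_height_target: Optional[float] = 1.0,
    labels: Optional[Sequence[str]] = None,
) -> dendropy.Tree:
    """Constant-rate birth-death tree conditioned on a tip count.

    Complete sampling; extinct lineages pruned; optionally rescaled to a
    fixed root height (default 1, the relative-time convention).
    """
    rng = np.random.default_rng(seed)
    for _ in range(RETRY_CAP):
        try:
            lineages, t_end = _forward_bd(
                rng, [birth], [death], [[0.0]], 0, n_extant=n_tips, max_time=None
            )
            extant = {l.idx for l in lineages if l.death_time == t_end and not l.children}
            if len(extant) < n_tips:
                continue
            tree, _ = _build_tree(
                lineages, t_end, extant, labels or _default_labels(len(extant))
            )
            if len(tree.leaf_nodes()) != n_tips:
                continue
            if root_height_target is not None:
                tree = rescale_root_height(tree, root_height_target)
            return tree
        except _Extinct:
            continue
    raise RuntimeError(f"no surviving simulation in {RETRY_CAP} attempts")


def simulate_bisse_tree(
    p: BisseParams,
    n_extant: Optional[int] = None,
    max_time: Optional[float] = None,
    seed: int = 0,
    start_state: Optional[int] = None,
    min_tips: int = 4,
    require_both_states: bool = False,
    rescale_to: Optional[float] = None,
    labels: Optional[Sequence[str]] = None,
) -> tuple[dendropy.Tree, CharacterMatrix]:
    """State-dependent birth-death tree with incomplete sampling.

    Forward simulation from a single lineage; extinct lineages pruned; each
    surviving tip is retained with probability ``p.rho``.  The returned tree
    is the reconstructed tree over retained tips with their true states.
    The start state defaults to a draw from the stationary distribution of
    the transition process.
    """
    rng = np.random.default_rng(seed)
    lam = [p.lam0, p.lam1]
    mu = [p.mu0, p.mu1]
    q = [[0.0, p.q01], [p.q10, 0.0]]
    for _ in range(RETRY_CAP):
        if start_state is None:
            tot = p.q01 + p.q10
            pi0 = p.q10 / tot if tot > 0 else 0.5
            s0 = 0 if rng.random() < pi0 else 1
        else:
            s0 = start_state
        try:
            lineages, t_end = _forward_bd(
                rng, lam, mu, q, s0, n_extant=n_extant, max_time=max_time
            )
        except _Extinct:
            continue
        extant = [l.idx for l in lineages if l.death_time == t_end and not l.children]
        keep = {i for i in extant if rng.random() < p.rho}
        if len(keep) < max(min_tips, 2):
            continue
        try:
            tree, states = _build_tree(
                lineages, t_end, keep, labels or _default_labels(len(keep))
            )
        except (_Extinct, IndexError):
            continue
        if require_both_states and len(set(states.values())) < 2:
            continue
        chars = CharacterMatrix(
            BINARY_STATES, {lab: BINARY_STATES[s] for lab, s in states.items()}
        )
        if rescale_to is not None:
            tree = rescale_root_height(tree, rescale_to)
        return tree, chars
    raise RuntimeError(f"no usable simulation in {RETRY_CAP} attempts")


# ---------------------------------------------------------------------------
# character simulation


def simulate_mk(
    tree: dendropy.Tree,
    model: MkModelSpec,
    theta: Sequence[float],
    states: Sequence[str],
    root_state: Optional[str] = None,
    seed: int = 0,
) -> CharacterMatrix:
    """Evolve a discrete character along a tree under the Mk jump process."""
    rng = np.random.default_rng(seed)
    Q = model.build_q(theta)
    n = model.n_states
    if len(states) != n:
        raise ValueError("state labels must match the model dimension")
    if root_state is None:
        # stationary distribution (left null vector of Q)
        w, V = np.linalg.eig(Q.T)
        pi = np.real(V[:, np.argmin(np.abs(w))])
        pi = np.abs(pi) / np.abs(pi).sum()
        s = int(rng.choice(n, p=pi))
    else:
        s = list(states).index(root_state)

    def evolve(state: int, t: float) -> int:
        while True:
            rate = -Q[state, state]
            if rate <= 0:
                return state
            wait = rng.exponential(1.0 / rate)
            if wait >= t:
                return state
            t -= wait
            probs = Q[state].copy()
            probs[state] = 0.0
            probs /= probs.sum()
            state = int(rng.choice(n, p=probs))

    node_state: dict[int, int] = {}
    data: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node_state[id(node)] = s
        else:
            node_state[id(node)] = evolve(
                node_state[id(node.parent_node)], node.edge.length or 0.0
            )
        if node.is_leaf():
            data[node.taxon.label] = states[node_state[id(node)]]
    return CharacterMatrix(tuple(states), data)


# ---------------------------------------------------------------------------
# pseudo-posterior and topology perturbation


def jitter_tree_sample(
    tree: dendropy.Tree, n: int, sigma: float, seed: int = 0
) -> dendropy.TreeList:
    """Pseudo-posterior: n copies with lognormal node-height jitter.

    Node ages are multiplied by independent lognormal(0, sigma) noise in
    preorder with the child-younger-than-parent constraint enforced, then
    renormalized to root height 1.  Topology is untouched.  This is an
    artifact stand-in for an MCMC tree sample, not a model of one.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = dendropy.TreeList(taxon_namespace=tree.taxon_namespace)
    for _ in range(n):
        t = tree.clone(depth=1)
        ages = node_ages(t)
        new_age: dict[dendropy.Node, float] = {}
        for node in t.preorder_node_iter():
            if node.is_leaf():
                new_age[node] = 0.0
                continue
            a = ages[node] * math.exp(sigma * rng.standard_normal())
            if node.parent_node is not None and a >= new_age[node.parent_node]:
                a = new_age[node.parent_node] * (
                    ages[node] / ages[node.parent_node] if ages[node.parent_node] > 0 else 0.5
                )
            new_age[node] = a
        scale = new_age[t.seed_node]
        if scale <= 0:
            scale = 1.0
        for node in t.preorder_node_iter():
            new_age[node] /= scale
        for node in t.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = new_age[node.parent_node] - new_age[node]
        out.append(t)
    return out


def perturb_topology(tree: dendropy.Tree, n_moves: int, seed: int = 0) -> dendropy.Tree:
    """Apply random NNI moves to internal edges (topology-only gene trees)."""
    rng = np.random.default_rng(seed)
    out = tree.clone(depth=1)
    for _ in range(n_moves):
        internal = [
            n for n in out.preorder_internal_node_iter()
            if n.parent_node is not None and len(n.child_nodes()) == 2
            and len(n.parent_node.child_nodes()) == 2
        ]
        if not internal:
            break
        node = internal[rng.integers(len(internal))]
        parent = node.parent_node
        sibling = [c for c in parent.child_nodes() if c is not node][0]
        child = node.child_nodes()[int(rng.integers(2))]
        # swap child with sibling
        node.remove_child(child)
        parent.remove_child(sibling)
        node.add_child(sibling)
        parent.add_child(child)
    return out


# ---------------------------------------------------------------------------
# the study-shaped fixture


@dataclass
class StudyFixture:
    tree: dendropy.Tree  # 35-tip ultrametric, root height 1, study taxon names
    sample: dendropy.TreeList  # pseudo-posterior
    chars5: CharacterMatrix
    chars_binary: CharacterMatrix  # scored taxa only
    binary_pruned: list[str]
    binary_tree: dendropy.Tree  # tree pruned to the binary-scored taxa


def make_study_fixture(seed: int = 1, n_posterior: int = 100,
                       jitter_sigma: float = 0.1, signal_rate: float = 2.0) -> StudyFixture:
    """Simulated 35-tip tree carrying the real study character table.

    The tree is a constant-rate birth-death simulation conditioned on 35
    tips, rescaled to root height 1; the pseudo-posterior is a jittered
    sample.  Taxon names are attached so the real trait columns carry
    phylogenetic signal comparable to a character evolved under an
    equal-rates Markov process at ``signal_rate`` events per unit relative
    time: a five-state character is simulated on the tree and each tip is
    given a study taxon whose recorded state matches the simulated one
    whenever the state counts allow.  The trait values themselves are the
    study's, untouched.
    """
    from .characters import FIVE_STATES
    from .mk import MkModelSpec
    from .traits import fixture_binary_pruned, load_fixture
    from .trees import prune_taxa

    chars5, _ = load_fixture()
    chars_binary, pruned = fixture_binary_pruned()
    rng = np.random.default_rng(seed)
    n = len(chars5)
    temp = [f"tmp{i}" for i in range(n)]
    tree = simulate_bd_tree(
        n, birth=1.0, death=0.25, seed=int(rng.integers(2**31 - 1)),
        root_height_target=1.0, labels=temp,
    )
    simulated = simulate_mk(
        tree, MkModelSpec(5, "ER"), [signal_rate], FIVE_STATES,
        seed=int(rng.integers(2**31 - 1)),
    )
    # pools of study taxa per recorded state; missing-state taxa are wildcards
    pools: dict[Optional[str], list[str]] = {}
    for taxon in chars5.taxa:
        pools.setdefault(chars5[taxon], []).append(taxon)
    assignment: dict[str, str] = {}
    leftover_tips: list[str] = []
    for leaf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label):
        s = simulated[leaf.taxon.label]
        if pools.get(s):
            i = int(rng.integers(len(pools[s])))
            assignment[leaf.taxon.label] = pools[s].pop(i)
        else:
            leftover_tips.append(leaf.taxon.label)
    remaining = [t for pool in pools.values() for t in pool]
    rng.shuffle(remaining)
    for tip, taxon in zip(leftover_tips, remaining):
        assignment[tip] = taxon
    for taxon_obj in tree.taxon_namespace:
        taxon_obj.label = assignment[taxon_obj.label]

    sample = jitter_tree_sample(tree, n_posterior, jitter_sigma,
                                seed=int(rng.integers(2**31 - 1)))
    binary_tree = prune_taxa(tree, pruned)
    return StudyFixture(tree, sample, chars5, chars_binary, pruned, binary_tree)
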