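"""Mk-n likelihood, ML fitting, AICc comparison and marginal ASR.

The Mk-n model is a continuous-time Markov chain on ``n`` discrete states
evolving along a rooted tree.  Three parameter-sharing schemes are provided:
ER (one rate for every transition), SYM (forward and reverse rates equal,
n(n-1)/2 parameters) and ARD (all rates different, n(n-1) parameters).
Likelihoods are computed by Felsenstein pruning with per-node log-scaling;
per-branch transition matrices come from an eigendecomposition of the rate
matrix, falling back to scaling-and-squaring when the decomposition is
ill-conditioned.

Three root treatments are supported throughout:

* ``"weighted"`` — root state likelihoods weighted by their own relative
  probability of producing the data (the FitzJohn weighting, the default in
  the comparative-methods literature);
* ``"flat"`` — a uniform root prior;
* ``"fixed:<state>"`` — the root state is known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .characters import CharacterMatrix

RATE_LOWER = 1e-8
RATE_UPPER = 1e3

SCHEMES = ("ER", "SYM", "ARD")


# ---------------------------------------------------------------------------
# model specification


@dataclass
class MkModelSpec:
    """An n-state Mk rate matrix with a parameter-sharing scheme."""

    n_states: int
    scheme: str = "ER"

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.n_states < 2:
            raise ValueError("need at least two states")

    @property
    def n_params(self) -> int:
        n = self.n_states
        return {"ER": 1, "SYM": n * (n - 1) // 2, "ARD": n * (n - 1)}[self.scheme]

    def param_index(self) -> np.ndarray:
        """Off-diagonal (i, j) -> shared parameter id; diagonal = -1."""
        n = self.n_states
        idx = -np.ones((n, n), dtype=int)
        if self.scheme == "ER":
            idx[~np.eye(n, dtype=bool)] = 0
        elif self.scheme == "SYM":
            p = 0
            for i in range(n):
                for j in range(i + 1, n):
                    idx[i, j] = idx[j, i] = p
                    p += 1
        else:  # ARD
            p = 0
            for i in range(n):
                for j in range(n):
                    if i != j:
                        idx[i, j] = p
                        p += 1
        return idx

    def build_q(self, theta: Sequence[float]) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(f"expected {self.n_params} rates, got {theta.shape}")
        if (theta < 0).any():
            raise ValueError("rates must be non-negative")
        idx = self.param_index()
        Q = np.where(idx >= 0, theta[np.clip(idx, 0, None)], 0.0)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def transition_matrices(Q: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """exp(Q t) for a batch of branch lengths.

    Uses an eigendecomposition of Q when it is well conditioned (one
    decomposition serves all branches); otherwise falls back to
    scaling-and-squaring per branch.
    """
    lengths = np.asarray(lengths, dtype=float)
    n = Q.shape[0]
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e8:
            E = np.exp(np.multiply.outer(lengths, w))  # (m, n)
            P = np.einsum("ij,tj,jk->tik", V, E, Vinv).real
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=2, keepdims=True)
            return P
    except np.linalg.LinAlgError:
        pass
    P = np.empty((len(lengths), n, n))
    for t, ell in enumerate(lengths):
        P[t] = scipy.linalg.expm(Q * ell)
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=2, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# tree linearisation (shared with the BiSSE module)


@dataclass
class TreeIndex:
    """Postorder array view of a rooted tree."""

    nodes: list  # postorder dendropy nodes
    children: list[list[int]]  # postorder indices of each node's children
    lengths: np.ndarray  # branch length above each node (0 for root)
    tip_label: dict[int, str]  # postorder index -> taxon label
    clades: list[frozenset]  # leaf-label set below each node

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> int:
        return self.n_nodes - 1


def linearize(tree: dendropy.Tree) -> TreeIndex:
    nodes = list(tree.postorder_node_iter())
    pos = {id(n): i for i, n in enumerate(nodes)}
    children = [[pos[id(c)] for c in n.child_nodes()] for n in nodes]
    lengths = np.array(
        [n.edge.length if (n.parent_node is not None and n.edge.length is not None) else 0.0
         for n in nodes]
    )
    tip_label = {i: n.taxon.label for i, n in enumerate(nodes) if n.is_leaf()}
    clades: list[frozenset] = [frozenset()] * len(nodes)
    for i, n in enumerate(nodes):
        if n.is_leaf():
            clades[i] = frozenset([n.taxon.label])
        else:
            s: frozenset = frozenset()
            for c in children[i]:
                s = s | clades[c]
            clades[i] = s
    return TreeIndex(nodes, children, lengths, tip_label, clades)


def _parse_root_mode(root_mode: str, states: Sequence[str]) -> tuple[str, int]:
    if root_mode in ("weighted", "flat"):
        return root_mode, -1
    if root_mode.startswith("fixed:"):
        label = root_mode.split(":", 1)[1]
        if label not in states:
            raise ValueError(f"unknown root state {label!r}")
        return "fixed", list(states).index(label)
    raise ValueError(f"unknown root mode {root_mode!r}")


def _tip_partial(chars: CharacterMatrix, label: str) -> np.ndarray:
    if label not in chars:
        raise ValueError(f"tip {label!r} absent from character matrix")
    n = chars.n_states
    s = chars.state_index(label)
    if s is None:
        return np.ones(n)  # missing data: uniform ambiguity
    v = np.zeros(n)
    v[s] = 1.0
    return v


def _mk_partials(
    ti: TreeIndex, chars: CharacterMatrix, Q: np.ndarray
) -> tuple[np.ndarray, float, np.ndarray]:
    """Tipward conditional likelihoods D and the accumulated log-scale.

    Returns (D, logscale, P) with D[i] the partial at node i (after
    combining its children, before the branch above it), and P[i] the
    transition matrix along the branch above node i.
    """
    n = Q.shape[0]
    P = transition_matrices(Q, ti.lengths)
    D = np.empty((ti.n_nodes, n))
    logscale = 0.0
    for i in range(ti.n_nodes):
        if not ti.children[i]:
            D[i] = _tip_partial(chars, ti.tip_label[i])
        else:
            v = np.ones(n)
            for c in ti.children[i]:
                v = v * (P[c] @ D[c])
            m = v.max()
            if m <= 0:
                return D, -math.inf, P
            D[i] = v / m
            logscale += math.log(m)
    return D, logscale, P


def _root_likelihood(d_root: np.ndarray, mode: str, fixed: int) -> float:
    total = d_root.sum()
    if total <= 0:
        return 0.0
    if mode == "weighted":
        return float((d_root * d_root).sum() / total)
    if mode == "flat":
        return float(total / len(d_root))
    return float(d_root[fixed])


def mk_loglik(
    tree: dendropy.Tree,
    chars: CharacterMatrix,
    model: MkModelSpec,
    theta: Sequence[float],
    root_mode: str = "weighted",
) -> float:
    """Log-likelihood of the tip states under the Mk model.

    Felsenstein pruning with per-node rescaling; tips with missing data get
    an all-ones partial.  Returns ``-inf`` when the data are impossible
    (e.g. a fixed root with zero rates and conflicting tips).
    """
    mode, fixed = _parse_root_mode(root_mode, chars.states)
    Q = model.build_q(theta)
    ti = linearize(tree)
    D, logscale, _ = _mk_partials(ti, chars, Q)
    if not math.isfinite(logscale):
        return -math.inf
    L = _root_likelihood(D[ti.root], mode, fixed)
    if L <= 0:
        return -math.inf
    return math.log(L) + logscale


# ---------------------------------------------------------------------------
# fitting and model comparison


def aicc(lnl: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 lnL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * lnl + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


@dataclass
class FitResult:
    model_id: str
    lnl: float
    theta: np.ndarray
    k: int
    n: int
    aicc: float
    converged: bool
    start_lnls: list[float] = field(default_factory=list)
    data_key: Optional[tuple] = None
    delta_aicc: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "model": self.model_id,
            "lnL": self.lnl,
            "k": self.k,
            "n": self.n,
            "AICc": self.aicc,
            "converged": self.converged,
            "theta": list(map(float, np.atleast_1d(self.theta))),
        }


def fit_mk(
    tree: dendropy.Tree,
    chars: CharacterMatrix,
    model: MkModelSpec,
    root_mode: str = "weighted",
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Maximum-likelihood Mk fit with seeded random restarts.

    Optimisation is bounded quasi-Newton on log-rates in
    [1e-8, 1e3] events per unit relative time.  The AICc sample size is the
    number of tips with non-missing data.
    """
    rng = np.random.default_rng(seed)
    tips = [lab for lab in (leaf.taxon.label for leaf in tree.leaf_node_iter())]
    sub = chars.subset(tips)
    n_data = sub.non_missing()
    ti = linearize(tree)
    mode, fixed = _parse_root_mode(root_mode, chars.states)

    def nll(x: np.ndarray) -> float:
        Q = model.build_q(np.exp(x))
        D, logscale, _ = _mk_partials(ti, chars, Q)
        if not math.isfinite(logscale):
            return 1e10
        L = _root_likelihood(D[ti.root], mode, fixed)
        if L <= 0:
            return 1e10
        return -(math.log(L) + logscale)

    bounds = [(math.log(RATE_LOWER), math.log(RATE_UPPER))] * model.n_params
    starts = [np.zeros(model.n_params)]
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(math.log(0.03), math.log(30.0), size=model.n_params))

    best = None
    start_lnls: list[float] = []
    converged = False
    for x0 in starts:
        res = scipy.optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        start_lnls.append(-res.fun)
        converged = converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not converged:
        raise RuntimeError(f"Mk optimisation failed in all starts: {start_lnls}")

    theta = np.exp(best.x)
    lnl = -best.fun
    return FitResult(
        model_id=f"mk{model.n_states}-{model.scheme}",
        lnl=lnl,
        theta=theta,
        k=model.n_params,
        n=n_data,
        aicc=aicc(lnl, model.n_params, n_data),
        converged=converged,
        start_lnls=start_lnls,
        data_key=(tuple(sorted(sub.data.items())), root_mode),
    )


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits by AICc (ascending) with delta-AICc relative to the best."""
    if not fits:
        raise ValueError("no fits to compare")
    keys = {f.data_key for f in fits if f.data_key is not None}
    if len(keys) > 1:
        raise ValueError("fits were made on different data")
    rows = sorted(fits, key=lambda f: f.aicc)
    best = rows[0].aicc
    for f in fits:
        f.delta_aicc = f.aicc - best
    return pd.DataFrame(
        {
            "model": [f.model_id for f in rows],
            "k": [f.k for f in rows],
            "lnL": [f.lnl for f in rows],
            "AICc": [f.aicc for f in rows],
            "delta_AICc": [f.aicc - best for f in rows],
            "best": [f.aicc == best for f in rows],
        }
    )


# ---------------------------------------------------------------------------
# marginal ancestral state reconstruction


@dataclass
class ASRResult:
    """Per-node marginal state probabilities, keyed by the node's clade."""

    states: tuple[str, ...]
    probs: dict[frozenset, np.ndarray]
    root_mode: str
    tie_nodes: list[frozenset] = field(default_factory=list)

    def argmax(self, clade: frozenset) -> int:
        """Highest-probability state index; ties go to the lowest index."""
        p = self.probs[clade]
        return int(np.flatnonzero(p == p.max())[0])

    def argmax_label(self, clade: frozenset) -> str:
        return self.states[self.argmax(clade)]


def asr_marginal(
    tree: dendropy.Tree,
    chars: CharacterMatrix,
    model: MkModelSpec,
    theta: Sequence[float],
    root_mode: str = "weighted",
) -> ASRResult:
    """Marginal (proportion-of-likelihood) state probabilities per node.

    Standard two-pass algorithm: tipward partials D from pruning, rootward
    partials U from a preorder sweep, marginal at a node proportional to
    D * U.  Under the weighted and flat root treatments the root marginal is
    the normalized root likelihood profile; under ``fixed:<state>`` the root
    gets probability one on that state and the constraint propagates to all
    other nodes through the rootward pass.
    """
    mode, fixed = _parse_root_mode(root_mode, chars.states)
    Q = model.build_q(theta)
    ti = linearize(tree)
    n = chars.n_states
    D, logscale, P = _mk_partials(ti, chars, Q)
    if not math.isfinite(logscale):
        raise ValueError("zero likelihood: cannot compute marginals")

    # rootward pass: U[i](s) = likelihood of everything outside the subtree
    # of node i, given state s at node i (root prior included)
    U = np.empty((ti.n_nodes, n))
    if mode == "fixed":
        prior = np.zeros(n)
        prior[fixed] = 1.0
    else:
        prior = np.full(n, 1.0 / n)
    U[ti.root] = prior
    for i in range(ti.n_nodes - 1, -1, -1):
        kids = ti.children[i]
        if not kids:
            continue
        msgs = {c: P[c] @ D[c] for c in kids}
        for c in kids:
            above = U[i].copy()
            for s in kids:
                if s != c:
                    above = above * msgs[s]
            U[c] = P[c].T @ above
            m = U[c].max()
            if m > 0:
                U[c] /= m

    probs: dict[frozenset, np.ndarray] = {}
    ties: list[frozenset] = []
    for i in range(ti.n_nodes):
        if not ti.children[i]:
            continue
        v = D[i] * U[i]
        total = v.sum()
        if total <= 0:
            raise ValueError("zero marginal at an internal node")
        p = v / total
        clade = ti.clades[i]
        probs[clade] = p
        if np.sum(p == p.max()) > 1:
            ties.append(clade)
    return ASRResult(tuple(chars.states), probs, root_mode, ties)


def tally_transitions(
    tree: dendropy.Tree, chars: CharacterMatrix, asr: ASRResult
) -> tuple[int, dict[tuple[str, str], int]]:
    """Count state changes along branches under the best-state assignment.

    Internal nodes take their marginal-ASR argmax state (ties resolved to
    the lowest state index); tips keep their observed states.  Edges leading
    to missing-data tips are excluded.  Returns the total number of changes
    and counts per ordered (from, to) state pair.
    """
    ti = linearize(tree)
    states = asr.states
    node_state: dict[int, Optional[int]] = {}
    for i in range(ti.n_nodes):
        if ti.children[i]:
            node_state[i] = asr.argmax(ti.clades[i])
        else:
            node_state[i] = chars.state_index(ti.tip_label[i])

    total = 0
    pairs: dict[tuple[str, str], int] = {}
    for i in range(ti.n_nodes):
        for c in ti.children[i]:
            a, b = node_state[i], node_state[c]
            if a is None or b is None:
                continue
            if a != b:
                total += 1
                key = (states[a], states[b])
                pairs[key] = pairs.get(key, 0) + 1
    return total, pairs
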