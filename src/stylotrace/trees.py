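"""Tree I/O, validation and manipulation on top of dendropy.

Trees are plain :class:`dendropy.Tree` objects (rooted, branch lengths in
relative-time units); tree samples are :class:`dendropy.TreeList` objects
over a shared taxon namespace.  This module adds the validation, pruning,
rescaling and maximum-clade-credibility summarisation used downstream.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
from dendropy.utility.error import DataParseError

log = logging.getLogger(__name__)

DEFAULT_ULTRAMETRIC_TOL = 1e-6


# ---------------------------------------------------------------------------
# reading / writing


def _infer_schema(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".nex", ".nexus", ".trees", ".t"}:
        return "nexus"
    return "newick"


def read_trees(
    path: str | Path,
    schema: Optional[str] = None,
    require_same_taxa: bool = True,
) -> dendropy.TreeList:
    """Read all trees from a Newick or NEXUS file, in file order.

    NEXUS translate tables and quoted labels are handled by dendropy.
    Underscores in unquoted labels are preserved verbatim.  Duplicate tip
    labels within a tree, or (if ``require_same_taxa``) differing leaf sets
    across trees, raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = schema or _infer_schema(path)
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema=schema,
            rooting="default-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except DataParseError as err:
        if "duplicate" in str(err).lower():
            raise ValueError(f"duplicate tip label in {path}: {err}") from err
        raise
    if len(trees) == 0:
        raise ValueError(f"no trees found in {path}")
    ref = None
    for i, t in enumerate(trees):
        labels = tip_labels(t)
        if len(labels) != len(set(labels)):
            raise ValueError(f"duplicate tip label in tree {i} of {path}")
        if require_same_taxa:
            if ref is None:
                ref = set(labels)
            elif set(labels) != ref:
                raise ValueError(f"tree {i} of {path} has a different leaf set")
        if len(t.seed_node.child_nodes()) > 2:
            # basal polytomy: keep, but flag the synthetic root so rooted
            # analyses can refuse it while concordance ignores rooting
            t.annotations.add_new("unrooted_origin", "true")
    return trees


def trees_from_string(s: str, schema: str = "newick") -> dendropy.TreeList:
    """Parse one or more trees from a string (see :func:`read_trees`)."""
    trees = dendropy.TreeList.get(
        data=s,
        schema=schema,
        rooting="default-rooted",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if len(trees) == 0:
        raise ValueError("no trees parsed")
    return trees


def tree_from_string(s: str, schema: str = "newick") -> dendropy.Tree:
    return trees_from_string(s, schema=schema)[0]


def write_trees(
    trees: Iterable[dendropy.Tree] | dendropy.TreeList,
    path: str | Path,
    schema: Optional[str] = None,
) -> None:
    """Write trees to Newick or NEXUS (schema inferred from extension)."""
    path = Path(path)
    schema = schema or _infer_schema(path)
    if isinstance(trees, dendropy.TreeList):
        tl = trees
    else:
        trees = list(trees)
        tl = dendropy.TreeList(taxon_namespace=trees[0].taxon_namespace)
        tl.extend(trees)
    tl.write(path=str(path), schema=schema, unquoted_underscores=True)


# ---------------------------------------------------------------------------
# basic queries


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Distance from the root to each node."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    return depths


def node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Age of each node = maximum path length to a descendant tip."""
    ages: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            ages[node] = max(ages[c] + (c.edge.length or 0.0) for c in node.child_nodes())
    return ages


def root_height(tree: dendropy.Tree) -> float:
    depths = node_depths(tree)
    return max(d for n, d in depths.items() if n.is_leaf())


def check_ultrametric(tree: dendropy.Tree, tol: float = DEFAULT_ULTRAMETRIC_TOL) -> bool:
    """True iff all root-to-tip path lengths agree within ``tol``."""
    depths = node_depths(tree)
    tip_d = [d for n, d in depths.items() if n.is_leaf()]
    return (max(tip_d) - min(tip_d)) <= tol


def validate_tree(tree: dendropy.Tree) -> None:
    """Raise ``ValueError`` on duplicate tips or negative/non-finite lengths."""
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            continue
        if not math.isfinite(edge.length) or edge.length < 0:
            raise ValueError(f"invalid branch length {edge.length}")


# ---------------------------------------------------------------------------
# manipulation


def prune_taxa(tree: dendropy.Tree, drop: Iterable[str]) -> dendropy.Tree:
    """Remove tips, suppressing unifurcations with branch lengths summed.

    Path lengths among the retained tips are conserved, so ultrametricity is
    preserved.  Dropping down to fewer than two tips is an error.
    """
    drop = set(drop)
    if not drop:
        return tree.clone(depth=1)
    tips = set(tip_labels(tree))
    unknown = drop - tips
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if len(tips - drop) < 2:
        raise ValueError("pruning would leave fewer than two tips")
    out = tree.clone(depth=1)
    out.prune_taxa_with_labels(list(drop), suppress_unifurcations=True)
    # a leftover root unifurcation keeps its child edge; collapse it so the
    # old internal node becomes the root
    while len(out.seed_node.child_nodes()) == 1:
        child = out.seed_node.child_nodes()[0]
        out.seed_node = child
        child.parent_node = None
    out.seed_node.edge.length = None
    return out


def rescale_root_height(tree: dendropy.Tree, height: float) -> dendropy.Tree:
    """Linearly rescale an ultrametric tree to the given root height."""
    if height <= 0:
        raise ValueError("target height must be positive")
    h = root_height(tree)
    if not check_ultrametric(tree, tol=max(DEFAULT_ULTRAMETRIC_TOL, 1e-6 * h)):
        raise ValueError("tree is not ultrametric")
    factor = height / h
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return out


# ---------------------------------------------------------------------------
# maximum clade credibility summarisation


def _clades(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset]:
    """Leaf-label set below each internal node (including the root)."""
    below: dict[dendropy.Node, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            s: frozenset = frozenset()
            for c in node.child_nodes():
                s = s | below[c]
            below[node] = s
    return below


def _topology_key(clades: Iterable[frozenset]) -> tuple:
    return tuple(sorted(tuple(sorted(c)) for c in clades))


def summarize_mcc(sample: dendropy.TreeList | Sequence[dendropy.Tree]) -> dendropy.Tree:
    """Maximum clade credibility tree with per-clade median node heights.

    The candidate set is the sample itself: the returned topology is the
    sample tree maximising the product of clade frequencies (ties broken by a
    canonical topology ordering so the result is independent of sample
    order).  Each internal node's height is then replaced by the median age
    of its clade across the trees that contain it; a child ending up older
    than its parent is clamped to the parent's height (zero-length branch)
    and logged.
    """
    sample = list(sample)
    if not sample:
        raise ValueError("empty tree sample")

    freq: dict[frozenset, int] = {}
    ages_by_clade: dict[frozenset, list[float]] = {}
    per_tree_clades: list[dict[dendropy.Node, frozenset]] = []
    for tree in sample:
        below = _clades(tree)
        ages = node_ages(tree)
        per_tree_clades.append(below)
        for node, clade in below.items():
            if node.is_leaf():
                continue
            freq[clade] = freq.get(clade, 0) + 1
            ages_by_clade.setdefault(clade, []).append(ages[node])

    n = len(sample)
    best_i, best_score, best_key = 0, -math.inf, None
    for i, tree in enumerate(sample):
        internal = [c for node, c in per_tree_clades[i].items() if not node.is_leaf()]
        score = sum(math.log(freq[c] / n) for c in internal)
        key = _topology_key(internal)
        if score > best_score or (score == best_score and (best_key is None or key < best_key)):
            best_i, best_score, best_key = i, score, key

    out = sample[best_i].clone(depth=1)
    below = _clades(out)
    target: dict[dendropy.Node, float] = {}
    for node in out.preorder_node_iter():
        if node.is_leaf():
            target[node] = 0.0
            continue
        med = float(np.median(ages_by_clade[below[node]]))
        if node.parent_node is not None and med > target[node.parent_node]:
            log.warning(
                "MCC: clamping node height %.6g to parent height %.6g (clade size %d)",
                med, target[node.parent_node], len(below[node]),
            )
            med = target[node.parent_node]
        target[node] = med
    for node in out.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = target[node.parent_node] - target[node]
    validate_tree(out)
    return out
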