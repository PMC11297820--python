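"""Gene-tree/species-tree concordance statistics and locus selection.

Covers the quantities used to audit a target-capture phylogenomic dataset:
Robinson-Foulds distances, exact normalized quartet scores, per-clade gene
tree support (gts), "gene shopping" (selecting the loci whose gene trees are
topologically closest to the species tree), alignment occupancy accounting,
and heterozygosity/recovery quality-control filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .trees import tip_labels

GAP_CHARS = set("-?")


# ---------------------------------------------------------------------------
# topology utilities


def collapse_short_branches(tree: dendropy.Tree, tol: float = 1e-6) -> dendropy.Tree:
    """Contract internal branches with length <= tol into polytomies.

    Tip branches are never contracted.  Child branch lengths are increased by
    the collapsed length so tip-to-tip path lengths are conserved.
    """
    out = tree.clone(depth=1)
    for node in list(out.postorder_internal_node_iter()):
        if node.parent_node is None:
            continue
        length = node.edge.length or 0.0
        if length <= tol:
            parent = node.parent_node
            for child in list(node.child_nodes()):
                node.remove_child(child)
                parent.add_child(child)
                if child.edge.length is not None:
                    child.edge.length += length
            parent.remove_child(node)
    return out


def bipartitions(tree: dendropy.Tree, taxa: Optional[Iterable[str]] = None) -> set[frozenset]:
    """Non-trivial unrooted bipartitions, optionally restricted to a taxon set.

    Each bipartition is a frozenset of its two sides (frozensets of labels),
    so the representation is orientation-free.  Restriction can merge edges;
    duplicates are removed.
    """
    all_tips = set(tip_labels(tree))
    keep = all_tips if taxa is None else (all_tips & set(taxa))
    out: set[frozenset] = set()
    below: dict[dendropy.Node, set] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = {node.taxon.label} & keep
        else:
            below[node] = set().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        side = frozenset(below[node])
        other = frozenset(keep - side)
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree, normalized: bool = True) -> float:
    """Robinson-Foulds distance between two trees (treated as unrooted).

    Trees are first restricted to their shared tips.  The normalized form
    divides the symmetric-difference count by the total number of
    non-trivial bipartitions in both trees (the maximum possible distance).
    """
    shared = set(tip_labels(t1)) & set(tip_labels(t2))
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared tips; need at least 4")
    b1 = bipartitions(t1, shared)
    b2 = bipartitions(t2, shared)
    raw = len(b1 ^ b2)
    if not normalized:
        return float(raw)
    denom = len(b1) + len(b2)
    return raw / denom if denom else 0.0


def clade_support(
    gene_trees: Sequence[dendropy.Tree],
    clade: Iterable[str],
    all_taxa: Iterable[str],
) -> float:
    """Percent of evaluable gene trees containing a clade's bipartition (gts).

    Each gene tree is restricted to its own sampled taxa; it is evaluable if
    at least two taxa remain on each side of the bipartition.  Branch lengths
    and rooting play no role.
    """
    clade = frozenset(clade)
    all_taxa = frozenset(all_taxa)
    if not clade or not clade < all_taxa:
        raise ValueError("clade must be a nonempty proper subset of the taxon set")
    n_eval = 0
    n_hit = 0
    for tree in gene_trees:
        taxa_t = frozenset(tip_labels(tree))
        side1 = clade & taxa_t
        side2 = (all_taxa - clade) & taxa_t
        if len(side1) < 2 or len(side2) < 2:
            continue
        n_eval += 1
        if frozenset((side1, side2)) in bipartitions(tree):
            n_hit += 1
    if n_eval == 0:
        raise ValueError("no evaluable gene trees for this clade")
    return 100.0 * n_hit / n_eval


# ---------------------------------------------------------------------------
# quartet score


def _topological_distances(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Tip labels and pairwise path lengths counting every edge as 1."""
    adj: dict[dendropy.Node, list[dendropy.Node]] = {}
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            adj.setdefault(node, []).append(child)
            adj.setdefault(child, []).append(node)
    leaves = [n for n in tree.leaf_node_iter()]
    labels = [n.taxon.label for n in leaves]
    index = {id(n): i for i, n in enumerate(leaves)}
    k = len(leaves)
    D = np.zeros((k, k))
    for i, src in enumerate(leaves):
        dist = {id(src): 0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb in adj.get(node, []):
                if id(nb) not in dist:
                    dist[id(nb)] = dist[id(node)] + 1
                    stack.append(nb)
        for leaf in leaves:
            D[i, index[id(leaf)]] = dist[id(leaf)]
    return labels, D


def _quartet_splits(D: np.ndarray, quartets: np.ndarray) -> np.ndarray:
    """Induced split of each quartet from a tree metric.

    Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc, -1 for unresolved, using
    the four-point condition: the pairing with the strictly smallest
    distance sum is the split of the induced quartet tree.
    """
    a, b, c, d = quartets.T
    sums = np.stack(
        [D[a, b] + D[c, d], D[a, c] + D[b, d], D[a, d] + D[b, c]], axis=1
    )
    order = np.argsort(sums, axis=1)
    smallest = np.take_along_axis(sums, order[:, :1], axis=1)[:, 0]
    second = np.take_along_axis(sums, order[:, 1:2], axis=1)[:, 0]
    split = order[:, 0].astype(np.int64)
    split[second <= smallest] = -1  # tie: polytomy, unresolved
    return split


def quartet_score(
    species_tree: dendropy.Tree, gene_trees: Sequence[dendropy.Tree]
) -> float:
    """Exact normalized quartet score of a species tree against gene trees.

    The fraction of (gene tree, resolved quartet) pairs whose induced
    four-taxon topology matches the species tree's.  Quartets left
    unresolved by a polytomy in a gene tree are excluded from both numerator
    and denominator; all four-taxon subsets are enumerated exactly.
    """
    sp_labels, sp_D = _topological_distances(species_tree)
    sp_index = {lab: i for i, lab in enumerate(sp_labels)}
    n_match = 0
    n_eval = 0
    for gt in gene_trees:
        labels, D = _topological_distances(gt)
        shared = [lab for lab in labels if lab in sp_index]
        if len(shared) < 4:
            continue
        gt_index = {lab: i for i, lab in enumerate(labels)}
        quartets = np.array(list(combinations(range(len(shared)), 4)), dtype=np.int64)
        g_ids = np.array([gt_index[lab] for lab in shared], dtype=np.int64)
        s_ids = np.array([sp_index[lab] for lab in shared], dtype=np.int64)
        g_split = _quartet_splits(D, g_ids[quartets])
        s_split = _quartet_splits(sp_D, s_ids[quartets])
        resolved = (g_split >= 0) & (s_split >= 0)
        n_eval += int(resolved.sum())
        n_match += int((resolved & (g_split == s_split)).sum())
    if n_eval == 0:
        raise ValueError("no informative quartets")
    return n_match / n_eval


# ---------------------------------------------------------------------------
# gene shopping


@dataclass
class GeneShopResult:
    selected: list[str]
    rf_by_locus: dict[str, float]
    warning: bool = False  # fewer qualifying loci than requested


def gene_shop(
    gene_trees: Mapping[str, dendropy.Tree],
    species_tree: dendropy.Tree,
    occupancy: Mapping[str, Iterable[str]],
    k: int = 12,
    rf_cutoff: float = 0.15,
) -> GeneShopResult:
    """Select loci for branch-length estimation ("gene shopping").

    Restricts to loci with full taxon sampling, computes each gene tree's
    normalized RF distance to the species tree, keeps loci with RF strictly
    below the cutoff, and returns the ``k`` smallest (ties broken by locus id
    ascending).  If fewer than ``k`` qualify, all are returned with a
    warning flag.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    master = set(tip_labels(species_tree))
    rf_by_locus: dict[str, float] = {}
    for locus, tree in gene_trees.items():
        if set(occupancy.get(locus, ())) != master:
            continue
        rf_by_locus[locus] = rf_distance(tree, species_tree, normalized=True)
    qualifying = sorted(
        (locus for locus, rf in rf_by_locus.items() if rf < rf_cutoff),
        key=lambda locus: (rf_by_locus[locus], locus),
    )
    if len(qualifying) < k:
        return GeneShopResult(qualifying, rf_by_locus, warning=True)
    return GeneShopResult(qualifying[:k], rf_by_locus)


# ---------------------------------------------------------------------------
# occupancy


@dataclass
class OccupancyReport:
    n_loci: int
    n_taxa: int
    sequence_count: int
    occupancy: float
    bases_per_taxon: dict[str, int]

    @property
    def median_bases(self) -> float:
        return float(np.median(list(self.bases_per_taxon.values())))

    @property
    def bases_range(self) -> tuple[int, int]:
        vals = list(self.bases_per_taxon.values())
        return (min(vals), max(vals))


def read_alignments(paths: Iterable[str | Path]) -> dict[str, dict[str, str]]:
    """Read FASTA alignments, keyed by locus id = filename stem."""
    out: dict[str, dict[str, str]] = {}
    for p in paths:
        p = Path(p)
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(p), "fasta")}
        if seqs:
            lengths = {len(s) for s in seqs.values()}
            if len(lengths) > 1:
                raise ValueError(f"unequal sequence lengths in {p}")
            out[p.stem] = seqs
    return out


def occupancy_stats(
    alignments: Mapping[str, Mapping[str, str]], taxa: Sequence[str]
) -> OccupancyReport:
    """Species-by-genes matrix occupancy and per-taxon recovered bases."""
    taxa = list(taxa)
    n_loci = len(alignments)
    count = 0
    bases = {t: 0 for t in taxa}
    for seqs in alignments.values():
        for taxon in taxa:
            seq = seqs.get(taxon)
            if seq is None:
                continue
            count += 1
            bases[taxon] += sum(1 for ch in seq if ch not in GAP_CHARS)
    occ = count / (n_loci * len(taxa)) if n_loci and taxa else 0.0
    return OccupancyReport(n_loci, len(taxa), count, occ, bases)


# ---------------------------------------------------------------------------
# QC filtering


@dataclass
class QCTable:
    """Per-(locus, sample) heterozygosity and recovery table.

    ``table`` columns: locus, sample, het_pct, recovered (bool/0-1).  A
    locus/sample pair absent from the table counts as not recovered.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"locus", "sample", "het_pct", "recovered"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"QC table missing columns: {sorted(missing)}")
        bad = self.table["het_pct"].dropna()
        if ((bad < 0) | (bad > 100)).any():
            raise ValueError("het_pct outside [0, 100]")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "QCTable":
        return cls(pd.read_csv(path, sep="\t"))

    def loci_per_sample(self) -> pd.Series:
        rec = self.table[self.table["recovered"].astype(bool)]
        return rec.groupby("sample")["locus"].nunique()

    def samples_per_locus(self) -> pd.Series:
        rec = self.table[self.table["recovered"].astype(bool)]
        return rec.groupby("locus")["sample"].nunique()


@dataclass
class QCFilterResult:
    kept_loci: list[str]
    kept_samples: list[str]
    exclusions: list[dict] = field(default_factory=list)


def qc_filter(
    qc: QCTable,
    het_cutoff: float = 3.0,
    min_loci_per_sample: int = 50,
    min_fraction_samples_per_locus: float = 1.0 / 3.0,
) -> QCFilterResult:
    """Apply the study's quality-control thresholds in narrative order.

    1. drop samples with fewer than ``min_loci_per_sample`` recovered loci;
    2. drop loci whose mean heterozygous-site percentage (across remaining
       samples in which they were recovered) exceeds ``het_cutoff``;
    3. drop loci recovered in less than ``min_fraction_samples_per_locus``
       of the remaining samples.

    Every exclusion is logged with the rule that triggered it.
    """
    df = qc.table.copy()
    df["recovered"] = df["recovered"].astype(bool)
    exclusions: list[dict] = []

    per_sample = df[df["recovered"]].groupby("sample")["locus"].nunique()
    all_samples = sorted(df["sample"].unique())
    kept_samples = []
    for s in all_samples:
        n = int(per_sample.get(s, 0))
        if n < min_loci_per_sample:
            exclusions.append(
                {"item": s, "kind": "sample", "rule": "min_loci_per_sample", "value": n}
            )
        else:
            kept_samples.append(s)

    df = df[df["sample"].isin(kept_samples)]
    all_loci = sorted(df["locus"].unique())
    rec = df[df["recovered"]]
    mean_het = rec.groupby("locus")["het_pct"].mean()
    kept_loci = []
    for locus in all_loci:
        h = float(mean_het.get(locus, 0.0))
        if h > het_cutoff:
            exclusions.append(
                {"item": locus, "kind": "locus", "rule": "het_cutoff", "value": h}
            )
        else:
            kept_loci.append(locus)

    n_samples = len(kept_samples)
    per_locus = rec.groupby("locus")["sample"].nunique()
    final_loci = []
    for locus in kept_loci:
        frac = float(per_locus.get(locus, 0)) / n_samples if n_samples else 0.0
        if frac < min_fraction_samples_per_locus:
            exclusions.append(
                {"item": locus, "kind": "locus", "rule": "min_fraction_samples", "value": frac}
            )
        else:
            final_loci.append(locus)

    if not final_loci or not kept_samples:
        raise ValueError("QC filtering removed everything")
    return QCFilterResult(final_loci, kept_samples, exclusions)
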