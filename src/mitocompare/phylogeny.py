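"""Concatenated-gene distance phylogeny: K2P matrix, neighbor joining,
column-resampling bootstrap, and newick round-tripping.

Neighbor joining follows Saitou & Nei's Q-criterion agglomeration and is
exact on additive distance matrices.  Tie-breaking is deterministic
(lexicographically smallest index pair in the current matrix) so a given
matrix always yields byte-identical trees.  Negative branch lengths are
clamped to zero and the clamped deficit is tracked on the tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import dendropy
import numpy as np

from .divergence import GeneAlignment, k2p_distance

logger = logging.getLogger("mitocompare")


@dataclass
class ConcatenatedAlignment:
    """Gene alignments joined end to end, with a 1-based partition map."""

    taxa: list[str]
    sequences: dict[str, str]
    partitions: dict[str, tuple[int, int]]

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def as_alignment(self, name: str = "concatenated") -> GeneAlignment:
        return GeneAlignment(name, dict(self.sequences))


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray              # symmetric, zero diagonal
    saturated_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class TreeNode:
    """One node of an (unrooted, trifurcating-root) phylogeny."""

    name: Optional[str] = None          # leaf taxon label
    length: float = 0.0                 # branch to parent, subs/site
    support: Optional[float] = None     # bootstrap %, internal nodes only
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]


@dataclass
class PhyloTree:
    root: TreeNode
    clamped_deficit: float = 0.0        # total negative length clamped away
    effective_replicates: Optional[int] = None

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-side leaf set
        (canonicalized against the full taxon set)."""
        all_taxa = frozenset(self.leaf_names())
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode):
            names = frozenset(node.leaf_names())
            if 1 < len(names) < len(all_taxa) - 1:
                other = all_taxa - names
                parts.add(min(names, other, key=lambda s: (len(s), sorted(s))))
            for c in node.children:
                walk(c)

        for child in self.root.children:
            walk(child)
        return parts


# ---------------------------------------------------------------------------
# concatenation and distances
# ---------------------------------------------------------------------------

def concatenate(gene_alignments: dict[str, GeneAlignment],
                gene_order: Sequence[str],
                pad_missing: bool = False) -> ConcatenatedAlignment:
    """Join per-gene alignments in ``gene_order``.

    Every alignment must cover the same taxon set unless ``pad_missing``
    fills absentees with gaps (flagged by a warning).
    """
    taxa: list[str] = sorted(
        {t for g in gene_order for t in gene_alignments[g].taxa})
    seqs = {t: [] for t in taxa}
    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for gene in gene_order:
        aln = gene_alignments[gene]
        missing = set(taxa) - set(aln.taxa)
        if missing and not pad_missing:
            raise ValueError(f"{gene}: missing taxa {sorted(missing)}")
        if missing:
            logger.warning("%s: padding %s with gaps", gene, sorted(missing))
        for t in taxa:
            seqs[t].append(aln.sequences.get(t, "-" * aln.length))
        partitions[gene] = (pos + 1, pos + aln.length)
        pos += aln.length
    return ConcatenatedAlignment(taxa=taxa,
                                 sequences={t: "".join(p) for t, p in seqs.items()},
                                 partitions=partitions)


def k2p_matrix(aln: GeneAlignment | ConcatenatedAlignment) -> DistanceMatrix:
    """Pairwise K2P distance matrix; saturated pairs flagged with NaN."""
    if isinstance(aln, ConcatenatedAlignment):
        aln = aln.as_alignment()
    taxa = aln.taxa
    n = len(taxa)
    m = np.zeros((n, n))
    saturated = []
    for i, j in combinations(range(n), 2):
        res = k2p_distance(aln.sequences[taxa[i]], aln.sequences[taxa[j]])
        if res.saturated:
            saturated.append((taxa[i], taxa[j]))
            m[i, j] = m[j, i] = math.nan
        else:
            m[i, j] = m[j, i] = res.d_k2p
    return DistanceMatrix(taxa=list(taxa), matrix=m, saturated_pairs=saturated)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    The returned tree is unrooted, represented with a trifurcating root.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    if dm.saturated_pairs or np.isnan(dm.matrix).any():
        raise ValueError("distance matrix contains saturated/NaN entries")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.matrix.astype(float).copy()
    deficit = 0.0

    def clamp(x: float) -> float:
        nonlocal deficit
        if x < 0:
            deficit += -x
            logger.debug("clamped negative branch length %.3g", x)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best, best_q = None, math.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:       # strict improvement
                    best_q, best = q, (i, j)
                # ties resolved by the earlier (i, j) in lexicographic order
        i, j = best
        li = clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))))
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        new = TreeNode(children=[ni, nj])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        for a, ka in enumerate(keep):
            for b, kb in enumerate(keep):
                new_d[a, b] = d[ka, kb]
        for a, ka in enumerate(keep):
            v = 0.5 * (d[i, ka] + d[j, ka] - d[i, j])
            new_d[a, m - 2] = new_d[m - 2, a] = v
        nodes = [nodes[k] for k in keep] + [new]
        d = new_d

    # three-point closed form for the final trifurcation
    a, b, c = nodes
    da = clamp(0.5 * (d[0, 1] + d[0, 2] - d[1, 2]))
    db = clamp(0.5 * (d[0, 1] + d[1, 2] - d[0, 2]))
    dc = clamp(0.5 * (d[0, 2] + d[1, 2] - d[0, 1]))
    a.length, b.length, c.length = da, db, dc
    return PhyloTree(root=TreeNode(children=[a, b, c]),
                     clamped_deficit=deficit)


def nj_tree(aln: GeneAlignment | ConcatenatedAlignment) -> PhyloTree:
    """Convenience: K2P matrix then neighbor joining."""
    return neighbor_joining(k2p_matrix(aln))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(concat: ConcatenatedAlignment, n_reps: int,
                      seed: int) -> PhyloTree:
    """Column-resampling bootstrap support for the full-data NJ tree.

    Support on each internal node = percentage of replicates whose NJ tree
    contains that node's bipartition.  Replicates whose resampled matrix has
    a saturated pair are dropped (logged); the effective replicate count is
    recorded on the tree.  Degenerate input (all sequences identical) leaves
    supports None.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    dm = k2p_matrix(concat)
    full = neighbor_joining(dm)
    if np.allclose(dm.matrix, 0.0):
        # identical sequences: the topology is arbitrary, supports undefined
        logger.warning("degenerate alignment (no variation); supports undefined")
        full.effective_replicates = 0
        return full
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    arrays = {t: np.frombuffer(s.encode(), dtype=np.uint8)
              for t, s in concat.sequences.items()}
    length = concat.length
    effective = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep = ConcatenatedAlignment(
            taxa=concat.taxa,
            sequences={t: arrays[t][cols].tobytes().decode()
                       for t in concat.taxa},
            partitions={"resampled": (1, length)})
        try:
            rep_tree = nj_tree(rep)
        except ValueError:
            logger.warning("bootstrap replicate dropped (saturation/degeneracy)")
            continue
        effective += 1
        rep_bps = rep_tree.bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    if effective:
        all_taxa = frozenset(concat.taxa)

        def annotate(node: TreeNode):
            names = frozenset(node.leaf_names())
            if not node.is_leaf and 1 < len(names) < len(all_taxa) - 1:
                bp = min(names, all_taxa - names,
                         key=lambda s: (len(s), sorted(s)))
                node.support = 100.0 * counts[bp] / effective
            for c in node.children:
                annotate(c)

        for child in full.root.children:
            annotate(child)
    else:
        logger.warning("no effective bootstrap replicates; supports undefined")
    full.effective_replicates = effective
    return full


# ---------------------------------------------------------------------------
# rooting and newick I/O
# ---------------------------------------------------------------------------

def root_with_outgroup(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Presentation-only rooting: rotate children so the outgroup is first."""
    kids = tree.root.children
    for idx, child in enumerate(kids):
        if outgroup in child.leaf_names():
            tree.root.children = [kids[idx]] + kids[:idx] + kids[idx + 1:]
            return tree
    raise ValueError(f"outgroup {outgroup!r} not in tree")


def _node_newick(node: TreeNode, precision: int) -> str:
    if node.is_leaf:
        return f"{node.name}:{node.length:.{precision}f}"
    inner = ",".join(_node_newick(c, precision) for c in node.children)
    label = "" if node.support is None else f"{node.support:g}"
    return f"({inner}){label}:{node.length:.{precision}f}"


def tree_to_newick(tree: PhyloTree, precision: int = 6) -> str:
    inner = ",".join(_node_newick(c, precision) for c in tree.root.children)
    return f"({inner});"


def write_newick(tree: PhyloTree, path, precision: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree, precision) + "\n")


def _from_dendropy(dnode) -> TreeNode:
    node = TreeNode()
    if dnode.is_leaf():
        node.name = dnode.taxon.label if dnode.taxon else dnode.label
    elif dnode.label is not None:
        try:
            node.support = float(dnode.label)
        except ValueError:
            node.name = dnode.label
    node.length = dnode.edge.length or 0.0
    for child in dnode.child_nodes():
        node.children.append(_from_dendropy(child))
    return node


def newick_to_tree(newick: str) -> PhyloTree:
    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    root = _from_dendropy(dtree.seed_node)
    root.length = 0.0
    return PhyloTree(root=root)


def read_newick(path) -> PhyloTree:
    with open(path) as fh:
        return newick_to_tree(fh.read())


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    """PHYLIP-style square matrix, tab separated."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.taxa)}\n")
        for i, t in enumerate(dm.taxa):
            row = "\t".join(f"{dm.matrix[i, j]:.6f}" for j in range(len(dm.taxa)))
            fh.write(f"{t}\t{row}\n")
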