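"""Distance-based phylogenetics for numt/mitochondrial homolog sets.

Provides Tajima-Nei (1984) pairwise distances (robust to unequal base
frequencies), Saitou-Nei neighbour joining, Newick round-tripping (parsing
delegated to dendropy), and partitioning of branches into the "numt clade"
versus the mitochondrial background — the branch classification consumed by
the codon selection models.

Branch classes are encoded in Newick as a ``#numt`` suffix on node labels,
e.g. ``(seal_numt#numt:0.01, seal_mt:0.2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "TreeNode",
    "DistanceMatrix",
    "tajima_nei",
    "distance_matrix",
    "neighbor_joining",
    "label_numt_clade",
    "parse_newick",
    "write_newick",
]

NUMT = "numt"
BACKGROUND = "background"


class SaturationError(ValueError):
    """Distance undefined because observed divergence exceeds the model ceiling."""


@dataclass
class TreeNode:
    """A rooted (possibly trifurcating-root) tree node with a branch above it."""

    name: str = ""
    length: float = 0.0
    branch_class: str = BACKGROUND
    children: list = field(default_factory=list)
    parent: "TreeNode | None" = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self):
        return [n.name for n in self.leaves()]

    def branches(self):
        """All non-root nodes (each carries the branch to its parent)."""
        return [n for n in self.postorder() if n.parent is not None]

    def copy(self) -> "TreeNode":
        node = TreeNode(self.name, self.length, self.branch_class)
        for c in self.children:
            node.add(c.copy())
        return node

    def __repr__(self):
        return f"TreeNode({write_newick(self)})"


# ---------------------------------------------------------------------------
# distances


def tajima_nei(seq_a: str, seq_b: str) -> float:
    """Tajima-Nei (1984) distance between two aligned sequences.

    d = -b ln(1 - p/b) with b = (1 - sum_i g_i^2 + p^2/h) / 2 and
    h = sum_{i<j} x_ij^2 / (2 g_i g_j), where g_i are base frequencies pooled
    over both sequences and x_ij the relative frequencies of mismatched base
    pairs.  Columns containing a gap or N in either sequence are skipped
    (pairwise deletion).  Reduces to Jukes-Cantor under equal frequencies.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    bases = "ACGT"
    counts = {x: 0 for x in bases}
    pair_counts: dict = {}
    n = 0
    diffs = 0
    for x, y in zip(a, b):
        if x not in bases or y not in bases:
            continue
        n += 1
        counts[x] += 1
        counts[y] += 1
        if x != y:
            diffs += 1
            key = tuple(sorted((x, y)))
            pair_counts[key] = pair_counts.get(key, 0) + 1
    if n == 0:
        raise ValueError("no comparable (gap-free, unambiguous) columns")
    if diffs == 0:
        return 0.0
    p = diffs / n
    g = {x: counts[x] / (2 * n) for x in bases}
    h = 0.0
    for (x, y), c in pair_counts.items():
        x_ij = c / n
        h += x_ij * x_ij / (2.0 * g[x] * g[y])
    bb = 0.5 * (1.0 - sum(v * v for v in g.values()) + p * p / h)
    if p >= bb:
        raise SaturationError(
            f"saturated pair (p={p:.3f} >= b={bb:.3f}); distance undefined"
        )
    return -bb * math.log(1.0 - p / bb)


@dataclass
class DistanceMatrix:
    taxa: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        k = len(self.taxa)
        if self.d.shape != (k, k):
            raise ValueError("matrix shape must match taxa")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.isfinite(self.d).all():
            raise ValueError("distances must be finite")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def __len__(self):
        return len(self.taxa)


def distance_matrix(names, seqs, metric=tajima_nei) -> DistanceMatrix:
    """Pairwise distance matrix over aligned sequences (Tajima-Nei default)."""
    k = len(names)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d[i, j] = d[j, i] = metric(seqs[i], seqs[j])
    return DistanceMatrix(list(names), d)


# ---------------------------------------------------------------------------
# neighbour joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining; returns an unrooted tree with a
    trifurcating root.

    Deterministic: ties in the Q criterion are broken by the lowest index
    pair.  Negative branch-length estimates are clamped to zero with the
    deficit moved to the sister branch, preserving path lengths.
    """
    if len(dm) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    nodes = [TreeNode(name=t) for t in dm.taxa]
    active = list(range(len(nodes)))
    D = dm.d.astype(float).copy()
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index pair among minima (deterministic tie-break)
        idx = np.argwhere(np.isclose(q, q.min(), rtol=0, atol=1e-12))
        ai, aj = sorted(map(int, idx[np.lexsort((idx[:, 1], idx[:, 0]))][0]))
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        # negative-length policy: clamp, move deficit to sister
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.add(nodes[i])
        parent.add(nodes[j])
        # distances from the new node to every other active node
        new_row = np.zeros(D.shape[0] + 1)
        for ak in range(m):
            k = active[ak]
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        new_index = len(nodes) - 1
        active = [k for k in active if k not in (i, j)] + [new_index]

    # join the last two nodes: the survivor's internal node becomes the
    # (trifurcating) root and the remaining distance one branch
    i, j = active
    if not nodes[j].is_leaf:
        root, other = nodes[j], nodes[i]
    else:
        root, other = nodes[i], nodes[j]
    other.length = max(D[i, j], 0.0)
    root.add(other)
    root.parent = None
    root.length = 0.0
    return root


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix (the additive metric of the tree)."""
    leaves = tree.leaves()
    names = [l.name for l in leaves]

    def path_to_root(node):
        out = []
        while node.parent is not None:
            out.append(node)
            node = node.parent
        return out

    k = len(leaves)
    d = np.zeros((k, k))
    paths = [path_to_root(l) for l in leaves]
    for i in range(k):
        for j in range(i + 1, k):
            pi = {id(n): n for n in paths[i]}
            shared = {id(n) for n in paths[j]} & set(pi)
            dist = sum(n.length for n in paths[i] if id(n) not in shared)
            dist += sum(n.length for n in paths[j] if id(n) not in shared)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# clade labelling


def label_numt_clade(tree: TreeNode, numt_taxa) -> TreeNode:
    """Label branches as numt-clade vs background on a copy of ``tree``.

    The numt taxa must form a clade in the unrooted sense (one edge separates
    them from everything else); the clade's internal branches and its stem
    are labelled ``numt``, all others ``background``.  Non-monophyletic sets
    raise a ValueError.
    """
    numt = set(numt_taxa)
    tree = tree.copy()
    all_leaves = set(tree.leaf_names())
    if not numt or not numt <= all_leaves:
        raise ValueError("numt taxa must be a non-empty subset of the leaves")

    for b in tree.branches():
        b.branch_class = BACKGROUND

    if numt == all_leaves:
        for b in tree.branches():
            b.branch_class = NUMT
        return tree

    leafset: dict = {}
    for node in tree.postorder():
        if node.is_leaf:
            leafset[id(node)] = frozenset([node.name])
        else:
            leafset[id(node)] = frozenset().union(
                *(leafset[id(c)] for c in node.children)
            )

    # direct clade: a node whose descendants are exactly the numt taxa
    for node in tree.postorder():
        if node.parent is not None and leafset[id(node)] == numt:
            for b in node.postorder():
                if b is not node:
                    b.branch_class = NUMT
            node.branch_class = NUMT  # stem
            return tree
    # complement clade (the clade wraps around the root in this rooting);
    # the subtree holding the background taxa keeps its branches, including
    # its own branch — the background side of the separating edge
    for node in tree.postorder():
        if node.parent is not None and leafset[id(node)] == all_leaves - numt:
            inside = {id(b) for b in node.postorder()}
            for b in tree.branches():
                if id(b) not in inside:
                    b.branch_class = NUMT
            return tree
    raise ValueError(f"numt taxa {sorted(numt)} are not monophyletic in this tree")


# ---------------------------------------------------------------------------
# Newick I/O


def _label(node: TreeNode) -> str:
    name = node.name or ""
    if node.branch_class == NUMT:
        name += "#numt"
    return name


def write_newick(tree: TreeNode, precision: int = 6) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            body = _label(node)
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")" + _label(node)
        if node.parent is not None:
            body += f":{node.length:.{precision}f}"
        return body

    return fmt(tree) + ";"


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (``#numt`` label suffixes become branch classes)."""
    dt = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)

    def convert(dnode) -> TreeNode:
        raw = ""
        if dnode.taxon is not None:
            raw = dnode.taxon.label or ""
        elif dnode.label:
            raw = dnode.label
        raw = raw.replace(" ", "_")
        cls = BACKGROUND
        if raw.endswith("#numt"):
            raw = raw[: -len("#numt")]
            cls = NUMT
        node = TreeNode(
            name=raw,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
            branch_class=cls,
        )
        for c in dnode.child_nodes():
            node.add(convert(c))
        return node

    root = convert(dt.seed_node)
    root.length = 0.0
    return root
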