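"""Distance-based tree building: UPGMA, neighbor joining, majority-rule consensus.

Trees are plain node hierarchies (:class:`TreeNode`) serializable to Newick.
UPGMA produces rooted ultrametric trees; NJ produces unrooted trees
represented with an arbitrary trifurcating root.  Tie-breaking in both
agglomerations is lexicographic on cluster labels so output is deterministic
across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TreeNode",
    "PhyloTree",
    "parse_newick",
    "format_newick",
    "upgma",
    "nj",
    "bipartitions",
    "majority_consensus",
]


@dataclass
class TreeNode:
    """A node in a phylogenetic tree.

    ``support`` is a percentage in (0, 100] attached to internal nodes by
    consensus/jackknife procedures; ``length`` is the branch length to the
    parent (``None`` when lengths are not meaningful, e.g. consensus trees).
    """

    name: Optional[str] = None
    length: Optional[float] = None
    support: Optional[float] = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        self.children.append(child)
        return child

    def traverse_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.traverse_preorder() if n.is_leaf()]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]


@dataclass
class PhyloTree:
    """A tree plus metadata about how it should be interpreted."""

    root: TreeNode
    rooted: bool = True

    @property
    def taxa(self) -> list[str]:
        return sorted(self.root.leaf_names())

    def to_newick(self) -> str:
        return format_newick(self.root)


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------

def _format_node(node: TreeNode) -> str:
    if node.is_leaf():
        label = _quote_label(node.name or "")
    else:
        inner = ",".join(_format_node(c) for c in node.children)
        if node.support is not None:
            sup = node.support
            label = f"({inner}){sup:g}"
        elif node.name:
            label = f"({inner}){_quote_label(node.name)}"
        else:
            label = f"({inner})"
    if node.length is not None:
        label += f":{node.length:.10g}"
    return label


def _quote_label(label: str) -> str:
    if any(c in label for c in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def format_newick(root: TreeNode) -> str:
    return _format_node(root) + ";"


class NewickError(ValueError):
    pass


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string.

    Numeric internal-node labels are interpreted as support values, which is
    how this package (and PHYLIP's CONSENSE) writes them.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(s) and s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(s):
                    raise NewickError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NewickError(f"unexpected character {s[pos]!r} at {pos}")
        label = _parse_label()
        if label:
            if node.children and _is_number(label):
                node.support = float(label)
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            pos += 1
            node.length = float(_parse_label())
        return node

    def _parse_label() -> str:
        nonlocal pos
        if pos < len(s) and s[pos] == "'":
            pos += 1
            out = []
            while pos < len(s):
                if s[pos] == "'":
                    if pos + 1 < len(s) and s[pos + 1] == "'":
                        out.append("'")
                        pos += 2
                        continue
                    pos += 1
                    break
                out.append(s[pos])
                pos += 1
            return "".join(out)
        start = pos
        while pos < len(s) and s[pos] not in "(),:;":
            pos += 1
        return s[start:pos].strip()

    root = parse_node()
    if pos != len(s):
        raise NewickError(f"trailing characters after position {pos}")
    return PhyloTree(root=root, rooted=len(root.children) == 2)


def _is_number(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Matrix validation helper
# ---------------------------------------------------------------------------

def _check_matrix(taxa: Iterable[str], values: np.ndarray) -> tuple[list[str], np.ndarray]:
    taxa = list(taxa)
    values = np.asarray(values, dtype=float)
    k = len(taxa)
    if values.shape != (k, k):
        raise ValueError(f"matrix shape {values.shape} does not match {k} taxa")
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    if (values < -1e-12).any():
        raise ValueError("distance matrix has negative entries")
    return taxa, values


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(matrix) -> PhyloTree:
    """Agglomerate a distance matrix into a rooted ultrametric tree.

    Cluster distances are arithmetic means weighted by cluster sizes; node
    heights are half the merge distance.  Among equally close pairs the pair
    with the lexicographically smallest (label, label) tuple merges first,
    where a cluster's label is its lexicographically smallest leaf.
    """
    taxa, d = _check_matrix(matrix.taxa, matrix.values)
    if len(taxa) < 2:
        raise ValueError("UPGMA needs at least 2 taxa")

    nodes = {i: TreeNode(name=t) for i, t in enumerate(taxa)}
    heights = {i: 0.0 for i in range(len(taxa))}
    sizes = {i: 1 for i in range(len(taxa))}
    labels = {i: t for i, t in enumerate(taxa)}
    dist = {(i, j): d[i, j] for i in range(len(taxa)) for j in range(i + 1, len(taxa))}
    active = set(range(len(taxa)))
    next_id = len(taxa)

    def pair_key(i: int, j: int):
        a, b = sorted((labels[i], labels[j]))
        return (dist[(min(i, j), max(i, j))], a, b)

    while len(active) > 1:
        best = min(
            ((i, j) for i in active for j in active if i < j),
            key=lambda ij: pair_key(*ij),
        )
        i, j = best
        h = dist[(i, j)] / 2.0
        parent = TreeNode()
        for child_id in (i, j):
            child = nodes[child_id]
            child.length = h - heights[child_id]
            parent.add_child(child)
        parent.children.sort(key=lambda c: min(c.leaf_names()))
        nodes[next_id] = parent
        heights[next_id] = h
        sizes[next_id] = sizes[i] + sizes[j]
        labels[next_id] = min(labels[i], labels[j])
        active -= {i, j}
        for k in active:
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            new = (sizes[i] * dist[a] + sizes[j] * dist[b]) / (sizes[i] + sizes[j])
            dist[(min(k, next_id), max(k, next_id))] = new
        active.add(next_id)
        next_id += 1

    return PhyloTree(root=nodes[next_id - 1], rooted=True)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj(matrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the standard Q criterion.

    Negative branch lengths are clamped to zero (with a warning), matching
    PHYLIP NEIGHBOR behaviour.  The returned tree is unrooted, represented
    with a trifurcating root.
    """
    taxa, d0 = _check_matrix(matrix.taxa, matrix.values)
    m = len(taxa)
    if m < 3:
        raise ValueError("NJ needs at least 3 taxa")

    nodes = {i: TreeNode(name=t) for i, t in enumerate(taxa)}
    labels = {i: t for i, t in enumerate(taxa)}
    dist = {(i, j): d0[i, j] for i in range(m) for j in range(i + 1, m)}
    active = list(range(m))
    next_id = m

    def get(i: int, j: int) -> float:
        return dist[(min(i, j), max(i, j))]

    def clamp(x: float) -> float:
        if x < 0:
            logger.warning("NJ produced negative branch length %.6g; clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        nA = len(active)
        best = None
        best_key = None
        for ai in range(nA):
            for aj in range(ai + 1, nA):
                i, j = active[ai], active[aj]
                q = (nA - 2) * get(i, j) - r[i] - r[j]
                a, b = sorted((labels[i], labels[j]))
                key = (q, a, b)
                if best_key is None or key < best_key:
                    best_key, best = key, (i, j)
        i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (nA - 2))
        lj = dij - li
        parent = TreeNode()
        nodes[i].length = clamp(li)
        nodes[j].length = clamp(lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.children.sort(key=lambda c: min(c.leaf_names()))
        nodes[next_id] = parent
        labels[next_id] = min(labels[i], labels[j])
        for k in active:
            if k in (i, j):
                continue
            new = 0.5 * (get(i, k) + get(j, k) - dij)
            dist[(min(k, next_id), max(k, next_id))] = new
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # resolve the final three clusters around a trifurcating root
    i, j, k = active
    dij, dik, djk = get(i, j), get(i, k), get(j, k)
    li = (dij + dik - djk) / 2
    lj = (dij + djk - dik) / 2
    lk = (dik + djk - dij) / 2
    root = TreeNode()
    for node_id, length in ((i, li), (j, lj), (k, lk)):
        nodes[node_id].length = clamp(length)
        root.add_child(nodes[node_id])
    root.children.sort(key=lambda c: min(c.leaf_names()))
    return PhyloTree(root=root, rooted=False)


# ---------------------------------------------------------------------------
# Bipartitions & consensus
# ---------------------------------------------------------------------------

def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Nontrivial bipartitions of a tree, canonicalized.

    Each split is represented by the side NOT containing the alphabetically
    first taxon; both sides must contain at least 2 taxa.
    """
    all_taxa = frozenset(tree.root.leaf_names())
    anchor = min(all_taxa)
    splits: set[frozenset] = set()

    def clade(node: TreeNode) -> frozenset:
        if node.is_leaf():
            return frozenset([node.name])
        below = frozenset().union(*(clade(c) for c in node.children))
        if node is not tree.root:
            side = below if anchor not in below else all_taxa - below
            if len(side) >= 2 and len(all_taxa - side) >= 2:
                splits.add(side)
        return below

    clade(tree.root)
    return splits


def majority_consensus(trees: list[PhyloTree], threshold: float = 0.5) -> PhyloTree:
    """Majority-rule consensus of replicate trees.

    Bipartitions occurring in strictly more than ``threshold`` of the input
    trees are retained (at threshold >= 0.5 they are mutually compatible, so
    no compatibility resolution is needed) and become internal nodes labeled
    with their percentage occurrence.  Branch lengths are not summarized.
    """
    if not trees:
        raise ValueError("no trees given")
    if threshold < 0.5:
        raise ValueError("threshold below 0.5 can yield incompatible splits")
    taxa = frozenset(trees[0].root.leaf_names())
    counts: dict[frozenset, int] = {}
    for t in trees:
        if frozenset(t.root.leaf_names()) != taxa:
            raise ValueError("all trees must share the same taxa")
        for split in bipartitions(t):
            counts[split] = counts.get(split, 0) + 1

    n_rep = len(trees)
    keep = {s: c for s, c in counts.items() if c / n_rep > threshold}

    anchor = min(taxa)
    # each retained split, viewed from the anchor, is a clade of the rooted
    # representation; nest clades by containment (majority splits are laminar)
    clades = sorted(keep, key=lambda s: (-len(s), sorted(s)))
    root = TreeNode()
    node_of: dict[frozenset, TreeNode] = {frozenset(taxa): root}
    parent_sets: list[frozenset] = [frozenset(taxa)]
    for clade_set in clades:
        host = frozenset(taxa)
        for cand in parent_sets:
            if clade_set < cand and len(cand) < len(host):
                host = cand
        node = TreeNode(support=round(100.0 * keep[clade_set] / n_rep))
        node_of[host].add_child(node)
        node_of[clade_set] = node
        parent_sets.append(clade_set)

    for leaf in sorted(taxa):
        host = frozenset(taxa)
        for cand in parent_sets:
            if leaf in cand and len(cand) < len(host):
                host = cand
        node_of[host].add_child(TreeNode(name=leaf))

    def sort_rec(node: TreeNode) -> str:
        if node.is_leaf():
            return node.name
        keys = [sort_rec(c) for c in node.children]
        order = sorted(range(len(keys)), key=lambda i: keys[i])
        node.children = [node.children[i] for i in order]
        return min(keys)

    sort_rec(root)
    return PhyloTree(root=root, rooted=False)
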