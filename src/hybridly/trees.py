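"""Minimal phylogenetic tree structure, Newick serialization and neighbor joining.

Trees are plain nested :class:`TreeNode` objects.  The neighbor-joining
implementation is the classic Saitou & Nei agglomeration with deterministic
tie-breaking by taxon-name order, so identical inputs always produce an
identical tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TreeNode",
    "to_newick",
    "neighbor_joining",
    "root_on_outgroup",
    "splits",
    "has_split",
]

# Characters that force a Newick label to be quoted.
_UNSAFE_LABEL = re.compile(r"[\s()\[\]{}:;,'\"]")


@dataclass
class TreeNode:
    """A node in a rooted (or conventionally rooted unrooted) tree.

    ``length`` is the length of the branch leading to this node; it is
    ``None`` for the root.
    """

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def iter_leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf():
            yield self
        else:
            for child in self.children:
                yield from child.iter_leaves()

    def leaf_names(self) -> list[str]:
        return [leaf.name or "" for leaf in self.iter_leaves()]


def _format_label(name: str) -> str:
    if _UNSAFE_LABEL.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _format_length(length: float) -> str:
    return f"{length:g}"


def _node_newick(node: TreeNode) -> str:
    if node.is_leaf():
        out = _format_label(node.name or "")
    else:
        out = "(" + ",".join(_node_newick(c) for c in node.children) + ")"
        if node.name:
            out += _format_label(node.name)
    if node.length is not None:
        out += ":" + _format_length(node.length)
    return out


def to_newick(tree: TreeNode) -> str:
    """Serialize ``tree`` as a Newick string (with trailing semicolon)."""
    return _node_newick(tree) + ";"


def _sort_key(node: TreeNode) -> str:
    """Deterministic ordering key: smallest leaf name in the subtree."""
    return min(node.leaf_names())


def neighbor_joining(names: Sequence[str], matrix: np.ndarray) -> TreeNode:
    """Classic neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree represented with a trifurcating root for three
    or more taxa; for exactly two taxa the distance is split evenly between
    the two pendant branches.  Negative branch lengths are clamped to zero.
    Ties in the Q criterion are broken by the sorted pair of subtree keys
    (smallest leaf name), making the result deterministic.
    """
    names = list(names)
    d = np.asarray(matrix, dtype=float)
    n = len(names)
    if n < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")
    if d.shape != (n, n):
        raise ValueError(f"distance matrix shape {d.shape} does not match {n} taxa")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix is not symmetric")

    nodes: list[TreeNode] = [TreeNode(name=name) for name in names]
    if n == 2:
        half = max(d[0, 1] / 2.0, 0.0)
        a, b = nodes
        a.length = half
        b.length = half
        return TreeNode(children=[a, b])

    active = list(range(n))
    dist = d.copy()

    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        best: tuple[float, str, str] | None = None
        best_pair: tuple[int, int] | None = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * sub[i, j] - r[i] - r[j]
                ka = _sort_key(nodes[active[i]])
                kb = _sort_key(nodes[active[j]])
                key = (q, min(ka, kb), max(ka, kb))
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        assert best_pair is not None
        i, j = best_pair
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        bi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = dij - bi
        child_i, child_j = nodes[ai], nodes[aj]
        child_i.length = max(bi, 0.0)
        child_j.length = max(bj, 0.0)
        parent = TreeNode(children=[child_i, child_j])

        # Grow the working matrix with the new node's distances.
        new_row = np.zeros(dist.shape[0] + 1)
        for idx in active:
            if idx in (ai, aj):
                continue
            new_row[idx] = max(0.5 * (dist[ai, idx] + dist[aj, idx] - dij), 0.0)
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, : len(new_row) - 1] = new_row[:-1]
        dist[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        active = [idx for idx in active if idx not in (ai, aj)] + [len(nodes) - 1]

    # Join the final three nodes at a central (trifurcating) node using the
    # three-point formulas.
    a, b, c = active
    dab, dac, dbc = dist[a, b], dist[a, c], dist[b, c]
    la = max((dab + dac - dbc) / 2.0, 0.0)
    lb = max((dab + dbc - dac) / 2.0, 0.0)
    lc = max((dac + dbc - dab) / 2.0, 0.0)
    for node, length in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        node.length = length
    children = sorted((nodes[a], nodes[b], nodes[c]), key=_sort_key)
    return TreeNode(children=children)


def _adjacency(tree: TreeNode) -> dict[int, list[tuple[TreeNode, float]]]:
    """Undirected adjacency (by id) with branch lengths taken from children."""
    adj: dict[int, list[tuple[TreeNode, float]]] = {}

    def walk(node: TreeNode) -> None:
        adj.setdefault(id(node), [])
        for child in node.children:
            length = child.length if child.length is not None else 0.0
            adj.setdefault(id(child), [])
            adj[id(node)].append((child, length))
            adj[id(child)].append((node, length))
            walk(child)

    walk(tree)
    return adj


def root_on_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Re-root ``tree`` on the midpoint of the outgroup's pendant edge."""
    leaves = {leaf.name: leaf for leaf in tree.iter_leaves()}
    if outgroup not in leaves:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    og = leaves[outgroup]
    adj = _adjacency(tree)
    neighbors = adj[id(og)]
    if len(neighbors) != 1:
        raise ValueError(f"outgroup {outgroup!r} is not a pendant leaf")
    anchor, pendant_len = neighbors[0]

    def reorient(node: TreeNode, came_from: TreeNode | None) -> TreeNode:
        new = TreeNode(name=node.name)
        for other, length in adj[id(node)]:
            if came_from is not None and other is came_from:
                continue
            child = reorient(other, node)
            child.length = length
            new.children.append(child)
        return new

    half = pendant_len / 2.0
    og_side = TreeNode(name=og.name, length=half)
    rest = reorient(anchor, og)
    rest.length = half
    return TreeNode(children=[og_side, rest])


def splits(tree: TreeNode) -> set[frozenset[str]]:
    """Leaf sets subtended by every non-root node (clades of the rooted view)."""
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode, is_root: bool) -> frozenset[str]:
        if node.is_leaf():
            leaf = frozenset([node.name or ""])
            if not is_root:
                out.add(leaf)
            return leaf
        below = frozenset().union(*(walk(c, False) for c in node.children))
        if not is_root:
            out.add(below)
        return below

    walk(tree, True)
    return out


def has_split(tree: TreeNode, group: set[str]) -> bool:
    """True if some edge of ``tree`` separates ``group`` from all other leaves.

    The check is unrooted: the complement of ``group`` counts too.
    """
    all_leaves = frozenset(tree.leaf_names())
    target = frozenset(group)
    if not target <= all_leaves:
        raise ValueError("group contains names that are not leaves of the tree")
    complement = all_leaves - target
    return any(s == target or s == complement for s in splits(tree))
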