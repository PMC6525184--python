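"""A minimal rooted tree with branch lengths and bootstrap supports.

Neighbor-joining produces an unrooted binary tree; here it is represented
rooted at the final join (a trifurcation at the root).  Supports live on
internal edges, i.e. on internal non-root nodes, each of which stands for the
edge to its parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TreeError


@dataclass
class Node:
    label: str | None = None  # leaf name; None for internal nodes
    length: float | None = None  # branch length to parent (clamped >= 0)
    raw_length: float | None = None  # pre-clamp estimate (may be negative)
    support: int | None = None  # bootstrap percentage, internal edges only
    children: list["Node"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf():
            yield self
        else:
            for child in self.children:
                yield from child.leaves()

    def leaf_labels(self) -> frozenset:
        return frozenset(leaf.label for leaf in self.leaves())


class Tree:
    def __init__(self, root: Node):
        self.root = root
        labels = [leaf.label for leaf in root.leaves()]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        if any(lab is None for lab in labels):
            raise TreeError("every leaf must be labelled")
        self.leaf_label_set = frozenset(labels)

    # -- traversal ----------------------------------------------------------

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def internal_nodes(self):
        """Internal non-root nodes; each represents one internal edge."""
        for node in self.preorder():
            if node is not self.root and not node.is_leaf():
                yield node

    # -- bipartitions -------------------------------------------------------

    def _canonical(self, side: frozenset) -> frozenset:
        ref = min(self.leaf_label_set)
        return side if ref not in side else self.leaf_label_set - side

    def bipartitions(self) -> dict:
        """Map canonical non-trivial bipartition -> internal node (edge).

        Each internal edge splits the leaves in two; the side not containing
        the lexicographically smallest label is the canonical key, so the
        encoding is invariant to rooting and input order.
        """
        n = len(self.leaf_label_set)
        out = {}
        for node in self.internal_nodes():
            side = node.leaf_labels()
            if 2 <= len(side) <= n - 2:
                out[self._canonical(side)] = node
        return out

    def bipartition_set(self) -> frozenset:
        return frozenset(self.bipartitions().keys())

    # -- metrics ------------------------------------------------------------

    def leaf_distances(self) -> tuple[list, np.ndarray]:
        """Patristic (path-length) distances between all leaves."""
        labels: list[str] = []
        # map label -> distance accumulated from root, plus root-paths
        paths: dict[str, list[Node]] = {}

        def walk(node: Node, path: list[Node]):
            path = path + [node]
            if node.is_leaf():
                labels.append(node.label)
                paths[node.label] = path
            for child in node.children:
                walk(child, path)

        walk(self.root, [])
        n = len(labels)
        dist = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pi, pj = paths[labels[i]], paths[labels[j]]
                k = 0
                while k < min(len(pi), len(pj)) and pi[k] is pj[k]:
                    k += 1
                d = sum(nd.length for nd in pi[k:]) + sum(nd.length for nd in pj[k:])
                dist[i, j] = dist[j, i] = d
        return labels, dist

    def edge_lengths(self) -> dict:
        """Map canonical bipartition (incl. trivial leaf splits) -> raw length.

        Used to compare recovered branch lengths against a generating tree.
        The two root-adjacent... every non-root node contributes its edge.
        """
        out = {}
        for node in self.preorder():
            if node is self.root:
                continue
            side = self._canonical(node.leaf_labels())
            length = node.raw_length if node.raw_length is not None else node.length
            out[side] = out.get(side, 0.0) + length
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree(n_leaves={len(self.leaf_label_set)})"
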