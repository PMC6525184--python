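"""Test helpers: exhaustive unrooted-topology enumeration and additive matrices.

Independent of the package's NJ code path: trees are built by leaf insertion
on every edge (the standard recursion counting (2n-5)!! unrooted shapes) and
distances are read off as path lengths, so they form an additive-matrix
oracle for consistency checks.
"""

from __future__ import annotations

import copy

import numpy as np

from barcodelim.records import DistanceMatrix
from barcodelim.tree import Node, Tree


def _non_root_nodes(root: Node) -> list[Node]:
    out, stack = [], [root]
    while stack:
        node = stack.pop()
        if node is not root:
            out.append(node)
        stack.extend(node.children)
    return out


def _parent_of(root: Node, target: Node) -> Node:
    stack = [root]
    while stack:
        node = stack.pop()
        if target in node.children:
            return node
        stack.extend(node.children)
    raise AssertionError("target not in tree")


def all_unrooted_topologies(labels: list[str]) -> list[Node]:
    """Every unrooted binary topology on the labels (3 children at root)."""
    assert len(labels) >= 3
    base = Node(
        children=[Node(label=labels[0]), Node(label=labels[1]), Node(label=labels[2])]
    )
    trees = [base]
    for lab in labels[3:]:
        grown = []
        for tree in trees:
            n_edges = len(_non_root_nodes(tree))
            for k in range(n_edges):
                t2 = copy.deepcopy(tree)
                target = _non_root_nodes(t2)[k]
                parent = _parent_of(t2, target)
                joint = Node(children=[target, Node(label=lab)])
                parent.children[parent.children.index(target)] = joint
                grown.append(t2)
        trees = grown
    return trees


def random_additive_tree(
    topology: Node, rng: np.random.Generator, low: float = 0.05, high: float = 1.0
) -> tuple[Tree, DistanceMatrix]:
    """Assign random positive branch lengths; return tree + its path metric."""
    tree = Tree(copy.deepcopy(topology))
    for node in tree.preorder():
        if node is not tree.root:
            node.length = float(rng.uniform(low, high))
    labels, dist = tree.leaf_distances()
    return tree, DistanceMatrix(labels, dist, "K2P")
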