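"""Shared fixtures: the worked-example tree and random-tree generators."""

from __future__ import annotations

import numpy as np
import pytest

from ptpdelim import Delimitation, RootedTree, example_tree
from ptpdelim.treeio import Node


@pytest.fixture
def fig_tree() -> RootedTree:
    """The 7-tip worked-example tree (4 species, 12 edges)."""
    return example_tree()


def random_topology(n_leaves: int, rng: np.random.Generator,
                    labels: list[str] | None = None) -> RootedTree:
    """Random rooted binary topology by sequential random joins; unit lengths."""
    labels = labels or [f"t{i}" for i in range(n_leaves)]
    subs = [(lab, 1.0, []) for lab in labels]
    while len(subs) > 1:
        i, j = sorted(rng.choice(len(subs), size=2, replace=False))
        b = subs.pop(j)
        a = subs.pop(i)
        subs.append((None, 1.0, [a, b]))
    label, _, kids = subs[0]
    return RootedTree.from_nested((label, None, kids))


def random_lengths(tree: RootedTree, rng: np.random.Generator,
                   scale: float = 1.0) -> RootedTree:
    """Copy of ``tree`` with i.i.d. exponential(1/scale) branch lengths."""
    nodes = [
        Node(n.id, n.label, n.parent,
             0.0 if n.parent is None else float(rng.exponential(scale)),
             list(n.children))
        for n in tree.nodes
    ]
    return RootedTree(nodes)


def random_antichain(tree: RootedTree, rng: np.random.Generator,
                     stop_p: float = 0.5) -> Delimitation:
    """A random non-degenerate delimitation (rejection-sampled)."""
    for _ in range(200):
        roots = []
        stack = [tree.root_id]
        while stack:
            nid = stack.pop()
            if tree.is_leaf(nid) or (nid != tree.root_id and rng.random() < stop_p):
                roots.append(nid)
            else:
                stack.extend(tree.children(nid))
        d = Delimitation(tree, roots)
        if not d.is_degenerate:
            return d
    raise RuntimeError("no non-degenerate delimitation found")


def two_class_tree(n_leaves: int, rng: np.random.Generator,
                   lambda1: float = 10.0, lambda2: float = 100.0) -> RootedTree:
    """A tree whose lengths follow the two-class model for a random true
    delimitation: among edges ~ Exp(lambda1), within edges ~ Exp(lambda2)."""
    topo = random_topology(n_leaves, rng)
    truth = random_antichain(topo, rng)
    among_ids = truth.among_edge_ids()
    nodes = [
        Node(n.id, n.label, n.parent,
             0.0 if n.parent is None else float(
                 rng.exponential(1.0 / lambda1) if n.id in among_ids
                 else rng.exponential(1.0 / lambda2)),
             list(n.children))
        for n in topo.nodes
    ]
    return RootedTree(nodes)


def caterpillar(m: int) -> RootedTree:
    """Caterpillar (fully pectinate) tree with m tips, unit lengths."""
    spec = (f"c{m}", 1.0, [])
    for i in range(m - 1, 0, -1):
        spec = (None, 1.0, [(f"c{i}", 1.0, []), spec])
    label, _, kids = spec
    return RootedTree.from_nested((label, None, kids))


def balanced(depth: int) -> RootedTree:
    """Fully balanced binary tree with 2**depth tips, unit lengths."""
    counter = [0]

    def rec(d):
        if d == 0:
            counter[0] += 1
            return (f"b{counter[0]}", 1.0, [])
        return (None, 1.0, [rec(d - 1), rec(d - 1)])

    label, _, kids = rec(depth)
    return RootedTree.from_nested((label, None, kids))


def canonical(tree: RootedTree, nid: int | None = None):
    """Label/length-aware canonical form for isomorphism comparison."""
    nid = tree.root_id if nid is None else nid
    n = tree.nodes[nid]
    length = None if n.parent is None else round(n.length, 12)
    if n.is_leaf:
        return (n.label, length, ())
    kids = tuple(sorted((canonical(tree, c) for c in n.children), key=repr))
    return (n.label, length, kids)
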