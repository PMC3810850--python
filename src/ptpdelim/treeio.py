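"""Rooted trees with branch lengths: parsing, writing, path and prune queries.

The model consumes a rooted phylogeny whose branch lengths are expected
substitutions per site.  :class:`RootedTree` is a lightweight immutable-ish
container with integer preorder node ids (root is always id 0); Newick parsing
is delegated to dendropy, with validation (unique leaf labels, finite
non-negative lengths) layered on top.  The tree is never re-rooted here:
correct rooting is the caller's responsibility, because the delimitation
search starts at the root.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import dendropy

from .errors import NewickParseError, TreeValidationError

__all__ = [
    "Node",
    "RootedTree",
    "parse_newick",
    "write_newick",
    "path_lengths",
    "prune_taxa",
]


@dataclass
class Node:
    id: int
    label: str | None
    parent: int | None
    length: float  # edge length of the edge into this node; 0.0 for the root
    children: list[int] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


# Nested spec used by builders: (label, length, [child specs]); length may be
# None only for the root.
_Spec = tuple


class RootedTree:
    """A rooted tree with per-edge branch lengths.

    Nodes are stored in preorder; node 0 is the root.  Leaf labels are
    mandatory and unique; internal labels are optional.  Every non-root node
    carries a finite edge length >= 0 (the root's own length is ignored and
    stored as 0).
    """

    def __init__(self, nodes: Sequence[Node]):
        self.nodes = list(nodes)
        self._validate()
        self._leaf_index = {
            n.label: n.id for n in self.nodes if n.is_leaf
        }

    # ---------------------------------------------------------------- build
    @classmethod
    def from_nested(cls, spec: _Spec) -> "RootedTree":
        """Build from nested ``(label, length, [children])`` tuples."""
        nodes: list[Node] = []

        def rec(s: _Spec, parent: int | None) -> None:
            label, length, kids = s
            if parent is None:
                length = 0.0 if length is None else float(length)
            elif length is None:
                raise TreeValidationError(
                    f"missing branch length on edge into node {label!r}"
                )
            else:
                length = float(length)
            nid = len(nodes)
            nodes.append(Node(nid, label, parent, length))
            if parent is not None:
                nodes[parent].children.append(nid)
            for k in kids:
                rec(k, nid)

        rec(spec, None)
        return cls(nodes)

    def to_nested(self) -> _Spec:
        def rec(nid: int) -> _Spec:
            n = self.nodes[nid]
            return (n.label, n.length, [rec(c) for c in n.children])

        return rec(0)

    # ------------------------------------------------------------- validate
    def _validate(self) -> None:
        if not self.nodes or self.nodes[0].parent is not None:
            raise TreeValidationError("node 0 must be the unique root")
        seen_labels: set[str] = set()
        for n in self.nodes:
            if n.parent is None and n.id != 0:
                raise TreeValidationError("more than one root")
            if n.parent is not None:
                if not math.isfinite(n.length):
                    raise TreeValidationError(
                        f"non-finite branch length on edge into node {n.label or n.id}"
                    )
                if n.length < 0:
                    raise TreeValidationError(
                        f"negative branch length {n.length} on edge into node "
                        f"{n.label or n.id}"
                    )
            if n.is_leaf:
                if not n.label:
                    raise TreeValidationError(f"leaf node {n.id} has no label")
                if n.label in seen_labels:
                    raise TreeValidationError(f"duplicate leaf label {n.label!r}")
                seen_labels.add(n.label)

    # -------------------------------------------------------------- queries
    @property
    def root_id(self) -> int:
        return 0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.nodes) - 1

    @property
    def leaf_ids(self) -> list[int]:
        return [n.id for n in self.nodes if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.nodes if n.is_leaf]  # type: ignore[misc]

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_index)

    def is_leaf(self, nid: int) -> bool:
        return self.nodes[nid].is_leaf

    def children(self, nid: int) -> list[int]:
        return self.nodes[nid].children

    def parent(self, nid: int) -> int | None:
        return self.nodes[nid].parent

    def label(self, nid: int) -> str | None:
        return self.nodes[nid].label

    def edge_length(self, nid: int) -> float:
        return self.nodes[nid].length

    def leaf_id(self, label: str) -> int:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise TreeValidationError(f"unknown leaf label {label!r}") from None

    def preorder(self) -> Iterator[int]:
        return iter(range(len(self.nodes)))

    def postorder(self) -> Iterator[int]:
        out: list[int] = []
        stack = [0]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.nodes[nid].children)
        return reversed(out)

    def ancestors(self, nid: int) -> Iterator[int]:
        """Proper ancestors, child-to-root order."""
        p = self.nodes[nid].parent
        while p is not None:
            yield p
            p = self.nodes[p].parent

    def depths(self) -> list[float]:
        """Root-to-node path length for every node (root depth 0)."""
        d = [0.0] * len(self.nodes)
        for n in self.nodes[1:]:
            d[n.id] = d[n.parent] + n.length  # type: ignore[index]
        return d

    def scaled(self, factor: float) -> "RootedTree":
        """A copy with every edge length multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")

        def rec(s: _Spec) -> _Spec:
            label, length, kids = s
            return (label, None if length is None else length * factor,
                    [rec(k) for k in kids])

        spec = self.to_nested()
        label, _, kids = spec
        return RootedTree.from_nested((label, None, [rec(k) for k in kids]))


# -------------------------------------------------------------------- parse

def parse_newick(text: str) -> RootedTree:
    """Parse a Newick string (must end with ';') into a validated RootedTree.

    Quoted labels, whitespace, ``[...]`` comments and scientific-notation
    branch lengths are accepted; multifurcations are preserved.  A missing
    root branch length is stored as 0; a missing length anywhere else is a
    validation error, as is a duplicate leaf label or a negative length.
    """
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("Newick string must end with ';'",
                               offset=len(stripped))
    try:
        dtree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        msg = str(exc)
        if "uplicate" in msg or "ultiple occurrences" in msg:
            raise TreeValidationError(f"duplicate leaf label: {msg}") from exc
        raise NewickParseError(
            f"malformed Newick: {msg}",
            offset=getattr(exc, "col_num", None),
            line=getattr(exc, "line_num", None),
        ) from exc

    def convert(dnode) -> _Spec:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        kids = [convert(c) for c in dnode.child_nodes()]
        return (label, dnode.edge.length, kids)

    return RootedTree.from_nested(convert(dtree.seed_node))


# -------------------------------------------------------------------- write

_NEEDS_QUOTE = set("()[]{}:;,='\" \t\n")


def _fmt_label(label: str) -> str:
    if any(ch in _NEEDS_QUOTE for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    return repr(float(x))


def write_newick(tree: RootedTree) -> str:
    """Serialize to Newick; ``parse_newick(write_newick(t))`` is isomorphic
    to ``t`` with identical labels and branch lengths."""

    def rec(nid: int) -> str:
        n = tree.nodes[nid]
        if n.is_leaf:
            s = _fmt_label(n.label)  # type: ignore[arg-type]
        else:
            s = "(" + ",".join(rec(c) for c in n.children) + ")"
            if n.label:
                s += _fmt_label(n.label)
        if n.parent is not None:
            s += ":" + _fmt_length(n.length)
        return s

    return rec(0) + ";"


# --------------------------------------------------------------------- ops

def path_lengths(tree: RootedTree, leaf: str) -> list[float]:
    """Edge lengths along the root-to-leaf path, in root-to-leaf order.

    Prefix sums of the result are the cumulative substitution depths of the
    branching events on that path.
    """
    nid = tree.leaf_id(leaf)
    out = [tree.edge_length(nid)]
    for anc in tree.ancestors(nid):
        if anc == tree.root_id:
            break
        out.append(tree.edge_length(anc))
    return out[::-1]


def prune_taxa(tree: RootedTree, labels: Iterable[str]) -> RootedTree:
    """Remove the listed leaves.

    Resulting degree-2 internal nodes are suppressed with their two incident
    edge lengths summed, so every surviving leaf keeps its root-to-leaf path
    length; a root left with a single child is collapsed into that child.
    """
    labels = set(labels)
    for lab in labels:
        tree.leaf_id(lab)  # raises on unknown label
    if not labels:
        return RootedTree.from_nested(tree.to_nested())
    if tree.n_leaves - len(labels) < 2:
        raise TreeValidationError(
            f"pruning {len(labels)} of {tree.n_leaves} leaves would leave "
            "fewer than 2 leaves"
        )

    def rec(nid: int) -> _Spec | None:
        n = tree.nodes[nid]
        if n.is_leaf:
            return None if n.label in labels else (n.label, n.length, [])
        kids = [rec(c) for c in n.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            clabel, clength, ckids = kids[0]
            # suppress this now-unary node; at the root this collapses the
            # root into its surviving child (whose length is then ignored)
            length = None if n.parent is None else n.length + clength
            return (clabel, length, ckids)
        return (n.label, n.length if n.parent is not None else None, kids)

    spec = rec(tree.root_id)
    assert spec is not None
    return RootedTree.from_nested(spec)
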