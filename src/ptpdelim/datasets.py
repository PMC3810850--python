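"""Built-in worked example.

A 7-tip tree with one singleton species (C) and three two-individual species
(D, E, F): within-species branches are an order of magnitude shorter than
among-species branches, so the two-class model separates them cleanly.  The
tree is constructed programmatically; ``example_newick()`` serialises it.
"""

from __future__ import annotations

from .treeio import RootedTree, write_newick

__all__ = ["example_tree", "example_newick"]

_SPEC = (
    "R", None,
    [
        ("A", 0.15, [
            ("C", 0.14, []),
            ("D", 0.1, [("d1", 0.01, []), ("d2", 0.02, [])]),
        ]),
        ("B", 0.11, [
            ("E", 0.1, [("e1", 0.015, []), ("e2", 0.014, [])]),
            ("F", 0.12, [("f1", 0.03, []), ("f2", 0.02, [])]),
        ]),
    ],
)


def example_tree() -> RootedTree:
    """The worked-example tree (7 tips, 12 edges)."""
    return RootedTree.from_nested(_SPEC)


def example_newick() -> str:
    """Newick string of the worked-example tree."""
    return write_newick(example_tree())
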