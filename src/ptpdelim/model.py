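"""The Poisson tree processes (PTP) likelihood machinery.

The model assumes branch lengths (expected substitutions) were generated by
two independent Poisson process classes: speciation events along among-species
paths, and within-species branching events inside each species.  Under each
process the branch lengths are exponentially distributed, so a delimitation
(an antichain of "species root" nodes covering every leaf) splits the tree's
edges into two exponential samples.  The log-likelihood of a delimitation with
among-species lengths x_1..x_k and within-species lengths x_{k+1}..x_n is

    L = k ln(lam1) - lam1 * sum(among) + (n-k) ln(lam2) - lam2 * sum(within)

with the maximum-likelihood rates lam1 = 1/mean(among), lam2 = 1/mean(within)
unless lam1 is externally fixed (reference-phylogeny mode, where the
speciation rate is estimated once on a reference tree).  A single-class
exponential fit serves as the null model of a likelihood-ratio test with one
degree of freedom.

Every edge length is floored at a small epsilon before likelihood work:
inferred trees contain zero-length branches which would otherwise yield
infinite rate estimates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from scipy.stats import chi2

from .errors import (
    CapExceededError,
    DegenerateDelimitationError,
    RateOverflowError,
    TreeValidationError,
)
from .treeio import RootedTree

__all__ = [
    "DEFAULT_EPSILON",
    "DEFAULT_CAP",
    "Delimitation",
    "PTPFit",
    "classify_edges",
    "estimate_rates",
    "two_class_loglik",
    "log_likelihood",
    "null_log_likelihood",
    "lrt_pvalue",
    "count_delimitations",
    "enumerate_delimitations",
]

#: Floor applied to every edge length before rate/likelihood computation.
DEFAULT_EPSILON = 1e-10

#: Default cap on exhaustive enumeration.
DEFAULT_CAP = 100_000


class Delimitation:
    """A species delimitation: an antichain of species-root nodes.

    ``species_roots`` must cover every leaf exactly once, i.e. each leaf has
    exactly one ancestor-or-self in the set.  The induced tip partition groups
    each leaf under its covering species root.
    """

    def __init__(self, tree: RootedTree, species_roots: Iterable[int]):
        self.tree = tree
        self.species_roots = frozenset(species_roots)
        self._validate()

    def _validate(self) -> None:
        tree = self.tree
        if not self.species_roots:
            raise TreeValidationError("delimitation has no species roots")
        for nid in self.species_roots:
            if not (0 <= nid < tree.n_nodes):
                raise TreeValidationError(f"node id {nid} not in tree")
        # count species_roots on each root path; DFS carrying coverage depth
        stack: list[tuple[int, int]] = [(tree.root_id, 0)]
        while stack:
            nid, seen = stack.pop()
            seen += nid in self.species_roots
            if seen > 1:
                raise TreeValidationError(
                    "species_roots is not an antichain: two roots on one "
                    "root-to-leaf path"
                )
            if tree.is_leaf(nid):
                if seen == 0:
                    raise TreeValidationError(
                        f"leaf {tree.label(nid)!r} is not covered by any "
                        "species root"
                    )
            else:
                for c in tree.children(nid):
                    stack.append((c, seen))

    # ------------------------------------------------------------- derived
    @property
    def n_species(self) -> int:
        return len(self.species_roots)

    @property
    def is_single_species(self) -> bool:
        return self.species_roots == {self.tree.root_id}

    @property
    def is_all_singletons(self) -> bool:
        return all(self.tree.is_leaf(n) for n in self.species_roots)

    @property
    def is_degenerate(self) -> bool:
        """True iff one of the two edge classes is empty."""
        return self.is_single_species or self.is_all_singletons

    def species_map(self) -> dict[int, int]:
        """leaf id -> covering species-root id."""
        out: dict[int, int] = {}
        stack: list[tuple[int, int | None]] = [(self.tree.root_id, None)]
        while stack:
            nid, root = stack.pop()
            if nid in self.species_roots:
                root = nid
            if self.tree.is_leaf(nid):
                out[nid] = root  # type: ignore[assignment]
            else:
                for c in self.tree.children(nid):
                    stack.append((c, root))
        return out

    def species_sets(self) -> list[set[str]]:
        """Tip partition as label sets, ordered by species-root preorder id."""
        groups: dict[int, set[str]] = {}
        for leaf, root in self.species_map().items():
            groups.setdefault(root, set()).add(self.tree.label(leaf))  # type: ignore[arg-type]
        return [groups[r] for r in sorted(groups)]

    def among_edge_ids(self) -> set[int]:
        """Nodes whose incoming edge is among-species: every node on a
        root-to-species-root path (species root included), except the root
        itself which has no incoming edge."""
        marked: set[int] = set()
        for s in self.species_roots:
            nid: int | None = s
            while nid is not None and nid not in marked:
                marked.add(nid)
                nid = self.tree.parent(nid)
        marked.discard(self.tree.root_id)
        return marked

    def speciation_nodes(self) -> set[int]:
        """The root plus every internal node terminating an among-species
        edge; these are the speciation events the delimitation implies."""
        nodes = {self.tree.root_id}
        for nid in self.among_edge_ids():
            if not self.tree.is_leaf(nid):
                nodes.add(nid)
        return nodes

    # ---------------------------------------------------------------- misc
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Delimitation)
            and self.species_roots == other.species_roots
            and self.tree is other.tree
        )

    def __hash__(self) -> int:
        return hash(self.species_roots)

    def __repr__(self) -> str:
        return f"Delimitation(n_species={self.n_species}, roots={sorted(self.species_roots)})"


@dataclass
class PTPFit:
    """A two-class PTP fit for one delimitation.

    ``lambda1`` is the speciation rate per substitution (None only when the
    among class is empty under a fixed-rate fit), ``lambda2`` the
    within-species branching rate, ``k`` the number of among-species edges
    and ``n`` the total number of classified edges.
    """

    lambda1: float | None
    lambda2: float
    logL: float
    k: int
    n: int
    delimitation: Delimitation
    lambda1_fixed: bool = False


# ------------------------------------------------------------------ classify

def classify_edges(
    tree: RootedTree, d: Delimitation
) -> tuple[list[float], list[float]]:
    """Split edge lengths into (among-species, within-species) classes.

    An edge (parent -> child) is among-species iff the child lies on a
    root-to-species-root path, species root included; all remaining edges are
    within-species.  Together the classes cover every edge exactly once.
    """
    if d.tree is not tree:
        raise TreeValidationError("delimitation was built for a different tree")
    among_ids = d.among_edge_ids()
    among = [tree.edge_length(n) for n in sorted(among_ids)]
    within = [
        tree.edge_length(n)
        for n in tree.preorder()
        if n != tree.root_id and n not in among_ids
    ]
    return among, within


# --------------------------------------------------------------------- rates

def _floored(xs: Sequence[float], epsilon: float) -> list[float]:
    return [max(float(x), epsilon) for x in xs]


def estimate_rates(
    among: Sequence[float],
    within: Sequence[float],
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[float, float]:
    """Maximum-likelihood exponential rates: the inverse mean length of each
    class (after the epsilon floor)."""
    if not among or not within:
        raise DegenerateDelimitationError(
            "both edge classes must be non-empty to estimate two rates"
        )
    sa = sum(_floored(among, epsilon))
    sw = sum(_floored(within, epsilon))
    if sa <= 0 or sw <= 0:
        raise RateOverflowError(
            "edge-class length sum is zero even after the epsilon floor "
            f"(epsilon={epsilon}); rate estimate would overflow"
        )
    return len(among) / sa, len(within) / sw


def two_class_loglik(
    among: Sequence[float],
    within: Sequence[float],
    fixed_lambda1: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> tuple[float | None, float, float]:
    """Evaluate the two-class PTP log-likelihood on raw edge-length classes.

    Returns ``(lambda1, lambda2, logL)``.  With ``fixed_lambda1`` only
    ``lambda2`` is estimated and an empty among class is tolerated.
    """
    among_f = _floored(among, epsilon)
    within_f = _floored(within, epsilon)
    if not within_f:
        raise DegenerateDelimitationError(
            "within-species edge class is empty; the two-class likelihood is "
            "undefined (use the single-class null model)"
        )
    sw = sum(within_f)
    if sw <= 0:
        raise RateOverflowError("within-class length sum is zero after floor")
    lam2 = len(within_f) / sw

    if fixed_lambda1 is not None:
        if fixed_lambda1 <= 0:
            raise ValueError("fixed_lambda1 must be positive")
        lam1: float | None = float(fixed_lambda1)
    elif among_f:
        sa = sum(among_f)
        if sa <= 0:
            raise RateOverflowError("among-class length sum is zero after floor")
        lam1 = len(among_f) / sa
    else:
        raise DegenerateDelimitationError(
            "among-species edge class is empty and no fixed rate was given"
        )

    logL = len(within_f) * math.log(lam2) - lam2 * sw
    if among_f:
        logL += len(among_f) * math.log(lam1) - lam1 * sum(among_f)
    return lam1, lam2, logL


def log_likelihood(
    tree: RootedTree,
    d: Delimitation,
    fixed_lambda1: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
) -> PTPFit:
    """Fit the two-class PTP model to ``d`` and return the scored fit."""
    among, within = classify_edges(tree, d)
    lam1, lam2, logL = two_class_loglik(among, within, fixed_lambda1, epsilon)
    return PTPFit(
        lambda1=lam1,
        lambda2=lam2,
        logL=logL,
        k=len(among),
        n=len(among) + len(within),
        delimitation=d,
        lambda1_fixed=fixed_lambda1 is not None,
    )


# ---------------------------------------------------------------- null / LRT

def null_log_likelihood(
    tree: RootedTree, epsilon: float = DEFAULT_EPSILON
) -> tuple[float, float]:
    """Single-class exponential fit to all edges: ``(lambda, logL0)``.

    This is the null model of the LRT; with n edges of total length S the MLE
    is lambda = n/S and logL0 = n ln(lambda) - n.
    """
    lengths = _floored(
        [tree.edge_length(n) for n in tree.preorder() if n != tree.root_id],
        epsilon,
    )
    if len(lengths) < 2:
        raise TreeValidationError("null model needs at least 2 edges")
    total = sum(lengths)
    if total <= 0:
        raise RateOverflowError("total edge length is zero after floor")
    n = len(lengths)
    lam = n / total
    return lam, n * math.log(lam) - n


def lrt_pvalue(
    logL1: float, logL0: float, tol: float = 1e-9
) -> tuple[float, float]:
    """Likelihood-ratio test of two branch-length classes vs one.

    Returns ``(statistic, p)`` where statistic = 2(logL1 - logL0) and p is
    the chi-square(1) upper-tail probability.  A statistic within ``tol``
    below zero is clamped to 0 (float noise); a large p-value means either
    all tips are one species or every tip is its own species.
    """
    stat = 2.0 * (logL1 - logL0)
    if stat < 0:
        if stat < -tol:
            raise ValueError(
                f"alternative log-likelihood {logL1} is below the null {logL0} "
                "by more than the numerical tolerance"
            )
        stat = 0.0
    return stat, float(chi2.sf(stat, df=1))


# ---------------------------------------------------------- count / enumerate

def count_delimitations(tree: RootedTree) -> int:
    """Exact number of delimitations (antichain covers), degenerates included.

    Recursion: D(leaf) = 1, D(node) = 1 + prod over children of D(child);
    exact big-integer arithmetic.  The count is m for a caterpillar tree with
    m tips and maximal for balanced trees.
    """
    d: dict[int, int] = {}
    for nid in tree.postorder():
        if tree.is_leaf(nid):
            d[nid] = 1
        else:
            prod = 1
            for c in tree.children(nid):
                prod *= d[c]
            d[nid] = 1 + prod
    return d[tree.root_id]


def enumerate_delimitations(
    tree: RootedTree, cap: int = DEFAULT_CAP
) -> Iterator[Delimitation]:
    """Yield every delimitation exactly once (degenerates included).

    Refuses with the exact count if it exceeds ``cap``.
    """
    total = count_delimitations(tree)
    if total > cap:
        raise CapExceededError(total, cap)

    def gen(nid: int) -> Iterator[tuple[int, ...]]:
        yield (nid,)
        if not tree.is_leaf(nid):
            for combo in itertools.product(
                *(list(gen(c)) for c in tree.children(nid))
            ):
                yield tuple(itertools.chain.from_iterable(combo))

    for roots in gen(tree.root_id):
        yield Delimitation(tree, roots)
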