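"""Maximum-likelihood delimitation search.

Two search modes over the lattice of antichain covers: exhaustive scoring of
every non-degenerate delimitation (exact, feasible when the delimitation
count is below a cap) and a SPLIT/MERGE hill-climb for larger trees.  The
``delimit`` driver prunes outgroups, picks the mode, runs the search and the
likelihood-ratio test against the single-class null, and reports the tip
partition.  ``classify_species`` tags each delimited species as a known
reference species or as new.

Degenerate delimitations (all tips one species, or every tip its own species)
have an empty edge class, so the two-class likelihood is undefined on them;
they are represented collectively by the null model.  Trees on which only
degenerate delimitations exist (a cherry, a star) therefore return the null
model as the result instead of erroring.

Determinism: candidate iteration follows node preorder ids; likelihood ties
break toward fewer species, then the lexicographically smallest sorted
species-root id list.  The seed only jitters restart initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import TreeValidationError
from .model import (
    DEFAULT_CAP,
    DEFAULT_EPSILON,
    Delimitation,
    PTPFit,
    count_delimitations,
    enumerate_delimitations,
    log_likelihood,
    lrt_pvalue,
    null_log_likelihood,
)
from .treeio import RootedTree, prune_taxa

__all__ = [
    "DelimitationResult",
    "SpeciesTag",
    "ClassifiedSpecies",
    "exhaustive_ml",
    "greedy_ml",
    "delimit",
    "classify_species",
]


@dataclass
class DelimitationResult:
    """Outcome of a delimitation search on one tree."""

    best_fit: PTPFit | None  # None when only degenerate delimitations exist
    null_lambda: float
    null_logL: float
    lrt_statistic: float
    p_value: float
    species: list[set[str]]
    search_mode: str
    evaluations: int
    n_delimitations: int

    @property
    def n_species(self) -> int:
        return len(self.species)

    def partition(self) -> dict[str, int]:
        """leaf label -> species index (for NMI against a ground truth)."""
        return {lab: i for i, grp in enumerate(self.species) for lab in grp}

    def summary_lines(self) -> list[str]:
        fit = self.best_fit
        lines = [
            f"species_count\t{self.n_species}",
            f"lambda1\t{'NA' if fit is None or fit.lambda1 is None else repr(fit.lambda1)}",
            f"lambda2\t{'NA' if fit is None else repr(fit.lambda2)}",
            f"logL\t{'NA' if fit is None else repr(fit.logL)}",
            f"null_lambda\t{self.null_lambda!r}",
            f"null_logL\t{self.null_logL!r}",
            f"lrt_statistic\t{self.lrt_statistic!r}",
            f"p_value\t{self.p_value!r}",
            f"search_mode\t{self.search_mode}",
            f"evaluations\t{self.evaluations}",
            f"delimitation_count\t{self.n_delimitations}",
        ]
        return lines


def _tie_key(fit: PTPFit) -> tuple[float, int, tuple[int, ...]]:
    """Sort key: higher logL first, then fewer species, then smallest ids."""
    d = fit.delimitation
    return (-fit.logL, d.n_species, tuple(sorted(d.species_roots)))


def _degenerate_result(
    tree: RootedTree, mode: str, epsilon: float, n_delim: int
) -> DelimitationResult:
    null_lam, null_logL = null_log_likelihood(tree, epsilon)
    return DelimitationResult(
        best_fit=None,
        null_lambda=null_lam,
        null_logL=null_logL,
        lrt_statistic=0.0,
        p_value=1.0,
        species=[set(tree.leaf_labels)],
        search_mode=mode,
        evaluations=0,
        n_delimitations=n_delim,
    )


def _finish(
    tree: RootedTree,
    fit: PTPFit,
    mode: str,
    evaluations: int,
    epsilon: float,
    n_delim: int,
) -> DelimitationResult:
    null_lam, null_logL = null_log_likelihood(tree, epsilon)
    stat, p = lrt_pvalue(fit.logL, null_logL)
    return DelimitationResult(
        best_fit=fit,
        null_lambda=null_lam,
        null_logL=null_logL,
        lrt_statistic=stat,
        p_value=p,
        species=fit.delimitation.species_sets(),
        search_mode=mode,
        evaluations=evaluations,
        n_delimitations=n_delim,
    )


# ----------------------------------------------------------------- exhaustive

def exhaustive_ml(
    tree: RootedTree,
    fixed_lambda1: float | None = None,
    epsilon: float = DEFAULT_EPSILON,
    cap: int = DEFAULT_CAP,
) -> DelimitationResult:
    """Score every non-degenerate delimitation and return the global optimum."""
    n_delim = count_delimitations(tree)
    best: PTPFit | None = None
    evals = 0
    for d in enumerate_delimitations(tree, cap):
        if d.is_degenerate:
            continue
        fit = log_likelihood(tree, d, fixed_lambda1, epsilon)
        evals += 1
        if best is None or _tie_key(fit) < _tie_key(best):
            best = fit
    if best is None:
        return _degenerate_result(tree, "exhaustive", epsilon, n_delim)
    return _finish(tree, best, "exhaustive", evals, epsilon, n_delim)


# --------------------------------------------------------------------- greedy

def _split_moves(tree: RootedTree, roots: frozenset[int]) -> list[frozenset[int]]:
    out = []
    for s in sorted(roots):
        if tree.is_leaf(s):
            continue
        cand = (roots - {s}) | set(tree.children(s))
        if not all(tree.is_leaf(n) for n in cand):  # exclude all-singletons
            out.append(frozenset(cand))
    return out


def _merge_moves(tree: RootedTree, roots: frozenset[int]) -> list[frozenset[int]]:
    out = []
    parents = sorted({p for s in roots if (p := tree.parent(s)) is not None})
    for p in parents:
        if p == tree.root_id:
            continue  # merging to the root is the degenerate single species
        kids = tree.children(p)
        if all(k in roots for k in kids):
            out.append(frozenset((roots - set(kids)) | {p}))
    return out


def _random_antichain(
    tree: RootedTree, rng: np.random.Generator
) -> frozenset[int]:
    """A random non-degenerate antichain cover (rejection-sampled)."""
    for _ in range(64):
        roots: list[int] = []
        stack = [tree.root_id]
        while stack:
            nid = stack.pop()
            if tree.is_leaf(nid) or (nid != tree.root_id and rng.random() < 0.5):
                roots.append(nid)
            else:
                stack.extend(tree.children(nid))
        cand = frozenset(roots)
        d = Delimitation(tree, cand)
        if not d.is_degenerate:
            return cand
    return frozenset(tree.children(tree.root_id))


def greedy_ml(
    tree: RootedTree,
    fixed_lambda1: float | None = None,
    seed: int = 0,
    restarts: int = 5,
    epsilon: float = DEFAULT_EPSILON,
) -> DelimitationResult:
    """Hill-climb over the delimitation lattice.

    Initial state: the children of the root.  Moves: SPLIT (replace an
    internal species root by its children) and MERGE (replace a full sibling
    set of species roots by their parent), both restricted to non-degenerate
    antichain covers.  Each iteration scores all legal moves and applies the
    single best strictly-improving one; terminates when none improves.
    Additional restarts (seeded) start from random antichains; the best state
    over all restarts is returned.
    """
    n_delim = count_delimitations(tree)
    init = frozenset(tree.children(tree.root_id))
    if all(tree.is_leaf(n) for n in init):
        # every antichain cover is {root} or all leaves: only degenerates exist
        return _degenerate_result(tree, "greedy", epsilon, n_delim)

    rng = np.random.default_rng(seed)
    evals = 0
    best_overall: PTPFit | None = None

    starts: list[frozenset[int]] = [init]
    for _ in range(max(0, restarts - 1)):
        starts.append(_random_antichain(tree, rng))

    for start in starts:
        current = log_likelihood(tree, Delimitation(tree, start), fixed_lambda1, epsilon)
        evals += 1
        while True:
            state = current.delimitation.species_roots
            best_move: PTPFit | None = None
            for cand in _split_moves(tree, state) + _merge_moves(tree, state):
                fit = log_likelihood(
                    tree, Delimitation(tree, cand), fixed_lambda1, epsilon
                )
                evals += 1
                if fit.logL <= current.logL:
                    continue
                if best_move is None or _tie_key(fit) < _tie_key(best_move):
                    best_move = fit
            if best_move is None:
                break
            current = best_move
        if best_overall is None or _tie_key(current) < _tie_key(best_overall):
            best_overall = current

    assert best_overall is not None
    return _finish(tree, best_overall, "greedy", evals, epsilon, n_delim)


# --------------------------------------------------------------------- driver

def delimit(
    tree: RootedTree,
    outgroup: Iterable[str] | None = None,
    fixed_lambda1: float | None = None,
    search: str = "auto",
    epsilon: float = DEFAULT_EPSILON,
    cap: int = DEFAULT_CAP,
    seed: int = 0,
    restarts: int = 5,
) -> DelimitationResult:
    """End-user driver: prune outgroups, search, test, report.

    ``search`` is ``auto`` (exhaustive iff the delimitation count is within
    ``cap``, else greedy), ``exhaustive`` or ``greedy``.
    """
    if outgroup:
        tree = prune_taxa(tree, outgroup)
        if tree.n_leaves < 3:
            raise TreeValidationError(
                "outgroup pruning left fewer than 3 leaves"
            )
    if search not in ("auto", "exhaustive", "greedy"):
        raise ValueError(f"unknown search mode {search!r}")
    if search == "auto":
        search = "exhaustive" if count_delimitations(tree) <= cap else "greedy"
    if search == "exhaustive":
        return exhaustive_ml(tree, fixed_lambda1, epsilon, cap)
    return greedy_ml(tree, fixed_lambda1, seed, restarts, epsilon)


# ------------------------------------------------------------------- tagging

@dataclass
class SpeciesTag:
    index: int
    members: set[str]
    tag: str  # "known" | "new"
    reference_members: set[str] = field(default_factory=set)


@dataclass
class ClassifiedSpecies:
    tags: list[SpeciesTag]
    n_known: int
    n_new: int


def classify_species(
    result: DelimitationResult, reference_labels: Iterable[str]
) -> ClassifiedSpecies:
    """Tag each delimited species as known (contains a reference tip, which
    assigns it to that reference species) or new (contains none)."""
    refs = set(reference_labels)
    all_leaves = set().union(*result.species) if result.species else set()
    unknown = refs - all_leaves
    if unknown:
        raise TreeValidationError(
            f"reference labels not present in the tree: {sorted(unknown)}"
        )
    tags = []
    for i, grp in enumerate(result.species):
        hit = grp & refs
        tags.append(
            SpeciesTag(
                index=i,
                members=grp,
                tag="known" if hit else "new",
                reference_members=hit,
            )
        )
    n_known = sum(t.tag == "known" for t in tags)
    return ClassifiedSpecies(tags=tags, n_known=n_known, n_new=len(tags) - n_known)
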