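"""Yule species trees and multispecies-coalescent gene trees with known truth.

The generator emulates the study design used to benchmark single-locus
delimitation: a pure-birth (Yule) species tree with scaled birth rate b',
a multispecies coalescent (MSC) gene tree over sampled individuals, and a
conversion of coalescent time to expected substitutions.  Species are treated
as populations that are completely isolated after divergence: gene lineages
within a population coalesce at rate j(j-1)/2 per coalescent unit, and lineage
sets merge (going rootward) at each species divergence.

Units.  Species-tree times and coalescent times share one unit (2N
generations) by default, with b' the birth rate per coalescent unit, so small
b' means long waits between speciations and hence large distances between
species.  Because species separation relative to coalescent depth is the
quantity that controls delimitability, ``msc_gene_tree`` takes a
``time_scale`` factor applied to species divergence times before the
coalescent runs, and ``calibrate_time_scale`` chooses it so the simulated
within/among mean branch-length ratio matches a target; see docs/methods.md.
Gene trees are ultrametric in time; ``scale_to_substitutions`` converts to
expected substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .evaluate import Partition
from .treeio import Node, RootedTree

__all__ = [
    "EvenSampling",
    "UnevenSampling",
    "BENCHMARK_UNEVEN_SCHEME",
    "BIRTH_RATE_GRID",
    "SimulationConfig",
    "GeneTreeSample",
    "yule_species_tree",
    "species_ages",
    "msc_gene_tree",
    "scale_to_substitutions",
    "simulate_dataset",
    "within_among_ratio",
    "calibrate_time_scale",
]

#: Scaled birth rates used in the benchmark grid.
BIRTH_RATE_GRID = (5, 10, 20, 40, 80, 160)


@dataclass(frozen=True)
class EvenSampling:
    """k individuals sampled from every species."""

    k: int

    def sizes(self, n_species: int) -> list[int]:
        if self.k < 1:
            raise ValueError("sample size must be >= 1")
        return [self.k] * n_species


@dataclass(frozen=True)
class UnevenSampling:
    """Groups of (species_count, individuals_per_species)."""

    groups: tuple[tuple[int, int], ...]

    def sizes(self, n_species: int) -> list[int]:
        if sum(c for c, _ in self.groups) != n_species:
            raise ValueError(
                "uneven scheme species counts must sum to n_species"
            )
        out: list[int] = []
        for count, k in self.groups:
            if k < 1 or count < 1:
                raise ValueError("all counts and sample sizes must be >= 1")
            out.extend([k] * count)
        return out


#: The benchmark's uneven design: 2 species with 100 individuals, 4 with 50,
#: 8 with 10 and 16 with 2 (30 species total).
BENCHMARK_UNEVEN_SCHEME = UnevenSampling(((2, 100), (4, 50), (8, 10), (16, 2)))


@dataclass
class GeneTreeSample:
    """A simulated gene tree, its true species partition, and the species
    tree it came from.  Gene-tree lengths are coalescent units until
    ``scale_to_substitutions`` is applied."""

    gene_tree: RootedTree
    true_partition: Partition
    species_tree: RootedTree


@dataclass
class SimulationConfig:
    """Conditions for one simulated dataset.

    Defaults mirror the benchmark design: 30 species, 10 individuals sampled
    per species.  ``subs_per_coalescent_unit`` converts coalescent time to
    expected substitutions (default 0.05, giving within-species branch
    lengths of a few hundredths of a substitution, the scale of typical
    single-locus barcoding trees); ``time_scale`` multiplies species
    divergence times before the coalescent (1.0 = shared-unit convention).
    """

    n_species: int = 30
    birth_rate: float = 5.0
    sampling: EvenSampling | UnevenSampling = field(
        default_factory=lambda: EvenSampling(10)
    )
    subs_per_coalescent_unit: float = 0.05
    time_scale: float = 1.0
    n_replicates: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        samp: dict[str, object]
        if isinstance(self.sampling, EvenSampling):
            samp = {"scheme": "even", "k": self.sampling.k}
        else:
            samp = {"scheme": "uneven", "groups": list(map(list, self.sampling.groups))}
        return {
            "n_species": self.n_species,
            "birth_rate": self.birth_rate,
            "sampling": samp,
            "subs_per_coalescent_unit": self.subs_per_coalescent_unit,
            "time_scale": self.time_scale,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }


# ----------------------------------------------------------------------- Yule

def yule_species_tree(
    n_species: int,
    birth_rate: float,
    rng: np.random.Generator | int,
) -> RootedTree:
    """Pure-birth species tree with ``n_species`` tips.

    With j extant lineages the waiting time to the next birth is
    exponential(rate j*b'); after the n-th lineage appears one further
    waiting time is drawn to place the present.  The returned tree is
    ultrametric with branch lengths in coalescent time units; tips are
    labelled s1..sn.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng

    # records: node -> (birth time, children record ids); root splits at t=0
    times = [0.0]
    children: list[list[int]] = [[]]
    active = [0, 0]  # parent record id of each open lineage
    t = 0.0
    j = 2
    while j < n_species:
        t += rng.exponential(1.0 / (j * birth_rate))
        idx = int(rng.integers(j))
        parent = active[idx]
        nid = len(times)
        times.append(t)
        children.append([])
        children[parent].append(nid)
        # the split lineage continues as two lineages below the new node
        active[idx] = nid
        active.append(nid)
        j += 1
    t += rng.exponential(1.0 / (n_species * birth_rate))
    t_end = t

    # close every open lineage with a tip
    for parent in active:
        nid = len(times)
        times.append(t_end)
        children.append([])
        children[parent].append(nid)

    # build RootedTree (preorder) from record 0
    counter = [0]

    def rec(ridx: int):
        kids = children[ridx]
        if not kids:
            counter[0] += 1
            return (f"s{counter[0]}", None, [], ridx)
        specs = [rec(k) for k in kids]
        return (None, None, specs, ridx)

    nested = rec(0)

    nodes: list[Node] = []

    def build(spec, parent: int | None) -> None:
        label, _, kids, ridx = spec
        length = 0.0 if parent is None else times[ridx] - times[_ridx_of[parent]]
        nid = len(nodes)
        _ridx_of[nid] = ridx
        nodes.append(Node(nid, label, parent, length))
        if parent is not None:
            nodes[parent].children.append(nid)
        for k in kids:
            build(k, nid)

    _ridx_of: dict[int, int] = {}
    build(nested, None)
    return RootedTree(nodes)


def species_ages(species_tree: RootedTree) -> dict[int, float]:
    """Node id -> age (time before present; tips at 0) of an ultrametric
    species tree."""
    depths = species_tree.depths()
    height = max(depths[i] for i in species_tree.leaf_ids)
    ages = {}
    for nid in species_tree.preorder():
        age = height - depths[nid]
        ages[nid] = 0.0 if species_tree.is_leaf(nid) else age
    return ages


# ------------------------------------------------------------------------ MSC

def msc_gene_tree(
    species_tree: RootedTree,
    sampling: EvenSampling | UnevenSampling,
    rng: np.random.Generator | int,
    time_scale: float = 1.0,
) -> GeneTreeSample:
    """Simulate one multispecies-coalescent gene tree.

    Within each population, j active lineages coalesce at rate j(j-1)/2 per
    coalescent unit; at each species divergence (going rootward) the lineage
    sets of the joining populations merge; coalescence continues without
    bound in the root population.  ``time_scale`` multiplies species
    divergence times before the coalescent runs.
    """
    if time_scale <= 0:
        raise ValueError("time_scale must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ages = {n: a * time_scale for n, a in species_ages(species_tree).items()}

    leaf_order = [n for n in species_tree.preorder() if species_tree.is_leaf(n)]
    sizes = sampling.sizes(len(leaf_order))

    # gene nodes: parallel lists of age / children / label
    g_age: list[float] = []
    g_children: list[list[int]] = []
    g_label: list[str | None] = []
    truth: dict[str, str] = {}

    def new_node(age: float, kids: list[int], label: str | None) -> int:
        g_age.append(age)
        g_children.append(kids)
        g_label.append(label)
        return len(g_age) - 1

    def coalesce(
        lineages: list[int], t_start: float, t_end: float
    ) -> list[int]:
        lineages = list(lineages)
        t = t_start
        while len(lineages) > 1:
            jj = len(lineages)
            t_next = t + rng.exponential(2.0 / (jj * (jj - 1)))
            if t_next >= t_end:
                break
            t = t_next
            i, k = sorted(rng.choice(jj, size=2, replace=False))
            merged = new_node(t, [lineages[i], lineages[k]], None)
            lineages = [
                lin for idx, lin in enumerate(lineages) if idx not in (i, k)
            ]
            lineages.append(merged)
        return lineages

    def survivors(st_node: int) -> list[int]:
        if species_tree.is_leaf(st_node):
            sp = species_tree.label(st_node)
            k = sizes[leaf_order.index(st_node)]
            lineages = []
            for i in range(1, k + 1):
                lab = f"{sp}_{i}"
                lineages.append(new_node(0.0, [], lab))
                truth[lab] = sp  # type: ignore[index]
        else:
            lineages = []
            for c in species_tree.children(st_node):
                lineages.extend(survivors(c))
        parent = species_tree.parent(st_node)
        t_end = ages[parent] if parent is not None else np.inf
        return coalesce(lineages, ages[st_node], t_end)

    roots = survivors(species_tree.root_id)
    assert len(roots) == 1
    g_root = roots[0]

    # convert ages to a RootedTree (edge length = parent age - child age)
    nodes: list[Node] = []

    def build(gid: int, parent: int | None, parent_age: float) -> None:
        length = 0.0 if parent is None else parent_age - g_age[gid]
        nid = len(nodes)
        nodes.append(Node(nid, g_label[gid], parent, length))
        if parent is not None:
            nodes[parent].children.append(nid)
        for c in g_children[gid]:
            build(c, nid, g_age[gid])

    build(g_root, None, 0.0)
    return GeneTreeSample(
        gene_tree=RootedTree(nodes),
        true_partition=Partition(truth),
        species_tree=species_tree,
    )


def scale_to_substitutions(
    sample: GeneTreeSample, subs_per_coalescent_unit: float
) -> GeneTreeSample:
    """Multiply every gene-tree edge length by the conversion factor; the
    true partition is unchanged."""
    return GeneTreeSample(
        gene_tree=sample.gene_tree.scaled(subs_per_coalescent_unit),
        true_partition=sample.true_partition,
        species_tree=sample.species_tree,
    )


# ------------------------------------------------------------------- datasets

def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[GeneTreeSample], dict]:
    """Simulate ``config.n_replicates`` independent (species tree, gene tree)
    pairs; one root seed is hierarchically split per replicate and the child
    seeds are recorded in the returned metadata."""
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_replicates)
    samples = []
    for child in children:
        rng = np.random.default_rng(child)
        st = yule_species_tree(config.n_species, config.birth_rate, rng)
        sample = msc_gene_tree(st, config.sampling, rng, config.time_scale)
        samples.append(
            scale_to_substitutions(sample, config.subs_per_coalescent_unit)
        )
    metadata = {
        "config": config.to_dict(),
        "replicate_seeds": [list(c.generate_state(2).tolist()) for c in children],
    }
    return samples, metadata


# ---------------------------------------------------------------- calibration

def within_among_ratio(samples: Sequence[GeneTreeSample]) -> float:
    """Mean within-species / mean among-species branch length, pooled.

    A gene-tree edge counts as within-species iff every tip below it belongs
    to one true species; all other edges are among-species.
    """
    within: list[float] = []
    among: list[float] = []
    for sample in samples:
        tree = sample.gene_tree
        truth = sample.true_partition
        species_below: dict[int, set] = {}
        for nid in tree.postorder():
            if tree.is_leaf(nid):
                species_below[nid] = {truth[tree.label(nid)]}
            else:
                acc: set = set()
                for c in tree.children(nid):
                    acc |= species_below[c]
                species_below[nid] = acc
            if nid != tree.root_id:
                (within if len(species_below[nid]) == 1 else among).append(
                    tree.edge_length(nid)
                )
    if not within or not among:
        raise ValueError("cannot compute ratio: an edge class is empty")
    return (sum(within) / len(within)) / (sum(among) / len(among))


def calibrate_time_scale(
    n_species: int,
    birth_rate: float,
    sampling: EvenSampling | UnevenSampling,
    target_ratio: float = 0.15,
    n_reps: int = 16,
    seed: int = 0,
    n_iter: int = 8,
) -> float:
    """Pick the species-time scale whose simulated within/among mean
    branch-length ratio matches ``target_ratio``.

    Fixed-point iteration on scale <- scale * ratio/target.  The ratio decays
    slightly slower than 1/scale (among-species gene-tree edges carry a
    scale-free coalescent overhead), so several iterations are needed; the
    same replicate seeds are reused at every iteration, making the result
    deterministic in ``seed``.
    """
    scale = 1.0
    for _ in range(n_iter):
        cfg = SimulationConfig(
            n_species=n_species,
            birth_rate=birth_rate,
            sampling=sampling,
            subs_per_coalescent_unit=1.0,
            time_scale=scale,
            n_replicates=n_reps,
            seed=seed,
        )
        samples, _ = simulate_dataset(cfg)
        ratio = within_among_ratio(samples)
        scale = scale * ratio / target_ratio
    return scale
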