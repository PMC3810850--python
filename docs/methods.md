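# Methods

## Model

PTP treats a rooted phylogeny's branch lengths (expected substitutions per
site) as draws from two independent exponential families. Along the paths
from the root down to the "species root" nodes of a delimitation, successive
branching events are speciations: waiting times (in substitutions) are
Exp(λ₁). Below a species root, branching is within-species and waiting times
are Exp(λ₂). A delimitation is any antichain of nodes covering every tip;
its edges split into k among-species and n−k within-species lengths, giving

L(λ₁, λ₂) = k ln λ₁ − λ₁ Σ_among x + (n−k) ln λ₂ − λ₂ Σ_within x,

maximized in closed form by λ̂ = class size / class length sum (inverse mean).
Assumptions worth stating: branch lengths are taken as substitution counts
exactly as inferred (no rescaling by alignment length); edges within a class
are treated as independent draws; and the tree must be correctly rooted,
because the among-class is defined from the root down. The library never
re-roots; `prune_taxa` is provided for outgroup removal, with unary nodes
suppressed by summing their incident edge lengths (a root left with one
child collapses into that child).

Degenerate delimitations — all tips one species ({root}) or every tip its
own species (all leaves) — leave one class empty, so Eq. above is undefined
on them. They are enumerated (they are genuine antichain covers and are part
of the delimitation count) but excluded from the two-class comparison; the
single-class null model represents them collectively, which matches the
test's interpretation: a non-significant LRT means "one species or all
singletons". On trees where only degenerate delimitations exist (a cherry, a
star) the driver returns the null model rather than erroring, since pipeline
use feeds many tiny per-branch trees.

With a fixed λ₁ (estimated once on a reference phylogeny), only λ₂ is
re-estimated per candidate delimitation; the single-species delimitation
then becomes scoreable (k = 0) but is still excluded from the search for
consistency.

## Search

The number of delimitations obeys D(leaf) = 1, D(node) = 1 + ∏_child
D(child) (big-integer arithmetic; the recursion and the enumerator are
cross-checked against each other in the tests). It equals m for an m-tip
caterpillar and grows fastest on balanced trees (26 at 8 tips, 677 at 16).
Below a cap (default 10⁵) the search is exhaustive and exact. Ties break
toward fewer species, then the lexicographically smallest sorted
species-root id list; node ids are preorder indices, so results are
deterministic and invariant to input leaf order.

Above the cap, a hill-climb starts from the children of the root and
repeatedly applies the best strictly-improving SPLIT (replace an internal
species root by its children) or MERGE (replace a complete sibling set of
species roots by their parent), stopping at a local optimum. A single start
proved insufficient: from the coarse initial state, the first splits are
often not individually improving (the within class is still a mixture of
both length classes, so λ̂₂ sits between them) and the climb stalls at 2–3
species. The default is therefore 5 starts — the initial state plus 4
seeded random antichain covers — keeping the best final state. On 500
random 8-leaf two-class instances (among Exp(10), within Exp(100)) this
matches the exhaustive optimum in ~93% of replicates and can never exceed
it; the seed affects restart initialisation only.

## Numerical choices

- Every edge length is floored at ε = 10⁻¹⁰ (configurable) before
  likelihood work; inferred trees contain zero-length branches that would
  otherwise give infinite rates.
- LRT statistics within 10⁻⁹ below zero are clamped to 0 (float noise);
  larger violations raise.
- Multifurcations are preserved end to end: the antichain definition, the
  count recursion (∏ over all children) and edge classification generalize
  unchanged.
- Scale covariance holds exactly: multiplying all lengths by c divides both
  rate estimates by c and shifts every delimitation's log-likelihood by
  −n ln c, so the arg-max is scale-invariant (property-tested).

## Simulator

`yule_species_tree` grows a pure-birth tree: with j lineages the next
speciation waits Exp(j·b′); after the n-th lineage one further waiting time
places the present, so for n = 2 the expected root age is 1/(2b′).
`msc_gene_tree` runs the standard backward-time multispecies coalescent:
within a population, j lineages coalesce at rate j(j−1)/2 per coalescent
unit; lineage sets merge at species divergences; the root population runs to
a single lineage. The true species of every tip is recorded. Sampling is
either even (k per species) or grouped-uneven (e.g. 2×100, 4×50, 8×10,
16×2 over 30 species). One root seed is split hierarchically per replicate
and recorded in the output metadata.

Units and the species-depth scale. Species-tree time and coalescent time
share one unit (2N generations), with b′ per coalescent unit. What governs
delimitability is species separation *relative to* coalescent depth; under
the shared-unit convention alone, b′ ≥ 5 puts species divergences far below
the coalescent scale and lineage sorting destroys the species signal
entirely. `msc_gene_tree` therefore exposes `time_scale`, a multiplier on
species divergence times, and `calibrate_time_scale` fixes it by a
deterministic fixed-point iteration so that the simulated mean
within/among branch-length ratio hits a target — 0.15 by default, the
ratio exhibited by the worked-example tree. Calibrated at b′ = 5 and held
fixed, raising b′ then compresses species divergences toward the coalescent
scale, which is exactly the "shrinking barcoding gap" regime: delimitation
accuracy (NMI against the truth) degrades monotonically with b′. The ratio
decays slightly slower than 1/scale (among-species gene-tree edges carry a
scale-free coalescent component), hence the default of 8 iterations on a
16-replicate pilot.

Benchmark conditions used in the accuracy-trend test: 10 species × 5
individuals, 20 replicates per birth rate, b′ ∈ {5, 160}, time scale
calibrated at b′ = 5, substitutions at 0.05 per coalescent unit (delimitation
is scale-invariant, so this only sets realistic absolute branch lengths).
These sizes keep the whole suite in seconds while leaving the qualitative
contrast large; measured means were ≈0.91 (b′ = 5) vs ≈0.63 (b′ = 160).

What the simulator does and does not emulate: it produces true gene trees
under Yule + MSC, so passing tests show the model and search recover species
when the two-class structure is present and degrade gracefully as it
vanishes. It does **not** simulate sequences or re-infer trees, so
inference error (finite alignment length, model misspecification, rooting
error) is absent; an accuracy on these gene trees is an upper bound on what
a full sequence-level pipeline would achieve. No migration, no indels, no
per-species population-size variation.

## Evaluation

NMI between the inferred and true partitions is computed from the
contingency table with natural-log entropies and geometric-mean
normalization, NMI = MI/√(H_a·H_b) (the arithmetic-mean variant is available
via a flag for cross-tool comparison). Degenerate conventions: both
partitions trivial → 1; exactly one trivial → 0. The implementation is
checked against an independent brute-force entropy computation to 1e−12 and
property-tested for symmetry, label invariance and range.

## Known limitations

- Single λ₂ class: heavily oversampled species with tiny within-species
  variation can drag λ̂₂ and cause over-splitting of sparsely sampled
  species; a multi-class extension is out of scope.
- The hill-climb is a local search; ~7% of small two-class instances end in
  a local optimum. Raising `restarts` trades time for quality.
- Rooting errors propagate directly into the among-class definition; the
  package deliberately refuses to guess a root.
- The species-depth calibration targets a summary statistic (mean length
  ratio) and reproduces it only up to Monte Carlo spread (~±25% on held-out
  replicate sets at the default pilot size).
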