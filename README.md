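# ptpdelim

Single-locus species delimitation with the **Poisson tree processes (PTP)**
model: given a rooted phylogeny whose branch lengths are expected
substitutions per site, find the maximum-likelihood partition of tips into
putative species — no ultrametric calibration, no similarity threshold.

The package is aimed at DNA-taxonomy and metabarcoding work: delimiting
putative species on single-gene trees, tagging delimited species as known or
new against a reference tip set, and benchmarking delimitation accuracy on
simulated multispecies-coalescent data.

## The model

Speciation is modelled directly in substitutions: each substitution carries a
small probability of triggering a speciation, so the number of substitutions
until the next speciation event is exponentially distributed. Within a
species, branching events (analogous to coalescences) follow a second,
independent Poisson process. A *delimitation* is an antichain of
"species-root" nodes covering every tip; it splits the tree's edges into
among-species lengths x₁…x_k and within-species lengths x_{k+1}…x_n, with
log-likelihood

    L = k·ln λ₁ − λ₁·Σ_among x  +  (n−k)·ln λ₂ − λ₂·Σ_within x

where the ML rates are the inverse mean branch lengths of each class, λ₁ =
k/Σ_among x (speciations per substitution) and λ₂ = (n−k)/Σ_within x. The
search maximizes L over delimitations — exactly by enumerating all antichain
covers when their number (computed by the recursion D(leaf)=1, D(node)=1+∏
D(child)) is small, and by a seeded SPLIT/MERGE hill-climb otherwise. A
likelihood-ratio test with one degree of freedom compares the two-class fit
against a single exponential fitted to all branches; a large p-value means
the tree shows no among/within contrast (all tips one species, or every tip
its own species).

Also included: a fixed-λ₁ mode (estimate the speciation rate once on a
reference phylogeny, then only fit λ₂ per query tree), a Yule +
multispecies-coalescent simulator producing gene trees with known true
species partitions, and normalized mutual information (NMI) for scoring a
delimitation against that truth.

## Worked example

The built-in 7-tip example tree has one singleton species (C) and three
two-individual species (D, E, F):

```sh
python -c "from ptpdelim import example_newick; print(example_newick())" > example.nwk
ptpdelim delimit example.nwk
```

prints the species table and summary:

```
species_id  leaf_label  tag
1           C           NA
2           d1          NA
2           d2          NA
3           e1          NA
3           e2          NA
4           f1          NA
4           f2          NA

species_count        4
lambda1              8.333333333333334
lambda2              55.04587155963303
logL                 24.770582413086835
null_lambda          14.475271411338962
null_logL            20.06930128361811
lrt_statistic        9.40256225893745
p_value              0.002166824184937238
search_mode          exhaustive
evaluations          14
delimitation_count   16
```

Reading this: of the 16 possible delimitations of this tree, the best
two-class fit (log-likelihood 24.77) recovers the four species with an
estimated speciation rate λ₁ ≈ 8.33 and within-species branching rate λ₂ ≈
55.05 per substitution — within-species branches are about 6.6× shorter on
average. The LRT rejects the single-class null (p ≈ 0.002), so the two
branch-length classes are real.

The same from Python:

```python
from ptpdelim import delimit, example_tree

result = delimit(example_tree())
print(result.n_species)          # 4
print(result.best_fit.logL)      # 24.770582413086835
print(result.species)            # [{'C'}, {'d1','d2'}, {'e1','e2'}, {'f1','f2'}]
```

Other subcommands: `ptpdelim count` (exact delimitation count),
`ptpdelim simulate` (MSC gene trees with truth TSVs), `ptpdelim nmi`
(compare two partition files).

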