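# Methods

## Model overview

`grnevolve` simulates populations of haploid, clonally reproducing
virtual organisms. A genotype has two coupled layers:

* a **coding genome** of *n* genes × *l* bp (*l* a multiple of 3), and
* a **regulatory genotype**: interaction matrix **R** (*n* × *n*,
  R\[i,j\] = effect of gene *j*'s product on gene *i*; dimensionless),
  activation thresholds **θ** (arbitrary quantity units) and per-step
  exponential decay rates **λ** (per developmental step), both ≥ 0.

The phenotype is the expression matrix **E** (*n* × *m*) produced by the
development recursion

q_t = ( ReLU_θ( R·q_{t−1} ) + q_{t−1}·e^{−λ} ) ∗ c,

seeded with quantity 1 for the first gene and 0 elsewhere. The rectifier
zeroes any input signal *strictly below* a gene's threshold (a value
exactly at θ passes). **c** is the coding mask: 0 for a gene with an
in-frame stop codon anywhere in its sequence, 1 otherwise, recomputed
from the sequence each time (a reverted stop restores the gene). The
seed quantity is injected at step 0, *before* the first application of
**c**: the seed gene therefore drives its targets at step 1 — and counts
as expressed — even when its own reading frame is broken. Gene *i* is
"expressed" iff q0\[i\] > 0 or E\[i,t\] > 0 at any step; under that single
definition the seed gene is always expressed and a fully silent system
(zero seed, zero trajectory) has no active links.

Development assumes monoexonic single-isoform genes and purely
transcriptional regulation; there is no expression noise and no
continuous-time variant.

## Mutation and the sequence→regulation coupling

Each base mutates independently with probability μ per generation
(sampled as a Binomial(*nl*, μ) count with uniform distinct placements);
the replacement base is uniform over the other three nucleotides
(Jukes–Cantor; no site-rate heterogeneity, no ts/tv bias). Events are
classified synonymous / nonsynonymous / nonsense against the codon state
immediately before each event, so two hits in one codon in one
generation see each other. Indels, duplications and recombination are
out of scope.

Every synonymous or nonsynonymous event in gene *g* triggers **exactly
one** regulatory mutation among gene *g*'s 2+*n* candidate scalars: the
*n* entries of row *g* of **R** (gene *g*'s incoming links, one per
source gene), θ_g and λ_g. Allocation:

* with probability 2/(2+*n*): θ_g or λ_g, each with probability 1/(2+*n*);
* otherwise one row-*g* entry, chosen uniformly among links whose
  **source** gene is expressed in the *parent's* E for a nonsynonymous
  event, or among unexpressed-source links for a synonymous one (silent
  "under the hood" rewiring that only becomes visible if the source gene
  is later activated);
* if the eligible link class is empty, the hit is redirected to θ_g or
  λ_g (equal probability) so the 1–1 coupling is never broken.

Row *g* is the only candidate set under which the active/inactive-source
distinction is meaningful: all of gene *g*'s *outgoing* links share the
same source (*g* itself), so distinguishing them by source activity would
be degenerate. The 2/(2+*n*) denominator counts the same 2+*n*
candidates either way.

The mutation kernel resamples the hit scalar uniformly from its
initialisation range (default). This keeps parameters in-range, keeps
θ/λ nonnegative by construction, and makes the drifting genotype's
stationary distribution equal the founder distribution — convenient for
neutral controls. An additive-Gaussian kernel (`mutation_kernel =
gaussian`, scale `gaussian_sigma`, θ/λ clipped at 0) is available for
studies of incremental regulatory change. Structurally zeroed (masked)
cells of **R** remain mutable, so network topology can evolve.

Nonsense events change no regulatory scalar: the silencing acts through
**c**, and the untouched parameters become functional again if the stop
reverts.

## Fitness

Four components, each in \[0, 1\], scored on **E** with window
*w* = `stability_window` (default *m*/5, at least 1):

* **boundedness** — terminal growth ratio
  g = Σ_i E\[i,m\] / (Σ_i E\[i,m−w\] + ε), ε = 1e−12. Score 1 for
  g ≤ 1, else max(0, 1 − (g−1)/`growth_cap`). A ratio penalty is robust
  and monotone where exponential curve-fitting would be fragile on short
  trajectories. Non-finite trajectories (double-precision overflow
  during development is carried, not raised) score 0.
* **participation** — fraction of genes expressed.
* **stability** — 1 / (1 + mean CV), the coefficient of variation of each
  expressed gene's quantities over the final *w* steps (never-expressed
  genes excluded; a gene flat at zero over the window contributes CV 0).
  Late-window CV distinguishes an attractor from a transient.
* **maturity** — 1 iff a designated marker gene (default: the last gene)
  exceeds `maturity_threshold` at some step *and* has positive quantity
  at step *m*; else 0.

Total fitness = maturity × boundedness × participation × stability: a
product makes any catastrophic failure fatal and maturity a hard gate.
The combination rule and component formulas are this package's own
concrete choices for the four criteria; alternatives (e.g. additive
weighting) would reorder intermediate genotypes but preserve the gate.

## Genetic algorithm and phylogeny traversal

Each generation: k = ⌈pN⌉ survivors are chosen — the k highest total
fitnesses under `high_pressure` (ties broken uniformly at random to
avoid index bias) or k uniform draws without replacement under `relaxed`
— and N offspring are produced round-robin over the survivors, so each
parents ⌊N/k⌋ or ⌈N/k⌉ children. Every organism's expression and fitness
are recomputed at creation; population size is conserved exactly.
Traces record mean fitness components and per-gene participation at
generation 0, every `trace_every` generations, and the final generation.

Branch lengths of the input Newick tree are nonnegative **integer
generation counts** (fractional lengths are rejected rather than
rounded, keeping time and rate separate). The founder population consists
of N fully independent random organisms — a variable founder population,
so founder-level variation in gene participation is representable;
clonal founding can be emulated with N = 1 plus a zero-length root
branch. At each split the end-of-branch population is deep-copied into
every child. Per-branch parameter overrides merge over the base
configuration. All randomness derives from one master seed through named
substreams (SHA-256 of the branch's root-path, mixed into a
`SeedSequence`), so results are bit-reproducible and independent of
traversal order.

## Default parameters

| parameter | default | units / meaning |
|---|---|---|
| μ (`mu`) | 5.33333e-6 | point mutations per base per generation; a conservative rate for a ~15 kb genome, giving ≈0.107 subs/site over 20,000 generations |
| *p* | 0.1 | surviving proportion per generation |
| N | 100 | population size |
| *m* (`dev_steps`) | 20 | developmental steps; long enough for a 5-gene cascade to reach an attractor or visibly diverge |
| R range | (−2, 2) | spans repression and activation; magnitudes > 1 allow signal amplification so both growth and silencing are reachable |
| sparseness | 0.25 | expected masked fraction of R (i.i.d. Bernoulli per cell; `exact_sparseness` masks an exact count) |
| θ range | (0, 1) | below the seed quantity 1, so a direct seed→target link of moderate strength can fire |
| λ range | (0, 2) | e^{−λ} per-step retention between 0.14 and 1 |
| maturity threshold | 1.0 | the seed quantity: the marker must be driven at least as high as the input |
| growth cap | 1.0 | boundedness hits 0 when late totals double within one window |

## Validation experiments and problem sizes

The test suite runs the full pipeline at reduced problem sizes chosen so
the whole suite completes in a few minutes:

* **Neutral calibration** — 20 replicates of a 5-gene × 3000 bp founder
  evolved along two independent 1,000-generation lineages at
  μ = 5.3333e-5 (10× rate, 1/10 generations: same rate-time product
  0.10667 as the reference setting), N = 1, random survival, coupling
  active. The mean genome-wide JC-corrected tip distance must match
  μ × 2000 within 3 standard errors. `scripts/acceptance.py` recomputes
  exactly this quantity.
* **Selection contrast** — 20 replicates of N = 50, 2 genes × 300 bp,
  μ = 2e-4, *m* = 10, 1,000 generations: mean fitness must rise under
  truncation selection in ≥18/20 replicates, and show no significant
  positive trend under random survival (one-sided t-test, α = 0.05).
* **Topology recovery** — 20 neutral replicates on a symmetric 4-tip
  tree (branches of 500 generations, settings as in the calibration):
  per-gene neighbor-joining trees from the tip alignments must match the
  input topology in ≥18/20 replicates.

The synthetic organisms emulate the statistical structure the model
assumes — uniform sense-codon usage, uniform regulatory values, no
site-rate heterogeneity, no linkage to external environments. Passing
these checks shows the simulator's internal consistency (rates, coupling
bookkeeping, selection response, tree signal); it does not show that real
genomes satisfy the model's assumptions (no indels, clonal reproduction,
single-isoform transcriptional regulation).

## Numerical notes and limitations

* Quantities are doubles; runaway trajectories (possible with strong
  positive feedback) propagate to inf/nan inside an `errstate` guard and
  are scored as maximally unbounded instead of raising.
* JC distance correction is undefined at p ≥ 0.75 and raises a
  saturation error; callers see the offending p.
* Fitness ties in truncation selection are broken uniformly at random;
  with many zero-fitness organisms this matters and is the only
  stochastic element of selection under `high_pressure`.
* Mid-branch parameter changes are available through the API (split a
  branch and run `run_branch` twice), not through tree annotations.
* Populations are panmictic within a branch; no migration between
  branches after a split.
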