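# Methods note

This note records the models implemented in `ddnetmap`, the defaults and
the reasoning behind them, what the synthetic generators do and do not
emulate, and the numerical choices that matter for reproducibility.

## Network propagation

The propagation operator is a random walk with restart. Let `A` be the
weighted adjacency of the undirected gene network (duplicate edges keep
the maximum weight; self-loops are dropped; isolated genes are excluded)
and `W` its column-normalized form, `W[i,j] = A[i,j] / colsum(A)[j]`.
With restart probability `1 − α` to the uniform seed vector `Y₀`
(total mass 1 over the seed genes), the stationary heat is

```
F = (I − αW)⁻¹ (1 − α) Y₀
```

Because `W` is column-stochastic, `sum(F) = 1` exactly; the test suite
enforces conservation to 1e-10. The linear system is solved by sparse LU
factorization (`scipy.sparse.linalg.splu`); the factorization is reused
across the null ensemble, and the residual of each solve is checked
against `solver_tol` (1e-10). An independent fixed-point iteration
`F ← (1 − α)Y₀ + αWF` is shipped as a cross-check oracle and agrees with
the direct solve to better than 1e-8 on random graphs.

Defaults: `α = 0.5` (equal weight to restart and diffusion — heat stays
local to the seeds while still reaching their neighborhood),
`n_null = 100`, `nps_threshold = 3`.

## Degree-matched null and NPS

Propagation heat is strongly degree-dependent, so observed heats are
calibrated against random seed sets that preserve the seed set's size
and degree profile. Genes are binned into 10 equal-width bins of
log10(degree + 1); bins with fewer than 2 members are merged into the
nearest bin. Each null set replaces every seed with a uniform draw from
the seed's bin, without replacement within a set, and a null set equal to
the exact seed set is rejected and redrawn. For gene *i* with observed
heat `F_i` and null heats `f_i^(1..m)`:

```
NPS_i = (ln F_i − mean(ln f_i)) / sd(ln f_i)        (population sd, ddof = 0)
```

Logs are used because propagation heats span orders of magnitude and
their logs are far closer to normal. Genes with zero observed heat are
excluded and flagged `zero_heat`; genes whose null heats are constant
are excluded and flagged `degenerate_null`. Selection is strict:
`NPS > threshold`. On held-out degree-matched sets the pooled NPS is
approximately standard normal (seed 1 run: mean 0.028, sd 1.004 over
4,000 gene scores), confirming the null is calibrated.

## Persistent multiscale hierarchy

The seed-proximal subnetwork (selected genes plus seeds) is partitioned
at each resolution `γ` of a grid (default 0.5, 1.0, …, 5.0) with a
seeded Leiden optimizer of the Reichardt–Bornholdt configuration-null
quality function, iterated to convergence (`n_iterations = -1`) so the
result is deterministic for a fixed seed. Blocks at consecutive
resolutions are matched one-to-one by greedy best-first Jaccard
similarity with threshold 0.75; a maximal matched chain's length is the
community's *persistence*, and chains of length ≥ 5 (half the grid)
become persistent communities, taking their gene set from the chain's
first (coarsest) resolution.

Blocks smaller than `min_size = 2` are excluded before chaining:
singleton blocks are not communities in any meaningful sense (they admit
no internal edge and cannot be enrichment-tested informatively), yet at
high resolution the quality function ties between keeping and splitting
small groups, which would let singletons persist for long stretches of
the grid.

The hierarchy is a DAG: parent `w` → child `v` whenever the containment
index `CI(v, w) = |v ∩ w| / |v|` strictly exceeds 0.75 and
`|v| < |w|` (the strict size condition rules out cycles). Equal-size
communities with mutual containment are merged, keeping the
earlier-resolution identity. `networkx.transitive_reduction` removes
implied edges (idempotent by construction), and a synthetic `root` node
spanning all subnetwork genes is added when more than one community
would otherwise be parentless; the root is excluded from enrichment by
default.

## Enrichment

For a community of size `n` and a trait set of size `K` (after
intersection with the universe of `N` genes; default universe = all
network genes) with overlap `a`, the p-value is the hypergeometric upper
tail `P(X ≥ a)` computed via `scipy.stats.hypergeom.sf(a − 1, N, K, n)`.
Odds ratios use the Haldane–Anscombe 0.5 correction when any cell of the
2×2 table is zero. q-values come from the Benjamini–Hochberg step-up
procedure applied over the full family of community × trait tests
(cross-checked against `statsmodels` in the test suite and verified to
control the null false-discovery proportion at ≤ 0.07 for nominal 0.05
over 1,000 seeded uniform-null replicates).

## Questionnaire scoring

Each of the 27 MCQ items implies an indifference rate
`k_item = (A_delayed / A_immediate − 1) / D`. Candidate rates are built
from the sorted distinct implied rates (values equal to within 1e-9
relative are collapsed first — two bank items share the exact rational
rate 1/6318 and differ only in floating-point rounding): the geometric
midpoints of consecutive rates, plus one candidate below and one above
the range by the same geometric spacing. A choice is *consistent* with
candidate `k` if the participant chose delayed when `k < k_item` or
immediate when `k > k_item`; exact boundary ties count as consistent
either way, and missing responses are excluded from the denominator.

The overall estimate `k_overall` is the geometric mean of the candidates
maximizing consistency over **all** answered items — the overall
response pattern, matched by an exhaustive grid-search oracle in the
tests. Per-magnitude-bin rates (`k_small`/`k_medium`/`k_large`, by
delayed amount ≤ 35 / ≤ 60 / larger) are the analogous plateau geometric
means within each bin. All-delayed (all-immediate) responders are pinned
to the smallest (largest) candidate with reason `floor_estimate`
(`ceiling_estimate`); such estimates are range bounds, not point
estimates. QC fails a participant for consistency < 0.75, more missing
items than allowed (default 0), or a uniform response vector. For
noiseless simulated responders with on-grid rates, recovery in log10
space is exact to machine precision — well within the half-grid-step
(0.105) resolution limit of the item bank.

## Synthetic generators

The planted network is a stochastic block model: contiguous near-equal
blocks, within/between-block edge probabilities (defaults 200 genes, 4
communities, 0.15 / 0.01), and uniform edge weights in [0.5, 1.0]. It
reproduces the features the pipeline is sensitive to — community
structure, degree heterogeneity, weighted edges — but *not* the
scale-free degree distribution, size, or functional annotation structure
of real gene networks; absolute NPS values and enrichment significances
on synthetic data are therefore not comparable to real-data runs. Seed
sets are drawn from one planted community with a purity parameter; trait
sets take exact rounded fractions from designated communities with the
remainder drawn outside all constrained communities, so the planted
overlap is exact. Simulated respondents choose by a logistic rule on the
hyperbolic value difference with a noise temperature; temperature 0 is
the deterministic chooser (value ties go to the delayed option).

## Determinism and numerics

Every stochastic step takes an explicit integer seed; the pipeline
derives stage behavior from the single `rng_seed` in the run
configuration, and all stage TSVs are written with `%.10g` formatting,
so reruns with the same inputs and seed are byte-identical (enforced by
an acceptance test). Community detection determinism relies on the
seeded, converged Leiden optimizer plus deterministic tie-breaking
(sorting by size, then lexicographic gene sets) in block ordering, chain
matching, and community numbering.

## Limitations

- NPS thresholding at 3 is a fixed convention, not an FDR-calibrated
  cutoff; the number of selected genes depends strongly on network
  density and seed coherence (on sparse synthetic presets few or no
  non-seed genes may pass).
- Persistence and containment thresholds (0.75/5) are heuristics; very
  small subnetworks yield few communities and wide confidence in none.
- MCQ estimates are bounded by the item bank's grid resolution (about
  0.1 log10 units at best) and are interval bounds, not point estimates,
  for uniform responders.
- Enrichment treats gene sets as unordered and ignores edge weights
  and gene-level covariates (e.g., gene length or LD structure) that
  real GWAS-derived sets inherit.
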