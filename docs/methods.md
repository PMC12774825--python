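# Methods

## Model

The sequentially Markov coalescent (SMC) is described here backwards in
time. The state at time `t` is a set of lineages, each labelled and
carrying a half-open genomic interval of material ancestral to the sample.
Two event types compete:

* **Recombination**, a Poisson process of rate `r` per link per generation
  over the splittable links of all lineages; a recombination at breakpoint
  `x` splits one lineage into a left part `[a, x)` and a right part
  `[x, b)`, conserving total ancestral material.
* **Coalescence** at rate `λ(t) = 1 / (2 Ne(t))` per *coalescible pair*.
  Lineages are strictly ordered by `(left endpoint, label)`; lineage `k`
  can coalesce into a later lineage `j` iff `j`'s left endpoint lies inside
  `k`'s interval. Each overlapping pair is therefore counted exactly once,
  and a recombination changes *which* lineages may coalesce into a given
  surviving lineage but not *how many* — the property that makes the
  backwards-time bookkeeping per-edge decomposable.

### The per-edge likelihood

Given an ARG as node/edge tables, the log-likelihood at `(r, λ)` is

```
n_RE log r + n_CA log λ + Σ_e [ log A_e(r) + log B_e(r, λ) ]
```

with the terms as defined in the README. Design points that matter:

* **Edge total order and overlap.** "Earlier edges overlapping `e`" is read
  as earlier edges whose genomic interval contains `e`'s *left endpoint*
  `x`, mirroring the lineage-order condition of the process (the rate at
  which a lineage coalesces is driven by what covers its left endpoint).
  Edge time support is half-open `[t_c, t_p)`.
* **Event counts, not raw degrees.** `n_RE` counts edges *initiated by a
  recombination breakpoint*: non-leftmost edges with a same-child edge
  ending exactly at their left coordinate. `n_CA` counts, per node, its
  distinct children minus one. On ARGs whose per-child edges tile a
  contiguous interval these equal the degree-based forms
  `|E| − |N| + n_roots` and `|E| − |N| + n_leaves` (which
  `degree_log_factor` reports). They differ on event-complete ARGs whose
  lineages carried multi-segment ancestral material (e.g. msprime
  `record_full_arg` output, where material past its local MRCA is
  stripped): there, two same-child edges separated by a genomic gap record
  one inheritance over split spans, not an extra recombination. Counting
  them as recombinations inflates the `r` exponent by ~25% at
  chromosome scale and visibly biases the rate MLE; with breakpoint-based
  counting the MLE on such input is within ~1% of truth and the `r`
  exponents of the per-edge and event-based (KYF) likelihoods agree
  exactly, which is what makes their ratio curves coincide.
  Correspondingly, a non-leftmost edge *without* an adjacent left
  neighbour (its child is a local root just left of it) carries no `r`
  factor and a plain survival `B` term — this is also what makes fully
  simplified ARGs evaluable.
* **Closed forms in log space.** On each constant piece of `I_e` the
  breakpoint-time integrand is a single exponential and is integrated
  analytically; pieces are combined by log-sum-exp. The kernel
  `log ∫_a^{a+d} e^{g s} ds` switches to the series
  `x/2 + x²/24, x = g d` when `|x| < 1e-6` (the `r ≈ λ k` degenerate
  case), giving ≤1e-18 relative error at the switch point. Zero-length
  edges (parent and child at equal times) make the log-likelihood exactly
  `−inf`; polytomies are handled by the event-count exponents as unresolved
  chains of zero-waiting mergers.
* **Complexity.** A single left-to-right sweep over edge left endpoints
  maintains the set of edges covering the current position (retired via a
  heap on right coordinates): `O(|E| log |E|)` plus output size, with a
  brute-force pairwise oracle as the correctness contract in the tests. A
  13,000-edge chromosome-scale ARG builds its evaluator in ~2 s and each
  additional `(r, λ)` evaluation is a vectorised pass (~0.1 s), so
  parameter grids are cheap.

### Time slicing and piecewise Ne

`time_slice` cuts each edge spanning a boundary by inserting a virtual
pass-through node (one per `(parent, child, boundary)`, so split-span edge
pairs share it). Virtual nodes are flagged, and a flag records whether the
cut edge was non-leftmost so the eligible-link convention survives slicing;
sub-edges above a virtual node contribute plain survival terms, with the
breakpoint-time integral confined to the slice containing the original
child (upper limit `min(t_p, t_p', slice end)`). Event-count exponents then
sum over slices to the whole-ARG exponents, and the summed per-slice
log-likelihood equals the unsliced value exactly whenever no
breakpoint-time integral's domain crosses a boundary; otherwise it is the
product-of-slices approximation.

`slice_posterior` evaluates each slice independently over an `Ne` grid
(uniform prior, log-space normalisation). Because truncating the
breakpoint-time integrals at a slice's upper boundary discards probability
mass in a `λ`-dependent way, the per-slice posterior mode is a slightly
conservative coalescence-rate estimate: in calibration runs at constant
`Ne` with 40 haploid samples on 10 kb, sliced modes ran ~5–10% above truth
in the lower slices and correspondingly below in the oldest slice, while
the unsliced posterior mode was median-unbiased. This is the cost of the
per-slice factorisation itself, shared by the sliced-inference experiment
the package replicates, and shrinks with the amount of data per slice.

### Event-based comparator

`kyf_log_likelihood` is the classical full-detail likelihood, reconstructed
from tables: it requires every lineage to end at a single dated event (all
parent edges of a node at one time) and charges `log λ` per coalescence,
`log r` per recombination, and the integrated hazard
`r B(t) + λ k(t)(k(t)−1)/2` between events, with `B(t)` accumulated with
the same per-edge link convention as `A_e` so the `r`-dependence of the two
likelihoods matches term for term. The `λ` side differs by construction
(all pairs vs overlapping pairs), which cancels in ratio curves over `r`.

## Simulator

The simulator is the generative counterpart of the model and produces the
test fixtures. Lineages internally carry segment lists; at each
coalescence, positions for which the merged lineage is the only remaining
carrier have reached their local MRCA and are dropped from further
tracking (a per-position carrier-count array makes this exact), so a
lineage occasionally carries more than one segment and the emitted edges
record each segment. Recombination draws a lineage proportional to its
splittable links and a uniform integer breakpoint strictly inside a
segment; both resulting parents are recorded as flagged recombination
nodes at the same time, in the two-node convention. Coalescence picks a
uniform coalescible ordered pair (SMC) or a uniform pair (Hudson, where
lineages are genuinely multi-interval and all pairs may coalesce).
Piecewise-constant `Ne` is handled by piecewise-exponential waiting-time
sampling with boundary clipping. The run stops when no coalescible pair
remains, leaving one root lineage per locally-MRCA'd span.

The no-stripping idealisation in which each lineage keeps a single
contiguous interval forever was implemented first and rejected: it keeps
generating recombinations on material that no longer segregates, inflating
the local-tree count at chromosome scale by ~20% relative to both the
standard coalescent machinery and the first-order expectation
`1 + r L · 4 Ne · H_{n−1}`, which the stripped implementation matches.
Consequences for tests: simulated fixtures reflect the standard
(local-MRCA-stopped) SMC, so test passes speak to that process; features of
real data such as mutation-model violations, sequencing error, and ARG
*inference* error are outside what the generator emulates (mutations, when
requested, are ideal infinite-sites Poisson drops on edges).

## Problem sizes and defaults

* Chromosome-scale replication (acceptance script): 200 haploid samples,
  1 Mb, `r = 1.25e-8`, `Ne = 10,000` — 10 replicates for the tree count,
  5 for the rate MLE (bracket `r/4 … 4r`, tolerance 1e-3 in `log10 r`).
* Sliced-Ne replication: 40 haploid samples, 10 kb, Hudson mode, epochs
  10,000 / 5,000 / 10,000 with changes at 1,000 and 5,000 generations;
  61-point log-spaced `Ne` grid on `[10³, 10⁵]`, 100 replicates, median of
  per-replicate posterior modes.
* The test suite uses reduced sizes (stated in each test) with expectations
  scaled by the same first-order formulas.

## Known limitations

* The likelihood is the SMC form only (no SMC′ adjacency coalescence); no
  migration, gene conversion, or multiple populations anywhere.
* Eligible-link counting follows the printed per-edge convention
  (`y − x` leftmost, `y − x − 1` otherwise); summed over a split child
  lineage this gives `y − x_c − 1` links, one fewer than the continuous
  rate description's `y − x_c` — an off-by-one of order `1/L` in the rate
  scale, immaterial at realistic genome lengths.
* The breakpoint-time integral uses absolute time in the `e^{−r s}` factor,
  as the per-edge decomposition defines it.
* Per-slice posteriors inherit the factorisation bias quantified above;
  joint multi-epoch inference (one likelihood, piecewise `λ`) would avoid
  it but is a different experiment and is not implemented.
* The likelihood expects each child's edges to be genomically disjoint;
  ARGs with contradictory inheritance statements are rejected by
  validation.
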