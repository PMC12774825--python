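# argsmc

SMC likelihoods, simulation and inference for general ancestral
recombination graphs (ARGs).

An ARG records who inherited which genomic segment from whom: a node table
(haploid genomes with times, in generations) and an edge table of
statements *"child c inherited [left, right) from parent p"*. Modern
scalable ARG inference tools output exactly this — but typically **without**
the precisely dated recombination events that the classical event-by-event
(Kuhner–Yamato–Felsenstein-style) likelihood requires. This package
computes the likelihood of such an ARG under the backwards-time sequentially
Markov coalescent (SMC) directly from the node/edge tables, integrating
over the unobserved recombination times.

For an ARG `G = (N, E)` with recombination rate `r` (per bp per
generation) and pairwise coalescence rate `λ = 1/(2 Ne)`:

```
L(G | r, λ) = r^{n_RE} · λ^{n_CA} · ∏_{e ∈ E} A_e(r) · B_e(r, λ)

A_e(r)    = exp(−r · links_e · (t_p − t_c))          no recombination on the edge
B_e(r, λ) = exp(−λ F(e, t_c, t_p))                    leftmost edge of its child
          = ∫_{t_c}^{t_p ∧ t_p'} e^{−r s} e^{−λ F(e, s, t_p)} ds   otherwise
```

where `links_e` counts the edge's eligible recombination links
(`y − x` for the leftmost edge above a child, `y − x − 1` otherwise),
`I_e(t)` counts the earlier edges (total order by `(left, child)`) whose
interval contains the edge's left endpoint and that exist at time `t`, and
`F(e, s, t) = ∫_s^t I_e(z) dz` is the cumulative coalescence hazard. `n_RE`
and `n_CA` count the recombinations and coalescences the tables imply.
Everything is evaluated in log space with exact piecewise closed forms;
no explicit recombination nodes are needed, and the computation is robust
to polytomies and other structural degradation.

The package also provides:

* `simulate` — a backwards-time SMC simulator (plus a minimal Hudson mode)
  emitting fully event-resolved ARGs with two flagged nodes per
  recombination, and an event log;
* ARG transforms — `remove_recombination_nodes`, `fully_simplify`,
  `drop_internal_nodes` (polytomy creation), `time_slice`, `squash_edges`;
* inference — likelihood-ratio curves in `r` (`loglik_curve`), the rate
  MLE (`mle_r`), and independent per-time-slice grid posteriors for
  piecewise-constant `Ne` (`slice_posterior`);
* `kyf_log_likelihood` — the classical event-decomposed comparator for
  fully event-resolved ARGs;
* a thin CLI (`argsmc simulate|loglik|curve|slices|transform`).

## Worked example

From `examples/recombination_rate_mle.py` — simulate 50 haploid samples on
200 kb at human-like rates, then profile the likelihood in `r`:

```
r / r_true   log likelihood-ratio
    0.25        -280.72
    0.50         -86.64
    1.00           0.00
    2.00        -128.23
    4.00        -686.22

MLE: r_hat = 1.265e-08  (truth 1.250e-08, ratio 1.01)
```

The curve is maximised at the generating rate: the edge "areas" (where
recombination did not happen) and the overlap hazards (how long lineage
pairs could have coalesced but didn't) jointly identify `r`.
`examples/robustness_to_simplification.py` repeats this after degrading
the ARG:

```
variant                         edges  argmax(r)/r_true
full ARG                         3437      1.00
RE nodes removed                 1948      1.00
25% internal nodes deleted       1843      1.00
fully simplified                 2503      2.52
```

Dated recombination nodes are unnecessary — the locally unary spans of
coalescent nodes carry the same information — but stripping those unary
spans too ("fully simplified") biases the estimate away from the truth.
The other examples walk through the per-edge terms on a four-edge ARG and
infer a three-epoch `Ne` history from a single 10 kb ARG.

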