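# Methods

## Model and assumptions

The miner assumes a complex is a dense subgraph *organized around a kernel*:
a small set of high-degree, closely connected proteins whose removal would
disrupt the network (the centrality–lethality premise). Detection therefore
proceeds from the inside out — seed at hubs, extend in stages — rather than
by scanning for dense subgraphs wholesale.

The topology is converted once to directed weights `w_st = cn_st / d_s`.
Three consequences of the definition are used as internal invariants:
`w_st · d_s = w_ts · d_t = cn_st` exactly; `cn_st ≤ min(d_s, d_t) − 1` on a
simple graph (each endpoint is a neighbour of the other but not of itself),
hence every weight lies in `[0, 1)`; and weights exist only on ordered
adjacent pairs. Consumers that need "weight or zero" over arbitrary pairs
(the local average) go through an accessor that returns 0 for missing pairs,
keeping the all-ordered-pairs sum well defined. The common-neighbour pass
costs O(n·d_max²).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `pk` | 0.01 | fraction of nodes admitted as seeds; the degree threshold k is the smallest degree at which at most this fraction qualifies. 0.01 suits interactome-scale networks (thousands of nodes); on small networks it admits ~1 node and should be raised (the worked example uses 0.15 on 100 nodes). If even k = d_max leaves the fraction above `pk` (massive degree ties), d_max is used, so the seed set is never empty. |
| `w_init` | 0.8 | mutual-weight threshold for grouping adjacent seeds into kernels, and the threshold of the *first* extension stage, where the kernel has no meaningful local neighbourhood average yet. High values demand near-clique kernels. |
| `t_alpha` | 7 | cap on the extension level α. Mean predicted size against α is the tuning diagnostic (`mke alpha-sweep`); it plateaus once kernels stop growing, and the cap is dataset-specific. |
| `overlap_threshold` | 0.2 | intersection-over-union at which two mined complexes merge. A conventional overlap cut-off in the complex-mining literature; exposed because no canonical value exists. |
| `min_size` | 3 | complexes below this size are dropped; smaller "complexes" are not biologically meaningful. |

## Reconstruction choices in the mining loop

The stage-wise loop admits several readings; the package fixes them as
follows, chosen for internal consistency and determinism:

- **Kernel grouping is transitive.** Kernels are connected components of the
  mutual-threshold relation among adjacent seeds, not maximal cliques of it.
- **Batch addition.** Each stage adds *all* qualifying best neighbours at
  once; the per-stage added count ΔN is only meaningful under batch
  semantics.
- **Single witness.** A neighbour qualifies through one internal member with
  mutually sufficient weights — extension is node-to-node, not
  consensus-to-node.
- **Threshold comparisons use ≥** (equality admits), matching the formulas
  rather than the looser prose around them.
- **Stopping.** ΔN of the first extension is compared against the
  first-level kernel's own size; extension stops when ΔN_current <
  ΔN_prior, when ΔN_current = 0, or when α would exceed `t_alpha`. The
  stage that triggers the stop keeps its additions (its count is the last
  history entry). α never exceeds `t_alpha + 1`.
- **w_ave timing.** In stages after the first, the local average weight is
  computed once per stage, before the batch is added.
- **Merge order.** Largest overlap merges first; ties break on the
  lexicographically smallest member union, making the fixed point
  independent of input order.
- Nodes may appear in several kernels' extensions; overlap is expected and
  resolved only at the merge step.

The pipeline is a pure function of (graph, configuration): repeated runs are
byte-identical.

## Numerical choices

- Degree thresholding, kernel grouping and merging are exact integer/set
  operations; only the weights are floats, and each weight is a single
  division of the exactly stored integer `cn` by a degree.
- The enrichment P-value is the hypergeometric upper-tail sum evaluated in
  exact integer arithmetic (`math.comb` plus one rational-to-float rounding)
  and clamped to [0, 1]. A `1 − cdf` float route loses far tails to
  cancellation; published per-complex values on real interactomes reach
  10⁻⁹¹, so the tail must be computed directly. `scipy.stats.hypergeom`
  serves as an independent cross-check in the test suite.
- The minimal P-value over a complex's member terms is reported per complex,
  with no multiple-testing correction (the number of terms tested is
  returned so a Bonferroni factor can be applied externally).
- Degenerate inputs: an edgeless graph mines to an empty set; an isolated
  cluster has local average weight 0 (with a warning); PPV is a domain error
  when predictions share nothing with the reference, rather than silently 0.

## Co-localization enrichment: two readings

The per-complex ratio is the maximum fraction of members found in one
compartment, unlabelled members counting in the denominator. For the
set-level aggregate the displayed-formula reading — the *unweighted* mean of
per-complex ratios — is the default; the size-weighted alternative
`Σ_j max_i l_ij / Σ_j N_j` (suggested by the prose description of the
measure) is available via `weighted=True` / `--coloc-weighted`. Both are
reported when asked; they differ only when complex sizes vary.

## Synthetic benchmark

`synthetic_data` plants `n_complexes` node-disjoint complexes (default 10 of
size 8): each internal edge appears with probability `p_in = 0.9`, the
designated hub's internal edges with `min(1, p_in + hub_boost) = 1.0`, and
every pair *not* inside one complex — across complexes, and to/among the 20
extra background nodes — with `p_out = 0.02` (the standard planted-partition
construction). Complexes are node-disjoint so Sn/PPV against the truth is
directly interpretable; an annotation generator assigns each complex a
dominant term with configurable purity for testing the enrichment and
co-localization measures. Everything is bit-reproducible from (parameters,
seed).

What the benchmark does *not* emulate: power-law degree structure and the
size of real interactomes (it is ~100 nodes, not thousands), experimental
false-positive noise beyond uniform background edges, shared subunits
between complexes (unless sizes/overlap are configured), and annotation
incompleteness. Passing the planted-recovery tests therefore shows the
pipeline recovers kernel-organized dense modules under controlled noise, not
that any particular parameter set is optimal on real data.

A structural consequence worth knowing before applying the defaults to small
networks: because the seed fraction `pk` is relative, a 100-node benchmark
yields one or two seed nodes at `pk = 0.01`, and `w_init = 0.8` exceeds the
typical intra-complex weight when `p_in = 0.9` (a member of a size-8 complex
has `w ≈ 5.4/8.8 ≈ 0.6` toward its hub once background edges inflate
degrees). Mining such a benchmark with the interactome defaults predicts
essentially nothing; the acceptance suite records this behaviour, and the
worked configuration for the benchmark scale is `pk = 0.15, w_init = 0.5`.

## Known limitations

- One complex per kernel: the number of predictions is bounded by the number
  of kernels, which `pk` controls coarsely on small networks.
- The non-shrinking-shell stopping rule halts multi-node kernels early
  (their first stage must add at least the kernel's own size), biasing
  predictions toward kernel cores on sparse data.
- GO semantic similarity is out of scope (no self-contained definition to
  implement); use dedicated GO tooling on the emitted complex files.
- Identifier handling is opaque and case-sensitive; no cross-database
  mapping is attempted.
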