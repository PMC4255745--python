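# mke — multistage kernel extension mining of protein complexes

`mke` detects protein complexes in protein–protein interaction (PPI)
networks. It is written for systems biologists who have an interactome as a
plain edge list (Krogan- or Collins-style yeast data, or anything in the same
two-column format) and want complex predictions plus the standard evaluation
battery — sensitivity/PPV/accuracy against a reference catalogue,
hypergeometric functional enrichment, and co-localization enrichment.

Unlike density-only methods (clique percolation, Markov clustering), the
algorithm exploits the *internal organization* of complexes: a complex forms
around a small kernel of critical, high-degree proteins (the
centrality–lethality observation) and grows outward in stages, the way a
social community grows around its founders.

## The algorithm

**Directed weights.** Each undirected interaction between proteins *s* and
*t* becomes two directed weights

```
w_st = cn_st / d_s        w_ts = cn_st / d_t
```

where `cn_st = |N_s ∩ N_t|` is their common-neighbour count and `d_s` the
degree of *s*. The asymmetry matters: a hub sees a small partner as a weak
co-complex candidate while the small partner sees the hub as a strong one.

**First-level kernels.** The degree threshold *k* is the smallest degree at
which at most a fraction `P(k)` (default 0.01) of all nodes qualifies.
Adjacent seed nodes whose directed weights are *mutually* ≥ `w_init`
(default 0.8) collapse into one kernel; the kernels are the connected
components of that relation.

**Stage-wise extension.** A neighbour *v* of the current kernel *c* joins
when a single witness member *u* makes it a *weighted best neighbour*:
`w_uv ≥ w_ave` and `w_vu ≥ w_ave`. The first stage uses `w_ave = w_init`;
later stages recompute `w_ave` as the mean directed weight over all ordered
pairs of the subgraph spanned by the kernel and its neighbours,

```
w_ave = Σ_{s≠t∈V} w_st / (|V|·(|V|−1)) .
```

All qualifying neighbours are added as a batch; extension stops when a stage
adds fewer nodes than the previous stage did (complexes grow outward in
non-shrinking shells), adds nothing, or the extension level exceeds the cap
`T_α` (default 7).

**Merging and filtering.** Complex pairs with intersection-over-union
`O_ij = |C_i∩C_j|/|C_i∪C_j|` at or above the overlap threshold (default 0.2)
merge, largest overlap first; complexes smaller than 3 proteins are dropped.

**Evaluation.** With the matching matrix `t(i,j) = |reference_i ∩ predicted_j|`:

```
Sn  = Σ_i max_j t(i,j) / Σ_i n(i)
PPV = Σ_j max_i t(i,j) / Σ_j Σ_i t(i,j)
Acc = √(Sn · PPV)
```

Functional enrichment of a complex of size *C* containing *k* carriers of a
function carried by *F* of the *N* network proteins is the hypergeometric
upper tail `P = 1 − Σ_{i<k} C(F,i)·C(N−F,C−i)/C(N,C)`, computed in exact
integer arithmetic so that interactome-scale tails (10⁻⁴⁰ and far beyond)
survive. Co-localization enrichment is the per-complex maximum fraction of
members sharing one cellular compartment, averaged over the predicted set.

## Worked example

Generate a synthetic benchmark of 10 planted size-8 complexes over a sparse
background, mine it, and score the predictions (on a 100-node network the
seed fraction is raised from the interactome default 0.01, which would admit
a single seed node):

```
$ mke simulate --seed 7 --out-edges net.tsv --out-truth truth.txt --out-annotations ann.tsv
$ mke mine --edges net.tsv --pk 0.15 --w-init 0.5 --out pred.txt
$ mke evaluate --pred pred.txt --ref truth.txt \
      --localizations ann.tsv --annotations ann.tsv --background-n 100
n_pred  n_matched  Sn     PPV    Acc    L      min_P
4       4          0.400  0.970  0.623  0.831  5.37e-12
```

Four complexes were mined and all four match a planted complex
(neighbourhood affinity ≥ 0.2). They cover 40 % of the planted membership
(Sn) and are 97 % pure (PPV), giving an accuracy of √(0.400·0.970) = 0.623.
On average 83 % of each complex's members share one synthetic compartment
(L), and the strongest complex is functionally enriched at P ≈ 5×10⁻¹².
The extension-level cap can be swept to pick a dataset-appropriate value
(mean predicted size stabilizes once kernels stop growing):

```
$ mke alpha-sweep --edges net.tsv --pk 0.15 --w-init 0.5 --alpha-min 1 --alpha-max 4
alpha   n_complexes     mean_size
1       3       6.000
2       4       8.000
3       4       8.500
4       4       8.500
```

`mke mine --out ...` also writes a `*.manifest.json` (resolved configuration,
input digest, version) so any run can be reproduced exactly; `mke weights`
dumps the directed weights as TSV. Library use mirrors the CLI:

```python
import mke
g = mke.read_edge_list("net.tsv")
complexes = mke.run_mke(g, mke.MKEConfig(pk=0.15, w_init=0.5))
```

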