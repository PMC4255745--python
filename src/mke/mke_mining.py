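"""Multistage kernel extension (MKE) mining of protein complexes.

The pipeline:

1. Convert the PPI graph to its directed weighted form.
2. Pick the degree threshold k so that at most a fraction ``pk`` of nodes
   qualify as high-degree seeds.
3. Group adjacent seeds whose directed weights are mutually at least
   ``w_init`` into first-level kernels (connected components of that
   relation; singleton kernels are common).
4. Extend each kernel stage by stage: a neighbour joins when some single
   kernel member is a mutual weighted best neighbour of it, i.e. both
   directed weights reach the current stage's average weight.  The first
   extension stage uses ``w_init`` as that threshold; later stages use the
   average weight of the subgraph spanned by the kernel and its neighbours.
   Extension stops when a stage adds fewer nodes than the previous one
   (complexes grow outward in non-shrinking shells), adds nothing, or the
   stage cap ``t_alpha`` is reached.
5. Merge mined complexes whose intersection-over-union reaches the overlap
   threshold, then drop complexes below the minimum size.

The whole pipeline is a deterministic pure function of (graph, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import AbstractSet, Hashable, Optional, Sequence

import networkx as nx

from .edge_weighting import DirectedWeightedGraph, to_directed_weighted
from .graph_core import ComplexSet, MKEConfig, preprocess_graph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cluster:
    """A kernel under extension: its members and per-stage growth history.

    ``delta_history[0]`` is the first-level kernel's own size (the nodes
    "added" by stage 1); each later entry is the number of nodes a stage
    added.  The extension level alpha is the number of completed stages.
    """

    members: frozenset
    delta_history: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a cluster must have at least one member")
        if not self.delta_history:
            raise ValueError("delta_history must have at least one entry")
        if any(d < 0 for d in self.delta_history):
            raise ValueError("delta_history entries must be >= 0")
        if sum(self.delta_history) != len(self.members):
            raise ValueError("delta_history must sum to the cluster size")

    @property
    def alpha(self) -> int:
        return len(self.delta_history)


def _canonical_key(members: AbstractSet) -> tuple[str, ...]:
    return tuple(sorted(str(m) for m in members))


def degree_threshold(g: nx.Graph, pk: float) -> int:
    """Smallest degree k at which at most a fraction ``pk`` of nodes has d >= k.

    If even the maximum degree leaves the qualifying fraction above ``pk``
    (massive ties at the top of the degree distribution), the maximum degree
    is returned, so the seed set is never empty.  With ``pk = 1`` the
    minimum degree present is returned: every node qualifies.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("degree threshold is undefined for an empty graph")
    if not 0.0 < pk <= 1.0:
        raise ValueError(f"pk must be in (0, 1], got {pk}")
    degrees = sorted(d for _, d in g.degree())
    d_min, d_max = degrees[0], degrees[-1]
    from bisect import bisect_left

    for k in range(d_min, d_max + 1):
        count = n - bisect_left(degrees, k)
        if count / n <= pk:
            return k
    return d_max


def identify_first_level_kernels(
    dwg: DirectedWeightedGraph, k: int, w_init: float
) -> list[Cluster]:
    """Group high-degree seed nodes into first-level kernels.

    Seeds are nodes of degree >= k.  Two adjacent seeds belong to the same
    kernel when their directed weights are *mutually* at least ``w_init``;
    kernels are the connected components of that relation, so a kernel is
    usually a single hub or a tight group of hubs.
    """
    g = dwg.base
    seeds = {v for v, d in g.degree() if d >= k}
    if not seeds:
        logger.info("no node reaches degree threshold k=%d; no kernels", k)
        return []
    relation = nx.Graph()
    relation.add_nodes_from(seeds)
    for s, t in g.edges():
        if (
            s in seeds
            and t in seeds
            and dwg.weight(s, t) >= w_init
            and dwg.weight(t, s) >= w_init
        ):
            relation.add_edge(s, t)
    kernels = [
        Cluster(frozenset(comp), (len(comp),))
        for comp in nx.connected_components(relation)
    ]
    kernels.sort(key=lambda c: _canonical_key(c.members))
    return kernels


def cluster_neighbours(g: nx.Graph, members: AbstractSet) -> set:
    """Nodes adjacent to the cluster but outside it."""
    out: set = set()
    for u in members:
        out.update(g.adj[u])
    return out - set(members)


def local_average_weight(dwg: DirectedWeightedGraph, members: AbstractSet) -> float:
    """Average directed weight of the subgraph spanned by a cluster and its neighbours.

    With V the union of the cluster and its neighbour set, this is the sum
    of w_st over *all* ordered pairs of distinct nodes of V (zero when the
    pair is not an edge) divided by |V|(|V|-1).  Both orientations of every
    internal edge contribute.  A degenerate isolated cluster (|V| < 2)
    yields 0 with a warning.
    """
    g = dwg.base
    nodes = set(members) | cluster_neighbours(g, members)
    size = len(nodes)
    if size < 2:
        logger.warning("local average weight undefined for |V| < 2; returning 0")
        return 0.0
    total = 0.0
    for u, v in g.subgraph(nodes).edges():
        if u == v:
            continue
        total += dwg.weight(u, v) + dwg.weight(v, u)
    return total / (size * (size - 1))


def best_neighbours(
    dwg: DirectedWeightedGraph, members: AbstractSet, w_ave: float
) -> set:
    """Neighbours that are mutual weighted best neighbours of the cluster.

    A neighbour v qualifies when a *single* internal witness u exists with
    w_uv >= w_ave and w_vu >= w_ave: a complex recruits a protein through
    one strong pairwise tie, not a consensus of all members.
    """
    if w_ave < 0:
        raise ValueError("w_ave must be >= 0")
    g = dwg.base
    member_set = set(members)
    out: set = set()
    for v in cluster_neighbours(g, members):
        for u in set(g.adj[v]) & member_set:
            if dwg.weight(u, v) >= w_ave and dwg.weight(v, u) >= w_ave:
                out.add(v)
                break
    return out


def extend_one_stage(
    dwg: DirectedWeightedGraph,
    cluster: Cluster,
    w_ave: Optional[float] = None,
) -> Cluster:
    """Run one extension stage, adding all qualifying neighbours at once.

    ``w_ave`` overrides the threshold (the run loop passes ``w_init`` for
    the first extension stage, before the kernel has a meaningful local
    average); when absent it is recomputed from the current cluster's local
    subgraph.  The returned cluster has alpha incremented and the number of
    added nodes (possibly 0) appended to its history.
    """
    if w_ave is None:
        w_ave = local_average_weight(dwg, cluster.members)
    added = best_neighbours(dwg, cluster.members, w_ave)
    return Cluster(
        frozenset(cluster.members | added),
        cluster.delta_history + (len(added),),
    )


def extend_kernel(
    dwg: DirectedWeightedGraph, kernel: Cluster, cfg: MKEConfig
) -> Cluster:
    """Extend a first-level kernel to its ultimate cluster.

    Stages run while the per-stage added count does not drop below the
    previous stage's count (the first stage is compared against the kernel's
    own size) and the extension level stays within ``t_alpha``.  A stage
    that adds nothing also terminates extension.
    """
    cluster = kernel
    delta_prior = len(kernel.members)
    first = True
    while cluster.alpha <= cfg.t_alpha:
        cluster = extend_one_stage(
            dwg, cluster, w_ave=cfg.w_init if first else None
        )
        first = False
        delta = cluster.delta_history[-1]
        if delta == 0 or delta < delta_prior:
            break
        delta_prior = delta
    return cluster


def overlap_ratio(a: AbstractSet, b: AbstractSet) -> float:
    """Intersection-over-union of two complexes."""
    if not a and not b:
        raise ValueError("overlap ratio is undefined for two empty sets")
    return len(set(a) & set(b)) / len(set(a) | set(b))


def merge_overlapping(cs: Sequence[AbstractSet], threshold: float) -> ComplexSet:
    """Repeatedly merge the most-overlapping pair until no pair reaches the threshold.

    The pair with the largest overlap ratio merges first; ties break on the
    lexicographically smallest member union, so the result does not depend
    on input order.  Exact duplicates always merge (O = 1).  Each merge
    reduces the complex count by one, so termination is guaranteed.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    work = [frozenset(c) for c in cs]
    while True:
        best = None  # (overlap, union_key, i, j)
        for i in range(len(work)):
            for j in range(i + 1, len(work)):
                o = overlap_ratio(work[i], work[j])
                if o >= threshold:
                    key = (-o, _canonical_key(work[i] | work[j]))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        if best is None:
            break
        _, i, j = best
        union = work[i] | work[j]
        work = [c for idx, c in enumerate(work) if idx not in (i, j)]
        work.append(union)
    work.sort(key=_canonical_key)
    return work


def run_mke(g: nx.Graph, cfg: Optional[MKEConfig] = None) -> ComplexSet:
    """Mine protein complexes from a PPI graph by multistage kernel extension.

    Returns the final complex set, deterministically ordered; every complex
    has at least ``cfg.min_size`` members and no remaining pair overlaps at
    or above ``cfg.overlap_threshold``.
    """
    if cfg is None:
        cfg = MKEConfig()
    g = preprocess_graph(g)
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        logger.info("graph has no edges; empty complex set")
        return []
    dwg = to_directed_weighted(g)
    k = degree_threshold(g, cfg.pk)
    kernels = identify_first_level_kernels(dwg, k, cfg.w_init)
    if not kernels:
        logger.info("no first-level kernels found; empty complex set")
        return []
    clusters = [extend_kernel(dwg, kern, cfg) for kern in kernels]
    merged = merge_overlapping([c.members for c in clusters], cfg.overlap_threshold)
    final = [c for c in merged if len(c) >= cfg.min_size]
    final.sort(key=_canonical_key)
    logger.info(
        "mined %d complexes from %d kernels (degree threshold k=%d)",
        len(final),
        len(kernels),
        k,
    )
    return final
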