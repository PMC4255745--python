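"""Conversion of an undirected PPI graph into a directed, weighted graph.

Every undirected interaction between proteins ``s`` and ``t`` becomes a pair
of directed weights

    w_st = cn_st / d_s        w_ts = cn_st / d_t

where ``cn_st = |N_s ∩ N_t|`` is the number of common neighbours and ``d_s``
the degree of ``s``.  The two weights are generally unequal: a hub sees a
low-degree partner as a weak candidate co-member, while the low-degree
partner sees the hub as a strong one.  Because ``t ∈ N_s`` but (with no
self-loops) ``t ∉ N_t``, the common-neighbour count is at most
``min(d_s, d_t) - 1`` and every weight lies in ``[0, 1)``.

Weights are *undefined* for non-adjacent ordered pairs; consumers that need
"weight or zero" (the local-average-weight sum) use :meth:`DirectedWeightedGraph.weight`,
which returns 0.0 for missing pairs.
"""

from __future__ import annotations

from typing import Hashable, Iterator

import networkx as nx


def common_neighbour_count(g: nx.Graph, s: Hashable, t: Hashable) -> int:
    """Number of nodes adjacent to both ``s`` and ``t``.

    Neither endpoint counts itself (guaranteed once self-loops are removed).

    Raises
    ------
    KeyError
        If either node is not in the graph.
    ValueError
        If ``s == t``.
    """
    if s not in g:
        raise KeyError(s)
    if t not in g:
        raise KeyError(t)
    if s == t:
        raise ValueError("common neighbours are defined for distinct nodes")
    return len(set(g.adj[s]) & set(g.adj[t]))


class DirectedWeightedGraph:
    """The directed, weighted view of a preprocessed PPI graph.

    Holds the base undirected graph, the integer common-neighbour count for
    every adjacent unordered pair, and the two directed weights per edge.
    The identity ``w_st * d_s == cn_st`` is maintained by construction: the
    count is stored exactly as an integer and each weight is the single
    float division ``cn / degree``.
    """

    __slots__ = ("base", "_cn", "_w")

    def __init__(
        self,
        base: nx.Graph,
        cn: dict[tuple, int],
        weights: dict[tuple, float],
    ) -> None:
        self.base = base
        self._cn = cn
        self._w = weights

    def weight(self, s: Hashable, t: Hashable) -> float:
        """Directed weight ``w_st``; 0.0 when (s, t) is not an edge."""
        return self._w.get((s, t), 0.0)

    def common_neighbours(self, s: Hashable, t: Hashable) -> int:
        """Exact common-neighbour count for an adjacent pair.

        Raises ``KeyError`` for non-adjacent pairs (the count is only
        materialized on edges).
        """
        return self._cn[(s, t)]

    def ordered_weights(self) -> Iterator[tuple[Hashable, Hashable, float]]:
        """Yield every ordered adjacent pair with its weight."""
        for (s, t), w in self._w.items():
            yield s, t, w

    def __contains__(self, pair: tuple) -> bool:
        return pair in self._w


def to_directed_weighted(g: nx.Graph) -> DirectedWeightedGraph:
    """Convert a preprocessed undirected graph to its directed weighted form.

    For every edge (s, t): ``w_st = cn_st / d_s`` and ``w_ts = cn_st / d_t``.
    Degree-0 nodes contribute no weights; division by zero cannot occur on an
    edge since an endpoint of an edge has degree >= 1.  The input graph is
    not mutated.

    The common-neighbour pass touches, for each node, pairs of its
    neighbours, so the cost is O(n * d_max^2).
    """
    adj = {v: set(g.adj[v]) for v in g}
    deg = dict(g.degree())
    cn: dict[tuple, int] = {}
    weights: dict[tuple, float] = {}
    for s, t in g.edges():
        if s == t:  # defensive: weights are undefined on loops
            continue
        c = len(adj[s] & adj[t])
        cn[(s, t)] = c
        cn[(t, s)] = c
        weights[(s, t)] = c / deg[s]
        weights[(t, s)] = c / deg[t]
    return DirectedWeightedGraph(g, cn, weights)
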