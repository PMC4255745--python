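"""Seeded generator of PPI-like networks with planted, kernel-organized complexes.

Every planted complex is a dense near-clique (each internal edge present
with probability ``p_in``) organized around one designated hub whose
internal edges appear with probability ``min(1, p_in + hub_boost)`` — the
structural premise that each complex carries a high-degree kernel node.
Every node pair *not* inside the same complex (between complexes, and
to/among optional extra background nodes) is connected with the background
probability ``p_out``, the standard planted-partition construction.

Complexes are node-disjoint so that sensitivity/PPV against the truth set is
directly interpretable.  Identical parameters and seed reproduce the
benchmark bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import networkx as nx
import numpy as np

from .evaluation import AnnotationMap
from .graph_core import ComplexSet, preprocess_graph


@dataclass(frozen=True)
class PlantedParams:
    """Parameters of the planted-complex benchmark.

    Defaults describe the package's reference benchmark: 10 node-disjoint
    complexes of size 8 with intra-complex edge probability 0.9 over a
    sparse background (p_out = 0.02) with 20 extra background nodes.
    """

    n_complexes: int = 10
    sizes: Union[int, tuple[int, ...]] = 8
    p_in: float = 0.9
    p_out: float = 0.02
    hub_boost: float = 0.1
    n_background: int = 20
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_complexes < 1:
            raise ValueError("need at least one planted complex")
        for s in self.size_list():
            if s < 3:
                raise ValueError(f"planted complex sizes must be >= 3, got {s}")
        if not 0.0 <= self.p_in <= 1.0 or not 0.0 <= self.p_out <= 1.0:
            raise ValueError("p_in and p_out must be probabilities")
        if self.p_in <= self.p_out:
            raise ValueError(
                f"planted complexes must be denser than background "
                f"(p_in={self.p_in} <= p_out={self.p_out})"
            )
        if self.hub_boost < 0:
            raise ValueError("hub_boost must be >= 0")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")

    def size_list(self) -> tuple[int, ...]:
        if isinstance(self.sizes, int):
            return (self.sizes,) * self.n_complexes
        sizes = tuple(self.sizes)
        if len(sizes) != self.n_complexes:
            raise ValueError("one size per planted complex is required")
        return sizes


@dataclass(frozen=True)
class PlantedBenchmark:
    """A generated network together with its ground-truth complex set."""

    graph: nx.Graph
    truth: ComplexSet
    params: PlantedParams = field(repr=False)


def generate_planted_network(params: PlantedParams) -> PlantedBenchmark:
    """Sample a planted-complex network; deterministic in (params, seed).

    Node names encode their role: ``C03.P00`` is the hub (member 0) of
    planted complex 3, ``B007`` a background node.
    """
    rng = np.random.default_rng(params.seed)
    g = nx.Graph()
    truth: ComplexSet = []
    membership: dict[str, int] = {}

    for c, size in enumerate(params.size_list()):
        members = [f"C{c:02d}.P{i:02d}" for i in range(size)]
        g.add_nodes_from(members)
        for m in members:
            membership[m] = c
        truth.append(frozenset(members))
        hub = members[0]
        p_hub = min(1.0, params.p_in + params.hub_boost)
        for i in range(size):
            for j in range(i + 1, size):
                p = p_hub if hub in (members[i], members[j]) else params.p_in
                if rng.random() < p:
                    g.add_edge(members[i], members[j])

    background = [f"B{i:03d}" for i in range(params.n_background)]
    g.add_nodes_from(background)
    for b in background:
        membership[b] = -1

    nodes = sorted(g.nodes())
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            u, v = nodes[i], nodes[j]
            if membership[u] == membership[v] and membership[u] != -1:
                continue  # intra-complex pairs already sampled
            if rng.random() < params.p_out:
                g.add_edge(u, v)

    return PlantedBenchmark(graph=preprocess_graph(g), truth=truth, params=params)


def generate_annotations(
    truth: Sequence[frozenset],
    purity: float = 0.9,
    n_terms: int | None = None,
    seed: int = 0,
    extra_proteins: Sequence[str] = (),
) -> AnnotationMap:
    """Assign each planted complex a dominant term, with label noise.

    Each member of complex j carries the dominant term ``T{j}`` with
    probability ``purity`` and a uniformly random *other* term otherwise;
    proteins listed in ``extra_proteins`` (e.g. background nodes) get a
    uniformly random term.  With ``purity = 1`` every complex is perfectly
    co-annotated.  Deterministic in (inputs, seed).
    """
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must be in [0, 1], got {purity}")
    n_complexes = len(truth)
    if n_terms is None:
        n_terms = n_complexes + 5
    if n_terms < max(n_complexes, 2):
        raise ValueError(
            f"need at least max(n_complexes, 2) = {max(n_complexes, 2)} terms"
        )
    terms = [f"T{i:03d}" for i in range(n_terms)]
    rng = np.random.default_rng(seed)
    annotations: AnnotationMap = {}
    for j, cx in enumerate(truth):
        dominant = terms[j]
        others = [t for t in terms if t != dominant]
        for p in sorted(cx):
            if rng.random() < purity:
                annotations[p] = frozenset({dominant})
            else:
                annotations[p] = frozenset({others[rng.integers(len(others))]})
    for p in sorted(extra_proteins):
        annotations[p] = frozenset({terms[rng.integers(n_terms)]})
    return annotations
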