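"""Graph data model, plain-text I/O and preprocessing for PPI networks.

A PPI network is held as a simple undirected :class:`networkx.Graph` whose
nodes are opaque protein identifier strings.  Preprocessing removes
self-interaction loops; duplicate interactions collapse automatically under
set semantics (a simple graph, not a multigraph).  Complex catalogues —
predicted or reference — are plain lists of frozensets of protein
identifiers, one complex per line on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

logger = logging.getLogger(__name__)

#: A set of protein complexes: each complex is a frozenset of member identifiers.
ComplexSet = list[frozenset]

PathLike = Union[str, Path]


class EdgeListFormatError(ValueError):
    """A line of an edge-list file could not be parsed.

    The message names the offending line number.
    """


@dataclass(frozen=True)
class MKEConfig:
    """Tunable parameters of the multistage kernel extension pipeline.

    Parameters
    ----------
    pk:
        Fraction of nodes admitted as high-degree seed nodes (the degree
        threshold k is the smallest degree at which at most this fraction of
        nodes qualifies).  Default 0.01: critical hub proteins are a small
        fraction of an interactome.
    w_init:
        Weight threshold used both to group adjacent seed nodes into
        first-level kernels and as the average-weight stand-in for the first
        extension stage, before a local neighbourhood exists to average over.
        Default 0.8.
    t_alpha:
        Cap on the extension level alpha (number of completed stages).
    overlap_threshold:
        Intersection-over-union at or above which two mined complexes are
        merged into one.
    min_size:
        Complexes smaller than this are dropped from the final set
        (biologically, a complex of fewer than 3 proteins is not meaningful).
    seed:
        Seed for any randomized helper routines; the mining pipeline itself
        is deterministic.
    """

    pk: float = 0.01
    w_init: float = 0.8
    t_alpha: int = 7
    overlap_threshold: float = 0.2
    min_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pk <= 1.0:
            raise ValueError(f"pk must be in (0, 1], got {self.pk}")
        if not 0.0 <= self.w_init <= 1.0:
            raise ValueError(f"w_init must be in [0, 1], got {self.w_init}")
        if int(self.t_alpha) != self.t_alpha or self.t_alpha < 1:
            raise ValueError(f"t_alpha must be a positive integer, got {self.t_alpha}")
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError(
                f"overlap_threshold must be in (0, 1], got {self.overlap_threshold}"
            )
        if int(self.min_size) != self.min_size or self.min_size < 1:
            raise ValueError(f"min_size must be an integer >= 1, got {self.min_size}")


def preprocess_graph(g: nx.Graph) -> nx.Graph:
    """Return a copy of ``g`` with self-interaction loops removed.

    Duplicate edges cannot exist in a simple graph, so loop removal is the
    only operation; it is idempotent.
    """
    h = g.copy()
    loops = list(nx.selfloop_edges(h))
    if loops:
        h.remove_edges_from(loops)
        logger.info("preprocessing removed %d self-interaction loop(s)", len(loops))
    return h


def read_edge_list(path: PathLike, preprocess: bool = True) -> nx.Graph:
    """Read a two-column whitespace/tab separated edge list into a graph.

    Extra columns (e.g. confidence scores) are ignored; the directed weights
    of the method are derived purely from topology.  Lines starting with
    ``#`` and blank lines are skipped.  Repeated pairs, in either
    orientation, collapse to a single edge.  With ``preprocess`` on (the
    default), self-interaction loops are dropped as well.

    Raises
    ------
    EdgeListFormatError
        If a non-comment line has fewer than two tokens; the message names
        the line number.
    """
    g = nx.Graph()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListFormatError(
                    f"{path}: line {lineno}: expected at least 2 columns, "
                    f"got {len(tokens)} ({line!r})"
                )
            s, t = tokens[0], tokens[1]
            if preprocess and s == t:
                continue
            g.add_edge(s, t)
    return preprocess_graph(g) if preprocess else g


def write_edge_list(g: nx.Graph, path: PathLike) -> None:
    """Write each unordered edge once as two tab-separated identifiers.

    Endpoints within a line and lines themselves are lexicographically
    sorted so output is deterministic.
    """
    lines = sorted("\t".join(sorted((str(u), str(v)))) for u, v in g.edges())
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")


def read_complex_set(path: PathLike) -> ComplexSet:
    """Read a one-complex-per-line catalogue of whitespace-separated members.

    Duplicate members within a line collapse to one (with a logged
    warning); empty lines are skipped with a logged warning; ``#`` comment
    lines are skipped silently.
    """
    complexes: ComplexSet = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s: line %d is empty, skipped", path, lineno)
                continue
            tokens = line.split()
            members = frozenset(tokens)
            if len(members) < len(tokens):
                logger.warning(
                    "%s: line %d has duplicate members, collapsed", path, lineno
                )
            complexes.append(members)
    return complexes


def write_complex_set(cs: Iterable[frozenset], path: PathLike) -> None:
    """Write one complex per line, members tab-separated.

    Members within a line and the lines themselves are sorted for a
    canonical, reproducible representation.
    """
    lines = sorted("\t".join(sorted(str(m) for m in cx)) for cx in cs)
    with open(path, "w", encoding="utf-8") as fh:
        for line in lines:
            fh.write(line + "\n")
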