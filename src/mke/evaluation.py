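"""Evaluation of predicted complex sets against references and annotations.

Three families of measures:

* Matching-matrix statistics.  With t(i, j) the number of proteins shared by
  reference complex i and predicted complex j,

      Sn  = sum_i max_j t(i, j) / sum_i n(i)
      PPV = sum_j max_i t(i, j) / sum_j sum_i t(i, j)
      Acc = sqrt(Sn * PPV)

* Functional enrichment: the hypergeometric upper-tail probability that at
  least k of the C members of a complex carry a function carried by F of
  the N network proteins.  Computed with exact integer arithmetic so that
  far-tail values (1e-40 and below on real interactomes) are meaningful.

* Co-localization enrichment: the per-complex maximum fraction of members
  sharing one cellular compartment, averaged over the predicted set.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import AbstractSet, Mapping, Optional, Sequence, Union

import numpy as np

logger = logging.getLogger(__name__)

#: protein identifier -> set of term identifiers (GO terms or compartments)
AnnotationMap = dict[str, frozenset]


@dataclass(frozen=True)
class MatchMatrix:
    """Co-occurrence counts between reference and predicted complexes.

    ``counts[i, j]`` is the number of proteins present in both reference
    complex i and predicted complex j; ``reference_sizes[i]`` is n(i).
    """

    counts: np.ndarray
    reference_sizes: np.ndarray


def match_matrix(
    reference: Sequence[AbstractSet], predicted: Sequence[AbstractSet]
) -> MatchMatrix:
    """Build the reference-by-predicted co-occurrence matrix."""
    if not reference or not predicted:
        raise ValueError("both complex sets must be non-empty")
    ref = [set(c) for c in reference]
    pred = [set(c) for c in predicted]
    counts = np.zeros((len(ref), len(pred)), dtype=np.int64)
    for i, r in enumerate(ref):
        for j, p in enumerate(pred):
            counts[i, j] = len(r & p)
    sizes = np.array([len(r) for r in ref], dtype=np.int64)
    return MatchMatrix(counts=counts, reference_sizes=sizes)


def sensitivity(mm: MatchMatrix) -> float:
    """Fraction of reference membership recovered by best-matching predictions."""
    denom = int(mm.reference_sizes.sum())
    if denom == 0:
        raise ValueError("sensitivity undefined: reference complexes are all empty")
    return float(mm.counts.max(axis=1).sum()) / denom


def positive_predictive_value(mm: MatchMatrix) -> float:
    """Fraction of co-occurring membership concentrated in best-matching references."""
    denom = int(mm.counts.sum())
    if denom == 0:
        raise ValueError(
            "PPV undefined: no predicted complex shares any protein with any "
            "reference complex"
        )
    return float(mm.counts.max(axis=0).sum()) / denom


def accuracy(sn: float, ppv: float) -> float:
    """Geometric mean of sensitivity and positive predictive value."""
    if not 0.0 <= sn <= 1.0:
        raise ValueError(f"Sn must be in [0, 1], got {sn}")
    if not 0.0 <= ppv <= 1.0:
        raise ValueError(f"PPV must be in [0, 1], got {ppv}")
    return math.sqrt(sn * ppv)


def complex_pvalue(N: int, F: int, C: int, k: int) -> float:
    """Hypergeometric upper-tail P-value of functional enrichment.

    Probability that a random C-subset of the N network proteins contains at
    least k of the F proteins carrying the function.  Equivalent to
    1 - sum_{i<k} C(F,i) C(N-F,C-i) / C(N,C), evaluated as the complementary
    upper-tail sum in exact integer arithmetic (stable arbitrarily far into
    the tail), then rounded once to float and clamped to [0, 1].
    """
    N, F, C, k = int(N), int(F), int(C), int(k)
    if not (0 <= C <= N and 0 <= F <= N):
        raise ValueError(f"need 0 <= C, F <= N; got N={N}, F={F}, C={C}")
    if not (0 <= k <= C and k <= F):
        raise ValueError(f"need 0 <= k <= min(C, F); got C={C}, F={F}, k={k}")
    total = math.comb(N, C)
    upper = sum(
        math.comb(F, i) * math.comb(N - F, C - i) for i in range(k, min(C, F) + 1)
    )
    p = float(Fraction(upper, total))
    return min(max(p, 0.0), 1.0)


def min_pvalue_annotation(
    members: AbstractSet,
    annotations: Mapping[str, AbstractSet],
    background_n: int,
) -> tuple[Optional[str], float, int]:
    """Best (minimal) enrichment P-value of a complex over its members' terms.

    Only terms carried by at least one member are tested; the term count per
    function (F) is taken over the supplied annotation map, and
    ``background_n`` is the network node count N.  Returns
    ``(term, p_value, n_terms_tested)``; ``(None, 1.0, 0)`` when no member
    is annotated.  No multiple-testing correction is applied; the number of
    terms tested is returned so a Bonferroni factor can be applied
    externally.
    """
    members = set(members)
    candidate_terms = set()
    for p in members:
        candidate_terms.update(annotations.get(p, ()))
    if not candidate_terms:
        return None, 1.0, 0
    term_totals: Counter = Counter()
    for terms in annotations.values():
        term_totals.update(terms)
    C = len(members)
    best_term, best_p = None, math.inf
    for term in sorted(candidate_terms):
        k = sum(1 for p in members if term in annotations.get(p, ()))
        F = min(term_totals[term], background_n)
        p_val = complex_pvalue(background_n, F, C, k)
        if p_val < best_p:
            best_term, best_p = term, p_val
    return best_term, best_p, len(candidate_terms)


def colocalization_enrichment(
    predicted: Sequence[AbstractSet],
    localization: Mapping[str, AbstractSet],
    weighted: bool = False,
) -> float:
    """Mean per-complex maximum fraction of members sharing one compartment.

    Each complex contributes the largest fraction of its members found in a
    single compartment; members without a localization label count in the
    complex size but in no compartment (a fully unlabelled complex
    contributes 0, with a warning).  By default complexes are averaged
    unweighted; with ``weighted=True`` the size-weighted alternative
    ``sum_j max_i l_ij / sum_j N_j`` is returned.
    """
    if not predicted:
        raise ValueError("co-localization enrichment needs a non-empty complex set")
    max_counts: list[int] = []
    sizes: list[int] = []
    for cx in predicted:
        counts: Counter = Counter()
        for p in cx:
            for compartment in localization.get(p, ()):
                counts[compartment] += 1
        best = max(counts.values(), default=0)
        if best == 0:
            logger.warning(
                "complex %s has no localized member; ratio 0",
                sorted(str(m) for m in cx)[:3],
            )
        max_counts.append(best)
        sizes.append(len(cx))
    if weighted:
        return sum(max_counts) / sum(sizes)
    return sum(c / s for c, s in zip(max_counts, sizes)) / len(predicted)


def neighbourhood_affinity(a: AbstractSet, b: AbstractSet) -> float:
    """The standard overlap score omega(A, B) = |A∩B|^2 / (|A|·|B|)."""
    if not a or not b:
        raise ValueError("neighbourhood affinity needs two non-empty sets")
    inter = len(set(a) & set(b))
    return inter * inter / (len(a) * len(b))


def matched_count(
    reference: Sequence[AbstractSet],
    predicted: Sequence[AbstractSet],
    omega_threshold: float = 0.2,
) -> int:
    """Number of predicted complexes matching some reference at omega >= threshold."""
    if not 0.0 < omega_threshold <= 1.0:
        raise ValueError(f"omega_threshold must be in (0, 1], got {omega_threshold}")
    count = 0
    for p in predicted:
        if any(neighbourhood_affinity(r, p) >= omega_threshold for r in reference):
            count += 1
    return count


def read_annotation_map(path: Union[str, Path]) -> AnnotationMap:
    """Read a two-column TSV of protein -> term, one pair per line.

    Multi-term proteins appear on multiple lines; ``#`` comments and blank
    lines are skipped.
    """
    raw: dict[str, set] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'protein<TAB>term', got {line!r}"
                )
            raw.setdefault(tokens[0], set()).add(tokens[1])
    return {p: frozenset(ts) for p, ts in raw.items()}
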