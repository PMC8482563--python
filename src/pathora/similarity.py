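"""Stability comparison of two enrichment results.

Two runs of the same analysis on different datasets for the same condition
should, if the method is stable, enrich largely the same pathways.  The
agreement between the two significant pathway-id sets :math:`P_1, P_2` is
quantified by

* the **Jaccard index** ``JI = |P1 ∩ P2| / |P1 ∪ P2|`` — 1 iff the sets
  are equal;
* the **meet-min index** ``mi = |P1 ∩ P2| / min(|P1|, |P2|)`` — 1 iff one
  set contains the other;

together with the raw bookkeeping NP1, NP2, union and intersection counts.
Matching is on pathway_id string equality (display names are
whitespace/case fragile).  Since the union is at least as large as the
smaller set, ``JI <= mi`` always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import pandas as pd

from .errors import EmptyComparisonError
from .enrichment import EnrichmentResults

__all__ = [
    "SimilarityReport",
    "jaccard_index",
    "meet_min_index",
    "compare_enrichments",
    "comparison_table",
]

ResultOrIds = Union[EnrichmentResults, Iterable[str]]

REPORT_COLUMNS = ["label", "np1", "np2", "union", "intersection",
                  "jaccard", "meet_min"]


@dataclass(frozen=True)
class SimilarityReport:
    """Pairwise agreement between two enriched pathway sets."""

    np1: int
    np2: int
    union_size: int
    intersection_size: int
    jaccard: float
    meet_min: float
    shared_ids: frozenset[str]

    def as_row(self, label: str = "") -> dict:
        return {
            "label": label, "np1": self.np1, "np2": self.np2,
            "union": self.union_size, "intersection": self.intersection_size,
            "jaccard": self.jaccard, "meet_min": self.meet_min,
        }


def jaccard_index(set1: Iterable[str], set2: Iterable[str]) -> float:
    """Intersection over union of two id sets; undefined (error) for 0/0."""
    s1, s2 = frozenset(set1), frozenset(set2)
    if not s1 and not s2:
        raise EmptyComparisonError("empty comparison: both sets are empty")
    return len(s1 & s2) / len(s1 | s2)


def meet_min_index(set1: Iterable[str], set2: Iterable[str]) -> float:
    """Intersection over the smaller set's size; requires both non-empty."""
    s1, s2 = frozenset(set1), frozenset(set2)
    if not s1 or not s2:
        side = "first" if not s1 else "second"
        raise EmptyComparisonError(f"empty comparison: {side} set is empty")
    return len(s1 & s2) / min(len(s1), len(s2))


def _significant_ids(result: ResultOrIds, alpha: float, side: str
                     ) -> frozenset[str]:
    if isinstance(result, EnrichmentResults):
        ids = result.significant_ids(alpha=alpha)
    else:
        ids = frozenset(result)
    if not ids:
        raise EmptyComparisonError(
            f"empty comparison: {side} enrichment has no significant "
            f"pathways at alpha={alpha}")
    return ids


def compare_enrichments(r1: ResultOrIds, r2: ResultOrIds,
                        alpha: float = 0.005) -> SimilarityReport:
    """Compare two enrichment results (or raw pathway-id sets).

    For :class:`EnrichmentResults` inputs the significant pathway-id sets
    at *alpha* are taken (on each result's configured p-value column);
    raw id iterables are used as-is.  All numeric fields are symmetric in
    the two arguments.
    """
    s1 = _significant_ids(r1, alpha, "first")
    s2 = _significant_ids(r2, alpha, "second")
    inter = s1 & s2
    return SimilarityReport(
        np1=len(s1), np2=len(s2),
        union_size=len(s1 | s2), intersection_size=len(inter),
        jaccard=jaccard_index(s1, s2),
        meet_min=meet_min_index(s1, s2),
        shared_ids=frozenset(inter),
    )


def comparison_table(pairs: Sequence[tuple[str, ResultOrIds, ResultOrIds]],
                     alpha: float = 0.005) -> pd.DataFrame:
    """Tabulate several labeled pairwise comparisons.

    *pairs* is a sequence of ``(label, result_a, result_b)``.  Returns one
    row per pair with columns NP1, NP2, union, intersection, JI and
    meet-min; serialize with ``df.to_csv(sep="\\t")``.  Per-pair errors
    propagate annotated with the pair's label.
    """
    if not pairs:
        raise EmptyComparisonError("comparison_table requires at least one pair")
    rows = []
    for label, a, b in pairs:
        try:
            rows.append(compare_enrichments(a, b, alpha=alpha).as_row(label))
        except EmptyComparisonError as exc:
            raise EmptyComparisonError(f"[{label}] {exc}") from exc
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
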