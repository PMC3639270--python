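"""Minimal annotation-term enrichment and cross-study term-set overlap.

Enrichment is a plain one-sided hypergeometric (Fisher) test of each term's
annotated genes against a query set drawn from a fixed background — a
deliberately simple stand-in for heavier annotation services, sufficient to
carry a gene list to a ranked term list with BH-adjusted p-values and fold
enrichment ``(k/n) / (K/N)``.

Overlap between two studies' enriched-term lists is reported as a percentage
of a chosen denominator set (the query list by default, matching the
directional phrasing "terms of A found in B").
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Iterable

import pandas as pd
from scipy import stats

from .de_model import adjust_bh

__all__ = ["TermSet", "AnnotationMap", "OverlapDenominator",
           "enrich", "overlap_percent"]


@dataclasses.dataclass(frozen=True)
class TermSet:
    """A named collection of annotation-term identifiers."""

    name: str
    terms: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, terms: Iterable[str]) -> "TermSet":
        return cls(name=name, terms=frozenset(str(t) for t in terms))


@dataclasses.dataclass
class AnnotationMap:
    """term -> annotated genes, over a fixed background gene universe."""

    term_to_genes: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        stray = set().union(*self.term_to_genes.values()) - self.background \
            if self.term_to_genes else set()
        if stray:
            raise ValueError(
                f"annotated genes missing from background: {sorted(stray)[:5]}"
            )


class OverlapDenominator(str, enum.Enum):
    A = "a"
    B = "b"
    UNION = "union"


def enrich(genes: set[str], annotation: AnnotationMap,
           alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric term enrichment of a gene set against the background.

    For a term annotating K of N background genes with k hits in the n query
    genes, ``p = P(X >= k)`` for X ~ Hypergeom(N, K, n).  Terms with no hit
    are skipped; BH runs over the tested terms.
    """
    stray = genes - annotation.background
    if stray:
        raise ValueError(f"query genes not in background: {sorted(stray)[:5]}")
    N = len(annotation.background)
    n = len(genes)
    rows = []
    for term, annotated in sorted(annotation.term_to_genes.items()):
        K = len(annotated)
        k = len(genes & annotated)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n and K else float("nan")
        rows.append({"term": term, "count": k, "term_size": K,
                     "fold_enrichment": fold, "p_raw": p})
    table = pd.DataFrame(rows, columns=["term", "count", "term_size",
                                        "fold_enrichment", "p_raw"])
    if len(table):
        table["p_adjusted"] = adjust_bh(table["p_raw"].to_numpy())
        table["significant"] = table["p_adjusted"] < alpha
        table = table.sort_values("p_raw", kind="stable").reset_index(drop=True)
    else:
        table["p_adjusted"] = []
        table["significant"] = []
    return table


def overlap_percent(a: TermSet, b: TermSet,
                    denominator: OverlapDenominator | str = OverlapDenominator.A
                    ) -> float:
    """Percentage of the denominator set shared between two term sets."""
    denominator = OverlapDenominator(denominator)
    if denominator is OverlapDenominator.A:
        denom = a.terms
    elif denominator is OverlapDenominator.B:
        denom = b.terms
    else:
        denom = a.terms | b.terms
    if not denom:
        raise ValueError(f"denominator set ({denominator.value}) is empty")
    return 100.0 * len(a.terms & b.terms) / len(denom)
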