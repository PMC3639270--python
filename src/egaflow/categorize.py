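"""Assign differentially expressed genes to the four transcript groups.

Significant genes are split by presence/absence and direction: maternal
transcripts present at the 2-cell stage but absent at the 4-cell stage
("2-cell only"), maternal-embryonic transcripts more abundant before genome
activation ("2-cell enriched"), transcripts rising after activation ("4-cell
enriched"), and embryonic transcripts found only at the 4-cell stage ("4-cell
only").  "Absent" means strictly zero raw tags across all samples of that
stage (a detection threshold can relax this); everything non-significant is
NOT_DE.
"""

from __future__ import annotations

import enum
from collections import Counter
from typing import Sequence

import numpy as np

from .de_model import GeneTestResult
from .io_tables import CountMatrix, SampleDesign, Stage

__all__ = ["TranscriptCategory", "categorize_genes", "category_counts"]


class TranscriptCategory(str, enum.Enum):
    TWO_CELL_ONLY = "2-cell only"
    TWO_CELL_ENRICHED = "2-cell enriched"
    FOUR_CELL_ENRICHED = "4-cell enriched"
    FOUR_CELL_ONLY = "4-cell only"
    NOT_DE = "not DE"


def categorize_genes(counts: CountMatrix, design: SampleDesign,
                     results: Sequence[GeneTestResult],
                     absence_threshold: int = 0,
                     ) -> dict[str, TranscriptCategory]:
    """Label every tested gene with its transcript category.

    A significant gene with summed raw counts <= ``absence_threshold``
    (default 0: strictly absent) across all 4-cell samples is TWO_CELL_ONLY,
    and symmetrically for FOUR_CELL_ONLY; otherwise the sign of the stage
    log2 fold change (4-cell over 2-cell) decides enriched direction.
    """
    by_gene = {r.gene_id: r for r in results}
    missing = set(by_gene) - set(counts.gene_ids)
    if missing:
        raise ValueError(f"results refer to genes absent from the matrix: "
                         f"{sorted(missing)[:5]}")
    mask2 = design.stage_mask(Stage.TWO_CELL)
    mask4 = design.stage_mask(Stage.FOUR_CELL)
    sum2 = counts.counts[:, mask2].sum(axis=1)
    sum4 = counts.counts[:, mask4].sum(axis=1)
    index = {g: i for i, g in enumerate(counts.gene_ids)}

    out: dict[str, TranscriptCategory] = {}
    for gene, res in by_gene.items():
        if not res.significant:
            out[gene] = TranscriptCategory.NOT_DE
            continue
        i = index[gene]
        absent4 = sum4[i] <= absence_threshold
        absent2 = sum2[i] <= absence_threshold
        assert not (absent2 and absent4), (
            f"gene {gene} significant with zero counts at both stages; "
            "the expected-count filter should have excluded it"
        )
        if absent4:
            out[gene] = TranscriptCategory.TWO_CELL_ONLY
        elif absent2:
            out[gene] = TranscriptCategory.FOUR_CELL_ONLY
        else:
            fc = res.log2_fold_change
            if not np.isfinite(fc):
                fc = res.log2_fold_change_cpm
            out[gene] = (TranscriptCategory.FOUR_CELL_ENRICHED if fc > 0
                         else TranscriptCategory.TWO_CELL_ENRICHED)
    return out


def category_counts(categories: dict[str, TranscriptCategory]) -> dict[TranscriptCategory, int]:
    """Group sizes in the reporting order of the four classes, then NOT_DE."""
    counter = Counter(categories.values())
    return {cat: counter.get(cat, 0) for cat in TranscriptCategory}
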