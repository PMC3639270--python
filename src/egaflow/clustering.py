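"""Log2 expression matrices, hierarchical sample/gene ordering, replicate QC.

Differentially expressed genes are displayed on the log2(CPM + 0.5) scale —
counts per million keep libraries of very different depth comparable, the
pseudocount keeps structural zeros finite without dominating low counts.
Ordering uses agglomerative clustering with Euclidean distance and complete
linkage (deterministic given the input order); the merge tree can be exported
as Newick.  Replicate correlation diagnostics report the Pearson r between
same-condition replicates on the log2 scale.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io_tables import CountMatrix, SampleDesign, Stage, Source

logger = logging.getLogger("egaflow")

__all__ = [
    "ExpressionMatrix",
    "ClusterAxis",
    "log2_normalize",
    "hierarchical_order",
    "linkage_to_newick",
    "replicate_correlation",
    "plot_heatmap",
]


class ClusterAxis(str, enum.Enum):
    GENES = "genes"
    SAMPLES = "samples"


@dataclasses.dataclass
class ExpressionMatrix:
    """log2(CPM + pseudocount) values for a gene subset, genes x samples."""

    values: pd.DataFrame
    pseudocount: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise ValueError("expression values must be finite")


def log2_normalize(counts: CountMatrix, gene_subset: Sequence[str] | None = None,
                   pseudocount: float = 0.5) -> ExpressionMatrix:
    """log2(1e6 * y / N + pseudocount) for the chosen genes."""
    if gene_subset is None:
        gene_subset = counts.gene_ids
    gene_subset = list(gene_subset)
    if not gene_subset:
        raise ValueError("empty gene subset")
    unknown = set(gene_subset) - set(counts.gene_ids)
    if unknown:
        raise ValueError(f"genes not in matrix: {sorted(unknown)[:5]}")
    index = {g: i for i, g in enumerate(counts.gene_ids)}
    rows = [index[g] for g in gene_subset]
    cpm = 1e6 * counts.counts[rows].astype(float) / counts.library_sizes[None, :]
    values = pd.DataFrame(np.log2(cpm + pseudocount), index=gene_subset,
                          columns=counts.sample_ids)
    return ExpressionMatrix(values=values, pseudocount=pseudocount)


@dataclasses.dataclass
class DendrogramOrder:
    labels: list[str]           # leaf order, left to right
    linkage: np.ndarray | None  # scipy merge tree (None for degenerate input)
    newick: str


def hierarchical_order(matrix: ExpressionMatrix,
                       axis: ClusterAxis = ClusterAxis.SAMPLES
                       ) -> DendrogramOrder:
    """Order one axis by complete-linkage Euclidean clustering.

    A constant matrix (all pairwise distances zero) keeps the input order and
    logs a warning.  Merge heights are non-decreasing (complete linkage is
    monotone).
    """
    data = matrix.values.to_numpy(dtype=float)
    labels = list(matrix.values.index if axis is ClusterAxis.GENES
                  else matrix.values.columns)
    if axis is ClusterAxis.SAMPLES:
        data = data.T
    if len(labels) < 2:
        raise ValueError("need >= 2 items to cluster")
    distances = pdist(data, metric="euclidean")
    if np.all(distances == 0):
        logger.warning("constant matrix: all distances zero, keeping input order")
        newick = "(" + ",".join(f"{l}:0" for l in labels) + ");"
        return DendrogramOrder(labels=labels, linkage=None, newick=newick)
    Z = hierarchy.linkage(distances, method="complete")
    order = hierarchy.leaves_list(Z)
    return DendrogramOrder(
        labels=[labels[i] for i in order],
        linkage=Z,
        newick=linkage_to_newick(Z, labels),
    )


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy merge tree as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(0.0, parent_height - node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"


def replicate_correlation(matrix: ExpressionMatrix, design: SampleDesign
                          ) -> pd.DataFrame:
    """Pearson r between replicate pairs within each (stage, source) condition.

    Rows: stage, source, sample_a, sample_b, r.  Conditions with a single
    replicate are omitted; a constant expression vector yields r = NaN.
    """
    rows = []
    for stage in Stage:
        for source in Source:
            mask = design.stage_mask(stage) & design.source_mask(source)
            samples = [design.sample_ids[i] for i in np.where(mask)[0]]
            for sa, sb in combinations(samples, 2):
                va = matrix.values[sa].to_numpy(dtype=float)
                vb = matrix.values[sb].to_numpy(dtype=float)
                if va.std() == 0 or vb.std() == 0:
                    r = float("nan")
                    logger.warning("constant expression vector for %s or %s; "
                                   "correlation undefined", sa, sb)
                else:
                    r = float(np.corrcoef(va, vb)[0, 1])
                rows.append({"stage": stage.value, "source": source.value,
                             "sample_a": sa, "sample_b": sb, "r": r})
    return pd.DataFrame(rows, columns=["stage", "source", "sample_a",
                                       "sample_b", "r"])


def plot_heatmap(matrix: ExpressionMatrix, path, gene_order=None,
                 sample_order=None) -> None:
    """Optional heatmap figure of the (reordered) expression matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values
    if gene_order is not None:
        values = values.loc[list(gene_order)]
    if sample_order is not None:
        values = values[list(sample_order)]
    fig, ax = plt.subplots(figsize=(6, 8))
    im = ax.imshow(values.to_numpy(dtype=float), aspect="auto", cmap="RdBu_r")
    ax.set_xticks(range(values.shape[1]), values.columns, rotation=90)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="log2(CPM + pc)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
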