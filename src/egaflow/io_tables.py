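"""Count/design/result table I/O, descriptive rate arithmetic, run manifests.

Tables are plain UTF-8 TSV: tab-separated, ``#`` comment lines ignored, no
quoting.  The count table has gene ids in the first column and one column per
sample; the design table has one row per sample with ``stage``, ``source``,
``replicate`` and (optionally) ``total_tags`` columns.

Library sizes are the per-sample sequencing depth used as the Poisson offset.
They default to the design table's ``total_tags`` column — normalisation is by
total reads per sample, not by per-gene column sums — and may legitimately
exceed the column sum of the count matrix (not every mappable tag lands in an
annotated gene).  When the column is absent we fall back to column sums with a
logged warning.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import logging
import platform
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("egaflow")

__all__ = [
    "Stage",
    "Source",
    "SampleDesign",
    "CountMatrix",
    "RateSummary",
    "developmental_rate",
    "read_counts",
    "write_counts",
    "read_design",
    "write_design",
    "read_table",
    "write_table",
    "write_manifest",
]


class Stage(str, enum.Enum):
    """Cleavage stage of the embryo pool: before or after genome activation."""

    TWO_CELL = "2-cell"
    FOUR_CELL = "4-cell"


class Source(str, enum.Enum):
    """Embryo origin: flushed in vivo or produced by IVM/IVF culture."""

    IN_VIVO = "in_vivo"
    IN_VITRO = "in_vitro"


def _parse_stage(value: str) -> Stage:
    key = str(value).strip().lower().replace("_", "-")
    for st in Stage:
        if key in (st.value, st.name.lower().replace("_", "-")):
            return st
    if key in ("2", "2cell", "two-cell"):
        return Stage.TWO_CELL
    if key in ("4", "4cell", "four-cell"):
        return Stage.FOUR_CELL
    raise ValueError(f"unrecognised stage label: {value!r}")


def _parse_source(value: str) -> Source:
    key = str(value).strip().lower().replace("-", "_")
    for so in Source:
        if key in (so.value, so.name.lower()):
            return so
    if key in ("ivv", "vivo"):
        return Source.IN_VIVO
    if key in ("ivt", "ivf", "vitro"):
        return Source.IN_VITRO
    raise ValueError(f"unrecognised source label: {value!r}")


@dataclasses.dataclass
class SampleDesign:
    """Per-sample experimental design: stage, source and replicate label."""

    sample_ids: list[str]
    stages: list[Stage]
    sources: list[Source]
    replicates: list[str]

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not (len(self.stages) == len(self.sources) == len(self.replicates) == n):
            raise ValueError("design columns have mismatched lengths")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids are not unique")
        if not {Stage.TWO_CELL, Stage.FOUR_CELL} <= set(self.stages):
            # at least one sample per stage; a one-stage design cannot test
            # a stage effect
            raise ValueError("design must contain at least one sample per stage")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def stage_mask(self, stage: Stage) -> np.ndarray:
        return np.array([s == stage for s in self.stages], dtype=bool)

    def source_mask(self, source: Source) -> np.ndarray:
        return np.array([s == source for s in self.sources], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "stage": [s.value for s in self.stages],
                "source": [s.value for s in self.sources],
                "replicate": self.replicates,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleDesign":
        required = {"sample_id", "stage", "source", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        return cls(
            sample_ids=[str(s) for s in frame["sample_id"]],
            stages=[_parse_stage(s) for s in frame["stage"]],
            sources=[_parse_source(s) for s in frame["source"]],
            replicates=[str(r) for r in frame["replicate"]],
        )


@dataclasses.dataclass
class CountMatrix:
    """Gene-by-sample integer tag counts plus per-sample library sizes.

    ``library_sizes`` are total tags per sample, the exposure of the Poisson
    rate model; they are not required to equal (or bound) the column sums.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.library_sizes = np.asarray(self.library_sizes)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count for gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.library_sizes.shape != (len(self.sample_ids),):
            raise ValueError("library_sizes length must equal number of samples")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.sample_ids,
        )


@dataclasses.dataclass(frozen=True)
class RateSummary:
    """A counted developmental rate, e.g. cleaved embryos / oocytes cultured."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise ValueError("denominator must be positive")
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must be in [0, denominator]")

    @property
    def percent(self) -> float:
        """Full-precision percentage."""
        return 100.0 * self.numerator / self.denominator

    @property
    def percent_display(self) -> int:
        """Percentage rounded half-up to the nearest integer for display."""
        return int(np.floor(self.percent + 0.5))

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent_display}%)"


def developmental_rate(numerator: int, denominator: int) -> RateSummary:
    """Developmental competence rate (cleavage/blastocyst), as n/d and %."""
    return RateSummary(int(numerator), int(denominator))


# ---------------------------------------------------------------------------
# TSV I/O

_TSV_KW = dict(sep="\t", comment="#")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, **_TSV_KW)


def write_table(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def read_design(path: str | Path) -> SampleDesign:
    return SampleDesign.from_frame(read_table(path))


def write_design(design: SampleDesign, path: str | Path,
                 library_sizes: Sequence[int] | None = None) -> None:
    frame = design.to_frame()
    if library_sizes is not None:
        frame["total_tags"] = list(library_sizes)
    write_table(frame, path)


def read_counts(path: str | Path, design_path: str | Path) -> tuple[CountMatrix, SampleDesign]:
    """Read and cross-validate a count table and its design table.

    Library sizes come from the design table's ``total_tags`` column when
    present, else from count-matrix column sums (with a warning).
    """
    raw = pd.read_csv(path, **_TSV_KW, dtype=str)
    if raw.shape[1] < 2:
        raise ValueError("count table needs a gene id column and >= 1 sample column")
    gene_col = raw.columns[0]
    gene_ids = [str(g) for g in raw[gene_col]]
    sample_ids = [str(c) for c in raw.columns[1:]]

    counts = np.empty((len(gene_ids), len(sample_ids)), dtype=np.int64)
    for j, sample in enumerate(sample_ids):
        for i, value in enumerate(raw[sample]):
            try:
                parsed = int(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {value!r} for gene {gene_ids[i]!r}, "
                    f"sample {sample!r}"
                ) from None
            if parsed < 0:
                raise ValueError(
                    f"negative count {parsed} for gene {gene_ids[i]!r}, "
                    f"sample {sample!r}"
                )
            counts[i, j] = parsed

    design_frame = read_table(design_path)
    design = SampleDesign.from_frame(design_frame)
    if set(design.sample_ids) != set(sample_ids):
        unmatched = sorted(
            set(design.sample_ids).symmetric_difference(sample_ids)
        )
        raise ValueError(f"sample mismatch between counts and design: {unmatched}")
    # reorder the design to the count-table column order
    order = [design.sample_ids.index(s) for s in sample_ids]
    design = SampleDesign(
        sample_ids=[design.sample_ids[i] for i in order],
        stages=[design.stages[i] for i in order],
        sources=[design.sources[i] for i in order],
        replicates=[design.replicates[i] for i in order],
    )

    if "total_tags" in design_frame.columns:
        by_sample = dict(zip(design_frame["sample_id"].astype(str),
                             design_frame["total_tags"]))
        library_sizes = np.array([int(by_sample[s]) for s in sample_ids])
    else:
        logger.warning(
            "design table has no total_tags column; falling back to count "
            "column sums as library sizes"
        )
        library_sizes = counts.sum(axis=0)

    matrix = CountMatrix(gene_ids, sample_ids, counts, library_sizes)
    return matrix, design


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    write_table(matrix.to_frame().reset_index(), path)


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Write a machine-readable run manifest (config echo + seed + versions)."""
    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "platform": platform.platform(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    try:
        import scipy

        manifest["versions"]["scipy"] = scipy.__version__
    except ImportError:  # pragma: no cover
        pass
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
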