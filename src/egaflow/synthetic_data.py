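"""Synthetic count matrices, truth tables and qPCR plates for the EGA design.

The generator emulates the downstream structure of a cleavage-stage embryo
RNA-seq experiment: six samples in an unbalanced 2x2 stage-by-source layout
(2-cell: one in vivo + two in vitro pools; 4-cell: two in vivo + one in vitro),
widely varying library sizes, five gene classes (2-cell only, 2-cell enriched,
4-cell enriched, 4-cell only, null) and extra-Poisson variability.

Counts are drawn with mean ``N_s * lambda`` and variance ``phi * mean``: plain
Poisson when ``phi = 1``, otherwise a gamma–Poisson (negative binomial) mixture,
the simplest count law with the quasi-Poisson mean–variance relation the
fitted model assumes.  The "only" classes are structural zeros (lambda = 0 at
the absent stage), matching the present-but-absent definition and making
categorisation exactly testable.

One global seed governs everything; each gene draws from its own sub-stream
derived deterministically from (seed, gene index), so results do not depend on
iteration order.
"""

from __future__ import annotations

import dataclasses
import enum
import math

import numpy as np
import pandas as pd

from .io_tables import CountMatrix, SampleDesign, Stage, Source

__all__ = [
    "GeneClass",
    "SimConfig",
    "SimTruth",
    "QpcrGroup",
    "QpcrPlate",
    "default_design",
    "DEFAULT_LIBRARY_SIZES",
    "simulate_counts",
    "simulate_qpcr",
    "simulate_dilution_series",
]


class GeneClass(str, enum.Enum):
    """True transcript class of a simulated gene."""

    TWO_CELL_ONLY = "2-cell only"
    TWO_CELL_ENRICHED = "2-cell enriched"
    FOUR_CELL_ENRICHED = "4-cell enriched"
    FOUR_CELL_ONLY = "4-cell only"
    NULL = "null"


class QpcrGroup(str, enum.Enum):
    """Sample groups measured on a qPCR plate."""

    GV = "GV"
    TWO_CELL = "2-cell"
    FOUR_CELL = "4-cell"
    BLASTOCYST = "blastocyst"


def default_design() -> SampleDesign:
    """The study layout: 2-cell 1 ivv + 2 ivt; 4-cell 2 ivv + 1 ivt."""
    return SampleDesign(
        sample_ids=["2c_ivv", "2c_ivt1", "2c_ivt2",
                    "4c_ivv1", "4c_ivv2", "4c_ivt"],
        stages=[Stage.TWO_CELL] * 3 + [Stage.FOUR_CELL] * 3,
        sources=[Source.IN_VIVO, Source.IN_VITRO, Source.IN_VITRO,
                 Source.IN_VIVO, Source.IN_VIVO, Source.IN_VITRO],
        replicates=["1", "1", "2", "1", "2", "1"],
    )


# mappable tags per sample, same order as default_design()
DEFAULT_LIBRARY_SIZES = (2320994, 1556761, 12791613, 2774378, 1682540, 2220189)

_DEFAULT_PROPORTIONS = {
    GeneClass.TWO_CELL_ONLY: 0.01,
    GeneClass.TWO_CELL_ENRICHED: 0.04,
    GeneClass.FOUR_CELL_ENRICHED: 0.04,
    GeneClass.FOUR_CELL_ONLY: 0.01,
    GeneClass.NULL: 0.90,
}


@dataclasses.dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    ``baseline_log_rate_mean/sd`` describe the natural-log per-tag expression
    rate lambda at the 2-cell in vivo baseline (lognormal across genes).  With
    the default -11.5 +/- 1 and the default library sizes, a typical gene sees
    a few dozen tags per sample, comparable to a moderately expressed
    transcript in a low-input embryo pool.  ``dispersion`` is the variance
    inflation factor phi (Poisson at 1).  Stage effects (log2, drawn uniform in
    ``stage_log2_effect_range``) push "enriched" classes up at their stage;
    ``source_effect_fraction`` of genes additionally get an in vitro
    perturbation at the stages in ``source_effect_stages`` (default: 2-cell
    only, mirroring culture effects concentrated before genome activation).
    """

    n_genes: int = 2000
    class_proportions: dict[GeneClass, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    baseline_log_rate_mean: float = -11.5
    baseline_log_rate_sd: float = 1.0
    stage_log2_effect_range: tuple[float, float] = (1.0, 2.0)
    source_effect_fraction: float = 0.0
    source_log2_effect_range: tuple[float, float] = (1.0, 2.0)
    source_effect_stages: tuple[Stage, ...] = (Stage.TWO_CELL,)
    dispersion: float = 3.0
    library_sizes: tuple[int, ...] = DEFAULT_LIBRARY_SIZES
    design: SampleDesign = dataclasses.field(default_factory=default_design)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if any(f < 0 for f in self.class_proportions.values()):
            raise ValueError("class proportions must be non-negative")
        if self.dispersion < 1.0:
            raise ValueError("dispersion must be >= 1")
        sizes = np.asarray(self.library_sizes)
        if np.any(sizes <= 0):
            raise ValueError("library sizes must be positive")
        if not np.all(np.mod(sizes, 1) == 0):
            raise ValueError("library sizes must be integers")
        if len(self.library_sizes) != self.design.n_samples:
            raise ValueError("one library size per design sample is required")
        for lo, hi in (self.stage_log2_effect_range, self.source_log2_effect_range):
            if not (0 < lo <= hi):
                raise ValueError("effect ranges must be positive (lo <= hi)")
        if not 0.0 <= self.source_effect_fraction <= 1.0:
            raise ValueError("source_effect_fraction must be in [0, 1]")


@dataclasses.dataclass
class SimTruth:
    """Ground truth of a simulated matrix: per-gene class, cell rates, effects.

    ``lam`` is genes x 4 with columns (2-cell ivv, 2-cell ivt, 4-cell ivv,
    4-cell ivt); "only" classes have exact zeros at the absent stage and null
    genes have a single rate everywhere.
    """

    gene_ids: list[str]
    classes: list[GeneClass]
    lam: np.ndarray
    stage_log2_effect: np.ndarray
    source_log2_effect: np.ndarray

    _CELL_COLS = ("lam_2c_ivv", "lam_2c_ivt", "lam_4c_ivv", "lam_4c_ivt")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"gene_id": self.gene_ids,
                              "class": [c.value for c in self.classes]})
        for j, col in enumerate(self._CELL_COLS):
            frame[col] = self.lam[:, j]
        frame["stage_log2_effect"] = self.stage_log2_effect
        frame["source_log2_effect"] = self.source_log2_effect
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SimTruth":
        return cls(
            gene_ids=[str(g) for g in frame["gene_id"]],
            classes=[GeneClass(c) for c in frame["class"]],
            lam=frame[list(cls._CELL_COLS)].to_numpy(dtype=float),
            stage_log2_effect=frame["stage_log2_effect"].to_numpy(dtype=float),
            source_log2_effect=frame["source_log2_effect"].to_numpy(dtype=float),
        )

    def class_of(self, gene_id: str) -> GeneClass:
        return self.classes[self.gene_ids.index(gene_id)]


def _class_counts(proportions: dict[GeneClass, float], n: int) -> dict[GeneClass, int]:
    """Largest-remainder apportionment so class counts sum exactly to n."""
    order = list(proportions)
    raw = np.array([proportions[c] * n for c in order])
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    for idx in np.argsort(-(raw - base))[:short]:
        base[idx] += 1
    return dict(zip(order, base))


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    # per-gene sub-stream, independent of iteration order
    return np.random.default_rng(np.random.SeedSequence((seed, index)))


def _draw_counts(rng: np.random.Generator, mean: np.ndarray,
                 dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 1.0:
        return rng.poisson(mean)
    shape = mean / (dispersion - 1.0)
    lam = np.where(mean > 0, rng.gamma(np.maximum(shape, 1e-300),
                                       dispersion - 1.0), 0.0)
    return rng.poisson(lam)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, SampleDesign, SimTruth]:
    """Draw a gene-by-sample count matrix with known ground truth."""
    config.validate()
    design = config.design
    n = config.n_genes
    sizes = np.asarray(config.library_sizes, dtype=float)

    counts_by_class = _class_counts(config.class_proportions, n)
    labels: list[GeneClass] = []
    for cls, k in counts_by_class.items():
        labels.extend([cls] * k)
    perm = np.random.default_rng(np.random.SeedSequence((config.seed, n, 0xC1A55))
                                 ).permutation(n)
    classes = [labels[i] for i in perm]

    stage_cols = np.array([2 if s == Stage.FOUR_CELL else 0 for s in design.stages])
    src_cols = np.array([1 if s == Source.IN_VITRO else 0 for s in design.sources])
    cell_index = stage_cols + src_cols  # column in the 4-wide lambda table

    lam = np.zeros((n, 4))
    stage_eff = np.zeros(n)
    src_eff = np.zeros(n)
    counts = np.zeros((n, design.n_samples), dtype=np.int64)
    lo, hi = config.stage_log2_effect_range
    slo, shi = config.source_log2_effect_range

    for g in range(n):
        rng = _gene_rng(config.seed, g)
        base = math.exp(rng.normal(config.baseline_log_rate_mean,
                                   config.baseline_log_rate_sd))
        cls = classes[g]
        if cls is GeneClass.TWO_CELL_ONLY:
            lam2, lam4 = base, 0.0
            stage_eff[g] = -np.inf
        elif cls is GeneClass.FOUR_CELL_ONLY:
            lam2, lam4 = 0.0, base
            stage_eff[g] = np.inf
        elif cls is GeneClass.TWO_CELL_ENRICHED:
            eff = rng.uniform(lo, hi)
            lam2, lam4 = base, base * 2.0 ** (-eff)
            stage_eff[g] = -eff
        elif cls is GeneClass.FOUR_CELL_ENRICHED:
            eff = rng.uniform(lo, hi)
            lam2, lam4 = base, base * 2.0 ** eff
            stage_eff[g] = eff
        else:
            lam2 = lam4 = base

        row = np.array([lam2, lam2, lam4, lam4])
        if rng.random() < config.source_effect_fraction:
            eff = rng.uniform(slo, shi) * rng.choice([-1.0, 1.0])
            src_eff[g] = eff
            if Stage.TWO_CELL in config.source_effect_stages:
                row[1] *= 2.0 ** eff
            if Stage.FOUR_CELL in config.source_effect_stages:
                row[3] *= 2.0 ** eff
        lam[g] = row

        mean = sizes * row[cell_index]
        counts[g] = _draw_counts(rng, mean, config.dispersion)

    gene_ids = [f"gene{g:05d}" for g in range(n)]
    matrix = CountMatrix(gene_ids, list(design.sample_ids), counts,
                         np.asarray(config.library_sizes, dtype=np.int64))
    truth = SimTruth(gene_ids, classes, lam, stage_eff, src_eff)
    return matrix, design, truth


# ---------------------------------------------------------------------------
# qPCR emulation


@dataclasses.dataclass
class QpcrPlate:
    """Per-well Ct values for target and reference across sample groups.

    ``wells`` columns: gene, group, replicate, ct_target, ct_reference.
    ``dilution_series`` maps a primer-pair name to (log10 dilution, Ct) pairs.
    """

    wells: pd.DataFrame
    dilution_series: dict[str, list[tuple[float, float]]] = dataclasses.field(
        default_factory=dict)

    def __post_init__(self) -> None:
        required = {"gene", "group", "replicate", "ct_target", "ct_reference"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate table missing columns: {sorted(missing)}")
        cts = self.wells[["ct_target", "ct_reference"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(cts)) or np.any(cts <= 0):
            raise ValueError("Ct values must be finite and positive")


_GROUP_STAGE = {QpcrGroup.TWO_CELL: (0, 1), QpcrGroup.FOUR_CELL: (2, 3)}


def _group_abundance(truth: SimTruth, g: int, group: QpcrGroup) -> float:
    """Relative template abundance of a group; GV and blastocyst flank the
    measured stages (GV tracks the 2-cell maternal pool, blastocyst sits a
    further 4-fold below it for maternal transcripts)."""
    lam2 = truth.lam[g, 0]
    lam4 = truth.lam[g, 2]
    if group is QpcrGroup.TWO_CELL:
        return lam2
    if group is QpcrGroup.FOUR_CELL:
        return lam4
    if group is QpcrGroup.GV:
        return lam2 if lam2 > 0 else lam4 / 4.0
    return lam4 / 4.0 if lam2 > 0 else lam4  # blastocyst


def simulate_qpcr(truth: SimTruth, genes: list[str], *,
                  groups: tuple[QpcrGroup, ...] = (QpcrGroup.TWO_CELL,
                                                   QpcrGroup.FOUR_CELL),
                  calibrator_group: QpcrGroup = QpcrGroup.TWO_CELL,
                  n_replicates: int = 3, noise_sd: float = 0.2,
                  reference_ct: float = 15.0, target_ct_center: float = 25.0,
                  seed: int = 0) -> QpcrPlate:
    """Generate Ct values whose ddCt inverts to the true fold changes.

    Target Ct falls by one cycle per doubling of template relative to the
    calibrator group; the spiked reference RNA gives a constant Ct across
    groups.  Gaussian technical noise of ``noise_sd`` cycles is added per well.
    """
    if calibrator_group not in groups:
        groups = tuple(groups) + (calibrator_group,)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCB)))
    rows = []
    for gene in genes:
        if gene not in truth.gene_ids:
            raise ValueError(f"gene {gene!r} not present in the truth table")
        g = truth.gene_ids.index(gene)
        cal = _group_abundance(truth, g, calibrator_group)
        if cal <= 0:
            raise ValueError(
                f"gene {gene!r} has zero abundance in calibrator group "
                f"{calibrator_group.value}; Ct undefined"
            )
        for group in groups:
            abundance = _group_abundance(truth, g, group)
            if abundance <= 0:
                continue  # no amplification: well absent from the plate
            true_delta = -math.log2(abundance / cal)  # cycles above calibrator
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "gene": gene,
                    "group": group.value,
                    "replicate": rep,
                    "ct_target": target_ct_center + true_delta
                    + rng.normal(0.0, noise_sd),
                    "ct_reference": reference_ct + rng.normal(0.0, noise_sd),
                })
    return QpcrPlate(wells=pd.DataFrame(rows))


def simulate_dilution_series(efficiency: float = 1.0, intercept: float = 20.0,
                             dilutions: tuple[float, ...] = (0.0, -1.0, -2.0, -3.0),
                             noise_sd: float = 0.0, seed: int = 0,
                             ) -> list[tuple[float, float]]:
    """Ct values along a serial dilution for a primer pair of efficiency E.

    The theoretical slope is ``-1 / log10(1 + E)`` cycles per log10 dilution
    (-3.3219 at E = 1).
    """
    if efficiency <= 0:
        raise ValueError("efficiency must be positive")
    slope = -1.0 / math.log10(1.0 + efficiency)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xD1)))
    return [(d, intercept + slope * d + rng.normal(0.0, noise_sd))
            for d in dilutions]
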