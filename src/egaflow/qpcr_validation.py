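"""qPCR standard curves, ddCt relative expression and RNA-seq concordance.

Primer efficiency comes from the slope of Ct against log10 template dilution:
``E = 10^(-1/slope) - 1`` (a slope of -3.3219 cycles/log10 is perfect
doubling, E = 100%).  Curves are acceptable when |r| >= 0.98 and E is within
85–100%.  Relative expression uses the ddCt method against a spiked reference
RNA and a calibrator group; fold change is ``2^(-ddCt)`` (an
efficiency-corrected ``(1+E)^(-ddCt)`` variant is available).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import QpcrPlate, QpcrGroup

__all__ = [
    "StandardCurve",
    "FoldChangeResult",
    "fit_standard_curve",
    "ddct_fold_change",
    "concordance_table",
]

_MIN_R = 0.98
_EFF_WINDOW = (0.85, 1.00)


@dataclasses.dataclass(frozen=True)
class StandardCurve:
    """Least-squares line of Ct vs log10 dilution and the implied efficiency."""

    slope: float
    intercept: float
    r_value: float
    efficiency: float  # nan when the slope is non-negative
    acceptable: bool


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Fit a primer standard curve from (log10 dilution, Ct) pairs."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 (log10 dilution, Ct) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("dilution values are all identical; no slope")
    fit = stats.linregress(x, y)
    if fit.slope < 0:
        efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    else:
        efficiency = float("nan")  # amplification cannot lose template
    # slopes are typically reported to 4-5 significant digits; allow the
    # matching rounding slack at the window edges
    acceptable = (
        math.isfinite(efficiency)
        and abs(fit.rvalue) >= _MIN_R
        and _EFF_WINDOW[0] - 1e-3 <= efficiency <= _EFF_WINDOW[1] + 1e-3
    )
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_value=float(fit.rvalue),
        efficiency=float(efficiency),
        acceptable=acceptable,
    )


@dataclasses.dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    group: str
    calibrator: str
    ddct_mean: float
    ddct_sd: float
    fold_change: float
    per_replicate_ddct: tuple[float, ...]


def _delta_ct(plate: QpcrPlate, gene: str, group: str) -> np.ndarray:
    sub = plate.wells[(plate.wells["gene"] == gene)
                      & (plate.wells["group"] == group)]
    if sub.empty:
        raise ValueError(f"gene {gene!r} has no wells for group {group!r}")
    return (sub["ct_target"] - sub["ct_reference"]).to_numpy(dtype=float)


def ddct_fold_change(plate: QpcrPlate, gene: str,
                     group_a: str | QpcrGroup,
                     calibrator_group: str | QpcrGroup,
                     efficiency: float | None = None) -> FoldChangeResult:
    """Relative expression of ``group_a`` vs the calibrator by ddCt.

    dCt = Ct_target - Ct_reference per replicate; ddCt = mean dCt(group_a) -
    mean dCt(calibrator); fold = 2^(-ddCt), or (1+E)^(-ddCt) when an
    ``efficiency`` is supplied.
    """
    group_a = group_a.value if isinstance(group_a, QpcrGroup) else group_a
    calibrator = (calibrator_group.value
                  if isinstance(calibrator_group, QpcrGroup) else calibrator_group)
    if calibrator not in set(plate.wells["group"]):
        raise ValueError(f"calibrator group {calibrator!r} missing from plate")
    dct_a = _delta_ct(plate, gene, group_a)
    dct_cal = _delta_ct(plate, gene, calibrator)
    per_rep = dct_a - dct_cal.mean()
    ddct = float(dct_a.mean() - dct_cal.mean())
    base = 2.0 if efficiency is None else 1.0 + efficiency
    return FoldChangeResult(
        gene=gene,
        group=group_a,
        calibrator=calibrator,
        ddct_mean=ddct,
        ddct_sd=float(per_rep.std(ddof=1)) if per_rep.size > 1 else 0.0,
        fold_change=float(base ** (-ddct)),
        per_replicate_ddct=tuple(float(v) for v in per_rep),
    )


def concordance_table(qpcr_folds: Mapping[str, float],
                      rnaseq_log2fc: Mapping[str, float],
                      min_effect: float = 0.5) -> tuple[pd.DataFrame, float]:
    """Side-by-side qPCR vs RNA-seq fold changes with direction agreement.

    Returns the per-gene table and the Pearson correlation of log2 folds over
    shared genes.  A gene is direction-concordant when both platforms agree in
    sign beyond ``min_effect`` log2 units, or both are flat within it.
    """
    shared = sorted(set(qpcr_folds) & set(rnaseq_log2fc))
    if not shared:
        raise ValueError("no genes shared between qPCR and RNA-seq inputs")
    rows = []
    for gene in shared:
        q = math.log2(qpcr_folds[gene])
        r = float(rnaseq_log2fc[gene])
        q_dir = 0 if abs(q) < min_effect else (1 if q > 0 else -1)
        r_dir = 0 if abs(r) < min_effect else (1 if r > 0 else -1)
        rows.append({
            "gene": gene,
            "qpcr_fold": qpcr_folds[gene],
            "qpcr_log2_fold": q,
            "rnaseq_log2_fold": r,
            "direction_concordant": q_dir == r_dir,
        })
    table = pd.DataFrame(rows)
    if len(shared) > 1:
        correlation = float(stats.pearsonr(
            table["qpcr_log2_fold"], table["rnaseq_log2_fold"]).statistic)
    else:
        correlation = float("nan")
    return table, correlation
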