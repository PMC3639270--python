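"""Per-gene Poisson-rate differential expression with optional overdispersion.

The model for gene *g* in sample *s* is

    y_gs ~ Poisson(mu_gs),   log mu_gs = log N_s + x_s' beta_g

where ``N_s`` is the sample's library size (total tags) and ``x_s`` encodes
cleavage stage and embryo source.  Counts are normalised by total reads per
sample through the offset, never rescaled.  Nested models are compared by the
likelihood-ratio test; genes whose full-model expected counts are >= 5 in at
least two samples are retained (to keep the chi-square asymptotics of the LRT
honest) and the Benjamini–Hochberg step-up controls the FDR over retained
genes.

Extra-Poisson variability is handled quasi-likelihood style: a Pearson
dispersion ``phi`` is estimated per gene under the full model (floored at 1 —
underdispersion never sharpens inference) and the LRT is scaled by it.  With
only a handful of samples the residual degrees of freedom are tiny and the
variability of ``phi`` matters: referring the scaled statistic to chi-square
is anticonservative, so the stage/source analyses refer ``LRT/(phi*df)`` to
``F(df, df_residual)`` by default; the plain scaled-chi-square form is
available via ``reference="chisq"``.

Fitting is by iteratively reweighted least squares, vectorised across genes
(one shared design matrix, per-gene weights).  Genes with a structurally empty
factor level (e.g. all 4-cell counts zero) have their MLE on the boundary; they
are fitted with the linear predictor clamped, flagged ``boundary``, and are
meant to be interpreted through categorisation rather than through their
asymptotic p-value alone.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import math
from typing import Sequence

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io_tables import CountMatrix, SampleDesign, Stage, Source

logger = logging.getLogger("egaflow")

__all__ = [
    "Formula",
    "Model",
    "GeneFit",
    "GeneTestResult",
    "fit_poisson",
    "lrt",
    "estimate_dispersion",
    "overdispersed_test",
    "expected_count_filter",
    "adjust_bh",
    "run_stage_analysis",
    "run_source_analysis",
]

LN2 = math.log(2.0)

# IRLS controls.  Convergence is on relative deviance change; the tolerance is
# kept well below 1e-8 so that converged log-likelihoods are good to ~1e-10
# (Newton steps are quadratic once close).
_IRLS_TOL = 1e-10
_IRLS_MAXIT = 50
_MU_FLOOR = 1e-8  # keeps weights/log-likelihood finite at boundary fits
_ETA_CLIP = 45.0


class Formula(enum.Enum):
    """Nested mean structures for the per-gene rate model."""

    FULL_MAIN = "full_main"                    # ~ stage + source
    REDUCED_NO_STAGE = "reduced_no_stage"      # ~ source
    FULL_INTERACTION = "full_interaction"      # ~ stage * source (cell means)
    REDUCED_NO_SOURCE_WITHIN_STAGE = "reduced_no_source_within_stage"


class Model(str, enum.Enum):
    STANDARD = "standard"
    OVERDISPERSED = "overdispersed"


# pairs (full, reduced) that admit a likelihood-ratio test
_NESTED: set[tuple[Formula, Formula]] = {
    (Formula.FULL_MAIN, Formula.REDUCED_NO_STAGE),
    (Formula.FULL_INTERACTION, Formula.REDUCED_NO_SOURCE_WITHIN_STAGE),
    (Formula.FULL_INTERACTION, Formula.FULL_MAIN),
}


@dataclasses.dataclass
class GeneFit:
    """A fitted per-gene Poisson rate model."""

    formula: Formula
    coef_names: list[str]
    coefficients: np.ndarray        # natural-log scale
    fitted_means: np.ndarray        # mu_gs, one per sample
    log_likelihood: float
    converged: bool
    boundary: bool                  # an MLE on the boundary (empty level)
    df_residual: int
    n_parameters: int

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.coef_names.index(name)])


@dataclasses.dataclass
class GeneTestResult:
    """Outcome of one gene's differential-expression test."""

    gene_id: str
    lrt_statistic: float
    dispersion_phi: float
    p_raw: float
    p_adjusted: float
    log2_fold_change: float
    retained_by_filter: bool
    significant: bool
    boundary: bool = False
    converged: bool = True
    log2_fold_change_cpm: float = float("nan")


def _design_matrix(design: SampleDesign, formula: Formula,
                   stage: Stage | None = None) -> tuple[np.ndarray, list[str]]:
    """Build the shared design matrix (samples x parameters).

    Treatment coding for the main-effects models (reference: 2-cell, in vivo);
    cell-means coding for the interaction model.  Factors constant in the
    design are dropped so that e.g. a single-source experiment still fits.
    """
    stage4 = design.stage_mask(Stage.FOUR_CELL).astype(float)
    ivt = design.source_mask(Source.IN_VITRO).astype(float)
    two_stages = 0.0 < stage4.mean() < 1.0
    two_sources = 0.0 < ivt.mean() < 1.0

    if formula is Formula.FULL_MAIN:
        cols, names = [np.ones(design.n_samples)], ["intercept"]
        if two_stages:
            cols.append(stage4)
            names.append("stage")
        if two_sources:
            cols.append(ivt)
            names.append("source")
        return np.column_stack(cols), names

    if formula is Formula.REDUCED_NO_STAGE:
        cols, names = [np.ones(design.n_samples)], ["intercept"]
        if two_sources:
            cols.append(ivt)
            names.append("source")
        return np.column_stack(cols), names

    if formula is Formula.FULL_INTERACTION:
        cols, names = [], []
        for st in (Stage.TWO_CELL, Stage.FOUR_CELL):
            for so in (Source.IN_VIVO, Source.IN_VITRO):
                mask = design.stage_mask(st) & design.source_mask(so)
                if mask.any():
                    cols.append(mask.astype(float))
                    names.append(f"cell[{st.value},{so.value}]")
        return np.column_stack(cols), names

    if formula is Formula.REDUCED_NO_SOURCE_WITHIN_STAGE:
        if stage is None:
            raise ValueError("REDUCED_NO_SOURCE_WITHIN_STAGE needs a stage")
        cols, names = [], []
        merged = design.stage_mask(stage)
        cols.append(merged.astype(float))
        names.append(f"stage[{stage.value}]")
        other = Stage.FOUR_CELL if stage is Stage.TWO_CELL else Stage.TWO_CELL
        for so in (Source.IN_VIVO, Source.IN_VITRO):
            mask = design.stage_mask(other) & design.source_mask(so)
            if mask.any():
                cols.append(mask.astype(float))
                names.append(f"cell[{other.value},{so.value}]")
        return np.column_stack(cols), names

    raise ValueError(f"unknown formula: {formula}")


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> np.ndarray:
    """Row-wise Poisson log-likelihood (full, including the y! term)."""
    return (special.xlogy(y, mu) - mu - special.gammaln(y + 1.0)).sum(axis=-1)


def _detect_boundary(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Genes whose MLE is on the boundary: some indicator column of the design
    covers only zero counts (or, with an intercept, the whole gene is zero)."""
    boundary = np.zeros(Y.shape[0], dtype=bool)
    for j in range(X.shape[1]):
        col = X[:, j]
        if not np.all((col == 0) | (col == 1)):
            continue
        mask = col == 1
        if mask.any():
            boundary |= Y[:, mask].sum(axis=1) == 0
    boundary |= Y.sum(axis=1) == 0
    return boundary


def _irls_batch(Y: np.ndarray, X: np.ndarray, offset: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit log mu = offset + X beta for every row of Y at once.

    Returns (betas, mus, logliks, converged).
    """
    Y = np.asarray(Y, dtype=float)
    G, S = Y.shape
    p = X.shape[1]

    # warm start from the linearised problem on (y + 0.5)
    z0 = np.log((Y + 0.5)) - offset[None, :]
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (G, p)

    eta = offset[None, :] + beta @ X.T
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    mu = np.maximum(np.exp(eta), _MU_FLOOR)
    dev = -2.0 * _poisson_loglik(Y, mu)
    converged = np.zeros(G, dtype=bool)

    for _ in range(_IRLS_MAXIT):
        active = ~converged
        if not active.any():
            break
        w = mu[active]                                   # Poisson weights
        z = (eta[active] - offset[None, :]) + (Y[active] - mu[active]) / mu[active]
        # normal equations per gene: (X' W X) beta = X' W z
        xtwx = np.einsum("sp,gs,sq->gpq", X, w, X)
        xtwz = np.einsum("sp,gs->gp", X, w * z)
        # tiny ridge keeps boundary genes (vanishing weights) solvable
        xtwx += 1e-12 * np.eye(p)[None, :, :]
        beta_new = np.linalg.solve(xtwx, xtwz[..., None])[..., 0]
        beta[active] = beta_new

        eta[active] = np.clip(offset[None, :] + beta_new @ X.T, -_ETA_CLIP, _ETA_CLIP)
        mu[active] = np.maximum(np.exp(eta[active]), _MU_FLOOR)
        dev_new = -2.0 * _poisson_loglik(Y[active], mu[active])
        rel = np.abs(dev_new - dev[active]) / (np.abs(dev[active]) + 0.1)
        dev[active] = dev_new
        newly = np.where(active)[0][rel < _IRLS_TOL]
        converged[newly] = True

    loglik = _poisson_loglik(Y, mu)
    return beta, mu, loglik, converged


def fit_poisson(gene_counts: Sequence[int], design: SampleDesign,
                library_sizes: Sequence[float], formula: Formula,
                stage: Stage | None = None) -> GeneFit:
    """Maximum-likelihood Poisson rate fit for one gene.

    ``log mu_s = log N_s + x_s' beta``, fitted by IRLS.  A structurally empty
    factor level does not raise: the fit is returned with ``boundary=True``
    and the linear predictor clamped at a large negative value.
    """
    y = np.asarray(gene_counts, dtype=float)
    if (y < 0).any() or not np.all(np.mod(y, 1) == 0):
        raise ValueError("gene counts must be non-negative integers")
    N = np.asarray(library_sizes, dtype=float)
    if (N <= 0).any():
        raise ValueError("library sizes must be positive")
    X, names = _design_matrix(design, formula, stage=stage)
    if y.shape[0] != X.shape[0]:
        raise ValueError("gene counts length does not match the design")
    for j in range(X.shape[1]):
        mask = X[:, j] == 1
        if np.all((X[:, j] == 0) | (X[:, j] == 1)) and not mask.any():
            raise ValueError(f"factor level {names[j]} has no samples")

    beta, mu, ll, conv = _irls_batch(y[None, :], X, np.log(N))
    boundary = bool(_detect_boundary(y[None, :], X)[0])
    return GeneFit(
        formula=formula,
        coef_names=names,
        coefficients=beta[0],
        fitted_means=mu[0],
        log_likelihood=float(ll[0]),
        converged=bool(conv[0]) or boundary,
        boundary=boundary,
        df_residual=y.shape[0] - X.shape[1],
        n_parameters=X.shape[1],
    )


def lrt(full: GeneFit, reduced: GeneFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (statistic, df, p).

    ``statistic = 2 (l_full - l_reduced)``, clamped at zero against round-off,
    referred to chi-square with df = parameter difference.
    """
    if (full.formula, reduced.formula) not in _NESTED:
        raise ValueError(
            f"{reduced.formula.name} is not nested in {full.formula.name}"
        )
    df = full.n_parameters - reduced.n_parameters
    if df <= 0:
        raise ValueError("full model has no extra parameters over the reduced")
    statistic = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def estimate_dispersion(fit: GeneFit, gene_counts: Sequence[int]) -> float:
    """Pearson dispersion under the fitted (full) model, floored at 1.

    ``phi = max(1, X^2 / df_residual)`` with ``X^2 = sum (y - mu)^2 / mu``.
    A saturated fit (df_residual = 0) cannot estimate dispersion; returns 1.
    """
    if fit.df_residual <= 0:
        logger.debug("saturated model: dispersion not estimable, phi = 1")
        return 1.0
    y = np.asarray(gene_counts, dtype=float)
    x2 = float(((y - fit.fitted_means) ** 2 / np.maximum(fit.fitted_means, _MU_FLOOR)).sum())
    return max(1.0, x2 / fit.df_residual)


def overdispersed_test(full: GeneFit, reduced: GeneFit, phi: float,
                       reference: str = "chisq") -> tuple[float, float]:
    """Dispersion-scaled likelihood-ratio test: (scaled_statistic, p).

    ``reference="chisq"``: LRT/phi vs chi-square(df).  ``reference="f"``:
    LRT/(phi*df) vs F(df, df_residual) — better calibrated when df_residual
    is small, since it accounts for the sampling noise of phi.
    """
    if phi < 1.0:
        raise ValueError("phi must be >= 1 (floored dispersion)")
    statistic, df, _ = lrt(full, reduced)
    scaled = statistic / phi
    if reference == "chisq":
        p = float(stats.chi2.sf(scaled, df))
    elif reference == "f":
        if full.df_residual <= 0:
            raise ValueError("F reference needs df_residual >= 1")
        p = float(stats.f.sf(scaled / df, df, full.df_residual))
    else:
        raise ValueError(f"unknown reference: {reference!r}")
    return scaled, p


def expected_count_filter(fitted_means: np.ndarray, min_count: float = 5.0,
                          min_samples: int = 2) -> np.ndarray:
    """Retention mask: full-model expected counts >= min_count in >= min_samples.

    ``fitted_means`` is genes x samples.  Genes failing the filter are excluded
    from testing to preserve the asymptotic behaviour of the LRT.
    """
    fitted_means = np.atleast_2d(np.asarray(fitted_means, dtype=float))
    return (fitted_means >= min_count).sum(axis=1) >= min_samples


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _cpm_log2fc(counts: np.ndarray, library_sizes: np.ndarray,
                mask_num: np.ndarray, mask_den: np.ndarray,
                pseudocount: float = 0.5) -> np.ndarray:
    """Descriptive log2 fold change of mean CPM (numerator over denominator)."""
    cpm = 1e6 * counts / library_sizes[None, :]
    num = cpm[:, mask_num].mean(axis=1) + pseudocount
    den = cpm[:, mask_den].mean(axis=1) + pseudocount
    return np.log2(num / den)


def _bh_over_retained(p_raw: np.ndarray, retained: np.ndarray) -> np.ndarray:
    p_adj = np.full_like(p_raw, np.nan)
    if retained.any():
        p_adj[retained] = adjust_bh(p_raw[retained])
    return p_adj


def run_stage_analysis(counts: CountMatrix, design: SampleDesign,
                       model: Model = Model.OVERDISPERSED,
                       alpha: float = 0.05,
                       min_expected: float = 5.0, min_samples: int = 2,
                       overdispersion_reference: str = "f",
                       ) -> list[GeneTestResult]:
    """Test every gene for a cleavage-stage effect (4-cell vs 2-cell).

    Fits ``~ stage + source`` against ``~ source`` per gene, applies the
    expected-count retention filter, scales by the Pearson dispersion when
    ``model`` is OVERDISPERSED, and BH-adjusts over retained genes only.
    ``log2_fold_change`` is the stage coefficient / ln 2 (4-cell over 2-cell);
    boundary genes additionally carry a descriptive CPM-based fold change.
    """
    Y = counts.counts.astype(float)
    N = counts.library_sizes.astype(float)
    offset = np.log(N)

    X_full, names_full = _design_matrix(design, Formula.FULL_MAIN)
    X_red, _ = _design_matrix(design, Formula.REDUCED_NO_STAGE)
    if "stage" not in names_full:
        raise ValueError("both stages must be present to test a stage effect")
    stage_idx = names_full.index("stage")
    df = X_full.shape[1] - X_red.shape[1]
    df_resid = counts.n_samples - X_full.shape[1]

    beta_f, mu_f, ll_f, conv_f = _irls_batch(Y, X_full, offset)
    _, _, ll_r, conv_r = _irls_batch(Y, X_red, offset)
    boundary = _detect_boundary(Y, X_full)

    retained = expected_count_filter(mu_f, min_expected, min_samples)
    statistic = np.maximum(0.0, 2.0 * (ll_f - ll_r))

    x2 = ((Y - mu_f) ** 2 / np.maximum(mu_f, _MU_FLOOR)).sum(axis=1)
    phi = np.maximum(1.0, x2 / df_resid) if df_resid > 0 else np.ones(len(Y))

    if model is Model.STANDARD:
        p_raw = stats.chi2.sf(statistic, df)
        phi_used = np.ones_like(phi)
    else:
        phi_used = phi
        if overdispersion_reference == "f":
            p_raw = stats.f.sf(statistic / (phi * df), df, df_resid)
        elif overdispersion_reference == "chisq":
            p_raw = stats.chi2.sf(statistic / phi, df)
        else:
            raise ValueError(
                f"unknown overdispersion reference: {overdispersion_reference!r}"
            )

    p_raw = np.where(retained, p_raw, np.nan)
    p_adj = _bh_over_retained(p_raw, retained)
    significant = retained & (p_adj < alpha)

    log2fc = beta_f[:, stage_idx] / LN2
    mask4 = design.stage_mask(Stage.FOUR_CELL)
    cpm_fc = _cpm_log2fc(counts.counts, N, mask4, ~mask4)

    results = []
    for g, gene in enumerate(counts.gene_ids):
        results.append(GeneTestResult(
            gene_id=gene,
            lrt_statistic=float(statistic[g]),
            dispersion_phi=float(phi_used[g]),
            p_raw=float(p_raw[g]),
            p_adjusted=float(p_adj[g]),
            log2_fold_change=float(log2fc[g]),
            retained_by_filter=bool(retained[g]),
            significant=bool(significant[g]),
            boundary=bool(boundary[g]),
            converged=bool(conv_f[g] and conv_r[g]) or bool(boundary[g]),
            log2_fold_change_cpm=float(cpm_fc[g]) if boundary[g] else float("nan"),
        ))
    return results


def run_source_analysis(counts: CountMatrix, design: SampleDesign,
                        model: Model = Model.OVERDISPERSED,
                        alpha: float = 0.05,
                        min_expected: float = 5.0, min_samples: int = 2,
                        overdispersion_reference: str = "f",
                        ) -> dict[Stage, list[GeneTestResult]]:
    """Test the in vitro vs in vivo contrast within each stage.

    Fits the stage-by-source interaction model (free cell means) and, per
    stage, drops the source split within that stage for the reduced model.
    BH is applied within each stage separately, over retained genes.
    Direction: positive log2 fold change = up in vitro.
    """
    Y = counts.counts.astype(float)
    N = counts.library_sizes.astype(float)
    offset = np.log(N)

    X_full, names_full = _design_matrix(design, Formula.FULL_INTERACTION)
    df_resid = counts.n_samples - X_full.shape[1]
    beta_f, mu_f, ll_f, conv_f = _irls_batch(Y, X_full, offset)
    boundary = _detect_boundary(Y, X_full)
    retained = expected_count_filter(mu_f, min_expected, min_samples)

    x2 = ((Y - mu_f) ** 2 / np.maximum(mu_f, _MU_FLOOR)).sum(axis=1)
    phi = np.maximum(1.0, x2 / df_resid) if df_resid > 0 else np.ones(len(Y))

    out: dict[Stage, list[GeneTestResult]] = {}
    for stage in (Stage.TWO_CELL, Stage.FOUR_CELL):
        in_stage = design.stage_mask(stage)
        sources_here = {design.sources[i] for i in range(design.n_samples) if in_stage[i]}
        if len(sources_here) < 2:
            logger.warning("stage %s has a single source; skipped", stage.value)
            continue

        X_red, _ = _design_matrix(
            design, Formula.REDUCED_NO_SOURCE_WITHIN_STAGE, stage=stage
        )
        _, _, ll_r, _ = _irls_batch(Y, X_red, offset)
        df = X_full.shape[1] - X_red.shape[1]
        statistic = np.maximum(0.0, 2.0 * (ll_f - ll_r))

        if model is Model.STANDARD:
            p_raw = stats.chi2.sf(statistic, df)
            phi_used = np.ones_like(phi)
        else:
            phi_used = phi
            if overdispersion_reference == "f":
                p_raw = stats.f.sf(statistic / (phi * df), df, df_resid)
            elif overdispersion_reference == "chisq":
                p_raw = stats.chi2.sf(statistic / phi, df)
            else:
                raise ValueError(
                    f"unknown overdispersion reference: {overdispersion_reference!r}"
                )

        p_raw = np.where(retained, p_raw, np.nan)
        p_adj = _bh_over_retained(p_raw, retained)
        significant = retained & (p_adj < alpha)

        ivt_col = names_full.index(f"cell[{stage.value},{Source.IN_VITRO.value}]")
        ivv_col = names_full.index(f"cell[{stage.value},{Source.IN_VIVO.value}]")
        log2fc = (beta_f[:, ivt_col] - beta_f[:, ivv_col]) / LN2

        mask_ivt = in_stage & design.source_mask(Source.IN_VITRO)
        mask_ivv = in_stage & design.source_mask(Source.IN_VIVO)
        cpm_fc = _cpm_log2fc(counts.counts, N, mask_ivt, mask_ivv)

        out[stage] = [
            GeneTestResult(
                gene_id=gene,
                lrt_statistic=float(statistic[g]),
                dispersion_phi=float(phi_used[g]),
                p_raw=float(p_raw[g]),
                p_adjusted=float(p_adj[g]),
                log2_fold_change=float(log2fc[g]),
                retained_by_filter=bool(retained[g]),
                significant=bool(significant[g]),
                boundary=bool(boundary[g]),
                converged=bool(conv_f[g]) or bool(boundary[g]),
                log2_fold_change_cpm=float(cpm_fc[g]) if boundary[g] else float("nan"),
            )
            for g, gene in enumerate(counts.gene_ids)
        ]
    return out


def results_to_frame(results: Sequence[GeneTestResult]):
    """Flatten results to a DataFrame with one row per gene."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(r) for r in results])
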