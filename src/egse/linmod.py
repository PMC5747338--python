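"""Gene-wise linear models with empirical-Bayes variance moderation.

Every base gene set test consumes the same gene-level statistics: per-contrast
log2 fold-changes, moderated t-statistics, two-sided p-values and BH false
discovery rates from weighted least-squares fits of each gene's expression on
the experimental design.  Variance moderation borrows strength across genes by
fitting a scaled inverse-chi-square prior (s0^2 on d0 degrees of freedom) to
the observed residual variances via a method-of-moments match on log s^2, then
shrinking each gene's variance towards s0^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "LinearFit",
    "GeneLevelStats",
    "fit_linear_model",
    "apply_contrasts",
    "ebayes_moderate",
    "gene_level_stats",
    "top_table",
    "bh_adjust",
    "read_design_csv",
    "read_contrasts_csv",
    "validate_design",
    "validate_contrasts",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def validate_design(design: pd.DataFrame, n_samples: int | None = None) -> np.ndarray:
    X = np.asarray(design, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be 2-D (samples x coefficients)")
    if n_samples is not None and X.shape[0] != n_samples:
        raise ValueError(f"design has {X.shape[0]} rows but data has {n_samples} samples")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not of full column rank")
    return X


def validate_contrasts(contrasts: pd.DataFrame, design: pd.DataFrame) -> np.ndarray:
    C = np.asarray(contrasts, dtype=float)
    if list(contrasts.index) != list(design.columns):
        raise ValueError(
            "contrast rows must match design coefficients: "
            f"{list(contrasts.index)} vs {list(design.columns)}"
        )
    if np.any(np.all(C == 0, axis=0)):
        raise ValueError("every contrast column must be non-zero")
    return C


@dataclass
class LinearFit:
    """Per-gene WLS fit: coefficients, residual variances/dofs and residuals."""

    design: pd.DataFrame
    coefficients: np.ndarray      # genes x p
    sigma2: np.ndarray            # genes
    df_residual: int
    residuals: np.ndarray         # genes x samples
    xtwx_inv: np.ndarray          # genes x p x p
    gene_ids: list[str]
    ave_expr: np.ndarray          # genes


def fit_linear_model(em, design: pd.DataFrame) -> LinearFit:
    """Weighted least squares per gene (weights from ``em.weights`` when present)."""
    X = validate_design(design, em.n_samples)
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom (n <= p)")
    y = em.values
    W = em.weights if em.weights is not None else np.ones_like(y)
    xtwx = np.einsum("ni,gn,nj->gij", X, W, X)
    xtwx_inv = np.linalg.inv(xtwx)
    xtwy = np.einsum("ni,gn,gn->gi", X, W, y)
    beta = np.einsum("gij,gj->gi", xtwx_inv, xtwy)
    resid = y - beta @ X.T
    sigma2 = np.einsum("gn,gn->g", W * resid, resid) / (n - p)
    return LinearFit(
        design=design,
        coefficients=beta,
        sigma2=sigma2,
        df_residual=n - p,
        residuals=resid,
        xtwx_inv=xtwx_inv,
        gene_ids=list(em.gene_ids),
        ave_expr=y.mean(axis=1),
    )


def apply_contrasts(fit: LinearFit, contrasts: pd.DataFrame):
    """Contrast estimates (logFC) and unscaled standard errors per gene.

    Returns ``(logfc, stdev_unscaled)``, each genes × contrasts.
    """
    C = validate_contrasts(contrasts, fit.design)
    logfc = fit.coefficients @ C
    var_unscaled = np.einsum("ic,gij,jc->gc", C, fit.xtwx_inv, C)
    return logfc, np.sqrt(var_unscaled)


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += step
        if abs(step) < tol * x:
            break
    return float(x)


@dataclass
class ModeratedStats:
    d0: float
    s0_sq: float
    posterior_var: np.ndarray     # genes
    t: np.ndarray                 # genes x contrasts
    p: np.ndarray                 # genes x contrasts
    df_total: float


def ebayes_moderate(sigma2: np.ndarray, df: int, logfc: np.ndarray,
                    stdev_unscaled: np.ndarray, prior_df: float | None = None) -> ModeratedStats:
    """Empirical-Bayes variance moderation and moderated t-statistics.

    Fits the prior (``d0``, ``s0_sq``) by matching moments of log sigma^2
    against the scaled-chi-square sampling distribution (digamma/trigamma
    identities).  Zero spread in log sigma^2 gives ``d0 = +inf`` (all
    posterior variances equal ``s0_sq`` and the t reference becomes normal).
    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary t-test).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    ok = np.isfinite(sigma2) & (sigma2 > 0)
    if ok.sum() < 2:
        raise ValueError("need at least two genes with positive residual variance")
    z = np.log(sigma2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))

    if prior_df is not None:
        d0 = float(prior_df)
        if d0 == 0:
            s0_sq = float(np.exp(e_mean))  # irrelevant at zero prior weight
        elif np.isinf(d0):
            s0_sq = float(np.mean(sigma2[ok]))
        else:
            s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    elif e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        # zero spread in log s^2: infinitely informative prior at the mean
        d0 = np.inf
        s0_sq = float(np.mean(sigma2[ok]))

    if np.isinf(d0):
        post_var = np.full_like(sigma2, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        post_var = sigma2.copy()
        df_total = float(df)
    else:
        post_var = (d0 * s0_sq + df * sigma2) / (d0 + df)
        df_total = float(d0 + df)

    post_sd = np.sqrt(post_var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / (stdev_unscaled * post_sd[:, None])
    t = np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return ModeratedStats(d0=d0, s0_sq=s0_sq, posterior_var=post_var,
                          t=t, p=p, df_total=df_total)


@dataclass
class GeneLevelStats:
    """Per-gene, per-contrast differential expression statistics."""

    gene_ids: list[str]
    contrast_names: list[str]
    logfc: np.ndarray             # genes x contrasts
    t: np.ndarray
    p: np.ndarray
    fdr: np.ndarray
    ave_expr: np.ndarray
    df_residual: int
    d0: float
    s0_sq: float
    posterior_sd: np.ndarray
    df_total: float
    residuals: np.ndarray
    design: pd.DataFrame
    contrasts: pd.DataFrame
    symbols: dict[str, str] = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def contrast_column(self, contrast: str) -> int:
        try:
            return self.contrast_names.index(contrast)
        except ValueError:
            raise KeyError(f"unknown contrast {contrast!r}; have {self.contrast_names}") from None

    def symbol_of(self, gene: str) -> str:
        return self.symbols.get(gene, gene)


def gene_level_stats(em, design: pd.DataFrame, contrasts: pd.DataFrame,
                     symbols: dict[str, str] | None = None,
                     prior_df: float | None = None) -> GeneLevelStats:
    """Fit, contrast and moderate in one step; BH-adjust p per contrast."""
    fit = fit_linear_model(em, design)
    logfc, se_u = apply_contrasts(fit, contrasts)
    mod = ebayes_moderate(fit.sigma2, fit.df_residual, logfc, se_u, prior_df=prior_df)
    fdr = np.column_stack([bh_adjust(mod.p[:, j]) for j in range(mod.p.shape[1])])
    return GeneLevelStats(
        gene_ids=fit.gene_ids,
        contrast_names=[str(c) for c in contrasts.columns],
        logfc=logfc,
        t=mod.t,
        p=mod.p,
        fdr=fdr,
        ave_expr=fit.ave_expr,
        df_residual=fit.df_residual,
        d0=mod.d0,
        s0_sq=mod.s0_sq,
        posterior_sd=np.sqrt(mod.posterior_var),
        df_total=mod.df_total,
        residuals=fit.residuals,
        design=design,
        contrasts=contrasts,
        symbols=dict(symbols or {}),
    )


def top_table(gls: GeneLevelStats, contrast: str, n: int | None = None) -> pd.DataFrame:
    """Top differentially expressed genes for one contrast, sorted by p-value."""
    j = gls.contrast_column(contrast)
    df = pd.DataFrame({
        "FeatureID": gls.gene_ids,
        "Symbol": [gls.symbol_of(g) for g in gls.gene_ids],
        "logFC": gls.logfc[:, j],
        "AveExpr": gls.ave_expr,
        "t": gls.t[:, j],
        "P.Value": gls.p[:, j],
        "adj.P.Val": gls.fdr[:, j],
    })
    df = df.sort_values(["P.Value", "FeatureID"], kind="stable").reset_index(drop=True)
    return df if n is None else df.head(n)


def read_design_csv(path: str | Path) -> pd.DataFrame:
    """Design CSV: header of coefficient names, first column of sample labels."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df.astype(float)


def read_contrasts_csv(path: str | Path) -> pd.DataFrame:
    """Contrast CSV: header of contrast names, first column of coefficient labels."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df.astype(float)
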