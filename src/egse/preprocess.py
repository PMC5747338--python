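"""Count and probe-level preprocessing.

Two optional entry paths feed the gene-level linear model:

* RNA-seq counts → TMM normalisation factors → log-CPM → mean–variance
  precision weights (the voom approach: model sqrt residual standard
  deviation against average log-count and weight each observation by the
  inverse fourth power of its predicted sqrt-sd).
* Microarray-style intensities → detection-p filtering (keep features
  detected, p < alpha, in at least ``min_samples`` arrays) → per-gene probe
  collapse keeping the probe with the highest average expression.

Both paths are optional: a ready-made log-expression matrix is accepted
directly by the rest of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "tmm_norm_factors",
    "log_cpm",
    "voom_weights",
    "detection_filter",
    "collapse_features",
    "read_counts_tsv",
    "read_expression_tsv",
]


@dataclass
class CountMatrix:
    """Raw counts, genes × samples, with library sizes and normalisation factors."""

    counts: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    norm_factors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        ng, ns = self.counts.shape
        if len(self.gene_ids) != ng or len(self.sample_ids) != ns:
            raise ValueError("gene/sample ID lengths do not match counts shape")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("duplicate gene IDs")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if self.norm_factors is None:
            self.norm_factors = np.ones(ns)
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class ExpressionMatrix:
    """Log2-scale expression, genes × samples, with optional observation weights."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        ng, ns = self.values.shape
        if len(self.gene_ids) != ng or len(self.sample_ids) != ns:
            raise ValueError("gene/sample ID lengths do not match values shape")
        if len(set(self.gene_ids)) != ng:
            raise ValueError("duplicate gene IDs")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no missing values)")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights shape must match values")
            if np.any(self.weights <= 0):
                raise ValueError("weights must be strictly positive")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              trim_m: float, trim_a: float) -> float:
    """Trimmed weighted mean of M-values for one library against the reference.

    Genes with a zero count in either library are excluded.  Trimming is
    rank-based: the most extreme ``trim_m`` fraction of M-values on each side
    and ``trim_a`` fraction of A-values on each side are removed before the
    precision-weighted average (weights are the delta-method binomial
    variances of M).
    """
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    # degenerate: essentially identical libraries
    if np.max(np.abs(m)) < 1e-6:
        return 0.0
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = np.empty(n, dtype=int)
    rank_m[np.argsort(m, kind="stable")] = np.arange(1, n + 1)
    rank_a = np.empty(n, dtype=int)
    rank_a[np.argsort(a, kind="stable")] = np.arange(1, n + 1)
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2):
        return 0.0
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep2]
    return float(np.sum(m[keep2] * inv_w) / np.sum(inv_w))


def tmm_norm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalisation factors, geometric mean 1.

    The reference library is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction across samples.
    """
    lib = cm.lib_sizes
    if np.any(lib <= 0):
        raise ValueError("every sample must have a positive library size")
    q75 = np.array([
        np.percentile(cm.counts[:, j][cm.counts[:, j] >= 0], 75) / lib[j]
        for j in range(cm.n_samples)
    ])
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    ref = cm.counts[:, ref_idx]
    log_f = np.array([
        _tmm_pair(cm.counts[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
        for j in range(cm.n_samples)
    ])
    f = 2.0 ** log_f
    f /= np.exp(np.mean(np.log(f)))
    return f


def log_cpm(cm: CountMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million: ``log2((count + prior) / (eff_lib + 2*prior) * 1e6)``.

    The effective library size is ``lib_size * norm_factor``.
    """
    eff = cm.lib_sizes * cm.norm_factors
    vals = np.log2((cm.counts + prior) / (eff + 2.0 * prior)[None, :] * 1e6)
    return ExpressionMatrix(values=vals, gene_ids=list(cm.gene_ids),
                            sample_ids=list(cm.sample_ids))


# ---------------------------------------------------------------------------
# Mean-variance precision weights
# ---------------------------------------------------------------------------

def voom_weights(cm: CountMatrix, design: pd.DataFrame, span: float = 0.5,
                 prior: float = 0.5) -> ExpressionMatrix:
    """Log-CPM with per-observation precision weights from the mean–variance trend.

    Gene-wise linear models are fitted to the log-CPM values; a lowess curve of
    sqrt residual standard deviation against average log2 count captures the
    mean–variance relationship; each observation's weight is the inverse fourth
    power of its predicted sqrt-sd (interpolated at the observation's fitted
    log-count, constant beyond the fitted range).  Weights are clipped to
    [1e-6, 1e6].
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n != cm.n_samples:
        raise ValueError("design rows must match sample count")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is not of full column rank")
    if n - p < 1:
        raise ValueError("no residual degrees of freedom")

    em = log_cpm(cm, prior=prior)
    y = em.values
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ beta).T
    resid = y - fitted
    sigma = np.sqrt((resid ** 2).sum(axis=1) / (n - p))

    eff = cm.lib_sizes * cm.norm_factors
    # average log2 count per gene (log-cpm mean shifted back to the count scale)
    mean_log_lib = np.mean(np.log2(eff + 2.0 * prior))
    sx = y.mean(axis=1) + mean_log_lib - np.log2(1e6)
    sy = np.sqrt(sigma)

    trend = _sm_lowess(sy, sx, frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # fitted log2-count for every observation, then interpolate sqrt-sd
    fitted_count = fitted + (np.log2(eff + 2.0 * prior) - np.log2(1e6))[None, :]
    pred = np.interp(fitted_count, tx, ty)  # constant extrapolation at both ends
    pred = np.clip(pred, 1e-3, None)
    w = np.clip(pred ** -4.0, 1e-6, 1e6)
    return ExpressionMatrix(values=y, gene_ids=list(cm.gene_ids),
                            sample_ids=list(cm.sample_ids), weights=w)


# ---------------------------------------------------------------------------
# Microarray-style filtering / probe collapse
# ---------------------------------------------------------------------------

def detection_filter(values: np.ndarray, alpha: float = 0.05, min_samples: int = 5) -> np.ndarray:
    """Keep-mask for features detected (p < alpha) in at least ``min_samples`` samples."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("detection p-values must be 2-D (features x samples)")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("detection p-values must lie in [0, 1]")
    if min_samples > values.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    return (values < alpha).sum(axis=1) >= min_samples


def collapse_features(em: ExpressionMatrix, feature_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse multiple probes per gene to the probe with the highest mean expression.

    Features without a gene mapping are dropped.  Ties on the row mean are
    broken by first occurrence in input order.
    """
    if not feature_to_gene:
        raise ValueError("empty feature-to-gene map")
    means = em.values.mean(axis=1)
    best: dict[str, int] = {}
    for row, feat in enumerate(em.gene_ids):
        gene = feature_to_gene.get(feat)
        if gene is None:
            continue
        cur = best.get(gene)
        if cur is None or means[row] > means[cur]:
            best[gene] = row
    order = sorted(best.items(), key=lambda kv: kv[1])
    rows = [row for _, row in order]
    genes = [g for g, _ in order]
    w = em.weights[rows] if em.weights is not None else None
    return ExpressionMatrix(values=em.values[rows], gene_ids=genes,
                            sample_ids=list(em.sample_ids), weights=w)


# ---------------------------------------------------------------------------
# TSV readers
# ---------------------------------------------------------------------------

def read_counts_tsv(path: str | Path) -> CountMatrix:
    """Counts TSV: first column gene ID, header row of sample IDs."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(counts=df.to_numpy(dtype=float),
                       gene_ids=[str(g) for g in df.index],
                       sample_ids=[str(s) for s in df.columns])


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Log-expression TSV in the same layout as the counts TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df.to_numpy(dtype=float),
                            gene_ids=[str(g) for g in df.index],
                            sample_ids=[str(s) for s in df.columns])
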