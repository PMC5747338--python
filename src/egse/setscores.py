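"""Per-sample gene set activity scores.

Three summaries reduce a set's expression submatrix to one score per sample:

* PLAGE — the first right-singular vector of the gene-standardised submatrix
  (the dominant "metagene" activity), sign-aligned to correlate positively
  with the member genes on balance.
* combined z-score — sum of gene-standardised values over the set divided by
  sqrt(set size).
* ssGSEA — a per-sample running-sum enrichment score comparing the weighted
  rank ECDF of in-set genes with the ECDF of out-of-set genes, normalised
  globally by the score range.

Each score matrix is then tested for a contrast effect with an ordinary
set-level linear model (:func:`set_contrast_test`).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .gmt import CollectionIndex
from .linmod import validate_contrasts, validate_design

__all__ = [
    "SetScoreMatrix",
    "standardize_genes",
    "plage_scores",
    "zscore_scores",
    "ssgsea_scores",
    "set_contrast_test",
]


class SetScoreMatrix:
    """Sets × samples activity scores for one scoring method."""

    def __init__(self, scores: np.ndarray, set_names: list[str], sample_ids: list[str],
                 method: str, valid: np.ndarray | None = None):
        self.scores = np.asarray(scores, dtype=float)
        self.set_names = list(set_names)
        self.sample_ids = list(sample_ids)
        self.method = method
        self.valid = np.ones(len(set_names), dtype=bool) if valid is None else valid
        if self.scores.shape != (len(self.set_names), len(self.sample_ids)):
            raise ValueError("score matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.sample_ids)


def standardize_genes(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardise (mean 0, sd 1); returns (z, keep-mask of non-constant rows)."""
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    keep = (sd[:, 0] > 0) & np.isfinite(sd[:, 0])
    z = np.zeros_like(values)
    np.divide(values - mu, sd, out=z, where=sd > 0)
    return z, keep


def plage_scores(em, index: CollectionIndex) -> SetScoreMatrix:
    if em.n_samples < 2:
        raise ValueError("PLAGE needs at least two samples")
    z, keep = standardize_genes(em.values)
    n_sets = len(index)
    scores = np.zeros((n_sets, em.n_samples))
    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        idx = [i for i in s.index if keep[i]]
        if len(idx) < len(s.index):
            warnings.warn(f"set {s.name!r}: dropped {len(s.index) - len(idx)} "
                          "zero-variance gene(s) for PLAGE", stacklevel=2)
        if not idx:
            valid[row] = False
            continue
        sub = z[idx, :]
        _, _, vt = np.linalg.svd(sub, full_matrices=False)
        activity = vt[0]
        # orient: member genes should correlate positively with activity overall
        if np.sum(sub @ activity) < 0:
            activity = -activity
        scores[row] = activity
    return SetScoreMatrix(scores, index.set_names(), list(em.sample_ids), "plage", valid)


def zscore_scores(em, index: CollectionIndex) -> SetScoreMatrix:
    z, keep = standardize_genes(em.values)
    n_sets = len(index)
    scores = np.zeros((n_sets, em.n_samples))
    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        idx = [i for i in s.index if keep[i]]
        if not idx:
            valid[row] = False
            continue
        scores[row] = z[idx, :].sum(axis=0) / np.sqrt(len(idx))
    return SetScoreMatrix(scores, index.set_names(), list(em.sample_ids), "zscore", valid)


def _ssgsea_sample(order: np.ndarray, member_mask: np.ndarray, tau: float) -> np.ndarray:
    """Enrichment scores for every set given one sample's descending gene order.

    ``order`` holds gene row positions sorted by expression, highest first;
    ``member_mask`` is sets × genes.  Rank weight of the gene at descending
    position j (1-based) is ``(G - j + 1) ** tau``.
    """
    G = order.size
    rank_weight = (np.arange(G, 0, -1, dtype=float)) ** tau
    in_set = member_mask[:, order]                              # sets x G, sorted
    w = np.where(in_set, rank_weight[None, :], 0.0)
    denom_in = w.sum(axis=1, keepdims=True)
    p_in = np.cumsum(w, axis=1) / np.where(denom_in > 0, denom_in, 1.0)
    m = in_set.sum(axis=1, keepdims=True)
    p_out = np.cumsum(~in_set, axis=1) / np.maximum(G - m, 1)
    return (p_in - p_out).sum(axis=1)


def ssgsea_scores(em, index: CollectionIndex, tau: float = 0.25,
                  normalise: bool = True) -> SetScoreMatrix:
    G = em.n_genes
    mask = index.membership_matrix()
    sizes = mask.sum(axis=1)
    valid = sizes < G
    if not np.all(valid):
        bad = [index.sets[i].name for i in np.flatnonzero(~valid)]
        warnings.warn(f"ssGSEA untestable for whole-universe set(s): {bad}", stacklevel=2)
    scores = np.zeros((len(index), em.n_samples))
    for j in range(em.n_samples):
        # stable sort: ties broken by input row order
        order = np.argsort(-em.values[:, j], kind="stable")
        scores[:, j] = _ssgsea_sample(order, mask, tau)
    if normalise:
        rng_all = scores[valid].max() - scores[valid].min() if valid.any() else 0.0
        if rng_all > 0:
            scores = scores / rng_all
    return SetScoreMatrix(scores, index.set_names(), list(em.sample_ids), "ssgsea", valid)


def set_contrast_test(ssm: SetScoreMatrix, design: pd.DataFrame, contrasts: pd.DataFrame,
                      contrast: str):
    """Ordinary least squares of each set's score on the design; contrast t-test.

    Returns ``(p, direction, valid)`` arrays over sets, with ``n - p`` residual
    degrees of freedom (no variance moderation at the set level).
    """
    X = validate_design(design, len(ssm.sample_ids))
    C = validate_contrasts(contrasts, design)
    j = list(contrasts.columns).index(contrast)
    c = C[:, j]
    n, p = X.shape
    if n - p < 1:
        raise ValueError("no residual degrees of freedom at the set level")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = ssm.scores @ X @ xtx_inv.T                     # sets x p
    resid = ssm.scores - beta @ X.T
    s2 = (resid ** 2).sum(axis=1) / (n - p)
    se = np.sqrt(np.maximum(s2, 1e-300) * float(c @ xtx_inv @ c))
    est = beta @ c
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    t = np.nan_to_num(t, nan=0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), n - p)
    direction = np.sign(est).astype(int)
    return pvals, direction, ssm.valid.copy()
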