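"""Base gene set tests.

Ten tests produce a two-sided p-value and a direction per set per contrast.
Competitive tests (ora, camera, gage) ask whether set genes respond more than
the genes outside the set; self-contained tests (fry rotations, padog,
globaltest, safe, and the score-based plage/zscore/ssgsea) ask whether the set
genes respond at all.  Label-permutation tests enumerate every group split
exactly when that is cheaper than Monte-Carlo sampling, which also makes them
deterministic at small sample sizes.

All stochastic components draw from streams derived from one master seed keyed
by (method, contrast, set), so results do not depend on evaluation order or
worker count.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

from ._rng import derive_rng
from .gmt import CollectionIndex
from .linmod import GeneLevelStats
from .setscores import (plage_scores, set_contrast_test, ssgsea_scores,
                        zscore_scores)

__all__ = [
    "MethodResultMatrix",
    "SUPPORTED_METHODS",
    "gene_zscores",
    "ora_test",
    "camera_test",
    "rotation_set_test",
    "gage_test",
    "padog_test",
    "globaltest_test",
    "safe_test",
    "run_base_methods",
    "two_group_assignment",
]

SUPPORTED_METHODS = ("ora", "camera", "fry", "gage", "padog",
                     "plage", "zscore", "ssgsea", "globaltest", "safe")

_KNOWN_UNSUPPORTED = {"gsva": "kernel-density scoring is not implemented"}


@dataclass
class MethodResultMatrix:
    """Sets × methods p-values/directions for one contrast."""

    set_names: list[str]
    method_names: list[str]
    contrast: str
    p: np.ndarray          # sets x methods
    direction: np.ndarray  # sets x methods, in {-1, 0, +1}
    valid: np.ndarray      # sets x methods boolean

    def __post_init__(self) -> None:
        shape = (len(self.set_names), len(self.method_names))
        for name in ("p", "direction", "valid"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must be {shape}")
        if np.any((self.p[self.valid] < 0) | (self.p[self.valid] > 1)):
            raise ValueError("valid p-values must lie in [0, 1]")

    def p_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.p, index=self.set_names, columns=self.method_names)
        return df.where(pd.DataFrame(self.valid, index=df.index, columns=df.columns))

    def testable(self) -> np.ndarray:
        """Sets with at least one valid method."""
        return self.valid.any(axis=1)


# ---------------------------------------------------------------------------
# shared transforms
# ---------------------------------------------------------------------------

_CDF_EPS = 1e-15


def _t_to_z(t: np.ndarray, df: float) -> np.ndarray:
    """Map t-statistics to standard-normal quantiles through the t CDF."""
    if np.isinf(df):
        return np.asarray(t, dtype=float)
    cdf = stats.t.cdf(t, df)
    return stats.norm.ppf(np.clip(cdf, _CDF_EPS, 1.0 - _CDF_EPS))


def gene_zscores(gls: GeneLevelStats, contrast: str) -> np.ndarray:
    """Per-gene normal-scale statistics for one contrast (sign preserved)."""
    j = gls.contrast_column(contrast)
    return _t_to_z(gls.t[:, j], gls.df_total)


def _set_direction(gls: GeneLevelStats, contrast: str, idx: list[int]) -> int:
    if not idx:
        return 0
    j = gls.contrast_column(contrast)
    return int(np.sign(np.mean(gls.logfc[idx, j])))


def two_group_assignment(design: pd.DataFrame, contrasts: pd.DataFrame, contrast: str):
    """Reduce a contrast to a two-group comparison where possible.

    Maps the contrast through the design (per-sample loading ``X @ c``) and
    takes positive loadings as group A, negative as group B.  Returns
    ``(samples, a_mask)`` over the retained samples, or ``None`` when either
    group has fewer than two samples (the contrast is then untestable for
    label-permutation methods).
    """
    X = np.asarray(design, dtype=float)
    c = np.asarray(contrasts[contrast], dtype=float)
    v = X @ c
    pos = np.flatnonzero(v > 1e-12)
    neg = np.flatnonzero(v < -1e-12)
    if pos.size < 2 or neg.size < 2:
        return None
    samples = np.concatenate([pos, neg])
    samples.sort()
    a_mask = np.isin(samples, pos)
    return samples, a_mask


def _moderated_two_group_t(vals: np.ndarray, a_mask: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per gene with moments-moderated variances."""
    na = int(a_mask.sum())
    nb = int((~a_mask).sum())
    ma = vals[:, a_mask].mean(axis=1)
    mb = vals[:, ~a_mask].mean(axis=1)
    va = vals[:, a_mask].var(axis=1, ddof=1)
    vb = vals[:, ~a_mask].var(axis=1, ddof=1)
    s2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    df = na + nb - 2
    ok = s2 > 0
    if ok.sum() >= 2:
        z = np.log(s2[ok])
        e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
        e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
        if e_var > 0:
            from .linmod import _trigamma_inverse
            d0 = 2.0 * _trigamma_inverse(e_var)
            s0 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
            s2 = (d0 * s0 + df * s2) / (d0 + df)
        else:
            s2 = np.full_like(s2, float(np.exp(np.mean(e))))
    denom = np.sqrt(np.maximum(s2, 1e-300) * (1.0 / na + 1.0 / nb))
    return (ma - mb) / denom


def _group_splits(n: int, n_a: int, budget: int, rng: np.random.Generator):
    """Label assignments: exhaustive when C(n, n_a) <= budget, else sampled.

    Returns ``(masks, exhaustive)`` with masks as a boolean array
    (n_assignments × n).
    """
    from math import comb

    total = comb(n, n_a)
    if total <= budget:
        masks = np.zeros((total, n), dtype=bool)
        for row, idx in enumerate(combinations(range(n), n_a)):
            masks[row, list(idx)] = True
        return masks, True
    masks = np.zeros((budget, n), dtype=bool)
    for row in range(budget):
        masks[row, rng.choice(n, size=n_a, replace=False)] = True
    return masks, False


def _perm_pvalue(stat_obs: float, stat_perm: np.ndarray, exhaustive: bool) -> float:
    hits = int(np.sum(stat_perm >= stat_obs - 1e-12))
    if exhaustive:
        return hits / stat_perm.size
    return (1 + hits) / (stat_perm.size + 1)


# ---------------------------------------------------------------------------
# competitive tests
# ---------------------------------------------------------------------------

def ora_test(gls: GeneLevelStats, index: CollectionIndex, contrast: str,
             fdr_cutoff: float = 0.05, top_n_fallback: int | None = None):
    """Over-representation: hypergeometric upper tail of the DE-gene overlap.

    DE genes are those with BH FDR below ``fdr_cutoff``; when none pass and
    ``top_n_fallback`` is given, the top-N genes by p-value are used instead.
    """
    j = gls.contrast_column(contrast)
    de = gls.fdr[:, j] < fdr_cutoff
    if not de.any() and top_n_fallback:
        order = np.argsort(gls.p[:, j], kind="stable")[:top_n_fallback]
        de = np.zeros(gls.n_genes, dtype=bool)
        de[order] = True
    G = gls.n_genes
    K = int(de.sum())
    n_sets = len(index)
    p = np.ones(n_sets)
    direction = np.zeros(n_sets, dtype=int)
    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        m = len(s.index)
        if m == 0:
            valid[row] = False
            continue
        k = int(de[s.index].sum())
        p[row] = stats.hypergeom.sf(k - 1, G, K, m)
        overlap = [i for i in s.index if de[i]]
        direction[row] = _set_direction(gls, contrast, overlap)
    return p, direction, valid


def _mean_intergene_correlation(rows: np.ndarray, rng: np.random.Generator,
                                max_genes: int = 200) -> float:
    """Mean off-diagonal correlation of (residual) rows, subsampled when large."""
    if rows.shape[0] < 2:
        return 0.0
    if rows.shape[0] > max_genes:
        pick = rng.choice(rows.shape[0], size=max_genes, replace=False)
        rows = rows[np.sort(pick)]
    sd = rows.std(axis=1)
    rows = rows[sd > 0]
    if rows.shape[0] < 2:
        return 0.0
    cor = np.corrcoef(rows)
    m = cor.shape[0]
    return float((cor.sum() - m) / (m * (m - 1)))


def _mean_cosine(rows: np.ndarray, rng: np.random.Generator,
                 max_genes: int = 200) -> float:
    """Mean off-diagonal cosine similarity of rows (no centering), subsampled."""
    if rows.shape[0] < 2:
        return 0.0
    if rows.shape[0] > max_genes:
        pick = rng.choice(rows.shape[0], size=max_genes, replace=False)
        rows = rows[np.sort(pick)]
    norms = np.linalg.norm(rows, axis=1)
    rows = rows[norms > 0] / norms[norms > 0, None]
    if rows.shape[0] < 2:
        return 0.0
    cos = rows @ rows.T
    m = cos.shape[0]
    return float((cos.sum() - m) / (m * (m - 1)))


def camera_test(gls: GeneLevelStats, index: CollectionIndex, contrast: str,
                seed: int = 0, max_genes_corr: int = 200):
    """Competitive test with a variance-inflation correction for inter-gene
    correlation, estimated from the set's residual rows."""
    if gls.df_residual < 2:
        raise ValueError("camera requires residual dof >= 2")
    z = gene_zscores(gls, contrast)
    G = z.size
    sum_all = z.sum()
    ss_all = ((z - z.mean()) ** 2).sum()
    n_sets = len(index)
    p = np.ones(n_sets)
    direction = np.zeros(n_sets, dtype=int)
    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        m = len(s.index)
        if m < 1 or m >= G:
            valid[row] = False
            continue
        rng = derive_rng(seed, "camera", contrast, s.name)
        # cosine of residual rows == correlation in the residual coordinate
        # space; the implied VIF = m*||mean unit residual vector||^2 is a
        # non-negative quadratic form, so it cannot undershoot into rejection
        rho = _mean_cosine(gls.residuals[s.index], rng, max_genes_corr)
        vif = max(1.0 + (m - 1) * rho, 1e-3)
        mean_in = z[s.index].mean()
        mean_out = (sum_all - z[s.index].sum()) / (G - m)
        # pooled two-group variance of the z's
        var_in = z[s.index].var(ddof=1) if m > 1 else 0.0
        out_mask = np.ones(G, dtype=bool)
        out_mask[s.index] = False
        var_out = z[out_mask].var(ddof=1)
        # floor guards the degenerate all-equal-z case (0/0 -> T = 0)
        s2 = ((m - 1) * var_in + (G - m - 1) * var_out) / (G - 2)
        denom = np.sqrt(max(s2, 1e-16) * (vif / m + 1.0 / (G - m)))
        T = (mean_in - mean_out) / denom
        # the estimated VIF carries ~chi^2_d/d noise; referring T to a t with
        # min(residual df, G-2) dof absorbs it (the camera convention when the
        # inter-gene correlation is estimated rather than fixed)
        p[row] = 2.0 * stats.t.sf(abs(T), min(gls.df_residual, G - 2))
        direction[row] = int(np.sign(mean_in - mean_out)) or 0
    return p, direction, valid


def gage_test(gls: GeneLevelStats, index: CollectionIndex, contrast: str):
    """Welch two-sample t of set genes' statistics against the background."""
    z = gene_zscores(gls, contrast)
    G = z.size
    n_sets = len(index)
    p = np.ones(n_sets)
    direction = np.zeros(n_sets, dtype=int)
    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        m = len(s.index)
        if m < 2 or m >= G - 1:
            valid[row] = False
            continue
        out_mask = np.ones(G, dtype=bool)
        out_mask[s.index] = False
        t_stat, pval = stats.ttest_ind(z[s.index], z[out_mask], equal_var=False)
        p[row] = pval
        direction[row] = int(np.sign(z[s.index].mean() - z[out_mask].mean())) or 0
    return p, direction, valid


# ---------------------------------------------------------------------------
# rotation test (fry-style)
# ---------------------------------------------------------------------------

def _rotation_coordinates(values: np.ndarray, design: pd.DataFrame,
                          contrasts: pd.DataFrame, contrast: str):
    """Per-gene coordinates in the (effect ⊕ residual) space.

    Returns ``V`` (genes × (d+1)) whose first column is the standardised
    contrast effect and remaining columns the residual-space coordinates in an
    orthonormal basis; the rotation null re-draws the effect direction
    uniformly within this space.
    """
    from scipy.linalg import null_space

    X = np.asarray(design, dtype=float)
    C = np.asarray(contrasts, dtype=float)
    j = list(contrasts.columns).index(contrast)
    c = C[:, j]
    n, pcols = X.shape
    d = n - pcols
    if d < 1:
        raise ValueError("rotation test needs at least one residual degree of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = values @ X @ xtx_inv.T
    effect = (beta @ c) / np.sqrt(float(c @ xtx_inv @ c))
    Q2 = null_space(X.T)                       # n x d orthonormal residual basis
    U = values @ Q2
    return np.column_stack([effect, U]), d


def rotation_set_test(em, design: pd.DataFrame, contrasts: pd.DataFrame, contrast: str,
                      index: CollectionIndex, n_rot: int = 9999,
                      mode: str = "analytic", seed: int = 0,
                      max_genes_corr: int = 200):
    """Self-contained rotation test (fast roast approximation).

    Assuming equal gene-wise variances, the set is summarised by the mean of
    its genes' coordinate vectors in the (effect ⊕ residual) rotation space;
    the set statistic is that aggregated vector's moderated-t analogue (its
    effect coordinate over its residual spread, ``d`` residual dof).  ``mc``
    mode redraws the effect direction uniformly on the rotation sphere and
    counts rotations at least as extreme; because the aggregated vector
    behaves exactly like a single gene under rotation, its statistic is
    t-distributed with ``d`` dof, which ``analytic`` mode uses directly.
    Gene–gene correlation is carried by the aggregation in both modes.
    """
    if mode not in ("mc", "analytic"):
        raise ValueError(f"unknown rotation mode {mode!r}")
    if mode == "mc" and n_rot < 99:
        raise ValueError("n_rot must be >= 99 in mc mode")
    V, d = _rotation_coordinates(em.values, design, contrasts, contrast)
    n_sets = len(index)
    p = np.ones(n_sets)
    direction = np.zeros(n_sets, dtype=int)
    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        idx = np.asarray(s.index)
        m = idx.size
        if m < 1:
            valid[row] = False
            continue
        vbar = V[idx].mean(axis=0)
        norm2 = float(vbar @ vbar)
        t_obs = vbar[0] / np.sqrt(max(norm2 - vbar[0] ** 2, 1e-300) / d)
        direction[row] = int(np.sign(t_obs)) or 0
        if mode == "analytic":
            p[row] = 2.0 * stats.t.sf(abs(t_obs), d)
        else:
            rng = derive_rng(seed, "fry", contrast, s.name)
            t_rot = np.empty(n_rot)
            chunk = 20000
            for start in range(0, n_rot, chunk):
                nb = min(chunk, n_rot - start)
                R = rng.standard_normal((d + 1, nb))
                R /= np.linalg.norm(R, axis=0, keepdims=True)
                e = vbar @ R
                t_rot[start:start + nb] = e / np.sqrt(
                    np.maximum(norm2 - e ** 2, 1e-300) / d)
            p[row] = (1 + np.sum(np.abs(t_rot) >= abs(t_obs) - 1e-12)) / (n_rot + 1)
    return p, direction, valid


# ---------------------------------------------------------------------------
# label-permutation tests
# ---------------------------------------------------------------------------

def padog_test(em, gls: GeneLevelStats, index: CollectionIndex, contrast: str,
               B: int = 500, seed: int = 0):
    """Down-weighted overlap analysis: mean of frequency-weighted |t| over the
    set, referred to a group-label permutation null.

    Genes appearing in many sets of the collection are down-weighted:
    ``w = 1 + sqrt((f_max - f) / (f_max - f_min))`` with ``f`` the number of
    sets containing the gene.
    """
    if B < 100:
        raise ValueError("padog needs B >= 100")
    grouping = two_group_assignment(gls.design, gls.contrasts, contrast)
    n_sets = len(index)
    p = np.ones(n_sets)
    direction = np.zeros(n_sets, dtype=int)
    if grouping is None:
        return p, direction, np.zeros(n_sets, dtype=bool)
    samples, a_mask = grouping
    vals = em.values[:, samples]

    freq = np.zeros(em.n_genes)
    for s in index:
        freq[s.index] += 1
    in_any = freq > 0
    if in_any.any() and freq[in_any].max() > freq[in_any].min():
        f_min, f_max = freq[in_any].min(), freq[in_any].max()
        w = 1.0 + np.sqrt(np.clip((f_max - freq) / (f_max - f_min), 0.0, 1.0))
    else:
        w = np.ones(em.n_genes)

    rng = derive_rng(seed, "padog", contrast)
    masks, exhaustive = _group_splits(len(samples), int(a_mask.sum()), B, rng)
    wt = np.empty((masks.shape[0], em.n_genes))
    for row in range(masks.shape[0]):
        wt[row] = w * np.abs(_moderated_two_group_t(vals, masks[row]))
    obs = w * np.abs(_moderated_two_group_t(vals, a_mask))

    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        idx = np.asarray(s.index)
        s_obs = obs[idx].mean()
        s_perm = wt[:, idx].mean(axis=1)
        p[row] = _perm_pvalue(s_obs, s_perm, exhaustive)
        direction[row] = _set_direction(gls, contrast, s.index)
    return p, direction, valid


def globaltest_test(em, gls: GeneLevelStats, index: CollectionIndex, contrast: str,
                    B: int = 1000, seed: int = 0):
    """Self-contained quadratic score test: mean squared projection of the
    centred group indicator onto the set's standardised genes, permutation null."""
    if B < 100:
        raise ValueError("globaltest needs B >= 100")
    grouping = two_group_assignment(gls.design, gls.contrasts, contrast)
    n_sets = len(index)
    p = np.ones(n_sets)
    direction = np.zeros(n_sets, dtype=int)
    if grouping is None:
        return p, direction, np.zeros(n_sets, dtype=bool)
    samples, a_mask = grouping
    vals = em.values[:, samples]
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    Z = np.zeros_like(vals)
    np.divide(vals - mu, sd, out=Z, where=sd > 0)

    rng = derive_rng(seed, "globaltest", contrast)
    masks, exhaustive = _group_splits(len(samples), int(a_mask.sum()), B, rng)
    y_obs = a_mask.astype(float) - a_mask.mean()
    yty = float(y_obs @ y_obs)
    Y = masks.astype(float).T - a_mask.mean()          # n x n_perm
    proj_obs = (Z @ y_obs) ** 2                        # genes
    proj_perm = (Z @ Y) ** 2                           # genes x n_perm

    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        idx = np.asarray(s.index)
        m = idx.size
        q_obs = proj_obs[idx].sum() / (m * yty)
        q_perm = proj_perm[idx].sum(axis=0) / (m * yty)
        p[row] = _perm_pvalue(q_obs, q_perm, exhaustive)
        direction[row] = _set_direction(gls, contrast, s.index)
    return p, direction, valid


def safe_test(em, gls: GeneLevelStats, index: CollectionIndex, contrast: str,
              B: int = 1000, seed: int = 0):
    """Significance analysis of function and expression: Wilcoxon rank-sum of
    set genes' |t| against the complement, label-permutation null with the
    gene statistics recomputed per permutation."""
    if B < 100:
        raise ValueError("safe needs B >= 100")
    grouping = two_group_assignment(gls.design, gls.contrasts, contrast)
    n_sets = len(index)
    p = np.ones(n_sets)
    direction = np.zeros(n_sets, dtype=int)
    if grouping is None:
        return p, direction, np.zeros(n_sets, dtype=bool)
    samples, a_mask = grouping
    vals = em.values[:, samples]

    rng = derive_rng(seed, "safe", contrast)
    masks, exhaustive = _group_splits(len(samples), int(a_mask.sum()), B, rng)
    ranks_perm = np.empty((masks.shape[0], em.n_genes))
    for row in range(masks.shape[0]):
        ranks_perm[row] = stats.rankdata(np.abs(_moderated_two_group_t(vals, masks[row])))
    ranks_obs = stats.rankdata(np.abs(_moderated_two_group_t(vals, a_mask)))

    valid = np.ones(n_sets, dtype=bool)
    for row, s in enumerate(index):
        idx = np.asarray(s.index)
        s_obs = ranks_obs[idx].sum()
        s_perm = ranks_perm[:, idx].sum(axis=1)
        p[row] = _perm_pvalue(s_obs, s_perm, exhaustive)
        direction[row] = _set_direction(gls, contrast, s.index)
    return p, direction, valid


# ---------------------------------------------------------------------------
# dispatcher
# ---------------------------------------------------------------------------

def _score_method(method: str, em, gls: GeneLevelStats, index: CollectionIndex,
                  contrast: str, tau: float):
    if method == "plage":
        ssm = plage_scores(em, index)
    elif method == "zscore":
        ssm = zscore_scores(em, index)
    else:
        ssm = ssgsea_scores(em, index, tau=tau)
    return set_contrast_test(ssm, gls.design, gls.contrasts, contrast)


def run_base_methods(gls: GeneLevelStats, em, index: CollectionIndex, contrast: str,
                     methods: list[str] | tuple[str, ...] = SUPPORTED_METHODS,
                     params: dict | None = None, seed: int = 0) -> MethodResultMatrix:
    """Run the requested base methods for one contrast on one collection.

    Individual method failures on individual sets are recorded in the validity
    mask and never abort the run.  ``params`` may carry per-method overrides:
    ``B`` (padog/globaltest/safe), ``n_rot`` and ``mode`` (fry), ``tau``
    (ssgsea), ``ora_fdr`` and ``ora_top_n`` (ora).
    """
    if not methods:
        raise ValueError("empty base-method list")
    for m in methods:
        if m in _KNOWN_UNSUPPORTED:
            raise NotImplementedError(f"base method {m!r}: {_KNOWN_UNSUPPORTED[m]}")
        if m not in SUPPORTED_METHODS:
            raise ValueError(f"unknown base method {m!r}; supported: {SUPPORTED_METHODS}")
    params = dict(params or {})
    n_sets = len(index)
    p = np.ones((n_sets, len(methods)))
    direction = np.zeros((n_sets, len(methods)), dtype=int)
    valid = np.zeros((n_sets, len(methods)), dtype=bool)
    for col, method in enumerate(methods):
        try:
            if method == "ora":
                # fallback keeps ORA informative when nothing clears the FDR cut
                default_top_n = max(1, round(0.05 * gls.n_genes))
                res = ora_test(gls, index, contrast,
                               fdr_cutoff=params.get("ora_fdr", 0.05),
                               top_n_fallback=params.get("ora_top_n", default_top_n))
            elif method == "camera":
                res = camera_test(gls, index, contrast, seed=seed)
            elif method == "fry":
                res = rotation_set_test(em, gls.design, gls.contrasts, contrast, index,
                                        n_rot=params.get("n_rot", 9999),
                                        mode=params.get("mode", "analytic"), seed=seed)
            elif method == "gage":
                res = gage_test(gls, index, contrast)
            elif method == "padog":
                res = padog_test(em, gls, index, contrast,
                                 B=params.get("B", 500), seed=seed)
            elif method == "globaltest":
                res = globaltest_test(em, gls, index, contrast,
                                      B=params.get("B", 1000), seed=seed)
            elif method == "safe":
                res = safe_test(em, gls, index, contrast,
                                B=params.get("B", 1000), seed=seed)
            else:
                res = _score_method(method, em, gls, index, contrast,
                                    tau=params.get("tau", 0.25))
        except (ValueError, np.linalg.LinAlgError):
            continue  # whole-method failure: column stays invalid
        p[:, col], direction[:, col], valid[:, col] = res
    return MethodResultMatrix(set_names=index.set_names(), method_names=list(methods),
                              contrast=contrast, p=p, direction=direction, valid=valid)
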