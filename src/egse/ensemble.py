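"""Consensus scoring: rank aggregation and combined significance per gene set.

For one contrast, the sets × methods p-value matrix is converted to per-method
ranks; the ensemble score table then carries, per set, the combined p-value
(and its BH adjustment within the collection × contrast), the minimum p-value,
minimum/average/median/vote rank, set-level fold-change summaries, a majority
direction and a 0–100 relative significance score.  The cross-contrast
comparative analysis combines each method's per-contrast p-values first and
then aggregates exactly as for a single contrast.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .combine import combine_pvalues
from .gmt import CollectionIndex
from .linmod import GeneLevelStats, bh_adjust
from .methods import MethodResultMatrix

__all__ = [
    "rank_by_method",
    "ensemble_scores",
    "comparative_scores",
    "top_sets",
    "SCORE_COLUMNS",
]

SCORE_COLUMNS = ["p.value", "p.adj", "direction", "vote.rank", "avg.rank",
                 "med.rank", "min.pvalue", "min.rank", "avg.logfc",
                 "avg.logfc.dir", "significance", "n_methods"]

# sort keys where larger means more interesting
_DESCENDING_KEYS = {"significance", "avg.logfc", "avg.logfc.dir"}


def rank_by_method(mrm: MethodResultMatrix) -> pd.DataFrame:
    """Integer ranks (1 = most significant) per method column.

    Ties share the minimum rank; invalid entries rank below every valid one
    (number of valid sets + 1).
    """
    n_sets, n_methods = mrm.p.shape
    ranks = np.zeros((n_sets, n_methods), dtype=int)
    for col in range(n_methods):
        ok = mrm.valid[:, col]
        n_valid = int(ok.sum())
        ranks[~ok, col] = n_valid + 1
        if n_valid:
            pv = mrm.p[ok, col]
            order = np.sort(pv)
            ranks[ok, col] = np.searchsorted(order, pv, side="left") + 1
    return pd.DataFrame(ranks, index=mrm.set_names, columns=mrm.method_names)


def _lower_median(values: np.ndarray) -> float:
    v = np.sort(values)
    return float(v[(v.size - 1) // 2])


def _vote_rank(ranks: np.ndarray, vote_bin: int) -> int:
    bins = np.ceil(ranks / vote_bin).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    modal = uniq[counts == counts.max()].min()  # ties to the smallest bin
    return int(vote_bin * modal)


def _set_logfc_stats(gls: GeneLevelStats, contrast: str, idx) -> tuple[float, float]:
    """(mean |logFC|, mean signed logFC) over the set's genes for one contrast."""
    j = gls.contrast_column(contrast)
    lfc = gls.logfc[list(idx), j]
    return float(np.mean(np.abs(lfc))), float(np.mean(lfc))


def _directional_mean(gls: GeneLevelStats, contrast: str, idx, direction: int) -> float:
    if direction == 0:
        return 0.0
    j = gls.contrast_column(contrast)
    lfc = gls.logfc[list(idx), j]
    sel = lfc[np.sign(lfc) == direction]
    return float(np.mean(sel)) if sel.size else 0.0


def _assemble_table(mrm: MethodResultMatrix, ranks: pd.DataFrame,
                    fold_stats: dict[str, tuple[float, float, float]],
                    combine_method: str, vote_bin: int) -> pd.DataFrame:
    """Shared scoring core; ``fold_stats`` maps set → (avg|lfc|, lfc.dir, direction)."""
    rows = []
    kept_names = []
    rank_mat = ranks.to_numpy()
    for i, name in enumerate(mrm.set_names):
        ok = mrm.valid[i]
        if not ok.any():
            continue
        kept_names.append(name)
        pvals = mrm.p[i, ok]
        rk = rank_mat[i, ok].astype(float)
        avg_lfc, lfc_dir, direction = fold_stats[name]
        rows.append({
            "p.value": combine_pvalues(pvals, combine_method),
            "direction": direction,
            "vote.rank": _vote_rank(rk, vote_bin),
            "avg.rank": float(np.mean(rk)),
            "med.rank": _lower_median(rk),
            "min.pvalue": float(np.min(pvals)),
            "min.rank": int(np.min(rk)),
            "avg.logfc": avg_lfc,
            "avg.logfc.dir": lfc_dir,
            "n_methods": int(ok.sum()),
        })
    if len(kept_names) < len(mrm.set_names):
        dropped = len(mrm.set_names) - len(kept_names)
        warnings.warn(f"{dropped} set(s) failed every base method and were dropped "
                      f"from contrast {mrm.contrast!r}", stacklevel=3)
    table = pd.DataFrame(rows, index=kept_names)
    table["p.adj"] = bh_adjust(table["p.value"].to_numpy())
    sigma = table["avg.logfc"].abs() * (-np.log10(np.clip(table["p.adj"], 1e-300, 1.0)))
    lo, hi = float(sigma.min()), float(sigma.max())
    if hi > lo:
        table["significance"] = 100.0 * (sigma - lo) / (hi - lo)
    else:
        table["significance"] = 50.0
    table = table.join(ranks.loc[kept_names])
    return table[SCORE_COLUMNS + list(ranks.columns)]


def ensemble_scores(mrm: MethodResultMatrix, gls: GeneLevelStats, index: CollectionIndex,
                    combine_method: str = "wilkinson", vote_bin: int = 5,
                    ranks: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ensemble score table for one contrast (sets as rows).

    ``significance`` is ``|avg.logfc| * (-log10 p.adj)`` min–max scaled to
    [0, 100] within this collection × contrast (a constant value maps to 50).
    """
    if ranks is None:
        ranks = rank_by_method(mrm)
    idx_by_name = {s.name: s.index for s in index}
    fold_stats = {}
    for name in mrm.set_names:
        avg_lfc, signed = _set_logfc_stats(gls, mrm.contrast, idx_by_name[name])
        direction = int(np.sign(signed))
        fold_stats[name] = (avg_lfc,
                            _directional_mean(gls, mrm.contrast, idx_by_name[name], direction),
                            direction)
    return _assemble_table(mrm, ranks, fold_stats, combine_method, vote_bin)


def comparative_scores(mrms: list[MethodResultMatrix], gls: GeneLevelStats,
                       index: CollectionIndex, combine_method: str = "wilkinson",
                       vote_bin: int = 5) -> pd.DataFrame:
    """Cross-contrast comparison table.

    For each base method, its per-contrast p-values are first combined (same
    combiner) into one method-level comparison p-value; ranks and ensemble
    scores are then computed exactly as for a single contrast.  Fold-change
    summaries average over contrasts; the direction is the sign of the mean of
    the per-contrast signed means (0 when contrasts cancel).
    """
    if not mrms:
        raise ValueError("need at least one contrast")
    names = mrms[0].set_names
    methods = mrms[0].method_names
    for m in mrms[1:]:
        if m.set_names != names or m.method_names != methods:
            raise ValueError("all contrasts must share sets and methods")

    n_sets, n_methods = len(names), len(methods)
    p = np.ones((n_sets, n_methods))
    direction = np.zeros((n_sets, n_methods), dtype=int)
    valid = np.zeros((n_sets, n_methods), dtype=bool)
    for i in range(n_sets):
        for j in range(n_methods):
            pv = [m.p[i, j] for m in mrms if m.valid[i, j]]
            if not pv:
                continue
            valid[i, j] = True
            p[i, j] = combine_pvalues(pv, combine_method)
            dirs = [m.direction[i, j] for m in mrms if m.valid[i, j]]
            direction[i, j] = int(np.sign(sum(dirs)))
    comp = MethodResultMatrix(set_names=list(names), method_names=list(methods),
                              contrast="comparison", p=p, direction=direction, valid=valid)

    idx_by_name = {s.name: s.index for s in index}
    fold_stats = {}
    for name in names:
        per_abs, per_signed = [], []
        for m in mrms:
            a, s = _set_logfc_stats(gls, m.contrast, idx_by_name[name])
            per_abs.append(a)
            per_signed.append(s)
        d = int(np.sign(np.mean(per_signed)))
        lfc_dir = float(np.mean([
            _directional_mean(gls, m.contrast, idx_by_name[name], d) for m in mrms
        ])) if d != 0 else 0.0
        fold_stats[name] = (float(np.mean(per_abs)), lfc_dir, d)
    return _assemble_table(comp, rank_by_method(comp), fold_stats, combine_method, vote_bin)


def top_sets(table: pd.DataFrame, sort_by: str = "p.adj", n: int = 10) -> pd.DataFrame:
    """Top-``n`` sets under a score or method-rank sort key.

    p-like and rank-like keys sort ascending; ``significance`` and fold-change
    keys sort descending.  Ties break by set name; a 1-based ``Rank`` column
    reports the position under the chosen key.
    """
    if sort_by not in table.columns:
        raise KeyError(f"unknown sort key {sort_by!r}; available: {list(table.columns)}")
    ascending = sort_by not in _DESCENDING_KEYS
    key = table[sort_by].to_numpy(dtype=float)
    order = np.lexsort((table.index.to_numpy(), key if ascending else -key))
    out = table.iloc[order].copy()
    out.insert(0, "Rank", np.arange(1, len(out) + 1))
    return out.head(n)
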