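"""Synthetic multi-group expression experiments with planted enriched sets.

The generator emulates a small log-scale expression study: per-gene baselines,
Gaussian noise (optionally with exchangeable within-set correlation through a
shared latent factor), a random gene set collection, and planted shifts added
to a chosen fraction of the member genes of selected sets in selected groups.
A counts mode draws negative-binomial reads around the log-scale means for
exercising the TMM/log-CPM path.  Everything is driven by one seed and can be
written out as plain-text files (expr.tsv or counts.tsv, sets.gmt, design.csv,
contrasts.csv, truth.json) so every pipeline stage is testable offline.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import derive_rng
from .gmt import GeneSet, write_gmt
from .preprocess import CountMatrix, ExpressionMatrix

__all__ = ["PlantedEffect", "SyntheticTruth", "SyntheticExperiment",
           "make_dataset", "make_rank_fixture", "default_contrasts"]


@dataclass
class PlantedEffect:
    """One planted enrichment: a set shifted in one contrast's positive group."""

    set_name: str
    contrast: str
    logfc: float
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction of active genes must be in (0, 1]")


@dataclass
class SyntheticTruth:
    planted: list[PlantedEffect]
    noise_sd: float
    rho: float
    seed: int
    active_genes: dict[str, list[str]] = field(default_factory=dict)

    def planted_names(self) -> list[str]:
        return sorted({e.set_name for e in self.planted})

    def to_json(self) -> str:
        return json.dumps({
            "planted": [vars(e) for e in self.planted],
            "noise_sd": self.noise_sd,
            "rho": self.rho,
            "seed": self.seed,
            "active_genes": self.active_genes,
        }, indent=2, sort_keys=True)


@dataclass
class SyntheticExperiment:
    expression: ExpressionMatrix | None
    counts: CountMatrix | None
    sets: list[GeneSet]
    design: pd.DataFrame
    contrasts: pd.DataFrame
    truth: SyntheticTruth


def default_contrasts(group_names: list[str]) -> pd.DataFrame:
    """All pairwise differences, later group minus earlier, named "B-A" style."""
    cols = {}
    for i, a in enumerate(group_names):
        for b in group_names[i + 1:]:
            c = np.zeros(len(group_names))
            c[group_names.index(b)] = 1.0
            c[group_names.index(a)] = -1.0
            cols[f"{b}-{a}"] = c
    return pd.DataFrame(cols, index=group_names)


def _parse_contrast_groups(contrast_col: pd.Series) -> tuple[list[str], list[str]]:
    up = [g for g, v in contrast_col.items() if v > 0]
    down = [g for g, v in contrast_col.items() if v < 0]
    return up, down


def make_dataset(
    n_genes: int = 2000,
    groups: dict[str, int] | None = None,
    n_sets: int = 200,
    set_size: int = 20,
    planted: list[PlantedEffect] | list[tuple] | None = None,
    rho: float = 0.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    mode: str = "logexpr",
    nb_dispersion: float = 0.1,
    baseline_mean: float = 7.0,
    baseline_sd: float = 2.0,
    contrasts: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> SyntheticExperiment:
    """Simulate a multi-group experiment with planted enriched gene sets.

    Baseline log2 expression is ``Normal(mu_g, noise_sd)`` per observation with
    gene baselines ``mu_g ~ Normal(baseline_mean, baseline_sd)``; with
    ``rho > 0`` each set shares a per-sample latent factor contributing
    ``rho`` of the noise variance (genes in several sets follow the first set
    containing them).  Each planted effect adds ``logfc`` to the positive-group
    samples of its contrast for a random ``fraction`` of the set's genes.
    ``mode="counts"`` draws negative-binomial counts with mean ``2**value``.
    """
    groups = dict(groups or {"A": 5, "B": 5})
    if any(sz < 2 for sz in groups.values()):
        raise ValueError("every group needs at least two samples")
    group_names = list(groups)
    if contrasts is None:
        contrasts = default_contrasts(group_names)
    if list(contrasts.index) != group_names:
        raise ValueError("contrast rows must be the group names")

    rng = derive_rng(seed, "synthetic", "data")
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    sample_ids = [f"{g}_{r + 1}" for g in group_names for r in range(groups[g])]
    group_of = np.repeat(np.arange(len(group_names)), [groups[g] for g in group_names])
    n_samples = len(sample_ids)

    design = pd.DataFrame(0.0, index=sample_ids, columns=group_names)
    for j, g in enumerate(group_names):
        design.iloc[group_of == j, j] = 1.0

    # random gene set collection (members sampled without replacement per set)
    set_rng = derive_rng(seed, "synthetic", "sets")
    sets = []
    for s in range(n_sets):
        members = set_rng.choice(n_genes, size=set_size, replace=False)
        sets.append(GeneSet(name=f"set{s + 1:03d}", description=f"synthetic set {s + 1}",
                            members=[gene_ids[i] for i in np.sort(members)]))
    members_of = {s.name: s.members for s in sets}

    planted_effects: list[PlantedEffect] = []
    for e in planted or []:
        eff = e if isinstance(e, PlantedEffect) else PlantedEffect(*e)
        if eff.set_name not in members_of:
            raise ValueError(f"planted set {eff.set_name!r} not among generated sets")
        if eff.contrast not in contrasts.columns:
            raise ValueError(f"planted contrast {eff.contrast!r} not in contrast matrix")
        planted_effects.append(eff)

    mu = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    signal = np.tile(mu[:, None], (1, n_samples))

    active_genes: dict[str, list[str]] = {}
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    for eff in planted_effects:
        members = members_of[eff.set_name]
        n_active = max(1, int(round(eff.fraction * len(members))))
        pick_rng = derive_rng(seed, "synthetic", "active", eff.set_name, eff.contrast)
        chosen = sorted(pick_rng.choice(len(members), size=n_active, replace=False))
        genes = [members[i] for i in chosen]
        active_genes.setdefault(eff.set_name, [])
        active_genes[eff.set_name] = sorted(set(active_genes[eff.set_name]) | set(genes))
        up, _ = _parse_contrast_groups(contrasts[eff.contrast])
        target = np.isin(np.array(group_names)[group_of], up)
        rows = [gene_pos[g] for g in genes]
        signal[np.ix_(rows, np.flatnonzero(target))] += eff.logfc

    noise = rng.normal(0.0, noise_sd * np.sqrt(max(1.0 - rho, 0.0)),
                       size=(n_genes, n_samples))
    if rho > 0:
        first_set = {}
        for s in sets:
            for g in s.members:
                first_set.setdefault(g, s.name)
        factors = {s.name: rng.normal(0.0, 1.0, size=n_samples) for s in sets}
        for g, sname in first_set.items():
            noise[gene_pos[g]] += noise_sd * np.sqrt(rho) * factors[sname]
    values = signal + noise

    truth = SyntheticTruth(planted=planted_effects, noise_sd=noise_sd, rho=rho,
                           seed=seed, active_genes=active_genes)

    em = cm = None
    if mode == "logexpr":
        em = ExpressionMatrix(values=values, gene_ids=gene_ids, sample_ids=sample_ids)
    elif mode == "counts":
        mean = np.clip(2.0 ** values, 1e-8, None)
        r = 1.0 / nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mean)).astype(float)
        cm = CountMatrix(counts=counts, gene_ids=gene_ids, sample_ids=sample_ids)
    else:
        raise ValueError(f"unknown mode {mode!r} (use 'logexpr' or 'counts')")

    exp = SyntheticExperiment(expression=em, counts=cm, sets=sets,
                              design=design, contrasts=contrasts, truth=truth)
    if out_dir is not None:
        _write_experiment(exp, Path(out_dir))
    return exp


def _write_experiment(exp: SyntheticExperiment, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if exp.expression is not None:
        exp.expression.to_frame().to_csv(out_dir / "expr.tsv", sep="\t",
                                         index_label="FeatureID")
    if exp.counts is not None:
        pd.DataFrame(exp.counts.counts.astype(int), index=exp.counts.gene_ids,
                     columns=exp.counts.sample_ids).to_csv(
            out_dir / "counts.tsv", sep="\t", index_label="FeatureID")
    write_gmt(exp.sets, out_dir / "sets.gmt")
    exp.design.to_csv(out_dir / "design.csv", index_label="Sample")
    exp.contrasts.to_csv(out_dir / "contrasts.csv", index_label="Coefficient")
    (out_dir / "truth.json").write_text(exp.truth.to_json() + "\n", encoding="utf-8")


def make_rank_fixture(n_sets: int, n_methods: int, structure: str = "random",
                      seed: int = 0):
    """Rank matrices with independently computed aggregation answers.

    ``structure="identical"`` repeats one random permutation in every method
    column; ``"random"`` draws independent permutations.  The returned answers
    (lower-median, mean, min, and modal 5-wide vote bin per row) are computed
    by plain per-row loops, independent of the aggregation code under test.
    """
    if n_methods < 1:
        raise ValueError("need at least one method column")
    rng = derive_rng(seed, "synthetic", "ranks", structure)
    if structure == "identical":
        perm = rng.permutation(n_sets) + 1
        ranks = np.tile(perm[:, None], (1, n_methods))
    elif structure == "random":
        ranks = np.column_stack([rng.permutation(n_sets) + 1 for _ in range(n_methods)])
    else:
        raise ValueError(f"unknown structure {structure!r}")
    med, avg, mn, vote = [], [], [], []
    for row in ranks:
        srt = sorted(row)
        med.append(srt[(len(srt) - 1) // 2])
        avg.append(sum(row) / len(row))
        mn.append(min(row))
        bins = [int(np.ceil(r / 5)) for r in row]
        counts = Counter(bins)
        top = max(counts.values())
        vote.append(5 * min(b for b, c in counts.items() if c == top))
    frame = pd.DataFrame(ranks, index=[f"set{i + 1:03d}" for i in range(n_sets)],
                         columns=[f"m{j + 1}" for j in range(n_methods)])
    answers = {"med.rank": np.array(med, dtype=float), "avg.rank": np.array(avg, dtype=float),
               "min.rank": np.array(mn, dtype=float), "vote.rank": np.array(vote, dtype=float)}
    return frame, answers
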