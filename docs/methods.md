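# Methods

`egse` performs ensemble gene set enrichment: it runs many base gene set tests
over the same log-expression matrix and design/contrast specification, then
combines their p-values and rankings into consensus scores per set. This note
describes the statistical model behind each stage, the tunable parameters, the
synthetic-data generator used throughout the tests, and the design decisions
taken where the problem was genuinely open.

## Gene-level model

Each gene's log2 expression is fitted by weighted least squares on the design
matrix `X` (samples × coefficients); contrasts `c` yield per-gene log
fold-changes `cᵀβ̂` and unscaled standard errors `√(cᵀ(XᵀWX)⁻¹c)`. Residual
variances are moderated by empirical Bayes: a scaled inverse-chi-square prior
(`s0²` on `d0` degrees of freedom) is fitted to the observed `s_g²` by matching
the first two moments of `log s²` (digamma/trigamma identities; the trigamma
inversion is a Newton iteration to 1e-8). The moderated variance is
`(d0·s0² + d·s_g²)/(d0 + d)` and the moderated t has `d0 + d` dof (normal when
`d0 = ∞`; zero spread in `log s²` maps `d0` to `∞` with `s0²` the arithmetic
mean of the variances). Gene-level p-values are two-sided; direction is carried
separately by `sign(logFC)`; multiplicity is handled by Benjamini–Hochberg per
contrast.

Counts enter through an optional path: trimmed-mean-of-M-values normalisation
factors (30 % trim on M, 5 % on A, precision weights from the delta-method
binomial variances, reference library = closest-to-mean upper-quartile
fraction, factors rescaled to geometric mean 1), log-CPM
`log2((count+0.5)/(eff.lib+1)·1e6)`, and observation-level precision weights
from a lowess fit (span 0.5) of `√(residual sd)` against average log-count,
interpolated at each observation's fitted log-count with constant
extrapolation and raised to the −4th power (clipped to [1e-6, 1e6]).
Microarray-style inputs are supported by a detection filter (keep features
with detection p < 0.05 in ≥ 5 samples, both configurable) and a probe
collapse that keeps the highest-mean probe per gene.

## Base gene set tests

Ten tests produce a two-sided p-value and a direction per set per contrast.
"Competitive" tests compare set genes against the rest of the genome;
"self-contained" tests ask whether the set genes respond at all.

- **ora** — hypergeometric upper tail of the overlap between the set and the
  DE genes (BH FDR < 0.05). When no gene clears the cut, the top 5 % of genes
  by p-value stand in; without this fallback the column degenerates to all
  ties whenever the experiment is underpowered at the single-gene level.
- **camera** — two-sample t of gene z-scores (set vs rest) with a
  variance-inflation factor `VIF = 1 + (m−1)ρ̄` for inter-gene correlation.
  `ρ̄` is the non-centred cosine correlation of the set's residual rows
  (equivalently `VIF = m·‖mean unit residual vector‖²`, a non-negative
  quadratic form). Because the estimated VIF carries `~χ²_d/d` noise when the
  residual dimension `d` is small, the statistic is referred to a t with
  `min(d, G−2)` dof — the convention for an estimated (rather than fixed)
  inter-gene correlation — which keeps the null rejection at nominal level
  even at 3-vs-3 designs.
- **fry** — self-contained rotation test assuming equal gene-wise variances.
  Each gene is represented by its coordinates in the (contrast-effect ⊕
  residual) space; the set is summarised by the *mean* coordinate vector,
  whose "one-gene" t statistic is exactly t-distributed with `d` dof under
  rotations of the effect direction. `analytic` mode (default in the
  pipeline) uses that reference distribution directly; `mc` mode redraws the
  direction uniformly on the sphere (`n_rot` default 9999) and counts
  rotations at least as extreme with the `(1+hits)/(n+1)` estimator. The two
  modes agree to Monte-Carlo noise by construction; an earlier variant that
  averaged per-gene normal scores and scaled by a residual-correlation VIF
  disagreed with its own rotation null by up to |Δp| ≈ 0.04 and was dropped.
- **gage** — Welch two-sample t of set-gene z-scores against the background.
- **padog** — mean of frequency-weighted |moderated t| over the set
  (`w = 1 + √((f_max−f)/(f_max−f_min))`, `f` = number of sets in the
  collection containing the gene), with a group-label permutation null.
- **globaltest** — quadratic score statistic
  `Q = ‖Z_setᵀ y_c‖²/(m·y_cᵀy_c)` of the centred group indicator against the
  gene-standardised set submatrix, permutation null.
- **safe** — Wilcoxon rank-sum of set |t| against the complement, with the
  gene statistics recomputed under each label permutation.
- **plage / zscore / ssgsea** — per-sample set activity scores (first right
  singular vector of the standardised set submatrix, sign-aligned to the
  member genes; combined z `Σz/√m`; single-sample enrichment score with rank
  weight `(G−j+1)^τ`, τ = 0.25, globally range-normalised), each tested for a
  contrast effect by an ordinary set-level linear model with `n−p` dof.

Permutation tests enumerate all label splits exactly whenever
`C(n, n_A) ≤ B` (B defaults: padog 500, globaltest/safe 1000), which also
makes them deterministic at small n; otherwise B random splits are drawn. At
3 vs 3 the 20 splits collapse into 10 complementary pairs, so the smallest
attainable permutation p is 0.1 — a structural granularity, not a bug, and
the reason discrete methods cannot reject at α = 0.05 in such designs.
Contrasts that do not reduce to two sample groups (after mapping the contrast
through the design) mark the permutation methods untestable rather than
failing the run.

All random streams derive from one master seed keyed by
(method, contrast, set) through `SeedSequence` spawn keys, so results are
independent of evaluation order and worker count.

## Consensus scores

Per method, sets are ranked by ascending p (ties share the minimum rank;
invalid entries rank last). Per set the table carries: the combined p-value
(default combiner **wilkinson**, the first order statistic `1−(1−p_min)^k` —
r = 1 matches the identity at k = 1 and the ensemble's minimum-p character),
its BH adjustment within collection × contrast, `min.pvalue`, `min.rank`,
`avg.rank`, `med.rank` (lower median, keeping integer values at even method
counts), `vote.rank` (bin width 5; modal bin of `⌈rank/5⌉`, ties to the
smallest bin), the mean |logFC| of the set genes, the directional mean logFC
(over genes matching the majority sign), the majority direction, and a
relative significance score `100·(σ−σ_min)/(σ_max−σ_min)` with
`σ = |avg.logfc|·(−log10 p.adj)` (constant σ maps to 50). Eight combiners are
available (fisher, wilkinson, average, logitp, sump, sumz, votep, median);
every combiner returns a single input p unchanged, with the printed formulas
applying from k = 2.

The cross-contrast comparison combines each method's per-contrast p-values
first (same combiner), then aggregates exactly as for a single contrast;
fold-change summaries average over contrasts and the direction is the sign of
the mean per-contrast signed mean. Consistency across contrasts is only
rewarded by the summing combiners (fisher/logitp/sumz): a minimum-p combiner
cannot distinguish "enriched in two contrasts" from "enriched in one", so the
comparative examples and tests use Fisher.

Known property of the combined p-value: the ten base methods share the data,
so their p-values are strongly positively dependent, and four of them are
discrete/conservative at very small n. The Wilkinson-combined p is therefore
conservative under the complete null (measured rejection ≈ 0.02 at α = 0.05
in a 3-vs-3 design) — the ranking scores (`med.rank`, `vote.rank`) are the
recommended sorting keys, and `scripts/acceptance.py` reports the measured
rejection so the behaviour stays visible.

## Synthetic data generator

`make_dataset` emulates a small log-scale expression study: gene baselines
`μ_g ~ N(7, 2)` (log2 units, a typical log-CPM range), observation noise
`N(0, 0.5)` — 0.5 being a realistic per-gene residual sd for log2-scale bulk
expression, the regime in which a 2-fold change at 5 vs 5 is conventionally
detectable — optional exchangeable within-set correlation via a shared
per-set latent factor carrying a fraction ρ of the noise variance, a random
collection (default 200 sets of 20 genes drawn from 2000; sets may overlap),
and planted shifts added to a random fraction of member genes in the positive
group of a chosen contrast. Counts mode draws negative-binomial reads with
dispersion 0.1 around `2^value`. The generator writes plain-text outputs
(expr/counts TSV, GMT, design/contrast CSV, truth JSON) that round-trip
through the package readers.

What the generator does *not* emulate: library-size and composition biases
beyond what counts mode induces, batch effects, heavy-tailed or
gene-dependent noise, realistic set-size distributions, and annotation noise.
Passing tests therefore demonstrate statistical correctness and calibration
under an idealised model, not performance on any particular real dataset.

## Numerical choices

- p-values are clipped to [1e-300, 1−1e-15] before log/logit transforms;
  t→normal score transforms clip the CDF at 1e-15.
- Gene-ID matching is exact string equality; indexed sets keep
  retained/original member counts; `min_set_size` defaults to 5 (small sets
  destabilise the score-based tests).
- camera subsamples at most 200 set genes (seeded) for the correlation
  estimate; its pooled variance is floored at 1e-16 so an all-equal-z set
  yields T = 0, p = 1.
- ssGSEA breaks expression ties by input row order (stable sort).
- The exhaustive-permutation p uses `hits/n_splits` (the observed labelling
  is one of the splits); sampled permutations use `(1+hits)/(B+1)`.
- Report colour semantics are categorical keys (`up`/`down`/`neutral`/
  `highlight`); the default renderer maps them to red/blue/purple/teal.
- Method–method distance for the MDS display is 1 − Spearman correlation of
  the rank columns; classical (Torgerson) scaling with sign fixed so the
  first method has non-negative coordinates.

## Problem sizes used by the test suite and acceptance script

Null calibration uses 2000 genes × 200 sets × (3 vs 3) over 5 seeds; planted
recovery uses 2000 genes × 200 sets × (5 vs 5) over 10 seeds with five sets
shifted by 1.0 log2 units in half their genes; rotation-mode agreement uses
20 000 rotations on 400-gene studies. These sizes give Monte-Carlo error
comfortably inside the asserted tolerances while keeping a full run in
minutes on one CPU.

## Limitations

- GSVA's kernel-density scoring is not implemented; requesting it fails with
  a clear error.
- The gene-level engine covers single linear contrasts only (no F-tests,
  duplicate-correlation blocks, or robust/trended moderation variants).
- ID conversion, pathway/GO graph rendering and bundled public collections
  are out of scope; collections arrive as GMT files.
- The combined p-value's null distribution depends on the base-method
  dependence structure (see above); treat `p.adj` as a conservative screen
  and prefer rank-based sorting for prioritisation.
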