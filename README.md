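# egse — ensemble gene set enrichment analysis

No single gene set test is best everywhere: competitive tests (camera, gage,
over-representation) excel at finding sets that stand out against the genome,
self-contained tests (rotation tests, globaltest, padog, safe) at detecting
any coordinated response, and per-sample scoring methods (PLAGE, combined
z-score, ssGSEA) at summarising activity. `egse` runs ten such tests over one
log-expression matrix and design/contrast specification, then merges their
evidence into a consensus ranking — for transcriptomics analysts who want
robust gene set prioritisation from bulk RNA-seq or microarray experiments
without betting on one algorithm.

## The model in brief

Gene-wise weighted linear models give per-contrast log fold-changes and
moderated t-statistics: residual variances s²_g (d dof) are shrunk towards an
empirical-Bayes prior s₀² (d₀ dof, fitted by moments on log s²), so
t̃_g = logFC_g / (se_g·s̃_g) with s̃²_g = (d₀s₀² + d s²_g)/(d₀+d) on d₀+d dof.
Each base method tests every set per contrast; per set the k method p-values
are combined (default Wilkinson: p = 1−(1−p_min)^k) and the per-method ranks
aggregated into avg.rank, med.rank (lower median), min.rank and vote.rank
(modal 5-wide rank bin). BH adjustment is applied within collection ×
contrast; a comparative table combines each method's p-values across
contrasts first and then aggregates identically. Full details and the design
decisions are in `docs/methods.md`.

## Worked example

```python
from egse import RunConfig, make_dataset, run_analysis

exp = make_dataset(n_genes=2000, groups={"A": 5, "B": 5}, n_sets=100,
                   set_size=20, planted=[("set007", "B-A", 1.0, 0.5)], seed=1)
result = run_analysis(exp.expression, exp.design, exp.contrasts,
                      {"synthetic": exp.sets}, RunConfig(seed=1))
print(result.top_sets("synthetic", "B-A", sort_by="med.rank", n=5)
      [["Rank", "p.value", "p.adj", "med.rank", "vote.rank", "direction"]])
```

prints

```
        Rank  p.value  p.adj  med.rank  vote.rank  direction
set007     1  0.00095  0.095         1          5          1
set046     2   0.0171  0.571         2          5         -1
set049     3    0.046   0.92         4          5          1
set037     4   0.0281  0.703         5          5         -1
set063     5  0.00782  0.391         5          5         -1
```

The planted set (`set007`, a 2-fold shift in half of its 20 genes) is ranked
first: `med.rank 1` means at least half of the ten base tests rank it top,
`p.value` is the Wilkinson-combined p over the methods, `p.adj` its BH
adjustment across the 100 sets, and `direction +1` says the set is up in
group B. More narrative scripts live in `examples/` (counts → TMM/log-CPM →
precision weights, the eight p-value combiners, multi-contrast comparative
analysis, HTML report generation); each prints its numbers with a line on
what they mean.

A thin CLI wraps the same pipeline for shell use:

```sh
egse simulate --out demo --planted set001:B-A:1.0:0.5 --seed 1
egse run demo-config.yaml        # paths + options in YAML/JSON
egse report <results-dir>        # rebuild the HTML index from stored tables
egse index sets.gmt expr.tsv     # resolve a GMT against an expression matrix
```

Inputs are plain text: GMT gene set collections, gene × sample TSV
(log-expression or raw counts — counts are TMM-normalised and
precision-weighted in-tool), and design/contrast CSVs. Outputs are ranked TSV
tables per collection × contrast (plus the cross-contrast comparison), plot
data/images, and a static HTML report.

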