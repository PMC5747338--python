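"""Cross-contrast comparative analysis: reward consistent enrichment.

Three treatment groups are compared against a shared control.  One set is
planted in two of the three contrasts, another in just one.  Combining each
base method's p-values across contrasts with Fisher's statistic ranks the
consistently enriched set ahead.
"""

import pandas as pd

from egse import RunConfig, make_dataset, run_analysis

contrasts = pd.DataFrame({"B-A": [-1., 1., 0., 0.], "C-A": [-1., 0., 1., 0.],
                          "D-A": [-1., 0., 0., 1.]}, index=list("ABCD"))
exp = make_dataset(
    n_genes=1000, groups={"A": 4, "B": 4, "C": 4, "D": 4}, n_sets=60,
    set_size=15,
    planted=[("set001", "B-A", 1.0, 0.5), ("set001", "C-A", 1.0, 0.5),
             ("set002", "B-A", 1.0, 0.5)],
    seed=5, contrasts=contrasts)
result = run_analysis(exp.expression, exp.design, exp.contrasts,
                      {"synthetic": exp.sets},
                      RunConfig(seed=5, combine_method="fisher"))

comp = result.top_sets("synthetic", "comparison", sort_by="med.rank", n=5)
print(comp[["Rank", "p.value", "med.rank", "direction"]]
      .to_string(float_format=lambda v: f"{v:.3g}"))
print()
for name in ("set001", "set002"):
    per = [f"{c}: p.adj={result.table('synthetic', c).loc[name, 'p.adj']:.2g}"
           for c in result.contrast_names]
    print(f"{name}  " + "  ".join(per))
print()
print("set001 (enriched in B-A and C-A) outranks set002 (B-A only) in the "
      "comparison table: summing evidence across contrasts rewards "
      "consistency, which a single-contrast ranking cannot see.")
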