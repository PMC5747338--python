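"""The eight p-value combiners on one vector of method p-values.

Given the p-values that different base tests assigned to one gene set, each
combiner summarises them into a single consensus p-value with a different
emphasis: Wilkinson (the default) follows the best method, Fisher and the
logit/Stouffer family reward agreement, votep simply counts methods below 0.5.
"""

from egse import COMBINE_METHODS, combine_pvalues

p = [0.001, 0.02, 0.08, 0.3, 0.6]
print(f"per-method p-values: {p}")
for method in COMBINE_METHODS:
    print(f"  {method:10s} -> {combine_pvalues(p, method):.5f}")
print()
print("The summing combiners (fisher, logitp, sumz) give the smallest values "
      "because several p-values are moderately small and they accumulate "
      "evidence; votep is coarse (3 of 5 methods below 0.5); Wilkinson "
      "depends only on the minimum p and the number of methods.")
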