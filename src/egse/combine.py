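"""Meta-analytic p-value combination.

Eight combiners turn the per-method p-values for one gene set into a single
consensus p-value.  ``wilkinson`` (the minimum-p order statistic, r = 1) is
the package default.  Inputs are clipped to [1e-300, 1 - 1e-15] so the log and
logit transforms stay finite; a single p-value is returned unchanged by every
combiner (each formula below applies for k >= 2).
"""

from __future__ import annotations

from math import comb, factorial

import numpy as np
from scipy import stats

__all__ = ["combine_pvalues", "COMBINE_METHODS"]

COMBINE_METHODS = ("fisher", "wilkinson", "average", "logitp",
                   "sump", "sumz", "votep", "median")

_P_LO = 1e-300
_P_HI = 1.0 - 1e-15


def _irwin_hall_cdf(s: float, k: int) -> float:
    """P(U1 + ... + Uk <= s) for iid Uniform(0,1)."""
    s = min(max(s, 0.0), float(k))
    total = 0.0
    for j in range(int(np.floor(s)) + 1):
        total += (-1) ** j * comb(k, j) * (s - j) ** k
    return min(max(total / factorial(k), 0.0), 1.0)


def combine_pvalues(p, method: str = "wilkinson") -> float:
    """Combine a vector of valid p-values into one consensus p-value.

    fisher
        chi-square (2k dof) upper tail at ``-2 * sum(log p)``.
    wilkinson
        first order statistic: ``1 - (1 - min p)^k``.
    average
        normal approximation to the mean: ``z = (0.5 - mean p) * sqrt(12 k)``.
    logitp
        Student-t approximation to the summed logits (5k + 4 dof).
    sump
        exact Irwin–Hall lower tail of ``sum p``.
    sumz
        Stouffer: ``1 - Phi(sum Phi^-1(1 - p) / sqrt(k))``.
    votep
        binomial upper tail of the count of p-values below 0.5 at rate 0.5.
    median
        Beta order-statistic CDF at the median p (rank ``ceil(k/2)``).
    """
    if method not in COMBINE_METHODS:
        raise ValueError(f"unknown combination method {method!r}; "
                         f"choose from {COMBINE_METHODS}")
    p = np.asarray(p, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("cannot combine an empty p-value vector")
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be finite and in [0, 1]")
    p = np.clip(p, _P_LO, _P_HI)
    k = p.size
    if k == 1:
        return float(p[0])

    if method == "fisher":
        stat = -2.0 * np.sum(np.log(p))
        out = stats.chi2.sf(stat, 2 * k)
    elif method == "wilkinson":
        out = 1.0 - (1.0 - p.min()) ** k
    elif method == "average":
        z = (0.5 - p.mean()) * np.sqrt(12.0 * k)
        out = stats.norm.sf(z)
    elif method == "logitp":
        denom = np.sqrt(k * np.pi ** 2 * (5 * k + 2) / (3.0 * (5 * k + 4)))
        stat = -np.sum(np.log(p / (1.0 - p))) / denom
        out = stats.t.sf(stat, 5 * k + 4)
    elif method == "sump":
        out = _irwin_hall_cdf(float(p.sum()), k)
    elif method == "sumz":
        z = np.sum(stats.norm.isf(p)) / np.sqrt(k)
        out = stats.norm.sf(z)
    elif method == "votep":
        n_small = int(np.sum(p < 0.5))
        out = stats.binom.sf(n_small - 1, k, 0.5)
    else:  # median
        r = int(np.ceil(k / 2))
        out = stats.beta.cdf(np.sort(p)[r - 1], r, k - r + 1)
    return float(min(max(out, 0.0), 1.0))
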