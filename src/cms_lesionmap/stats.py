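"""Group statistics: Welch t-tests, Cohen's d, chi-square, rate-by-load curve.

Welch's unequal-variance t-test is used throughout, with Satterthwaite
degrees of freedom reported both exactly and floored (published tables
conventionally print the floor).  Both Cohen's d conventions are available
because summary tables in the literature mix them: the pooled-SD formula and
the from-t conversion d = t*sqrt(1/n1 + 1/n2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupSummary:
    """Mean, SD and size of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "GroupSummary":
        arr = np.asarray(values, dtype=float)
        return cls(float(arr.mean()), float(arr.std(ddof=1)), int(arr.size))


@dataclass(frozen=True)
class GroupComparison:
    t: float
    df: float
    df_floor: int
    p: float
    alternative: str


def welch_t(a: GroupSummary, b: GroupSummary,
            alternative: str = "two_sided") -> GroupComparison:
    """Welch's unequal-variance t-test from group summaries.

    ``alternative='greater'`` tests mean_a > mean_b one-tailed.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError("alternative must be greater, less or two_sided")
    va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
    if va + vb == 0:
        raise ValueError("both group variances are zero")
    t = (a.mean - b.mean) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    if alternative == "greater":
        p = float(sps.t.sf(t, df))
    elif alternative == "less":
        p = float(sps.t.cdf(t, df))
    else:
        p = float(2 * sps.t.sf(abs(t), df))
    return GroupComparison(float(t), float(df), int(math.floor(df)), p, alternative)


def welch_t_from_values(a: Sequence[float], b: Sequence[float],
                        alternative: str = "two_sided") -> GroupComparison:
    return welch_t(GroupSummary.from_values(a), GroupSummary.from_values(b),
                   alternative)


def cohens_d(a: GroupSummary, b: GroupSummary, method: str = "pooled",
             t: float | None = None) -> float:
    """Cohen's d between two groups.

    ``pooled`` uses the pooled SD; ``from_t`` converts a (Welch) t statistic
    via d = t*sqrt(1/n_a + 1/n_b) and requires ``t``.
    """
    if method == "pooled":
        sp2 = ((a.n - 1) * a.sd ** 2 + (b.n - 1) * b.sd ** 2) / (a.n + b.n - 2)
        if sp2 == 0:
            raise ValueError("zero pooled variance")
        return (a.mean - b.mean) / math.sqrt(sp2)
    if method == "from_t":
        if t is None:
            raise ValueError("from_t requires the t statistic")
        return t * math.sqrt(1 / a.n + 1 / b.n)
    raise ValueError("method must be pooled or from_t")


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, optional Yates correction."""
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=correction)
    return float(chi2), float(p)


DEFAULT_BIN_EDGES = (0.0, 25.0, 50.0, 75.0, 100.0)


@dataclass
class RateCurve:
    """CMS rate per lesion-load bin.

    Bins are half-open [lo, hi) with the last bin closed; with
    ``isolate_zero`` the exactly-zero loads form their own leading bin (the
    fully-spared group is qualitatively distinct from low-but-nonzero
    loads).  It is off by default: at realistic CMS rates the zero bin and
    the first nonzero bin differ by less than sampling noise, so isolating
    zeros tends to show spurious rate inversions.  Empty bins carry rate
    None, not zero.
    """

    bin_lo: list
    bin_hi: list
    n: list
    n_cms: list

    @property
    def rates(self) -> list:
        return [c / n if n > 0 else None for c, n in zip(self.n_cms, self.n)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_lo": self.bin_lo, "bin_hi": self.bin_hi,
                             "n": self.n, "n_cms": self.n_cms,
                             "rate": [r if r is not None else np.nan
                                      for r in self.rates]})

    def nonempty_rates(self) -> list[float]:
        return [r for r in self.rates if r is not None]

    def is_nondecreasing(self) -> bool:
        r = self.nonempty_rates()
        return all(b >= a - 1e-12 for a, b in zip(r, r[1:]))


def rate_by_load_bins(loads, labels, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
                      isolate_zero: bool = False) -> RateCurve:
    """CMS rate within lesion-load bins over [0, 100]."""
    loads = np.asarray(loads, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if loads.shape != labels.shape:
        raise ValueError("loads and labels must have equal length")
    edges = list(map(float, bin_edges))
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("bin_edges must be increasing with at least two edges")
    lo_list, hi_list, ns, cs = [], [], [], []
    remaining = np.ones(loads.shape, dtype=bool)
    if isolate_zero:
        at_zero = loads == 0
        lo_list.append(0.0)
        hi_list.append(0.0)
        ns.append(int(at_zero.sum()))
        cs.append(int(labels[at_zero].sum()))
        remaining &= ~at_zero
    for lo, hi in zip(edges, edges[1:]):
        last = hi == edges[-1]
        sel = remaining & (loads >= lo) & ((loads <= hi) if last else (loads < hi))
        lo_list.append(lo)
        hi_list.append(hi)
        ns.append(int(sel.sum()))
        cs.append(int(labels[sel].sum()))
    return RateCurve(lo_list, hi_list, ns, cs)
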