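"""Paired nonparametric comparisons of per-patient ROI statistics.

The workhorse is the Wilcoxon signed-rank test.  Zero differences are dropped
(the classic Wilcoxon convention) and tied absolute differences receive
average ranks.  For n <= 20 retained pairs the two-sided p-value is exact: the
null distribution of the positive-rank sum W is built over all 2^n equally
likely sign assignments (computed by dynamic programming over the rank
multiset, which is algebraically identical to full enumeration).  Above n = 20
a normal approximation with tie correction is used.

Group comparisons (enhancing vs non-enhancing patients) follow the reference
design: with equal group sizes the patients are paired by index order within
group and the signed-rank test applied; because that pairing is an imposed
convention for independent groups, an unpaired Mann-Whitney rank-sum p-value
is always computed alongside as a cross-check, and is the fallback when group
sizes differ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_LIMIT = 20


class DegenerateTestError(ValueError):
    """All paired differences are zero: the signed-rank test is undefined."""


class InsufficientDataError(ValueError):
    """Fewer than two usable pairs."""


@dataclass(frozen=True)
class PairedTestResult:
    """Signed-rank test outcome.

    statistic is W, the sum of the ranks of positive differences; n_pairs
    counts the pairs retained after dropping zero differences.
    """

    statistic: float
    p_value: float
    n_pairs: int
    method: str  # "exact" | "normal-approximation"


@dataclass(frozen=True)
class GroupComparisonResult:
    """Two-group comparison: index-paired signed-rank plus rank-sum cross-check."""

    signed_rank: PairedTestResult | None
    rank_sum_p: float
    n_a: int
    n_b: int


def _signed_rank_w(diffs: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(diffs))
    w = float(ranks[diffs > 0].sum())
    return w, ranks

def _exact_two_sided_p(w: float, ranks: np.ndarray) -> float:
    """P-value from the exact null distribution of W over all sign vectors.

    Ranks are multiples of 1/2 (average ranks), so doubling them gives
    integers; the distribution of 2W is the convolution, over ranks r, of
    {0, 2r} — each term taken with probability 1/2.
    """
    scaled = np.rint(2.0 * ranks).astype(np.int64)
    total = int(scaled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    top = 0
    for r in scaled:
        counts[r : top + r + 1] += counts[0 : top + 1]
        top += r
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w))
    cdf = counts[: w2 + 1].sum()
    sf = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(cdf, sf)))


def wilcoxon_signed_rank(x_values, y_values) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test of paired samples x and y.

    Exact for up to 20 non-zero pairs, normal approximation with tie
    correction above.  Raises :class:`DegenerateTestError` if every
    difference is zero.
    """
    x = np.asarray(x_values, dtype=np.float64)
    y = np.asarray(y_values, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 1")
    diffs = x - y
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        raise DegenerateTestError("all paired differences are zero")
    w, ranks = _signed_rank_w(diffs)
    if n <= EXACT_LIMIT:
        return PairedTestResult(w, _exact_two_sided_p(w, ranks), n, "exact")
    # normal approximation with tie correction
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean_w) / np.sqrt(var_w)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return PairedTestResult(w, p, n, "normal-approximation")


def compare_rois(
    cohort_stats: pd.DataFrame,
    roi_a: str,
    roi_b: str,
    map_name: str,
    statistic: str,
) -> PairedTestResult:
    """Paired test of one statistic of one map between two regions.

    ``cohort_stats`` is the tidy frame from
    :func:`relaxroi.stats.cohort_statistics`.  Only patients contributing both
    regions are paired (patients without an enhancing core drop out of
    t1e comparisons).
    """
    sel = cohort_stats[
        (cohort_stats["map"] == map_name) & (cohort_stats["statistic"] == statistic)
    ]
    a = sel[sel["roi"] == roi_a].set_index("patient_id")["value"]
    b = sel[sel["roi"] == roi_b].set_index("patient_id")["value"]
    common = a.index.intersection(b.index)
    if len(common) < 2:
        raise InsufficientDataError(
            f"only {len(common)} patients have both {roi_a!r} and {roi_b!r}"
        )
    return wilcoxon_signed_rank(a.loc[common].to_numpy(), b.loc[common].to_numpy())


def compare_groups(values_a, values_b) -> GroupComparisonResult:
    """Compare a per-patient feature between two patient groups.

    Equal group sizes: signed-rank on index-paired values (the imposed-pairing
    convention) plus a Mann-Whitney rank-sum cross-check.  Unequal sizes: the
    signed-rank slot is None and only the rank-sum p is meaningful (a warning
    is emitted).
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("both groups must be non-empty")
    rank_sum_p = float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if a.size == b.size:
        signed = wilcoxon_signed_rank(a, b)
    else:
        warnings.warn(
            "unequal group sizes: falling back to the rank-sum test only",
            stacklevel=2,
        )
        signed = None
    return GroupComparisonResult(signed, rank_sum_p, int(a.size), int(b.size))
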