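"""Comparison machinery: rank tests, sign test, Spearman CIs, quartile bins.

Conventions (fixed so that p-values are bit-for-bit reproducible):

* rank-sum -- exact enumeration when the pooled sample has <= 20 values and
  no ties, otherwise normal approximation with average ranks, tie-corrected
  variance and continuity correction;
* signed-rank -- zero differences dropped (Wilcoxon's convention); exact
  null distribution when n < 20 and |differences| are tie-free, otherwise
  the tie-corrected normal approximation with continuity correction;
* sign test -- exact two-sided binomial at theta = 1/2, zero differences
  excluded;
* Spearman CI -- Fisher z transform with standard error 1/sqrt(n-3).

All tests drop undefined (NaN) records before computing and the group
summaries report how many were dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def _rankdata(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with ties sharing their mean rank."""
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _exact_ranksum_pvalue(n1: int, n2: int, w: float) -> float:
    """Exact two-sided p for the rank-sum W of sample 1 (no ties).

    DP over the distribution of the sum of n1 ranks drawn without
    replacement from 1..n1+n2.
    """
    n = n1 + n2
    max_w = n1 * (2 * n - n1 + 1) // 2
    # ways[k][s] = number of k-subsets of {1..r} with sum s
    ways = np.zeros((n1 + 1, max_w + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, : max_w + 1 - r]
    dist = ways[n1]
    total = dist.sum()
    w_int = int(round(w))
    lower = dist[: w_int + 1].sum() / total
    upper = dist[w_int:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value."""
    x, y = _clean(x), _clean(y)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("rank_sum_test requires non-empty samples")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    n1, n2, n = len(x), len(y), len(pooled)
    no_ties = len(np.unique(pooled)) == n
    ranks = _rankdata(pooled)
    w = ranks[:n1].sum()
    if n <= 20 and no_ties:
        return _exact_ranksum_pvalue(n1, n2, w)
    mu = n1 * (n + 1) / 2.0
    tie_term = 0.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma2 <= 0:
        return 1.0
    diff = w - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def _exact_signed_rank_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ given integer tie-free ranks."""
    max_w = int(ranks.sum())
    dist = np.zeros(max_w + 1)
    dist[0] = 1.0
    for r in ranks.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: max_w + 1 - r]
        dist = dist + shifted
    total = dist.sum()
    w_int = int(round(w_plus))
    lower = dist[: w_int + 1].sum() / total
    upper = dist[w_int:].sum() / total
    return min(1.0, 2.0 * min(lower, upper))


def signed_rank_test(differences) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired differences."""
    d = _clean(differences)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = np.abs(d)
    ranks = _rankdata(absd)
    w_plus = ranks[d > 0].sum()
    no_ties = len(np.unique(absd)) == n
    if n < 20 and no_ties:
        return _exact_signed_rank_pvalue(ranks, w_plus)
    mu = n * (n + 1) / 4.0
    _, counts = np.unique(absd, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
    if sigma2 <= 0:
        return 1.0
    diff = w_plus - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def sign_test(differences) -> float:
    """Exact two-sided binomial sign test (theta = 1/2), zeros excluded."""
    d = _clean(differences)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0
    k = int(np.sum(d > 0))
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class CorrelationByBin:
    bin_label: str
    n: int
    rho: float
    ci_low: float
    ci_high: float
    p_value: float


def spearman_ci(x, y, bin_label: str = "all") -> CorrelationByBin:
    """Spearman correlation with a 95% Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise ValueError("spearman_ci requires n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationByBin(bin_label, n, np.nan, np.nan, np.nan, np.nan)
    rx, ry = _rankdata(x), _rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if abs(rho) >= 1.0 - 1e-13:
        rho = float(np.sign(rho))
        return CorrelationByBin(bin_label, n, rho, rho, rho, 0.0)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), n - 2))
    z = np.arctanh(rho)
    half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
    return CorrelationByBin(
        bin_label=bin_label,
        n=n,
        rho=rho,
        ci_low=float(np.tanh(z - half)),
        ci_high=float(np.tanh(z + half)),
        p_value=min(1.0, p),
    )


@dataclass(frozen=True)
class BinAssignment:
    labels: tuple[str, ...]
    edges: tuple[float, ...]
    k: int
    merged: bool


def quartile_bin(values, k: int = 4) -> BinAssignment:
    """Assign values to k empirical quantile bins (Q1..Qk).

    Edges are the 1/k..(k-1)/k quantiles of the pooled values; a value
    exactly equal to an edge goes to the lower bin.  Degenerate
    distributions yield merged bins with a warning.
    """
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("quartile_bin requires finite values")
    if len(v) < k:
        raise ValueError(f"need at least {k} values for {k} bins")
    qs = np.quantile(v, [i / k for i in range(1, k)])
    edges = np.unique(qs)
    merged = len(edges) < k - 1
    if merged:
        warnings.warn(
            "fewer distinct quantile edges than requested bins; bins merged",
            stacklevel=2,
        )
    idx = np.searchsorted(edges, v, side="left")
    labels = tuple(f"Q{i + 1}" for i in idx)
    return BinAssignment(
        labels=labels, edges=tuple(float(e) for e in edges), k=k, merged=merged
    )


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n: int
    median: float
    q1: float
    q3: float
    ratio_to_reference: float
    p_value: float
    n_undefined_dropped: int


def compare_to_reference(
    reference_values,
    group_values,
    group_label: str,
    reference_median: float | None = None,
) -> GroupSummary:
    """Median/quartile summary of one group against a reference sample."""
    ref = _clean(reference_values)
    grp_raw = np.asarray(group_values, dtype=float)
    grp = grp_raw[~np.isnan(grp_raw)]
    dropped = len(grp_raw) - len(grp)
    if len(grp) == 0:
        raise ValueError(f"group {group_label!r} has no defined values")
    med = float(np.median(grp))
    refmed = (
        float(np.median(ref)) if reference_median is None else reference_median
    )
    same = grp is ref or (
        len(grp) == len(ref) and np.array_equal(np.sort(grp), np.sort(ref))
    )
    p = 1.0 if same else rank_sum_test(grp, ref)
    return GroupSummary(
        group_label=group_label,
        n=len(grp),
        median=med,
        q1=float(np.quantile(grp, 0.25)),
        q3=float(np.quantile(grp, 0.75)),
        ratio_to_reference=med / refmed if refmed else np.nan,
        p_value=p,
        n_undefined_dropped=dropped,
    )


def summarize_groups(
    records: Sequence[tuple[str, float]],
    reference_group: str,
) -> list[GroupSummary]:
    """Per-group summaries with rank-sum p and median ratio vs reference.

    ``records`` are (group_label, value) pairs; NaN values are dropped and
    counted.  The reference group appears first with ratio 1 and p = 1.
    """
    by_group: dict[str, list[float]] = {}
    for label, value in records:
        by_group.setdefault(label, []).append(value)
    if reference_group not in by_group:
        raise ValueError(f"reference group {reference_group!r} missing")
    ref_raw = np.asarray(by_group[reference_group], dtype=float)
    ref = ref_raw[~np.isnan(ref_raw)]
    refmed = float(np.median(ref))
    out = [
        GroupSummary(
            group_label=reference_group,
            n=len(ref),
            median=refmed,
            q1=float(np.quantile(ref, 0.25)),
            q3=float(np.quantile(ref, 0.75)),
            ratio_to_reference=1.0,
            p_value=1.0,
            n_undefined_dropped=len(ref_raw) - len(ref),
        )
    ]
    for label in sorted(by_group):
        if label == reference_group:
            continue
        vals = np.asarray(by_group[label], dtype=float)
        defined = vals[~np.isnan(vals)]
        if len(defined) == 0:
            warnings.warn(f"group {label!r} empty after dropping undefined")
            continue
        out.append(
            compare_to_reference(
                ref, vals, group_label=label, reference_median=refmed
            )
        )
    return out


def summaries_frame(summaries: Sequence[GroupSummary]):
    import pandas as pd

    return pd.DataFrame(
        {
            "group": [s.group_label for s in summaries],
            "n": [s.n for s in summaries],
            "median": [s.median for s in summaries],
            "q1": [s.q1 for s in summaries],
            "q3": [s.q3 for s in summaries],
            "ratio": [s.ratio_to_reference for s in summaries],
            "p_value": [s.p_value for s in summaries],
            "n_undefined_dropped": [s.n_undefined_dropped for s in summaries],
        }
    )
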