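"""Independent brute-force oracles used only by the test suite.

Each function re-derives a statistic from first principles (exact
enumeration, direct loops) without touching the package's implementation,
so agreement is a genuine two-route check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def fisher_two_sided_enum(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by hypergeometric enumeration.

    Minimum-likelihood convention: sum P(table) over all tables with the
    same margins whose point probability is <= that of the observed table.
    Exact rational arithmetic.
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x: int) -> Fraction:
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs)
    return float(total)


def kruskal_h_and_p(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p, by hand."""
    from scipy.stats import chi2

    values = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    i = 0
    sv = values[order]
    while i < n:
        j = i
        while j + 1 < n and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        k = len(g)
        rbar = ranks[start:start + k].mean()
        h += k * (rbar - (n + 1) / 2.0) ** 2
        start += k
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(values, return_counts=True)
    corr = 1.0 - ((counts**3 - counts).sum()) / (n**3 - n)
    if corr <= 0:
        return 0.0, 1.0
    h /= corr
    return h, float(chi2.sf(h, df=len(groups) - 1))


def sam_d_brute(case: np.ndarray, control: np.ndarray, s0: float) -> float:
    """SAM moderated difference, written out longhand."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = len(case), len(control)
    m1, m2 = case.mean(), control.mean()
    ss = ((case - m1) ** 2).sum() + ((control - m2) ** 2).sum()
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    denom = s + s0
    if denom == 0:
        return 0.0
    return (m1 - m2) / denom


def average_linkage_heights(D: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering, O(n^3) with sets.

    Ties are broken by the smallest pair indices, matching no particular
    implementation: only the multiset of heights is meant for comparison.
    """
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for i, j in itertools.combinations(keys, 2):
            dist = np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
            if best is None or dist < best[0] - 1e-15:
                best = (dist, i, j)
        dist, i, j = best
        heights.append(dist)
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return heights


def uncentered_distance(X: np.ndarray) -> np.ndarray:
    norms = np.sqrt((X**2).sum(axis=1))
    return 1.0 - (X @ X.T) / np.outer(norms, norms)


def loocv_errors_brute(
    X: np.ndarray, is_case: np.ndarray, mz: np.ndarray, k_max: int,
    s0_fn,
) -> np.ndarray:
    """LOOCV misclassification counts per k, direct nested loops.

    ``s0_fn(r, s) -> s0`` supplies the fold fudge factor so both routes use
    the same s0 definition while everything else is re-derived.
    """
    n, m = X.shape
    mis = np.zeros(k_max, dtype=int)
    for i in range(n):
        idx = [t for t in range(n) if t != i]
        Xf = X[idx]
        yf = is_case[idx]
        d = np.empty(m)
        r = np.empty(m)
        s = np.empty(m)
        for g in range(m):
            case, ctrl = Xf[yf, g], Xf[~yf, g]
            n1, n2 = len(case), len(ctrl)
            m1, m2 = case.mean(), ctrl.mean()
            ss = ((case - m1) ** 2).sum() + ((ctrl - m2) ** 2).sum()
            r[g] = m1 - m2
            s[g] = np.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
        s0 = s0_fn(r, s)
        for g in range(m):
            d[g] = 0.0 if s[g] + s0 == 0 else r[g] / (s[g] + s0)
        order = sorted(range(m), key=lambda g: (-abs(d[g]), mz[g]))
        for k in range(1, k_max + 1):
            v = 0.0
            for g in order[:k]:
                case, ctrl = Xf[yf, g], Xf[~yf, g]
                w = (case.mean() - ctrl.mean()) / (
                    case.std(ddof=1) + ctrl.std(ddof=1)
                )
                b = (case.mean() + ctrl.mean()) / 2.0
                v += w * (X[i, g] - b)
            pred_case = v > 0
            if pred_case != is_case[i]:
                mis[k - 1] += 1
    return mis
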