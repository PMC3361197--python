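"""Three-test differential screen: Fisher exact, Kruskal-Wallis, SAM.

Each binned signal is tested for case/control differential intensity by

* a two-sided Fisher exact test on dichotomized intensities (median-split
  by default, presence/absence as an alternative), Bonferroni-corrected;
* a Kruskal-Wallis rank test (equivalent to a two-sided Wilcoxon rank-sum
  for two groups), Bonferroni-corrected;
* the SAM moderated difference statistic d = (mean1 - mean2) / (s + s0)
  with the fudge factor s0 chosen to stabilize the coefficient of variation
  of d across the spread of per-signal standard errors, and a per-signal
  false-discovery q-value from label permutations (median number of false
  calls over permutations, divided by the observed call count).

A signal is selected when it meets at least ``min_criteria_met`` of the
three criteria (corrected Fisher p < alpha, corrected KW p < alpha,
SAM q < sam_fdr_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError
from .preprocessing import FeatureTable

__all__ = [
    "SelectionCriteria",
    "ScreenResults",
    "DifferentialScreen",
    "fisher_per_signal",
    "kruskal_wallis_per_signal",
    "sam_statistic",
    "pooled_se",
    "estimate_s0",
    "sam_fdr",
    "bonferroni",
    "select_signals",
]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds and settings of the three-test screen."""

    alpha: float = 0.05
    sam_fdr_max: float = 0.001
    min_criteria_met: int = 2
    n_permutations: int = 1000
    dichotomize_rule: str = "median-split"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0.0 < self.sam_fdr_max < 1.0:
            raise ConfigurationError("sam_fdr_max must lie in (0, 1)")
        if self.min_criteria_met not in (1, 2, 3):
            raise ConfigurationError("min_criteria_met must be 1, 2 or 3")
        if self.n_permutations < 100:
            raise ConfigurationError("n_permutations must be at least 100")
        if self.dichotomize_rule not in ("median-split", "nonzero-presence"):
            raise ConfigurationError(
                f"unknown dichotomize_rule: {self.dichotomize_rule!r}"
            )


def _two_class_masks(labels: pd.Series, positive: str) -> tuple[np.ndarray, np.ndarray]:
    y = labels.to_numpy()
    classes = pd.unique(y)
    if len(classes) != 2:
        raise DataError(f"exactly two classes required, got {list(classes)}")
    if positive not in classes:
        raise DataError(f"positive class {positive!r} absent from labels")
    case = y == positive
    if case.all() or not case.any():
        raise DataError("each class needs at least one sample")
    return case, ~case


def bonferroni(p, m: int):
    """Family-wise correction min(1, m * p)."""
    if m < 1:
        raise ConfigurationError("number of tests m must be >= 1")
    return np.minimum(1.0, m * np.asarray(p, dtype=float)) if np.ndim(p) else min(
        1.0, m * float(p)
    )


def fisher_per_signal(
    table: FeatureTable,
    labels: pd.Series | None = None,
    rule: str = "median-split",
    positive: str = "PDAC",
) -> pd.Series:
    """Two-sided Fisher exact p per signal on dichotomized intensities.

    ``median-split`` calls a value "high" when it exceeds the overall median
    of that signal across all samples; ``nonzero-presence`` when it is
    positive.  The two-sided p-value follows the minimum-likelihood
    convention (sum of hypergeometric probabilities of tables no more
    likely than the observed one).
    """
    labels = table.labels if labels is None else labels
    case, ctrl = _two_class_masks(labels, positive)
    X = table.intensities.to_numpy(dtype=float)
    if rule == "median-split":
        high = X > np.median(X, axis=0, keepdims=True)
    elif rule == "nonzero-presence":
        high = X > 0
    else:
        raise ConfigurationError(f"unknown dichotomize rule: {rule!r}")

    n_case = int(case.sum())
    a = high[case].sum(axis=0)  # cases high
    k_tot = high.sum(axis=0)  # column margin: total high
    n = X.shape[0]

    cache: dict[tuple[int, int], float] = {}
    out = np.empty(table.n_signals)
    for j in range(table.n_signals):
        key = (int(a[j]), int(k_tot[j]))
        p = cache.get(key)
        if p is None:
            tbl = [
                [key[0], n_case - key[0]],
                [key[1] - key[0], (n - n_case) - (key[1] - key[0])],
            ]
            p = float(stats.fisher_exact(tbl, alternative="two-sided")[1])
            cache[key] = p
        out[j] = p
    return pd.Series(out, index=table.signal_ids, name="p_fisher")


def kruskal_wallis_per_signal(
    table: FeatureTable, labels: pd.Series | None = None, positive: str = "PDAC"
) -> pd.Series:
    """Kruskal-Wallis p per signal (ties-corrected H, chi-square df = k-1).

    Vectorized over signals; a signal with all values tied yields H = 0 and
    p = 1 rather than an error.
    """
    labels = table.labels if labels is None else labels
    case, _ = _two_class_masks(labels, positive)
    X = table.intensities.to_numpy(dtype=float)
    n, m = X.shape
    ranks = stats.rankdata(X, axis=0)

    groups = [case, ~case]
    h = np.zeros(m)
    for g in groups:
        r_mean = ranks[g].mean(axis=0)
        h += g.sum() * (r_mean - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))

    # tie correction: per signal, sum of (t^3 - t) over tied groups
    tie_term = np.empty(m)
    Xs = np.sort(X, axis=0)
    for j in range(m):
        _, counts = np.unique(Xs[:, j], return_counts=True)
        tie_term[j] = float(((counts**3) - counts).sum())
    denom = 1.0 - tie_term / (n**3 - n)
    p = np.ones(m)
    ok = denom > 0
    p[ok] = stats.chi2.sf(h[ok] / denom[ok], df=len(groups) - 1)
    p[~ok] = 1.0  # all values tied
    return pd.Series(p, index=table.signal_ids, name="p_kw")


def _group_stats(X: np.ndarray, case: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(mean_case - mean_ctrl, pooled SE s_g, means tuple) per column."""
    n1, n2 = int(case.sum()), int((~case).sum())
    m1 = X[case].mean(axis=0)
    m2 = X[~case].mean(axis=0)
    ss1 = ((X[case] - m1) ** 2).sum(axis=0)
    ss2 = ((X[~case] - m2) ** 2).sum(axis=0)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    return m1 - m2, s, (m1, m2)


def pooled_se(table: FeatureTable, labels: pd.Series | None = None,
              positive: str = "PDAC") -> pd.Series:
    """SAM per-signal pooled standard error s_g."""
    labels = table.labels if labels is None else labels
    case, _ = _two_class_masks(labels, positive)
    _, s, _ = _group_stats(table.intensities.to_numpy(dtype=float), case)
    return pd.Series(s, index=table.signal_ids, name="s")


def sam_statistic(
    table: FeatureTable,
    labels: pd.Series | None = None,
    s0: float = 0.0,
    positive: str = "PDAC",
) -> pd.Series:
    """SAM moderated difference d_g = (mean_case - mean_ctrl) / (s_g + s0)."""
    if s0 < 0:
        raise ConfigurationError("s0 must be nonnegative")
    labels = table.labels if labels is None else labels
    case, _ = _two_class_masks(labels, positive)
    r, s, _ = _group_stats(table.intensities.to_numpy(dtype=float), case)
    denom = s + s0
    d = np.where(denom > 0, r / np.where(denom > 0, denom, 1.0), 0.0)
    return pd.Series(d, index=table.signal_ids, name="sam_d")


def estimate_s0(
    table: FeatureTable, labels: pd.Series | None = None, positive: str = "PDAC"
) -> float:
    """Fudge factor s0 chosen from percentiles of the s_g distribution.

    Candidates are the 0, 5, ..., 100 percentiles of {s_g}.  For each
    candidate the d-statistics are formed, signals are grouped into deciles
    of s_g, and the candidate minimizing the coefficient of variation of
    the within-decile median absolute deviations of d is returned.
    Deterministic.
    """
    labels = table.labels if labels is None else labels
    case, _ = _two_class_masks(labels, positive)
    if case.sum() < 2 or (~case).sum() < 2:
        raise DataError("estimate_s0 needs at least 2 samples per class")
    r, s, _ = _group_stats(table.intensities.to_numpy(dtype=float), case)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    if np.allclose(s, s[0]):
        return float(candidates[0])

    # decile windows of s (fixed across candidates)
    edges = np.percentile(s, np.arange(0, 101, 10))
    which = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 9)

    best_cv, best_s0 = np.inf, float(candidates[0])
    for s0 in candidates:
        d = r / (s + s0) if s0 > 0 else np.divide(
            r, s, out=np.zeros_like(r), where=s > 0
        )
        mads = []
        for w in range(10):
            dw = d[which == w]
            if len(dw) == 0:
                continue
            mads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        mads = np.asarray(mads)
        mean = mads.mean()
        cv = mads.std(ddof=0) / mean if mean > 0 else np.inf
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_fdr(
    table: FeatureTable,
    labels: pd.Series | None = None,
    d: pd.Series | None = None,
    n_permutations: int = 1000,
    seed: int = 0,
    s0: float | None = None,
    positive: str = "PDAC",
) -> pd.Series:
    """Per-signal q: the minimal permutation FDR at which the signal is called.

    Labels are permuted ``n_permutations`` times; for a cutoff delta the FDR
    is the median over permutations of the number of |d*| >= delta, divided
    by the observed number of |d| >= delta.  q_g is the minimum FDR over all
    cutoffs delta <= |d_g|, clipped to [0, 1].
    """
    if n_permutations < 100:
        raise ConfigurationError("n_permutations must be at least 100")
    labels = table.labels if labels is None else labels
    case, _ = _two_class_masks(labels, positive)
    X = table.intensities.to_numpy(dtype=float)
    n, m = X.shape
    n1 = int(case.sum())
    n2 = n - n1

    if s0 is None:
        s0 = estimate_s0(table, labels, positive=positive)
    if d is None:
        d = sam_statistic(table, labels, s0=s0, positive=positive)
    d_abs = np.abs(d.to_numpy(dtype=float))

    rng = np.random.default_rng(seed)
    # permutation membership matrix: rows are permutations, true where "case"
    member = np.zeros((n_permutations, n), dtype=bool)
    for i in range(n_permutations):
        member[i, rng.permutation(n)[:n1]] = True

    P = member.astype(float)
    sum1 = P @ X  # per-perm case sums
    sum_all = X.sum(axis=0)[None, :]
    sq1 = P @ (X**2)
    sq_all = (X**2).sum(axis=0)[None, :]
    m1 = sum1 / n1
    m2 = (sum_all - sum1) / n2
    ss1 = sq1 - n1 * m1**2
    ss2 = (sq_all - sq1) - n2 * m2**2
    ss1 = np.maximum(ss1, 0.0)
    ss2 = np.maximum(ss2, 0.0)
    s_perm = np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))
    d_perm_abs = np.abs((m1 - m2) / (s_perm + s0))

    # observed calls at cutoffs = sorted observed |d| (descending)
    order = np.argsort(-d_abs, kind="stable")
    cutoffs = d_abs[order]
    n_called = np.arange(1, m + 1)

    perm_sorted = np.sort(d_perm_abs.ravel())
    # count of permuted |d*| >= each cutoff, summed over perms, then median
    # via per-permutation counts
    false_counts = np.empty((n_permutations, m))
    for i in range(n_permutations):
        row = np.sort(d_perm_abs[i])
        false_counts[i] = len(row) - np.searchsorted(row, cutoffs, side="left")
    med_false = np.median(false_counts, axis=0)

    fdr = np.clip(med_false / n_called, 0.0, 1.0)
    # q at cutoff i: min FDR over cutoffs j >= i (i.e. delta <= |d_(i)|)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    return pd.Series(q, index=table.signal_ids, name="sam_q")


def select_signals(result: pd.DataFrame, criteria: SelectionCriteria) -> list[str]:
    """Signal ids meeting at least ``min_criteria_met`` of the three criteria."""
    flags = (
        (result["p_fisher_bonf"] < criteria.alpha).astype(int)
        + (result["p_kw_bonf"] < criteria.alpha).astype(int)
        + (result["sam_q"] < criteria.sam_fdr_max).astype(int)
    )
    return list(result.index[flags >= criteria.min_criteria_met])


@dataclass
class ScreenResults:
    """Per-signal statistics of the three-test screen plus the selection mask."""

    frame: pd.DataFrame
    criteria: SelectionCriteria
    s0: float
    n_case: int
    n_control: int
    positive: str

    @property
    def selected_ids(self) -> list[str]:
        return list(self.frame.index[self.frame["selected"]])

    @property
    def n_selected(self) -> int:
        return int(self.frame["selected"].sum())

    def to_tsv(self, path: str | Path) -> None:
        out = self.frame.copy()
        out.index.name = "signal_id"
        out.to_csv(path, sep="\t", float_format="%.6g")

    def summary(self) -> str:
        c = self.criteria
        lines = [
            "Differential screen (Fisher exact / Kruskal-Wallis / SAM)",
            "=" * 60,
            f"signals tested:        {len(self.frame)}",
            f"cases / controls:      {self.n_case} / {self.n_control}"
            f"  (positive class: {self.positive})",
            f"Bonferroni alpha:      {c.alpha}",
            f"SAM FDR threshold:     {c.sam_fdr_max}  (s0 = {self.s0:.4g}, "
            f"{c.n_permutations} permutations)",
            f"rule:                  >= {c.min_criteria_met} of 3 criteria"
            f"  (dichotomization: {c.dichotomize_rule})",
            f"signals selected:      {self.n_selected}",
        ]
        return "\n".join(lines)


class DifferentialScreen:
    """Model object for the three-test screen on a labelled feature table.

    Parameters
    ----------
    table
        Feature table with per-sample class labels (exactly two classes).
    criteria
        Thresholds; defaults follow the screening design (Bonferroni 0.05,
        SAM FDR 0.1%, at least 2 of 3 criteria).
    positive
        Label of the case (cancer) class.
    """

    def __init__(
        self,
        table: FeatureTable,
        criteria: SelectionCriteria | None = None,
        positive: str = "PDAC",
    ) -> None:
        if table.labels is None:
            raise DataError("DifferentialScreen requires a labelled feature table")
        self.table = table
        self.criteria = criteria or SelectionCriteria()
        self.positive = positive

    def fit(self, seed: int = 0) -> ScreenResults:
        """Run all three tests and apply the selection rule."""
        table, labels = self.table, self.table.labels
        crit = self.criteria
        m = table.n_signals

        p_fisher = fisher_per_signal(table, labels, rule=crit.dichotomize_rule,
                                     positive=self.positive)
        p_kw = kruskal_wallis_per_signal(table, labels, positive=self.positive)
        s0 = estimate_s0(table, labels, positive=self.positive)
        d = sam_statistic(table, labels, s0=s0, positive=self.positive)
        q = sam_fdr(table, labels, d=d, n_permutations=crit.n_permutations,
                    seed=seed, s0=s0, positive=self.positive)

        frame = pd.DataFrame(
            {
                "mz": table.mz.reindex(table.signal_ids).to_numpy(),
                "p_fisher": p_fisher,
                "p_kw": p_kw,
                "p_fisher_bonf": bonferroni(p_fisher.to_numpy(), m),
                "p_kw_bonf": bonferroni(p_kw.to_numpy(), m),
                "sam_d": d,
                "sam_q": q,
            },
            index=pd.Index(table.signal_ids, name="signal_id"),
        )
        flags = (
            (frame["p_fisher_bonf"] < crit.alpha).astype(int)
            + (frame["p_kw_bonf"] < crit.alpha).astype(int)
            + (frame["sam_q"] < crit.sam_fdr_max).astype(int)
        )
        frame["criteria_met"] = flags
        frame["selected"] = flags >= crit.min_criteria_met

        case = (labels == self.positive).sum()
        return ScreenResults(
            frame=frame,
            criteria=crit,
            s0=s0,
            n_case=int(case),
            n_control=int(len(labels) - case),
            positive=self.positive,
        )
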