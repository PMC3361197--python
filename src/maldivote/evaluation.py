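"""Diagnostic-accuracy evaluation with exact binomial confidence intervals.

Confusion counts treat the cancer class as positive and pool every
noncancerous class (healthy, acute/chronic pancreatitis, AIP) as negative.
Sensitivity, specificity, PPV, NPV and accuracy are reported as percentages
to one decimal (half-up rounding, matching clinical-table convention), each
with an exact two-sided Clopper-Pearson 95% interval.  Subgroup tables
reproduce the per-stratum row structure (n, correct, %, CI), subgroup
contrasts use a two-sided Fisher exact test, and an OR-rule combines the
proteomic model with a scalar serum marker at a strict cutoff
(marker-positive when value > cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

__all__ = [
    "ConfusionCounts",
    "BinomialCI",
    "MetricValue",
    "MetricSet",
    "confusion",
    "metrics",
    "clopper_pearson",
    "fisher_2x2",
    "chi2_2x2",
    "combine_with_marker",
    "subgroup_report",
    "round_percent",
]

POSITIVE_CLASS = "PDAC"


def round_percent(value: float, decimals: int = 1) -> float:
    """Half-up rounding of a percentage, e.g. 89.65 -> 89.7."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class BinomialCI:
    """Exact (Clopper-Pearson) two-sided binomial interval, in percent."""

    x: int
    n: int
    level: float
    lower: float  # percent, 1 decimal
    upper: float  # percent, 1 decimal

    def __str__(self) -> str:
        return f"{self.lower:.1f}-{self.upper:.1f}"


def clopper_pearson(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact two-sided binomial CI via the beta-quantile characterization.

    lower = Beta^{-1}(alpha/2; x, n-x+1), upper = Beta^{-1}(1-alpha/2; x+1, n-x);
    x = 0 pins the lower bound at 0 and x = n the upper bound at 100.
    """
    if n < 1 or not 0 <= x <= n:
        raise DataError(f"invalid binomial counts x={x}, n={n}")
    if not 0.0 < level < 1.0:
        raise ConfigurationError("confidence level must lie in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialCI(
        x=int(x), n=int(n), level=level,
        lower=round_percent(100.0 * lower), upper=round_percent(100.0 * upper),
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with cancer as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DataError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


def confusion(
    predictions: pd.Series,
    labels: pd.Series,
    positive: str = POSITIVE_CLASS,
) -> ConfusionCounts:
    """Confusion counts from aligned per-sample predictions and true classes.

    ``predictions`` holds predicted class names (or booleans, True = cancer);
    every true class other than ``positive`` counts as negative.
    """
    if len(predictions) == 0:
        raise DataError("empty prediction set")
    unmatched = predictions.index.difference(labels.index)
    if len(unmatched):
        raise DataError(f"predictions without labels: {list(unmatched)[:10]}")
    truth = labels.reindex(predictions.index)
    pred_pos = (
        predictions.astype(bool)
        if predictions.dtype == bool
        else predictions == positive
    )
    true_pos = truth == positive
    tp = int((pred_pos & true_pos).sum())
    fp = int((pred_pos & ~true_pos).sum())
    fn = int((~pred_pos & true_pos).sum())
    tn = int((~pred_pos & ~true_pos).sum())
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass(frozen=True)
class MetricValue:
    """One diagnostic metric: percentage (1 decimal) with its exact CI."""

    percent: float | None
    x: int
    n: int
    ci: BinomialCI | None
    defined: bool = True

    def __str__(self) -> str:
        if not self.defined:
            return "NA"
        return f"{self.percent:.1f}% ({self.x}/{self.n}, 95% CI {self.ci})"


def _metric(x: int, n: int, level: float) -> MetricValue:
    if n == 0:
        return MetricValue(percent=None, x=x, n=0, ci=None, defined=False)
    return MetricValue(
        percent=round_percent(100.0 * x / n),
        x=x, n=n, ci=clopper_pearson(x, n, level),
    )


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, PPV, NPV and accuracy for one cohort."""

    sensitivity: MetricValue
    specificity: MetricValue
    ppv: MetricValue
    npv: MetricValue
    accuracy: MetricValue
    counts: ConfusionCounts

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            m: MetricValue = getattr(self, name)
            rows.append(
                {
                    "metric": name,
                    "x": m.x,
                    "n": m.n,
                    "percent": m.percent,
                    "ci_lower": m.ci.lower if m.ci else None,
                    "ci_upper": m.ci.upper if m.ci else None,
                    "defined": m.defined,
                }
            )
        return pd.DataFrame(rows).set_index("metric")

    def summary(self) -> str:
        c = self.counts
        lines = [
            "Diagnostic accuracy",
            "=" * 56,
            f"TP={c.tp}  FN={c.fn}  TN={c.tn}  FP={c.fp}  (n={c.total})",
        ]
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            lines.append(f"{name:<12} {getattr(self, name)}")
        return "\n".join(lines)


def metrics(counts: ConfusionCounts, level: float = 0.95) -> MetricSet:
    """Standard diagnostic metrics with exact CIs; zero denominators flagged."""
    c = counts
    return MetricSet(
        sensitivity=_metric(c.tp, c.tp + c.fn, level),
        specificity=_metric(c.tn, c.tn + c.fp, level),
        ppv=_metric(c.tp, c.tp + c.fp, level),
        npv=_metric(c.tn, c.tn + c.fn, level),
        accuracy=_metric(c.tp + c.tn, c.total, level),
        counts=c,
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (minimum-likelihood convention)."""
    if min(a, b, c, d) < 0 or a + b + c + d == 0:
        raise DataError("fisher_2x2 needs nonnegative counts with a positive total")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square p without continuity correction.

    Provided alongside :func:`fisher_2x2` because published subgroup
    contrasts are sometimes computed this way even when labelled exact.
    """
    res = stats.chi2_contingency([[a, b], [c, d]], correction=False)
    return float(res.pvalue)


def combine_with_marker(
    model_positive: pd.Series,
    marker: pd.Series,
    cutoff: float = 37.0,
) -> pd.DataFrame:
    """OR-combination of model calls with a serum marker (positive if > cutoff).

    Returns a frame indexed like ``model_positive`` with boolean ``combined``
    and a ``source`` column recording the provenance of each positive call
    (``model`` / ``marker`` / ``both`` / ``none``); samples with a missing
    marker value fall back to the model call with source ``model-only``.
    """
    model_positive = model_positive.astype(bool)
    marker = marker.reindex(model_positive.index)
    known = marker.notna()
    if (marker[known] < 0).any():
        bad = list(marker.index[known & (marker < 0)])[:5]
        raise DataError(f"negative marker value(s) for: {bad}")
    marker_pos = known & (marker > cutoff)
    combined = model_positive | marker_pos
    source = np.select(
        [
            ~known,
            model_positive & marker_pos,
            model_positive & ~marker_pos,
            ~model_positive & marker_pos,
        ],
        ["model-only", "both", "model", "marker"],
        default="none",
    )
    return pd.DataFrame(
        {"combined": combined, "marker_value": marker, "source": source},
        index=model_positive.index,
    )


def subgroup_report(
    correct: pd.Series,
    grouping: pd.Series,
    level: float = 0.95,
    group_order: list[str] | None = None,
) -> pd.DataFrame:
    """Per-group correct-call counts with exact CIs (clinical-table rows).

    ``correct`` is a boolean per sample; ``grouping`` assigns each sample to
    one stratum.  Groups listed in ``group_order`` but absent from the data
    yield an ``n = 0`` row with NA percentage and CI.
    """
    missing = correct.index.difference(grouping.index)
    if len(missing):
        raise DataError(f"samples without a group: {list(missing)[:10]}")
    grouping = grouping.reindex(correct.index)
    groups = group_order if group_order is not None else sorted(
        pd.unique(grouping.dropna())
    )
    rows = []
    for g in groups:
        mask = grouping == g
        n = int(mask.sum())
        if n == 0:
            rows.append(
                {"group": g, "n": 0, "correct": None, "percent": None,
                 "ci_lower": None, "ci_upper": None}
            )
            continue
        x = int(correct[mask].sum())
        ci = clopper_pearson(x, n, level)
        rows.append(
            {"group": g, "n": n, "correct": x,
             "percent": round_percent(100.0 * x / n),
             "ci_lower": ci.lower, "ci_upper": ci.upper}
        )
    return pd.DataFrame(rows).set_index("group")
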