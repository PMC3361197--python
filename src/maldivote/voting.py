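"""Signal-to-noise weighted-voting classifier and LOOCV model-size selection.

For each signature signal g the training data yield class means mu1 (cancer)
and mu2 (noncancer) and sample standard deviations sigma1, sigma2.  The
weight is the signal-to-noise ratio w = (mu1 - mu2) / (sigma1 + sigma2) and
the decision boundary is the midpoint b = (mu1 + mu2) / 2.  A new sample x
casts one vote per signal, v_g = w_g (x_g - b_g); the voting sum V = sum v_g
classifies the sample as cancer when V > 0 (ties go to noncancer).  The
prediction strength PS = (V_win - V_lose) / (V_win + V_lose), with V_win the
absolute vote mass agreeing with the call, measures the margin.

Model size is chosen by leave-one-out cross-validation: for every held-out
sample the remaining samples re-rank the candidate signals by |SAM d|, a
voting model on the top-k signals predicts the held-out sample, and the
total misclassification count per k is recorded.  The optimal k minimizes
that count (ties broken toward the smaller k), and the final signature is
the k signals most shared across the per-fold top-k lists.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .preprocessing import FeatureTable
from .screen import _group_stats, _two_class_masks, estimate_s0

__all__ = [
    "PUBLISHED_SIGNATURE_MZ",
    "PUBLISHED_SIGNATURE_PROTEINS",
    "WeightedVoting",
    "VotingResults",
    "CrossValCurve",
    "loocv_curve",
    "extract_shared_signature",
]

#: the published 7-signal plasma signature (m/z, one decimal) kept as
#: metadata for report formatting; it is a property of the original plasma
#: cohorts and cannot be recomputed from synthetic data.
PUBLISHED_SIGNATURE_MZ: tuple[float, ...] = (
    8562.3, 8684.4, 8765.1, 9423.5, 13761.5, 14145.2, 17250.8,
)

#: protein identities reported for part of the published signature.
PUBLISHED_SIGNATURE_PROTEINS: dict[float, str] = {
    8765.1: "apolipoprotein C-III",
    13761.5: "transthyretin",
    17250.8: "apolipoprotein A-I",
}


@dataclass
class VotingResults:
    """Fitted weighted-voting model.

    ``params`` has one row per signature signal with columns
    ``mz, mean_case, mean_control, sd_case, sd_control, weight, boundary``
    (weight = signal-to-noise ratio, boundary = class-mean midpoint).
    """

    params: pd.DataFrame
    n_case: int
    n_control: int
    positive: str = "PDAC"
    negative: str = "noncancer"
    normalization: str = "total-intensity"

    @property
    def signature_ids(self) -> list[str]:
        return list(self.params.index)

    def predict(self, data: FeatureTable | pd.DataFrame) -> pd.DataFrame:
        """Votes, voting sum, prediction strength and class per sample.

        ``data`` must contain a column for every signature signal.  Returns a
        frame indexed by sample id with columns ``voting_sum``,
        ``prediction_strength`` and ``predicted``.
        """
        X = data.intensities if isinstance(data, FeatureTable) else data
        missing = [s for s in self.signature_ids if s not in X.columns]
        if missing:
            raise DataError(f"sample data lack signature signal(s): {missing}")
        mat = X[self.signature_ids].to_numpy(dtype=float)
        w = self.params["weight"].to_numpy()
        b = self.params["boundary"].to_numpy()
        votes = w[None, :] * (mat - b[None, :])
        v_sum = votes.sum(axis=1)
        positive_call = v_sum > 0  # V = 0 -> noncancer (conservative)
        agree = np.where(positive_call[:, None], votes > 0, votes < 0)
        v_win = np.where(agree, np.abs(votes), 0.0).sum(axis=1)
        v_lose = np.abs(votes).sum(axis=1) - v_win
        denom = v_win + v_lose
        ps = np.divide(v_win - v_lose, denom, out=np.zeros_like(denom),
                       where=denom > 0)
        return pd.DataFrame(
            {
                "voting_sum": v_sum,
                "prediction_strength": ps,
                "predicted": np.where(positive_call, self.positive, self.negative),
            },
            index=X.index,
        )

    def summary(self) -> str:
        lines = [
            "Weighted-voting proteomic model",
            "=" * 64,
            f"signature size:    {len(self.params)}",
            f"training samples:  {self.n_case} {self.positive} / "
            f"{self.n_control} {self.negative}",
            f"normalization:     {self.normalization}",
            "",
            f"{'signal':<12}{'m/z':>10}{'weight':>12}{'boundary':>14}",
            "-" * 48,
        ]
        for sid, row in self.params.iterrows():
            lines.append(
                f"{sid:<12}{row['mz']:>10.1f}{row['weight']:>12.4f}"
                f"{row['boundary']:>14.6g}"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialize to a structured TSV with a commented header."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write("# maldivote weighted-voting model\n")
            fh.write(f"# positive={self.positive}\tnegative={self.negative}\n")
            fh.write(f"# n_case={self.n_case}\tn_control={self.n_control}\n")
            fh.write(f"# normalization={self.normalization}\n")
            out = self.params.copy()
            out.index.name = "signal_id"
            out.to_csv(fh, sep="\t", float_format="%.10g")

    @classmethod
    def load(cls, path: str | Path) -> "VotingResults":
        meta: dict[str, str] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                for token in line[1:].strip().split("\t"):
                    if "=" in token:
                        k, v = token.split("=", 1)
                        meta[k] = v
                body_start = i + 1
            else:
                break
        from io import StringIO

        params = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t",
                             dtype={"signal_id": str})
        params = params.set_index("signal_id").astype(float)
        return cls(
            params=params,
            n_case=int(meta.get("n_case", 0)),
            n_control=int(meta.get("n_control", 0)),
            positive=meta.get("positive", "PDAC"),
            negative=meta.get("negative", "noncancer"),
            normalization=meta.get("normalization", "total-intensity"),
        )


class WeightedVoting:
    """Weighted-voting model builder over a labelled feature table.

    The positive (cancer) class contributes mu1/sigma1, everything else is
    pooled as noncancer.  ``fit`` computes per-signal weights and boundaries
    for a given signature; ``loocv_curve`` selects the signature size.
    """

    def __init__(
        self,
        table: FeatureTable,
        labels: pd.Series | None = None,
        positive: str = "PDAC",
        negative: str = "noncancer",
    ) -> None:
        self.table = table
        self.labels = table.labels if labels is None else labels
        if self.labels is None:
            raise DataError("WeightedVoting requires sample labels")
        self.positive = positive
        self.negative = negative

    @classmethod
    def from_feature_table(cls, table: FeatureTable, positive: str = "PDAC"
                           ) -> "WeightedVoting":
        return cls(table, positive=positive)

    def fit(self, signature_ids: list[str] | None = None) -> VotingResults:
        """Fit means, SDs, weights and boundaries for the signature signals."""
        ids = signature_ids if signature_ids is not None else self.table.signal_ids
        missing = [s for s in ids if s not in self.table.intensities.columns]
        if missing:
            raise DataError(f"signature signal(s) absent from table: {missing}")
        if len(ids) == 0:
            raise DataError("signature must be nonempty")
        case_mask = (self.labels.to_numpy() == self.positive)
        if case_mask.sum() < 2 or (~case_mask).sum() < 2:
            raise DataError("need at least 2 samples per class to fit")
        X = self.table.intensities[ids].to_numpy(dtype=float)
        mu1 = X[case_mask].mean(axis=0)
        mu2 = X[~case_mask].mean(axis=0)
        sd1 = X[case_mask].std(axis=0, ddof=1)
        sd2 = X[~case_mask].std(axis=0, ddof=1)
        denom = sd1 + sd2
        zero = np.where(denom == 0)[0]
        if len(zero):
            bad = [ids[i] for i in zero]
            raise DataError(
                f"signal(s) with zero total class SD cannot carry a vote: {bad}"
            )
        params = pd.DataFrame(
            {
                "mz": self.table.mz.reindex(ids).to_numpy(),
                "mean_case": mu1,
                "mean_control": mu2,
                "sd_case": sd1,
                "sd_control": sd2,
                "weight": (mu1 - mu2) / denom,
                "boundary": (mu1 + mu2) / 2.0,
            },
            index=pd.Index(ids, name="signal_id"),
        )
        return VotingResults(
            params=params,
            n_case=int(case_mask.sum()),
            n_control=int((~case_mask).sum()),
            positive=self.positive,
            negative=self.negative,
        )

    def loocv_curve(self, candidate_ids: list[str], k_max: int | None = None
                    ) -> "CrossValCurve":
        return loocv_curve(self.table, self.labels, candidate_ids,
                           k_max=k_max, positive=self.positive)


@dataclass
class CrossValCurve:
    """LOOCV misclassification counts per signature size k.

    ``fold_orders`` holds, per held-out sample, the candidate ids ranked by
    within-fold |SAM d| (descending); ``fold_d`` the corresponding d values
    (folds x candidates).  ``optimal_k`` attains the minimum count, ties
    resolved toward the smallest k.
    """

    ks: np.ndarray
    misclassifications: np.ndarray
    optimal_k: int
    fold_orders: list[list[str]]
    fold_d: pd.DataFrame
    n_samples: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "misclassifications": self.misclassifications}
        )

    def summary(self) -> str:
        mis = dict(zip(self.ks.tolist(), self.misclassifications.tolist()))
        return (
            "LOOCV model-size curve\n"
            + "=" * 40
            + f"\nsamples: {self.n_samples}   k range: 1..{self.ks[-1]}"
            + f"\noptimal k: {self.optimal_k} "
            + f"({mis[self.optimal_k]} of {self.n_samples} misclassified)"
        )


def loocv_curve(
    table: FeatureTable,
    labels: pd.Series | None = None,
    candidate_ids: list[str] | None = None,
    k_max: int | None = None,
    positive: str = "PDAC",
) -> CrossValCurve:
    """Leave-one-out misclassification counts for signature sizes 1..k_max.

    Each fold re-ranks the candidates by |SAM d| (with the fold's own fudge
    factor), fits voting models of every size on the remaining samples, and
    predicts the held-out sample.  Fully deterministic: the ranking uses the
    d statistic only, no permutations.
    """
    labels = table.labels if labels is None else labels
    case, _ = _two_class_masks(labels, positive)
    ids = candidate_ids if candidate_ids is not None else table.signal_ids
    missing = [s for s in ids if s not in table.intensities.columns]
    if missing:
        raise DataError(f"candidate signal(s) absent from table: {missing}")
    if k_max is None:
        k_max = len(ids)
    if k_max < 1:
        raise ConfigurationError("k_max must be at least 1")
    if k_max > len(ids):
        raise ConfigurationError("k_max cannot exceed the number of candidates")

    X = table.intensities[ids].to_numpy(dtype=float)
    mz = table.mz.reindex(ids).to_numpy(dtype=float)
    n = X.shape[0]
    y = case  # True = cancer

    mis = np.zeros(k_max, dtype=int)
    fold_orders: list[list[str]] = []
    fold_d_rows = np.empty((n, len(ids)))

    sub_table_cols = list(ids)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xf, yf = X[keep], y[keep]
        if yf.sum() < 2 or (~yf).sum() < 2:
            raise DataError("LOOCV needs at least 3 samples per class")
        r, s, (m1, m2) = _group_stats(Xf, yf)
        s0 = _fold_s0(r, s)
        d = np.divide(r, s + s0, out=np.zeros_like(r), where=(s + s0) > 0)
        fold_d_rows[i] = d

        # rank by |d| desc; ties -> smaller m/z, then id order (stable)
        order = np.lexsort((mz, -np.abs(d)))
        # drop degenerate candidates (zero total SD within the fold)
        sd1 = Xf[yf].std(axis=0, ddof=1)
        sd2 = Xf[~yf].std(axis=0, ddof=1)
        usable = (sd1 + sd2) > 0
        order = np.array([j for j in order if usable[j]], dtype=int)
        if len(order) < k_max:
            raise DataError("not enough non-degenerate candidates within a fold")
        top = order[:k_max]
        fold_orders.append([sub_table_cols[j] for j in top])

        w = (m1[top] - m2[top]) / (sd1[top] + sd2[top])
        b = (m1[top] + m2[top]) / 2.0
        votes = w * (X[i, top] - b)
        v_cum = np.cumsum(votes)
        pred_case = v_cum > 0
        mis += (pred_case != y[i]).astype(int)

    ks = np.arange(1, k_max + 1)
    optimal_k = int(ks[np.argmin(mis)])  # argmin returns first (smallest k) tie
    fold_d = pd.DataFrame(fold_d_rows, columns=sub_table_cols,
                          index=table.intensities.index)
    return CrossValCurve(
        ks=ks,
        misclassifications=mis,
        optimal_k=optimal_k,
        fold_orders=fold_orders,
        fold_d=fold_d,
        n_samples=n,
    )


def _fold_s0(r: np.ndarray, s: np.ndarray) -> float:
    """Lightweight s0 for within-fold ranking (same procedure as estimate_s0)."""
    candidates = np.percentile(s, np.arange(0, 101, 5))
    if np.allclose(s, s.flat[0] if s.size else 0.0):
        return float(candidates[0])
    edges = np.percentile(s, np.arange(0, 101, 10))
    which = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, 9)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for s0 in candidates:
        d = np.divide(r, s + s0, out=np.zeros_like(r), where=(s + s0) > 0)
        mads = []
        for w in range(10):
            dw = d[which == w]
            if len(dw):
                mads.append(np.median(np.abs(dw - np.median(dw))) / 0.64)
        mads = np.asarray(mads)
        mean = mads.mean()
        cv = mads.std(ddof=0) / mean if mean > 0 else np.inf
        if cv < best_cv - 1e-12:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def extract_shared_signature(curve: CrossValCurve, k: int | None = None) -> list[str]:
    """The k signals most shared across the per-fold top-k lists.

    Ranking: appearance frequency across folds, then larger mean |d| across
    folds, then smaller m/z (via the candidate's mean rank id order).
    """
    if k is None:
        k = curve.optimal_k
    from collections import Counter

    counts: Counter[str] = Counter()
    for order in curve.fold_orders:
        counts.update(order[:k])
    if k > len(counts):
        raise ConfigurationError(
            f"k={k} exceeds the {len(counts)} distinct signals seen across folds"
        )
    mean_abs_d = curve.fold_d.abs().mean(axis=0)

    def sort_key(sid: str):
        return (-counts[sid], -float(mean_abs_d.get(sid, 0.0)), _mz_of(sid), sid)

    ranked = sorted(counts, key=sort_key)
    return ranked[:k]


def _mz_of(signal_id: str) -> float:
    """Numeric m/z from a bin id like '8562.3' (fallback: lexicographic)."""
    try:
        return float(signal_id.split("#")[0])
    except ValueError:
        return float("inf")
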