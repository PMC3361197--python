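"""Peak binning, replicate averaging and normalization.

Replicate-level MALDI peak lists are turned into one feature table with a
row per plasma sample and a column per binned m/z signal:

1. ``bin_peaks`` — all peak m/z values from all spectra are pooled, sorted,
   and split into bins wherever the gap between adjacent peaks exceeds the
   binning tolerance (single-linkage clustering in one dimension).  Each
   bin's centre is the intensity-weighted mean m/z, reported to one decimal.
2. ``normalize`` — optional per-spectrum total-intensity scaling, applied
   before replicate averaging so spot-to-spot total-signal variation is
   removed first.
3. ``average_replicates`` — arithmetic mean over each sample's replicate
   spectra; a peak absent from a replicate counts as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "PeakSpectrumSet",
    "BinningConfig",
    "BinnedSpectra",
    "FeatureTable",
    "bin_peaks",
    "average_replicates",
    "normalize",
    "read_peaks_tsv",
    "read_sample_sheet",
]

#: number of decimals used for reported bin centres (8562.3-style notation)
MZ_DECIMALS = 1


@dataclass
class PeakSpectrumSet:
    """Replicate-level peak lists plus the spectrum-to-sample mapping.

    Parameters
    ----------
    peaks
        Long-format table with columns ``spectrum_id``, ``mz``, ``intensity``.
    spectrum_to_sample
        Series mapping every spectrum id to its sample id.
    """

    peaks: pd.DataFrame
    spectrum_to_sample: pd.Series

    def __post_init__(self) -> None:
        required = {"spectrum_id", "mz", "intensity"}
        missing = required - set(self.peaks.columns)
        if missing:
            raise DataError(f"peak table lacks columns: {sorted(missing)}")
        if len(self.peaks) and (self.peaks["mz"] <= 0).any():
            raise DataError("peak m/z values must be strictly positive")
        if len(self.peaks) and (self.peaks["intensity"] < 0).any():
            raise DataError("peak intensities must be nonnegative")

    @property
    def spectrum_ids(self) -> list[str]:
        return list(pd.unique(self.peaks["spectrum_id"]))

    @property
    def n_spectra(self) -> int:
        return self.peaks["spectrum_id"].nunique()

    def to_tsv(self, path: str | Path) -> None:
        self.peaks.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(
        cls, peaks_path: str | Path, sample_sheet: pd.DataFrame
    ) -> "PeakSpectrumSet":
        peaks = pd.read_csv(peaks_path, sep="\t")
        mapping = sample_sheet.set_index("spectrum_id")["sample_id"]
        return cls(peaks=peaks, spectrum_to_sample=mapping)


@dataclass(frozen=True)
class BinningConfig:
    """Cross-spectrum binning parameters.

    ``tolerance`` is the maximum gap between adjacent sorted peak m/z values
    that still keeps them in one bin; relative (fraction of m/z, evaluated at
    the left peak) when ``relative`` is true, absolute Daltons otherwise.
    ``min_presence`` drops bins observed in fewer than that fraction of
    spectra.
    """

    tolerance: float = 5e-4
    relative: bool = True
    min_presence: float = 0.0

    def __post_init__(self) -> None:
        if not self.tolerance > 0:
            raise ConfigurationError("tolerance must be positive")
        if not 0.0 <= self.min_presence <= 1.0:
            raise ConfigurationError("min_presence must lie in [0, 1]")

    def window(self, mz: float | np.ndarray) -> float | np.ndarray:
        """Absolute gap threshold at a given m/z."""
        return self.tolerance * mz if self.relative else self.tolerance


@dataclass
class BinnedSpectra:
    """Spectrum-level binned intensities (rows = spectra, columns = bins)."""

    intensities: pd.DataFrame
    mz: pd.Series  # bin id -> centre m/z (1 decimal)
    spectrum_to_sample: pd.Series

    @property
    def signal_ids(self) -> list[str]:
        return list(self.intensities.columns)


@dataclass
class FeatureTable:
    """Samples x binned-signal intensity matrix with labels and m/z centres.

    ``intensities`` is indexed by sample id; columns are bin ids (the
    one-decimal m/z string).  ``mz`` maps bin id to its numeric centre and is
    strictly increasing.  ``labels`` assigns each sample its class.
    """

    intensities: pd.DataFrame
    mz: pd.Series
    labels: pd.Series | None = None
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.intensities.isna().any().any():
            raise DataError("feature table contains missing entries")
        vals = self.mz.to_numpy(dtype=float)
        if len(vals) > 1 and not np.all(np.diff(vals) > 0):
            raise DataError("bin m/z centres must be strictly increasing")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.intensities.index)
            if self.labels.isna().any():
                orphans = list(self.labels.index[self.labels.isna()])
                raise DataError(f"samples without class label: {orphans[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def signal_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return len(self.intensities)

    @property
    def n_signals(self) -> int:
        return self.intensities.shape[1]

    def restrict(self, signal_ids: list[str]) -> "FeatureTable":
        """Sub-table over a subset of signals (keeps m/z order)."""
        keep = [s for s in self.signal_ids if s in set(signal_ids)]
        return FeatureTable(
            intensities=self.intensities[keep].copy(),
            mz=self.mz.loc[keep],
            labels=None if self.labels is None else self.labels.copy(),
            cohort=self.cohort,
        )

    def to_tsv(self, path: str | Path, labels_path: str | Path | None = None) -> None:
        out = self.intensities.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", float_format="%.8g")
        if labels_path is not None and self.labels is not None:
            side = self.labels.rename("class").to_frame()
            side.index.name = "sample_id"
            side["cohort"] = self.cohort
            side.to_csv(labels_path, sep="\t")


def _bin_id(mz_center: float) -> str:
    return f"{mz_center:.{MZ_DECIMALS}f}"


def bin_peaks(spectra: PeakSpectrumSet, cfg: BinningConfig) -> BinnedSpectra:
    """Single-linkage gap binning of all peaks across all spectra.

    Pools every peak, sorts by m/z, and opens a new bin whenever the gap to
    the previous peak exceeds ``cfg.window`` evaluated at the previous
    (left) peak's m/z.  Within a spectrum, intensities of peaks falling in
    the same bin are summed.  The result is independent of the order in
    which spectra are supplied.
    """
    peaks = spectra.peaks
    if len(peaks) == 0:
        raise DataError("cannot bin an empty peak set")

    mz = peaks["mz"].to_numpy(dtype=float)
    order = np.argsort(mz, kind="stable")
    mz_sorted = mz[order]
    gaps = np.diff(mz_sorted)
    thresholds = np.asarray(cfg.window(mz_sorted[:-1]))
    # bin index per sorted peak: a gap strictly above threshold opens a bin
    bin_idx_sorted = np.concatenate([[0], np.cumsum(gaps > thresholds)])
    bin_idx = np.empty(len(mz), dtype=np.int64)
    bin_idx[order] = bin_idx_sorted

    inten = peaks["intensity"].to_numpy(dtype=float)
    n_bins = int(bin_idx.max()) + 1
    # intensity-weighted centre; zero-intensity bins fall back to plain mean
    w_sum = np.bincount(bin_idx, weights=inten, minlength=n_bins)
    wmz_sum = np.bincount(bin_idx, weights=inten * mz, minlength=n_bins)
    cnt = np.bincount(bin_idx, minlength=n_bins)
    mz_sum = np.bincount(bin_idx, weights=mz, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        centers = np.where(w_sum > 0, wmz_sum / np.where(w_sum > 0, w_sum, 1.0),
                           mz_sum / cnt)
    centers = np.round(centers, MZ_DECIMALS)

    ids = [_bin_id(c) for c in centers]
    if len(set(ids)) != len(ids):
        # two bins rounding to the same 1-decimal centre: disambiguate
        seen: dict[str, int] = {}
        uniq = []
        for s in ids:
            k = seen.get(s, 0)
            uniq.append(s if k == 0 else f"{s}#{k}")
            seen[s] = k + 1
        ids = uniq

    wide = (
        pd.DataFrame(
            {
                "spectrum_id": peaks["spectrum_id"].to_numpy(),
                "bin": np.asarray(ids, dtype=object)[bin_idx],
                "intensity": inten,
            }
        )
        .pivot_table(index="spectrum_id", columns="bin", values="intensity",
                     aggfunc="sum", fill_value=0.0)
    )
    # deterministic ordering: spectra sorted by id, bins by m/z
    wide = wide.reindex(sorted(wide.index))
    wide = wide[ids]  # centers were built in ascending m/z order
    wide.columns.name = None

    mz_series = pd.Series(centers, index=ids, name="mz")

    if cfg.min_presence > 0:
        presence = (wide > 0).mean(axis=0)
        keep = presence[presence >= cfg.min_presence].index
        wide = wide[list(keep)]
        mz_series = mz_series.loc[list(keep)]

    mapping = spectra.spectrum_to_sample
    return BinnedSpectra(intensities=wide, mz=mz_series, spectrum_to_sample=mapping)


def average_replicates(
    binned: BinnedSpectra,
    spectrum_to_sample: Mapping[str, str] | pd.Series | None = None,
    labels: pd.Series | None = None,
    cohort: str = "",
) -> FeatureTable:
    """Average each sample's replicate spectra into one row per sample."""
    mapping = (
        pd.Series(spectrum_to_sample)
        if spectrum_to_sample is not None
        else binned.spectrum_to_sample
    )
    spectra_ids = binned.intensities.index
    orphans = [s for s in spectra_ids if s not in mapping.index]
    if orphans:
        raise DataError(f"spectra with no sample mapping: {orphans[:10]}")
    groups = mapping.loc[spectra_ids]
    table = binned.intensities.groupby(groups.to_numpy()).mean()
    table = table.reindex(sorted(table.index))
    table.index.name = "sample_id"
    return FeatureTable(intensities=table, mz=binned.mz.copy(), labels=labels,
                        cohort=cohort)


def normalize(table, method: str = "total-intensity"):
    """Per-row normalization of a :class:`BinnedSpectra` or :class:`FeatureTable`.

    ``total-intensity`` rescales every row to unit sum; ``none`` is the
    identity.  A row summing to zero cannot be normalized and raises,
    naming the offending spectrum/sample.
    """
    if method not in ("none", "total-intensity"):
        raise ConfigurationError(f"unknown normalization method: {method!r}")
    if method == "none":
        return table
    mat = table.intensities
    totals = mat.sum(axis=1)
    bad = totals[totals <= 0]
    if len(bad):
        raise DataError(f"all-zero row(s) under total-intensity: {list(bad.index)[:10]}")
    scaled = mat.div(totals, axis=0)
    if isinstance(table, FeatureTable):
        return replace(table, intensities=scaled)
    return replace(table, intensities=scaled)


def log2_transform(table: FeatureTable, pseudocount: float | None = None
                   ) -> FeatureTable:
    """Log2 intensity scale for modelling.

    MALDI peak intensities are approximately log-normal with abundances
    spanning orders of magnitude; on the log2 scale within-class spreads
    become comparable across signals, which the signal-to-noise voting
    weights and the SAM statistic implicitly assume.  Zeros (peaks absent
    from every replicate) are handled with a pseudocount, by default half
    the smallest positive intensity in the table.
    """
    mat = table.intensities.to_numpy(dtype=float)
    if pseudocount is None:
        positive = mat[mat > 0]
        if positive.size == 0:
            raise DataError("cannot log-transform an all-zero table")
        pseudocount = 0.5 * float(positive.min())
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be positive")
    out = pd.DataFrame(
        np.log2(mat + pseudocount),
        index=table.intensities.index,
        columns=table.intensities.columns,
    )
    return replace(table, intensities=out)


def read_peaks_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "spectrum_id", "class"}
    missing = required - set(sheet.columns)
    if missing:
        raise DataError(f"sample sheet lacks columns: {sorted(missing)}")
    return sheet
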