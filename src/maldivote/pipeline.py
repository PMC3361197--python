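"""End-to-end orchestration: discovery on a training cohort, frozen-model
validation on independent cohorts.

``run_discovery`` executes bin -> per-spectrum total-intensity normalize ->
replicate average -> three-test screen -> LOOCV model-size curve ->
most-shared signature -> final weighted-voting fit -> training report, and
writes every artifact (with the config and seed) to the output directory.

``run_validation`` takes a frozen model only: test-cohort spectra are binned
independently, their bins are matched to the model's signature by m/z
within the binning tolerance, and predictions, subgroup and marker-
combination reports are produced without touching any model parameter
(train/test firewall).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import branch_purity, hierarchical_cluster
from .errors import ConfigurationError, DataError
from .evaluation import (
    combine_with_marker,
    confusion,
    metrics,
    subgroup_report,
)
from .preprocessing import (
    BinningConfig,
    FeatureTable,
    PeakSpectrumSet,
    average_replicates,
    bin_peaks,
    log2_transform,
    normalize,
    read_peaks_tsv,
    read_sample_sheet,
)
from .screen import DifferentialScreen, ScreenResults, SelectionCriteria
from .voting import (
    CrossValCurve,
    VotingResults,
    WeightedVoting,
    extract_shared_signature,
)

__all__ = ["PipelineConfig", "DiscoveryResult", "ValidationResult",
           "run_discovery", "run_validation", "build_feature_table"]

log = logging.getLogger("maldivote")


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (serializable to YAML)."""

    peaks_path: str = ""
    samples_path: str = ""
    output_dir: str = "maldivote_out"
    binning: BinningConfig = field(default_factory=BinningConfig)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    normalization: str = "total-intensity"
    log_transform: bool = True
    k_max: int | None = None
    marker_cutoff: float = 37.0
    clustering_metric: str = "uncentered"
    clustering_linkage: str = "average"
    positive_class: str = "PDAC"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        binning = BinningConfig(**raw.pop("binning", {}))
        criteria = SelectionCriteria(**raw.pop("criteria", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config field(s): {sorted(unknown)}")
        return cls(binning=binning, criteria=criteria, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


def build_feature_table(
    spectra: PeakSpectrumSet,
    sheet: pd.DataFrame,
    binning: BinningConfig,
    normalization: str = "total-intensity",
    cohort: str = "",
    log_transform: bool = True,
) -> FeatureTable:
    """Bin -> per-spectrum normalize -> replicate average (-> log2 scale)."""
    binned = bin_peaks(spectra, binning)
    binned = normalize(binned, normalization)
    labels = sheet.drop_duplicates("sample_id").set_index("sample_id")["class"]
    table = average_replicates(binned, labels=labels, cohort=cohort)
    if log_transform:
        table = log2_transform(table)
    return table


@dataclass
class DiscoveryResult:
    """Artifacts of one discovery run on a training cohort."""

    table: FeatureTable
    screen: ScreenResults
    curve: CrossValCurve
    signature: list[str]
    model: VotingResults
    training_predictions: pd.DataFrame
    training_metrics: "object"
    branch_report: pd.DataFrame | None = None


def run_discovery(
    config: PipelineConfig,
    spectra: PeakSpectrumSet | None = None,
    sheet: pd.DataFrame | None = None,
    write: bool = True,
) -> DiscoveryResult:
    """Full discovery on the training cohort; see module docstring."""
    t0 = time.time()
    if spectra is None or sheet is None:
        if not Path(config.samples_path).exists():
            raise ConfigurationError(f"sample sheet not found: {config.samples_path}")
        if not Path(config.peaks_path).exists():
            raise ConfigurationError(f"peak list not found: {config.peaks_path}")
        sheet = read_sample_sheet(config.samples_path)
        spectra = PeakSpectrumSet(
            peaks=read_peaks_tsv(config.peaks_path),
            spectrum_to_sample=sheet.set_index("spectrum_id")["sample_id"],
        )

    table = build_feature_table(spectra, sheet, config.binning,
                                config.normalization, cohort="training",
                                log_transform=config.log_transform)
    classes = set(table.labels.unique())
    if config.positive_class not in classes or len(classes) < 2:
        raise DataError(
            f"training cohort must contain {config.positive_class!r} and one "
            f"other class; found {sorted(classes)}"
        )
    log.info("binned %d spectra into %d signals for %d samples (%.1fs)",
             spectra.n_spectra, table.n_signals, table.n_samples, time.time() - t0)

    screen = DifferentialScreen(table, config.criteria,
                                positive=config.positive_class).fit(seed=config.seed)
    log.info("screen selected %d of %d signals", screen.n_selected, table.n_signals)
    selected = screen.selected_ids
    if not selected:
        raise DataError("screen selected no signals; nothing to cross-validate")

    k_max = config.k_max if config.k_max is not None else len(selected)
    k_max = min(k_max, len(selected))
    model_builder = WeightedVoting(table, positive=config.positive_class)
    curve = model_builder.loocv_curve(selected, k_max=k_max)
    signature = extract_shared_signature(curve, curve.optimal_k)
    log.info("LOOCV optimal k = %d (%d misclassified of %d)",
             curve.optimal_k,
             int(curve.misclassifications[curve.optimal_k - 1]), curve.n_samples)

    model = model_builder.fit(signature)
    preds = model.predict(table)
    counts = confusion(preds["predicted"], table.labels,
                       positive=config.positive_class)
    train_metrics = metrics(counts)

    branch_report = None
    if len(selected) >= 1 and table.n_samples >= 2:
        dendro = hierarchical_cluster(table.restrict(selected),
                                      metric=config.clustering_metric,
                                      linkage=config.clustering_linkage)
        branch_report = branch_purity(dendro, table.labels)

    result = DiscoveryResult(
        table=table, screen=screen, curve=curve, signature=signature,
        model=model, training_predictions=preds, training_metrics=train_metrics,
        branch_report=branch_report,
    )
    if write:
        _write_discovery(config, result)
    return result


def _write_discovery(config: PipelineConfig, res: DiscoveryResult) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    res.table.to_tsv(out / "feature_table.tsv", out / "labels.tsv")
    res.screen.to_tsv(out / "selection.tsv")
    res.curve.to_frame().to_csv(out / "loocv_curve.tsv", sep="\t", index=False)
    res.model.save(out / "model.tsv")
    res.training_predictions.to_csv(out / "training_predictions.tsv", sep="\t",
                                    index_label="sample_id")
    res.training_metrics.to_frame().to_csv(out / "training_metrics.tsv", sep="\t")
    if res.branch_report is not None:
        res.branch_report.to_csv(out / "branch_purity.tsv", sep="\t")
    summary = {
        "seed": config.seed,
        "n_samples": res.table.n_samples,
        "n_signals": res.table.n_signals,
        "n_selected": res.screen.n_selected,
        "optimal_k": res.curve.optimal_k,
        "signature": res.signature,
        "signature_mz": [float(res.model.params.loc[s, "mz"]) for s in res.signature],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))


@dataclass
class ValidationResult:
    """Frozen-model evaluation on an independent cohort."""

    predictions: pd.DataFrame
    counts: "object"
    metrics: "object"
    per_class_report: pd.DataFrame
    marker_report: pd.DataFrame | None = None
    combined_metrics: "object" = None


def match_signature(
    model: VotingResults, table: FeatureTable, binning: BinningConfig
) -> pd.DataFrame:
    """Map each signature signal to the nearest test bin within tolerance.

    Independent batches are binned separately, so signature m/z values are
    matched to test-cohort bin centres within the binning tolerance window.
    Returns the test table's columns renamed to the model's signal ids.
    """
    test_mz = table.mz.to_numpy(dtype=float)
    cols = []
    unmatched = []
    for sid, row in model.params.iterrows():
        target = float(row["mz"])
        delta = np.abs(test_mz - target)
        j = int(np.argmin(delta))
        if delta[j] > binning.window(target):
            unmatched.append(target)
        else:
            cols.append((sid, table.signal_ids[j]))
    if unmatched:
        raise DataError(
            f"signature m/z not found in test binning within tolerance: {unmatched}"
        )
    renamed = table.intensities[[c for _, c in cols]].copy()
    renamed.columns = [s for s, _ in cols]
    return renamed


def run_validation(
    config: PipelineConfig,
    model: VotingResults,
    spectra: PeakSpectrumSet | None = None,
    sheet: pd.DataFrame | None = None,
    table: FeatureTable | None = None,
    marker: pd.Series | None = None,
    write: bool = False,
) -> ValidationResult:
    """Predict an independent cohort with a frozen model and report accuracy."""
    if table is None:
        if spectra is None or sheet is None:
            sheet = read_sample_sheet(config.samples_path)
            spectra = PeakSpectrumSet(
                peaks=read_peaks_tsv(config.peaks_path),
                spectrum_to_sample=sheet.set_index("spectrum_id")["sample_id"],
            )
        table = build_feature_table(spectra, sheet, config.binning,
                                    config.normalization, cohort="validation",
                                    log_transform=config.log_transform)
    if marker is None and sheet is not None and "marker" in sheet.columns:
        marker = sheet.drop_duplicates("sample_id").set_index("sample_id")["marker"]

    matched = match_signature(model, table, config.binning)
    preds = model.predict(matched)
    counts = confusion(preds["predicted"], table.labels, positive=model.positive)
    metric_set = metrics(counts)
    correct = (
        (preds["predicted"] == model.positive)
        == (table.labels.reindex(preds.index) == model.positive)
    )
    per_class = subgroup_report(correct, table.labels.reindex(preds.index))

    marker_report = None
    combined_metrics = None
    if marker is not None:
        marker = pd.to_numeric(marker, errors="coerce")
        if marker.notna().any():
            model_pos = preds["predicted"] == model.positive
            marker_report = combine_with_marker(model_pos, marker,
                                                cutoff=config.marker_cutoff)
            combined_calls = pd.Series(
                np.where(marker_report["combined"], model.positive, "noncancer"),
                index=preds.index,
            )
            combined_metrics = metrics(
                confusion(combined_calls, table.labels.reindex(preds.index),
                          positive=model.positive)
            )

    result = ValidationResult(
        predictions=preds, counts=counts, metrics=metric_set,
        per_class_report=per_class, marker_report=marker_report,
        combined_metrics=combined_metrics,
    )
    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        preds.to_csv(out / "validation_predictions.tsv", sep="\t",
                     index_label="sample_id")
        metric_set.to_frame().to_csv(out / "validation_metrics.tsv", sep="\t")
        per_class.to_csv(out / "validation_per_class.tsv", sep="\t")
        if marker_report is not None:
            marker_report.to_csv(out / "marker_combination.tsv", sep="\t",
                                 index_label="sample_id")
            combined_metrics.to_frame().to_csv(
                out / "combined_metrics.tsv", sep="\t"
            )
    return result
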