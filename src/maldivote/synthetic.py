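"""Synthetic MALDI-like cohorts with planted ground truth.

The generator emulates the structure of a plasma MALDI-TOF case/control
profiling study: a panel of protein signals spread over 2-50 kDa, six
replicate spot spectra per plasma sample, log-normal intensities with
multiplicative replicate noise and occasional peak dropout, and a planted
subset of differential signals whose log-intensity means are shifted
between cases (PDAC) and controls by specified standardized effect sizes
(Cohen's d on the log2 scale).  A scalar serum tumour marker (CA19-9-like,
U/mL) is generated per sample from class-specific log-normal distributions
on an independent random stream.

Signal m/z positions are laid out on a jittered log-spaced grid whose
spacing is several times the downstream binning tolerance, and each
replicate peak's m/z is jittered uniformly within half the binning
tolerance, so gap-based binning recovers the generating panel exactly by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .preprocessing import PeakSpectrumSet

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "generate_marker",
           "write_cohort", "DEFAULT_MARKER_PARAMS"]

CASE_CLASS = "PDAC"
CONTROL_CLASS = "healthy"

#: class -> (median U/mL, sigma of log). Medians give roughly the clinical
#: picture for a CA19-9-like marker: ~75% of cases but <10% of healthy
#: subjects above the 37 U/mL cutoff, ~20% of benign pancreatitis elevated.
DEFAULT_MARKER_PARAMS: dict[str, tuple[float, float]] = {
    "PDAC": (100.0, 1.5),
    "healthy": (10.0, 1.0),
    "acute_pancreatitis": (15.0, 1.2),
    "chronic_pancreatitis": (15.0, 1.2),
    "AIP": (15.0, 1.2),
}


@dataclass
class CohortConfig:
    """Design of one synthetic cohort.

    ``effect_sizes`` (one signed Cohen's d per planted differential signal,
    strong signals first) may be given explicitly; by default the
    ``n_strong`` strong signals get ``strong_effect`` and the remaining
    planted signals draw |d| uniformly from ``moderate_effect_range``, with
    random sign (markers go both up and down in cases).

    Strong signals are independent "drivers"; the remaining planted
    ("satellite") signals realize their marginal effects through
    ``n_factors`` shared latent disease factors of standardized separation
    ``factor_separation`` — emulating co-regulated protein species whose
    joint information saturates at the factor level even though each is
    marginally differential.  ``outlier_fraction`` of subjects carry
    biological noise inflated by ``outlier_scale`` (contaminated normal),
    as outlier plasma profiles do in real cohorts.
    """

    n_cases: int = 80
    n_controls: int = 80
    n_signals: int = 1063
    n_differential: int = 134
    n_strong: int = 7
    effect_sizes: np.ndarray | None = None
    strong_effect: float = 2.0
    moderate_effect_range: tuple[float, float] = (1.0, 1.4)
    n_factors: int = 2
    factor_separation: float = 2.0
    replicate_count: int = 6
    mz_range: tuple[float, float] = (2000.0, 50000.0)
    binning_tolerance: float = 5e-4  # relative; jitter stays within half of it
    biological_cv_log2: float = 0.5  # between-sample SD of log2 intensity
    outlier_fraction: float = 0.05  # samples with inflated biological noise
    outlier_scale: float = 2.5  # noise-SD inflation factor for those samples
    replicate_cv: float = 0.25  # CV of multiplicative replicate noise
    peak_dropout_prob: float = 0.05
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 2.0
    marker_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PARAMS)
    )
    cohort_name: str = "training"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls", "n_signals", "replicate_count"):
            if getattr(self, name) < (1 if name == "replicate_count" else 0):
                raise ConfigurationError(f"{name} is invalid: {getattr(self, name)}")
        if not 0 <= self.n_strong <= self.n_differential <= self.n_signals:
            raise ConfigurationError(
                "need n_strong <= n_differential <= n_signals, got "
                f"{self.n_strong}/{self.n_differential}/{self.n_signals}"
            )
        if not 0.0 <= self.peak_dropout_prob <= 1.0:
            raise ConfigurationError("peak_dropout_prob must lie in [0, 1]")
        if not self.mz_range[0] > 0 or not self.mz_range[1] > self.mz_range[0]:
            raise ConfigurationError(f"mz_range is invalid: {self.mz_range}")
        if self.replicate_cv < 0:
            raise ConfigurationError("replicate_cv must be nonnegative")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ConfigurationError("outlier_fraction must lie in [0, 1]")
        if self.outlier_scale < 1.0:
            raise ConfigurationError("outlier_scale must be >= 1")
        if self.n_factors < 1:
            raise ConfigurationError("n_factors must be >= 1")
        if self.effect_sizes is None and self.factor_separation < max(
            self.moderate_effect_range
        ):
            raise ConfigurationError(
                "factor_separation must be >= the largest satellite effect "
                "(loadings cannot exceed 1)"
            )
        if self.binning_tolerance <= 0:
            raise ConfigurationError("binning_tolerance must be positive")
        if self.effect_sizes is not None:
            self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
            if len(self.effect_sizes) != self.n_differential:
                raise ConfigurationError(
                    "effect_sizes must have length n_differential "
                    f"({len(self.effect_sizes)} != {self.n_differential})"
                )


@dataclass
class GroundTruth:
    """Planted truth for parameter-recovery tests; never read by the pipeline."""

    differential_signal_ids: list[str]
    strong_signal_ids: list[str]
    effect_size: pd.Series  # signal id -> signed d (0 for null signals)
    sample_class: pd.Series  # sample id -> class
    signal_mz: pd.Series  # signal id -> true m/z

    def __post_init__(self) -> None:
        if not set(self.strong_signal_ids) <= set(self.differential_signal_ids):
            raise ConfigurationError("strong signals must be a subset of differential")

    def to_tsv(self, path: str | Path) -> None:
        out = pd.DataFrame(
            {
                "signal_id": self.effect_size.index,
                "mz": self.signal_mz.reindex(self.effect_size.index).to_numpy(),
                "effect_size": self.effect_size.to_numpy(),
                "differential": [
                    s in set(self.differential_signal_ids) for s in self.effect_size.index
                ],
                "strong": [s in set(self.strong_signal_ids) for s in self.effect_size.index],
            }
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _signal_positions(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Jittered log-spaced m/z grid, spacing safely above the bin tolerance."""
    lo, hi = cfg.mz_range
    if cfg.n_signals == 1:
        return np.array([np.sqrt(lo * hi)])
    log_step = (np.log(hi) - np.log(lo)) / (cfg.n_signals + 1)
    if log_step < 3.0 * cfg.binning_tolerance:
        raise ConfigurationError(
            "n_signals too large for mz_range at the configured binning_tolerance"
        )
    base = np.log(lo) + log_step * (1 + np.arange(cfg.n_signals))
    jitter = rng.uniform(-0.2, 0.2, size=cfg.n_signals) * log_step
    return np.exp(base + jitter)


def _effect_vector(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.effect_sizes is not None:
        return cfg.effect_sizes.copy()
    d = np.empty(cfg.n_differential)
    d[: cfg.n_strong] = cfg.strong_effect
    lo, hi = cfg.moderate_effect_range
    d[cfg.n_strong:] = rng.uniform(lo, hi, size=cfg.n_differential - cfg.n_strong)
    sign = rng.choice([-1.0, 1.0], size=cfg.n_differential)
    return d * sign


def generate_cohort(
    config: CohortConfig,
    cohort_stream: int = 0,
) -> tuple[PeakSpectrumSet, pd.DataFrame, GroundTruth]:
    """Generate replicate peak spectra, a sample sheet, and the planted truth.

    Returns ``(spectra, sample_sheet, truth)`` where the sample sheet has one
    row per spectrum with columns ``sample_id, spectrum_id, class, cohort``.
    Deterministic for a fixed ``config.seed``.

    The signal panel (m/z grid, baselines, planted subset and effect sizes)
    is drawn from a stream keyed by the seed alone, while per-sample data
    use ``cohort_stream`` as an extra key — so a validation cohort sharing
    the training panel is obtained by calling again with a different
    ``cohort_stream`` (adjusting ``n_cases``/``n_controls``/``cohort_name``
    as needed).
    """
    rng_panel = np.random.default_rng([config.seed, 2])
    rng = np.random.default_rng([config.seed, 0, cohort_stream])

    n_samples = config.n_cases + config.n_controls
    prefix = "" if cohort_stream == 0 else f"v{cohort_stream}"
    sample_ids = [f"{prefix}case{i + 1:03d}" for i in range(config.n_cases)] + [
        f"{prefix}ctrl{i + 1:03d}" for i in range(config.n_controls)
    ]
    classes = np.array(
        [CASE_CLASS] * config.n_cases + [CONTROL_CLASS] * config.n_controls, dtype=object
    )

    signal_ids = [f"sig{i + 1:04d}" for i in range(config.n_signals)]
    mz = _signal_positions(config, rng_panel)

    # planted differential subset: random signal indices, strong first
    diff_idx = rng_panel.choice(config.n_signals, size=config.n_differential,
                                replace=False)
    strong_idx = diff_idx[: config.n_strong]
    d_signed = _effect_vector(config, rng_panel)

    effect = np.zeros(config.n_signals)
    effect[diff_idx] = d_signed

    base_log2 = rng_panel.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                                 size=config.n_signals)
    bio_sd = config.biological_cv_log2
    # per-sample biological log2 intensity; cases shifted by d * bio_sd.
    # Satellite signals realize their deviations partly through shared
    # latent factors (loading lambda = |d| / factor_separation), so their
    # joint information saturates at the factor level; strong drivers and
    # null signals are independent.  A small fraction of subjects carry
    # globally inflated biological noise (contaminated normal).
    shift = np.where(classes[:, None] == CASE_CLASS, effect[None, :] * bio_sd, 0.0)

    dev = rng.normal(0.0, 1.0, size=(n_samples, config.n_signals))
    sat_idx = diff_idx[config.n_strong:]
    if len(sat_idx):
        sat_d = np.abs(effect[sat_idx])
        if np.any(sat_d > config.factor_separation + 1e-12):
            raise ConfigurationError(
                "satellite |effect| exceeds factor_separation (loading > 1)"
            )
        lam = sat_d / config.factor_separation
        sign = np.sign(effect[sat_idx])
        factor_of = np.arange(len(sat_idx)) % config.n_factors
        factors = rng.normal(0.0, 1.0, size=(n_samples, config.n_factors))
        dev[:, sat_idx] = (
            sign[None, :] * lam[None, :] * factors[:, factor_of]
            + np.sqrt(1.0 - lam**2)[None, :] * dev[:, sat_idx]
        )

    inflate = np.where(
        rng.random(n_samples) < config.outlier_fraction, config.outlier_scale, 1.0
    )
    sample_log2 = base_log2[None, :] + shift + bio_sd * inflate[:, None] * dev

    rep = config.replicate_count
    sigma_rep = np.sqrt(np.log1p(config.replicate_cv**2))  # log-normal CV -> sigma
    rep_noise = rng.normal(0.0, sigma_rep, size=(n_samples, rep, config.n_signals))
    intensity = np.exp2(sample_log2)[:, None, :] * np.exp(rep_noise - sigma_rep**2 / 2)

    keep = rng.random((n_samples, rep, config.n_signals)) >= config.peak_dropout_prob
    half_window = 0.5 * config.binning_tolerance * mz
    mz_jitter = rng.uniform(-1.0, 1.0, size=(n_samples, rep, config.n_signals)) * half_window

    spectrum_ids = np.array(
        [f"{sid}_r{r + 1}" for sid in sample_ids for r in range(rep)], dtype=object
    )
    sample_per_spectrum = np.repeat(np.asarray(sample_ids, dtype=object), rep)

    flat_keep = keep.reshape(n_samples * rep, config.n_signals)
    counts = flat_keep.sum(axis=1)
    peaks = pd.DataFrame(
        {
            "spectrum_id": np.repeat(spectrum_ids, counts),
            "mz": (mz[None, None, :] + mz_jitter)[keep],
            "intensity": intensity[keep],
        }
    )

    sheet = pd.DataFrame(
        {
            "sample_id": sample_per_spectrum,
            "spectrum_id": spectrum_ids,
            "class": np.repeat(classes, rep),
            "cohort": config.cohort_name,
        }
    )

    truth = GroundTruth(
        differential_signal_ids=[signal_ids[i] for i in diff_idx],
        strong_signal_ids=[signal_ids[i] for i in strong_idx],
        effect_size=pd.Series(effect, index=signal_ids, name="effect_size"),
        sample_class=pd.Series(classes, index=sample_ids, name="class"),
        signal_mz=pd.Series(mz, index=signal_ids, name="mz"),
    )

    spectra = PeakSpectrumSet(
        peaks=peaks, spectrum_to_sample=sheet.set_index("spectrum_id")["sample_id"]
    )
    return spectra, sheet, truth


def measured_effect_sizes(config: CohortConfig, truth: GroundTruth) -> pd.Series:
    """Effect sizes on the replicate-averaged log2 scale.

    Replicate averaging shrinks the replicate-noise component, so the
    standardized separation seen by the pipeline is the planted d times
    bio_sd / sqrt(bio_sd^2 + sigma_rep^2 / R) with sigma_rep the log2 SD of
    the multiplicative replicate noise and R the replicate count.
    """
    bio = config.biological_cv_log2
    sigma_rep = np.sqrt(np.log1p(config.replicate_cv**2)) / np.log(2)
    atten = bio / np.sqrt(bio**2 + sigma_rep**2 / config.replicate_count)
    return truth.effect_size * atten


def bayes_rates(config: CohortConfig, truth: GroundTruth,
                signal_ids: list[str]) -> float:
    """Bayes-optimal per-class accuracy of a given signal subset.

    Accounts for the generator's full structure: satellite signals share
    latent factors (so their joint information saturates), replicate
    averaging attenuates effects, and outlier subjects carry inflated
    noise.  The returned value is the per-class accuracy of the linear
    rule optimal for the majority (non-outlier) population, averaged over
    the outlier mixture — identical for sensitivity and specificity by
    symmetry.
    """
    from scipy.stats import norm

    bio = config.biological_cv_log2
    rep2 = (np.log1p(config.replicate_cv**2) / np.log(2) ** 2) / config.replicate_count

    ids = list(signal_ids)
    m = len(ids)
    d_signed = truth.effect_size.reindex(ids).to_numpy(dtype=float)
    delta = bio * d_signed  # class-mean difference on the log2 scale

    # biological correlation from the shared factors among satellites
    satellites = truth.differential_signal_ids[len(truth.strong_signal_ids):]
    sat_pos = {sid: i for i, sid in enumerate(satellites)}
    loading = np.zeros(m)
    factor = np.full(m, -1)
    for j, sid in enumerate(ids):
        if sid in sat_pos:
            loading[j] = abs(d_signed[j]) / config.factor_separation * np.sign(
                d_signed[j]
            )
            factor[j] = sat_pos[sid] % config.n_factors
    R = np.eye(m)
    for a in range(m):
        for b in range(m):
            if a != b and factor[a] >= 0 and factor[a] == factor[b]:
                R[a, b] = loading[a] * loading[b]

    cov = bio**2 * R + rep2 * np.eye(m)
    w = np.linalg.solve(cov, delta)
    margin = 0.5 * float(w @ delta)
    sd_normal = float(np.sqrt(w @ cov @ w))
    cov_out = config.outlier_scale**2 * bio**2 * R + rep2 * np.eye(m)
    sd_out = float(np.sqrt(w @ cov_out @ w))
    pi = config.outlier_fraction
    return float(
        (1 - pi) * norm.cdf(margin / sd_normal) + pi * norm.cdf(margin / sd_out)
    )


def generate_marker(config: CohortConfig, sheet: pd.DataFrame) -> pd.Series:
    """Per-sample serum marker values (U/mL), log-normal per class.

    Uses a random stream independent of the spectra so adding the marker
    does not perturb the proteomic data.
    """
    rng = np.random.default_rng([config.seed, 1])
    per_sample = sheet.drop_duplicates("sample_id").set_index("sample_id")["class"]
    missing = sorted(set(per_sample.unique()) - set(config.marker_params))
    if missing:
        raise ConfigurationError(f"marker_params missing for class(es): {missing}")
    values = np.empty(len(per_sample))
    for i, cls in enumerate(per_sample.to_numpy()):
        median, sigma = config.marker_params[cls]
        values[i] = median * np.exp(rng.normal(0.0, sigma)) if sigma > 0 else median
    return pd.Series(values, index=per_sample.index, name="marker")


def write_cohort(
    outdir: str | Path,
    spectra: PeakSpectrumSet,
    sheet: pd.DataFrame,
    truth: GroundTruth | None = None,
    marker: pd.Series | None = None,
) -> dict[str, Path]:
    """Write peaks.tsv, samples.tsv and (optionally) truth.tsv to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"peaks": outdir / "peaks.tsv", "samples": outdir / "samples.tsv"}
    spectra.to_tsv(paths["peaks"])
    out_sheet = sheet.copy()
    if marker is not None:
        out_sheet["marker"] = marker.reindex(out_sheet["sample_id"]).to_numpy()
    out_sheet.to_csv(paths["samples"], sep="\t", index=False, float_format="%.6g")
    if truth is not None:
        paths["truth"] = outdir / "truth.tsv"
        truth.to_tsv(paths["truth"])
    return paths
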