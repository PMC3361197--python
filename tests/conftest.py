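import numpy as np
import pandas as pd
import pytest

from maldivote.preprocessing import FeatureTable


def make_table(
    X: np.ndarray,
    labels: list[str] | None = None,
    mz: np.ndarray | None = None,
    sample_ids: list[str] | None = None,
) -> FeatureTable:
    """Build a FeatureTable straight from a matrix (rows = samples)."""
    n, m = X.shape
    if mz is None:
        mz = 2000.0 + 50.0 * np.arange(m)
    ids = [f"{v:.1f}" for v in mz]
    samples = sample_ids or [f"s{i:03d}" for i in range(n)]
    table = pd.DataFrame(X, index=samples, columns=ids)
    lab = None if labels is None else pd.Series(labels, index=samples)
    return FeatureTable(
        intensities=table,
        mz=pd.Series(np.asarray(mz, dtype=float), index=ids),
        labels=lab,
    )


def gaussian_cohort_table(
    rng: np.random.Generator,
    n_case: int,
    n_control: int,
    n_signals: int,
    effects: dict[int, float] | None = None,
) -> FeatureTable:
    """Gaussian log-intensity table with optional planted shifts (in SDs)."""
    n = n_case + n_control
    X = rng.normal(10.0, 1.0, size=(n, n_signals))
    if effects:
        for j, d in effects.items():
            X[:n_case, j] += d
    labels = ["PDAC"] * n_case + ["healthy"] * n_control
    return make_table(X, labels)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic replicate cohort shared across tests (seed 7)."""
    import maldivote as mv

    cfg = mv.CohortConfig(
        n_cases=20, n_controls=20, n_signals=120, n_differential=20,
        n_strong=4, seed=7,
    )
    spectra, sheet, truth = mv.generate_cohort(cfg)
    return cfg, spectra, sheet, truth
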