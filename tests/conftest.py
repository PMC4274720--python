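import dataclasses

import numpy as np
import pytest

from hsqcstocsy import correlation, dataset, synthetic
from hsqcstocsy.bruker_io import HSQCSpectrum, SpectrumGrid


def small_grid(n_f2: int = 12, n_f1: int = 8) -> SpectrumGrid:
    """A tiny grid for unit tests (1H 0..6 ppm, 13C 0..80 ppm)."""
    return SpectrumGrid(
        ppm_f2=6.0 - np.arange(n_f2) * (6.0 / n_f2),
        ppm_f1=80.0 - np.arange(n_f1) * (80.0 / n_f1),
    )


def matrix_from_values(values: np.ndarray, grid: SpectrumGrid | None = None):
    """Wrap a raw n x K array as a full (no exclusion) SpectralMatrix."""
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    if grid is None:
        # factor K into a plausible n_f1 x n_f2
        n_f1 = next(d for d in range(2, k + 1) if k % d == 0)
        grid = small_grid(n_f2=k // n_f1, n_f1=n_f1)
    assert grid.n_f1 * grid.n_f2 == k
    return dataset.SpectralMatrix(
        values=values,
        grid=grid,
        sample_ids=[f"s{i}" for i in range(n)],
        kept_mask=np.ones(k, dtype=bool),
    )


def spectra_from_rows(rows: np.ndarray, grid: SpectrumGrid):
    return [
        HSQCSpectrum(
            grid=grid,
            intensities=row.reshape(grid.n_f1, grid.n_f2),
            sample_id=f"s{i}",
        )
        for i, row in enumerate(rows)
    ]


@dataclasses.dataclass
class Study:
    """A processed synthetic study: model, masked matrix and scaled matrix."""

    model: synthetic.MixtureModel
    grid: SpectrumGrid
    matrix: dataset.SpectralMatrix
    scaled: correlation.ScaledMatrix
    threshold: float


def run_study(jitter_scale: float = 1.0, seed: int = 1, n_samples: int = 50) -> Study:
    model = synthetic.default_model(
        n_samples=n_samples, seed=seed, jitter_scale=jitter_scale
    )
    grid = synthetic.default_grid()
    bundle = synthetic.generate_dataset(model, grid)
    spectra = [dataset.calibrate_to_reference(s) for s in bundle.spectra]
    matrix = dataset.stack(spectra)
    threshold = dataset.suggest_noise_threshold(matrix)
    matrix = dataset.apply_noise_exclusion(matrix, threshold)
    return Study(
        model=model,
        grid=grid,
        matrix=matrix,
        scaled=correlation.autoscale(matrix),
        threshold=threshold,
    )


@pytest.fixture(scope="session")
def default_study() -> Study:
    """The default study conditions: n = 50 urine-like spectra, 1024 x 512 grid."""
    return run_study(jitter_scale=1.0, seed=1)


@pytest.fixture(scope="session")
def stressed_study() -> Study:
    """Same conditions under the 3x chemical-shift jitter stress preset."""
    return run_study(jitter_scale=3.0, seed=1)
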