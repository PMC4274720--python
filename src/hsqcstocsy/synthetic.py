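"""Synthetic multi-sample HSQC datasets with known ground truth.

Real biofluid HSQC series are rarely shareable, so validation runs on
simulated urine-like datasets: a library of metabolites, each a set of
2D Gaussian cross-peaks at fixed chemical shifts, whose per-sample
amplitudes follow independently varying log-normal concentrations.  The
generator reproduces the statistical features the correlation method
relies on (or is threatened by):

* concentrations independent across metabolites, optionally with a
  pathway-like correlation between chosen pairs;
* weak long-range cross-peaks riding on the same concentration vector as
  their parent compound;
* additive white noise;
* small per-sample chemical-shift jitter (pH/ionic-strength variation),
  drawn once per (sample, metabolite) so a metabolite's peaks move
  coherently;
* a constant-amplitude TSP reference peak at (0, 0) ppm so axis
  calibration is exercised.

It does not attempt physically accurate NMR simulation (J-coupling fine
structure, relaxation, phase/baseline artifacts): the correlation method
only sees amplitude co-variation, so Gaussian peak shapes suffice.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .bruker_io import HSQCSpectrum, SpectrumGrid
from .errors import HsqcStocsyError
from .identify import ReferencePeakList

__all__ = [
    "CrossPeak",
    "SyntheticMetabolite",
    "MixtureModel",
    "SyntheticDataset",
    "sample_concentrations",
    "render_spectrum",
    "generate_dataset",
    "default_library",
    "singleton_library",
    "default_protocol",
    "default_model",
    "default_grid",
    "library_to_references",
]

DEFAULT_LINEWIDTH_H = 0.020  # Gaussian sd, ppm
DEFAULT_LINEWIDTH_C = 0.40
DEFAULT_NOISE_SIGMA = 0.005  # vs. relative peak amplitudes in (0, 1]
DEFAULT_JITTER_SD = (0.005, 0.05)  # ppm (1H, 13C)
DEFAULT_LOG_CONC_SD = 0.5
TSP_AMPLITUDE = 0.5
LONG_RANGE_AMPLITUDE = 0.05


@dataclasses.dataclass(frozen=True)
class CrossPeak:
    ppm_h: float
    ppm_c: float
    relative_amplitude: float = 1.0
    linewidth_h: float = DEFAULT_LINEWIDTH_H  # Gaussian sd in ppm
    linewidth_c: float = DEFAULT_LINEWIDTH_C
    is_long_range: bool = False


@dataclasses.dataclass(frozen=True)
class SyntheticMetabolite:
    name: str
    cross_peaks: tuple[CrossPeak, ...]

    def __post_init__(self):
        if not self.cross_peaks:
            raise HsqcStocsyError(f"'{self.name}' needs at least one cross-peak")
        for p in self.cross_peaks:
            if not 0 < p.relative_amplitude <= 1:
                raise HsqcStocsyError(
                    f"'{self.name}': relative amplitude must be in (0, 1]"
                )
            if p.linewidth_h <= 0 or p.linewidth_c <= 0:
                raise HsqcStocsyError(f"'{self.name}': linewidths must be > 0")


@dataclasses.dataclass
class MixtureModel:
    """Ground truth for a dataset: who is present, how much, and how noisy."""

    metabolites: list[SyntheticMetabolite]
    n_samples: int = 50
    log_conc_mean: float = 0.0
    log_conc_sd: float = DEFAULT_LOG_CONC_SD
    concentration_correlation: np.ndarray | None = None  # M x M, default identity
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    shift_jitter_sd: tuple[float, float] = DEFAULT_JITTER_SD
    tsp_amplitude: float = TSP_AMPLITUDE
    seed: int = 0

    def __post_init__(self):
        m = len(self.metabolites)
        if self.concentration_correlation is None:
            self.concentration_correlation = np.eye(m)
        self.concentration_correlation = np.asarray(
            self.concentration_correlation, dtype=float
        )
        corr = self.concentration_correlation
        if corr.shape != (m, m):
            raise HsqcStocsyError("concentration correlation must be M x M")
        if not np.allclose(corr, corr.T):
            raise HsqcStocsyError("concentration correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise HsqcStocsyError("concentration correlation must have unit diagonal")

    def metabolite_index(self, name: str) -> int:
        for i, met in enumerate(self.metabolites):
            if met.name == name:
                return i
        raise KeyError(name)


def sample_concentrations(model: MixtureModel) -> np.ndarray:
    """n x M positive concentrations, log-normal with the given correlation.

    Deterministic for a fixed model seed.  A symmetric PSD factor is used
    instead of Cholesky so degenerate (perfectly correlated) pairs are
    allowed.
    """
    corr = model.concentration_correlation
    w, v = np.linalg.eigh(corr)
    if w.min() < -1e-8:
        raise HsqcStocsyError(
            "concentration correlation matrix is not positive semi-definite"
        )
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng([model.seed, 0])
    z = rng.standard_normal((model.n_samples, len(model.metabolites)))
    log_conc = model.log_conc_mean + model.log_conc_sd * (z @ factor.T)
    return np.exp(log_conc)


def _add_gaussian(intensities, grid: SpectrumGrid, ppm_h, ppm_c, amplitude, sd_h, sd_c):
    """Add a separable 2D Gaussian, evaluated on a +/- 5 sd window only."""
    step_h, step_c = -grid.step_f2, -grid.step_f1  # positive ppm per point
    c2 = (grid.ppm_f2[0] - ppm_h) / step_h
    c1 = (grid.ppm_f1[0] - ppm_c) / step_c
    h2, h1 = 5 * sd_h / step_h, 5 * sd_c / step_c
    lo2, hi2 = max(0, int(np.floor(c2 - h2))), min(grid.n_f2, int(np.ceil(c2 + h2)) + 1)
    lo1, hi1 = max(0, int(np.floor(c1 - h1))), min(grid.n_f1, int(np.ceil(c1 + h1)) + 1)
    if lo2 >= hi2 or lo1 >= hi1:
        return
    g2 = np.exp(-((grid.ppm_f2[lo2:hi2] - ppm_h) ** 2) / (2 * sd_h**2))
    g1 = np.exp(-((grid.ppm_f1[lo1:hi1] - ppm_c) ** 2) / (2 * sd_c**2))
    intensities[lo1:hi1, lo2:hi2] += amplitude * np.outer(g1, g2)


def render_spectrum(
    model: MixtureModel, sample_index: int, grid: SpectrumGrid
) -> HSQCSpectrum:
    """Render one sample's spectrum (peaks + TSP + noise), reproducibly.

    Peak amplitude = concentration x relative amplitude; the Gaussian shape
    has unit maximum so the planted height is the amplitude itself (up to
    grid discretization).  A peak whose nominal centre lies outside the grid
    is dropped with a warning.
    """
    if not 0 <= sample_index < model.n_samples:
        raise HsqcStocsyError(
            f"sample_index {sample_index} outside 0..{model.n_samples - 1}"
        )
    conc = sample_concentrations(model)[sample_index]
    rng = np.random.default_rng([model.seed, 1, sample_index])
    jit_h, jit_c = model.shift_jitter_sd

    intensities = np.zeros((grid.n_f1, grid.n_f2))
    # one coherent shift per metabolite per sample; TSP gets the last draw
    jitters = rng.normal(0.0, 1.0, (len(model.metabolites) + 1, 2))
    for m, met in enumerate(model.metabolites):
        dh, dc = jitters[m, 0] * jit_h, jitters[m, 1] * jit_c
        for peak in met.cross_peaks:
            if not grid.contains(peak.ppm_h, peak.ppm_c):
                warnings.warn(
                    f"peak {peak.ppm_h}/{peak.ppm_c} of '{met.name}' lies outside "
                    "the grid; dropped",
                    stacklevel=2,
                )
                continue
            _add_gaussian(
                intensities,
                grid,
                peak.ppm_h + dh,
                peak.ppm_c + dc,
                conc[m] * peak.relative_amplitude,
                peak.linewidth_h,
                peak.linewidth_c,
            )
    dh, dc = jitters[-1, 0] * jit_h, jitters[-1, 1] * jit_c
    _add_gaussian(
        intensities, grid, dh, dc, model.tsp_amplitude,
        DEFAULT_LINEWIDTH_H, DEFAULT_LINEWIDTH_C,
    )
    if model.noise_sigma > 0:
        intensities += rng.normal(0.0, model.noise_sigma, intensities.shape)
    return HSQCSpectrum(
        grid=grid, intensities=intensities, sample_id=f"sample_{sample_index:03d}"
    )


@dataclasses.dataclass
class SyntheticDataset:
    spectra: list[HSQCSpectrum]
    ground_truth: pd.DataFrame  # metabolite, ppm_h, ppm_c, relative_amplitude, is_long_range
    concentrations: pd.DataFrame  # samples x metabolites
    model: MixtureModel
    grid: SpectrumGrid


def generate_dataset(model: MixtureModel, grid: SpectrumGrid) -> SyntheticDataset:
    """Render all samples and tabulate machine-readable ground truth."""
    if model.n_samples < 2:
        raise HsqcStocsyError("need n >= 2 samples")
    spectra = [render_spectrum(model, i, grid) for i in range(model.n_samples)]
    truth = pd.DataFrame(
        [
            {
                "metabolite": met.name,
                "ppm_h": p.ppm_h,
                "ppm_c": p.ppm_c,
                "relative_amplitude": p.relative_amplitude,
                "is_long_range": p.is_long_range,
            }
            for met in model.metabolites
            for p in met.cross_peaks
        ]
    )
    conc = pd.DataFrame(
        sample_concentrations(model),
        index=[s.sample_id for s in spectra],
        columns=[m.name for m in model.metabolites],
    )
    return SyntheticDataset(
        spectra=spectra, ground_truth=truth, concentrations=conc, model=model, grid=grid
    )


# ---------------------------------------------------------------------------
# Default urine-like metabolite library
# ---------------------------------------------------------------------------
#
# 23 multi-peak metabolites. The first peak of each entry is the "selected"
# cross-peak used for correlation, at shifts typical for human urine; the
# companion peaks are synthetic but chemically plausible.  The per-metabolite
# cutoff is the one used by the default identification protocol.  Amplitudes
# are fixed per peak (multiplet intensities differ), long-range peaks are
# deliberately weak.
_LIBRARY: list[tuple[str, float, list[tuple]]] = [
    # (name, cutoff, [(ppm_h, ppm_c, amplitude, long_range?), ...]) — first peak = selected
    ("Trigonelline", 0.9, [
        (9.12, 148.4, 1.0), (8.84, 147.5, 0.85), (8.08, 130.2, 0.8),
        (8.06, 126.2, 0.75), (4.43, 57.7, 0.9)]),
    ("Hippuric acid", 0.9, [
        (7.82, 129.6, 1.0), (7.64, 134.4, 0.5), (7.55, 131.2, 0.95),
        (3.97, 46.4, 0.85)]),
    ("Indoxyl sulphate", 0.8, [
        (7.69, 119.9, 1.0), (7.50, 115.6, 0.9), (7.36, 130.1, 0.6),
        (7.28, 124.5, 0.85), (7.19, 121.9, 0.8)]),
    ("Phenylacetylglutamine", 0.8, [
        (7.41, 131.5, 1.0), (7.35, 128.6, 0.9), (7.29, 126.0, 0.45),
        (4.18, 55.5, 0.5), (3.67, 45.0, 0.85), (2.48, 34.8, 0.55),
        (2.27, 33.9, 0.6), (1.97, 28.2, 0.6),
        (2.27, 30.4, LONG_RANGE_AMPLITUDE, True)]),
    ("trans-Aconitic acid", 0.74, [
        (6.58, 133.5, 1.0), (3.47, 35.5, 0.9)]),
    ("Levoglucosan", 0.88, [
        (5.45, 104.0, 1.0), (4.60, 75.0, 0.7), (4.37, 71.0, 0.65),
        (4.10, 73.5, 0.8), (3.95, 69.5, 0.75), (3.66, 68.9, 0.6),
        (3.53, 64.5, 0.85)]),
    ("Carnitine", 0.7, [
        (4.56, 66.8, 1.0), (3.42, 72.1, 0.7), (3.20, 57.2, 0.95),
        (2.44, 45.5, 0.8)]),
    ("Creatine", 0.9, [
        (3.92, 56.5, 1.0), (3.03, 39.7, 0.95)]),
    ("Mannitol", 0.9, [
        (3.80, 72.0, 1.0), (3.87, 66.3, 0.8), (3.76, 76.3, 0.75),
        (3.70, 64.2, 0.85)]),
    ("Erythritol", 0.86, [
        (3.69, 74.9, 1.0), (3.60, 65.9, 0.8), (3.82, 63.0, 0.75)]),
    ("Galactitol", 0.65, [
        (3.66, 72.6, 1.0), (3.46, 66.5, 0.85), (3.99, 71.2, 0.7)]),
    ("Taurine", 0.9, [
        (3.44, 38.0, 1.0), (3.25, 49.8, 0.95)]),
    ("4-Hydroxyphenylacetic acid", 0.9, [
        (3.44, 46.1, 1.0), (7.16, 132.8, 0.9), (6.86, 117.7, 0.85)]),
    ("Betaine", 0.8, [
        (3.26, 55.8, 1.0), (3.89, 68.0, 0.35)]),
    ("Ethanolamine", 0.85, [
        (3.14, 44.2, 1.0), (3.77, 60.5, 0.9)]),
    ("Isocitric acid", 0.84, [
        (2.98, 51.6, 1.0), (2.63, 40.1, 0.8), (4.01, 76.8, 0.7),
        (2.39, 44.0, 0.75)]),
    ("Citric acid", 0.89, [
        (2.54, 48.1, 1.0), (2.70, 48.3, 0.95)]),
    ("Glutamine", 0.8, [
        (2.14, 29.0, 1.0), (2.45, 33.3, 0.9), (3.78, 57.3, 0.7)]),
    ("Spermine", 0.9, [
        (1.81, 25.4, 1.0), (3.11, 49.4, 0.8), (3.01, 45.9, 0.75),
        (2.10, 26.5, 0.85), (1.77, 31.8, 0.7)]),
    ("Lysine", 0.7, [
        (1.70, 29.0, 1.0), (1.90, 32.9, 0.9), (1.47, 24.6, 0.85),
        (1.43, 20.4, 0.5), (3.02, 42.0, 0.8), (3.69, 57.0, 0.75)]),
    ("Adipic acid", 0.8, [
        (1.54, 28.3, 1.0), (2.20, 39.9, 0.95)]),
    ("3-Hydroxyisovaleric acid", 0.8, [
        (1.26, 30.6, 1.0), (2.55, 52.1, 0.4)]),
    ("3-Aminoisobutanoic acid", 0.8, [
        (1.20, 17.6, 1.0), (2.61, 42.5, 0.7), (3.08, 46.8, 0.8),
        (3.35, 48.9, 0.75)]),
]

# single-cross-peak urine metabolites: no correlation plot of their own, but
# rendered into the mixture and injected into merged spectra as singletons
_SINGLETONS: list[tuple[str, float, float]] = [
    ("Glycine", 3.56, 44.2),
    ("Methanol", 3.36, 51.6),
    ("1-Methyluric acid", 3.28, 30.3),
    ("TMAO", 3.26, 62.0),
    ("Dimethylamine", 2.72, 37.4),
    ("Succinic acid", 2.40, 36.7),
    ("Acetic acid", 1.92, 26.1),
]

# the pathway-emulation pair: biologically related TCA-cycle acids whose
# log-concentrations co-vary with this correlation in the default model
CORRELATED_PAIR = ("Citric acid", "trans-Aconitic acid")
PAIR_CORRELATION = 0.7


def _build(name: str, peaks: list[tuple]) -> SyntheticMetabolite:
    return SyntheticMetabolite(
        name=name,
        cross_peaks=tuple(
            CrossPeak(
                ppm_h=p[0], ppm_c=p[1], relative_amplitude=p[2],
                is_long_range=bool(p[3]) if len(p) > 3 else False,
            )
            for p in peaks
        ),
    )


def default_library() -> list[SyntheticMetabolite]:
    """The 23 multi-peak metabolites of the default urine-like mixture."""
    return [_build(name, peaks) for name, _, peaks in _LIBRARY]


def singleton_library() -> list[SyntheticMetabolite]:
    """The 7 single-cross-peak metabolites."""
    return [
        _build(name, [(h, c, 1.0)]) for name, h, c in _SINGLETONS
    ]


def default_protocol() -> pd.DataFrame:
    """Selected peak and cutoff for each multi-peak metabolite."""
    return pd.DataFrame(
        {
            "metabolite": [name for name, _, _ in _LIBRARY],
            "selected_h_ppm": [peaks[0][0] for _, _, peaks in _LIBRARY],
            "selected_c_ppm": [peaks[0][1] for _, _, peaks in _LIBRARY],
            "cutoff": [cutoff for _, cutoff, _ in _LIBRARY],
        }
    )


def default_grid() -> SpectrumGrid:
    return SpectrumGrid.from_acquisition()


def default_model(
    n_samples: int = 50,
    seed: int = 0,
    jitter_scale: float = 1.0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
    include_singletons: bool = True,
) -> MixtureModel:
    """The default urine-like study conditions: 30 metabolites, n = 50.

    ``jitter_scale=3`` is the stress preset demonstrating the
    low-correlation failure mode of large chemical-shift variation.
    """
    metabolites = default_library() + (singleton_library() if include_singletons else [])
    m = len(metabolites)
    corr = np.eye(m)
    names = [met.name for met in metabolites]
    i, j = names.index(CORRELATED_PAIR[0]), names.index(CORRELATED_PAIR[1])
    corr[i, j] = corr[j, i] = PAIR_CORRELATION
    jh, jc = DEFAULT_JITTER_SD
    return MixtureModel(
        metabolites=metabolites,
        n_samples=n_samples,
        concentration_correlation=corr,
        noise_sigma=noise_sigma,
        shift_jitter_sd=(jh * jitter_scale, jc * jitter_scale),
        seed=seed,
    )


def library_to_references(
    metabolites: list[SyntheticMetabolite], include_long_range: bool = True
) -> list[ReferencePeakList]:
    """Ground-truth peak lists in the reference-matching format."""
    return [
        ReferencePeakList(
            metabolite=met.name,
            peaks=tuple(
                (p.ppm_h, p.ppm_c)
                for p in met.cross_peaks
                if include_long_range or not p.is_long_range
            ),
            source="synthetic ground truth",
        )
        for met in metabolites
    ]
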