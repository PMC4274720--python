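"""Assembling spectra into the flattened data matrix X.

Each spectrum is unrolled into a row vector (f1-major: flat index
``i1 * n_f2 + i2``), the rows are stacked into an ``n x K`` matrix, and
columns where *no* spectrum rises above a noise threshold are dropped.
Correlation downstream operates on the kept columns only; excluded
columns are re-introduced as zeros when plots are reconstructed on the
grid.
"""

from __future__ import annotations

import dataclasses
import os
import warnings
from typing import Sequence

import h5py
import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation

from .bruker_io import HSQCSpectrum, SpectrumGrid
from .errors import GridMismatchError, HsqcStocsyError, NoSignalError

__all__ = [
    "SpectralMatrix",
    "calibrate_to_reference",
    "normalize_total_intensity",
    "stack",
    "suggest_noise_threshold",
    "apply_noise_exclusion",
    "save_matrix",
    "load_matrix",
]

NORMALIZATION_CONSTANT = 1e6


@dataclasses.dataclass
class SpectralMatrix:
    """The noise-masked ``n x K_kept`` data matrix with coordinate bookkeeping.

    ``kept_mask`` is a boolean vector over all ``K_total = n_f1 * n_f2``
    flattened grid points; ``values[:, j]`` corresponds to the j-th *kept*
    point, in flat-index order.
    """

    values: np.ndarray
    grid: SpectrumGrid
    sample_ids: list[str]
    kept_mask: np.ndarray
    noise_threshold: float | None = None

    def __post_init__(self):
        # C-contiguous so reductions are bit-reproducible across save/load
        self.values = np.ascontiguousarray(self.values, dtype=float)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)
        if self.kept_mask.size != self.grid.n_f1 * self.grid.n_f2:
            raise HsqcStocsyError("kept_mask length must equal n_f1 * n_f2")
        if self.values.shape != (len(self.sample_ids), int(self.kept_mask.sum())):
            raise HsqcStocsyError(
                "values must be n_samples x K_kept "
                f"(got {self.values.shape}, expected "
                f"{(len(self.sample_ids), int(self.kept_mask.sum()))})"
            )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k_kept(self) -> int:
        return self.values.shape[1]

    @property
    def k_total(self) -> int:
        return self.kept_mask.size

    @property
    def kept_indices(self) -> np.ndarray:
        """Flat grid indices of the kept columns, in column order."""
        return np.flatnonzero(self.kept_mask)

    @property
    def coordinate_map(self) -> pd.DataFrame:
        """One row per kept column: grid indices and ppm coordinates."""
        flat = self.kept_indices
        i1, i2 = np.divmod(flat, self.grid.n_f2)
        return pd.DataFrame(
            {
                "column": np.arange(flat.size),
                "f1_index": i1,
                "f2_index": i2,
                "ppm_f1": self.grid.ppm_f1[i1],
                "ppm_f2": self.grid.ppm_f2[i2],
            }
        )

    def to_full_vector(self, kept_values: np.ndarray) -> np.ndarray:
        """Re-introduce zeros at excluded columns (length K_total)."""
        full = np.zeros(self.k_total, dtype=float)
        full[self.kept_mask] = kept_values
        return full

    def unstack_row(self, i: int) -> np.ndarray:
        """Row i as an ``n_f1 x n_f2`` matrix, zeros at excluded points."""
        return self.to_full_vector(self.values[i]).reshape(
            self.grid.n_f1, self.grid.n_f2
        )


# ---------------------------------------------------------------------------
# Per-spectrum preparation
# ---------------------------------------------------------------------------


def _integer_shift(matrix: np.ndarray, d1: int, d2: int) -> np.ndarray:
    """Translate a matrix by whole indices, zero-filling vacated edges."""
    out = np.zeros_like(matrix)
    n1, n2 = matrix.shape
    s1_dst = slice(max(d1, 0), n1 + min(d1, 0))
    s1_src = slice(max(-d1, 0), n1 + min(-d1, 0))
    s2_dst = slice(max(d2, 0), n2 + min(d2, 0))
    s2_src = slice(max(-d2, 0), n2 + min(-d2, 0))
    out[s1_dst, s2_dst] = matrix[s1_src, s2_src]
    return out


def calibrate_to_reference(
    spectrum: HSQCSpectrum,
    search_window: tuple[tuple[float, float], tuple[float, float]] | None = None,
    reference_ppm: tuple[float, float] = (0.0, 0.0),
) -> HSQCSpectrum:
    """Re-reference a spectrum to a reference peak (TSP by default).

    The maximum-intensity point inside ``search_window`` (ppm ranges
    ``((h_lo, h_hi), (c_lo, c_hi))``, default reference +/- 0.25 ppm 1H and
    +/- 5 ppm 13C) is moved onto the grid point nearest ``reference_ppm`` by
    translating the intensity matrix a whole number of grid points in each
    dimension (no interpolation: values are repositioned, never altered;
    edge rows/columns vacated by the shift are zero-filled).  The grid
    itself stays fixed, so calibrated spectra remain stackable on one
    common grid.  If the window maximum does not rise above the spectrum's
    noise floor estimate the spectrum is returned unshifted, flagged
    ``"uncalibrated"``.
    """
    ref_h, ref_c = reference_ppm
    if search_window is None:
        search_window = ((ref_h - 0.25, ref_h + 0.25), (ref_c - 5.0, ref_c + 5.0))
    (h_lo, h_hi), (c_lo, c_hi) = search_window
    grid = spectrum.grid
    in2 = np.flatnonzero((grid.ppm_f2 >= h_lo) & (grid.ppm_f2 <= h_hi))
    in1 = np.flatnonzero((grid.ppm_f1 >= c_lo) & (grid.ppm_f1 <= c_hi))
    if in2.size == 0 or in1.size == 0:
        raise HsqcStocsyError("calibration search window lies outside the grid")

    sub = spectrum.intensities[np.ix_(in1, in2)]
    j1, j2 = np.unravel_index(np.argmax(sub), sub.shape)
    i1, i2 = int(in1[j1]), int(in2[j2])
    peak = spectrum.intensities[i1, i2]

    noise_floor = 5.0 * median_abs_deviation(
        spectrum.intensities, axis=None, scale="normal"
    )
    if peak < noise_floor:
        warnings.warn(
            f"calibration window maximum ({peak:.3g}) below noise floor "
            f"({noise_floor:.3g}); spectrum '{spectrum.sample_id}' left uncalibrated",
            stacklevel=2,
        )
        out = dataclasses.replace(spectrum, metadata=dict(spectrum.metadata))
        out.metadata["calibration"] = "uncalibrated"
        return out

    r1, r2 = grid.index_of(ref_h, ref_c)
    d1, d2 = r1 - i1, r2 - i2
    out = dataclasses.replace(
        spectrum,
        intensities=_integer_shift(spectrum.intensities, d1, d2)
        if (d1, d2) != (0, 0)
        else spectrum.intensities,
        metadata=dict(spectrum.metadata),
    )
    out.metadata["calibration"] = "calibrated"
    out.metadata["calibration_shift_points"] = (int(d1), int(d2))
    return out


def normalize_total_intensity(spectrum: HSQCSpectrum) -> HSQCSpectrum:
    """Scale so the sum of positive intensities equals 1e6 (optional step)."""
    positive_sum = spectrum.intensities[spectrum.intensities > 0].sum()
    if positive_sum <= 0:
        raise HsqcStocsyError(
            f"spectrum '{spectrum.sample_id}' has no positive intensity to normalize"
        )
    out = dataclasses.replace(
        spectrum,
        intensities=spectrum.intensities * (NORMALIZATION_CONSTANT / positive_sum),
        metadata=dict(spectrum.metadata),
    )
    out.metadata["normalized"] = True
    return out


# ---------------------------------------------------------------------------
# Stacking and noise exclusion
# ---------------------------------------------------------------------------


def stack(spectra: Sequence[HSQCSpectrum]) -> SpectralMatrix:
    """Flatten each spectrum (f1-major) and stack into an n x K matrix.

    All spectra must share one grid exactly; there is no silent resampling.
    """
    spectra = list(spectra)
    if len(spectra) < 2:
        raise HsqcStocsyError(
            "need at least 2 spectra (correlation is undefined for n < 2)"
        )
    grid = spectra[0].grid
    for s in spectra[1:]:
        if s.grid != grid:
            for name in ("ppm_f2", "ppm_f1"):
                a, b = getattr(grid, name), getattr(s.grid, name)
                if a.size != b.size:
                    raise GridMismatchError(
                        f"'{s.sample_id}': {name} has {b.size} points, expected {a.size}"
                    )
                diff = np.flatnonzero(a != b)
                if diff.size:
                    j = diff[0]
                    raise GridMismatchError(
                        f"'{s.sample_id}': {name}[{j}] = {b[j]!r}, expected {a[j]!r}"
                    )
            raise GridMismatchError(f"'{s.sample_id}': grid differs")  # pragma: no cover
    values = np.stack([s.intensities.ravel(order="C") for s in spectra])
    return SpectralMatrix(
        values=values,
        grid=grid,
        sample_ids=[s.sample_id for s in spectra],
        kept_mask=np.ones(grid.n_f1 * grid.n_f2, dtype=bool),
    )


def suggest_noise_threshold(matrix: SpectralMatrix, multiplier: float = 5.0) -> float:
    """Advisory threshold: ``multiplier`` x (normal-consistent) MAD of all values.

    The MAD is a robust noise-scale estimate because signal occupies a tiny
    fraction of the grid.  For degenerate (near-constant) data the MAD, and
    hence the suggestion, is 0 — set a threshold manually in that case.
    """
    if matrix.values.size == 0:
        raise HsqcStocsyError("cannot estimate noise of an empty matrix")
    mad = float(median_abs_deviation(matrix.values, axis=None, scale="normal"))
    threshold = multiplier * mad
    if threshold == 0:
        warnings.warn(
            "MAD-based noise estimate is 0 (near-constant data); "
            "choose a threshold manually",
            stacklevel=2,
        )
    return threshold


def apply_noise_exclusion(
    matrix: SpectralMatrix, threshold: float, signed: bool = False
) -> SpectralMatrix:
    """Drop columns where every spectrum stays below ``threshold``.

    A column is kept iff at least one of the n values has magnitude >=
    threshold (``signed=True`` compares raw values instead, for data known
    to be all-positive).  Composes with earlier exclusions: re-applying a
    higher threshold only removes further columns.
    """
    if threshold < 0:
        raise HsqcStocsyError("threshold must be >= 0")
    compared = matrix.values if signed else np.abs(matrix.values)
    keep = (compared >= threshold).any(axis=0)
    if not keep.any():
        raise NoSignalError(
            f"no signal columns remain at threshold {threshold}"
        )
    kept_mask = matrix.kept_mask.copy()
    kept_mask[matrix.kept_indices[~keep]] = False
    return SpectralMatrix(
        values=matrix.values[:, keep],
        grid=matrix.grid,
        sample_ids=list(matrix.sample_ids),
        kept_mask=kept_mask,
        noise_threshold=float(threshold),
    )


# ---------------------------------------------------------------------------
# Persistence (used by the stage-wise CLI)
# ---------------------------------------------------------------------------


def save_matrix(matrix: SpectralMatrix, path: os.PathLike | str) -> None:
    with h5py.File(path, "w") as fh:
        kw = dict(track_times=False)
        fh.create_dataset("values", data=matrix.values, **kw)
        fh.create_dataset("kept_mask", data=matrix.kept_mask, **kw)
        fh.create_dataset("ppm_f1", data=matrix.grid.ppm_f1, **kw)
        fh.create_dataset("ppm_f2", data=matrix.grid.ppm_f2, **kw)
        fh.create_dataset(
            "sample_ids",
            data=np.array(matrix.sample_ids, dtype=object),
            dtype=h5py.string_dtype(),
            **kw,
        )
        if matrix.noise_threshold is not None:
            fh.attrs["noise_threshold"] = matrix.noise_threshold


def load_matrix(path: os.PathLike | str) -> SpectralMatrix:
    with h5py.File(path, "r") as fh:
        grid = SpectrumGrid(ppm_f2=fh["ppm_f2"][()], ppm_f1=fh["ppm_f1"][()])
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample_ids"][()]]
        return SpectralMatrix(
            values=fh["values"][()],
            grid=grid,
            sample_ids=ids,
            kept_mask=fh["kept_mask"][()],
            noise_threshold=float(fh.attrs["noise_threshold"])
            if "noise_threshold" in fh.attrs
            else None,
        )
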