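"""The statistical core: autoscaling, single-peak correlation, cutoffs, merging.

With the data matrix X autoscaled column-wise (mean 0, standard deviation 1
with the n-1 denominator), the inner product ``(1/(n-1)) v_peak' X`` is
exactly the vector of Pearson correlation coefficients between the selected
peak's intensity profile and every other grid point's profile across the
sample series.  Grid points whose profiles co-vary perfectly belong, with
overwhelming probability, to the same compound — so thresholding the
coefficient field at a high cutoff yields a "sub-spectrum" resembling the
pure compound.

``full_correlation_matrix`` computes the complete K x K correlation matrix
``C = (1/(n-1)) X'X``; it exists as the small-scale oracle against which the
per-peak route is verified, and is guarded by a size limit since K is
typically far too large for the square matrix in routine use.
"""

from __future__ import annotations

import dataclasses
import os

import h5py
import numpy as np
import pandas as pd

from .bruker_io import HSQCSpectrum, SpectrumGrid
from .dataset import SpectralMatrix
from .errors import GridMismatchError, HsqcStocsyError, ZeroVarianceError

__all__ = [
    "ScaledMatrix",
    "PeakSelection",
    "CorrelationPlot",
    "autoscale",
    "correlate_peak",
    "full_correlation_matrix",
    "apply_cutoff",
    "merge_plots",
    "singleton_plot",
    "MergedPlot",
    "save_plot",
    "load_plot",
]

CLIP_TOLERANCE = 1e-9
DEFAULT_K_LIMIT = 5000


@dataclasses.dataclass(frozen=True)
class PeakSelection:
    """A user-requested peak coordinate resolved onto a kept grid column."""

    requested_ppm: tuple[float, float]  # (1H, 13C)
    resolved_column: int  # index into the kept columns
    resolved_ppm: tuple[float, float]


@dataclasses.dataclass
class ScaledMatrix:
    """Autoscaled view of a :class:`SpectralMatrix` plus the scaling tables."""

    values: np.ndarray
    means: np.ndarray
    stds: np.ndarray
    zero_variance: np.ndarray
    source: SpectralMatrix

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class CorrelationPlot:
    """A correlation-coefficient field over the full grid.

    ``coefficients`` is zero at noise-excluded points and, once a cutoff is
    applied, at sub-cutoff points; ``support`` distinguishes genuinely
    surviving points from structural zeros.
    """

    coefficients: np.ndarray
    support: np.ndarray
    source: PeakSelection
    grid: SpectrumGrid
    cutoff: float | None = None
    label: str = ""

    def to_spectrum(self, sample_id: str | None = None) -> HSQCSpectrum:
        return HSQCSpectrum(
            grid=self.grid,
            intensities=self.coefficients,
            sample_id=sample_id if sample_id is not None else (self.label or "plot"),
        )


def autoscale(matrix: SpectralMatrix) -> ScaledMatrix:
    """Mean-center each kept column and scale to unit standard deviation.

    Standard deviations use the n-1 denominator.  Zero-variance columns are
    set to all-zeros and flagged rather than producing NaNs.
    """
    if matrix.n < 2:
        raise HsqcStocsyError("autoscaling requires n >= 2 spectra")
    means = matrix.values.mean(axis=0)
    stds = matrix.values.std(axis=0, ddof=1)
    zero_variance = stds == 0
    safe = np.where(zero_variance, 1.0, stds)
    scaled = (matrix.values - means) / safe
    scaled[:, zero_variance] = 0.0
    return ScaledMatrix(
        values=scaled,
        means=means,
        stds=stds,
        zero_variance=zero_variance,
        source=matrix,
    )


def _check_range(values: np.ndarray) -> np.ndarray:
    excess = np.abs(values).max(initial=0.0) - 1.0
    if excess > CLIP_TOLERANCE:
        raise HsqcStocsyError(
            f"correlation coefficient out of range by {excess:.3g}; "
            "this indicates a scaling bug upstream"
        )
    return np.clip(values, -1.0, 1.0)


def correlate_peak(scaled: ScaledMatrix, selection: PeakSelection) -> CorrelationPlot:
    """Correlation of every kept grid point with the selected peak column.

    Computes ``(1/(n-1)) v' X`` on the autoscaled matrix, re-introduces
    zeros at noise-excluded points and reshapes onto the grid.  Coefficients
    are clipped to [-1, 1] only within a 1e-9 floating-point tolerance;
    larger excursions raise.
    """
    col = selection.resolved_column
    if scaled.zero_variance[col]:
        raise ZeroVarianceError(
            f"selected peak at {selection.resolved_ppm} has no variance"
        )
    v = scaled.values[:, col]
    coeffs = _check_range(v @ scaled.values / (scaled.n - 1))
    coeffs[scaled.zero_variance] = 0.0

    src = scaled.source
    field = src.to_full_vector(coeffs).reshape(src.grid.n_f1, src.grid.n_f2)
    support = np.zeros(src.k_total, dtype=bool)
    support[src.kept_indices[~scaled.zero_variance]] = True
    return CorrelationPlot(
        coefficients=field,
        support=support.reshape(src.grid.n_f1, src.grid.n_f2),
        source=selection,
        grid=src.grid,
    )


def full_correlation_matrix(
    scaled: ScaledMatrix, k_limit: int = DEFAULT_K_LIMIT
) -> np.ndarray:
    """The complete correlation matrix ``C = (1/(n-1)) X'X`` (small K only).

    Refuses above ``k_limit`` columns — use :func:`correlate_peak`, which
    computes a single row of C without materializing the square matrix.
    """
    k = scaled.values.shape[1]
    if k > k_limit:
        raise HsqcStocsyError(
            f"K_kept = {k} exceeds the limit {k_limit} for the full correlation "
            "matrix; use correlate_peak for single-peak correlation instead"
        )
    c = scaled.values.T @ scaled.values / (scaled.n - 1)
    c[scaled.zero_variance, :] = 0.0
    c[:, scaled.zero_variance] = 0.0
    return _check_range(c)


def apply_cutoff(plot: CorrelationPlot, cutoff: float) -> CorrelationPlot:
    """Keep only coefficients strictly greater than ``cutoff``; zero the rest.

    Idempotent, and successive cutoffs compose to the maximum of the two.
    """
    if not -1.0 <= cutoff <= 1.0:
        raise HsqcStocsyError(f"cutoff must lie in [-1, 1], got {cutoff}")
    support = plot.support & (plot.coefficients > cutoff)
    effective = cutoff if plot.cutoff is None else max(plot.cutoff, cutoff)
    return CorrelationPlot(
        coefficients=np.where(support, plot.coefficients, 0.0),
        support=support,
        source=plot.source,
        grid=plot.grid,
        cutoff=float(effective),
        label=plot.label,
    )


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class MergedPlot:
    """A constructed spectrum: pointwise maximum over cutoff plots.

    ``provenance`` has one row per (surviving grid point, contributing
    plot) pair, so overlapping contributions remain attributable.
    """

    spectrum: HSQCSpectrum
    provenance: pd.DataFrame


def singleton_plot(
    grid: SpectrumGrid, label: str, ppm_h: float, ppm_c: float
) -> CorrelationPlot:
    """Unit-value single-point plot for a metabolite with one cross-peak.

    Such metabolites produce no informative correlation plot of their own
    (nothing to correlate with), but still belong in a merged, constructed
    spectrum.
    """
    i1, i2 = grid.index_of(ppm_h, ppm_c)
    coeffs = np.zeros((grid.n_f1, grid.n_f2))
    coeffs[i1, i2] = 1.0
    support = coeffs > 0
    resolved = (float(grid.ppm_f2[i2]), float(grid.ppm_f1[i1]))
    return CorrelationPlot(
        coefficients=coeffs,
        support=support,
        source=PeakSelection((ppm_h, ppm_c), -1, resolved),
        grid=grid,
        cutoff=0.0,
        label=label,
    )


def merge_plots(plots: list[CorrelationPlot]) -> MergedPlot:
    """Pointwise maximum of surviving coefficients across cutoff plots."""
    if not plots:
        raise HsqcStocsyError("cannot merge an empty list of plots")
    grid = plots[0].grid
    for p in plots[1:]:
        if p.grid != grid:
            raise GridMismatchError(f"plot '{p.label}' is on a different grid")
    for p in plots:
        if p.cutoff is None:
            raise HsqcStocsyError(
                f"plot '{p.label}' has no cutoff applied; apply_cutoff first"
            )
    stack_coeffs = np.stack([np.where(p.support, p.coefficients, -np.inf) for p in plots])
    merged = stack_coeffs.max(axis=0)
    any_support = np.isfinite(merged)
    merged = np.where(any_support, merged, 0.0)

    rows = []
    for p in plots:
        i1, i2 = np.nonzero(p.support)
        rows.append(
            pd.DataFrame(
                {
                    "f1_index": i1,
                    "f2_index": i2,
                    "ppm_f1": grid.ppm_f1[i1],
                    "ppm_f2": grid.ppm_f2[i2],
                    "coefficient": p.coefficients[i1, i2],
                    "label": p.label,
                }
            )
        )
    provenance = pd.concat(rows, ignore_index=True).sort_values(
        ["f1_index", "f2_index", "label"], kind="stable", ignore_index=True
    )
    return MergedPlot(
        spectrum=HSQCSpectrum(grid=grid, intensities=merged, sample_id="merged"),
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Plot persistence (stage-wise CLI)
# ---------------------------------------------------------------------------


def save_plot(plot: CorrelationPlot, path: os.PathLike | str) -> None:
    with h5py.File(path, "w") as fh:
        kw = dict(track_times=False)
        fh.create_dataset("coefficients", data=plot.coefficients, **kw)
        fh.create_dataset("support", data=plot.support, **kw)
        fh.create_dataset("ppm_f1", data=plot.grid.ppm_f1, **kw)
        fh.create_dataset("ppm_f2", data=plot.grid.ppm_f2, **kw)
        fh.attrs["label"] = plot.label
        fh.attrs["requested_ppm"] = plot.source.requested_ppm
        fh.attrs["resolved_ppm"] = plot.source.resolved_ppm
        fh.attrs["resolved_column"] = plot.source.resolved_column
        if plot.cutoff is not None:
            fh.attrs["cutoff"] = plot.cutoff


def load_plot(path: os.PathLike | str) -> CorrelationPlot:
    with h5py.File(path, "r") as fh:
        grid = SpectrumGrid(ppm_f2=fh["ppm_f2"][()], ppm_f1=fh["ppm_f1"][()])
        return CorrelationPlot(
            coefficients=fh["coefficients"][()],
            support=fh["support"][()],
            source=PeakSelection(
                tuple(fh.attrs["requested_ppm"]),
                int(fh.attrs["resolved_column"]),
                tuple(fh.attrs["resolved_ppm"]),
            ),
            grid=grid,
            cutoff=float(fh.attrs["cutoff"]) if "cutoff" in fh.attrs else None,
            label=str(fh.attrs["label"]),
        )
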