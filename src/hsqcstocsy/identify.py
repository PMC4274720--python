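"""Peak selection, plot peak extraction and reference matching.

A correlation plot is scored against a reference peak list (e.g. shifts
taken from a spectral database) by collapsing surviving grid points into
8-connected clusters, reporting each cluster's best point as one peak, and
greedily assigning plot peaks to reference peaks within a ppm tolerance
box.  The resulting found/expected/extra bookkeeping mirrors how such
plots are judged by eye against a reference spectrum.
"""

from __future__ import annotations

import dataclasses
import os

import numpy as np
import pandas as pd
from scipy import ndimage

from .bruker_io import HSQCSpectrum
from .correlation import CorrelationPlot, PeakSelection
from .dataset import SpectralMatrix
from .errors import AllNoiseError, HsqcStocsyError

__all__ = [
    "ReferencePeakList",
    "RecoveryReport",
    "select_peak",
    "extract_plot_peaks",
    "match_to_reference",
    "load_reference_peak_lists",
    "save_reference_peak_lists",
    "reports_to_frame",
]

DEFAULT_WINDOW = (0.03, 0.5)  # ppm half-widths (1H, 13C)
DEFAULT_TOLERANCES = (0.05, 0.5)  # ppm matching tolerances (1H, 13C)


@dataclasses.dataclass(frozen=True)
class ReferencePeakList:
    """Known cross-peaks of one metabolite: [(1H ppm, 13C ppm), ...]."""

    metabolite: str
    peaks: tuple[tuple[float, float], ...]
    source: str = ""

    def __post_init__(self):
        if not self.peaks:
            raise HsqcStocsyError(f"'{self.metabolite}' has an empty peak list")
        if not np.all(np.isfinite(np.asarray(self.peaks, dtype=float))):
            raise HsqcStocsyError(f"'{self.metabolite}' has non-finite peak positions")


@dataclasses.dataclass(frozen=True)
class RecoveryReport:
    """Found/expected bookkeeping for one metabolite's correlation plot."""

    metabolite: str
    selected_peak: tuple[float, float]
    cutoff: float
    found: int
    expected: int
    extra: int

    def __post_init__(self):
        if not (0 <= self.found <= self.expected) or self.extra < 0:
            raise HsqcStocsyError(
                f"inconsistent recovery counts for '{self.metabolite}'"
            )


def select_peak(
    matrix: SpectralMatrix,
    requested_ppm: tuple[float, float],
    window: tuple[float, float] = DEFAULT_WINDOW,
    spectrum: HSQCSpectrum | None = None,
) -> PeakSelection:
    """Snap a requested (1H, 13C) coordinate to the best nearby kept point.

    Within ``window`` half-widths around the request, the kept grid point
    with the highest mean intensity across samples (or intensity in the
    supplied ``spectrum``) is chosen — the most central data point of a
    cross-peak usually coincides with its local maximum.
    """
    ppm_h, ppm_c = requested_ppm
    if not matrix.grid.contains(ppm_h, ppm_c):
        raise HsqcStocsyError(f"requested peak {requested_ppm} lies outside the grid")
    coords = matrix.coordinate_map
    inside = (
        (np.abs(coords["ppm_f2"].to_numpy() - ppm_h) <= window[0])
        & (np.abs(coords["ppm_f1"].to_numpy() - ppm_c) <= window[1])
    )
    if not inside.any():
        raise AllNoiseError(
            f"selected region around {requested_ppm} is all noise "
            "(no kept grid point in window)"
        )
    candidates = np.flatnonzero(inside)
    if spectrum is None:
        heights = matrix.values[:, candidates].mean(axis=0)
    else:
        i1 = coords["f1_index"].to_numpy()[candidates]
        i2 = coords["f2_index"].to_numpy()[candidates]
        heights = spectrum.intensities[i1, i2]
    best = int(candidates[np.argmax(heights)])
    return PeakSelection(
        requested_ppm=(float(ppm_h), float(ppm_c)),
        resolved_column=best,
        resolved_ppm=(
            float(coords["ppm_f2"].iloc[best]),
            float(coords["ppm_f1"].iloc[best]),
        ),
    )


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def extract_plot_peaks(plot: CorrelationPlot) -> pd.DataFrame:
    """Collapse surviving points into 8-connected clusters, one peak each.

    Neighbouring grid points of a real cross-peak correlate almost as well
    as its centre, so surviving points arrive in clusters; each cluster is
    reported once, at its maximum-coefficient point.  Columns: ``ppm_h``,
    ``ppm_c``, ``coefficient``, sorted by descending coefficient.
    """
    labels, n_clusters = ndimage.label(plot.support, structure=_EIGHT_CONNECTED)
    if n_clusters == 0:
        return pd.DataFrame(columns=["ppm_h", "ppm_c", "coefficient"])
    peaks = ndimage.maximum_position(
        plot.coefficients, labels=labels, index=np.arange(1, n_clusters + 1)
    )
    i1 = np.array([p[0] for p in peaks])
    i2 = np.array([p[1] for p in peaks])
    frame = pd.DataFrame(
        {
            "ppm_h": plot.grid.ppm_f2[i2],
            "ppm_c": plot.grid.ppm_f1[i1],
            "coefficient": plot.coefficients[i1, i2],
        }
    )
    return frame.sort_values("coefficient", ascending=False, ignore_index=True)


def match_to_reference(
    plot_peaks: pd.DataFrame,
    reference: ReferencePeakList,
    tolerances: tuple[float, float] = DEFAULT_TOLERANCES,
    selected_peak: tuple[float, float] = (np.nan, np.nan),
    cutoff: float = np.nan,
) -> RecoveryReport:
    """Greedy nearest-first one-to-one assignment of plot to reference peaks.

    Distance is the Chebyshev metric in tolerance units,
    ``max(|d1H|/tol_h, |d13C|/tol_c)``; only pairs with distance <= 1 are
    assignable.  Ties are broken by higher plot-peak coefficient, then
    lower 1H shift.  Unassigned plot peaks are counted as ``extra`` —
    informative additions (unknown correlates, long-range peaks absent
    from the reference), never folded into ``found``.
    """
    tol_h, tol_c = tolerances
    if tol_h <= 0 or tol_c <= 0:
        raise HsqcStocsyError("matching tolerances must be positive")
    ref = np.asarray(reference.peaks, dtype=float)
    n_plot = len(plot_peaks)

    pairs = []
    for i in range(n_plot):
        ph = plot_peaks["ppm_h"].iloc[i]
        pc = plot_peaks["ppm_c"].iloc[i]
        coeff = plot_peaks["coefficient"].iloc[i]
        d = np.maximum(np.abs(ref[:, 0] - ph) / tol_h, np.abs(ref[:, 1] - pc) / tol_c)
        for j in np.flatnonzero(d <= 1.0):
            pairs.append((float(d[j]), -float(coeff), float(ph), i, int(j)))
    pairs.sort()

    used_plot: set[int] = set()
    used_ref: set[int] = set()
    for _, _, _, i, j in pairs:
        if i in used_plot or j in used_ref:
            continue
        used_plot.add(i)
        used_ref.add(j)

    return RecoveryReport(
        metabolite=reference.metabolite,
        selected_peak=tuple(float(x) for x in selected_peak),
        cutoff=float(cutoff),
        found=len(used_ref),
        expected=len(reference.peaks),
        extra=n_plot - len(used_plot),
    )


# ---------------------------------------------------------------------------
# Delimited-text interchange
# ---------------------------------------------------------------------------


def load_reference_peak_lists(path: os.PathLike | str) -> list[ReferencePeakList]:
    """Read reference lists from CSV columns metabolite, delta_h_ppm, delta_c_ppm."""
    table = pd.read_csv(path)
    out = []
    for name, group in table.groupby("metabolite", sort=False):
        out.append(
            ReferencePeakList(
                metabolite=str(name),
                peaks=tuple(
                    (float(h), float(c))
                    for h, c in zip(group["delta_h_ppm"], group["delta_c_ppm"])
                ),
            )
        )
    return out


def save_reference_peak_lists(
    references: list[ReferencePeakList], path: os.PathLike | str
) -> None:
    rows = [
        {"metabolite": r.metabolite, "delta_h_ppm": h, "delta_c_ppm": c}
        for r in references
        for h, c in r.peaks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def reports_to_frame(reports: list[RecoveryReport]) -> pd.DataFrame:
    """Recovery reports as a table mirroring the usual summary columns."""
    return pd.DataFrame(
        {
            "metabolite": [r.metabolite for r in reports],
            "selected_h_ppm": [r.selected_peak[0] for r in reports],
            "selected_c_ppm": [r.selected_peak[1] for r in reports],
            "cutoff": [r.cutoff for r in reports],
            "found": [r.found for r in reports],
            "expected": [r.expected for r in reports],
            "extra": [r.extra for r in reports],
        }
    )
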