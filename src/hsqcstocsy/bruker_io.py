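"""Spectrum containers and I/O for processed 2D HSQC data.

Two on-disk representations are supported:

* the Bruker processed-data dialect — a ``2rr`` file of 32-bit integers
  (optionally stored as XDIM-tiled submatrices) plus JCAMP-DX style
  ``procs``/``proc2s`` parameter files.  ``procs`` describes the direct
  (F2, 1H) dimension, ``proc2s`` the indirect (F1, 13C) dimension.  The
  keys honoured are SI, SF, OFFSET, SW_p, XDIM, BYTORDP and NC_proc.
* a portable single-file HDF5 container holding a whole dataset of
  spectra on one grid at full float64 precision, so synthetic ground
  truth is never degraded by integer quantization.

ppm axes follow the convention that OFFSET is the chemical shift of the
first (left-edge) point and axes decrease toward high field:
``ppm[i] = OFFSET - i * (SW_p / SF) / SI``.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .errors import (
    CorruptDataError,
    GridMismatchError,
    HsqcStocsyError,
    MissingBrukerFileError,
    MissingParameterError,
)

__all__ = [
    "SpectrumGrid",
    "HSQCSpectrum",
    "read_bruker_processed",
    "write_bruker_processed",
    "read_portable",
    "write_portable",
]

_INT32_MAX = np.iinfo(np.int32).max


@dataclasses.dataclass(frozen=True)
class SpectrumGrid:
    """Shared ppm axes of a 2D spectrum.

    ``ppm_f2`` is the direct (1H) axis of length ``n_f2``; ``ppm_f1`` the
    indirect (13C) axis of length ``n_f1``.  Both axes are strictly
    decreasing (high field last) and uniformly spaced.
    """

    ppm_f2: np.ndarray
    ppm_f1: np.ndarray

    def __post_init__(self):
        for name in ("ppm_f2", "ppm_f1"):
            axis = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, axis)
            if axis.ndim != 1 or axis.size < 2:
                raise HsqcStocsyError(f"{name} must be a 1D axis with >= 2 points")
            steps = np.diff(axis)
            if not np.all(steps < 0):
                raise HsqcStocsyError(f"{name} must be strictly decreasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=0):
                raise HsqcStocsyError(f"{name} must be uniformly spaced")
            axis.setflags(write=False)

    @property
    def n_f2(self) -> int:
        return self.ppm_f2.size

    @property
    def n_f1(self) -> int:
        return self.ppm_f1.size

    @property
    def step_f2(self) -> float:
        """Signed per-point increment of the 1H axis (negative)."""
        return float(self.ppm_f2[1] - self.ppm_f2[0])

    @property
    def step_f1(self) -> float:
        return float(self.ppm_f1[1] - self.ppm_f1[0])

    @classmethod
    def from_acquisition(
        cls,
        n_f2: int = 1024,
        n_f1: int = 512,
        center_f2: float = 4.7,
        sweep_f2: float = 16.0,
        center_f1: float = 75.0,
        sweep_f1: float = 165.0,
    ) -> "SpectrumGrid":
        """Grid from carrier offsets and sweep widths in ppm.

        Defaults reproduce a common urine HSQC processing scheme:
        1024 x 512 points, 16/165 ppm sweeps centred at 4.7/75 ppm.
        """
        left2 = center_f2 + sweep_f2 / 2.0
        left1 = center_f1 + sweep_f1 / 2.0
        return cls(
            ppm_f2=left2 - np.arange(n_f2) * (sweep_f2 / n_f2),
            ppm_f1=left1 - np.arange(n_f1) * (sweep_f1 / n_f1),
        )

    def index_of(self, ppm_h: float, ppm_c: float) -> tuple[int, int]:
        """Nearest grid indices (f1, f2) of a (1H, 13C) coordinate."""
        i2 = int(np.argmin(np.abs(self.ppm_f2 - ppm_h)))
        i1 = int(np.argmin(np.abs(self.ppm_f1 - ppm_c)))
        return i1, i2

    def contains(self, ppm_h: float, ppm_c: float) -> bool:
        return (
            self.ppm_f2[-1] <= ppm_h <= self.ppm_f2[0]
            and self.ppm_f1[-1] <= ppm_c <= self.ppm_f1[0]
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectrumGrid):
            return NotImplemented
        return np.array_equal(self.ppm_f2, other.ppm_f2) and np.array_equal(
            self.ppm_f1, other.ppm_f1
        )

    def isclose(self, other: "SpectrumGrid", atol: float = 1e-9) -> bool:
        return (
            self.n_f2 == other.n_f2
            and self.n_f1 == other.n_f1
            and np.allclose(self.ppm_f2, other.ppm_f2, rtol=0, atol=atol)
            and np.allclose(self.ppm_f1, other.ppm_f1, rtol=0, atol=atol)
        )


@dataclasses.dataclass
class HSQCSpectrum:
    """One processed 2D spectrum: an ``n_f1 x n_f2`` intensity matrix on a grid."""

    grid: SpectrumGrid
    intensities: np.ndarray
    sample_id: str = ""
    scale_exponent: int = 0
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        expected = (self.grid.n_f1, self.grid.n_f2)
        if self.intensities.shape != expected:
            raise HsqcStocsyError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"grid {expected} (n_f1 x n_f2)"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise HsqcStocsyError("intensities must be finite")


# ---------------------------------------------------------------------------
# Bruker processed-data dialect
# ---------------------------------------------------------------------------

_REQUIRED_KEYS = ("SI", "SF", "OFFSET", "SW_p", "XDIM", "BYTORDP", "NC_proc")


def _parse_jcampdx(path: Path) -> dict:
    """Parse ``##$KEY= value`` lines of a procs/proc2s file into a dict."""
    params: dict[str, float] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line.startswith("##$"):
            continue
        key, _, value = line[3:].partition("=")
        value = value.strip()
        try:
            params[key.strip()] = float(value)
        except ValueError:
            params[key.strip()] = value
    return params


def _detile(flat: np.ndarray, si1: int, si2: int, xdim1: int, xdim2: int) -> np.ndarray:
    """Reorder XDIM-tiled submatrix storage into a row-major si1 x si2 matrix."""
    if xdim1 == si1 and xdim2 == si2:
        return flat.reshape(si1, si2)
    if si1 % xdim1 or si2 % xdim2:
        raise CorruptDataError(
            f"XDIM ({xdim1} x {xdim2}) does not divide SI ({si1} x {si2})"
        )
    tiles = flat.reshape(si1 // xdim1, si2 // xdim2, xdim1, xdim2)
    return tiles.swapaxes(1, 2).reshape(si1, si2)


def _tile(matrix: np.ndarray, xdim1: int, xdim2: int) -> np.ndarray:
    """Inverse of :func:`_detile`."""
    si1, si2 = matrix.shape
    tiles = matrix.reshape(si1 // xdim1, xdim1, si2 // xdim2, xdim2)
    return tiles.swapaxes(1, 2).reshape(si1 * si2)


def _axis_from_params(params: dict) -> np.ndarray:
    si = int(params["SI"])
    step = (params["SW_p"] / params["SF"]) / si
    return params["OFFSET"] - np.arange(si) * step


def read_bruker_processed(directory_path: os.PathLike | str) -> HSQCSpectrum:
    """Read a processed 2D spectrum (2rr + procs/proc2s) from a directory.

    Accepts both byte orders and both tiled and untiled 2rr layouts.
    Intensities are returned as ``int32 * 2**NC_proc`` in float64.
    """
    directory = Path(directory_path)
    paths = {}
    for name in ("2rr", "procs", "proc2s"):
        paths[name] = directory / name
        if not paths[name].is_file():
            raise MissingBrukerFileError(f"missing '{name}' in {directory}")

    dims = {}
    for name, fname in (("f2", "procs"), ("f1", "proc2s")):
        params = _parse_jcampdx(paths[fname])
        for key in _REQUIRED_KEYS:
            if key not in params:
                raise MissingParameterError(f"'{key}' missing from {paths[fname]}")
        dims[name] = params

    si2, si1 = int(dims["f2"]["SI"]), int(dims["f1"]["SI"])
    byte_order = "<" if int(dims["f2"]["BYTORDP"]) == 0 else ">"
    raw = np.fromfile(paths["2rr"], dtype=np.dtype(byte_order + "i4"))
    if raw.size != si1 * si2:
        raise CorruptDataError(
            f"2rr holds {raw.size} int32 values but procs declare "
            f"SI1 x SI2 = {si1} x {si2} = {si1 * si2}"
        )
    matrix = _detile(raw, si1, si2, int(dims["f1"]["XDIM"]), int(dims["f2"]["XDIM"]))

    nc_proc = int(dims["f2"]["NC_proc"])
    grid = SpectrumGrid(
        ppm_f2=_axis_from_params(dims["f2"]), ppm_f1=_axis_from_params(dims["f1"])
    )
    return HSQCSpectrum(
        grid=grid,
        intensities=matrix.astype(np.float64) * 2.0**nc_proc,
        sample_id=directory.name,
        scale_exponent=nc_proc,
    )


def write_bruker_processed(
    spectrum: HSQCSpectrum,
    directory_path: os.PathLike | str,
    value_scale: float = 1.0,
    sf_f2: float = 600.13,
    sf_f1: float = 150.90,
) -> None:
    """Write a spectrum as little-endian untiled 2rr + minimal procs/proc2s.

    Values are stored as ``round(value * value_scale)`` with NC_proc = 0, so
    a ``value_scale`` of 1e6 preserves six decimal digits of a correlation
    coefficient in [-1, 1].  Spectrometer frequencies are only needed to
    serialize the ppm axes (SW_p is back-computed from the axis step) and
    default to a 600 MHz instrument.
    """
    if value_scale <= 0:
        raise HsqcStocsyError("value_scale must be > 0")
    if not np.all(np.isfinite(spectrum.intensities)):
        raise HsqcStocsyError("cannot write non-finite intensities")
    scaled = np.round(spectrum.intensities * value_scale)
    if np.abs(scaled).max(initial=0) > _INT32_MAX:
        raise HsqcStocsyError(
            "integer overflow at value_scale "
            f"{value_scale}: maximum representable value is "
            f"{_INT32_MAX / value_scale}"
        )

    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    scaled.astype("<i4").tofile(directory / "2rr")

    grid = spectrum.grid
    for fname, axis, sf in (("procs", grid.ppm_f2, sf_f2), ("proc2s", grid.ppm_f1, sf_f1)):
        si = axis.size
        step = float(axis[0] - axis[1])
        lines = [
            "##TITLE= Processed data parameters",
            f"##$SI= {si}",
            f"##$SF= {sf!r}",
            f"##$OFFSET= {float(axis[0])!r}",
            f"##$SW_p= {step * si * sf!r}",
            f"##$XDIM= {si}",
            "##$BYTORDP= 0",
            "##$NC_proc= 0",
            "##END=",
        ]
        (directory / fname).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Portable HDF5 container
# ---------------------------------------------------------------------------


def write_portable(spectra: Sequence[HSQCSpectrum], path: os.PathLike | str) -> None:
    """Write a list of spectra sharing one grid to a single HDF5 file."""
    spectra = list(spectra)
    if not spectra:
        raise HsqcStocsyError("cannot write an empty spectrum list")
    grid = spectra[0].grid
    mismatched = [s.sample_id for s in spectra[1:] if s.grid != grid]
    if mismatched:
        raise GridMismatchError(
            "spectra are not on a common grid: " + ", ".join(mismatched)
        )
    data = np.stack([s.intensities for s in spectra])
    with h5py.File(path, "w") as fh:
        kw = dict(track_times=False)
        fh.create_dataset("intensities", data=data, **kw)
        fh.create_dataset("ppm_f1", data=grid.ppm_f1, **kw)
        fh.create_dataset("ppm_f2", data=grid.ppm_f2, **kw)
        fh.create_dataset(
            "sample_ids",
            data=np.array([s.sample_id for s in spectra], dtype=object),
            dtype=h5py.string_dtype(),
            **kw,
        )
        fh.create_dataset(
            "scale_exponents", data=np.array([s.scale_exponent for s in spectra]), **kw
        )


def read_portable(path: os.PathLike | str) -> list[HSQCSpectrum]:
    """Read back a portable container; order and values are preserved exactly."""
    with h5py.File(path, "r") as fh:
        grid = SpectrumGrid(ppm_f2=fh["ppm_f2"][()], ppm_f1=fh["ppm_f1"][()])
        intensities = fh["intensities"][()]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["sample_ids"][()]]
        exponents = fh["scale_exponents"][()]
    return [
        HSQCSpectrum(
            grid=grid,
            intensities=intensities[i],
            sample_id=ids[i],
            scale_exponent=int(exponents[i]),
        )
        for i in range(intensities.shape[0])
    ]
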