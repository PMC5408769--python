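"""Spectrum container, two-column text I/O and the normalized RMSD metric.

Far-UV CD spectra live on a fixed integer-nanometre wavelength grid
(default 175-240 nm, 66 points) with intensities in mean-residue delta-
epsilon units (M^-1 cm^-1 residue^-1). Generated and observed spectra are
compared by a normalized root-mean-square deviation whose normalizer is a
property of the basis set, making the metric unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .basis import BasisSet

__all__ = ["WavelengthGrid", "Spectrum", "read_spectrum", "write_spectrum",
           "nrmsd", "basis_normalizer"]


@dataclass(frozen=True)
class WavelengthGrid:
    start_nm: int = 175
    end_nm: int = 240
    step_nm: int = 1

    def __post_init__(self) -> None:
        if self.start_nm >= self.end_nm:
            raise ValueError("grid start must precede end")
        if (self.end_nm - self.start_nm) % self.step_nm:
            raise ValueError("grid span not divisible by step")

    @property
    def n_points(self) -> int:
        return (self.end_nm - self.start_nm) // self.step_nm + 1

    def wavelengths(self) -> np.ndarray:
        return np.arange(self.start_nm, self.end_nm + 1, self.step_nm, dtype=float)


@dataclass
class Spectrum:
    grid: WavelengthGrid
    values: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_points,):
            raise ValueError(
                f"spectrum {self.id!r}: {self.values.size} values for a "
                f"{self.grid.n_points}-point grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"spectrum {self.id!r} has non-finite values")


def read_spectrum(path: str | Path, grid: WavelengthGrid | None = None) -> Spectrum:
    """Read a two-column (wavelength nm, intensity) text spectrum.

    Rows may be in any order; '#' starts a comment. Values are linearly
    interpolated onto the grid; a file whose wavelength range does not cover
    the grid is an error naming the uncovered region (request a truncated
    evaluation grid instead).
    """
    grid = grid or WavelengthGrid()
    path = Path(path)
    try:
        data = np.loadtxt(path, comments="#", ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric data in spectrum file {path}: {exc}") from exc
    if data.size == 0 or data.shape[1] < 2:
        raise ValueError(f"spectrum file {path} needs two numeric columns")
    order = np.argsort(data[:, 0])
    wl, val = data[order, 0], data[order, 1]
    lo, hi = wl[0], wl[-1]
    gw = grid.wavelengths()
    if gw[0] < lo or gw[-1] > hi:
        missing = []
        if gw[0] < lo:
            missing.append(f"{gw[0]:g}-{min(lo, gw[-1]):g} nm")
        if gw[-1] > hi:
            missing.append(f"{max(hi, gw[0]):g}-{gw[-1]:g} nm")
        raise ValueError(
            f"spectrum file {path} covers {lo:g}-{hi:g} nm and does not cover "
            f"the requested grid ({', '.join(missing)} missing)")
    return Spectrum(grid=grid, values=np.interp(gw, wl, val), id=path.stem)


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   header_lines: Iterable[str] = ()) -> None:
    """Write a spectrum as two-column text with optional '#' header lines."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for wl, v in zip(spectrum.grid.wavelengths(), spectrum.values):
            fh.write(f"{wl:.1f}\t{v:.6f}\n")


def basis_normalizer(spectra: Iterable[Spectrum]) -> float:
    """Largest per-wavelength absolute difference between any two basis spectra.

    A single scalar over the whole basis: max over wavelengths l and entry
    pairs (i, j) of |CD_i,l - CD_j,l|. Acts as the NRMSD normalizer M.
    """
    mat = np.array([s.values for s in spectra])
    if mat.shape[0] < 2:
        raise ValueError("normalizer needs at least two basis spectra")
    return float(np.max(mat.max(axis=0) - mat.min(axis=0)))


def nrmsd(generated: Spectrum, observed: Spectrum,
          basis: "BasisSet | Iterable[Spectrum] | float") -> float:
    """Normalized RMSD between a generated and an observed spectrum.

    ``sqrt(sum_l (e_l - o_l)^2) / M`` where the sum runs over the common
    wavelength grid and M is the basis normalizer (largest per-wavelength
    spread between basis spectra). ``basis`` may be a BasisSet, an iterable
    of spectra, or a precomputed M. Zero iff the spectra are identical.
    """
    if generated.grid != observed.grid:
        raise ValueError("spectra are on different wavelength grids")
    if isinstance(basis, (int, float)):
        m = float(basis)
    else:
        spectra = getattr(basis, "spectra", None)
        m = basis_normalizer(spectra() if callable(spectra) else basis)
    if m <= 0:
        raise ValueError("degenerate basis: all spectra identical (M = 0)")
    return float(np.sqrt(np.sum((generated.values - observed.values) ** 2)) / m)
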