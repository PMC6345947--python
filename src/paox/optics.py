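"""Hemoglobin optical-property spectra.

Molar extinction coefficients of oxy- and deoxyhemoglobin are the spectral
dictionary for both the forward photoacoustic model and the least-squares
unmixing inversion.  The package bundles a synthetic tabulation modeled on
the standard compiled whole-blood spectra (see the CSV header for
provenance); any table with the same CSV layout can be substituted.

Conventions: wavelengths in nm, extinction in cm^-1 M^-1.  The three
wavelengths used for in vivo oximetry in this package are 690 nm (deoxy-Hb
absorption dominant), ~808 nm (near the isosbestic point, where both species
absorb almost equally) and 950 nm (oxy-Hb dominant).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Union

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, ValidationError

__all__ = [
    "ExtinctionTable",
    "load_extinction_table",
    "default_table",
    "epsilon_at",
    "isosbestic_wavelength",
]

Species = Literal["hb", "hbo2"]

_REQUIRED_COLUMNS = ("wavelength_nm", "eps_hbo2", "eps_hb")


@dataclass(frozen=True)
class ExtinctionTable:
    """Wavelength-indexed molar extinction coefficients for Hb and HbO2.

    Attributes
    ----------
    wavelength_nm:
        Strictly increasing sampling grid (nm).
    eps_hbo2, eps_hb:
        Molar extinction of oxy- and deoxyhemoglobin at each grid point
        (cm^-1 M^-1), strictly positive.
    """

    wavelength_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        o = np.asarray(self.eps_hbo2, dtype=float)
        d = np.asarray(self.eps_hb, dtype=float)
        if wl.ndim != 1 or wl.size < 2:
            raise ValidationError("extinction table needs at least two wavelengths")
        if o.shape != wl.shape or d.shape != wl.shape:
            raise ValidationError("extinction columns must match the wavelength grid")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelengths must be strictly increasing with no duplicates")
        if not (np.all(wl > 0) and np.all(o > 0) and np.all(d > 0)):
            raise ValidationError("wavelengths and extinction values must be strictly positive")
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "eps_hbo2", o)
        object.__setattr__(self, "eps_hb", d)

    @property
    def range_nm(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def __len__(self) -> int:
        return int(self.wavelength_nm.size)


def load_extinction_table(path: Union[str, Path]) -> ExtinctionTable:
    """Read an extinction CSV (columns ``wavelength_nm,eps_hbo2,eps_hb``).

    Lines starting with ``#`` are comments.  Raises :class:`FormatError` on a
    missing column and :class:`ValidationError` on unsorted wavelengths or
    non-positive coefficients.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"extinction CSV missing column(s): {', '.join(missing)}")
    if len(df) < 2:
        raise FormatError("extinction CSV needs at least 2 rows")
    return ExtinctionTable(
        wavelength_nm=df["wavelength_nm"].to_numpy(float),
        eps_hbo2=df["eps_hbo2"].to_numpy(float),
        eps_hb=df["eps_hb"].to_numpy(float),
    )


def default_table() -> ExtinctionTable:
    """The bundled hemoglobin tabulation (650-1000 nm, 2-nm grid)."""
    with resources.as_file(
        resources.files("paox.data").joinpath("hb_extinction_synthetic.csv")
    ) as p:
        return load_extinction_table(p)


def _column(table: ExtinctionTable, species: str) -> np.ndarray:
    if species == "hb":
        return table.eps_hb
    if species == "hbo2":
        return table.eps_hbo2
    raise ValidationError(f"unknown species {species!r}; expected 'hb' or 'hbo2'")


def epsilon_at(
    table: ExtinctionTable,
    wavelength: Union[float, Iterable[float]],
    species: Species,
) -> Union[float, np.ndarray]:
    """Molar extinction at ``wavelength`` (nm), linearly interpolated.

    Exact at grid points; linear between them.  Raises :class:`RangeError`
    outside the tabulated range.
    """
    wl = np.asarray(wavelength, dtype=float)
    lo, hi = table.range_nm
    if np.any(wl < lo) or np.any(wl > hi):
        raise RangeError(
            f"wavelength(s) outside tabulated range [{lo:g}, {hi:g}] nm"
        )
    out = np.interp(wl, table.wavelength_nm, _column(table, species))
    return float(out) if np.ndim(wavelength) == 0 else out


def isosbestic_wavelength(
    table: ExtinctionTable,
    lo: float,
    hi: float,
    step_nm: float = 0.1,
) -> float:
    """Wavelength in ``[lo, hi]`` minimizing ``|eps_hb - eps_hbo2|``.

    The search runs on a dense linearly interpolated grid (``step_nm``
    spacing); ties resolve to the smallest wavelength, so the result is
    deterministic.  If the window excludes the crossing, the boundary with
    the smallest gap is returned.
    """
    table_lo, table_hi = table.range_nm
    if not (table_lo <= lo < hi <= table_hi):
        raise RangeError(
            f"search window [{lo:g}, {hi:g}] must be non-empty and inside "
            f"the tabulated range [{table_lo:g}, {table_hi:g}]"
        )
    n = max(2, int(np.ceil((hi - lo) / step_nm)) + 1)
    grid = np.linspace(lo, hi, n)
    gap = np.abs(
        np.interp(grid, table.wavelength_nm, table.eps_hb)
        - np.interp(grid, table.wavelength_nm, table.eps_hbo2)
    )
    return float(grid[int(np.argmin(gap))])  # argmin takes the first minimum
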