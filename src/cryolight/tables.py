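"""Loaders for spectral coefficient tables.

Tables are two-column delimited text (wavelength nm, coefficient); the
shipped defaults are constructed stand-ins (see the ``*_synthetic.tsv``
headers) and any user table in the same format can be substituted.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np

from .solar import SpectralGrid

__all__ = [
    "load_two_column",
    "ice_absorption",
    "phyto_specific_absorption",
    "water_absorption",
]


def load_two_column(source) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (wavelength, coefficient) text table.

    ``source`` is a filesystem path or the name of a packaged table.
    Lines starting with ``#`` are comments; columns split on whitespace.
    """
    import os

    name = str(source)
    if os.path.exists(name):
        with open(name) as fh:
            text = fh.read()
    else:
        text = resources.files("cryolight.data").joinpath(name).read_text()
    wl, val = [], []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        wl.append(float(parts[0]))
        val.append(float(parts[1]))
    wl_arr = np.asarray(wl)
    val_arr = np.asarray(val)
    if np.any(val_arr < 0):
        raise ValueError(f"negative coefficients in table {source}")
    order = np.argsort(wl_arr)
    return wl_arr[order], val_arr[order]


def _interp_to_grid(wl_tab, val_tab, grid: SpectralGrid, fill=np.nan) -> np.ndarray:
    out = np.interp(grid.wavelengths, wl_tab, val_tab, left=fill, right=fill)
    return out


@lru_cache(maxsize=8)
def ice_absorption(table: str = "ice_absorption_synthetic.tsv") -> np.ndarray:
    """Sea-ice attenuation k(lambda) (m-1) on the model grid.

    Defined for 200–1000 nm; wavelengths beyond the table range are NaN and
    treated as fully absorbed by the transmission step.
    """
    grid = SpectralGrid()
    wl, val = load_two_column(table)
    return _interp_to_grid(wl, val, grid, fill=np.nan)


@lru_cache(maxsize=8)
def phyto_specific_absorption(table: str = "phyto_absorption_synthetic.tsv") -> np.ndarray:
    """Chlorophyll-specific absorption a*(lambda) (m2 mg-1) on the model
    grid; zero outside the table's spectral range."""
    grid = SpectralGrid()
    wl, val = load_two_column(table)
    return _interp_to_grid(wl, val, grid, fill=0.0)


@lru_cache(maxsize=8)
def water_absorption(table: str = "water_absorption_synthetic.tsv") -> np.ndarray:
    """Pure-seawater absorption (m-1) on the model grid, edge-extended."""
    grid = SpectralGrid()
    wl, val = load_two_column(table)
    return np.interp(grid.wavelengths, wl, val)
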