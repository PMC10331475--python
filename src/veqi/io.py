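"""Raster-stack I/O.

Stacks travel as NetCDF (classic format via the scipy backend) with the
canonical dimension order (time, y, x) — or (year, y, x) for annual grids.
No-data is carried as NaN in float variables; boolean masks are encoded as
byte grids. Reading restores the canonical order regardless of how the
file on disk is laid out.
"""

from __future__ import annotations

import os

import numpy as np
import xarray as xr

from .errors import IOFormatError

_CANONICAL_ORDERS = (("time", "y", "x"), ("year", "y", "x"))


def write_raster_stack(ds: xr.Dataset | xr.DataArray, path: str) -> str:
    """Write a stack to NetCDF; returns the path."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    parent = os.path.dirname(os.path.abspath(path))
    if parent and not os.path.isdir(parent):
        raise IOFormatError(f"parent directory does not exist: {parent}")
    ds.to_netcdf(path, engine="scipy")
    return path


def read_raster_stack(path: str, expected_dims: tuple[str, ...] | None = None) -> xr.Dataset:
    """Read a NetCDF stack, restore canonical dimension order, and verify
    the expected dimensions are present."""
    if not os.path.exists(path):
        raise IOFormatError(f"no such file: {path}")
    try:
        with xr.open_dataset(path, engine="scipy") as handle:
            ds = handle.load()
    except (OSError, ValueError, TypeError, KeyError) as exc:
        raise IOFormatError(f"unreadable raster stack {path}: {exc}") from exc
    if expected_dims is not None:
        missing = [d for d in expected_dims if d not in ds.dims]
        if missing:
            raise IOFormatError(f"{path} lacks expected dimensions {missing}; has {tuple(ds.dims)}")
    priority = [d for d in ("time", "year", "y", "x") if d in ds.dims]
    if priority:
        ds = ds.transpose(*priority, ...)
    return ds


def grids_to_dataset(grids: dict[str, np.ndarray], time_dim: str = "year") -> xr.Dataset:
    """Bundle (time, y, x) and (y, x) numpy grids into one Dataset."""
    data = {}
    for name, arr in grids.items():
        arr = np.asarray(arr)
        if arr.ndim == 3:
            data[name] = ((time_dim, "y", "x"), arr)
        elif arr.ndim == 2:
            data[name] = (("y", "x"), arr)
        else:
            raise IOFormatError(f"grid {name!r} must be 2-D or 3-D, got {arr.ndim}-D")
    return xr.Dataset(data)
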