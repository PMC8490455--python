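"""NetCDF read/write helpers (classic NetCDF via xarray's built-in scipy engine)."""

from __future__ import annotations

from pathlib import Path

import xarray as xr


def save_netcdf(ds: xr.Dataset | xr.DataArray, path: str | Path) -> None:
    """Write a dataset/array as classic NetCDF with CF-style metadata intact."""
    if isinstance(ds, xr.DataArray):
        ds = ds.to_dataset(name=ds.name or "data")
    ds.to_netcdf(path, engine="scipy")


def load_netcdf(path: str | Path) -> xr.Dataset:
    # load eagerly so the file handle is released immediately
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()
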