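"""Region polygons and gridded population counts for the synthetic study area."""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import xarray as xr
from shapely.geometry import Polygon, mapping, shape

from ..errors import ConfigError


@dataclass(frozen=True)
class Region:
    """A sub-national analysis region (the study's spatial unit)."""

    region_id: str
    country: str
    polygon: Polygon


def grid_regions(
    grid_shape: tuple[int, int],
    n_regions: int,
    n_countries: int = 1,
    lat0: float = 40.0,
    lon0: float = 0.0,
    dlat: float = 0.5,
    dlon: float = 0.5,
) -> list[Region]:
    """Partition the model grid into ``n_regions`` rectangular regions.

    Regions are contiguous column bands of the grid (split along longitude),
    assigned round-robin-in-blocks to ``n_countries`` countries. Polygon
    edges sit on cell boundaries so every cell center falls in exactly one
    region.
    """
    ny, nx = grid_shape
    if n_regions < 1 or n_regions > nx:
        raise ConfigError(f"n_regions must be in [1, nx={nx}], got {n_regions}")
    if n_countries < 1 or n_countries > n_regions:
        raise ConfigError("need 1 <= n_countries <= n_regions")
    edges = np.linspace(0, nx, n_regions + 1).round().astype(int)
    lat_lo, lat_hi = lat0 - dlat / 2, lat0 + dlat * (ny - 1) + dlat / 2
    regions = []
    per_country = int(np.ceil(n_regions / n_countries))
    for i in range(n_regions):
        lon_lo = lon0 - dlon / 2 + dlon * edges[i]
        lon_hi = lon0 - dlon / 2 + dlon * edges[i + 1]
        poly = Polygon(
            [(lon_lo, lat_lo), (lon_hi, lat_lo), (lon_hi, lat_hi), (lon_lo, lat_hi)]
        )
        country = f"C{i // per_country:02d}"
        regions.append(Region(region_id=f"R{i:03d}", country=country, polygon=poly))
    return regions


def generate_population(
    grid_shape: tuple[int, int],
    snapshot_years: tuple[int, ...] = (2000, 2005, 2010, 2015, 2020),
    total: float = 1e6,
    concentration: float = 1.0,
    growth_rate: float = 0.005,
    lat0: float = 40.0,
    lon0: float = 0.0,
    dlat: float = 0.5,
    dlon: float = 0.5,
    seed: int = 0,
) -> xr.DataArray:
    """Gridded population counts with spatial concentration, one layer per snapshot year.

    The spatial pattern is a lognormal field (``concentration`` is the log-s.d.;
    0 gives a uniform population), fixed across snapshots, scaled by a constant
    exponential growth between snapshot years. Counts are non-negative and sum
    to ``total`` in the first snapshot year.
    """
    ny, nx = grid_shape
    rng = np.random.default_rng(seed)
    pattern = rng.lognormal(0.0, concentration, size=(ny, nx))
    pattern *= total / pattern.sum()
    years = np.asarray(sorted(snapshot_years))
    scale = np.exp(growth_rate * (years - years[0]))
    data = pattern[None, :, :] * scale[:, None, None]
    return xr.DataArray(
        data,
        dims=("year", "lat", "lon"),
        coords={
            "year": years,
            "lat": lat0 + dlat * np.arange(ny),
            "lon": lon0 + dlon * np.arange(nx),
        },
        name="population",
        attrs={"units": "persons", "seed": seed},
    )


def write_regions_geojson(regions: list[Region], path: str) -> None:
    fc = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"region_id": r.region_id, "country": r.country},
                "geometry": mapping(r.polygon),
            }
            for r in regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_regions_geojson(path: str) -> list[Region]:
    with open(path) as fh:
        fc = json.load(fh)
    return [
        Region(
            region_id=f["properties"]["region_id"],
            country=f["properties"]["country"],
            polygon=shape(f["geometry"]),
        )
        for f in fc["features"]
    ]
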