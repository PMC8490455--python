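"""End-to-end orchestration: synthetic inputs → detection → exposure → CGE.

The pipeline is driven by a single :class:`RunConfig` (YAML-loadable) and
split into four cached stages, each writing CSV/JSON artifacts into the run
directory so it can be re-run individually:

1. ``climate``  — generate hourly meteorology (with injected heatwaves),
   population and regions; write regional daily Tmax and regional hourly
   WBGT (sun and shade) for the analysis years.
2. ``detect``   — TX90p thresholds from the reference period, event
   catalogue and catalogue statistics, WBDD severity.
3. ``exposure`` — sectoral workability losses and the annual shock τ_rs.
4. ``cge``      — calibrate the toy economy, apply τ, solve, impact tables.

A JSON run manifest records seed, config hash and package versions; outputs
are byte-identical for identical config + seed. NaNs in any stage artifact
abort the run (no silent propagation).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cge import ElasticityConfig, apply_shock, calibrate, impact_report, solve
from .errors import ConfigError, HeateconError
from .exposure import (
    ProductivityShock,
    annualize_shock,
    daily_shift_workability,
    population_regional_mean,
    uniform_quarterly_weights,
    workability,
)
from .heat_stress import wbgt_field
from .heatwaves import (
    HeatwaveCatalogue,
    HeatwaveEvent,
    catalogue_stats,
    compute_thresholds,
    compute_wbdd,
    daily_tmax,
    detect_events,
)
from .synthetic import (
    HeatwaveSpec,
    SyntheticClimateConfig,
    ToyEconomyConfig,
    generate_meteo,
    generate_population,
    generate_toy_economy,
    grid_regions,
    inject_heatwave,
    write_regions_geojson,
)
from .synthetic.economy import SectorSpec

log = logging.getLogger("heatecon")

STANDARDS = ("ISO", "NIOSH", "Hothaps")


@dataclass
class RunConfig:
    """Run configuration; see ``RunConfig.from_yaml`` for the file layout."""

    seed: int = 0
    output_dir: str = "runs/run0"
    reference_period: tuple[int, int] = (1995, 1999)
    analysis_years: tuple[int, ...] = (2000,)
    standard: str = "ISO"
    climate: dict = field(default_factory=dict)
    heatwaves: list[dict] = field(default_factory=list)
    regions: dict = field(default_factory=lambda: {"n_regions": 2, "n_countries": 1})
    population: dict = field(default_factory=dict)
    economy: dict = field(default_factory=dict)
    elasticities: dict = field(default_factory=dict)
    save_fields: bool = False  # also write gridded meteorology/WBGT as NetCDF

    def validate(self) -> None:
        if self.standard not in STANDARDS:
            raise ConfigError(f"standard must be one of {STANDARDS}")
        r0, r1 = self.reference_period
        if r1 < r0 + 1:
            raise ConfigError("reference period must span at least 2 years")
        if not self.analysis_years:
            raise ConfigError("need at least one analysis year")
        if min(self.analysis_years) < r0:
            raise ConfigError("reference period must precede or contain analysis years")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items() if k in known})
        cfg.reference_period = tuple(cfg.reference_period)  # type: ignore[assignment]
        cfg.analysis_years = tuple(cfg.analysis_years)  # type: ignore[assignment]
        return cfg

    def config_hash(self) -> str:
        # output_dir is a run location, not part of the scientific configuration
        payload = {
            k: getattr(self, k) for k in self.__dataclass_fields__ if k != "output_dir"
        }
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # --- derived sub-configs -------------------------------------------------
    def climate_config(self) -> SyntheticClimateConfig:
        y0 = min(self.reference_period[0], min(self.analysis_years))
        y1 = max(self.reference_period[1], max(self.analysis_years))
        return SyntheticClimateConfig(years=(y0, y1), seed=self.seed, **self.climate)

    def economy_config(self) -> ToyEconomyConfig:
        eco = dict(self.economy)
        if "sectors" in eco:
            eco["sectors"] = [SectorSpec(**s) for s in eco["sectors"]]
        eco.setdefault("n_regions", self.regions.get("n_regions", 2))
        eco.setdefault("n_countries", self.regions.get("n_countries", 1))
        eco.setdefault("seed", self.seed)
        return ToyEconomyConfig(**eco)


def _check_nan(name: str, frame) -> None:
    arr = frame.to_numpy() if hasattr(frame, "to_numpy") else np.asarray(frame)
    if np.isnan(arr).any():
        raise HeateconError(f"stage artifact {name!r} contains NaNs")


class _Stage:
    """Context manager tagging failures with the stage name and timing it."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is not None:
            log.error("stage %s: failed after %.1fs: %s", self.name, dt, exc)
            raise HeateconError(f"stage {self.name!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", self.name, dt)


def stage_climate(config: RunConfig, outdir: Path) -> dict:
    """Generate inputs and reduce them to regional series; write artifacts."""
    with _Stage("climate"):
        ccfg = config.climate_config()
        field_ = generate_meteo(ccfg)
        for hw in config.heatwaves:
            field_ = inject_heatwave(field_, HeatwaveSpec(**hw))
        if config.save_fields:
            from .io import save_netcdf

            save_netcdf(field_, outdir / "meteo.nc")

        geo = dict(lat0=ccfg.lat0, lon0=ccfg.lon0, dlat=ccfg.dlat, dlon=ccfg.dlon)
        regions = grid_regions(ccfg.grid_shape, **config.regions, **geo)
        pop = generate_population(
            ccfg.grid_shape, seed=config.seed, **config.population, **geo
        )
        write_regions_geojson(regions, outdir / "regions.geojson")

        # regional daily Tmax over the full span, weighted by the earliest
        # population snapshot (fixed mask for the reference/history period)
        tmax = daily_tmax(field_)
        pop0 = pop.isel(year=0)
        reg_tmax = population_regional_mean(tmax, pop0, regions)
        _check_nan("daily_tmax_regional", reg_tmax)
        reg_tmax.to_csv(outdir / "daily_tmax_regional.csv")

        # regional hourly WBGT for the analysis years, year-specific population
        wbgt_frames = {"sun": [], "shade": []}
        for year in config.analysis_years:
            sub = field_.sel(time=str(year))
            for variant in ("sun", "shade"):
                w = wbgt_field(sub, variant)
                if config.save_fields:
                    from .io import save_netcdf

                    save_netcdf(w, outdir / f"wbgt_{variant}_{year}.nc")
                reg = population_regional_mean(w, pop, regions, year=year)
                wbgt_frames[variant].append(reg)
        wbgt_reg = {v: pd.concat(frames) for v, frames in wbgt_frames.items()}
        for v, frame in wbgt_reg.items():
            _check_nan(f"wbgt_{v}_regional", frame)
            frame.to_csv(outdir / f"wbgt_{v}_regional.csv")
        return {"daily_tmax": reg_tmax, "wbgt": wbgt_reg, "regions": regions}


def stage_detect(config: RunConfig, outdir: Path, daily_tmax_reg=None, wbgt_sun=None) -> dict:
    """Thresholds, event catalogue, catalogue stats and WBDD severity."""
    with _Stage("detect"):
        if daily_tmax_reg is None:
            daily_tmax_reg = pd.read_csv(outdir / "daily_tmax_regional.csv", index_col=0, parse_dates=True)
        if wbgt_sun is None:
            wbgt_sun = pd.read_csv(outdir / "wbgt_sun_regional.csv", index_col=0, parse_dates=True)
        r0, r1 = config.reference_period
        ref = daily_tmax_reg.loc[str(r0) : str(r1)]
        catalogues = []
        thr_rows = {}
        for region in daily_tmax_reg.columns:
            thr = compute_thresholds(ref[region], region=region)
            thr_rows[region] = thr.values
            for year in config.analysis_years:
                series = daily_tmax_reg.loc[str(year), region]
                catalogues.append(detect_events(series, thr, region=region))
        catalogue = HeatwaveCatalogue.merge(*catalogues)
        pd.DataFrame(thr_rows).to_csv(outdir / "thresholds.csv", index_label="calendar_day")

        compute_wbdd(wbgt_sun, catalogue)
        frame = catalogue.to_frame()
        _check_nan("catalogue.wbdd", frame[["wbdd"]]) if len(frame) else None
        frame.to_csv(outdir / "catalogue.csv", index=False)

        stats = catalogue_stats(catalogue, list(daily_tmax_reg.columns))
        stats["area_affected"].to_csv(outdir / "area_affected.csv")
        stats["duration"].to_csv(outdir / "duration_summary.csv")
        return {"catalogue": catalogue}


def _catalogue_from_csv(path: Path) -> HeatwaveCatalogue:
    frame = pd.read_csv(path, parse_dates=["start"])
    events = [
        HeatwaveEvent(
            region=row.region,
            start=row.start,
            duration=int(row.duration),
            summer=bool(row.summer),
            severity=float(row.wbdd),
        )
        for row in frame.itertuples()
    ]
    return HeatwaveCatalogue(events)


def stage_exposure(config: RunConfig, outdir: Path, wbgt=None, catalogue=None, economy=None) -> dict:
    """Sectoral workability losses on heatwave days → annual shock τ_rs."""
    with _Stage("exposure"):
        if wbgt is None:
            wbgt = {
                v: pd.read_csv(outdir / f"wbgt_{v}_regional.csv", index_col=0, parse_dates=True)
                for v in ("sun", "shade")
            }
        if catalogue is None:
            catalogue = _catalogue_from_csv(outdir / "catalogue.csv")
        if economy is None:
            economy = generate_toy_economy(config.economy_config())
        sector_map = economy.sector_map()
        regions = list(wbgt["sun"].columns)
        weights = uniform_quarterly_weights(regions, list(sector_map.index))

        shocks = {}
        for year in config.analysis_years:
            losses = {}
            for sector, row in sector_map.iterrows():
                variant = "sun" if row["outdoor"] else "shade"
                hourly = wbgt[variant].loc[str(year)]
                wa = hourly.apply(lambda col: workability(col, row["workload"], config.standard))
                daily = daily_shift_workability(wa)
                for region in regions:
                    losses[(region, sector)] = 1.0 - daily[region]
            loss_frame = pd.DataFrame(losses)
            loss_frame.columns = pd.MultiIndex.from_tuples(loss_frame.columns, names=["region", "sector"])
            shocks[year] = annualize_shock(loss_frame, catalogue, weights, year)
            _check_nan(f"tau_{year}", shocks[year].tau)
        tau_all = pd.concat(
            {y: s.tau for y, s in shocks.items()}, names=["year", "region"]
        )
        tau_all.to_csv(outdir / "tau.csv")
        return {"shocks": shocks, "economy": economy}


def stage_cge(config: RunConfig, outdir: Path, shocks=None, economy=None) -> dict:
    """Calibrate, apply τ per analysis year, solve, and write impact tables."""
    with _Stage("cge"):
        if economy is None:
            economy = generate_toy_economy(config.economy_config())
        if shocks is None:
            tau_all = pd.read_csv(outdir / "tau.csv", index_col=[0, 1])
            shocks = {
                int(y): ProductivityShock(tau=tau_all.loc[y], year=int(y))
                for y in tau_all.index.get_level_values(0).unique()
            }
        params = calibrate(economy, ElasticityConfig(**config.elasticities))
        benchmark = solve(params)
        reports = []
        for year, shock in sorted(shocks.items()):
            eq = solve(apply_shock(params, shock))
            rep = impact_report(eq, benchmark, params)
            rep.insert(0, "year", year)
            reports.append(rep)
        impacts = pd.concat(reports, ignore_index=True)
        _check_nan("impacts", impacts[["gdp_pct", "gva_pp_contribution"]])
        impacts.to_csv(outdir / "impacts.csv", index=False)
        return {"impacts": impacts, "benchmark": benchmark, "params": params}


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the in-memory artifacts of each stage."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        clim = stage_climate(config, outdir)
        det = stage_detect(
            config, outdir, daily_tmax_reg=clim["daily_tmax"], wbgt_sun=clim["wbgt"]["sun"]
        )
        economy = generate_toy_economy(config.economy_config())
        exp = stage_exposure(
            config, outdir, wbgt=clim["wbgt"], catalogue=det["catalogue"], economy=economy
        )
        cge_out = stage_cge(config, outdir, shocks=exp["shocks"], economy=economy)
    except Exception:
        # no partial runs: a manifest marks a completed run, and its absence a failed one
        manifest = outdir / "manifest.json"
        if manifest.exists():
            manifest.unlink()
        raise
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "heatecon_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "analysis_years": list(config.analysis_years),
        "standard": config.standard,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {**clim, **det, **exp, **cge_out, "manifest": manifest}


def run_historical(config: RunConfig) -> pd.DataFrame:
    """Historical-reference mode: loop detection+exposure+CGE over every
    reference-period year and return the distribution of regional GDP losses.

    The population mask is fixed to the earliest snapshot throughout (the
    regional series produced by the climate stage already use it for Tmax).
    """
    config.validate()
    years = tuple(range(config.reference_period[0], config.reference_period[1] + 1))
    cfg = RunConfig(
        **{
            **{k: getattr(config, k) for k in config.__dataclass_fields__},
            "analysis_years": years,
        }
    )
    out = run_pipeline(cfg)
    impacts = out["impacts"]
    dist = (
        impacts.drop_duplicates(["year", "region"])[["year", "region", "gdp_pct"]]
        .pivot(index="year", columns="region", values="gdp_pct")
    )
    dist.to_csv(Path(cfg.output_dir) / "historical_gdp_losses.csv")
    return dist
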