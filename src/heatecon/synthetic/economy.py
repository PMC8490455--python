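"""Balanced toy multi-region economies (social accounting matrices).

A toy economy stands in for the regionalised SAM database that calibrates the
general-equilibrium model: a set of regions (grouped into countries), each
with the same list of sectors, linked by intermediate use and bilateral trade.

Construction guarantees an exactly balanced SAM. At unit benchmark prices,
one value unit of any activity's output splits into intermediate purchases
(``io_density``) and value added (the rest), value added flows to the regional
household, the household spends everything (consumption + saving-financed
investment), and every composite-good demand is sourced domestically or from
other regions with shares summing to one. The induced demand-share matrix *B*
over activities therefore has unit column sums, so gross outputs are the
Perron eigenvector of *B* — a consistent circular flow with zero balance
residual by construction rather than by iterative adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..errors import ConfigError

WORKLOAD_CLASSES = ("low", "moderate", "high")


@dataclass(frozen=True)
class SectorSpec:
    """One economic sector: workload intensity class and indoor/outdoor flag."""

    name: str
    workload: str  # low | moderate | high
    outdoor: bool
    labour_share: float = 0.55  # labour share of value added
    weight: float = 1.0  # relative final-demand size

    def __post_init__(self):
        if self.workload not in WORKLOAD_CLASSES:
            raise ConfigError(f"unknown workload class {self.workload!r}")
        if not (0.0 < self.labour_share < 1.0):
            raise ConfigError("labour_share must be in (0, 1)")


def default_sectors() -> list[SectorSpec]:
    """Four stylised sectors: two outdoor (heat-exposed), two indoor."""
    return [
        SectorSpec("agriculture", "high", outdoor=True, labour_share=0.6, weight=0.7),
        SectorSpec("construction", "moderate", outdoor=True, labour_share=0.6, weight=0.9),
        SectorSpec("manufacturing", "moderate", outdoor=False, labour_share=0.5, weight=1.2),
        SectorSpec("services", "low", outdoor=False, labour_share=0.55, weight=2.0),
    ]


@dataclass
class ToyEconomyConfig:
    n_regions: int = 2
    n_countries: int = 1
    sectors: list[SectorSpec] = field(default_factory=default_sectors)
    io_density: float = 0.3  # intermediate share of each sector's output cost
    trade_openness: float = 0.2  # share of composite demand that is imported
    saving_rate: float = 0.1
    total_output: float = 1000.0
    mix_jitter: float = 0.3  # seeded heterogeneity of input mixes
    seed: int = 0

    def validate(self) -> None:
        if self.n_regions < 1:
            raise ConfigError("need at least one region")
        if not (1 <= self.n_countries <= self.n_regions):
            raise ConfigError("need 1 <= n_countries <= n_regions")
        if len(self.sectors) < 2:
            raise ConfigError("need at least two sectors")
        if not any(s.outdoor for s in self.sectors) or not any(not s.outdoor for s in self.sectors):
            raise ConfigError("need at least one outdoor and one indoor sector")
        if len({s.name for s in self.sectors}) != len(self.sectors):
            raise ConfigError("sector names must be unique")
        if not (0.0 <= self.io_density < 1.0):
            raise ConfigError("io_density must lie in [0, 1)")
        if not (0.0 <= self.trade_openness <= 1.0):
            raise ConfigError("trade_openness must lie in [0, 1]")
        if self.n_regions == 1 and self.trade_openness > 0:
            raise ConfigError("single-region economy cannot import (set trade_openness=0)")
        if not (0.0 <= self.saving_rate < 1.0):
            raise ConfigError("saving_rate must lie in [0, 1)")


@dataclass
class ToyEconomy:
    """Benchmark flows of a balanced toy economy, all at unit prices.

    Array dimension order is (region, sector) unless noted; ``io_use`` is
    (region, input sector, using sector) — intermediate purchases of the home
    composite; ``trade`` is (sector, origin region, destination region) with a
    zero diagonal.
    """

    regions: list[str]
    countries: dict[str, str]
    sectors: list[SectorSpec]
    output: np.ndarray  # (R, S) gross output X
    io_use: np.ndarray  # (R, S_in, S_use)
    va_labour: np.ndarray  # (R, S)
    va_capital: np.ndarray  # (R, S)
    consumption: np.ndarray  # (R, S)
    investment: np.ndarray  # (R, S)
    domestic: np.ndarray  # (R, S) composite demand met domestically
    trade: np.ndarray  # (S, R_origin, R_dest)
    saving_rate: float

    @property
    def sector_names(self) -> list[str]:
        return [s.name for s in self.sectors]

    @property
    def composite_demand(self) -> np.ndarray:
        """(R, S) total demand for each region's composite good."""
        return self.io_use.sum(axis=2) + self.consumption + self.investment

    def sector_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sector": [s.name for s in self.sectors],
                "workload": [s.workload for s in self.sectors],
                "outdoor": [s.outdoor for s in self.sectors],
            }
        ).set_index("sector")

    def sam(self) -> pd.DataFrame:
        """Assemble the square SAM (rows receive, columns pay)."""
        R, S = self.output.shape
        acts = [("act", r, s) for r in range(R) for s in range(S)]
        coms = [("com", r, s) for r in range(R) for s in range(S)]
        facs = [("fac", r, f) for r in range(R) for f in ("labour", "capital")]
        hhs = [("hh", r, "") for r in range(R)]
        sis = [("si", r, "") for r in range(R)]
        accounts = acts + coms + facs + hhs + sis
        idx = {a: i for i, a in enumerate(accounts)}
        m = np.zeros((len(accounts), len(accounts)))
        for r in range(R):
            for s in range(S):
                a, c = idx[("act", r, s)], idx[("com", r, s)]
                # commodity receives from users
                for s2 in range(S):
                    m[c, idx[("act", r, s2)]] += self.io_use[r, s, s2]
                m[c, idx[("hh", r, "")]] += self.consumption[r, s]
                m[c, idx[("si", r, "")]] += self.investment[r, s]
                # activity receives domestic sales and exports
                m[a, c] += self.domestic[r, s]
                for d in range(R):
                    if d != r:
                        m[a, idx[("com", d, s)]] += self.trade[s, r, d]
                # factors receive from activity
                m[idx[("fac", r, "labour")], a] += self.va_labour[r, s]
                m[idx[("fac", r, "capital")], a] += self.va_capital[r, s]
            m[idx[("hh", r, "")], idx[("fac", r, "labour")]] += self.va_labour[r].sum()
            m[idx[("hh", r, "")], idx[("fac", r, "capital")]] += self.va_capital[r].sum()
            m[idx[("si", r, "")], idx[("hh", r, "")]] += self.saving_rate * (
                self.va_labour[r].sum() + self.va_capital[r].sum()
            )
        labels = ["_".join(str(p) for p in a if p != "") for a in accounts]
        return pd.DataFrame(m, index=labels, columns=labels)

    def balance_residual(self) -> float:
        """Max |row sum − column sum| over accounts, relative to total output."""
        sam = self.sam().to_numpy()
        return float(np.abs(sam.sum(axis=1) - sam.sum(axis=0)).max() / self.output.sum())

    def write_csv(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.sam().to_csv(outdir / "sam.csv")
        self.sector_map().to_csv(outdir / "sectors.csv")
        pd.DataFrame(self.output, index=self.regions, columns=self.sector_names).to_csv(
            outdir / "gross_output.csv"
        )


def generate_toy_economy(config: ToyEconomyConfig) -> ToyEconomy:
    """Generate a balanced toy economy from structural parameters.

    See the module docstring for the construction; the returned economy has
    ``balance_residual() < 1e-12`` up to floating-point accumulation, each
    sector's intermediate-cost share equal to ``io_density`` exactly, and all
    bilateral trade zero when ``trade_openness`` is zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    R, S = config.n_regions, len(config.sectors)
    per_country = int(np.ceil(R / config.n_countries))
    regions = [f"R{i:03d}" for i in range(R)]
    countries = {regions[i]: f"C{i // per_country:02d}" for i in range(R)}

    weights = np.array([s.weight for s in config.sectors], dtype=float)
    beta = weights / weights.sum()  # household expenditure shares
    theta = beta.copy()  # investment demand shares

    # input mix per using sector: weight-proportional with seeded jitter
    mix = np.empty((S, S))
    for s in range(S):
        w = weights * np.exp(rng.normal(0.0, config.mix_jitter, S))
        mix[:, s] = w / w.sum()

    sav, od, openness = config.saving_rate, config.io_density, config.trade_openness
    # per unit of activity output value, demand placed on the home composite s'
    final_share = (1.0 - od) * ((1.0 - sav) * beta + sav * theta)  # via household
    comp_demand = od * mix + final_share[:, None]  # (S_in, S_use), columns sum to 1

    # sourcing shares: destination d buys (1-openness) at home, rest uniformly abroad
    src = np.zeros((R, R))  # (origin, destination)
    for d in range(R):
        src[d, d] = 1.0 - openness
        if R > 1:
            for o in range(R):
                if o != d:
                    src[o, d] = openness / (R - 1)

    # demand-share matrix over activities, column-stochastic by construction
    B = np.zeros((R * S, R * S))
    for d in range(R):
        for s_use in range(S):
            col = d * S + s_use
            for s_in in range(S):
                for o in range(R):
                    B[o * S + s_in, col] += comp_demand[s_in, s_use] * src[o, d]

    # Perron vector (eigenvalue exactly 1): power iteration from uniform
    x = np.full(R * S, 1.0 / (R * S))
    for _ in range(10_000):
        x_new = B @ x
        x_new /= x_new.sum()
        if np.abs(x_new - x).max() < 1e-15:
            x = x_new
            break
        x = x_new
    X = (x * config.total_output).reshape(R, S)

    va = (1.0 - od) * X
    lab = np.array([s.labour_share for s in config.sectors])
    va_labour = va * lab[None, :]
    va_capital = va - va_labour
    io_use = np.einsum("ij,rj->rij", od * mix, X)  # (R, S_in, S_use)

    income = va.sum(axis=1)
    consumption = (1.0 - sav) * income[:, None] * beta[None, :]
    investment = sav * income[:, None] * theta[None, :]

    Q = io_use.sum(axis=2) + consumption + investment  # composite demand (R, S)
    domestic = (1.0 - openness) * Q
    trade = np.zeros((S, R, R))
    for s in range(S):
        for d in range(R):
            for o in range(R):
                if o != d:
                    trade[s, o, d] = Q[d, s] * src[o, d]

    return ToyEconomy(
        regions=regions,
        countries=countries,
        sectors=list(config.sectors),
        output=X,
        io_use=io_use,
        va_labour=va_labour,
        va_capital=va_capital,
        consumption=consumption,
        investment=investment,
        domestic=domestic,
        trade=trade,
        saving_rate=sav,
    )
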