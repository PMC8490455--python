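"""Compact multi-region multi-sector comparative-static CGE model.

Structure (one good per sector, regionally differentiated):

* **Production** per (region r, sector s): Leontief between a value-added
  bundle and intermediate composite inputs; value added is CES between
  effective capital χK and effective labour ψL with sectoral elasticity σ_s.
  The heat shock enters as labour-augmenting productivity, ψ′ = (1 − τ)ψ.
* **Trade**: each destination combines its domestic variety and an aggregate
  import via Armington CES (σ_ARM); the import aggregate is sourced across
  origin regions through a CRESH nest with pair-specific σ_IMP, raised by a
  20% border factor for within-country pairs.
* **Demand**: the regional household earns all factor income, saves a fixed
  share (saving-driven investment, spent locally), and spends the rest on
  composites with Cobb-Douglas shares.
* **Closure**: regional factor endowments fixed and fully employed (factors
  mobile across sectors, not across regions); numeraire = region 0's factor
  price index.

Equilibrium = prices (domestic goods, regional wage and capital rent) such
that zero-profit holds in every activity and factor markets clear; goods
markets clear by construction (output solved from the linear demand system at
candidate prices), and the one redundant factor equation (Walras's law) is
replaced by the numeraire and reported as a diagnostic residual. The solve
runs on log-prices from the benchmark point; calibration reproduces the SAM
exactly at unit prices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import root

from ..errors import ConfigError, ConvergenceError
from ..exposure import ProductivityShock
from ..synthetic.economy import ToyEconomy
from .cresh import CreshNest

#: residual tolerance of the equilibrium solve
SOLVE_TOL = 1e-10
#: acceptance tolerance on reported residual norms
RESIDUAL_TOL = 1e-8
#: within-country import-substitution elasticities exceed cross-country ones by this factor
BORDER_FACTOR = 1.2


@dataclass
class ElasticityConfig:
    sigma_va: float | dict[str, float] = 0.8  # capital–labour substitution, per sector
    sigma_arm: float = 2.0  # domestic vs aggregate imports
    sigma_imp: float = 5.0  # cross-country import sourcing (CRESH)
    border_factor: float = BORDER_FACTOR

    def sigma_va_for(self, sector: str) -> float:
        if isinstance(self.sigma_va, dict):
            return float(self.sigma_va[sector])
        return float(self.sigma_va)


@dataclass
class CGEParams:
    """Calibrated parameters plus benchmark flows (all benchmark prices = 1)."""

    regions: list[str]
    sectors: list[str]
    countries: dict[str, str]
    # technology
    a_int: np.ndarray  # (R, S_in, S_use) composite input per unit output
    v_coeff: np.ndarray  # (R, S) value added per unit output
    share_l: np.ndarray  # (R, S) labour share of value added
    sigma_va: np.ndarray  # (S,)
    psi: np.ndarray  # (R, S) labour productivity
    chi: np.ndarray  # (R, S) capital productivity
    # trade
    sigma_arm: float
    dom_share: np.ndarray  # (R, S) benchmark domestic share of composite demand
    cresh: dict[tuple[int, int], CreshNest]  # (dest, sector) -> sourcing nest
    # demand
    beta: np.ndarray  # (R, S) consumption shares
    theta: np.ndarray  # (R, S) investment shares
    saving_rate: float
    # endowments and benchmark
    labour: np.ndarray  # (R,)
    capital: np.ndarray  # (R,)
    x_bar: np.ndarray  # (R, S) benchmark gross output
    va_bar: np.ndarray  # (R, S) benchmark value added

    @property
    def shape(self) -> tuple[int, int]:
        return self.x_bar.shape


@dataclass
class EquilibriumSolution:
    prices: np.ndarray  # (R, S) domestic output prices
    wage: np.ndarray  # (R,)
    rent: np.ndarray  # (R,)
    output: np.ndarray  # (R, S) gross output quantities
    va_quantity: np.ndarray  # (R, S) real value added
    real_gdp: np.ndarray  # (R,) Σ_s va_quantity at benchmark prices
    residual_norm: float
    walras_residual: float
    iterations: int

    def gdp_change_pct(self, benchmark: "EquilibriumSolution") -> np.ndarray:
        return 100.0 * (self.real_gdp / benchmark.real_gdp - 1.0)


def calibrate(economy: ToyEconomy, elasticities: ElasticityConfig | None = None) -> CGEParams:
    """Calibrate the model to a balanced toy economy at unit benchmark prices."""
    elasticities = elasticities or ElasticityConfig()
    if economy.balance_residual() > 1e-7:
        raise ConfigError("SAM is not balanced; cannot calibrate")
    R, S = economy.output.shape
    X = economy.output
    va = economy.va_labour + economy.va_capital
    with np.errstate(divide="ignore", invalid="ignore"):
        a_int = economy.io_use / X[:, None, :]
        v_coeff = va / X
        share_l = np.where(va > 0, economy.va_labour / np.maximum(va, 1e-300), 0.5)
    Q = economy.composite_demand
    dom_share = np.where(Q > 0, economy.domestic / np.maximum(Q, 1e-300), 1.0)

    sigma_imp = np.full((R, R), float(elasticities.sigma_imp))
    regs = economy.regions
    for d in range(R):
        for o in range(R):
            if o != d and economy.countries[regs[o]] == economy.countries[regs[d]]:
                sigma_imp[d, o] *= elasticities.border_factor

    cresh: dict[tuple[int, int], CreshNest] = {}
    for d in range(R):
        for s in range(S):
            flows = economy.trade[s, :, d]
            origins = np.array([o for o in range(R) if o != d and flows[o] > 0])
            if len(origins):
                cresh[(d, s)] = CreshNest.calibrate(
                    origins, flows[origins], sigma_imp[d, origins]
                )

    income = va.sum(axis=1)
    beta = economy.consumption / economy.consumption.sum(axis=1, keepdims=True)
    theta = economy.investment / np.maximum(economy.investment.sum(axis=1, keepdims=True), 1e-300)
    return CGEParams(
        regions=list(regs),
        sectors=economy.sector_names,
        countries=dict(economy.countries),
        a_int=a_int,
        v_coeff=v_coeff,
        share_l=share_l,
        sigma_va=np.array([elasticities.sigma_va_for(s) for s in economy.sector_names]),
        psi=np.ones((R, S)),
        chi=np.ones((R, S)),
        sigma_arm=float(elasticities.sigma_arm),
        dom_share=dom_share,
        cresh=cresh,
        beta=beta,
        theta=theta,
        saving_rate=economy.saving_rate,
        labour=economy.va_labour.sum(axis=1),
        capital=economy.va_capital.sum(axis=1),
        x_bar=X.copy(),
        va_bar=va.copy(),
    )


def apply_shock(params: CGEParams, shock: ProductivityShock) -> CGEParams:
    """Scale labour productivity by (1 − τ) in every shocked region-sector."""
    tau = shock.tau.reindex(index=params.regions, columns=params.sectors).fillna(0.0).to_numpy()
    if np.any(tau < 0) or np.any(tau >= 1):
        raise ConfigError("tau must lie in [0, 1)")
    return replace(params, psi=params.psi * (1.0 - tau))


def _ces_unit_cost(pk: np.ndarray, pl: np.ndarray, sk: np.ndarray, sl: np.ndarray, sigma) -> np.ndarray:
    """Calibrated-share CES unit cost of value added (effective factor prices pk, pl)."""
    sigma = np.asarray(sigma, dtype=float)
    cd = np.abs(sigma - 1.0) < 1e-12
    out = np.empty(np.broadcast(pk, pl, sk, sl).shape)
    if np.any(cd):
        out[..., cd] = (pk[..., cd] ** sk[..., cd]) * (pl[..., cd] ** sl[..., cd])
    if np.any(~cd):
        e = 1.0 - sigma[~cd]
        out[..., ~cd] = (
            sk[..., ~cd] * pk[..., ~cd] ** e + sl[..., ~cd] * pl[..., ~cd] ** e
        ) ** (1.0 / e)
    return out


def _arm_cost(pd_: np.ndarray, pm: np.ndarray, sd: np.ndarray, sigma: float) -> np.ndarray:
    """Armington composite unit cost; degenerate shares handled exactly."""
    sm = 1.0 - sd
    if abs(sigma - 1.0) < 1e-12:
        return pd_**sd * np.where(sm > 0, pm, 1.0) ** sm
    e = 1.0 - sigma
    return (sd * pd_**e + np.where(sm > 0, sm * pm**e, 0.0)) ** (1.0 / e)


def _evaluate(params: CGEParams, logp: np.ndarray):
    """All equilibrium objects at candidate log-prices; returns dict."""
    R, S = params.shape
    p = np.exp(logp[: R * S]).reshape(R, S)
    w = np.exp(logp[R * S : R * S + R])
    rk = np.exp(logp[R * S + R :])

    # import aggregate price and sourcing shares per (destination, sector)
    pm = np.ones((R, S))
    y_shares: dict[tuple[int, int], np.ndarray] = {}
    for (d, s), nest in params.cresh.items():
        y = nest.shares(p[nest.origins, s])
        y_shares[(d, s)] = y
        pm[d, s] = nest.unit_cost(p[nest.origins, s], y)

    pc = _arm_cost(p, pm, params.dom_share, params.sigma_arm)

    # value added: effective factor prices and unit cost
    pk_eff = rk[:, None] / params.chi
    pl_eff = w[:, None] / params.psi
    sk = 1.0 - params.share_l
    sigma = np.broadcast_to(params.sigma_va, (R, S))
    pva = _ces_unit_cost(pk_eff, pl_eff, sk, params.share_l, params.sigma_va)

    # conditional factor demands per unit of value added (physical units)
    with np.errstate(divide="ignore"):
        l_per_va = params.share_l * (pva / pl_eff) ** sigma / params.psi
        k_per_va = sk * (pva / pk_eff) ** sigma / params.chi

    unit_cost = np.einsum("ris,ri->rs", params.a_int, pc) + params.v_coeff * pva

    # demand side: incomes and final demand for composites (quantities)
    income = w * params.labour + rk * params.capital
    spend = (1.0 - params.saving_rate) * params.beta + params.saving_rate * params.theta
    final_q = spend * income[:, None] / pc

    # linear system for gross output: X = T Q, Q = A X + F
    n = R * S
    dshare_q = params.dom_share * (pc / p) ** params.sigma_arm  # domestic per unit Q
    T = np.zeros((n, n))
    for d in range(R):
        for s in range(S):
            col = d * S + s
            T[d * S + s, col] += dshare_q[d, s]
            nest = params.cresh.get((d, s))
            if nest is not None:
                m_per_q = (1.0 - params.dom_share[d, s]) * (pc[d, s] / pm[d, s]) ** params.sigma_arm
                for o, y in zip(nest.origins, y_shares[(d, s)]):
                    T[o * S + s, col] += y * m_per_q
    A = np.zeros((n, n))
    for r in range(R):
        for s_in in range(S):
            for s_use in range(S):
                A[r * S + s_in, r * S + s_use] = params.a_int[r, s_in, s_use]
    F = final_q.reshape(n)
    X = np.linalg.solve(np.eye(n) - T @ A, T @ F).reshape(R, S)

    va_q = params.v_coeff * X
    labour_demand = (va_q * l_per_va).sum(axis=1)
    capital_demand = (va_q * k_per_va).sum(axis=1)
    return {
        "p": p, "w": w, "rk": rk, "pc": pc, "pva": pva, "unit_cost": unit_cost,
        "X": X, "va_q": va_q,
        "labour_demand": labour_demand, "capital_demand": capital_demand,
        "income": income,
    }


def _residuals(params: CGEParams, logp: np.ndarray) -> np.ndarray:
    R, S = params.shape
    ev = _evaluate(params, logp)
    zero_profit = (ev["p"] / ev["unit_cost"] - 1.0).reshape(R * S)
    lab = ev["labour_demand"] / params.labour - 1.0
    cap = ev["capital_demand"] / params.capital - 1.0
    # numeraire: region 0 factor price index = 1 (replaces region 0 capital market)
    l0, k0 = params.labour[0], params.capital[0]
    numeraire = (ev["w"][0] * l0 + ev["rk"][0] * k0) / (l0 + k0) - 1.0
    return np.concatenate([zero_profit, lab, cap[1:], [numeraire]])


def solve(params: CGEParams) -> EquilibriumSolution:
    """Solve for the comparative-static equilibrium from the benchmark point."""
    R, S = params.shape
    x0 = np.zeros(R * S + 2 * R)
    sol = root(lambda x: _residuals(params, x), x0, method="hybr", tol=1e-12)
    res = _residuals(params, sol.x)
    norm = float(np.max(np.abs(res)))
    if norm > RESIDUAL_TOL:
        raise ConvergenceError(
            f"equilibrium solve did not converge (max residual {norm:.2e})",
            residual=norm,
            iterations=int(sol.nfev),
        )
    ev = _evaluate(params, sol.x)
    # Walras diagnostic: value of factor excess demand (region 0 capital market
    # was replaced by the numeraire; at the solution it must clear by identity)
    walras = float(
        abs(
            (ev["w"] * (ev["labour_demand"] - params.labour)).sum()
            + (ev["rk"] * (ev["capital_demand"] - params.capital)).sum()
        )
        / params.x_bar.sum()
    )
    return EquilibriumSolution(
        prices=ev["p"],
        wage=ev["w"],
        rent=ev["rk"],
        output=ev["X"],
        va_quantity=ev["va_q"],
        real_gdp=ev["va_q"].sum(axis=1),
        residual_norm=norm,
        walras_residual=walras,
        iterations=int(sol.nfev),
    )


def impact_report(
    eq: EquilibriumSolution, benchmark: EquilibriumSolution, params: CGEParams
) -> pd.DataFrame:
    """Regional GDP % change with per-sector GVA percentage-point contributions.

    The sectoral contributions (change in sectoral real value added relative
    to the region's benchmark GVA, in points) sum exactly to the regional GVA
    % change.
    """
    if eq.va_quantity.shape != benchmark.va_quantity.shape:
        raise ConfigError("solutions have different economy dimensions")
    R, S = eq.va_quantity.shape
    rows = []
    for r in range(R):
        gva0 = benchmark.real_gdp[r]
        gdp_pct = 100.0 * (eq.real_gdp[r] / gva0 - 1.0)
        for s in range(S):
            rows.append(
                {
                    "region": params.regions[r],
                    "sector": params.sectors[s],
                    "gdp_pct": gdp_pct,
                    "gva_pp_contribution": 100.0
                    * (eq.va_quantity[r, s] - benchmark.va_quantity[r, s])
                    / gva0,
                }
            )
    return pd.DataFrame(rows)
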