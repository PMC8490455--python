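import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from heatecon import cge
from heatecon.cge.cresh import CreshNest
from heatecon.errors import ConfigError, HeateconError
from heatecon.exposure import ProductivityShock
from heatecon.synthetic import ToyEconomyConfig, generate_toy_economy
from heatecon.synthetic.economy import SectorSpec, ToyEconomy


def _shock(params, entries, year=2001):
    tau = pd.DataFrame(0.0, index=params.regions, columns=params.sectors)
    for (r, s), v in entries.items():
        tau.loc[r, s] = v
    return ProductivityShock(tau=tau, year=year)


def one_sector_economy(theta=0.6, output=100.0):
    """Single region, single sector, no intermediates, no saving."""
    return ToyEconomy(
        regions=["R000"],
        countries={"R000": "C00"},
        sectors=[SectorSpec("only", "low", outdoor=True, labour_share=theta)],
        output=np.array([[output]]),
        io_use=np.zeros((1, 1, 1)),
        va_labour=np.array([[theta * output]]),
        va_capital=np.array([[(1 - theta) * output]]),
        consumption=np.array([[output]]),
        investment=np.zeros((1, 1)),
        domestic=np.array([[output]]),
        trade=np.zeros((1, 1, 1)),
        saving_rate=0.0,
    )


class TestCresh:
    def test_benchmark_shares_recovered_at_unit_prices(self):
        nest = CreshNest.calibrate([0, 1, 2], [10.0, 30.0, 60.0], [5.0, 6.0, 7.0])
        y = nest.shares(np.ones(3))
        assert np.allclose(y, [0.1, 0.3, 0.6], atol=1e-10)
        assert np.isclose(nest.unit_cost(np.ones(3)), 1.0)

    def test_collapses_to_ces_when_elasticities_equal(self):
        """Oracle: numerical cost minimisation under the calibrated CES aggregator."""
        x_bar = np.array([20.0, 30.0, 50.0])
        sigma = 4.0
        nest = CreshNest.calibrate([0, 1, 2], x_bar, np.full(3, sigma))
        prices = np.array([1.3, 0.8, 1.1])
        y = nest.shares(prices)

        y_bar = x_bar / x_bar.sum()
        rho = (sigma - 1.0) / sigma

        def agg(x):
            return (y_bar @ (x / y_bar) ** rho) ** (1.0 / rho)

        res = minimize(
            lambda x: prices @ x,
            y_bar,
            constraints={"type": "eq", "fun": lambda x: agg(x) - 1.0},
            bounds=[(1e-6, None)] * 3,
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        oracle = res.x / agg(res.x)
        assert np.allclose(y / y.sum(), oracle / oracle.sum(), atol=1e-5)

    def test_pairwise_elasticities_foc_satisfied(self):
        nest = CreshNest.calibrate([0, 1], [40.0, 60.0], [3.0, 8.0])
        p = np.array([1.2, 0.9])
        y = nest.shares(p)
        # constraint of the implicit aggregator holds
        assert np.isclose(nest.B @ y**nest.h, 1.0, atol=1e-10)
        # cost-minimising bundle beats the benchmark-share bundle
        assert nest.unit_cost(p, y) <= p @ nest.base_shares + 1e-12

    def test_sigma_below_one_rejected(self):
        with pytest.raises(ConfigError):
            CreshNest.calibrate([0, 1], [1.0, 1.0], [0.5, 2.0])


class TestCalibration:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_regions": 2},
            {"n_regions": 3, "n_countries": 2, "trade_openness": 0.3, "seed": 4},
            {"n_regions": 2, "io_density": 0.5, "saving_rate": 0.2},
        ],
    )
    def test_unshocked_solve_replicates_benchmark(self, kwargs):
        eco = generate_toy_economy(ToyEconomyConfig(**kwargs))
        params = cge.calibrate(eco)
        eq = cge.solve(params)
        assert np.max(np.abs(eq.output / params.x_bar - 1.0)) < 1e-8
        assert np.max(np.abs(eq.va_quantity / params.va_bar - 1.0)) < 1e-8
        assert np.max(np.abs(eq.gdp_change_pct(eq))) < 1e-8

    def test_border_effect_raises_within_country_elasticity_by_20pct(self):
        eco = generate_toy_economy(
            ToyEconomyConfig(n_regions=4, n_countries=2, trade_openness=0.3)
        )
        params = cge.calibrate(eco, cge.ElasticityConfig(sigma_imp=5.0))
        nest = params.cresh[(0, 0)]  # destination R000 (country C00)
        sigma = 1.0 / (1.0 - nest.h)
        by_origin = dict(zip(nest.origins, sigma))
        within, cross = by_origin[1], by_origin[2]  # R001 same country, R002 other
        assert np.isclose(within / cross, 1.2)

    def test_cobb_douglas_factor_shares_match_sam(self):
        eco = generate_toy_economy(ToyEconomyConfig(n_regions=2))
        params = cge.calibrate(eco, cge.ElasticityConfig(sigma_va=1.0))
        sam_share = eco.va_labour / (eco.va_labour + eco.va_capital)
        assert np.allclose(params.share_l, sam_share)

    def test_unbalanced_sam_rejected(self, toy_economy):
        import copy

        broken = copy.deepcopy(toy_economy)
        broken.consumption[0, 0] *= 1.5
        with pytest.raises(ConfigError):
            cge.calibrate(broken)


class TestShock:
    def test_zero_shock_leaves_params_unchanged(self, toy_economy):
        params = cge.calibrate(toy_economy)
        shocked = cge.apply_shock(params, _shock(params, {}))
        assert np.array_equal(shocked.psi, params.psi)

    def test_single_cell_scaling(self, toy_economy):
        params = cge.calibrate(toy_economy)
        shocked = cge.apply_shock(params, _shock(params, {("R000", "agriculture"): 0.1}))
        assert np.isclose(shocked.psi[0, 0], 0.9)
        assert np.all(shocked.psi.ravel()[1:] == 1.0)

    def test_sequential_shocks_compose_multiplicatively(self, toy_economy):
        params = cge.calibrate(toy_economy)
        s1 = cge.apply_shock(params, _shock(params, {("R000", "services"): 0.1}))
        s2 = cge.apply_shock(s1, _shock(params, {("R000", "services"): 0.2}))
        assert np.isclose(s2.psi[0, params.sectors.index("services")], 0.9 * 0.8)

    @pytest.mark.parametrize("bad_tau", [1.0, 1.5, -0.1])
    def test_invalid_tau_rejected(self, toy_economy, bad_tau):
        params = cge.calibrate(toy_economy)
        tau = pd.DataFrame(0.0, index=params.regions, columns=params.sectors)
        tau.iloc[0, 0] = bad_tau
        with pytest.raises(ConfigError):
            ProductivityShock(tau=tau, year=2001)
        shock = ProductivityShock.__new__(ProductivityShock)  # bypass validation
        shock.tau, shock.year = tau, 2001
        with pytest.raises(ConfigError):
            cge.apply_shock(params, shock)


class TestEquilibrium:
    def test_cobb_douglas_closed_form_gdp_change(self):
        """One-sector Cobb-Douglas: real GDP change = (1−τ)^θ − 1."""
        for theta, tau in [(0.6, 0.2), (0.4, 0.05), (0.75, 0.5)]:
            eco = one_sector_economy(theta=theta)
            params = cge.calibrate(eco, cge.ElasticityConfig(sigma_va=1.0))
            bench = cge.solve(params)
            eq = cge.solve(cge.apply_shock(params, _shock(params, {("R000", "only"): tau})))
            got = eq.gdp_change_pct(bench)[0]
            expected = 100.0 * ((1.0 - tau) ** theta - 1.0)
            assert np.isclose(got, expected, atol=1e-6)

    def test_autarky_shock_does_not_transmit(self):
        eco = generate_toy_economy(ToyEconomyConfig(n_regions=2, trade_openness=0.0))
        params = cge.calibrate(eco)
        bench = cge.solve(params)
        eq = cge.solve(cge.apply_shock(params, _shock(params, {("R000", "agriculture"): 0.3})))
        change = eq.gdp_change_pct(bench)
        assert change[0] < -1e-3  # shocked region loses
        assert abs(change[1]) < 1e-8  # no transmission channel

    def test_walras_residual_small(self, toy_economy):
        params = cge.calibrate(toy_economy)
        eq = cge.solve(cge.apply_shock(params, _shock(params, {("R000", "construction"): 0.2})))
        assert eq.walras_residual < 1e-8
        assert eq.residual_norm < 1e-8

    def test_gdp_loss_monotone_in_tau(self):
        eco = generate_toy_economy(ToyEconomyConfig(n_regions=2, trade_openness=0.2))
        params = cge.calibrate(eco)
        bench = cge.solve(params)
        losses = []
        for tau in (0.0, 0.05, 0.1, 0.2, 0.4):
            eq = cge.solve(cge.apply_shock(params, _shock(params, {("R000", "agriculture"): tau})))
            total = eq.real_gdp.sum() / bench.real_gdp.sum() - 1.0
            losses.append(-total)
        assert np.all(np.diff(losses) >= -1e-12)

    def test_trade_buffers_the_shock(self):
        """Higher Armington/import elasticities weakly reduce the shocked region's loss."""
        eco = generate_toy_economy(ToyEconomyConfig(n_regions=2, trade_openness=0.3))
        shock_entries = {("R000", "agriculture"): 0.3, ("R000", "construction"): 0.3}
        losses = {}
        for label, (s_arm, s_imp) in {"low": (1.5, 3.0), "high": (6.0, 12.0)}.items():
            params = cge.calibrate(eco, cge.ElasticityConfig(sigma_arm=s_arm, sigma_imp=s_imp))
            bench = cge.solve(params)
            eq = cge.solve(cge.apply_shock(params, _shock(params, shock_entries)))
            losses[label] = -eq.gdp_change_pct(bench)[0]
        assert losses["high"] <= losses["low"] + 1e-10

    def test_numeraire_normalisation(self, toy_economy):
        params = cge.calibrate(toy_economy)
        eq = cge.solve(cge.apply_shock(params, _shock(params, {("R001", "services"): 0.1})))
        l0, k0 = params.labour[0], params.capital[0]
        index = (eq.wage[0] * l0 + eq.rent[0] * k0) / (l0 + k0)
        assert np.isclose(index, 1.0, atol=1e-10)


class TestImpactReport:
    def test_no_change_when_equal(self, toy_economy):
        params = cge.calibrate(toy_economy)
        bench = cge.solve(params)
        rep = cge.impact_report(bench, bench, params)
        assert np.allclose(rep["gdp_pct"], 0.0) and np.allclose(rep["gva_pp_contribution"], 0.0)

    def test_sectoral_contributions_sum_to_regional_change(self, toy_economy):
        params = cge.calibrate(toy_economy)
        bench = cge.solve(params)
        eq = cge.solve(
            cge.apply_shock(
                params, _shock(params, {("R000", "agriculture"): 0.3, ("R001", "services"): 0.1})
            )
        )
        rep = cge.impact_report(eq, bench, params)
        for region, grp in rep.groupby("region"):
            assert np.isclose(grp["gva_pp_contribution"].sum(), grp["gdp_pct"].iloc[0], atol=1e-10)

    def test_outdoor_shock_drags_indoor_sectors_via_intermediates(self):
        eco = generate_toy_economy(ToyEconomyConfig(n_regions=2, trade_openness=0.2))
        params = cge.calibrate(eco)
        bench = cge.solve(params)
        entries = {
            (r, s): 0.25
            for r in params.regions
            for s in ("agriculture", "construction")
        }
        eq = cge.solve(cge.apply_shock(params, _shock(params, entries)))
        rep = cge.impact_report(eq, bench, params).set_index(["region", "sector"])
        indoor = rep.loc[("R000", "services"), "gva_pp_contribution"]
        assert indoor < 0  # losses propagate to unshocked indoor sectors

    def test_dimension_mismatch_rejected(self, toy_economy):
        params = cge.calibrate(toy_economy)
        bench = cge.solve(params)
        eco1 = one_sector_economy()
        p1 = cge.calibrate(eco1, cge.ElasticityConfig(sigma_va=1.0))
        b1 = cge.solve(p1)
        with pytest.raises((ConfigError, HeateconError)):
            cge.impact_report(b1, bench, params)
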