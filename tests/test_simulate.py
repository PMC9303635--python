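"""Tests for the flat-panel chemostat growth simulator."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from phycokin import (
    AbsorptionSpectrum,
    DielLight,
    EnergyConstants,
    OperatingSchedule,
    ReactorConfig,
    SpectralDistribution,
    SpeciesParams,
    areal_productivity,
    depth_avg_growth,
    local_growth_rate,
    optimize_dilution,
    photosynthetic_efficiency,
    simulate_chemostat,
    species_params,
    yield_on_light,
)
from phycokin.simulate import SimResult

SECONDS_PER_DAY = 86400.0


def grey_picochlorum(cross: float = 0.2) -> SpeciesParams:
    sp = species_params("picochlorum")
    return SpeciesParams(
        name=sp.name,
        yield_max=sp.yield_max,
        maintenance_rate=sp.maintenance_rate,
        mu_max=sp.mu_max,
        stoichiometry=sp.stoichiometry,
        absorption=AbsorptionSpectrum.grey(cross),
    )


class TestLocalGrowthRate:
    def test_dark_decay_rate(self):
        sp = grey_picochlorum()
        assert local_growth_rate(0.0, sp) == pytest.approx(-0.079)

    def test_saturation_limit(self):
        sp = grey_picochlorum()
        assert local_growth_rate(1.0, sp) == pytest.approx(4.98 - 0.079, rel=1e-9)

    def test_hand_computed_midrange_value(self):
        # independent scalar arithmetic: phi = 4.8 m2/mol * 100e-6 mol/m2/s
        sp = grey_picochlorum()
        phi = 4.8 * 100e-6
        drive = (1.38 / 24.0) * phi * SECONDS_PER_DAY  # day^-1
        expected = 4.98 * math.tanh(drive / 4.98) - 0.079
        assert local_growth_rate(phi, sp) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.14, abs=2e-3)

    def test_bounded_between_maintenance_and_saturation(self):
        sp = grey_picochlorum()
        phis = np.logspace(-8, 0, 50)
        mu = local_growth_rate(phis, sp)
        assert np.all(mu >= -sp.maintenance_rate)
        assert np.all(mu <= sp.mu_max - sp.maintenance_rate)
        assert local_growth_rate(1e-8, sp) < sp.mu_max - sp.maintenance_rate

    def test_negative_absorption_rejected(self):
        with pytest.raises(ValueError):
            local_growth_rate(-1e-6, grey_picochlorum())


class TestDepthAvgGrowth:
    def test_dark_surface_gives_maintenance_decay(self):
        sp = grey_picochlorum()
        mu = depth_avg_growth(10.0, 0.0, sp, ReactorConfig(), SpectralDistribution.flat())
        assert mu == pytest.approx(-0.079)

    def test_optically_thin_culture_sees_surface_rate(self):
        sp = grey_picochlorum()
        rc = ReactorConfig()
        mu_avg = depth_avg_growth(1e-6, 200.0, sp, rc, SpectralDistribution.flat())
        phi0 = 4.8 * 200e-6
        assert mu_avg == pytest.approx(local_growth_rate(phi0, sp), rel=1e-6)

    def test_grey_case_matches_adaptive_quadrature_oracle(self):
        """Trapezoid depth average vs scipy adaptive quadrature (< 0.1%)."""
        sp = grey_picochlorum()
        rc = ReactorConfig(depth=0.015, n_layers=100)
        conc, i_tot = 120.0, 800.0  # mol/m3, µmol/m2/s
        a = 4.8  # m2/mol
        phi0 = a * i_tot * 1e-6
        y = sp.yield_max_molar * SECONDS_PER_DAY

        def integrand(z: float) -> float:
            phi = phi0 * math.exp(-a * conc * z)
            return sp.mu_max * math.tanh(y * phi / sp.mu_max) - sp.maintenance_rate

        # sanity-check the quadrature machinery against the exact log-cosh
        # identity for the light-weighted integrand ∫ tanh(g)·g dz
        k = a * conc
        g0 = y * phi0 / sp.mu_max
        exact = (1.0 / k) * (
            math.log(math.cosh(g0)) - math.log(math.cosh(g0 * math.exp(-k * rc.depth)))
        )
        weighted, _ = quad(
            lambda z: math.tanh(g0 * math.exp(-k * z)) * g0 * math.exp(-k * z),
            0.0, rc.depth,
        )
        assert weighted == pytest.approx(exact, rel=1e-9)

        oracle, _ = quad(integrand, 0.0, rc.depth)
        oracle /= rc.depth
        mu = depth_avg_growth(conc, i_tot, sp, rc, SpectralDistribution.flat())
        assert mu == pytest.approx(oracle, rel=1e-3)

    def test_layer_refinement_converged(self):
        sp = grey_picochlorum()
        shape = SpectralDistribution.flat()
        coarse = depth_avg_growth(150.0, 1000.0, sp, ReactorConfig(n_layers=100), shape)
        fine = depth_avg_growth(150.0, 1000.0, sp, ReactorConfig(n_layers=200), shape)
        assert fine == pytest.approx(coarse, rel=1e-3)


class TestSimulateChemostat:
    def test_dark_decay_is_exponential(self):
        """In darkness with no dilution the density decays at the maintenance rate."""
        sp = grey_picochlorum()
        sched = OperatingSchedule(daily_dilution=0.0, initial_biomass=2.0, n_days=2, dt=300.0)
        res = simulate_chemostat(
            sp, ReactorConfig(n_layers=10), sched,
            DielLight(peak_irradiance=0.0), SpectralDistribution.flat(),
        )
        one_day = int(SECONDS_PER_DAY / 300.0)
        factor = res.biomass_conc[one_day] / res.biomass_conc[0]
        assert factor == pytest.approx(math.exp(-0.079), rel=1e-6)
        assert factor == pytest.approx(0.9240, abs=5e-5)

    def test_constant_light_steady_state_matches_root_oracle(self):
        """Under constant light and dilution, C_x settles where µ(C_x) = D."""
        sp = grey_picochlorum()
        rc = ReactorConfig(n_layers=50)
        shape = SpectralDistribution.flat()
        light = DielLight(peak_irradiance=150.0, constant=True)
        d_rate = 0.3

        c_star = brentq(
            lambda c: depth_avg_growth(c, 150.0, sp, rc, shape) - d_rate,
            1.0, 2000.0, rtol=1e-12,
        )
        c0_gl = c_star * 24.0 / 1000.0 * 1.05
        sched = OperatingSchedule(
            daily_dilution=d_rate, initial_biomass=c0_gl,
            daylight_only=False, n_days=25, dt=480.0,
        )
        res = simulate_chemostat(sp, rc, sched, light, shape)
        assert res.biomass_conc[-1] == pytest.approx(c_star, rel=1e-3)
        # harvest bookkeeping: M_x(T) equals the integral of D·C_x dt
        harvest_quad = np.trapezoid(res.dilution * res.biomass_conc, res.time_days)
        assert res.harvested[-1] == pytest.approx(harvest_quad, rel=1e-3)

    def test_rk4_step_halving_converged(self):
        sp = grey_picochlorum()
        rc = ReactorConfig(n_layers=30)
        shape = SpectralDistribution.flat()
        ends = []
        for dt in (120.0, 60.0):
            sched = OperatingSchedule(daily_dilution=0.68, initial_biomass=2.9,
                                      n_days=1, dt=dt)
            with pytest.warns(UserWarning, match="pseudo-steady"):
                res = simulate_chemostat(sp, rc, sched, DielLight(), shape)
            ends.append(res.biomass_conc[-1])
        assert ends[1] == pytest.approx(ends[0], rel=5e-4)

    def test_headline_scenarios_reach_pseudo_steady(self, headline_sims):
        for key in ("picochlorum", "neochloris"):
            res = headline_sims[key]
            assert res.pseudo_steady
            assert np.all(np.diff(res.harvested) >= 0)
            assert np.all(res.biomass_conc > 0)

    def test_one_day_run_is_not_pseudo_steady(self):
        sp = grey_picochlorum()
        sched = OperatingSchedule(daily_dilution=0.5, initial_biomass=2.9, n_days=1, dt=600.0)
        with pytest.warns(UserWarning, match="pseudo-steady"):
            res = simulate_chemostat(sp, ReactorConfig(n_layers=10), sched,
                                     DielLight(), SpectralDistribution.flat())
        assert not res.pseudo_steady


def _fake_result(d_cx: float, d_mx: float) -> SimResult:
    steps = 1440
    t = np.arange(2 * steps + 1) / steps
    cx = np.full(t.size, 100.0)
    cx[steps:] += np.linspace(0.0, d_cx, steps + 1)
    mx = np.zeros(t.size)
    mx[steps:] = np.linspace(0.0, d_mx, steps + 1)
    return SimResult(
        time_days=t, biomass_conc=cx, harvested=mx,
        irradiance=np.zeros(t.size), dilution=np.zeros(t.size),
        areal_productivity=np.nan, areal_productivity_mol=np.nan,
        yield_on_light=np.nan, pe_percent=np.nan, daily_dose=52.25,
        pseudo_steady=True,
    )


class TestProductivityMetrics:
    def test_areal_productivity_arithmetic(self):
        # ΔC_x = 0, ΔM_x = 89.5 mol/m3 over the last day, l = 0.015 m
        res = _fake_result(0.0, 89.5)
        r = areal_productivity(res, ReactorConfig(depth=0.015))
        assert r == pytest.approx(1.3425, rel=1e-9)
        assert r * 24.0 == pytest.approx(32.22, rel=1e-3)

    def test_no_harvest_no_growth_is_zero(self):
        res = _fake_result(0.0, 0.0)
        assert areal_productivity(res, ReactorConfig(depth=0.015)) == 0.0

    def test_linear_in_depth(self):
        res = _fake_result(10.0, 50.0)
        r1 = areal_productivity(res, ReactorConfig(depth=0.015))
        r2 = areal_productivity(res, ReactorConfig(depth=0.030))
        assert r2 == pytest.approx(2.0 * r1, rel=1e-12)

    def test_short_trajectory_rejected(self):
        res = _fake_result(0.0, 1.0)
        short = SimResult(
            time_days=res.time_days[:100], biomass_conc=res.biomass_conc[:100],
            harvested=res.harvested[:100], irradiance=res.irradiance[:100],
            dilution=res.dilution[:100], areal_productivity=np.nan,
            areal_productivity_mol=np.nan, yield_on_light=np.nan,
            pe_percent=np.nan, daily_dose=52.25, pseudo_steady=False,
        )
        with pytest.raises(ValueError):
            areal_productivity(short, ReactorConfig())

    def test_yield_on_light_division(self):
        y = yield_on_light(1.3425, 52.25)
        assert y == pytest.approx(0.025693, rel=1e-3)
        assert y * 24.0 == pytest.approx(0.61664, rel=1e-3)

    def test_yield_zero_productivity(self):
        assert yield_on_light(0.0, 52.25) == 0.0

    def test_yield_requires_positive_dose(self):
        with pytest.raises(ValueError):
            yield_on_light(1.0, 0.0)

    def test_observed_yield_below_maximal_yield(self, headline_sims):
        for key, res in headline_sims.items():
            sp = species_params(key)
            assert res.yield_on_light < sp.yield_max

    def test_photosynthetic_efficiency_hand_value(self):
        # 100 * 32.2 * 22.5 / (52.25375 * 217.5 / 0.43) = 2.741 %
        pe = photosynthetic_efficiency(32.2, 52.25375, EnergyConstants())
        assert pe == pytest.approx(2.741, abs=2e-3)

    def test_pe_linear_in_productivity(self):
        pe1 = photosynthetic_efficiency(10.0, 52.25)
        pe2 = photosynthetic_efficiency(20.0, 52.25)
        assert pe2 == pytest.approx(2.0 * pe1, rel=1e-12)
        assert photosynthetic_efficiency(0.0, 52.25) == 0.0


class TestOptimizeDilution:
    def test_productivity_curve_is_unimodal(self):
        sp = grey_picochlorum()
        rc = ReactorConfig(n_layers=40)
        shape = SpectralDistribution.flat()
        with pytest.warns(UserWarning):
            d_star, r_star, curve = optimize_dilution(
                sp, rc, DielLight(), shape,
                search_range=(0.3, 1.1), resolution=0.2,
                initial_biomass=2.9, n_days=4, dt=240.0,
            )
        values = [curve[d] for d in sorted(curve)]
        diffs = np.diff(values)
        # rises to one peak, then falls: at most one sign change
        signs = np.sign(diffs[diffs != 0])
        assert np.sum(np.diff(signs) != 0) <= 1
        assert r_star == pytest.approx(max(values))
        assert 0.3 <= d_star <= 1.1

    def test_empty_grid_rejected(self):
        sp = grey_picochlorum()
        with pytest.raises(ValueError):
            optimize_dilution(sp, ReactorConfig(), DielLight(),
                              SpectralDistribution.flat(), resolution=-1.0)
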