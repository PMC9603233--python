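"""Ventilation, settling and SRMM droplet-evaporation rates."""

import numpy as np
import pytest

from spraymix.aerosol import (
    composition_derivative,
    diameter_derivative,
    droplet_count,
    droplet_density,
    droplet_evaporation_rates,
    equilibrium_concentrations,
    mass_fraction_1,
    settling_loss_rate,
    settling_velocity,
    ventilation_loss_rate,
)
from spraymix.fixtures import toy_components
from spraymix.physchem import Environment, R_GAS

ENV = Environment(T_room=293.0, T_dr=293.0)
T = 293.0


class TestSimpleRates:
    def test_ventilation_rate(self):
        assert ventilation_loss_rate(1e-3, 0.125) == pytest.approx(1.25e-4)
        assert ventilation_loss_rate(0.0, 0.125) == 0.0
        assert ventilation_loss_rate(1e-3, 0.0) == 0.0

    def test_settling_velocity_reference(self):
        v = settling_velocity(100e-6, 1000.0, ENV, warn=False)
        assert v == pytest.approx(0.29945, rel=1e-4)
        assert settling_velocity(0.0, 1000.0, ENV, warn=False) == 0.0

    def test_settling_quadratic_in_diameter(self):
        v1 = settling_velocity(25e-6, 1000.0, ENV, warn=False)
        v2 = settling_velocity(50e-6, 1000.0, ENV, warn=False)
        assert v2 == pytest.approx(4.0 * v1)

    def test_large_droplet_warning(self):
        with pytest.warns(UserWarning, match="Stokes"):
            settling_velocity(200e-6, 1000.0, ENV)

    def test_settling_loss_rate_identity_and_split(self):
        comps = toy_components(psat1=2308.0, psat2=0.0)
        total, per_comp = settling_loss_rate(1e-3, 100e-6, 0.8, 60.0, comps, ENV)
        rho = droplet_density(0.8, comps)
        v = settling_velocity(100e-6, rho, ENV, warn=False)
        assert total == pytest.approx(60.0 * v * 1e-3)
        assert per_comp.sum() == pytest.approx(total)

    def test_droplet_count_reference_and_inverse(self):
        n = droplet_count(1e-3, 150.0, 100e-6, 1000.0)
        assert n == pytest.approx(2.8648e8, rel=1e-4)
        # inverting the count reproduces the concentration
        A = n * (np.pi / 6) * (100e-6) ** 3 * 1000.0 / 150.0
        assert A == pytest.approx(1e-3)


class TestEvaporationRates:
    def test_zero_at_equilibrium(self):
        comps = toy_components(psat1=2308.0, psat2=179.0)
        x1 = 0.7
        C_eq = equilibrium_concentrations(x1, comps, T)
        rates = droplet_evaporation_rates(1e-3, 50e-6, x1, C_eq, comps, 150.0, T)
        np.testing.assert_allclose(rates, 0.0, atol=1e-20)

    def test_pure_component_one_gives_zero_for_two(self):
        comps = toy_components(psat1=2308.0, psat2=179.0)
        rates = droplet_evaporation_rates(1e-3, 50e-6, 1.0, (0.0, 0.0), comps, 150.0, T)
        assert rates[1] == 0.0
        assert rates[0] > 0

    def test_zero_aerosol_zero_rates(self):
        comps = toy_components(psat1=2308.0, psat2=179.0)
        rates = droplet_evaporation_rates(0.0, 50e-6, 0.5, (0.0, 0.0), comps, 150.0, T)
        np.testing.assert_allclose(rates, 0.0)

    def test_d2_law_lifetime_from_diameter_derivative(self):
        # pure volatile, zero backpressure: d^2 decays linearly; the 50 um
        # lifetime follows the closed form d0^2 R T / (8 p* Vm D)
        comps = toy_components(psat1=2308.0, psat2=0.0, Vm=(1.8e-5, 3e-5), D=(2.4e-5, 1e-5))
        tau_closed = (50e-6) ** 2 * R_GAS * T / (8 * 2308.0 * 1.8e-5 * 2.4e-5)
        assert tau_closed == pytest.approx(0.7636, abs=2e-3)
        d, t, dt = 50e-6, 0.0, 1e-5
        while d > 1e-6:
            d += dt * diameter_derivative(d, 1.0, (0.0, 0.0), comps, T)
            t += dt
        assert t == pytest.approx(tau_closed, rel=1e-2)


class TestDerivatives:
    def test_diameter_derivative_pure_limit(self):
        comps = toy_components(psat1=2308.0, psat2=0.0)
        dd = diameter_derivative(50e-6, 1.0, (0.0, 0.0), comps, T)
        expected = -4 * 2308.0 * 1.8e-5 * (2.4e-5 / (R_GAS * T)) / 50e-6
        assert dd == pytest.approx(expected, rel=1e-12)

    def test_identical_components_symmetric(self):
        comps = toy_components(
            psat1=1000.0, psat2=1000.0, M=(0.02, 0.02), Vm=(2e-5, 2e-5), D=(1e-5, 1e-5)
        )
        for x1 in (0.2, 0.5, 0.9):
            dd = diameter_derivative(40e-6, x1, (0.0, 0.0), comps, T)
            dd_pure = diameter_derivative(40e-6, 1.0, (0.0, 0.0), comps, T)
            assert dd == pytest.approx(dd_pure, rel=1e-12)
            assert composition_derivative(40e-6, x1, (0.0, 0.0), comps, T) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_volatile_fraction_depletes(self):
        comps = toy_components(psat1=2308.0, psat2=0.0)
        dx = composition_derivative(50e-6, 0.6, (0.0, 0.0), comps, T)
        assert dx < 0

    def test_composition_derivative_matches_mole_balance_oracle(self, rng):
        # independent oracle: evolve the per-droplet mole contents with the
        # raw fluxes and differentiate x1 = n1/(n1+n2) numerically
        comps = toy_components(psat1=2308.0, psat2=179.0)
        M = np.array([c.M for c in comps])
        D = np.array([c.D for c in comps])
        for _ in range(20):
            d = rng.uniform(5e-6, 200e-6)
            x1 = rng.uniform(0.05, 0.95)
            C = rng.uniform(0.0, 0.015, size=2) * np.array([1.0, 0.1])
            C_eq = equilibrium_concentrations(x1, comps, T)
            flux_n = -2 * np.pi * d * D * (C_eq - C) / M      # mol/s per droplet
            Vm = np.array([c.Vm for c in comps])
            n_tot = (np.pi / 6) * d**3 / (Vm[0] * x1 + Vm[1] * (1 - x1))
            n = n_tot * np.array([x1, 1 - x1])
            h = 1e-7
            n_new = n + h * flux_n
            fd = (n_new[0] / n_new.sum() - x1) / h
            dx = composition_derivative(d, x1, C, comps, T)
            assert dx == pytest.approx(fd, rel=1e-4, abs=1e-12)

    def test_mass_rate_consistency_of_rate_and_geometry_equations(self, rng):
        # total mass change implied by the d and x1 derivatives must equal
        # the sum of the two component evaporation rates
        comps = toy_components(psat1=2308.0, psat2=179.0)
        V_room = 150.0
        for _ in range(20):
            d = rng.uniform(5e-6, 200e-6)
            x1 = rng.uniform(0.05, 0.95)
            A = rng.uniform(1e-6, 1e-3)
            C = rng.uniform(0.0, 0.01, size=2) * np.array([1.0, 0.05])
            rho = droplet_density(x1, comps)
            n_dr = 6 * A * V_room / (np.pi * rho * d**3)
            dd = diameter_derivative(d, x1, C, comps, T)
            dx = composition_derivative(d, x1, C, comps, T)
            # per-droplet mass m = (pi/6) d^3 rho(x1); chain rule
            h = 1e-8
            m0 = (np.pi / 6) * d**3 * droplet_density(x1, comps)
            m1 = (np.pi / 6) * (d + h * dd) ** 3 * droplet_density(x1 + h * dx, comps)
            dm_dt_geom = n_dr * (m1 - m0) / h
            rates = droplet_evaporation_rates(A, d, x1, C, comps, V_room, T)
            assert -rates.sum() == pytest.approx(dm_dt_geom, rel=1e-5)

    def test_dry_residue_component_mass_conserved(self):
        # with a nonvolatile second component and no backpressure, the
        # second component's pulse mass is invariant while d and x1 evolve
        comps = toy_components(psat1=2308.0, psat2=0.0)
        V_room = 150.0
        d, x1 = 60e-6, 0.995
        rho = droplet_density(x1, comps)
        n_dr = 6 * 1e-3 * V_room / (np.pi * rho * d**3)
        dt = 1e-4
        mass2_0 = None
        for _ in range(2000):
            rho = droplet_density(x1, comps)
            m_pulse = n_dr * (np.pi / 6) * d**3 * rho
            mass2 = m_pulse * (1 - mass_fraction_1(x1, comps))
            if mass2_0 is None:
                mass2_0 = mass2
            d += dt * diameter_derivative(d, x1, (0.0, 0.0), comps, T)
            x1 += dt * composition_derivative(d, x1, (0.0, 0.0), comps, T)
        assert mass2 == pytest.approx(mass2_0, rel=1e-3)
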