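"""Stability indicator, capillary length, formation energy and energy oracle."""

import math

import numpy as np
import pytest

import conepocket as cp

from test_equilibrium import random_positive_pressure_inputs

DEG = math.pi / 180.0


class TestCapillaryLength:
    def test_liquid_iron(self, iron_corundum):
        """sigma=1.6 N/m, rho=7000 kg/m^3: l_c rounds to 4.8 mm."""
        assert cp.capillary_length(iron_corundum) * 1e3 == pytest.approx(4.8, abs=0.1)

    def test_unit_construction(self):
        """sigma = rho * g numerically gives exactly one metre."""
        system = cp.FluidSolidSystem(sigma=9810.0, rho=1000.0, theta=1.0, p_l=0.0, g=9.81)
        assert cp.capillary_length(system) == pytest.approx(1.0, rel=1e-12)

    def test_water(self):
        system = cp.FluidSolidSystem(sigma=0.0728, rho=998.0, theta=1.0, p_l=0.0)
        assert cp.capillary_length(system) * 1e3 == pytest.approx(2.7, abs=0.05)

    def test_scaling_homogeneity(self):
        """l_c is homogeneous of degree 1/2 in sigma and -1/2 in rho*g."""
        base = cp.FluidSolidSystem(sigma=0.5, rho=1200.0, theta=1.0, p_l=0.0, g=9.81)
        l0 = cp.capillary_length(base)
        for k in (0.25, 4.0, 9.0):
            up_sigma = cp.FluidSolidSystem(sigma=k * 0.5, rho=1200.0, theta=1.0, p_l=0.0)
            up_rho = cp.FluidSolidSystem(sigma=0.5, rho=k * 1200.0, theta=1.0, p_l=0.0)
            assert cp.capillary_length(up_sigma) == pytest.approx(math.sqrt(k) * l0)
            assert cp.capillary_length(up_rho) == pytest.approx(l0 / math.sqrt(k))


class TestStabilityPsi:
    def test_flat_interface_psi_is_pressure_over_volume(self, flat_case):
        """With H identically small, dH/ds ~ 0 and Psi reduces to p_g / V."""
        system, cavity, nrt = flat_case
        pocket = cp.equilibrium_radius(system, cavity, nrt).pocket
        report = cp.stability_psi(pocket)
        assert report.psi == pytest.approx(pocket.gas.p_g / pocket.cap.V, rel=1e-6)
        assert report.stable

    def test_all_cone_equilibria_stable_under_positive_pressure(self):
        """Psi > 0 for every p_l > 0 equilibrium, both curvature signs."""
        rng = np.random.default_rng(37)
        seen = {1.0: 0, -1.0: 0}
        for system, cavity, nrt in random_positive_pressure_inputs(rng, 100):
            result = cp.equilibrium_radius(system, cavity, nrt)
            for pocket in result.pockets + result.overfilled:
                report = cp.stability_psi(pocket)
                assert report.psi > 0.0
                if pocket.cap.H != 0.0:
                    seen[math.copysign(1.0, pocket.cap.H)] += 1
        assert seen[1.0] > 0 and seen[-1.0] > 0

    def test_dhdv_analytic_matches_finite_differences(self):
        rng = np.random.default_rng(41)
        for system, cavity, nrt in random_positive_pressure_inputs(rng, 40):
            result = cp.equilibrium_radius(system, cavity, nrt)
            for pocket in result.pockets + result.overfilled:
                report = cp.stability_psi(pocket)
                scale = max(abs(report.dH_dV_analytic), abs(report.dH_dV_numeric))
                assert abs(report.dH_dV_analytic - report.dH_dV_numeric) <= 1e-4 * scale

    def test_capillary_bound_flag(self, iron_corundum):
        small = cp.ConeCavity(epsilon=30 * DEG, s_c=2.5e-3)
        large = cp.ConeCavity(epsilon=30 * DEG, s_c=10e-3)
        for cavity, expected in ((small, True), (large, False)):
            nrt = cp.gas_content_from_fill(cavity, 1e5, 0.5)
            pocket = cp.equilibrium_radius(iron_corundum, cavity, nrt).pocket
            assert cp.stability_psi(pocket).within_capillary_bound is expected

    def test_psi_sign_matches_curvature_response(self):
        """Recomputing Psi with the finite-difference dH/dV (the geometric
        response of curvature to a contact-line shift) reproduces the
        stable/unstable classification, including the unstable tension root."""
        system = cp.FluidSolidSystem(sigma=0.0728, rho=998.0, theta=60 * DEG, p_l=-1e5)
        cavity = cp.ConeCavity(epsilon=30 * DEG, s_c=5e-6)
        result = cp.equilibrium_radius(system, cavity, 4e-14)
        flags = []
        for pocket in result.pockets:
            report = cp.stability_psi(pocket)
            psi_fd = pocket.gas.p_g / pocket.cap.V + (
                2 * system.sigma * report.dH_dV_numeric
            )
            assert (psi_fd > 0) == report.stable
            flags.append(report.stable)
        assert sorted(flags) == [False, True]


class TestFormationEnergy:
    def test_boundary_cancels_exactly(self):
        """On theta = epsilon + 90 deg: H=0, A_lg = pi s^2, A_sg cos(theta) = -pi s^2."""
        for eps_deg in (1.0, 15.0, 30.0, 60.0, 85.0):
            eps = eps_deg * DEG
            system = cp.FluidSolidSystem(
                sigma=1.6, rho=7000.0, theta=eps + math.pi / 2, p_l=1e5
            )
            cavity = cp.ConeCavity(epsilon=eps, s_c=2e-3)
            report = cp.formation_energy(2e-3, system, cavity)
            assert abs(report.delta_E) < 1e-12 * system.sigma * (2e-3) ** 2

    def test_prototype_is_ferrophobic(self, iron_corundum, prototype_cavity):
        """theta=130, eps=30: the air pocket is the favourable state."""
        report = cp.formation_energy(2.5e-3, iron_corundum, prototype_cavity)
        assert report.delta_E < 0.0
        assert report.ferrophobic

    @pytest.mark.parametrize("eps_deg", [5.0, 20.0, 45.0, 70.0, 85.0])
    def test_iron_on_copper_always_wets(self, iron_copper, eps_deg):
        """theta=37 deg: wetting is favourable in every cone."""
        cavity = cp.ConeCavity(epsilon=eps_deg * DEG, s_c=2.5e-3)
        report = cp.formation_energy(2.5e-3, iron_copper, cavity)
        assert report.delta_E > 0.0
        assert not report.ferrophobic

    def test_components_sum_to_total(self):
        rng = np.random.default_rng(43)
        for system, cavity, _ in random_positive_pressure_inputs(rng, 30):
            report = cp.formation_energy(cavity.s_c, system, cavity)
            total = report.delta_E_V + report.delta_E_lg + report.delta_E_sg
            assert report.delta_E == pytest.approx(total, rel=1e-12)

    def test_sign_matches_flag_off_boundary(self):
        rng = np.random.default_rng(47)
        for system, cavity, _ in random_positive_pressure_inputs(rng, 50):
            if abs(system.theta - cavity.epsilon - math.pi / 2) < 1e-3:
                continue
            report = cp.formation_energy(cavity.s_c, system, cavity)
            assert (report.delta_E < 0) == report.ferrophobic


class TestAngleCriteria:
    def test_prototype_admissible(self):
        assert cp.ferrophobicity_criterion(130 * DEG, 30 * DEG)

    def test_boundary_excluded(self):
        """theta = eps + 90 exactly is not admissible (strict inequality)."""
        assert not cp.ferrophobicity_criterion(130 * DEG, 40 * DEG)

    def test_wetting_iron(self):
        assert not cp.ferrophobicity_criterion(37 * DEG, 1 * DEG)

    def test_interval_iron_corundum(self):
        """theta = 130 deg restricts the cone to 0 < eps < 40 deg."""
        interval = cp.admissible_cone_angles(130 * DEG)
        assert math.degrees(interval.upper) == pytest.approx(40.0, rel=1e-12)
        assert interval.contains(30 * DEG) and not interval.contains(45 * DEG)

    @pytest.mark.parametrize("theta_deg", [90.0, 45.0, 0.0])
    def test_interval_empty_at_or_below_90(self, theta_deg):
        assert cp.admissible_cone_angles(theta_deg * DEG).is_empty

    def test_interval_maximal_contact_angle(self):
        interval = cp.admissible_cone_angles(math.pi)
        assert math.degrees(interval.upper) == pytest.approx(90.0)


class TestEnergyProfile:
    def test_flat_case_argmin_at_millimetre(self, flat_case):
        """Grid minimisation recovers the constructed 1 mm equilibrium."""
        system, cavity, nrt = flat_case
        grid = np.linspace(3e-3 / 10_000, 3e-3, 10_000)
        profile = cp.energy_profile(system, cavity, nrt, grid)
        s_min = float(profile["s"].iloc[int(profile["E_total"].idxmin())])
        assert abs(s_min - 1e-3) <= grid[1] - grid[0]

    def test_no_root_case_has_no_interior_minimum(self):
        """When the cubic has no positive root the landscape is minimum-free."""
        system = cp.FluidSolidSystem(sigma=0.0728, rho=998.0, theta=60 * DEG, p_l=-1e5)
        cavity = cp.ConeCavity(epsilon=30 * DEG, s_c=5e-6)
        assert not cp.equilibrium_radius(system, cavity, 1e-12).exists
        grid = np.linspace(5e-6 / 4000, 5e-6 * 3, 4000)
        minima, _ = cp.profile_stationary_points(
            cp.energy_profile(system, cavity, 1e-12, grid)
        )
        assert minima.size == 0

    def test_gauge_invariance_of_argmin(self, flat_case):
        """Adding a constant reference offset cannot move the minimum."""
        system, cavity, nrt = flat_case
        grid = np.linspace(3e-3 / 4000, 3e-3, 4000)
        profile = cp.energy_profile(system, cavity, nrt, grid)
        shifted = profile["E_total"] + 12.34
        assert int(profile["E_total"].idxmin()) == int(shifted.idxmin())

    def test_tension_roots_are_min_then_max(self):
        """Two tension equilibria: the stable one is the landscape minimum,
        the unstable one the maximum, each within one grid step."""
        system = cp.FluidSolidSystem(sigma=0.0728, rho=998.0, theta=60 * DEG, p_l=-1e5)
        cavity = cp.ConeCavity(epsilon=30 * DEG, s_c=5e-6)
        result = cp.equilibrium_radius(system, cavity, 4e-14)
        roots = sorted(p.s for p in result.pockets)
        grid = np.linspace(2e-8, 3e-6, 30_000)
        minima, maxima = cp.profile_stationary_points(
            cp.energy_profile(system, cavity, 4e-14, grid)
        )
        step = grid[1] - grid[0]
        assert len(minima) == 1 and len(maxima) == 1
        assert abs(grid[minima[0]] - roots[0]) <= step
        assert abs(grid[maxima[0]] - roots[1]) <= step

    def test_rejects_bad_grid(self, flat_case):
        system, cavity, nrt = flat_case
        with pytest.raises(ValueError):
            cp.energy_profile(system, cavity, nrt, np.array([2e-3, 1e-3]))
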