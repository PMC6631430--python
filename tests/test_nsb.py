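import numpy as np
import pytest

import brushflow as bf
from brushflow.constants import EPS0, NM, V_PER_NM
from brushflow.electrolyte import gouy_chapman_potential
from brushflow.grid import GridProfile
from brushflow.nsb import (NSBParams, charge_density, hindrance_K, solve_nsb,
                           viscosity_profile, volume_fraction)

from helpers import segments_to_nodes, solve_piecewise_constant_bvp


def flat(z, value, unit=""):
    return GridProfile(z, np.full_like(z, float(value)), unit)


@pytest.fixture(scope="module")
def zgrid():
    return np.linspace(0.0, 20.0, 2001)


class TestVolumeFraction:
    def test_zero_density(self, zgrid):
        phi = volume_fraction(flat(zgrid, 0.0, "nm^-3"), a0=0.156)
        assert np.all(phi.values == 0)

    def test_hand_value(self, zgrid):
        # (4 pi / 3) * 0.156^3 * 10 = 0.15899...
        phi = volume_fraction(flat(zgrid, 10.0, "nm^-3"), a0=0.156)
        expected = 4.0 * np.pi / 3.0 * 0.156**3 * 10.0
        np.testing.assert_allclose(phi.values, expected)
        assert expected == pytest.approx(0.159, abs=5e-4)

    def test_linear_in_density(self, zgrid):
        n1 = flat(zgrid, 2.0, "nm^-3")
        phi1 = volume_fraction(n1, 0.156)
        phi2 = volume_fraction(n1.with_values(2 * n1.values), 0.156)
        np.testing.assert_allclose(phi2.values, 2 * phi1.values)

    def test_negative_density_rejected(self, zgrid):
        with pytest.raises(ValueError):
            volume_fraction(flat(zgrid, -1.0), 0.156)

    def test_unphysical_packing_warns(self, zgrid):
        with pytest.warns(UserWarning, match="close packing"):
            volume_fraction(flat(zgrid, 100.0, "nm^-3"), 0.156)


class TestViscosity:
    def test_pure_solvent(self, zgrid):
        mu = viscosity_profile(flat(zgrid, 0.0), mu0=0.85e-3)
        np.testing.assert_allclose(mu.values, 0.85e-3)

    def test_einstein_coefficient(self, zgrid):
        mu = viscosity_profile(flat(zgrid, 0.1), mu0=1.0e-3)
        np.testing.assert_allclose(mu.values, 1.25e-3)

    def test_monotone_in_phi(self, zgrid):
        phi = GridProfile(zgrid, np.linspace(0, 0.5, len(zgrid)))
        mu = viscosity_profile(phi, 1e-3)
        assert np.all(np.diff(mu.values) >= 0)

    def test_rejects_phi_at_one(self, zgrid):
        with pytest.raises(ValueError):
            viscosity_profile(flat(zgrid, 1.0), 1e-3)


class TestHindrance:
    def test_isolated_sphere_limit(self):
        assert hindrance_K(0.0) == pytest.approx(1.0)
        assert hindrance_K(0.0, model="unity") == 1.0

    def test_strictly_increasing_with_crowding(self):
        K1, K2 = hindrance_K(0.1), hindrance_K(0.2)
        assert K2 > K1 > 1.0
        phis = np.linspace(0.0, 0.64, 65)
        assert np.all(np.diff(hindrance_K(phis)) > 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            hindrance_K(0.7)
        with pytest.raises(ValueError):
            hindrance_K(-0.01)


class TestChargeDensity:
    def test_symmetric_bulk_is_neutral(self, zgrid):
        c = flat(zgrid, 0.034, "mol/L")
        rho = charge_density({+1: c, -1: c})
        np.testing.assert_allclose(rho.values, 0.0, atol=1e-10)

    def test_faraday_times_concentration(self, zgrid):
        rho = charge_density({+1: flat(zgrid, 1.0, "mol/m^3")})
        np.testing.assert_allclose(rho.values, 96485.33, rtol=1e-4)

    def test_valence_sign_flip_negates(self, zgrid):
        cp, cm = flat(zgrid, 0.05, "mol/L"), flat(zgrid, 0.02, "mol/L")
        rho = charge_density({+1: cp, -1: cm})
        flipped = charge_density({-1: cp, +1: cm})
        np.testing.assert_allclose(flipped.values, -rho.values)

    def test_grid_mismatch_rejected(self, zgrid):
        other = GridProfile(np.linspace(0, 20, 101), np.full(101, 1.0), "mol/L")
        with pytest.raises(ValueError, match="grid"):
            charge_density({+1: flat(zgrid, 1.0, "mol/L"), -1: other})


def piecewise_instance(rng, z, width=20.0, n_segs=3):
    """Random piecewise-constant (mu, n, rho) profiles plus their exact
    half-slit solution via the independent closed-form oracle.

    Also returns a builder that samples the same instance onto another
    grid (segment interfaces sit at cell faces of ``z``)."""
    params = NSBParams(a_bead=0.019, hindrance_model="unity", Eext=1.6e-2, width=width)
    half = width / 2.0
    m = (len(z) - 1) // 2
    h = z[1] - z[0]
    # segment interfaces at cell faces so nodes never sit on a jump
    faces = np.sort(rng.choice(np.arange(1, m - 1), size=n_segs - 1, replace=False)) + 0.5
    fracs = faces * h / half
    mu_vals = rng.uniform(0.5e-3, 2.0e-3, n_segs)
    n_vals = rng.uniform(0.0, 6.0, n_segs)
    rho_vals = rng.uniform(-4e6, 4e6, n_segs)

    def build(z_any):
        return (GridProfile(z_any, segments_to_nodes(z_any, width, fracs, mu_vals), "Pa s"),
                GridProfile(z_any, segments_to_nodes(z_any, width, fracs, n_vals), "nm^-3"),
                GridProfile(z_any, segments_to_nodes(z_any, width, fracs, rho_vals), "C/m^3"))

    mu, n, rho = build(z)
    boundaries = np.concatenate([[0.0], fracs * half, [half]]) * NM
    c_vals = 6.0 * np.pi * mu_vals * (n_vals * 1e27) * (params.a_bead * NM)
    f_vals = rho_vals * params.Eext * V_PER_NM
    oracle = solve_piecewise_constant_bvp(boundaries, mu_vals, c_vals, f_vals)
    return params, mu, n, rho, oracle, build


class TestSolver:
    def test_zero_field_gives_zero_flow(self, zgrid):
        params = NSBParams(Eext=0.0)
        mu = flat(zgrid, 0.85e-3, "Pa s")
        n = flat(zgrid, 1.0, "nm^-3")
        rho = flat(zgrid, 1e6, "C/m^3")
        u = solve_nsb(mu, n, rho, params)
        np.testing.assert_allclose(u.values, 0.0, atol=1e-30)

    def test_neutral_fluid_gives_zero_flow(self, zgrid):
        params = NSBParams()
        u = solve_nsb(flat(zgrid, 0.85e-3, "Pa s"), flat(zgrid, 1.0, "nm^-3"),
                      flat(zgrid, 0.0, "C/m^3"), params)
        np.testing.assert_allclose(u.values, 0.0, atol=1e-30)

    def test_no_slip_and_mirror_symmetry(self, small_scenario):
        _, _, u = small_scenario
        assert u.values[0] == 0.0
        np.testing.assert_allclose(u.values, u.values[::-1], rtol=1e-10)

    def test_nonpositive_viscosity_rejected(self, zgrid):
        mu = flat(zgrid, 0.85e-3, "Pa s")
        bad = mu.with_values(mu.values * np.where(zgrid > 10, -1, 1))
        with pytest.raises(ValueError, match="singular|positive"):
            solve_nsb(bad, flat(zgrid, 0.0, "nm^-3"), flat(zgrid, 0.0, "C/m^3"),
                      NSBParams())

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_piecewise_constant_oracle(self, seed):
        z = np.linspace(0.0, 20.0, 4001)
        rng = np.random.default_rng(seed)
        params, mu, n, rho, oracle, _ = piecewise_instance(rng, z)
        u = solve_nsb(mu, n, rho, params)
        m = (len(z) - 1) // 2
        exact = oracle(z[: m + 1] * NM)
        scale = np.max(np.abs(exact))
        assert scale > 0
        assert np.max(np.abs(u.values[: m + 1] - exact)) / scale < 1e-4

    def test_second_order_grid_convergence(self):
        # refining the grid 3x keeps the jumps on cell faces and must
        # shrink the error by ~9x for a second-order scheme
        rng = np.random.default_rng(77)
        z_c = np.linspace(0.0, 20.0, 501)
        params, mu, n, rho, oracle, build = piecewise_instance(rng, z_c, n_segs=2)
        err_c = np.max(np.abs(solve_nsb(mu, n, rho, params).values[:251]
                              - oracle(z_c[:251] * NM)))
        z_f = np.linspace(0.0, 20.0, 1501)
        mu_f, n_f, rho_f = build(z_f)
        err_f = np.max(np.abs(solve_nsb(mu_f, n_f, rho_f, params).values[:751]
                              - oracle(z_f[:751] * NM)))
        assert err_c / err_f == pytest.approx(9.0, rel=0.5)

    def test_helmholtz_smoluchowski_plateau(self):
        # no polymer, thin double layer: plateau u = -eps eps0 zeta E / mu0
        spec = bf.ElectrolyteSpec()
        params = NSBParams(a_bead=0.0)
        ions = bf.gouy_chapman_profiles(spec, w=params.width, n_grid=8001)
        z = ions[1].z
        mu = flat(z, params.mu0, "Pa s")
        n = flat(z, 0.0, "nm^-3")
        u = solve_nsb(mu, n, ions, params)
        zeta = gouy_chapman_potential(spec, np.array([0.0]), params.width)[0]
        u_hs = -spec.dielectric_constant * EPS0 * zeta * params.Eext * V_PER_NM / params.mu0
        mid = (len(z) - 1) // 2
        assert u.values[mid] == pytest.approx(u_hs, rel=0.05)

    def test_linearity_in_applied_field(self, small_scenario):
        scen, profiles, u1 = small_scenario
        p1 = bf.scenario_params(scen)
        p2 = NSBParams(mu0=p1.mu0, a_bead=p1.a_bead, a0=p1.a0, Eext=2 * p1.Eext,
                       width=p1.width)
        u2 = solve_nsb(profiles["mu"], profiles["n"], profiles["ions"], p2)
        np.testing.assert_allclose(u2.values, 2.0 * u1.values, rtol=1e-12)

    def test_mid_slit_speed_decreases_with_bead_radius(self, small_scenario):
        scen, profiles, _ = small_scenario
        mids = []
        for a in (0.0, 0.01, 0.02, 0.05, 0.156):
            u = solve_nsb(profiles["mu"], profiles["n"], profiles["ions"],
                          bf.scenario_params(scen, a_bead=a))
            mids.append(abs(u.values[len(u) // 2]))
        assert np.all(np.diff(mids) < 0)

    def test_mid_slit_speed_decreases_with_density_scaling(self, small_scenario):
        scen, profiles, _ = small_scenario
        params = bf.scenario_params(scen)
        mids = []
        for s in (0.5, 1.0, 2.0, 4.0):
            n_s = profiles["n"].with_values(s * profiles["n"].values)
            phi = volume_fraction(n_s, params.a0)
            mu = viscosity_profile(phi, params.mu0)
            u = solve_nsb(mu, n_s, profiles["ions"], params)
            mids.append(abs(u.values[len(u) // 2]))
        assert np.all(np.diff(mids) < 0)

    def test_half_grid_input_gives_mirrored_full_profile(self, zgrid):
        params = NSBParams()
        m = 1000
        z_half = zgrid[: m + 1]
        mu = flat(z_half, 0.85e-3, "Pa s")
        n = flat(z_half, 1.0, "nm^-3")
        rho = flat(z_half, 1e6, "C/m^3")
        u = solve_nsb(mu, n, rho, params)
        assert len(u) == 2 * m + 1
        np.testing.assert_allclose(u.values, u.values[::-1], rtol=1e-12)
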