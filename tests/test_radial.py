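"""Radial reduction about the target and the effective potential."""

import math

import numpy as np
import pytest

import steric_stepper as ss
from steric_stepper.radial import (
    EmptySupportError,
    RadialPotential,
    UnreachableContactError,
    effective_potential,
)


class TestRadialEquilibriumDensity:
    def test_target_at_tether_concentrates_at_shell_radius(self, walker36):
        # with a = 0 the target distance is |r|, pinned near L by the shell
        rp = ss.radial_equilibrium_density(
            "baseline", walker36, ss.TargetGeometry(a=0.0, epsilon=2.0))
        mode = rp.rho[int(np.argmax(rp.radial_density))]
        step = float(np.diff(rp.rho).max())
        assert abs(mode - walker36.L) < step

    def test_unit_mass(self, potential_cache):
        for scenario in ("baseline", "tail", "trench", "combined"):
            rp = potential_cache(scenario)
            assert float(np.trapezoid(rp.radial_density, rp.rho)) \
                == pytest.approx(1.0, abs=1e-4)

    def test_matches_sampled_distance_histogram(self, walker36):
        """rho^2 P_eq is the true density of the distance to the target:
        it must match a histogram of distances from sampled positions."""
        geom = ss.TargetGeometry(a=11.5, epsilon=2.0)
        rp = ss.radial_equilibrium_density("baseline", walker36, geom)
        cloud = ss.sample_free_end("baseline", walker36, 400_000, seed=99)
        d = np.linalg.norm(cloud.positions - np.array([11.5, 0.0, 0.0]),
                           axis=1)
        d = d[d >= geom.epsilon]  # model lives on [epsilon, rho_max]
        frac_in = len(d) / len(cloud)
        edges = np.linspace(geom.epsilon, rp.rho_max, 41)
        counts, _ = np.histogram(d, bins=edges)
        n = len(d)
        w = rp.radial_density
        for i in range(len(edges) - 1):
            sel = (rp.rho >= edges[i]) & (rp.rho <= edges[i + 1])
            grid = np.concatenate([[edges[i]], rp.rho[sel], [edges[i + 1]]])
            vals = np.interp(grid, rp.rho, w)
            p_model = float(np.trapezoid(vals, grid))
            p_emp = counts[i] / n
            se = math.sqrt(max(p_model * (1 - p_model), 1e-12) / n)
            assert abs(p_emp - p_model) < max(3.5 * se, 2e-4), \
                f"bin {i}: {p_emp} vs {p_model}"
        # nearly all sampled points fall inside [epsilon, rho_max]
        assert frac_in > 0.995

    def test_gauss_agrees_with_adaptive_quadrature(self, walker36):
        geom = ss.TargetGeometry(a=11.5, epsilon=2.0)
        grid = np.geomspace(2.0, 8.0, 24)
        for scenario in ("baseline", "combined"):
            fast = ss.radial_equilibrium_density(scenario, walker36, geom,
                                                 rho_grid=grid)
            slow = ss.radial_equilibrium_density(scenario, walker36, geom,
                                                 rho_grid=grid,
                                                 method="adaptive")
            # unnormalized shapes agree up to a common constant (the fixed
            # rule carries ~1e-5 error from the steric-cut kinks)
            ratio = fast.p_eq / slow.p_eq
            assert np.nanstd(ratio) / np.nanmean(ratio) < 1e-4

    @pytest.mark.parametrize("scenario", ["baseline", "tail", "trench",
                                          "combined"])
    def test_matches_cartesian_shell_binning(self, walker36, scenario):
        """Brute-force oracle: bin the 3-D density into spherical shells
        about the target on a Cartesian grid; relative L1 error < 1e-2."""
        a = 11.5
        box = ss.bounding_box(scenario, walker36, a_max=a)
        n = 220
        xs = np.linspace(box[0][0], box[0][1], n)
        ys = np.linspace(box[1][0], box[1][1], n)
        zs = np.linspace(box[2][0], box[2][1], n)
        dens = ss.geometry.density_xyz(
            scenario, xs[:, None, None], ys[None, :, None],
            zs[None, None, :], walker36)
        dist = np.sqrt((xs[:, None, None] - a) ** 2 + ys[None, :, None] ** 2
                       + zs[None, None, :] ** 2)
        eps = 2.0
        rho_max = a + walker36.reach
        edges = np.linspace(eps, rho_max, 201)
        inside = (dist >= eps) & (dist < rho_max)
        hist, _ = np.histogram(dist[inside], bins=edges,
                               weights=dens[inside])
        hist = hist / hist.sum()
        rp = ss.radial_equilibrium_density(
            scenario, walker36, ss.TargetGeometry(a=a, epsilon=eps))
        w = rp.radial_density
        model = np.empty(len(edges) - 1)
        for i in range(len(edges) - 1):
            grid = np.linspace(edges[i], edges[i + 1], 8)
            model[i] = np.trapezoid(np.interp(grid, rp.rho, w), grid)
        model = model / model.sum()
        assert float(np.abs(hist - model).sum()) < 1e-2

    @pytest.mark.parametrize("scenario,rtol", [("tail", 1e-6),
                                               ("combined", 1e-2)])
    def test_phi_half_domain_uses_exact_mirror_symmetry(self, walker36,
                                                        scenario, rtol):
        """Doubling the phi domain to [0, 2 pi] (and halving) changes
        nothing beyond quadrature error (the trench cut makes the combined
        integrand kinked, hence the looser tolerance there)."""
        from numpy.polynomial.legendre import leggauss
        from steric_stepper.geometry import density_xyz

        geom = ss.TargetGeometry(a=11.5, epsilon=2.0)
        grid = np.geomspace(2.0, 20.0, 64)
        rp = ss.radial_equilibrium_density(scenario, walker36, geom,
                                           rho_grid=grid)
        # full-circle quadrature oracle
        t, wt = leggauss(128)
        theta = 0.25 * math.pi * (t + 1)
        wt = wt * 0.25 * math.pi
        pnodes, wp = leggauss(256)
        phi = math.pi * (pnodes + 1)       # [0, 2 pi]
        wp = wp * math.pi
        st_, ct = np.sin(theta), np.cos(theta)
        g = np.empty_like(grid)
        for i, r in enumerate(grid):
            x = geom.a + r * st_[:, None] * np.cos(phi)[None, :]
            y = r * st_[:, None] * np.sin(phi)[None, :]
            z = r * ct[:, None] * np.ones_like(phi)[None, :]
            vals = density_xyz(scenario, x, y, z, walker36)
            g[i] = float((wt * st_) @ vals @ wp) / 2.0  # halve the circle
        w_full = grid ** 2 * g
        w_full /= np.trapezoid(w_full, grid)
        np.testing.assert_allclose(rp.radial_density, w_full,
                                   rtol=rtol, atol=1e-9)

    def test_empty_support_raises(self, walker36):
        # target far beyond the walker's reach: density vanishes on the grid
        geom = ss.TargetGeometry(a=40.0, epsilon=2.0)
        grid = np.geomspace(2.0, 10.0, 32)  # entirely inside the hole
        with pytest.raises(EmptySupportError):
            ss.radial_equilibrium_density("baseline", walker36, geom,
                                          rho_grid=grid)

    def test_grid_must_start_at_epsilon(self, walker36):
        geom = ss.TargetGeometry(a=11.5, epsilon=2.0)
        with pytest.raises(ValueError, match="start at epsilon"):
            ss.radial_equilibrium_density("baseline", walker36, geom,
                                          rho_grid=np.geomspace(3.0, 20.0, 32))


class TestEffectivePotential:
    def test_flat_density_gives_constant_potential(self):
        rp = ss.flat_radial_potential(2.0, 12.0)
        np.testing.assert_allclose(rp.beta_u, math.log(10.0), rtol=1e-12)

    def test_doubling_density_shifts_by_log_two(self):
        rp = ss.flat_radial_potential(2.0, 12.0)
        doubled = RadialPotential(rho=rp.rho, p_eq=2.0 * rp.p_eq,
                                  rho_max=rp.rho_max)
        effective_potential(doubled)
        np.testing.assert_allclose(doubled.beta_u, rp.beta_u - math.log(2.0),
                                   rtol=1e-12)

    def test_minimum_at_radial_density_mode(self, potential_cache):
        rp = potential_cache("baseline")
        assert int(np.argmin(rp.beta_u)) == int(np.argmax(rp.radial_density))

    def test_all_unreachable_raises(self):
        rp = ss.flat_radial_potential(2.0, 12.0)
        rp.p_eq = np.zeros_like(rp.p_eq)
        with pytest.raises(EmptySupportError):
            effective_potential(rp)


class TestRoundTrip:
    def test_csv_round_trip(self, potential_cache, tmp_path):
        rp = potential_cache("tail")
        path = tmp_path / "potential.csv"
        ss.write_radial_csv(rp, path)
        back = ss.read_radial_csv(path)
        np.testing.assert_array_equal(back.rho, rp.rho)
        np.testing.assert_array_equal(back.p_eq, rp.p_eq)
        np.testing.assert_array_equal(back.beta_u, rp.beta_u)
        assert back.meta["scenario"] == "tail"
        assert back.rho_max == rp.rho_max
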