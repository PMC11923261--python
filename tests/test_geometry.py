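"""Confined free-end densities: supports, literal values, marginals, limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import steric_stepper as ss
from steric_stepper.geometry import GridCoverageError
from steric_stepper.params import ParameterError


class TestEvalDensity:
    def test_baseline_on_shell_equals_height_prefactor(self, walker36):
        # at |r| = L the Gaussian exponent vanishes, leaving the z prefactor
        assert ss.eval_density("baseline", (0.0, 0.0, 11.5), walker36) \
            == pytest.approx(11.5)

    @pytest.mark.parametrize("z", [0.0, 12.5])
    def test_tail_vanishes_at_slit_boundaries(self, walker36, z):
        assert ss.eval_density("tail", (3.0, -2.0, z), walker36) == 0.0

    @pytest.mark.parametrize("y", [-4.5, 4.5])
    def test_trench_vanishes_at_walls(self, walker36, y):
        assert ss.eval_density("trench", (5.0, y, 3.0), walker36) == 0.0

    def test_combined_factorizes_as_tail_times_cosine(self, walker36):
        rng = np.random.default_rng(5)
        pts = rng.uniform([-12, -4.4, 0.1], [12, 4.4, 12.4], size=(200, 3))
        combined = ss.eval_density("combined", pts, walker36)
        tail = ss.eval_density("tail", pts, walker36)
        cosine = np.cos(math.pi * pts[:, 1] / walker36.h_max)
        np.testing.assert_allclose(combined, tail * cosine, rtol=1e-12)

    @pytest.mark.parametrize("scenario,point", [
        ("baseline", (1.0, 1.0, -0.1)),       # below the substrate
        ("tail", (0.0, 0.0, 12.6)),           # above the slit
        ("combined", (0.0, 4.6, 5.0)),        # outside the trench
        ("trench", (0.0, -4.51, 5.0)),
    ])
    def test_hard_zero_outside_support(self, walker36, scenario, point):
        assert ss.eval_density(scenario, point, walker36) == 0.0

    def test_non_finite_coordinates_rejected(self, walker36):
        with pytest.raises(ValueError, match="non-finite"):
            ss.eval_density("baseline", (np.nan, 0.0, 1.0), walker36)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            ss.ConfinementParams(beta_k=-1.0, L=11.5)
        with pytest.raises(ParameterError):
            ss.ConfinementParams(beta_k=5.0, L=0.0)
        with pytest.raises(ParameterError):
            # tail scenario without slit parameters
            ss.ConfinementParams(beta_k=5.0, L=11.5).require_for("tail")
        with pytest.raises(ParameterError):
            ss.walker36_params().require_for("trench_series")

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        scenario=st.sampled_from(["baseline", "tail", "trench", "combined"]),
        x=st.floats(-20, 20), y=st.floats(-20, 20), z=st.floats(-5, 20),
    )
    def test_density_nonnegative_and_supported(self, scenario, x, y, z):
        p = ss.walker36_params()
        val = ss.eval_density(scenario, (x, y, z), p)
        assert val >= 0.0
        outside = z < 0.0
        if scenario in ("tail", "combined"):
            outside = outside or z > p.z_max
        if scenario in ("trench", "combined"):
            outside = outside or abs(y) > p.h_max / 2
        if outside:
            assert val == 0.0


class TestNormalization:
    def test_matches_monte_carlo_estimate(self, walker36):
        z_quad = ss.normalization_constant("baseline", walker36)
        box = ss.bounding_box("baseline", walker36)
        rng = np.random.default_rng(17)
        n = 1_000_000
        lo = np.array([b[0] for b in box])
        span = np.array([b[1] - b[0] for b in box])
        pts = lo + span * rng.random((n, 3))
        vals = ss.eval_density("baseline", pts, walker36)
        vol = float(np.prod(span))
        z_mc = vol * float(vals.mean())
        se = vol * float(vals.std(ddof=1)) / math.sqrt(n)
        assert abs(z_quad - z_mc) < max(3 * se, 0.01 * z_quad)

    def test_stable_under_box_enlargement(self, walker36):
        z1 = ss.normalization_constant("baseline", walker36)
        big = tuple((lo * 1.3 if lo < 0 else lo, hi * 1.3)
                    for lo, hi in ss.bounding_box("baseline", walker36))
        z2 = ss.normalization_constant("baseline", walker36, box=big,
                                       n_nodes=220)
        assert z2 == pytest.approx(z1, rel=1e-6)

    def test_agrees_with_adaptive_quadrature(self, walker36):
        z_gauss = ss.normalization_constant("trench", walker36)
        z_nquad = ss.normalization_constant("trench", walker36,
                                            method="nquad")
        assert z_gauss == pytest.approx(z_nquad, rel=1e-5)

    def test_wide_trench_recovers_baseline_constant(self, walker36):
        # cos(pi y / h_max) -> 1 on the occupied region as the trench widens;
        # the leading correction is ~ (pi/h_max)^2 <y^2> / 2
        z_base = ss.normalization_constant("baseline", walker36)
        wide = walker36.replace(h_max=1000.0)
        z_wide = ss.normalization_constant("trench", wide)
        assert z_wide == pytest.approx(z_base, rel=1e-3)


class TestMarginals:
    GRID = np.linspace(-15.0, 15.0, 241)
    ZGRID = np.linspace(0.0, 15.0, 241)

    @pytest.mark.parametrize("scenario,axis,grid", [
        ("baseline", "x", GRID), ("baseline", "z", ZGRID),
        ("tail", "x", GRID), ("tail", "z", np.linspace(0, 12.5, 241)),
        ("trench", "y", np.linspace(-4.5, 4.5, 241)),
        ("combined", "x", GRID),
    ])
    def test_unit_mass(self, walker36, scenario, axis, grid):
        m = ss.marginal_density(scenario, axis, walker36, grid)
        assert float(np.trapezoid(m, grid)) == pytest.approx(1.0, abs=1e-3)

    @pytest.mark.parametrize("scenario", ["baseline", "tail", "trench",
                                          "combined"])
    @pytest.mark.parametrize("axis", ["x", "y"])
    def test_in_plane_marginals_are_even(self, walker36, scenario, axis):
        grid = np.linspace(-15.0, 15.0, 301) if axis == "x" \
            else np.linspace(-14.9, 14.9, 299)
        if scenario in ("trench", "combined") and axis == "y":
            grid = np.linspace(-4.5, 4.5, 301)
        m = ss.marginal_density(scenario, axis, walker36, grid)
        assert float(np.max(np.abs(m - m[::-1]))) < 1e-9

    def test_baseline_x_marginal_peaks_at_origin(self, walker36):
        m = ss.marginal_density("baseline", "x", walker36, self.GRID)
        assert int(np.argmax(m)) == len(self.GRID) // 2

    def test_tail_z_marginal_vanishes_at_slit_edges(self, walker36):
        grid = np.linspace(0.0, 12.5, 251)
        m = ss.marginal_density("tail", "z", walker36, grid)
        assert m[0] == pytest.approx(0.0, abs=1e-12)
        assert m[-1] == pytest.approx(0.0, abs=1e-12)

    def test_combined_x_marginal_is_bimodal(self, walker36):
        m = ss.marginal_density("combined", "x", walker36, self.GRID)
        modes = ss.detect_modes(m, self.GRID)
        assert len(modes) == 2
        assert modes[0] == pytest.approx(-modes[1], abs=2 * 0.125)

    def test_grid_missing_mass_raises(self, walker36):
        with pytest.raises(GridCoverageError):
            ss.marginal_density("baseline", "x", walker36,
                                np.linspace(-3.0, 3.0, 101))


class TestLimits:
    def test_wide_trench_density_tends_to_baseline(self, walker36):
        wide = walker36.replace(h_max=1000.0)
        rng = np.random.default_rng(2)
        pts = rng.uniform([-13, -13, 0.0], [13, 13, 13], size=(300, 3))
        d_t = ss.eval_density("trench", pts, wide)
        d_b = ss.eval_density("baseline", pts, walker36)
        np.testing.assert_allclose(d_t, d_b, rtol=1e-3, atol=1e-12)

    def test_wide_trench_combined_tends_to_tail(self, walker36):
        wide = walker36.replace(h_max=1000.0)
        rng = np.random.default_rng(3)
        pts = rng.uniform([-13, -13, 0.0], [13, 13, 12.4], size=(300, 3))
        d_c = ss.eval_density("combined", pts, wide)
        d_t = ss.eval_density("tail", pts, walker36)
        np.testing.assert_allclose(d_c, d_t, rtol=1e-3, atol=1e-12)


class TestSeriesDiagnostics:
    def test_clipped_mass_negligible_at_reference_parameters(self, walker36):
        assert ss.clipped_mass_fraction("tail", walker36) < 1e-3
        assert ss.clipped_mass_fraction("combined", walker36) < 1e-3
        assert ss.clipped_mass_fraction("baseline", walker36) == 0.0

    def test_trench_series_needs_its_stiffness(self, walker36):
        with_series = walker36.replace(beta_k_dprime=1.0)
        val = ss.eval_density("trench_series", (5.0, 0.0, 3.0), with_series)
        assert val > 0.0
        assert ss.eval_density("trench_series", (5.0, 4.5, 3.0),
                               with_series) == 0.0

    def test_config_round_trip(self, walker36, tmp_path):
        path = tmp_path / "params.yaml"
        walker36.save(path)
        assert ss.ConfinementParams.load(path) == walker36
        jpath = tmp_path / "params.json"
        walker36.save(jpath)
        assert ss.ConfinementParams.load(jpath) == walker36
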