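"""Field solver: coaxial closed-form oracle, linearity, maximum principle,
Picard convergence, resistance and conductivity calibration."""

import numpy as np
import pytest

import ireplan as ip
from ireplan import units
from ireplan.errors import ConfigurationError, DegenerateSolutionError, DomainError
from ireplan.solver import current_through_contour

from conftest import CONST_SIGMA, coaxial_ring_mask


class TestCoaxialOracle:
    """Single centered needle, grounded wall: φ(r) = V ln(R/r)/ln(R/a)."""

    def test_potential_matches_closed_form(self, coaxial):
        sol, geom, a_cm, R_cm, V, _ = coaxial
        xx, yy = geom.cell_centers_m()
        r_cm = np.hypot(xx, yy) * 100.0
        ring = coaxial_ring_mask(geom, a_cm, R_cm)
        with np.errstate(divide="ignore"):
            exact = V * np.log(R_cm / r_cm) / np.log(R_cm / a_cm)
        err = np.abs(sol.potential - exact)[ring] / V
        assert err.max() < 0.02

    def test_field_matches_closed_form(self, coaxial):
        sol, geom, a_cm, R_cm, V, _ = coaxial
        xx, yy = geom.cell_centers_m()
        r_cm = np.hypot(xx, yy) * 100.0
        ring = coaxial_ring_mask(geom, a_cm, R_cm)
        with np.errstate(divide="ignore"):
            exact = V / (r_cm * np.log(R_cm / a_cm))  # V/cm
        rel = np.abs(sol.field_magnitude - exact)[ring] / exact[ring]
        assert rel.max() < 0.03

    def test_resistance_matches_closed_form(self, coaxial):
        sol, geom, a_cm, R_cm, V, sigma = coaxial
        h_m = units.cm_to_m(geom.height_cm)
        exact = np.log(R_cm / a_cm) / (2 * np.pi * sigma * h_m)
        assert ip.compute_resistance(sol) == pytest.approx(exact, rel=0.02)

    def test_error_decreases_under_refinement(self):
        sigma, a_cm, V = 0.1, 0.1, 100.0
        errs = []
        for h in (0.01, 0.005):
            geom = ip.make_well_geometry(
                24, grid_spacing_cm=h,
                conductivity=ip.ConductivityModel.constant(sigma),
            )
            el = ip.ElectrodeConfig(positions_cm=[(0.0, 0.0)], radius_cm=a_cm)
            sol = ip.solve_field(
                geom, el, ("E1", None), V, ip.SolverOptions(grounded_wall=True)
            )
            R_cm = geom.outer_diameter_cm / 2.0
            xx, yy = geom.cell_centers_m()
            r_cm = np.hypot(xx, yy) * 100.0
            ring = coaxial_ring_mask(geom, a_cm, R_cm)
            with np.errstate(divide="ignore"):
                exact = V * np.log(R_cm / r_cm) / np.log(R_cm / a_cm)
            errs.append(np.abs(sol.potential - exact)[ring].max() / V)
        assert errs[1] < errs[0]


class TestLinearityAndSymmetry:
    def test_zero_amplitude_gives_zero_solution(self, well24, pair_electrodes):
        sol = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), 0.0)
        assert np.nanmax(np.abs(sol.potential)) == pytest.approx(0.0, abs=1e-12)
        assert sol.field_magnitude.max() == pytest.approx(0.0, abs=1e-12)
        assert sol.current_A == pytest.approx(0.0, abs=1e-15)

    def test_field_scales_linearly_with_amplitude(self, well24, pair_electrodes):
        s1 = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), 1000.0)
        s2 = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), 2000.0)
        m = s1.domain
        assert np.allclose(s2.field_magnitude[m], 2 * s1.field_magnitude[m], rtol=1e-9)
        assert s2.current_A == pytest.approx(2 * s1.current_A, rel=1e-9)

    def test_swapped_polarity_complements_to_amplitude(self, well24, pair_electrodes):
        V = 1000.0
        fwd = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), V)
        rev = ip.solve_field(well24, pair_electrodes, ("E2", "E1"), V)
        free = fwd.domain
        assert np.allclose(fwd.potential[free] + rev.potential[free], V, atol=1e-6)

    def test_maximum_principle(self, well24, pair_electrodes):
        V = 1100.0
        sol = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), V)
        phi = sol.potential[sol.domain]
        assert phi.min() >= -1e-9
        assert phi.max() <= V + 1e-9

    def test_mirror_symmetry_about_bisector(self, well24, pair_electrodes):
        sol = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), 1100.0)
        E = sol.field_magnitude
        # electrodes sit on the x axis: |E| is symmetric under y -> -y,
        # and under x -> -x (anode/cathode exchange leaves |E| unchanged)
        assert np.allclose(E, E[:, ::-1], atol=1e-6 * E.max())
        assert np.allclose(E, E[::-1, :], atol=1e-6 * E.max())


class TestCurrentAndResistance:
    def test_current_contour_independent(self, well24, pair_electrodes):
        sol = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), 1100.0)
        i0 = current_through_contour(sol, dilation=0)
        i5 = current_through_contour(sol, dilation=5)
        assert i5 == pytest.approx(i0, rel=0.01)

    def test_resistance_halves_when_sigma_doubles(self, pair_electrodes):
        rs = []
        for s in (CONST_SIGMA, 2 * CONST_SIGMA):
            geom = ip.make_well_geometry(
                24, grid_spacing_cm=0.02,
                conductivity=ip.ConductivityModel.constant(s),
            )
            sol = ip.solve_field(geom, pair_electrodes, ("E1", "E2"), 100.0)
            rs.append(ip.compute_resistance(sol))
        assert rs[1] == pytest.approx(rs[0] / 2, rel=1e-9)

    def test_zero_current_is_degenerate(self, well24, pair_electrodes):
        sol = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), 100.0)
        sol.current_A = 0.0
        with pytest.raises(DegenerateSolutionError):
            ip.compute_resistance(sol)


class TestCalibration:
    def test_round_trip_recovers_sigma(self, well24, pair_electrodes):
        true_sigma = 0.027
        r = ip.synth_resistance(well24, pair_electrodes, ("E1", "E2"), true_sigma)
        got = ip.calibrate_conductivity(well24, pair_electrodes, ("E1", "E2"), 100.0, r)
        assert got == pytest.approx(true_sigma, rel=0.005)

    def test_inverse_proportionality(self, well24, pair_electrodes):
        s1 = ip.calibrate_conductivity(well24, pair_electrodes, ("E1", "E2"), 100.0, 5000.0)
        s2 = ip.calibrate_conductivity(well24, pair_electrodes, ("E1", "E2"), 100.0, 10000.0)
        assert s2 == pytest.approx(s1 / 2, rel=1e-9)

    def test_hepg2_range_round_trip(self, well24, pair_electrodes):
        # conductivities across the small-hydrogel calibration interval
        rng = np.random.default_rng(7)
        for sigma in rng.uniform(0.022, 0.032, size=3):
            r = ip.synth_resistance(well24, pair_electrodes, ("E1", "E2"), sigma)
            got = ip.calibrate_conductivity(
                well24, pair_electrodes, ("E1", "E2"), 100.0, r
            )
            assert 0.022 <= got <= 0.032
            assert got == pytest.approx(sigma, rel=0.005)

    def test_bad_resistance_rejected(self, well24, pair_electrodes):
        with pytest.raises(DomainError):
            ip.calibrate_conductivity(
                well24, pair_electrodes, ("E1", "E2"), 100.0, float("nan")
            )


class TestPicardIteration:
    def test_field_dependent_converges_with_bounded_sigma(self):
        geom = ip.make_well_geometry(24, grid_spacing_cm=0.02)  # liver sigmoid
        el = ip.place_electrodes(geom, "pair", 0.8)
        sol = ip.solve_field(geom, el, ("E1", "E2"), 1100.0)
        assert sol.converged
        assert sol.residual < 1e-3
        assert 1 < sol.iterations <= 50
        sig = sol.sigma_S_per_m[sol.domain]
        assert sig.min() >= 0.4 - 1e-12
        assert sig.max() <= 1.6 + 1e-12

    def test_nonlinear_field_between_endpoint_linear_solves(self):
        """The σ(E) solution current lies between the σ0-only and σf-only ones."""
        el_geo = ip.make_well_geometry(24, grid_spacing_cm=0.02)
        el = ip.place_electrodes(el_geo, "pair", 0.8)
        nonlin = ip.solve_field(el_geo, el, ("E1", "E2"), 1100.0)
        currents = {}
        for s in (0.4, 1.6):
            g = ip.make_well_geometry(
                24, grid_spacing_cm=0.02,
                conductivity=ip.ConductivityModel.constant(s),
            )
            currents[s] = ip.solve_field(g, el, ("E1", "E2"), 1100.0).current_A
        assert currents[0.4] < nonlin.current_A < currents[1.6]


class TestSolveValidation:
    def test_unknown_electrode_label(self, well24, pair_electrodes):
        with pytest.raises(ConfigurationError):
            ip.solve_field(well24, pair_electrodes, ("E1", "E9"), 100.0)

    def test_negative_amplitude(self, well24, pair_electrodes):
        with pytest.raises(DomainError):
            ip.solve_field(well24, pair_electrodes, ("E1", "E2"), -5.0)

    def test_inactive_electrode_is_a_hole(self):
        geom = ip.make_well_geometry(6, grid_spacing_cm=0.02,
                                     conductivity=ip.ConductivityModel.constant(0.1))
        el = ip.place_electrodes(geom, "square", 1.4)
        sol = ip.solve_field(geom, el, ("E1", "E2"), 1000.0)
        from ireplan.solver import electrode_masks

        masks = electrode_masks(geom, el)
        assert not sol.domain[masks["E3"]].any()
        assert np.isnan(sol.potential[masks["E3"]]).all()
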