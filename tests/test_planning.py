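"""Plan execution, superposition, sweeps, coverage and classification."""

import numpy as np
import pytest

import ireplan as ip
from ireplan.errors import DomainError, EmptyInputError
from ireplan.planning import LABEL_EXP_ONLY, LABEL_REP, LABEL_UNTREATED

from conftest import CONST_SIGMA


class TestRunPlan:
    def test_single_activation_equals_its_field(self, well24, pair_electrodes, cum_1100):
        sol = ip.solve_field(well24, pair_electrodes, ("E1", "E2"), 1100.0)
        t = cum_1100.tissue
        assert np.allclose(cum_1100.cumulative_magnitude[t], sol.field_magnitude[t])

    def test_repeated_plan_is_idempotent(self, well24, pair_electrodes, cum_1100):
        plan2 = ip.ActivationPlan.uniform([("E1", "E2"), ("E1", "E2")], 1100.0, 100)
        cum2 = ip.run_plan(well24, pair_electrodes, plan2)
        assert np.allclose(cum2.cumulative_magnitude, cum_1100.cumulative_magnitude)

    def test_cumulative_dominates_each_activation(self):
        geom = ip.make_well_geometry(6, grid_spacing_cm=0.04,
                                     conductivity=ip.ConductivityModel.constant(CONST_SIGMA))
        el = ip.place_electrodes(geom, "square", 1.4)
        pairs = ip.enumerate_pairs(el, "all")
        cum = ip.run_plan(geom, el, ip.ActivationPlan.uniform(pairs, 1100.0, 100))
        for sol in cum.solutions:
            assert (cum.cumulative_magnitude >= sol.field_magnitude - 1e-9).all()

    def test_six_pair_superposition_is_rot90_invariant(self):
        geom = ip.make_well_geometry(6, grid_spacing_cm=0.04,
                                     conductivity=ip.ConductivityModel.constant(CONST_SIGMA))
        el = ip.place_electrodes(geom, "square", 1.4)
        pairs = ip.enumerate_pairs(el, "all")
        cum = ip.run_plan(geom, el, ip.ActivationPlan.uniform(pairs, 1100.0, 100))
        E = cum.cumulative_magnitude
        assert np.abs(E - np.rot90(E)).max() <= 0.01 * E.max()

    def test_empty_plan_rejected(self, well24, pair_electrodes):
        with pytest.raises(EmptyInputError):
            ip.run_plan(well24, pair_electrodes, ip.ActivationPlan([]))

    def test_failed_activation_reports_context(self, well24, pair_electrodes):
        plan = ip.ActivationPlan.uniform([("E1", "E9")], 1100.0, 100)
        with pytest.raises(Exception, match="E9"):
            ip.run_plan(well24, pair_electrodes, plan)


class TestAblationSweep:
    def test_monotone_non_increasing(self, sweep_1100):
        assert (np.diff(sweep_1100.ablated_measure) <= 1e-9).all()

    def test_extreme_thresholds(self, cum_1100):
        t = cum_1100.region_tissue_mask()
        vals = cum_1100.cumulative_magnitude[t]
        lo = ip.ablation_sweep(cum_1100, vals.min() / 2, vals.max() * 2, vals.max())
        # first rung below every cell's field: the whole region ablates
        assert lo.ablated_measure[0] == pytest.approx(lo.domain_measure)
        # last rung above the maximum field: nothing ablates
        assert lo.ablated_measure[-1] == 0.0

    def test_coaxial_iso_area_closed_form(self, coaxial):
        sol, geom, a_cm, R_cm, V, _ = coaxial
        cum = ip.CumulativeField(
            geometry=geom, electrodes=sol.electrodes,
            cumulative_magnitude=sol.field_magnitude,
            solutions=[sol], tissue=sol.domain & ~sol.anode_mask,
        )
        sweep = ip.ablation_sweep(cum, 50.0, 400.0, 1.0)
        for e_th in (100.0, 200.0, 300.0):
            r_star = min(V / (e_th * np.log(R_cm / a_cm)), R_cm)
            exact = (np.pi * r_star**2 - np.pi * a_cm**2) * 100.0  # cm² -> mm²
            got = float(np.interp(e_th, sweep.thresholds_V_per_cm, sweep.ablated_measure))
            assert got == pytest.approx(exact, rel=0.03)

    def test_adding_activation_never_shrinks_ablation(self, well24, pair_electrodes):
        geom = ip.make_well_geometry(6, grid_spacing_cm=0.04,
                                     conductivity=ip.ConductivityModel.constant(CONST_SIGMA))
        el = ip.place_electrodes(geom, "square", 1.4)
        pairs = ip.enumerate_pairs(el, "all")
        prev = None
        for k in (1, 3, 6):
            cum = ip.run_plan(geom, el, ip.ActivationPlan.uniform(pairs[:k], 1100.0, 100))
            sweep = ip.ablation_sweep(cum, 200.0, 2500.0, 20.0)
            if prev is not None:
                assert (sweep.ablated_measure >= prev - 1e-9).all()
            prev = sweep.ablated_measure

    def test_ablation_grows_along_voltage_ladder(self, well24, pair_electrodes):
        """600 V < 1100 V < 2300 V orders the ablated fraction at threshold."""
        fractions = []
        for V in (600.0, 1100.0, 2300.0):
            cum = ip.run_plan(well24, pair_electrodes,
                              ip.ActivationPlan.uniform([("E1", "E2")], V, 100))
            fractions.append(ip.coverage_fraction(cum, 544.0))
        assert fractions[0] < fractions[1] < fractions[2]

    def test_grid_refinement_changes_area_below_2pct(self, pair_electrodes):
        areas = []
        for h in (0.01, 0.005):
            geom = ip.make_well_geometry(24, grid_spacing_cm=h,
                                         conductivity=ip.ConductivityModel.constant(CONST_SIGMA))
            cum = ip.run_plan(geom, pair_electrodes,
                              ip.ActivationPlan.uniform([("E1", "E2")], 1100.0, 100))
            sweep = ip.ablation_sweep(cum, 500.0, 600.0, 4.0)
            areas.append(float(np.interp(544.0, sweep.thresholds_V_per_cm,
                                         sweep.ablated_measure)))
        assert abs(areas[1] - areas[0]) / areas[0] < 0.02

    def test_invalid_ladder_rejected(self, cum_1100):
        with pytest.raises(DomainError):
            ip.ablation_sweep(cum_1100, 500.0, 400.0, 1.0)
        with pytest.raises(DomainError):
            ip.ablation_sweep(cum_1100, 200.0, 400.0, -1.0)


class TestCoverage:
    def test_full_coverage_below_min_field(self, cum_1100):
        vals = cum_1100.cumulative_magnitude[cum_1100.region_tissue_mask()]
        assert ip.coverage_fraction(cum_1100, vals.min() * 0.5) == 1.0

    def test_zero_coverage_above_max_field(self, cum_1100):
        vals = cum_1100.cumulative_magnitude[cum_1100.region_tissue_mask()]
        assert ip.coverage_fraction(cum_1100, vals.max() * 2.0) == 0.0

    def test_half_coverage_on_constructed_field(self, well24, pair_electrodes):
        cum = ip.run_plan(well24, pair_electrodes,
                          ip.ActivationPlan.uniform([("E1", "E2")], 1100.0, 100))
        mask = cum.region_tissue_mask()
        median = float(np.median(cum.cumulative_magnitude[mask]))
        frac = ip.coverage_fraction(cum, median)
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_fraction_always_in_unit_interval(self, cum_1100):
        for t in (1.0, 200.0, 544.0, 800.0, 1e5):
            f = ip.coverage_fraction(cum_1100, t)
            assert 0.0 <= f <= 1.0


class TestClassification:
    def test_labels_partition_the_domain(self, cum_1100):
        labels = ip.classify_field_map(cum_1100)
        inside = cum_1100.geometry.inside
        counts = [(labels[inside] == k).sum() for k in
                  (LABEL_UNTREATED, LABEL_EXP_ONLY, LABEL_REP)]
        assert sum(counts) == inside.sum()
        assert (labels[~inside] == -1).all()

    def test_uniform_field_classifies_between_thresholds(self, well24, pair_electrodes):
        cum = ip.run_plan(well24, pair_electrodes,
                          ip.ActivationPlan.uniform([("E1", "E2")], 1100.0, 100))
        cum.cumulative_magnitude = np.where(well24.inside, 600.0, 0.0)
        labels = ip.classify_field_map(cum, 544.0, 800.0)
        assert (labels[well24.inside] == LABEL_EXP_ONLY).all()

    def test_zero_field_all_untreated(self, well24, cum_1100):
        import copy

        cum = copy.copy(cum_1100)
        cum.cumulative_magnitude = np.zeros_like(cum_1100.cumulative_magnitude)
        labels = ip.classify_field_map(cum)
        assert (labels[well24.inside] == LABEL_UNTREATED).all()

    def test_equal_thresholds_collapse_middle_band(self, cum_1100):
        labels = ip.classify_field_map(cum_1100, 544.0, 544.0)
        assert not (labels == LABEL_EXP_ONLY).any()

    def test_inverted_thresholds_rejected(self, cum_1100):
        with pytest.raises(DomainError):
            ip.classify_field_map(cum_1100, 800.0, 544.0)


class TestTreatmentTime:
    def test_eight_pulses_at_1hz_is_8s(self):
        plan = ip.ActivationPlan.uniform([("E1", "E2")], 2300.0, 8)
        assert ip.treatment_time(plan) == pytest.approx(8.0)

    def test_three_pairs_100_pulses(self):
        pairs = [("E1", "E2"), ("E1", "E3"), ("E2", "E3")]
        plan = ip.ActivationPlan.uniform(pairs, 1100.0, 100)
        assert ip.treatment_time(plan) == pytest.approx(300.0)

    def test_empty_plan_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert ip.treatment_time(ip.ActivationPlan([])) == 0.0

    def test_frequency_scales_duration(self):
        plan = ip.ActivationPlan.uniform([("E1", "E2")], 1100.0, 100, frequency_Hz=2.0)
        assert ip.treatment_time(plan) == pytest.approx(50.0)

    def test_pulse_width_cannot_exceed_period(self):
        with pytest.raises(DomainError):
            ip.PulseProtocol(amplitude_V=100.0, n_pulses=1,
                             pulse_width_us=2e6, frequency_Hz=1.0)
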