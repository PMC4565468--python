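import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eptplan.coverage_planner import (PlannerConstraints, coverage_fraction,
                                      cumulative_coverage_curve,
                                      optimize_pair_voltages,
                                      plan_needle_count)
from eptplan.electrode_model import ElectrodeSpec, place_parallel_array, \
    rasterize_electrodes
from eptplan.field_solver import default_protocols, load_tissue_config, \
    properties_by_label, protocol_thresholds, solve_sequence


class TestCoverageFraction:
    def test_uniformly_covered(self):
        E = np.full((8, 8, 4), 500.0)
        mask = np.ones((8, 8, 4), dtype=bool)
        assert coverage_fraction(E, mask, 400.0) == 1.0

    def test_half_covered_by_construction(self):
        E = np.zeros((8, 8, 4))
        mask = np.zeros((8, 8, 4), dtype=bool)
        mask[:4] = True
        sel = np.argwhere(mask)
        half = sel[: len(sel) // 2]
        E[tuple(half.T)] = 800.0  # exactly half the mask at 2x threshold
        assert coverage_fraction(E, mask, 400.0) == 0.5

    def test_zero_threshold_full_coverage(self):
        rng = np.random.default_rng(0)
        E = rng.uniform(0, 100, (8, 8, 4))
        assert coverage_fraction(E, np.ones_like(E, dtype=bool), 0.0) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            coverage_fraction(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool), 1.0)


class TestCoverageCurve:
    def test_starts_at_one(self):
        rng = np.random.default_rng(1)
        E = rng.uniform(0, 900, (8, 8, 4))
        curve = cumulative_coverage_curve(E, np.ones_like(E, dtype=bool))
        assert curve.fractions[0] == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_nonincreasing_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        E = rng.uniform(0, 1000, (6, 6, 3))
        curve = cumulative_coverage_curve(E, np.ones_like(E, dtype=bool), 20)
        assert np.all(np.diff(curve.fractions) <= 0)

    def test_uniform_map_step_shape(self):
        E = np.full((8, 8, 4), 300.0)
        mask = np.ones_like(E, dtype=bool)
        curve = cumulative_coverage_curve(E, mask, 10)
        assert np.all(curve.fractions[curve.thresholds <= 300.0] == 1.0)
        assert coverage_fraction(E, mask, 300.1) == 0.0


def _planner_fixture(n_needles=2, shape=(28, 28, 16), spacing=(2.0, 2.0, 2.0),
                     needle_gap=12.0, tumor_r=7.0):
    spec = ElectrodeSpec("var", "variable", 1.5, [16.0], 16.0, 3000.0)
    center = np.asarray(shape) * np.asarray(spacing) / 2.0
    entry = center - np.array([0, 0, center[2]])
    target = center + np.array([0, 0, 4.0])
    array = place_parallel_array(spec, entry, target, n_needles=n_needles,
                                 spacing_mm=needle_gap)
    elec = rasterize_electrodes(array, shape, spacing)
    x, y, z = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                          indexing="ij")
    tumor = ((x - center[0]) ** 2 + (y - center[1]) ** 2
             + (z - center[2]) ** 2) <= tumor_r ** 2
    tissue = np.ones(shape, dtype=np.int16)
    tissue[tumor] = 2
    protocol = default_protocols()["ECT"]
    thr = protocol_thresholds(protocol)
    props = properties_by_label({1: "liver", 2: "tumor"},
                                load_tissue_config(protocol))
    return array, elec, tissue, tumor, props, thr, spacing


class TestOptimizer:
    def test_already_covered_returns_minimum(self):
        array, elec, tissue, tumor, props, thr, spacing = _planner_fixture()
        c = PlannerConstraints(voltage_step=100.0, min_voltage=1500.0,
                               max_voltage=3000.0)
        plan = optimize_pair_voltages(tissue, elec, array, props, tumor,
                                      50.0, spacing, c)  # trivially low e_rev
        assert plan.feasible
        assert plan.voltages == [1500.0] * len(array.pairs)

    def test_monotone_in_voltage(self):
        array, elec, tissue, tumor, props, thr, spacing = _planner_fixture()
        e_rev = thr["tumor"][0]
        covs = []
        for U in (400.0, 900.0, 1600.0):
            sol = solve_sequence(tissue, elec, array.pairs,
                                 [U] * len(array.pairs), props, spacing)
            covs.append(coverage_fraction(sol.cumulative_field, tumor, e_rev))
        assert covs == sorted(covs)

    def test_bisection_matches_grid_search(self):
        array, elec, tissue, tumor, props, thr, spacing = _planner_fixture()
        e_rev = thr["tumor"][0]
        step = 100.0
        c = PlannerConstraints(voltage_step=step, min_voltage=400.0,
                               max_voltage=2400.0)
        plan = optimize_pair_voltages(tissue, elec, array, props, tumor, e_rev,
                                      spacing, c, per_pair_descent=False)
        assert plan.feasible
        # brute-force oracle: scan the voltage lattice from below
        oracle = None
        for U in np.arange(c.min_voltage, c.max_voltage + step, step):
            sol = solve_sequence(tissue, elec, array.pairs,
                                 [U] * len(array.pairs), props, spacing)
            if coverage_fraction(sol.cumulative_field, tumor, e_rev) >= 1.0:
                oracle = U
                break
        assert oracle is not None
        assert abs(plan.voltages[0] - oracle) <= step

    def test_determinism(self):
        array, elec, tissue, tumor, props, thr, spacing = _planner_fixture()
        c = PlannerConstraints(voltage_step=200.0, min_voltage=400.0,
                               max_voltage=2400.0)
        p1 = optimize_pair_voltages(tissue, elec, array, props, tumor,
                                    thr["tumor"][0], spacing, c)
        p2 = optimize_pair_voltages(tissue, elec, array, props, tumor,
                                    thr["tumor"][0], spacing, c)
        assert p1.voltages == p2.voltages
        assert p1.target_coverage == p2.target_coverage

    def test_infeasible_flagged_not_raised(self):
        array, elec, tissue, tumor, props, thr, spacing = _planner_fixture()
        c = PlannerConstraints(voltage_step=100.0, min_voltage=100.0,
                               max_voltage=300.0)  # far too low
        plan = optimize_pair_voltages(tissue, elec, array, props, tumor,
                                      thr["tumor"][0], spacing, c)
        assert not plan.feasible
        assert plan.target_coverage < 1.0


class TestNeedleCountPlanner:
    def test_small_target_needs_two_needles(self):
        _, _, tissue, tumor, props, thr, spacing = _planner_fixture()
        spec = ElectrodeSpec("var", "variable", 1.5, [16.0], 16.0, 3000.0)
        center = np.asarray(tissue.shape) * np.asarray(spacing) / 2.0
        c = PlannerConstraints(voltage_step=200.0, min_voltage=400.0,
                               max_voltage=3000.0, max_needles=4)
        array, plan = plan_needle_count(
            tissue, spec, center - np.array([0, 0, center[2]]),
            center + np.array([0, 0, 4.0]), props, tumor, thr["tumor"][0],
            spacing, needle_spacing_mm=12.0, constraints=c)
        assert plan.feasible
        assert array.n_needles == 2

    def test_escalates_for_oblong_target(self):
        shape, spacing = (28, 36, 16), (2.0, 2.0, 2.0)
        x, y, z = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, spacing)],
                              indexing="ij")
        center = np.asarray(shape) * np.asarray(spacing) / 2.0
        # oblong along y — the axis the variable row grows along — so that a
        # single 2-needle pair at the voltage cap cannot cover it
        tumor = (((x - center[0]) / 4.0) ** 2 + ((y - center[1]) / 18.0) ** 2
                 + ((z - center[2]) / 4.0) ** 2) <= 1.0
        tissue = np.ones(shape, dtype=np.int16)
        tissue[tumor] = 2
        protocol = default_protocols()["ECT"]
        thr = protocol_thresholds(protocol)
        props = properties_by_label({1: "liver", 2: "tumor"},
                                    load_tissue_config(protocol))
        spec = ElectrodeSpec("var", "variable", 1.5, [16.0], 16.0, 2400.0)
        c = PlannerConstraints(voltage_step=200.0, min_voltage=400.0,
                               max_voltage=2400.0, max_needles=5)
        array, plan = plan_needle_count(
            tissue, spec, np.array([center[0], center[1], 0.0]),
            np.array([center[0], center[1], 24.0]), props, tumor,
            thr["tumor"][0], spacing, needle_spacing_mm=12.0, constraints=c)
        assert array.n_needles > 2
        assert plan.feasible

    def test_fixed_spec_rejected(self):
        from eptplan.electrode_model import get_spec
        _, _, tissue, tumor, props, thr, spacing = _planner_fixture()
        with pytest.raises(ValueError, match="variable"):
            plan_needle_count(tissue, get_spec("linear-2"), (0, 0, 0),
                              (0, 0, 10), props, tumor, 400.0, spacing)
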