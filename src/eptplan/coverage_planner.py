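"""Coverage statistics and treatment-parameter optimization.

Turns cumulative field maps into target-coverage fractions and
dose-volume-histogram-style cumulative coverage curves, searches for the
minimal per-pair voltages that cover the target at the reversible threshold,
and escalates the needle count for variable-geometry arrays when a fixed
count cannot reach feasibility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .electrode_model import ElectrodeArray, ElectrodeSpec, place_parallel_array, \
    rasterize_electrodes
from .field_solver import FieldSolution, TissueProperties, solve_sequence

__all__ = [
    "CoverageCurve",
    "VoltagePlan",
    "PlannerConstraints",
    "coverage_fraction",
    "cumulative_coverage_curve",
    "optimize_pair_voltages",
    "plan_needle_count",
]


@dataclass
class CoverageCurve:
    """Volume fraction of a mask at or above each field threshold."""

    thresholds: np.ndarray  # ascending, V/cm
    fractions: np.ndarray  # in [0, 1], nonincreasing

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(np.diff(self.thresholds) < 0):
            raise ValueError("thresholds must be ascending")
        if np.any(self.fractions < 0) or np.any(self.fractions > 1):
            raise ValueError("fractions must lie in [0, 1]")

    def to_rows(self):
        return np.column_stack([self.thresholds, self.fractions])


@dataclass
class VoltagePlan:
    """Optimized per-pair voltages with the achieved dose statistics."""

    pairs: List[Tuple[int, int]]
    voltages: List[float]
    target_coverage: float  # fraction of target >= its reversible threshold
    healthy_irreversible_mm3: Dict[str, float]
    feasible: bool
    solution: Optional[FieldSolution] = None

    def to_json(self) -> dict:
        return {
            "pairs": [list(p) for p in self.pairs],
            "voltages": self.voltages,
            "target_coverage": self.target_coverage,
            "healthy_irreversible_mm3": self.healthy_irreversible_mm3,
            "feasible": self.feasible,
        }


@dataclass
class PlannerConstraints:
    required_coverage: float = 1.0
    max_voltage: float = 3000.0
    min_voltage: float = 100.0
    voltage_step: float = 10.0  # search tolerance ΔU
    max_healthy_irreversible_mm3: Optional[float] = None  # off by default
    max_needles: int = 6
    solver_tol: float = 1e-3
    solver_max_iter: int = 20


def coverage_fraction(E: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """Fraction of mask voxels with field ≥ threshold (inclusive)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != E.shape:
        raise ValueError("mask and field map shapes differ")
    total = mask.sum()
    if total == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(E[mask] >= threshold)) / float(total)


def cumulative_coverage_curve(E: np.ndarray, mask: np.ndarray,
                              n_thresholds: int = 50) -> CoverageCurve:
    """Coverage fraction over thresholds linearly spaced on [0, max E in mask]."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    top = float(E[mask].max())
    thresholds = np.linspace(0.0, top if top > 0 else 1.0, n_thresholds)
    fractions = np.array([coverage_fraction(E, mask, t) for t in thresholds])
    return CoverageCurve(thresholds, fractions)


def _healthy_irr_volumes(solution: FieldSolution, tissue_labels: np.ndarray,
                         mask_table: Dict[int, str], target_label: int,
                         thresholds: Dict[str, Tuple[float, float]],
                         voxel_mm3: float) -> Dict[str, float]:
    out = {}
    for lab, name in mask_table.items():
        if lab == target_label:
            continue
        sel = tissue_labels == lab
        if not sel.any():
            continue
        e_irr = thresholds.get(name, thresholds.get("default", (400.0, 800.0)))[1]
        out[name] = float(np.count_nonzero(solution.cumulative_field[sel] >= e_irr)
                          ) * voxel_mm3
    return out


def _evaluate(voltages, tissue_labels, electrode_labels, pairs, props, spacing,
              target_mask, e_rev, constraints) -> Tuple[float, FieldSolution]:
    sol = solve_sequence(tissue_labels, electrode_labels, pairs, voltages, props,
                         spacing, tol=constraints.solver_tol,
                         max_iter=constraints.solver_max_iter)
    return coverage_fraction(sol.cumulative_field, target_mask, e_rev), sol


def optimize_pair_voltages(tissue_labels: np.ndarray, electrode_labels: np.ndarray,
                           array: ElectrodeArray,
                           props: Dict[int, TissueProperties],
                           target_mask: np.ndarray, e_rev: float,
                           spacing=(1.0, 1.0, 1.0),
                           constraints: PlannerConstraints = None,
                           mask_table: Dict[int, str] = None,
                           target_label: int = None,
                           thresholds: Dict[str, Tuple[float, float]] = None,
                           per_pair_descent: bool = True) -> VoltagePlan:
    """Minimal voltages covering the target at the reversible threshold.

    Stage 1 bisects a common voltage applied to every pair on the ΔU lattice
    between the generator limits (coverage is monotone in voltage, checked
    during the search). Stage 2 optionally lowers each pair's voltage in ΔU
    steps while coverage holds. Infeasibility at the maximum voltage returns
    the best-found plan flagged infeasible rather than raising, so a caller
    can escalate the needle count. Fully deterministic.
    """
    c = constraints or PlannerConstraints()
    pairs = array.pairs
    step = c.voltage_step

    def common(U):
        return [float(U)] * len(pairs)

    cov_hi, sol_hi = _evaluate(common(c.max_voltage), tissue_labels,
                               electrode_labels, pairs, props, spacing,
                               target_mask, e_rev, c)
    if cov_hi < c.required_coverage:
        return _finish(pairs, common(c.max_voltage), cov_hi, sol_hi, False,
                       tissue_labels, mask_table, target_label, thresholds, spacing)

    cov_lo, sol_lo = _evaluate(common(c.min_voltage), tissue_labels,
                               electrode_labels, pairs, props, spacing,
                               target_mask, e_rev, c)
    if cov_lo >= c.required_coverage:
        best_U, cov, sol = c.min_voltage, cov_lo, sol_lo
    else:
        if cov_lo > cov_hi + 1e-12:
            raise RuntimeError("coverage decreased with voltage during bisection")
        # bisection on the ΔU lattice: invariant cov(hi) feasible, cov(lo) not
        lo_steps = 0
        hi_steps = int(np.ceil((c.max_voltage - c.min_voltage) / step))
        best = (c.max_voltage, cov_hi, sol_hi)
        while hi_steps - lo_steps > 1:
            mid = (lo_steps + hi_steps) // 2
            U = min(c.min_voltage + mid * step, c.max_voltage)
            cov, sol = _evaluate(common(U), tissue_labels, electrode_labels,
                                 pairs, props, spacing, target_mask, e_rev, c)
            if cov >= c.required_coverage:
                hi_steps = mid
                best = (U, cov, sol)
            else:
                lo_steps = mid
        best_U, cov, sol = best

    voltages = common(best_U)
    if per_pair_descent and len(pairs) > 1:
        improved = True
        while improved:
            improved = False
            for k in range(len(pairs)):
                while voltages[k] - step >= c.min_voltage:
                    trial = list(voltages)
                    trial[k] = voltages[k] - step
                    cov_t, sol_t = _evaluate(trial, tissue_labels, electrode_labels,
                                             pairs, props, spacing, target_mask,
                                             e_rev, c)
                    if cov_t >= c.required_coverage:
                        voltages, cov, sol = trial, cov_t, sol_t
                        improved = True
                    else:
                        break
    return _finish(pairs, voltages, cov, sol, True, tissue_labels, mask_table,
                   target_label, thresholds, spacing)


def _finish(pairs, voltages, cov, sol, feasible, tissue_labels, mask_table,
            target_label, thresholds, spacing) -> VoltagePlan:
    healthy = {}
    if mask_table is not None and thresholds is not None and target_label is not None:
        healthy = _healthy_irr_volumes(sol, tissue_labels, mask_table,
                                       target_label, thresholds,
                                       float(np.prod(spacing)))
    return VoltagePlan([tuple(p) for p in pairs], [float(v) for v in voltages],
                       float(cov), healthy, bool(feasible), sol)


def plan_needle_count(tissue_labels: np.ndarray, spec: ElectrodeSpec,
                      entry_mm, target_mm,
                      props: Dict[int, TissueProperties],
                      target_mask: np.ndarray, e_rev: float,
                      spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0),
                      needle_spacing_mm: float = 10.0,
                      constraints: PlannerConstraints = None,
                      **plan_kwargs):
    """Escalate the needle count of a variable array until feasible.

    Starts at 2 needles on the placement row; each time the voltage
    optimization is infeasible one more needle is added (the row grows
    symmetrically around the target, so needles nearest the target come
    first) and the optimization re-runs. Returns ``(array, plan)``; the plan
    is flagged infeasible if even ``max_needles`` cannot cover the target.
    """
    if spec.style != "variable":
        raise ValueError("needle-count planning applies to variable-geometry specs")
    c = constraints or PlannerConstraints()
    best = None
    for n in range(2, c.max_needles + 1):
        array = place_parallel_array(spec, entry_mm, target_mm, n_needles=n,
                                     spacing_mm=needle_spacing_mm)
        electrode_labels = rasterize_electrodes(array, tissue_labels.shape,
                                                spacing, origin)
        plan = optimize_pair_voltages(tissue_labels, electrode_labels, array,
                                      props, target_mask, e_rev, spacing, c,
                                      **plan_kwargs)
        best = (array, plan)
        if plan.feasible:
            return best
    return best
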