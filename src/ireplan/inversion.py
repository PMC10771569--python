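"""Threshold inversion: from measured ablation areas to a field threshold.

The bench workflow measures an ablation area per replicate (segmented
live/dead imaging), simulates the same delivery, and asks which field
iso-level encloses exactly the measured area.  Reading the ablation sweep
backwards therefore turns each measured area into a per-sample threshold;
pooling replicates gives the tissue's irreversible-electroporation
threshold as mean ± SD (for Hep-G2 hydrogels, 544 ± 61 V/cm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EmptyInputError, OutOfRangeError
from .planning import AblationSweep, ActivationPlan, ablation_sweep, run_plan
from . import synthetic


@dataclass
class ThresholdEstimate:
    """Per-sample inverted thresholds pooled into mean ± SD (V/cm)."""

    per_sample_V_per_cm: list
    mean_V_per_cm: float
    sd_V_per_cm: float
    n: int

    @classmethod
    def from_samples(cls, per_sample) -> "ThresholdEstimate":
        return aggregate_thresholds(per_sample)


def invert_threshold(sweep: AblationSweep, measured_area: float) -> float:
    """Threshold at which the simulated ablated measure equals a measurement.

    Monotone piecewise-linear interpolation of the (threshold, area)
    table; among exact ties the smallest threshold is returned.  A
    measurement larger than any simulated ablation is an error (the
    simulation cannot explain it); one smaller than the ablation at the
    top of the ladder returns the ladder maximum with a warning.
    """
    m = float(measured_area)
    if not np.isfinite(m) or m < 0:
        raise DomainError("measured area must be finite and non-negative")
    t = sweep.thresholds_V_per_cm
    A = sweep.ablated_measure
    if m > A[0]:
        raise OutOfRangeError(
            f"measured area {m:.4g} {sweep.units_label} exceeds the maximum "
            f"simulated ablation {A[0]:.4g} at threshold {t[0]:.4g} V/cm"
        )
    if m < A[-1]:
        warnings.warn(
            "measured area below the sweep range; returning the ladder maximum",
            stacklevel=2,
        )
        return float(t[-1])
    # A is non-increasing, so -A is non-decreasing: first index with A <= m
    j = int(np.searchsorted(-A, -m, side="left"))
    if A[j] == m:
        return float(t[j])
    frac = (A[j - 1] - m) / (A[j - 1] - A[j])
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def aggregate_thresholds(per_sample) -> ThresholdEstimate:
    """Pool per-sample thresholds: arithmetic mean and sample SD (n−1)."""
    values = np.asarray(list(per_sample), dtype=float)
    if values.size == 0:
        raise EmptyInputError("no per-sample thresholds to aggregate")
    if not np.isfinite(values).all():
        raise DomainError("per-sample thresholds must be finite")
    n = int(values.size)
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return ThresholdEstimate(
        per_sample_V_per_cm=values.tolist(),
        mean_V_per_cm=mean,
        sd_V_per_cm=sd,
        n=n,
    )


def recover_from_sweep(
    sweep: AblationSweep,
    true_threshold_V_per_cm: float,
    noise_cv: float,
    n_samples: int,
    seed: int,
) -> ThresholdEstimate:
    """Synthetic recovery against an existing sweep (no new solves).

    Draws noisy measured areas around the sweep's own area at the ground
    truth threshold, inverts each and pools.  Useful for replicating the
    noise experiment many times without re-running the field solver.
    """
    ms = synthetic.measurements_from_sweep(
        sweep, true_threshold_V_per_cm, noise_cv, n_samples, seed
    )
    per_sample = [invert_threshold(sweep, a) for a in ms.areas_mm]
    return aggregate_thresholds(per_sample)


def threshold_recovery_experiment(
    geometry,
    electrodes,
    plan: ActivationPlan,
    true_threshold_V_per_cm: float,
    noise_cv: float,
    n_samples: int,
    seed: int,
    e_min_V_per_cm: float = 200.0,
    e_max_V_per_cm: float = 1200.0,
    step_V_per_cm: float = 1.0,
    region: int | None = None,
    options=None,
) -> ThresholdEstimate:
    """End-to-end synthetic parameter recovery.

    Runs the forward model once, generates ``n_samples`` noisy measured
    areas under a known ground-truth threshold, inverts each through the
    sweep and aggregates.  Fully reproducible for a fixed seed.  The
    default ladder (200–1200 V/cm, 1 V/cm) matches the small-well
    surface-integration convention.
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be non-negative")
    if n_samples < 1:
        raise DomainError("n_samples must be at least 1")
    cum = run_plan(geometry, electrodes, plan, options)
    sweep = ablation_sweep(
        cum, e_min_V_per_cm, e_max_V_per_cm, step_V_per_cm, region=region
    )
    return recover_from_sweep(
        sweep, true_threshold_V_per_cm, noise_cv, n_samples, seed
    )
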