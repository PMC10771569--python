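"""Synthetic stand-ins for the wet-lab inputs.

Every generator here is a pure function of its parameters and a seed:
noisy "measured" ablation areas drawn around the forward model's own
prediction, bumpy-ellipsoid tumor masks standing in for CT segmentations,
inter-electrode resistance readouts, and binary live/dead z-stacks with a
pixel-counting measurement that emulates the image-analysis step.

Replicate scatter on ablation areas is modeled as multiplicative Gaussian
noise (a coefficient of variation), since observed scatter grows with
ablation size; areas are clipped to physical bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .errors import DomainError, EmptyInputError, FormatError
from .geometry import HydrogelGeometry, TumorModel
from .planning import AblationSweep, CumulativeField, ablation_sweep, run_plan
from .solver import SolverOptions, compute_resistance, solve_field
from .conductivity import ConductivityModel


@dataclass
class SyntheticMeasurementSet:
    """Noisy synthetic ablation measurements with known ground truth."""

    areas_mm: np.ndarray
    true_threshold_V_per_cm: float
    noise_cv: float
    seed: int
    provenance: dict = field(default_factory=dict)


def measurements_from_sweep(
    sweep: AblationSweep,
    true_threshold_V_per_cm: float,
    noise_cv: float,
    n: int,
    seed: int,
    provenance: dict | None = None,
) -> SyntheticMeasurementSet:
    """Draw noisy areas around the sweep's area at the true threshold.

    area_i = A(true_threshold) · (1 + ε_i), ε_i ~ N(0, noise_cv²),
    clipped to [0, domain measure].
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be non-negative")
    if n < 1:
        raise DomainError("need at least one sample")
    a_true = float(
        np.interp(
            true_threshold_V_per_cm,
            sweep.thresholds_V_per_cm,
            sweep.ablated_measure,
        )
    )
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_cv, size=n) if noise_cv > 0 else np.zeros(n)
    areas = np.clip(a_true * (1.0 + eps), 0.0, sweep.domain_measure)
    return SyntheticMeasurementSet(
        areas_mm=areas,
        true_threshold_V_per_cm=true_threshold_V_per_cm,
        noise_cv=noise_cv,
        seed=seed,
        provenance=provenance or {},
    )


def synth_ablation_measurements(
    geometry: HydrogelGeometry,
    electrodes,
    plan,
    true_threshold_V_per_cm: float,
    noise_cv: float,
    n: int,
    seed: int,
    e_min_V_per_cm: float = 200.0,
    e_max_V_per_cm: float = 1200.0,
    step_V_per_cm: float = 1.0,
    region: int | None = None,
    options: SolverOptions | None = None,
) -> SyntheticMeasurementSet:
    """Run the forward model and emit noisy measured areas around it."""
    cum = run_plan(geometry, electrodes, plan, options)
    sweep = ablation_sweep(
        cum, e_min_V_per_cm, e_max_V_per_cm, step_V_per_cm, region=region
    )
    prov = {
        "shape": geometry.shape,
        "grid_spacing_cm": geometry.spacing_cm,
        "n_activations": len(plan),
    }
    return measurements_from_sweep(
        sweep, true_threshold_V_per_cm, noise_cv, n, seed, provenance=prov
    )


def _real_spherical_perturbation(theta, phi, max_degree: int, rng) -> np.ndarray:
    """Seeded low-order real spherical-harmonic surface perturbation.

    Sums degrees 1..max_degree with standard-normal coefficients and
    normalizes to unit max amplitude, so the caller's bumpiness parameter
    bounds the relative radial excursion exactly.
    """
    f = np.zeros(theta.shape)
    for l in range(1, max_degree + 1):
        for m in range(0, l + 1):
            y = sph_harm_y(l, m, theta, phi)
            f += rng.normal() * y.real
            if m > 0:
                f += rng.normal() * y.imag
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def synth_tumor(
    base_radius_mm: float,
    bumpiness: float = 0.2,
    n_lobes: int = 3,
    voxel_size_mm: float = 0.5,
    seed: int = 0,
) -> TumorModel:
    """Star-convex bumpy tumor mask standing in for a CT segmentation.

    The surface is r(θ, φ) = R·(1 + b·p(θ, φ)) with p a seeded
    low-order spherical-harmonic perturbation of unit max amplitude, so
    b = 0 gives a sphere and b < 0.5 keeps the shape star-convex about
    its center.  Radii around 5.2, 6.4 and 9.3 mm reproduce the 0.6, 1.1
    and 3.4 cm³ tumor-mold volumes.
    """
    if base_radius_mm <= voxel_size_mm:
        raise DomainError("base_radius must exceed the voxel size")
    if not (0.0 <= bumpiness < 0.5):
        raise DomainError("bumpiness must lie in [0, 0.5)")
    if n_lobes < 1:
        raise DomainError("n_lobes must be at least 1")
    if voxel_size_mm <= 0:
        raise DomainError("voxel size must be positive")

    rng = np.random.default_rng(seed)
    r_max = base_radius_mm * (1.0 + bumpiness)
    k = int(np.ceil(r_max / voxel_size_mm)) + 1
    ax = voxel_size_mm * np.arange(-k, k + 1)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, zz / np.maximum(r, 1e-300), 1.0), -1, 1))
    phi = np.arctan2(yy, xx)

    if bumpiness > 0:
        p = _real_spherical_perturbation(theta, phi, n_lobes, rng)
        surface = base_radius_mm * (1.0 + bumpiness * p)
    else:
        surface = np.full(r.shape, base_radius_mm)
    mask = r <= surface
    return TumorModel(mask=mask, voxel_size_mm=voxel_size_mm)


def radius_for_volume_cm3(volume_cm3: float) -> float:
    """Sphere radius (mm) for a target tumor volume in cm³."""
    if volume_cm3 <= 0:
        raise DomainError("volume must be positive")
    return float((3.0 * volume_cm3 * 1e3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def synth_resistance(
    geometry: HydrogelGeometry,
    electrodes,
    pair,
    true_sigma_S_per_m: float,
    noise_cv: float = 0.0,
    seed: int = 0,
    amplitude_V: float = 100.0,
    options: SolverOptions | None = None,
) -> float:
    """Noisy inter-electrode resistance readout at a known conductivity.

    Solves the constant-σ forward problem and perturbs the resulting
    resistance multiplicatively, emulating a pulse generator's readout.
    """
    if true_sigma_S_per_m <= 0:
        raise DomainError("true conductivity must be positive")
    if noise_cv < 0:
        raise DomainError("noise_cv must be non-negative")
    geom = HydrogelGeometry(
        shape=geometry.shape,
        spacing_m=geometry.spacing_m,
        inside=geometry.inside,
        region=geometry.region,
        region_conductivity={
            rid: ConductivityModel.constant(true_sigma_S_per_m)
            for rid in geometry.region_conductivity
        },
        origin_m=geometry.origin_m,
        height_cm=geometry.height_cm,
        outer_diameter_cm=geometry.outer_diameter_cm,
        inner_diameter_cm=geometry.inner_diameter_cm,
    )
    sol = solve_field(geom, electrodes, pair, amplitude_V, options)
    r = compute_resistance(sol, amplitude_V)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        r *= 1.0 + rng.normal(0.0, noise_cv)
    if r <= 0:
        raise DomainError("noise drove the synthetic resistance non-positive")
    return float(r)


def render_ablation_stack(
    cum: CumulativeField,
    threshold_V_per_cm: float,
    n_slices: int = 5,
    pixel_size_mm: float | None = None,
) -> np.ndarray:
    """Binary live/dead z-stack of the super-threshold region.

    Emulates the confocal z-stack of a treated hydrogel: pages are (y, x)
    masks of cells at or above the threshold.  A 2D field is replicated
    across ``n_slices``; a 3D field is sampled at ``n_slices`` evenly
    spaced z planes.  ``pixel_size_mm`` defaults to the grid spacing;
    other values resample by nearest neighbor.
    """
    if n_slices < 1:
        raise DomainError("n_slices must be at least 1")
    grid_mm = cum.geometry.spacing_m * 1e3
    if pixel_size_mm is None:
        pixel_size_mm = grid_mm
    if pixel_size_mm <= 0:
        raise DomainError("pixel size must be positive")

    binary = (cum.cumulative_magnitude >= threshold_V_per_cm) & cum.tissue
    if cum.geometry.ndim == 2:
        slices = [binary] * n_slices
    else:
        zi = np.linspace(0, binary.shape[2] - 1, n_slices).round().astype(int)
        slices = [binary[:, :, k] for k in zi]

    pages = []
    for sl in slices:
        page = sl.T  # (x, y) -> image convention (row=y, col=x)
        if not np.isclose(pixel_size_mm, grid_mm):
            from scipy.ndimage import zoom

            page = zoom(page.astype(np.uint8), grid_mm / pixel_size_mm, order=0) > 0
        pages.append(page.astype(np.uint8))
    return np.stack(pages, axis=0)


def measure_stack(
    stack: np.ndarray, pixel_size_mm: float, slice_thickness_mm: float
):
    """Pixel-counting measurement of a binary z-stack.

    Returns (area per slice in mm², total volume in mm³): area is the
    foreground pixel count times the pixel area, volume the sum of slice
    areas times the slice thickness — the standard image-analysis
    estimate of an unviable volume from segmented planes.
    """
    stack = np.asarray(stack)
    if stack.size == 0:
        raise EmptyInputError("empty stack")
    if stack.ndim == 2:
        stack = stack[None]
    if not np.isin(np.unique(stack), (0, 1)).all():
        raise FormatError("stack must be binary (0/1)")
    if pixel_size_mm <= 0 or slice_thickness_mm <= 0:
        raise DomainError("pixel size and slice thickness must be positive")
    areas = stack.reshape(stack.shape[0], -1).sum(axis=1) * pixel_size_mm**2
    volume = float(areas.sum() * slice_thickness_mm)
    return areas.astype(float), volume
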