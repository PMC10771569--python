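"""Activation plans, field superposition, ablation sweeps and coverage.

A treatment is an ordered list of pair activations.  Pairs are energized
sequentially, so each activation is solved as its own boundary-value
problem and the *cumulative* exposure at a point is the pointwise maximum
field magnitude it saw over the plan — the peak local exposure is what
governs whether a cell electroporates.  The ablation sweep tabulates, for
a ladder of candidate field thresholds, the area (2D) or volume (3D) of
the super-threshold region by cell counting; this table is the bridge
between simulation and the measured ablation areas, and its inverse is the
threshold-estimation step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError, EmptyInputError
from .geometry import ElectrodeConfig, HydrogelGeometry
from .solver import FieldSolution, SolverOptions, electrode_masks, solve_field

#: experimentally determined irreversible-electroporation threshold for
#: Hep-G2 hydrogels, V/cm
EXPERIMENTAL_IRE_THRESHOLD_V_PER_CM = 544.0
#: threshold reported in vivo for healthy liver, V/cm
REPORTED_IRE_THRESHOLD_V_PER_CM = 800.0

LABEL_UNTREATED = 0
LABEL_EXP_ONLY = 1
LABEL_REP = 2


@dataclass(frozen=True)
class PulseProtocol:
    """One pulse train: amplitude, pulse count, width and repetition rate.

    The default 100 μs width at 1 Hz matches standard bench protocols;
    pulse count and rate enter the model only through the treatment time
    (field maps are quasi-static per pulse).
    """

    amplitude_V: float
    n_pulses: int
    pulse_width_us: float = 100.0
    frequency_Hz: float = 1.0

    def __post_init__(self):
        if self.amplitude_V <= 0 or self.n_pulses <= 0:
            raise DomainError("amplitude and pulse count must be positive")
        if self.pulse_width_us <= 0 or self.frequency_Hz <= 0:
            raise DomainError("pulse width and frequency must be positive")
        if self.pulse_width_us * 1e-6 > 1.0 / self.frequency_Hz:
            raise DomainError("pulse width exceeds the pulse period")

    @property
    def duration_s(self) -> float:
        return self.n_pulses / self.frequency_Hz


@dataclass
class ActivationPlan:
    """Ordered (electrode pair, pulse protocol) activations."""

    activations: list  # list[(tuple[str, str], PulseProtocol)]

    def __post_init__(self):
        self.activations = [(tuple(p), proto) for p, proto in self.activations]

    def __len__(self) -> int:
        return len(self.activations)

    @classmethod
    def uniform(cls, pairs, amplitude_V, n_pulses, **kwargs) -> "ActivationPlan":
        """Same protocol delivered to every pair in ``pairs``."""
        proto = PulseProtocol(amplitude_V=amplitude_V, n_pulses=n_pulses, **kwargs)
        return cls([(p, proto) for p in pairs])


@dataclass
class CumulativeField:
    """Pointwise-maximum field magnitude over a plan's activations.

    ``tissue`` marks in-domain cells that are not occupied by any needle;
    ablation areas and coverage fractions are counted over tissue cells.
    """

    geometry: HydrogelGeometry
    electrodes: ElectrodeConfig
    cumulative_magnitude: np.ndarray  # V/cm
    solutions: list = field(default_factory=list, repr=False)
    tissue: np.ndarray = None

    def region_tissue_mask(self, region_id: int | None = None) -> np.ndarray:
        mask = self.tissue if region_id is None else (
            self.tissue & (self.geometry.region == region_id)
        )
        if not mask.any():
            raise EmptyInputError(f"region {region_id!r} contains no tissue cells")
        return mask


@dataclass
class AblationSweep:
    """Monotone table: candidate threshold → ablated area (or volume).

    ``ablated_measure`` is in mm² for 2D domains and mm³ for 3D ones;
    ``domain_measure`` is the total tissue measure of the swept region.
    """

    thresholds_V_per_cm: np.ndarray
    ablated_measure: np.ndarray
    domain_measure: float
    units_label: str  # "mm2" or "mm3"

    def __post_init__(self):
        t = np.asarray(self.thresholds_V_per_cm, dtype=float)
        a = np.asarray(self.ablated_measure, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise DomainError("thresholds must be strictly ascending")
        if np.any(np.diff(a) > 1e-9 * max(1.0, a.max(initial=0.0))):
            raise DomainError("ablated measure must be non-increasing in threshold")
        self.thresholds_V_per_cm = t
        self.ablated_measure = a


def run_plan(
    geometry: HydrogelGeometry,
    electrodes: ElectrodeConfig,
    plan: ActivationPlan,
    options: SolverOptions | None = None,
) -> CumulativeField:
    """Solve every activation and superpose by pointwise maximum.

    Per-activation :class:`FieldSolution` records are kept for audit.
    Cells occupied by a needle in *any* activation are excluded from the
    tissue mask (metal sites are not hydrogel), and a cell that is outside
    one activation's conducting domain simply contributes zero exposure
    for that activation.
    """
    if len(plan) == 0:
        raise EmptyInputError("activation plan is empty")
    masks = electrode_masks(geometry, electrodes)
    tissue = geometry.inside.copy()
    for m in masks.values():
        tissue &= ~m

    cumulative = np.zeros(geometry.inside.shape)
    solutions = []
    for k, (pair, proto) in enumerate(plan.activations):
        try:
            sol = solve_field(geometry, electrodes, pair, proto.amplitude_V, options)
        except Exception as exc:
            raise type(exc)(
                f"activation {k} (pair {pair}, {proto.amplitude_V} V) failed: {exc}"
            ) from exc
        np.maximum(cumulative, sol.field_magnitude, out=cumulative)
        solutions.append(sol)

    cumulative[~geometry.inside] = 0.0
    return CumulativeField(
        geometry=geometry,
        electrodes=electrodes,
        cumulative_magnitude=cumulative,
        solutions=solutions,
        tissue=tissue,
    )


def ablation_sweep(
    cum: CumulativeField,
    e_min_V_per_cm: float,
    e_max_V_per_cm: float,
    step_V_per_cm: float,
    region: int | None = None,
) -> AblationSweep:
    """Tabulate super-threshold tissue measure over a threshold ladder.

    A cell counts as ablated at threshold t iff its cumulative magnitude
    is ≥ t (boundary cells count as ablated).  The measure is cell count
    times cell area/volume — no sub-cell correction, so refine the grid
    rather than the ladder for accuracy.  Typical ladders are 200–1200
    V/cm in 1 V/cm steps for small wells and 20 V/cm steps for larger
    domains and tumors.
    """
    if not (e_min_V_per_cm < e_max_V_per_cm):
        raise DomainError("e_min must be below e_max")
    if step_V_per_cm <= 0:
        raise DomainError("step must be positive")
    mask = cum.region_tissue_mask(region)

    thresholds = np.arange(
        e_min_V_per_cm, e_max_V_per_cm + 0.5 * step_V_per_cm, step_V_per_cm
    )
    values = np.sort(cum.cumulative_magnitude[mask])
    n = values.size
    counts = n - np.searchsorted(values, thresholds, side="left")
    measure = cum.geometry.cell_measure_mm
    return AblationSweep(
        thresholds_V_per_cm=thresholds,
        ablated_measure=counts * measure,
        domain_measure=n * measure,
        units_label="mm2" if cum.geometry.ndim == 2 else "mm3",
    )


def coverage_fraction(
    cum: CumulativeField, threshold_V_per_cm: float, region: int | None = None
) -> float:
    """Fraction of a region's tissue at or above a field threshold.

    1.0 means complete coverage of the region (e.g. a fully treated
    tumor); 0.0 means no cell reached the threshold.
    """
    mask = cum.region_tissue_mask(region)
    return float(
        np.count_nonzero(cum.cumulative_magnitude[mask] >= threshold_V_per_cm)
    ) / int(mask.sum())


def classify_field_map(
    cum: CumulativeField,
    exp_threshold_V_per_cm: float = EXPERIMENTAL_IRE_THRESHOLD_V_PER_CM,
    rep_threshold_V_per_cm: float = REPORTED_IRE_THRESHOLD_V_PER_CM,
) -> np.ndarray:
    """Tri-level coverage map over the domain.

    0 = untreated (below the experimental threshold), 1 = above the
    experimental but below the reported in-vivo threshold, 2 = above the
    reported threshold.  Ties go to the higher label.  Cells outside the
    domain are -1.
    """
    if exp_threshold_V_per_cm > rep_threshold_V_per_cm:
        raise DomainError("exp_threshold must not exceed rep_threshold")
    E = cum.cumulative_magnitude
    labels = np.full(E.shape, -1, dtype=np.int8)
    inside = cum.geometry.inside
    labels[inside] = LABEL_UNTREATED
    labels[inside & (E >= exp_threshold_V_per_cm)] = LABEL_EXP_ONLY
    labels[inside & (E >= rep_threshold_V_per_cm)] = LABEL_REP
    return labels


def treatment_time(plan: ActivationPlan) -> float:
    """Total delivery time in seconds: Σ pulses / repetition rate."""
    if len(plan) == 0:
        warnings.warn("empty plan has zero treatment time", stacklevel=2)
        return 0.0
    return float(sum(proto.duration_s for _, proto in plan.activations))
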