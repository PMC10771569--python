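"""Computational domains: well-plate hydrogel discs, co-culture annuli,
electrode layouts and voxelized tumor models.

Conventions
-----------
* Axial-plane coordinates are 2D Cartesian ``(x, y)`` with the well center
  at the origin; needles are parallel to the z axis, so tumor voxels are
  indexed ``(x, y, z)``.
* All grids are regular Cartesian with an inside/outside flag (embedded
  boundary).  A cell belongs to the domain, and to a region, iff its
  *center* does.
* Interfaces use cm (wells, electrodes) and mm (voxels); arrays are stored
  with SI spacing internally (see :mod:`ireplan.units`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .conductivity import (
    ConductivityModel,
    HCC_SIGMA_S_PER_M,
    UMBILICAL_SIGMA_S_PER_M,
)
from .errors import (
    ConfigurationError,
    DomainError,
    EmptyInputError,
    FormatError,
    PlacementError,
)
from . import units

#: nominal hydrogel cross-section areas by well-plate format, mm²
PLATE_AREAS_MM2 = {24: 190.0, 12: 380.0, 6: 950.0}

#: co-culture annulus: outer endothelial disk and inner tumor core, cm
COCULTURE_OUTER_DIAMETER_CM = 1.56
COCULTURE_INNER_DIAMETER_CM = 1.0

#: blunt-tip G19 needle, 0.91 mm outer diameter -> 0.0455 cm radius
DEFAULT_ELECTRODE_RADIUS_CM = 0.0455
#: modeled electrode height (3 mm stainless-steel cylinders)
DEFAULT_MODELED_HEIGHT_CM = 0.3

CORE_REGION = 0
RING_REGION = 1
BACKGROUND_REGION = 0
TUMOR_REGION = 1


@dataclass
class HydrogelGeometry:
    """A discretized hydrogel domain (disc, annulus or voxel mask).

    ``inside`` and ``region`` are 2D ``(nx, ny)`` or 3D ``(nx, ny, nz)``
    arrays; ``region`` is -1 outside the domain.  ``origin_m`` gives the
    physical coordinate of the center of cell index 0 along each axis.
    """

    shape: str
    spacing_m: float
    inside: np.ndarray
    region: np.ndarray
    region_conductivity: dict[int, ConductivityModel]
    origin_m: tuple
    height_cm: float = DEFAULT_MODELED_HEIGHT_CM
    outer_diameter_cm: float | None = None
    inner_diameter_cm: float | None = None

    def __post_init__(self):
        if self.shape not in ("disc", "annulus", "voxel_mask"):
            raise DomainError(f"unknown domain shape {self.shape!r}")
        if self.spacing_m <= 0:
            raise DomainError("grid spacing must be positive")
        if not self.inside.any():
            raise EmptyInputError("domain mask is empty")
        labels = np.unique(self.region[self.inside])
        missing = set(labels.tolist()) - set(self.region_conductivity)
        if missing:
            raise ConfigurationError(f"regions without conductivity: {missing}")
        if (self.region[self.inside] < 0).any():
            raise ConfigurationError("inside cells must carry a region label")

    # -- grid accessors -------------------------------------------------

    @property
    def ndim(self) -> int:
        return self.inside.ndim

    @property
    def spacing_cm(self) -> float:
        return units.m_to_cm(self.spacing_m)

    def axis_coords_m(self, axis: int) -> np.ndarray:
        n = self.inside.shape[axis]
        return self.origin_m[axis] + self.spacing_m * np.arange(n)

    def cell_centers_m(self):
        """Meshgrid of cell-center coordinates (SI), ``indexing='ij'``."""
        coords = [self.axis_coords_m(a) for a in range(self.ndim)]
        return np.meshgrid(*coords, indexing="ij")

    # -- measures -------------------------------------------------------

    @property
    def cell_measure_mm(self) -> float:
        """Area of one cell in mm² (2D) or volume in mm³ (3D)."""
        h_mm = self.spacing_m * units.M_TO_MM
        return h_mm ** self.ndim

    def region_mask(self, region_id: int | None = None) -> np.ndarray:
        if region_id is None:
            return self.inside.copy()
        return self.inside & (self.region == region_id)

    def region_measure_mm(self, region_id: int | None = None) -> float:
        """Discretized area (mm², 2D) or volume (mm³, 3D) of a region."""
        return float(self.region_mask(region_id).sum()) * self.cell_measure_mm

    @property
    def wall_radius_m(self) -> float:
        if self.outer_diameter_cm is None:
            raise ConfigurationError("voxel-mask domain has no wall radius")
        return units.cm_to_m(self.outer_diameter_cm) / 2.0


def _centered_axis(radius_m: float, spacing_m: float) -> np.ndarray:
    """Symmetric cell centers covering [-radius, radius], odd count.

    An odd, centered grid keeps 90-degree rotations exact on the lattice,
    which the multi-pair superposition tests rely on.
    """
    k = int(np.floor(radius_m / spacing_m + 0.5))
    return spacing_m * np.arange(-k, k + 1)


def make_well_geometry(
    plate_format: int,
    coculture: bool = False,
    grid_spacing_cm: float = 0.01,
    conductivity: ConductivityModel | None = None,
    inner_conductivity: ConductivityModel | None = None,
    outer_conductivity: ConductivityModel | None = None,
    height_cm: float = DEFAULT_MODELED_HEIGHT_CM,
) -> HydrogelGeometry:
    """Build the axial cross-section of a well-plate hydrogel.

    Monoculture wells are discs whose nominal area matches the plate
    format (24-well: 190 mm², 12-well: 380 mm², 6-well: 950 mm²).  The
    co-culture configuration (24-well only) is an annulus: a Ø 1.0 cm
    tumor-cell core inside a Ø 1.56 cm endothelial ring, with the
    hepatocellular-carcinoma and umbilical-cord conductivities (1.26 and
    1.46 S/m) as region defaults.

    Parameters
    ----------
    plate_format:
        24, 12 or 6.
    coculture:
        Build the two-region annular model (24-well only).
    grid_spacing_cm:
        Cell size; must be at most one tenth of the outer diameter.
    conductivity:
        Region model for monoculture discs.  Defaults to the
        field-dependent liver sigmoid (0.4 → 1.6 S/m).
    """
    if plate_format not in PLATE_AREAS_MM2:
        raise ConfigurationError(f"unknown plate format {plate_format}")
    if coculture and plate_format != 24:
        raise ConfigurationError("co-culture geometry is defined for 24-well plates only")
    if grid_spacing_cm <= 0:
        raise DomainError("grid_spacing_cm must be positive")

    if coculture:
        outer_d_cm = COCULTURE_OUTER_DIAMETER_CM
        inner_d_cm = COCULTURE_INNER_DIAMETER_CM
    else:
        area_mm2 = PLATE_AREAS_MM2[plate_format]
        outer_d_cm = 2.0 * np.sqrt(area_mm2 / np.pi) / 10.0
        inner_d_cm = None

    if grid_spacing_cm > outer_d_cm / 10.0:
        raise DomainError("grid_spacing_cm must be at most outer_diameter / 10")

    h_m = units.cm_to_m(grid_spacing_cm)
    r_m = units.cm_to_m(outer_d_cm) / 2.0
    ax = _centered_axis(r_m, h_m)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    rr2 = xx**2 + yy**2
    inside = rr2 <= r_m**2

    region = np.full(inside.shape, -1, dtype=np.int8)
    if coculture:
        r_in_m = units.cm_to_m(inner_d_cm) / 2.0
        core = inside & (rr2 <= r_in_m**2)
        region[inside] = RING_REGION
        region[core] = CORE_REGION
        region_conductivity = {
            CORE_REGION: inner_conductivity
            or ConductivityModel.constant(HCC_SIGMA_S_PER_M),
            RING_REGION: outer_conductivity
            or ConductivityModel.constant(UMBILICAL_SIGMA_S_PER_M),
        }
        shape = "annulus"
    else:
        region[inside] = CORE_REGION
        region_conductivity = {
            CORE_REGION: conductivity or ConductivityModel.liver_field_dependent()
        }
        shape = "disc"

    return HydrogelGeometry(
        shape=shape,
        spacing_m=h_m,
        inside=inside,
        region=region,
        region_conductivity=region_conductivity,
        origin_m=(float(ax[0]), float(ax[0])),
        height_cm=height_cm,
        outer_diameter_cm=outer_d_cm,
        inner_diameter_cm=inner_d_cm,
    )


@dataclass
class ElectrodeConfig:
    """Needle electrode positions in the axial plane.

    Needles are modeled as circular cross-sections of ``radius_cm`` at the
    listed ``(x, y)`` positions (cm); in 3D domains they extend along z
    through the whole grid.  Labels run E1, E2, ...
    """

    positions_cm: list
    radius_cm: float = DEFAULT_ELECTRODE_RADIUS_CM
    modeled_height_cm: float = DEFAULT_MODELED_HEIGHT_CM
    labels: list = field(default_factory=list)
    layout: str | None = None

    def __post_init__(self):
        self.positions_cm = [tuple(map(float, p)) for p in self.positions_cm]
        if not self.labels:
            self.labels = [f"E{i + 1}" for i in range(len(self.positions_cm))]
        if len(self.labels) != len(self.positions_cm):
            raise ConfigurationError("labels and positions length mismatch")
        if self.radius_cm <= 0:
            raise DomainError("electrode radius must be positive")
        pos = np.asarray(self.positions_cm, dtype=float)
        if len(pos) >= 2:
            d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
            iu = np.triu_indices(len(pos), k=1)
            if np.any(d[iu] <= 2 * self.radius_cm):
                raise PlacementError("electrodes overlap")

    def position_of(self, label: str):
        try:
            return self.positions_cm[self.labels.index(label)]
        except ValueError as exc:
            raise ConfigurationError(f"unknown electrode label {label!r}") from exc

    def __len__(self) -> int:
        return len(self.positions_cm)


_LAYOUT_ARITY = {"pair": 2, "triangle": 3, "square": 4}


def place_electrodes(
    geometry: HydrogelGeometry,
    layout: str,
    spacing_cm: float,
    electrode_radius_cm: float = DEFAULT_ELECTRODE_RADIUS_CM,
    modeled_height_cm: float | None = None,
) -> ElectrodeConfig:
    """Place a symmetric needle layout centered on the well axis.

    ``pair`` is two collinear needles ``spacing_cm`` apart on the x axis;
    ``triangle`` an equilateral triangle of side ``spacing_cm``;
    ``square`` an axis-aligned square of side ``spacing_cm`` (so opposite
    corners sit ``spacing * sqrt(2)`` apart).  Raises
    :class:`PlacementError` if any needle would leave less than one
    electrode radius of clearance to the well wall.
    """
    if layout not in _LAYOUT_ARITY:
        raise ConfigurationError(f"unknown layout {layout!r}")
    if spacing_cm <= 2 * electrode_radius_cm:
        raise PlacementError("electrode spacing must exceed the needle diameter")

    s = spacing_cm
    if layout == "pair":
        pos = [(-s / 2, 0.0), (s / 2, 0.0)]
    elif layout == "triangle":
        rc = s / np.sqrt(3.0)  # circumradius of an equilateral triangle
        angles = np.deg2rad([90.0, 210.0, 330.0])
        pos = [(rc * np.cos(a), rc * np.sin(a)) for a in angles]
    else:  # square, labeled counterclockwise from the lower-left corner
        pos = [(-s / 2, -s / 2), (s / 2, -s / 2), (s / 2, s / 2), (-s / 2, s / 2)]

    r_wall_cm = units.m_to_cm(geometry.wall_radius_m)
    for p in pos:
        if np.hypot(*p) > r_wall_cm - 2 * electrode_radius_cm:
            raise PlacementError(
                f"electrode at {p} leaves <1 radius clearance to the "
                f"Ø {2 * r_wall_cm:.2f} cm wall"
            )

    return ElectrodeConfig(
        positions_cm=pos,
        radius_cm=electrode_radius_cm,
        modeled_height_cm=(
            geometry.height_cm if modeled_height_cm is None else modeled_height_cm
        ),
        layout=layout,
    )


def enumerate_pairs(config: ElectrodeConfig, mode: str = "all") -> list:
    """Ordered electrode pairs available for sequential activation.

    ``all`` returns every unordered pair, n(n-1)/2 of them, in
    lexicographic label order.  ``adjacent`` is defined for the square
    layout only and returns the four edge-sharing pairs (shortest
    interspace); the remaining two diagonal pairs are the "opposite"
    needles at ``spacing * sqrt(2)``.
    """
    if len(config) < 2:
        raise ConfigurationError("need at least two electrodes to form a pair")
    if mode not in ("adjacent", "all"):
        raise ConfigurationError(f"unknown pair mode {mode!r}")

    all_pairs = sorted(combinations(sorted(config.labels), 2))
    if mode == "all":
        return [tuple(p) for p in all_pairs]

    if config.layout != "square":
        raise ConfigurationError("adjacent pairs are defined for the square layout only")
    pos = {lab: np.asarray(config.position_of(lab)) for lab in config.labels}
    dists = {p: np.linalg.norm(pos[p[0]] - pos[p[1]]) for p in all_pairs}
    dmin = min(dists.values())
    return [p for p in all_pairs if dists[p] <= dmin * (1 + 1e-9)]


@dataclass
class TumorModel:
    """Voxelized binary tumor mask, axes ``(x, y, z)``, isotropic voxels."""

    mask: np.ndarray
    voxel_size_mm: float
    needle_trajectories_cm: list = field(default_factory=list)

    def __post_init__(self):
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 3:
            raise FormatError("tumor mask must be a 3D array")
        if not self.mask.any():
            raise EmptyInputError("tumor mask is empty")
        if self.voxel_size_mm <= 0:
            raise DomainError("voxel size must be strictly positive")

    @property
    def volume_mm3(self) -> float:
        return float(self.mask.sum()) * self.voxel_size_mm**3


def _trim_to_bbox(mask: np.ndarray, margin: int) -> np.ndarray:
    idx = np.nonzero(mask)
    slices = []
    for ax, ind in enumerate(idx):
        lo = max(int(ind.min()) - margin, 0)
        hi = min(int(ind.max()) + 1 + margin, mask.shape[ax])
        slices.append(slice(lo, hi))
    return mask[tuple(slices)]


def load_tumor_mask(
    path, voxel_size_mm: float | None = None, margin_voxels: int = 2
) -> TumorModel:
    """Read a binary tumor mask from NIfTI (.nii/.nii.gz) or multi-page TIFF.

    NIfTI voxel size comes from the header when not given; TIFF stacks
    (read as z-pages) require an explicit ``voxel_size_mm``.  The mask is
    trimmed to its bounding box plus ``margin_voxels`` background voxels.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if voxel_size_mm is None:
            zooms = img.header.get_zooms()[:3]
            if not np.allclose(zooms, zooms[0]):
                raise FormatError("anisotropic voxels are not supported")
            voxel_size_mm = float(zooms[0])
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        data = tifffile.imread(str(path))
        if data.ndim == 2:
            data = data[None]
        data = np.transpose(data, (2, 1, 0))  # (z, y, x) pages -> (x, y, z)
        if voxel_size_mm is None:
            raise ConfigurationError("voxel_size_mm is required for TIFF masks")
    else:
        raise FormatError(f"unsupported tumor mask format: {path.name}")

    values = np.unique(data)
    if not np.isin(values, (0, 1)).all():
        raise FormatError("tumor mask must be binary (0/1)")
    mask = data.astype(bool)
    if not mask.any():
        raise EmptyInputError(f"tumor mask {path.name} contains no foreground voxels")
    return TumorModel(mask=_trim_to_bbox(mask, margin_voxels), voxel_size_mm=voxel_size_mm)


def make_tumor_geometry(
    tumor: TumorModel,
    margin_mm: float = 4.0,
    tumor_conductivity: ConductivityModel | None = None,
    background_conductivity: ConductivityModel | None = None,
) -> HydrogelGeometry:
    """Embed a tumor mask in a box of background hydrogel for 3D solves.

    The box extends ``margin_mm`` beyond the tumor bounding box on every
    side and is centered at the origin.  Region 1 is tumor, region 0 the
    surrounding gel; both default to the hepatocellular-carcinoma
    conductivity so the baseline model is electrically homogeneous.
    """
    if margin_mm < 0:
        raise DomainError("margin_mm must be non-negative")
    h_m = units.mm_to_m(tumor.voxel_size_mm)
    pad = int(np.ceil(margin_mm / tumor.voxel_size_mm))
    mask = np.pad(tumor.mask, pad)
    inside = np.ones_like(mask, dtype=bool)
    region = np.where(mask, TUMOR_REGION, BACKGROUND_REGION).astype(np.int8)
    sigma_t = tumor_conductivity or ConductivityModel.constant(HCC_SIGMA_S_PER_M)
    sigma_b = background_conductivity or ConductivityModel.constant(HCC_SIGMA_S_PER_M)
    origin = tuple(-h_m * (n - 1) / 2.0 for n in mask.shape)
    return HydrogelGeometry(
        shape="voxel_mask",
        spacing_m=h_m,
        inside=inside,
        region=region,
        region_conductivity={TUMOR_REGION: sigma_t, BACKGROUND_REGION: sigma_b},
        origin_m=origin,
        height_cm=units.m_to_cm(h_m * mask.shape[2]),
    )
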