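"""Export of field maps, sweeps, label maps and synthetic data.

Formats are deliberately plain: CSV grids with unit-suffixed headers,
legacy ASCII VTK structured points for 3D viewers, 8-bit multi-page TIFF
for binary/label stacks, NIfTI for tumor masks.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import HydrogelGeometry, TumorModel
from .planning import AblationSweep, CumulativeField
from .solver import FieldSolution
from . import units


def field_map_frame(obj: FieldSolution | CumulativeField) -> pd.DataFrame:
    """Tabulate in-domain cells: coordinates (cm), potential, |E| (V/cm)."""
    if isinstance(obj, FieldSolution):
        geometry, mask = obj.geometry, obj.domain
        columns = {"phi_V": obj.potential, "E_V_per_cm": obj.field_magnitude}
    else:
        geometry, mask = obj.geometry, obj.geometry.inside
        columns = {"E_V_per_cm": obj.cumulative_magnitude}
    centers = geometry.cell_centers_m()
    names = ["x_cm", "y_cm", "z_cm"][: geometry.ndim]
    data = {n: units.m_to_cm(c[mask]) for n, c in zip(names, centers)}
    for name, arr in columns.items():
        data[name] = arr[mask]
    return pd.DataFrame(data)


def write_field_csv(obj, path) -> None:
    field_map_frame(obj).to_csv(path, index=False)


def sweep_frame(sweep: AblationSweep) -> pd.DataFrame:
    cols = {
        "threshold_V_per_cm": sweep.thresholds_V_per_cm,
        f"ablated_{sweep.units_label}": sweep.ablated_measure,
        "fraction": sweep.ablated_measure / sweep.domain_measure,
    }
    return pd.DataFrame(cols)


def write_sweep_csv(sweep: AblationSweep, path) -> None:
    sweep_frame(sweep).to_csv(path, index=False)


def write_vtk_structured(
    path, geometry: HydrogelGeometry, fields: dict
) -> None:
    """Legacy ASCII VTK structured-points file of cell-centered scalars.

    Arrays are (nx, ny[, nz]); VTK wants x varying fastest, so data is
    flattened in Fortran order.  Units are declared in the scalar names.
    """
    shape = geometry.inside.shape
    nx, ny = shape[0], shape[1]
    nz = shape[2] if geometry.ndim == 3 else 1
    h = geometry.spacing_m
    org = list(geometry.origin_m) + [0.0] * (3 - geometry.ndim)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("ireplan field map (SI coordinates, scalars unit-suffixed)\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {org[0]:.9g} {org[1]:.9g} {org[2]:.9g}\n")
        fh.write(f"SPACING {h:.9g} {h:.9g} {h:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            a = np.nan_to_num(np.asarray(arr, dtype=float))
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, a.ravel(order="F"), fmt="%.6g")


def write_label_map_tiff(path, labels: np.ndarray) -> None:
    """Tri-level (0/1/2) coverage map as 8-bit TIFF; -1 (outside) -> 255."""
    import tifffile

    a = np.asarray(labels)
    out = np.where(a < 0, 255, a).astype(np.uint8)
    if out.ndim == 2:
        out = out.T  # (x, y) -> image (row=y, col=x)
    else:
        out = np.transpose(out, (2, 1, 0))  # (x, y, z) -> pages (z, y, x)
    tifffile.imwrite(str(path), out, photometric="minisblack")


def write_stack_tiff(path, stack: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(
        str(path), np.asarray(stack, dtype=np.uint8), photometric="minisblack"
    )


def read_stack_tiff(path) -> np.ndarray:
    import tifffile

    data = tifffile.imread(str(path))
    return data[None] if data.ndim == 2 else data


def write_tumor_nifti(path, tumor: TumorModel) -> None:
    import nibabel as nib

    affine = np.diag([tumor.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(tumor.mask.astype(np.uint8), affine)
    nib.save(img, str(path))


def geometry_summary(geometry: HydrogelGeometry) -> dict:
    """JSON-ready description of a discretized domain."""
    return {
        "shape": geometry.shape,
        "ndim": geometry.ndim,
        "grid_spacing_cm": geometry.spacing_cm,
        "outer_diameter_cm": geometry.outer_diameter_cm,
        "inner_diameter_cm": geometry.inner_diameter_cm,
        "height_cm": geometry.height_cm,
        "n_cells_inside": int(geometry.inside.sum()),
        "measure_" + ("mm2" if geometry.ndim == 2 else "mm3"): (
            geometry.region_measure_mm()
        ),
        "regions": {
            str(rid): {
                "form": model.form,
                "sigma0_S_per_m": model.sigma0,
                "sigmaf_S_per_m": model.sigmaf,
            }
            for rid, model in geometry.region_conductivity.items()
        },
    }
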