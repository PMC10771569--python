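"""Quasi-static conduction solver for needle-electrode fields.

Each pulse train is treated in the quasi-static limit: the potential obeys
the generalized Laplace equation ``∇·(σ∇φ) = 0`` with Dirichlet data on the
active electrode pair (amplitude on the anode, ground on the cathode), zero
normal current through the insulating well wall, and conductivity that is
either constant per region or a sigmoid function of the local field
magnitude.

Discretization is a cell-centered finite-volume scheme on the geometry's
regular grid (5-point stencil in 2D, 7-point in 3D) with harmonic-mean face
conductivities, so the discrete operator is a symmetric M-matrix and the
discrete maximum principle holds.  The nonlinear σ(|E|) coupling is
resolved by damped Picard (fixed-point) iteration on the conductivity
field.  Inactive electrodes are removed from the domain and act as
insulating holes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .conductivity import ConductivityModel, sigma_of_E
from .errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateSolutionError,
    DomainError,
)
from .geometry import ElectrodeConfig, HydrogelGeometry
from . import units


@dataclass(frozen=True)
class SolverOptions:
    """Knobs for the nonlinear solve.

    ``tol`` is the relative max-norm change of the field magnitude between
    Picard iterates at which the fixed point is declared converged;
    ``relaxation`` damps the conductivity update.  ``grounded_wall``
    replaces the insulating wall with a Dirichlet ground — physically
    wrong for a plastic well, but it turns a single centered electrode
    into the coaxial-resistor configuration with a closed-form solution,
    which the validation suite uses as an oracle.
    """

    tol: float = 1e-3
    max_iterations: int = 50
    relaxation: float = 0.5
    grounded_wall: bool = False


@dataclass
class FieldSolution:
    """Potential and field maps for a single pair activation.

    ``potential`` is in volts, ``field_magnitude`` in V/cm;
    both are NaN / zero outside the solved domain.  ``current_A`` is the
    total current leaving the energized electrode (for 2D sections,
    integrated over the modeled electrode height).
    """

    geometry: HydrogelGeometry
    electrodes: ElectrodeConfig
    active_pair: tuple
    amplitude_V: float
    potential: np.ndarray
    field_magnitude: np.ndarray
    sigma_S_per_m: np.ndarray
    domain: np.ndarray
    current_A: float
    converged: bool
    iterations: int
    residual: float
    anode_mask: np.ndarray = field(repr=False, default=None)


def electrode_masks(
    geometry: HydrogelGeometry, electrodes: ElectrodeConfig
) -> dict:
    """Boolean cell masks occupied by each needle.

    In 2D a needle is the set of cells whose centers lie within the
    electrode radius of its position; in 3D the same disc is extruded
    along z through the full grid (needles parallel to the z axis).
    """
    x = geometry.axis_coords_m(0)
    y = geometry.axis_coords_m(1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    r_m = units.cm_to_m(electrodes.radius_cm)
    masks = {}
    for lab, (px_cm, py_cm) in zip(electrodes.labels, electrodes.positions_cm):
        px, py = units.cm_to_m(px_cm), units.cm_to_m(py_cm)
        disc = (xx - px) ** 2 + (yy - py) ** 2 <= r_m**2
        if geometry.ndim == 3:
            disc = np.broadcast_to(disc[:, :, None], geometry.inside.shape).copy()
        m = disc & geometry.inside
        if not m.any():
            raise ConfigurationError(
                f"electrode {lab} covers no grid cell; refine the grid or "
                "check its position"
            )
        masks[lab] = m
    return masks


def _shift(a: np.ndarray, axis: int, step: int):
    """View of ``a`` shifted by ``step`` along ``axis`` (no wraparound)."""
    sl_src = [slice(None)] * a.ndim
    sl_dst = [slice(None)] * a.ndim
    if step > 0:
        sl_src[axis] = slice(None, -step)
        sl_dst[axis] = slice(step, None)
    else:
        sl_src[axis] = slice(-step, None)
        sl_dst[axis] = slice(None, step)
    return tuple(sl_dst), tuple(sl_src)


def _face_conductance(sig_a, sig_b, ndim: int, h_m: float):
    """Harmonic-mean conductance of the face between two cells.

    2D returns conductance per unit height (σ·h/h = σ); 3D returns
    absolute conductance (σ·h²/h = σ·h).
    """
    g = 2.0 * sig_a * sig_b / (sig_a + sig_b)
    return g * h_m if ndim == 3 else g


def _linear_solve(domain, dirichlet, phi_fixed, sigma, h_m):
    """One constant-coefficient solve of ∇·σ∇φ = 0 on the masked grid."""
    ndim = domain.ndim
    free = domain & ~dirichlet
    nfree = int(free.sum())
    phi = np.full(domain.shape, np.nan)
    phi[dirichlet] = phi_fixed[dirichlet]
    if nfree == 0:
        return phi

    index = np.full(domain.shape, -1, dtype=np.int64)
    index[free] = np.arange(nfree)

    rows, cols, vals = [], [], []
    diag = np.zeros(nfree)
    b = np.zeros(nfree)
    for ax in range(ndim):
        dst, src = _shift(domain, ax, 1)
        # face between cell (src) and its +1 neighbor (dst)
        both = domain[src] & domain[dst]
        g = np.zeros(both.shape)
        g[both] = _face_conductance(sigma[src][both], sigma[dst][both], ndim, h_m)

        i_lo, i_hi = index[src], index[dst]
        f_lo, f_hi = free[src], free[dst]
        d_lo, d_hi = dirichlet[src], dirichlet[dst]

        ff = both & f_lo & f_hi
        np.add.at(diag, i_lo[ff], g[ff])
        np.add.at(diag, i_hi[ff], g[ff])
        rows.append(i_lo[ff]); cols.append(i_hi[ff]); vals.append(-g[ff])
        rows.append(i_hi[ff]); cols.append(i_lo[ff]); vals.append(-g[ff])

        fd = both & f_lo & d_hi
        np.add.at(diag, i_lo[fd], g[fd])
        np.add.at(b, i_lo[fd], g[fd] * phi_fixed[dst][fd])

        df = both & d_lo & f_hi
        np.add.at(diag, i_hi[df], g[df])
        np.add.at(b, i_hi[df], g[df] * phi_fixed[src][df])

    rows.append(np.arange(nfree)); cols.append(np.arange(nfree)); vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(nfree, nfree),
    )
    # Direct factorization is fastest for 2D sections; conjugate gradients
    # (the system is SPD) scale better for 3D tumor grids.  Both are
    # deterministic for fixed inputs.
    if ndim == 2 or nfree < 20000:
        phi[free] = spla.spsolve(A, b)
    else:
        M = sp.diags(1.0 / A.diagonal())
        x, info = spla.cg(A, b, rtol=1e-10, atol=0.0, maxiter=10 * nfree, M=M)
        if info != 0:
            raise ConvergenceError(
                f"conjugate-gradient solve failed (info={info})",
                residual=float(np.linalg.norm(A @ x - b)),
                iterations=info if info > 0 else 0,
            )
        phi[free] = x
    return phi


def _field_magnitude(phi, domain, h_m):
    """|∇φ| in V/m: central differences inside, one-sided at boundaries."""
    grad2 = np.zeros(phi.shape)
    phi0 = np.where(domain, phi, 0.0)
    for ax in range(phi.ndim):
        g = np.zeros(phi.shape)
        has_f = np.zeros(phi.shape, dtype=bool)
        has_b = np.zeros(phi.shape, dtype=bool)
        phi_f = np.zeros(phi.shape)
        phi_b = np.zeros(phi.shape)
        dst, src = _shift(domain, ax, 1)
        # forward neighbor of src cells is dst cells
        has_f[src] = domain[dst]
        phi_f[src] = phi0[dst]
        has_b[dst] = domain[src]
        phi_b[dst] = phi0[src]

        central = domain & has_f & has_b
        g[central] = (phi_f[central] - phi_b[central]) / (2 * h_m)
        fwd = domain & has_f & ~has_b
        g[fwd] = (phi_f[fwd] - phi0[fwd]) / h_m
        bwd = domain & ~has_f & has_b
        g[bwd] = (phi0[bwd] - phi_b[bwd]) / h_m
        grad2 += g**2
    return np.sqrt(grad2)


def _wall_cells(inside: np.ndarray) -> np.ndarray:
    """Inside cells with at least one outside (or grid-edge) neighbor."""
    wall = np.zeros(inside.shape, dtype=bool)
    for ax in range(inside.ndim):
        for step in (1, -1):
            nb_inside = np.zeros(inside.shape, dtype=bool)
            dst, src = _shift(inside, ax, step)
            nb_inside[dst] = inside[src]
            wall |= inside & ~nb_inside
    return wall


def _sigma_cells(geometry, E_V_per_cm):
    """Evaluate each region's conductivity model at the current field."""
    sig = np.zeros(geometry.inside.shape)
    for rid, model in geometry.region_conductivity.items():
        m = geometry.inside & (geometry.region == rid)
        if m.any():
            sig[m] = sigma_of_E(model, E_V_per_cm[m])
    return sig


def solve_field(
    geometry: HydrogelGeometry,
    electrodes: ElectrodeConfig,
    active_pair: tuple,
    amplitude_V: float,
    options: SolverOptions | None = None,
) -> FieldSolution:
    """Solve one pair activation: anode at ``amplitude_V``, cathode grounded.

    Cells covered by the two active needles are Dirichlet; cells covered
    by any inactive needle are removed from the conducting domain.  With a
    field-dependent conductivity the σ–E fixed point is iterated (damped
    Picard) until the relative max-norm change of ``field_magnitude``
    drops below ``options.tol``; constant-conductivity problems are linear
    and solved in a single step.
    """
    options = options or SolverOptions()
    if amplitude_V < 0:
        raise DomainError("amplitude must be non-negative")
    anode, cathode = active_pair
    if anode == cathode:
        raise ConfigurationError("active pair must name two distinct electrodes")
    if cathode is None and not options.grounded_wall:
        raise ConfigurationError(
            "a lone energized electrode requires the grounded-wall option"
        )

    masks = electrode_masks(geometry, electrodes)
    for lab in (anode, cathode):
        if lab is not None and lab not in masks:
            raise ConfigurationError(f"unknown electrode label {lab!r}")

    inactive = np.zeros(geometry.inside.shape, dtype=bool)
    for lab, m in masks.items():
        if lab not in (anode, cathode):
            inactive |= m
    domain = geometry.inside & ~inactive

    dirichlet = np.zeros(domain.shape, dtype=bool)
    phi_fixed = np.zeros(domain.shape)
    dirichlet |= masks[anode] & domain
    phi_fixed[masks[anode]] = amplitude_V
    if cathode is not None:
        dirichlet |= masks[cathode] & domain
        phi_fixed[masks[cathode] & domain] = 0.0
    if options.grounded_wall:
        wall = _wall_cells(geometry.inside) & domain & ~dirichlet
        dirichlet |= wall

    h_m = geometry.spacing_m
    field_dependent = any(
        m.is_field_dependent for m in geometry.region_conductivity.values()
    )

    E_cm = np.zeros(domain.shape)
    sigma = _sigma_cells(geometry, E_cm)
    if not field_dependent:
        phi = _linear_solve(domain, dirichlet, phi_fixed, sigma, h_m)
        E_cm = units.v_per_m_to_v_per_cm(_field_magnitude(phi, domain, h_m))
        converged, iterations, residual = True, 1, 0.0
    else:
        converged, residual = False, np.inf
        for iterations in range(1, options.max_iterations + 1):
            phi = _linear_solve(domain, dirichlet, phi_fixed, sigma, h_m)
            E_new = units.v_per_m_to_v_per_cm(_field_magnitude(phi, domain, h_m))
            scale = max(float(E_new.max()), 1e-300)
            residual = float(np.abs(E_new - E_cm).max()) / scale
            E_cm = E_new
            if residual < options.tol:
                converged = True
                break
            target = _sigma_cells(geometry, E_cm)
            sigma = (1 - options.relaxation) * sigma + options.relaxation * target
        if not converged:
            raise ConvergenceError(
                f"Picard iteration did not converge within "
                f"{options.max_iterations} iterations (residual {residual:.3e})",
                residual=residual,
                iterations=iterations,
            )

    # metal interior carries no field; outside the domain there is nothing
    E_cm[dirichlet] = 0.0
    E_cm[~domain] = 0.0

    sol = FieldSolution(
        geometry=geometry,
        electrodes=electrodes,
        active_pair=(anode, cathode),
        amplitude_V=float(amplitude_V),
        potential=phi,
        field_magnitude=E_cm,
        sigma_S_per_m=sigma,
        domain=domain,
        current_A=0.0,
        converged=converged,
        iterations=iterations,
        residual=residual,
        anode_mask=masks[anode] & domain,
    )
    sol.current_A = current_through_contour(sol, dilation=0)
    return sol


def current_through_contour(solution: FieldSolution, dilation: int = 0) -> float:
    """Total current crossing a closed contour around the energized needle.

    The contour is the discrete boundary of the anode cell set dilated by
    ``dilation`` cells (Chebyshev metric).  Discrete charge conservation
    makes the result contour-independent as long as the contour does not
    swallow the counter electrode.
    """
    geometry = solution.geometry
    h_m = geometry.spacing_m
    ndim = geometry.ndim
    S = solution.anode_mask.copy()
    if dilation > 0:
        from scipy.ndimage import binary_dilation

        S = binary_dilation(S, iterations=dilation) & solution.domain
    domain, phi, sigma = solution.domain, solution.potential, solution.sigma_S_per_m

    total = 0.0
    for ax in range(ndim):
        dst, src = _shift(domain, ax, 1)
        both = domain[src] & domain[dst]
        out_lo = both & S[src] & ~S[dst]  # flux src -> dst leaves S
        out_hi = both & S[dst] & ~S[src]
        g = np.zeros(both.shape)
        sel = out_lo | out_hi
        g[sel] = _face_conductance(sigma[src][sel], sigma[dst][sel], ndim, h_m)
        total += float(np.sum(g[out_lo] * (phi[src][out_lo] - phi[dst][out_lo])))
        total += float(np.sum(g[out_hi] * (phi[dst][out_hi] - phi[src][out_hi])))
    if ndim == 2:
        total *= units.cm_to_m(solution.electrodes.modeled_height_cm)
    return total


def compute_resistance(solution: FieldSolution, amplitude_V: float | None = None) -> float:
    """Inter-electrode resistance R = V / I, Ω (per modeled height in 2D)."""
    if amplitude_V is None:
        amplitude_V = solution.amplitude_V
    if amplitude_V <= 0:
        raise DomainError("amplitude must be positive to define a resistance")
    if not solution.converged:
        raise ConvergenceError(
            "resistance requested from a non-converged solution",
            residual=solution.residual,
            iterations=solution.iterations,
        )
    if abs(solution.current_A) < 1e-300:
        raise DegenerateSolutionError("zero current: resistance undefined")
    return amplitude_V / solution.current_A


def calibrate_conductivity(
    geometry: HydrogelGeometry,
    electrodes: ElectrodeConfig,
    pair: tuple,
    amplitude_V: float,
    measured_R_ohm: float,
    options: SolverOptions | None = None,
) -> float:
    """Constant conductivity that reproduces a measured resistance.

    For constant σ the problem is linear, so R ∝ 1/σ exactly and one
    reference solve at σ_ref = 1 S/m suffices:
    σ = σ_ref · R(σ_ref) / R_measured.  This mirrors the bench procedure
    of backing a hydrogel's conductivity out of the pulse generator's
    resistance readout.
    """
    if not np.isfinite(measured_R_ohm) or measured_R_ohm <= 0:
        raise DomainError("measured resistance must be finite and positive")
    sigma_ref = 1.0
    ref_geom = HydrogelGeometry(
        shape=geometry.shape,
        spacing_m=geometry.spacing_m,
        inside=geometry.inside,
        region=geometry.region,
        region_conductivity={
            rid: ConductivityModel.constant(sigma_ref)
            for rid in geometry.region_conductivity
        },
        origin_m=geometry.origin_m,
        height_cm=geometry.height_cm,
        outer_diameter_cm=geometry.outer_diameter_cm,
        inner_diameter_cm=geometry.inner_diameter_cm,
    )
    sol = solve_field(ref_geom, electrodes, pair, amplitude_V, options)
    r_ref = compute_resistance(sol, amplitude_V)
    return sigma_ref * r_ref / measured_R_ohm
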