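import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ireplan as ip

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

CONST_SIGMA = 0.027  # calibrated Hep-G2 small-hydrogel conductivity, S/m


@pytest.fixture(scope="session")
def well24():
    """24-well disc, constant conductivity, coarse grid for fast solves."""
    return ip.make_well_geometry(
        24, grid_spacing_cm=0.02,
        conductivity=ip.ConductivityModel.constant(CONST_SIGMA),
    )


@pytest.fixture(scope="session")
def pair_electrodes(well24):
    return ip.place_electrodes(well24, "pair", 0.8)


@pytest.fixture(scope="session")
def cum_1100(well24, pair_electrodes):
    plan = ip.ActivationPlan.uniform([("E1", "E2")], 1100.0, 100)
    return ip.run_plan(well24, pair_electrodes, plan)


@pytest.fixture(scope="session")
def sweep_1100(cum_1100):
    return ip.ablation_sweep(cum_1100, 200.0, 1200.0, 5.0)


@pytest.fixture(scope="session")
def coaxial():
    """Single centered electrode, grounded wall: the closed-form oracle.

    Returns (solution, geometry, a_cm, R_cm, V, sigma).
    """
    sigma = 0.1
    geom = ip.make_well_geometry(
        24, grid_spacing_cm=0.005,
        conductivity=ip.ConductivityModel.constant(sigma),
    )
    a_cm, V = 0.1, 100.0
    electrodes = ip.ElectrodeConfig(positions_cm=[(0.0, 0.0)], radius_cm=a_cm)
    sol = ip.solve_field(
        geom, electrodes, ("E1", None), V,
        ip.SolverOptions(grounded_wall=True),
    )
    return sol, geom, a_cm, geom.outer_diameter_cm / 2.0, V, sigma


def coaxial_ring_mask(geom, a_cm, R_cm, inner=2.0, outer=0.85):
    """Cells away from the electrode staircase and the wall staircase."""
    xx, yy = geom.cell_centers_m()
    r_cm = np.hypot(xx, yy) * 100.0
    return geom.inside & (r_cm > inner * a_cm) & (r_cm < outer * R_cm)
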