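"""Tissue conductivity models.

Electroporation transiently permeabilizes cell membranes, which raises the
bulk electrical conductivity of tissue as the local field magnitude grows.
The standard phenomenological description is a smooth sigmoid transition
between a low-field baseline ``sigma0`` and a fully electroporated plateau
``sigmaf``.  For liver-mimicking hydrogel work the endpoints are
σ_0 = 0.4 S/m and σ_f = 1.6 S/m; calibrated hydrogel phantoms instead use a
constant conductivity obtained from an inter-electrode resistance readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DomainError

#: low/high-field liver conductivities under electroporation, S/m
LIVER_SIGMA0_S_PER_M = 0.4
LIVER_SIGMAF_S_PER_M = 1.6

#: hepatocellular-carcinoma and umbilical-cord conductivities used for the
#: co-culture (tumor core / endothelial ring) two-region model, S/m
HCC_SIGMA_S_PER_M = 1.26
UMBILICAL_SIGMA_S_PER_M = 1.46


@dataclass(frozen=True)
class ConductivityModel:
    """Per-region conductivity, either constant or field-dependent.

    Parameters
    ----------
    form:
        ``"constant"`` or ``"field_dependent"``.
    sigma0:
        Low-field conductivity, S/m.  For the constant form this is the
        conductivity, full stop.
    sigmaf:
        High-field plateau, S/m (field-dependent form only).
    e_center_V_per_cm:
        Field magnitude at which the sigmoid transition is halfway, V/cm.
        Default 500 V/cm places the transition across the reversible-to-
        irreversible electroporation range.
    e_width_V_per_cm:
        Transition width (sigmoid scale), V/cm.
    """

    form: str = "constant"
    sigma0: float = 1.0
    sigmaf: float | None = None
    e_center_V_per_cm: float = 500.0
    e_width_V_per_cm: float = 100.0

    def __post_init__(self):
        if self.form not in ("constant", "field_dependent"):
            raise DomainError(f"unknown conductivity form {self.form!r}")
        if self.sigma0 <= 0:
            raise DomainError("sigma0 must be positive")
        if self.form == "field_dependent":
            if self.sigmaf is None:
                raise DomainError("field_dependent form requires sigmaf")
            if self.sigmaf < self.sigma0:
                raise DomainError("sigmaf must be >= sigma0")
            if self.e_width_V_per_cm <= 0:
                raise DomainError("e_width_V_per_cm must be positive")

    @classmethod
    def constant(cls, sigma_S_per_m: float) -> "ConductivityModel":
        return cls(form="constant", sigma0=sigma_S_per_m)

    @classmethod
    def liver_field_dependent(
        cls,
        sigma0: float = LIVER_SIGMA0_S_PER_M,
        sigmaf: float = LIVER_SIGMAF_S_PER_M,
        e_center_V_per_cm: float = 500.0,
        e_width_V_per_cm: float = 100.0,
    ) -> "ConductivityModel":
        """Sigmoid liver model rising from 0.4 to 1.6 S/m."""
        return cls(
            form="field_dependent",
            sigma0=sigma0,
            sigmaf=sigmaf,
            e_center_V_per_cm=e_center_V_per_cm,
            e_width_V_per_cm=e_width_V_per_cm,
        )

    @property
    def is_field_dependent(self) -> bool:
        return self.form == "field_dependent"


def sigma_of_E(model: ConductivityModel, E_V_per_cm):
    """Evaluate conductivity at field magnitude ``E`` (V/cm).

    The field-dependent form is
    ``sigma0 + (sigmaf - sigma0) * s((E - E_center) / E_width)`` with
    ``s`` the logistic sigmoid, so the value is 0.5 of the way between the
    endpoints exactly at ``E_center`` and is bounded by [sigma0, sigmaf].

    Accepts scalars or arrays; negative field magnitudes are rejected.
    """
    E = np.asarray(E_V_per_cm, dtype=float)
    if np.any(E < 0):
        raise DomainError("field magnitude must be non-negative")
    if not model.is_field_dependent:
        out = np.full_like(E, model.sigma0)
    else:
        s = expit((E - model.e_center_V_per_cm) / model.e_width_V_per_cm)
        out = model.sigma0 + (model.sigmaf - model.sigma0) * s
    if np.isscalar(E_V_per_cm) or np.ndim(E_V_per_cm) == 0:
        return float(out)
    return out
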