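"""Unit conversion layer.

All internal computation is carried out in SI (m, V, V/m, S/m, Ω).  Public
interfaces speak the bench units of electroporation practice: lengths in cm
(well and electrode dimensions) or mm (voxels), field magnitudes in V/cm,
areas in mm², volumes in mm³.  Every conversion goes through this module so
there is exactly one place where a factor of 100 can hide.
"""

CM_TO_M = 1e-2
M_TO_CM = 1e2
MM_TO_M = 1e-3
M_TO_MM = 1e3

V_PER_M_TO_V_PER_CM = 1e-2
V_PER_CM_TO_V_PER_M = 1e2

M2_TO_MM2 = 1e6
M3_TO_MM3 = 1e9


def cm_to_m(x):
    return x * CM_TO_M


def m_to_cm(x):
    return x * M_TO_CM


def mm_to_m(x):
    return x * MM_TO_M


def v_per_m_to_v_per_cm(e):
    return e * V_PER_M_TO_V_PER_CM


def v_per_cm_to_v_per_m(e):
    return e * V_PER_CM_TO_V_PER_M


def m2_to_mm2(a):
    return a * M2_TO_MM2


def m3_to_mm3(v):
    return v * M3_TO_MM3
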