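"""Unit constants and converters.

Geometry is carried in millimetres, volumetric flow in m^3/s (SI) at the
boundary-condition level, and pressure in mmHg.  The feature tables expose
flow in ml/s so that the unscaled training data have magnitudes of order
10--100 rather than 1e-4.
"""

MMHG_PA: float = 133.322
"""Pascals per millimetre of mercury."""

MM_M: float = 1e-3
"""Metres per millimetre."""

ML_S_M3_S: float = 1e-6
"""m^3/s per ml/s."""


def mmhg_to_pa(p_mmhg: float) -> float:
    return p_mmhg * MMHG_PA


def pa_to_mmhg(p_pa: float) -> float:
    return p_pa / MMHG_PA


def mm_to_m(x_mm: float) -> float:
    return x_mm * MM_M


def m_to_mm(x_m: float) -> float:
    return x_m / MM_M


def mls_to_m3s(f_mls: float) -> float:
    return f_mls * ML_S_M3_S


def m3s_to_mls(f_m3s: float) -> float:
    return f_m3s / ML_S_M3_S
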