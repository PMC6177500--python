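"""Unit conversions, centralised so every stage agrees on scales.

Geometry is in mm, velocities in cm/s, shear rates in 1/s and wall shear
stress in Pa.  A velocity gradient of 1 (cm/s)/mm equals 10 1/s.
"""

CM_PER_S_TO_M_PER_S = 0.01
MM_TO_M = 0.001

#: multiply a gradient in (cm/s)/mm by this to obtain 1/s
GRADIENT_CMPS_PER_MM_TO_PER_S = CM_PER_S_TO_M_PER_S / MM_TO_M  # = 10.0

#: default blood dynamic viscosity [Pa*s]; common literature constant,
#: configurable everywhere it is used and recorded in all outputs.
DEFAULT_VISCOSITY_PA_S = 3.2e-3


def shear_rate_per_s(gradient_cmps_per_mm: float) -> float:
    """Convert a wall velocity gradient from (cm/s)/mm to 1/s."""
    return gradient_cmps_per_mm * GRADIENT_CMPS_PER_MM_TO_PER_S


def wss_pa(gradient_cmps_per_mm, viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S):
    """Wall shear stress in Pa from a gradient in (cm/s)/mm."""
    return viscosity_pa_s * shear_rate_per_s(gradient_cmps_per_mm)


def poiseuille_wss_pa(peak_velocity_cmps, radius_mm, viscosity_pa_s=DEFAULT_VISCOSITY_PA_S):
    """Closed-form Poiseuille wall shear stress mu*2*v_peak/R in Pa.

    For v_peak = 60 cm/s, R = 3 mm, mu = 3.2e-3 Pa*s this is 1.28 Pa.
    """
    v = peak_velocity_cmps * CM_PER_S_TO_M_PER_S
    r = radius_mm * MM_TO_M
    return viscosity_pa_s * 2.0 * v / r
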