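"""Centralized unit handling.

Internally the physics is done in SI (m, s, kg, J).  The public API speaks
the units of the experimental literature on particle tracking in mucus:
micrometres for lengths and displacements, µm²/s (or µm²/s^α) for diffusion
constants, mPa·s for viscosities, pN·nm for thermal energies, and mL/h for
encounter-rate kernels.  Every conversion constant lives here so that no
other module hard-codes a power of ten.
"""

from __future__ import annotations

import math

# --- length ---
M_PER_UM = 1e-6
M_PER_NM = 1e-9
UM_PER_NM = 1e-3

# --- diffusivity ---
M2_PER_UM2 = 1e-12  # 1 µm²/s = 1e-12 m²/s (also valid for µm²/s^α prefactors)

# --- viscosity ---
PAS_PER_MPAS = 1e-3  # 1 mPa·s = 1e-3 Pa·s

# --- energy ---
J_PER_PN_NM = 1e-21  # 1 pN·nm = 1e-12 N × 1e-9 m

# --- encounter kernels ---
# 1 µm³ = 1e-12 mL and 1 h = 3600 s, so 1 µm³/s = 3.6e-9 mL/h.
ML_H_PER_UM3_S = 3.6e-9
# 1 m³ = 1e6 mL, so 1 m³/s = 3.6e9 mL/h.
ML_H_PER_M3_S = 3.6e9

# --- reference physical constants (37 °C, overridable everywhere) ---
KT_BODY_PN_NM = 4.28       # thermal energy kT at 37 °C, pN·nm
ETA_WATER_MPAS = 0.69      # viscosity of water at 37 °C, mPa·s


def um3_s_to_ml_h(value: float) -> float:
    """Convert an encounter kernel from µm³/s to mL/h."""
    return value * ML_H_PER_UM3_S


def ml_h_to_um3_s(value: float) -> float:
    return value / ML_H_PER_UM3_S


def m3_s_to_ml_h(value: float) -> float:
    """Convert an encounter kernel from m³/s to mL/h."""
    return value * ML_H_PER_M3_S


def um2_s_to_m2_s(value: float) -> float:
    return value * M2_PER_UM2


def m2_s_to_um2_s(value: float) -> float:
    return value / M2_PER_UM2


def friction_coefficient(viscosity_mpas: float, radius_m: float) -> float:
    """Stokes drag γ = 6πηR in kg/s for a sphere of radius ``radius_m`` (m)."""
    return 6.0 * math.pi * viscosity_mpas * PAS_PER_MPAS * radius_m
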