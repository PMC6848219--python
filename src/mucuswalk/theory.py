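"""Closed-form encounter-rate kernels for a bacterium in a phage suspension.

In the rest frame of the bacterium the relative phage–bacterium MSD is the
sum of the two species' MSDs,

    ⟨r²⟩(t) = 2d·(v_B²⟨τ_R⟩/3)·t + 2d·D_α·t^α,

whose instantaneous diffusivity (in d = 3) is

    𝔇(t) = v_B²⟨τ_R⟩/3 + α·D_α·t^(α−1).

Feeding 𝔇(t) into a Smoluchowski-type absorbing-sphere problem gives the
time-dependent flux onto the adsorption sphere of radius R_C,

    𝒥(t) = 4π·P_∞·R_C·𝔇(t)·(1 + sqrt(R_C²/(π·λ(t)))),    λ(t) = ∫₀ᵗ 𝔇 dt',

and the encounter kernel β(t) = 𝒥(t)/P_∞.  Classical limits are recovered:
α = 1, v_B = 0 gives the Smoluchowski transient 4πR_C·D·(1 + R_C/√(πDt))
with steady state 4πR_C·D, a motile bacterium adds v_B²⟨τ_R⟩/3 to the
long-time diffusivity, and a strictly subdiffusive phage around a static
bacterium has a decaying kernel with no nonzero steady state.  A bacterium
whose runs are long compared to the observation time sweeps a cylinder
instead, giving the ballistic kernel β_ball = π·R_C²·v_B.

Lengths are µm, speeds µm/s, diffusivities µm²/s^α at the interface;
internally SI.  Kernels are returned in mL/h (the unit adsorption-rate
constants are usually quoted in), diffusivities in m²/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from . import units


@dataclass(frozen=True)
class RelativeMotionParams:
    """Parameters of the relative phage–bacterium motion.

    ``v_B`` (µm/s) and ``mean_run_time`` (s) describe the bacterium;
    ``D_alpha`` (µm²/s^α) and ``alpha`` the phage MSD; ``R_C`` (µm) the
    adsorption radius; ``P_inf`` (µm⁻³) the far-field phage concentration.
    """

    v_B: float
    mean_run_time: float
    D_alpha: float
    alpha: float
    R_C: float = 1.1
    P_inf: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v_B", "mean_run_time", "D_alpha", "R_C", "P_inf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")

    @property
    def ballistic_diffusivity(self) -> float:
        """The bacterial contribution v_B²⟨τ_R⟩/3 in m²/s."""
        return (self.v_B * units.M_PER_UM) ** 2 * self.mean_run_time / 3.0


class SteadyStateKernel(NamedTuple):
    """Long-time kernel in mL/h; ``exists`` is False when β(t) → 0."""

    beta_ml_h: float
    exists: bool


def ballistic_kernel(R_C: float, v_B: float) -> float:
    """Swept-cylinder kernel β_ball = π·R_C²·v_B, in mL/h.

    ``R_C`` in µm, ``v_B`` in µm/s.  Valid when the bacterium's run length
    dominates every diffusive displacement in the problem.
    """
    if R_C < 0 or v_B < 0:
        raise ValueError("R_C and v_B must be >= 0")
    return units.um3_s_to_ml_h(math.pi * R_C ** 2 * v_B)


def instantaneous_diffusivity(t, params: RelativeMotionParams):
    """𝔇(t) = v_B²⟨τ_R⟩/3 + α·D_α·t^(α−1), in m²/s.

    For α < 1 the phage term is singular at t = 0, so t must be positive;
    at α = 1 the result is time-independent.  Accepts scalar or array t.
    """
    t = np.asarray(t, dtype=float)
    if params.alpha < 1.0 and np.any(t <= 0):
        raise ValueError("t must be > 0 when alpha < 1 (singular at t = 0)")
    d_phage = (params.alpha * params.D_alpha * units.M2_PER_UM2
               * t ** (params.alpha - 1.0))
    out = params.ballistic_diffusivity + d_phage
    return out if out.ndim else float(out)


def lambda_integral(t, params: RelativeMotionParams):
    """λ(t) = ∫₀ᵗ 𝔇 dt' = v_B²⟨τ_R⟩·t/3 + D_α·t^α, in m².

    The integration constant is fixed by λ(0) = 0, which reduces the α = 1,
    v_B = 0 case to the textbook Smoluchowski transient.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    out = (params.ballistic_diffusivity * t
           + params.D_alpha * units.M2_PER_UM2 * t ** params.alpha)
    return out if out.ndim else float(out)


def encounter_flux(t, params: RelativeMotionParams):
    """Absorbing-sphere flux 𝒥(t) (phage/s) and kernel β(t) (mL/h).

    𝒥(t) = 4π·P_∞·R_C·𝔇(t)·(1 + sqrt(R_C²/(π·λ(t)))); β(t) = 𝒥(t)/P_∞.
    Requires t > 0 (λ(0) = 0 makes the transient term singular).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be > 0")
    lam = lambda_integral(t, params)
    diff = instantaneous_diffusivity(t, params)
    r_c = params.R_C * units.M_PER_UM
    beta_m3_s = (4.0 * math.pi * r_c * np.asarray(diff)
                 * (1.0 + np.sqrt(r_c ** 2 / (math.pi * np.asarray(lam)))))
    p_inf_m3 = params.P_inf / units.M_PER_UM ** 3
    flux = p_inf_m3 * beta_m3_s
    beta = units.m3_s_to_ml_h(beta_m3_s)
    if beta.ndim:
        return flux, beta
    return float(flux), float(beta)


def steady_state_kernel(params: RelativeMotionParams) -> SteadyStateKernel:
    """Long-time limit of β(t), in mL/h.

    As t → ∞ the transient factor converges to one and the phage term of
    𝔇 survives only at α = 1, so β_∞ = 4π·R_C·(v_B²⟨τ_R⟩/3 + [D if α = 1]).
    With a static bacterium and a strictly subdiffusive phage the kernel
    decays to zero: no nonzero steady state (``exists=False``).
    """
    diff_inf = params.ballistic_diffusivity
    if params.alpha == 1.0:
        diff_inf += params.D_alpha * units.M2_PER_UM2
    if diff_inf == 0.0:
        return SteadyStateKernel(0.0, False)
    r_c = params.R_C * units.M_PER_UM
    return SteadyStateKernel(units.m3_s_to_ml_h(4.0 * math.pi * r_c * diff_inf), True)


def rms_displacement(D_alpha: float, alpha: float, t: float,
                     dimension: int = 3) -> float:
    """RMS displacement sqrt(2d·D_α·t^α) in µm (D_α in µm²/s^α, t in s)."""
    if D_alpha < 0 or alpha < 0 or t < 0:
        raise ValueError("D_alpha, alpha and t must be >= 0")
    if dimension not in (2, 3):
        raise ValueError("dimension must be 2 or 3")
    return math.sqrt(2.0 * dimension * D_alpha * t ** alpha)


def kernel_ratio(beta_a: float, beta_b: float) -> float:
    """Ratio β_a/β_b of two kernels in matching units."""
    if beta_b <= 0:
        raise ZeroDivisionError("beta_b must be > 0")
    return beta_a / beta_b


def kernel_series(t_grid, params: RelativeMotionParams) -> dict[str, np.ndarray]:
    """Tabulate 𝔇(t), λ(t) and β(t) on a time grid (for the CLI writer)."""
    t = np.asarray(t_grid, dtype=float)
    flux, beta = encounter_flux(t, params)
    return {
        "time_s": t,
        "instantaneous_diffusivity_m2_s": np.asarray(
            instantaneous_diffusivity(t, params)),
        "lambda_m2": np.asarray(lambda_integral(t, params)),
        "beta_ml_h": np.asarray(beta),
        "beta_um3_s": np.asarray(beta) / units.ML_H_PER_UM3_S,
        "flux_per_s": np.asarray(flux),
    }
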