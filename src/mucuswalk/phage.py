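"""Phage trajectory generators.

The mucin-adherent wild-type phage is a continuous-time random walk: it
sticks to mucin for a heavy-tailed (Pareto) waiting time, then takes one
free Gaussian diffusion step of duration τ_D, and sticks again.  With tail
exponent 0 < ν < 1 the mean waiting time is infinite and the ensemble MSD
grows as t^ν (subdiffusion).  The non-adherent mutant has no waiting times
and performs plain Brownian motion with the same step rule
x_{k+1} = x_k + sqrt(2·D·τ_D)·ξ_k.

Scheduling follows a single-timer discretization: the walker's timer is
initialized to zero, so it takes its first step at the first grid time; at
each displacement a new waiting time τ = τ₀·(1/U)^(1/ν) is drawn and the
next displacement happens at the first grid time ≥ (current time + τ).
"""

from __future__ import annotations

import math

import numpy as np

from .calibration import CTRWParams
from .trajectory import Trajectory


def sample_waiting_time(params: CTRWParams, u: float) -> float:
    """Invert the Pareto CDF, cdf(τ) = 1 − (τ₀/τ)^ν, at uniform variate ``u``.

    Returns τ = τ₀·(1/u)^(1/ν) with support [τ₀, ∞).  ``u`` must lie in
    (0, 1]; u → 0 would give an infinite waiting time.  For ν ≤ 1 the mean
    of this law is infinite.
    """
    if not 0.0 < u <= 1.0:
        raise ValueError(f"u must be in (0, 1], got {u}")
    return params.tau_0 * (1.0 / u) ** (1.0 / params.nu)


def _displacement_steps(params: CTRWParams, n_steps: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Grid-step indices (1-based) at which the walker displaces.

    With the single-timer scheme the steps between consecutive
    displacements are ceil(τ/τ_D) ≥ 1, so drawing ``n_steps`` waiting
    times always covers the grid.
    """
    if params.tau_0 == 0.0:
        # no sticking: every step displaces
        return np.arange(1, n_steps + 1)
    u = rng.random(n_steps)
    tau = params.tau_0 * (1.0 / (1.0 - u)) ** (1.0 / params.nu)  # U(0,1] tail
    # heavy tails can exceed the whole grid (or float range); any gap longer
    # than n_steps ends the trajectory, so clip before the integer cast
    gaps_f = np.minimum(np.ceil(tau / params.tau_D), float(n_steps + 1))
    gaps = np.maximum(gaps_f.astype(np.int64), 1)
    steps = 1 + np.concatenate(([0], np.cumsum(gaps)[:-1]))
    return steps[steps <= n_steps]


def simulate_ctrw(params: CTRWParams, n_steps: int, dimension: int = 3,
                  seed: int | np.random.SeedSequence = 0,
                  particle_kind: str = "phage-wt") -> Trajectory:
    """Simulate one CTRW trajectory starting at the origin.

    The time grid has spacing ``params.tau_D``; while the walker's waiting
    time has not elapsed it stays put, and on the step where it elapses it
    takes a single Gaussian step with per-axis standard deviation
    sqrt(2·D·τ_D).  Identical ``(params, seed)`` give identical output.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    disp_steps = _displacement_steps(params, n_steps, rng)
    sigma = math.sqrt(2.0 * params.D * params.tau_D)
    increments = np.zeros((n_steps + 1, dimension))
    increments[disp_steps] = sigma * rng.standard_normal((len(disp_steps), dimension))
    positions = np.cumsum(increments, axis=0)
    times = np.arange(n_steps + 1) * params.tau_D
    return Trajectory(times, positions, dimension, particle_kind)


def simulate_brownian(D: float, tau_D: float, n_steps: int, dimension: int = 3,
                      seed: int | np.random.SeedSequence = 0,
                      particle_kind: str = "phage-dhoc") -> Trajectory:
    """Simulate plain Brownian motion, x_{k+1} = x_k + sqrt(2Dτ_D)·ξ_k."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if D < 0 or tau_D <= 0:
        raise ValueError("D must be >= 0 and tau_D > 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(2.0 * D * tau_D)
    increments = np.zeros((n_steps + 1, dimension))
    increments[1:] = sigma * rng.standard_normal((n_steps, dimension))
    positions = np.cumsum(increments, axis=0)
    times = np.arange(n_steps + 1) * tau_D
    return Trajectory(times, positions, dimension, particle_kind)


def simulate_ctrw_ensemble(params: CTRWParams, n_steps: int, n_replicates: int,
                           dimension: int = 3,
                           seed: int | np.random.SeedSequence = 0) -> np.ndarray:
    """Simulate independent CTRW replicates; returns (n_rep, n_steps+1, d).

    Each replicate runs on its own deterministically derived RNG substream,
    so trajectory ``i`` is reproducible regardless of ``n_replicates``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    base = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = base.spawn(n_replicates)
    out = np.empty((n_replicates, n_steps + 1, dimension))
    for i, child in enumerate(children):
        out[i] = simulate_ctrw(params, n_steps, dimension, child).positions
    return out
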