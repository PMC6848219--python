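"""Run-and-tumble bacterium trajectories.

The bacterium swims in a straight line at constant speed v_B during a run,
then instantaneously reorients (zero-duration tumble) and starts a new run.
Run durations are exponential with rate ω_T, so the mean run time is
⟨τ_R⟩ = 1/ω_T.  In the overdamped limit thermal noise on a swimming
bacterium is negligible against propulsion, so a non-swimming (static)
bacterium is exactly immobile.

Two tumble-direction laws are provided.  The default draws the polar and
azimuthal angles λ, θ independently uniform on [0, 2π) and sets the
direction to (cosλcosθ, cosλsinθ, sinλ); this parameterization yields unit
vectors by construction but is not uniform on the sphere (it over-weights
the poles).  An isotropic (area-uniform) mode is available; since run
directions are independent between runs, long-time transport statistics
are insensitive to the choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .trajectory import Trajectory


@dataclass(frozen=True)
class BacteriumParams:
    """Run-and-tumble parameters: radius (µm), speed (µm/s), tumble rate (1/s)."""

    R_B: float = 1.0
    v_B: float = 30.0
    omega_T: float = 1.0
    regime: str = "run-tumble"  # "run-tumble" | "static"

    def __post_init__(self) -> None:
        if self.R_B <= 0:
            raise ValueError(f"R_B must be > 0, got {self.R_B}")
        if self.v_B < 0:
            raise ValueError(f"v_B must be >= 0, got {self.v_B}")
        if self.regime not in ("run-tumble", "static"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "run-tumble" and self.omega_T <= 0:
            raise ValueError("omega_T must be > 0 in the run-tumble regime")

    @property
    def mean_run_time(self) -> float:
        """⟨τ_R⟩ = 1/ω_T in seconds."""
        return 1.0 / self.omega_T


def sample_run_time(omega_T: float, u: float) -> float:
    """Invert the exponential run-time CDF: τ_R = −ln(u)/ω_T.

    ``u`` must lie in (0, 1]; u = 1 gives a zero-length run.
    """
    if omega_T <= 0:
        raise ValueError(f"omega_T must be > 0, got {omega_T}")
    if not 0.0 < u <= 1.0:
        raise ValueError(f"u must be in (0, 1], got {u}")
    return -np.log(u) / omega_T


def direction_from_angles(polar: float, azimuth: float) -> np.ndarray:
    """Unit vector (cosλcosθ, cosλsinθ, sinλ) from polar angle λ and azimuth θ.

    Unit norm holds for any angles (cos²λ + sin²λ = 1); drawing both angles
    uniformly on [0, 2π) gives the default, pole-weighted tumble law.
    """
    return np.array([
        np.cos(polar) * np.cos(azimuth),
        np.cos(polar) * np.sin(azimuth),
        np.sin(polar),
    ])


def sample_direction(rng: np.random.Generator, isotropic: bool = False) -> np.ndarray:
    """Draw one tumble direction (3-component unit vector).

    Default: λ, θ ~ Uniform(0, 2π), direction (cosλcosθ, cosλsinθ, sinλ).
    ``isotropic=True`` instead draws uniformly on the unit sphere.
    """
    if isotropic:
        v = rng.standard_normal(3)
        return v / np.linalg.norm(v)
    lam, theta = rng.uniform(0.0, 2.0 * np.pi, size=2)
    return direction_from_angles(lam, theta)


def _run_directions_and_lengths(params: BacteriumParams, dt: float, n_steps: int,
                                rng: np.random.Generator,
                                isotropic: bool) -> tuple[np.ndarray, np.ndarray]:
    """Per-run unit directions and run lengths in grid steps covering n_steps.

    The run timer starts at zero, so the direction is (re)drawn on the first
    step; each run then lasts until the first step boundary at or after its
    drawn exponential duration (at least one step, so the schedule always
    advances).
    """
    tau_R = rng.exponential(1.0 / params.omega_T, size=n_steps)
    # a run outlasting the whole grid is equivalent to one of n_steps steps
    gaps_f = np.minimum(np.ceil(tau_R / dt), float(n_steps))
    gaps = np.maximum(gaps_f.astype(np.int64), 1)
    n_runs = int(np.searchsorted(np.cumsum(gaps), n_steps) + 1)
    gaps = gaps[:n_runs]
    if isotropic:
        dirs = rng.standard_normal((n_runs, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    else:
        lam = rng.uniform(0.0, 2.0 * np.pi, size=n_runs)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n_runs)
        dirs = np.column_stack([
            np.cos(lam) * np.cos(theta),
            np.cos(lam) * np.sin(theta),
            np.sin(lam),
        ])
    return dirs, gaps


def simulate_run_tumble(params: BacteriumParams, dt: float, n_steps: int,
                        seed: int | np.random.SeedSequence = 0,
                        isotropic: bool = False) -> Trajectory:
    """Simulate one bacterium trajectory starting at the origin.

    During a run the bacterium advances v_B·dt along the current direction
    each step; tumbles are instantaneous.  ``regime="static"`` returns a
    constant trajectory.  Identical ``(params, dt, seed)`` give identical
    output.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    times = np.arange(n_steps + 1) * dt
    if params.regime == "static" or params.v_B == 0.0:
        positions = np.zeros((n_steps + 1, 3))
        return Trajectory(times, positions, 3, "bacterium")
    rng = np.random.default_rng(seed)
    dirs, gaps = _run_directions_and_lengths(params, dt, n_steps, rng, isotropic)
    step_dirs = np.repeat(dirs, gaps, axis=0)[:n_steps]
    increments = np.vstack([np.zeros(3), params.v_B * dt * step_dirs])
    positions = np.cumsum(increments, axis=0)
    return Trajectory(times, positions, 3, "bacterium")


def bacterial_diffusion_constant(v_B: float, mean_run_time: float) -> float:
    """Effective long-time diffusion constant D_B = v_B²·⟨τ_R⟩/3, in m²/s.

    ``v_B`` in µm/s, ``mean_run_time`` in s.  This is the velocity-jump
    diffusion limit for exponentially distributed runs with uncorrelated
    successive directions.
    """
    if v_B < 0:
        raise ValueError(f"v_B must be >= 0, got {v_B}")
    if mean_run_time <= 0:
        raise ValueError(f"mean_run_time must be > 0, got {mean_run_time}")
    return (v_B * units.M_PER_UM) ** 2 * mean_run_time / 3.0
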