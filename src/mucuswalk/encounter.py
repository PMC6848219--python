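"""Periodic-box phage–bacterium encounter-rate simulator.

One bacterium and a swarm of non-interacting phage evolve in a cubic box
with periodic boundaries.  Whenever an active phage comes within the
adsorption radius R_C = R_B + R_P of the bacterium (minimum-image metric)
an encounter is tallied and the phage is flagged inactive; it keeps moving
under its own dynamics and is reactivated once it has drifted a set
distance away.  The per-step encounter-rate kernel estimator is

    β = N_enc · V / (N_act · dt)

with V the box volume, N_enc the encounters tallied during the step and
N_act the number of phage that were active (eligible) at its start.  β has
units volume·bacterium⁻¹·time⁻¹ and is reported in both µm³/s and mL/h.

Phage are initialized uniformly over the box excluding the adsorption
sphere; the bacterium starts at the box center.  Encounter detection is
end-of-step only, which is safe as long as no particle can cross R_C in a
single step (validated at configuration time).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import units
from .bacteria import BacteriumParams, _run_directions_and_lengths
from .calibration import CTRWParams


@dataclass(frozen=True)
class EncounterConfig:
    """Geometry, particle models and schedule of one encounter experiment."""

    n_phage: int
    n_steps: int
    phage_model: CTRWParams
    bacterium: BacteriumParams
    box_length: float = 100.0            # µm
    R_C: float = 1.1                     # adsorption radius, µm
    reactivation_distance: float = 50.0  # µm
    dt: float = 0.01                     # s (the diffusion step time)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phage < 1:
            raise ValueError("n_phage must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        max_dist = self.box_length * np.sqrt(3.0) / 2.0
        if not (0.0 < self.R_C < self.reactivation_distance < max_dist):
            raise ValueError(
                "require 0 < R_C < reactivation_distance < box_length*sqrt(3)/2, "
                f"got R_C={self.R_C}, reactivation={self.reactivation_distance}, "
                f"max minimum-image distance={max_dist:.3f}"
            )
        step_b = self.bacterium.v_B * self.dt if self.bacterium.regime != "static" else 0.0
        step_p = 3.0 * np.sqrt(2.0 * self.phage_model.D * self.dt)  # 3 sigma
        if step_b >= self.R_C or step_p >= self.R_C:
            warnings.warn(
                "per-step displacement may exceed the adsorption radius "
                f"(bacterium {step_b:.3g} µm, phage 3σ {step_p:.3g} µm vs "
                f"R_C {self.R_C} µm): encounters can tunnel through the sphere",
                stacklevel=2,
            )

    @property
    def volume(self) -> float:
        """Box volume in µm³."""
        return self.box_length ** 3


@dataclass
class KernelSeries:
    """Per-step encounter tallies and kernel estimates of one simulation."""

    times: np.ndarray           # s, end-of-step times
    n_encounters: np.ndarray    # tallied per step
    n_active: np.ndarray        # active phage at the start of each step
    beta_um3_s: np.ndarray      # per-step kernel, NaN where n_active == 0
    config: EncounterConfig = field(repr=False)

    @property
    def beta_ml_h(self) -> np.ndarray:
        return self.beta_um3_s * units.ML_H_PER_UM3_S

    def cumulative_beta(self, discard: int = 0) -> np.ndarray:
        """Running mean of the per-step kernel (µm³/s) from step ``discard``."""
        beta = self.beta_um3_s[discard:]
        valid = ~np.isnan(beta)
        running = np.cumsum(np.where(valid, beta, 0.0)) / np.maximum(
            np.cumsum(valid), 1)
        return running

    def moving_average(self, window: int = 100) -> np.ndarray:
        """Centered-window moving average of β (µm³/s) for plotting/reporting."""
        beta = np.nan_to_num(self.beta_um3_s, nan=0.0)
        kernel = np.ones(window) / window
        return np.convolve(beta, kernel, mode="same")

    def time_averaged_beta(self, discard: int = 500) -> tuple[float, float]:
        """Post-transient time-averaged kernel in mL/h with Monte-Carlo error.

        Uses the ratio estimator β̄ = V·ΣN_enc / (dt·ΣN_act) over steps after
        ``discard``; the standard error treats the encounter count as
        Poisson, se(β̄) = β̄/sqrt(ΣN_enc).
        """
        enc = self.n_encounters[discard:]
        act = self.n_active[discard:]
        total_enc = float(enc.sum())
        exposure = float(act.sum()) * self.config.dt
        if exposure <= 0:
            return float("nan"), float("nan")
        beta = self.config.volume * total_enc / exposure * units.ML_H_PER_UM3_S
        stderr = beta / np.sqrt(total_enc) if total_enc > 0 else float("nan")
        return beta, stderr


def minimum_image_displacement(a: np.ndarray, b: np.ndarray,
                               L: float) -> tuple[np.ndarray, np.ndarray]:
    """Minimum-image displacement a − b and distance in a periodic box.

    Each component is mapped into [−L/2, L/2).  ``a`` and ``b`` broadcast;
    the distance is the Euclidean norm along the last axis.
    """
    disp = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
            + L / 2.0) % L - L / 2.0
    return disp, np.linalg.norm(disp, axis=-1)


def kernel_estimate(n_enc: float, n_act: float, V: float,
                    dt: float) -> tuple[float, float]:
    """Kernel estimate β = n_enc·V/(n_act·dt), returned in (µm³/s, mL/h).

    ``n_act = 0`` yields (nan, nan): no phage were eligible, the kernel is
    undefined for that step.
    """
    if n_act == 0:
        return float("nan"), float("nan")
    beta = n_enc * V / (n_act * dt)
    return beta, beta * units.ML_H_PER_UM3_S


def _initial_phage_positions(n: int, L: float, center: np.ndarray, R_C: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Uniform positions over the box excluding the adsorption sphere."""
    pos = rng.uniform(0.0, L, size=(n, 3))
    while True:
        _, dist = minimum_image_displacement(pos, center, L)
        inside = dist < R_C
        if not inside.any():
            return pos
        pos[inside] = rng.uniform(0.0, L, size=(int(inside.sum()), 3))


def _bacterium_step_directions(cfg: EncounterConfig,
                               rng: np.random.Generator) -> np.ndarray | None:
    """Precomputed per-step unit directions of the bacterium, or None if static."""
    b = cfg.bacterium
    if b.regime == "static" or b.v_B == 0.0:
        return None
    dirs, gaps = _run_directions_and_lengths(b, cfg.dt, cfg.n_steps, rng, False)
    return np.repeat(dirs, gaps, axis=0)[: cfg.n_steps]


def run_encounter_simulation(config: EncounterConfig,
                             initial_phage_positions: np.ndarray | None = None,
                             bacterium_start: np.ndarray | None = None,
                             ) -> KernelSeries:
    """Run the encounter experiment and return the kernel time series.

    Per step: advance the bacterium, advance every phage (active or not),
    wrap positions into the box, tally active phage entering the adsorption
    sphere (marking them inactive), reactivate inactive phage beyond the
    reactivation distance, and record the per-step kernel estimate.  The
    phage count is conserved throughout.  Identical configs (including the
    seed) give identical series.

    By default the bacterium starts at the box center and phage are placed
    uniformly outside the adsorption sphere; both may be overridden (in µm,
    positions are wrapped into the box).
    """
    cfg = config
    L = cfg.box_length
    model = cfg.phage_model
    root = np.random.SeedSequence(cfg.seed)
    seq_init, seq_bact, seq_phage = root.spawn(3)
    rng_init = np.random.default_rng(seq_init)
    rng_phage = np.random.default_rng(seq_phage)

    if bacterium_start is None:
        bact = np.full(3, L / 2.0)
    else:
        bact = np.asarray(bacterium_start, dtype=float) % L
    step_dirs = _bacterium_step_directions(cfg, np.random.default_rng(seq_bact))
    if initial_phage_positions is None:
        phage = _initial_phage_positions(cfg.n_phage, L, bact, cfg.R_C, rng_init)
    else:
        phage = np.array(initial_phage_positions, dtype=float) % L
        if phage.shape != (cfg.n_phage, 3):
            raise ValueError("initial_phage_positions must have shape (n_phage, 3)")

    sticky = model.tau_0 > 0.0
    # absolute times at which each phage next displaces; timers start at zero
    # so everyone is eligible to move on the first step
    release = np.zeros(cfg.n_phage)
    sigma = np.sqrt(2.0 * model.D * cfg.dt)

    active = np.ones(cfg.n_phage, dtype=bool)
    n_enc = np.zeros(cfg.n_steps, dtype=np.int64)
    n_act = np.zeros(cfg.n_steps, dtype=np.int64)
    v_step = cfg.bacterium.v_B * cfg.dt

    for k in range(cfg.n_steps):
        t = (k + 1) * cfg.dt
        n_act[k] = int(active.sum())

        if step_dirs is not None:
            bact = (bact + v_step * step_dirs[k]) % L

        if sticky:
            moving = t >= release
            n_mov = int(moving.sum())
            if n_mov:
                phage[moving] = (
                    phage[moving] + sigma * rng_phage.standard_normal((n_mov, 3))
                ) % L
                u = rng_phage.random(n_mov)
                release[moving] = t + model.tau_0 * (1.0 - u) ** (-1.0 / model.nu)
        else:
            phage = (phage + sigma * rng_phage.standard_normal((cfg.n_phage, 3))) % L

        _, dist = minimum_image_displacement(phage, bact, L)
        hits = active & (dist < cfg.R_C)
        n_enc[k] = int(hits.sum())
        active[hits] = False
        active |= dist >= cfg.reactivation_distance

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(n_act > 0, n_enc * cfg.volume / (n_act * cfg.dt), np.nan)
    if np.any(n_act == 0):
        warnings.warn("no active phage on some steps; kernel recorded as missing",
                      stacklevel=2)
    times = np.arange(1, cfg.n_steps + 1) * cfg.dt
    return KernelSeries(times=times, n_encounters=n_enc, n_active=n_act,
                        beta_um3_s=beta, config=cfg)
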