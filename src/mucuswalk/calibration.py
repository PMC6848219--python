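"""Model calibration from empirical phage-tracking data.

Everything a simulation needs is extracted from two measured quantities per
mucin concentration: the subdiffusive wild-type phage's anomalous MSD
parameters (α, D_α) and the non-adherent mutant's standard diffusion
constant D.  The closed-form relations are

* Stokes–Einstein inversion, η = kT / (6π R_P D), which turns the mutant's
  diffusion constants into mucus viscosities (microrheology with the phage
  itself as the probe particle);
* the CTRW consistency relations τ_D = (D/D_α)^(1/(α−1)) and
  τ₀ = τ_D · sinc(ν)^(1/ν) (normalized sinc, sinc(x) = sin(πx)/(πx)),
  which turn (α, D_α, D) into the Pareto waiting-time parameters used by
  the trajectory simulator;
* two-region power-law fits η_M = a·[mucin]^b + η_W on log-transformed
  data, characterizing the sub- and super-linear growth of viscosity with
  mucin concentration below and above the ~1% crossover.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from . import units


class CalibrationDomainError(ValueError):
    """An input parameter is outside the physical domain of a relation."""


class InsufficientDataError(ValueError):
    """Too few usable data points for a regression."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhageDiffusivity:
    """One row of the empirical diffusivity table.

    ``alpha`` and ``D_alpha`` (µm²/s^α) describe the phage's own MSD,
    MSD(t) = 2d·D_α·t^α.  ``D`` (µm²/s) is the standard diffusion constant
    of the non-adherent reference phage at the same mucin concentration; it
    sets the free-diffusion step of the CTRW.
    """

    mucin_concentration: float  # % w/v
    alpha: float
    D_alpha: float
    D: float
    alpha_sd: float = 0.0
    D_alpha_sd: float = 0.0
    D_sd: float = 0.0
    phage_type: str = "wt"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise CalibrationDomainError(f"alpha must be > 0, got {self.alpha}")
        if self.D_alpha <= 0:
            raise CalibrationDomainError(f"D_alpha must be > 0, got {self.D_alpha}")
        if self.D <= 0:
            raise CalibrationDomainError(f"D must be > 0, got {self.D}")
        if self.mucin_concentration < 0:
            raise CalibrationDomainError(
                f"mucin_concentration must be >= 0, got {self.mucin_concentration}"
            )


@dataclass(frozen=True)
class MucusEnvironment:
    """Viscosity of a mucin solution with its error band, in mPa·s."""

    mucin_concentration: float
    viscosity: float
    viscosity_upper: float
    viscosity_lower: float
    kT: float = units.KT_BODY_PN_NM       # pN·nm
    eta_water: float = units.ETA_WATER_MPAS  # mPa·s

    def __post_init__(self) -> None:
        if not (self.viscosity_lower <= self.viscosity <= self.viscosity_upper):
            raise CalibrationDomainError(
                "viscosity must lie between its lower and upper bounds"
            )
        if self.mucin_concentration > 0 and self.viscosity < self.eta_water:
            raise CalibrationDomainError(
                "mucin solution cannot be less viscous than water"
            )


@dataclass(frozen=True)
class CTRWParams:
    """Calibrated continuous-time random walk parameters.

    ``nu`` is the Pareto tail exponent, ``tau_0`` the minimum sticking time
    (s), ``tau_D`` the duration of one free diffusive step (s), and ``D``
    the standard diffusion constant (µm²/s) governing the Gaussian step
    size sqrt(2·D·τ_D).  For 0 < ν < 1 the constraint
    τ₀ = τ_D·sinc(ν)^(1/ν) ties the sticking floor to the step time (it is
    validated here to 1e-12 relative).  ``tau_0 = 0`` marks pure diffusion:
    no waiting times, every step displaces.  ν > 1 with a finite τ₀ also
    diffuses normally at long times (the waiting-time mean is finite).
    """

    nu: float
    tau_0: float
    tau_D: float
    D: float

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise CalibrationDomainError(f"nu must be > 0, got {self.nu}")
        if self.tau_D <= 0:
            raise CalibrationDomainError(f"tau_D must be > 0, got {self.tau_D}")
        if self.D <= 0:
            raise CalibrationDomainError(f"D must be > 0, got {self.D}")
        if self.tau_0 < 0:
            raise CalibrationDomainError(f"tau_0 must be >= 0, got {self.tau_0}")
        if self.nu < 1:
            if self.tau_0 <= 0:
                raise CalibrationDomainError("tau_0 must be > 0 for nu < 1")
            expected = self.tau_D * normalized_sinc(self.nu) ** (1.0 / self.nu)
            if not math.isclose(self.tau_0, expected, rel_tol=1e-12):
                raise CalibrationDomainError(
                    "tau_0 violates the sticking-time constraint "
                    f"tau_D*sinc(nu)^(1/nu): got {self.tau_0}, expected {expected}"
                )

    @property
    def is_subdiffusive(self) -> bool:
        return self.nu < 1.0


def ctrw_params_for_nu(nu: float, D: float, tau_D: float) -> CTRWParams:
    """CTRW parameters for a given Pareto exponent ν, step time and D.

    For 0 < ν < 1 the sticking floor follows the consistency constraint
    τ₀ = τ_D·sinc(ν)^(1/ν).  At ν = 1 the constraint gives τ₀ = 0 (regular
    diffusion).  For ν > 1 the constraint leaves its domain of derivation
    (the normalized sinc goes negative), but the walk diffuses normally for
    any finite floor; τ₀ = τ_D is used so that waiting and stepping share
    one time scale.
    """
    if nu <= 0:
        raise CalibrationDomainError(f"nu must be > 0, got {nu}")
    if nu < 1:
        tau_0 = tau_D * normalized_sinc(nu) ** (1.0 / nu)
    elif nu == 1:
        tau_0 = 0.0
    else:
        tau_0 = tau_D
    return CTRWParams(nu=nu, tau_0=tau_0, tau_D=tau_D, D=D)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log(η_M − η_W) = b·log([mucin]) + A over one region."""

    prefactor_log: float     # intercept A (natural log of prefactor a)
    exponent: float          # slope b
    exponent_stderr: float
    intercept_stderr: float
    r_squared: float
    region: tuple[float, float] = field(default=(0.0, math.inf))

    def __post_init__(self) -> None:
        if self.exponent_stderr < 0:
            raise CalibrationDomainError("exponent_stderr must be >= 0")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise CalibrationDomainError("r_squared must lie in [0, 1]")

    @property
    def prefactor(self) -> float:
        """The prefactor a of η_M = a·[mucin]^b + η_W, in mPa·s."""
        return math.exp(self.prefactor_log)


# ---------------------------------------------------------------------------
# closed-form relations
# ---------------------------------------------------------------------------

def normalized_sinc(x: float) -> float:
    """sinc(x) = sin(πx)/(πx), with sinc(0) = 1."""
    return float(np.sinc(x))


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise CalibrationDomainError(f"{name} must be > 0, got {value}")


def stokes_einstein_viscosity(D: float, R_P: float = 90.0,
                              kT: float = units.KT_BODY_PN_NM) -> float:
    """Viscosity (mPa·s) from a measured diffusion constant.

    Inverts D = kT/(6πηR) for η.  ``D`` in µm²/s, ``R_P`` in nm, ``kT`` in
    pN·nm.
    """
    _require_positive(D=D, R_P=R_P, kT=kT)
    eta_pas = (kT * units.J_PER_PN_NM) / (
        6.0 * math.pi * R_P * units.M_PER_NM * D * units.M2_PER_UM2
    )
    return eta_pas / units.PAS_PER_MPAS


def hydrodynamic_radius(D_water: float, kT: float = units.KT_BODY_PN_NM,
                        eta_water: float = units.ETA_WATER_MPAS) -> float:
    """Effective hydrodynamic radius (nm) of a particle diffusing in water.

    R = kT/(6πη_W·D).  ``D_water`` in µm²/s, ``kT`` in pN·nm, ``eta_water``
    in mPa·s.
    """
    _require_positive(D_water=D_water, kT=kT, eta_water=eta_water)
    r_m = (kT * units.J_PER_PN_NM) / (
        6.0 * math.pi * eta_water * units.PAS_PER_MPAS * D_water * units.M2_PER_UM2
    )
    return r_m / units.M_PER_NM


def fit_viscosity_powerlaw(concentrations, viscosities,
                           eta_water: float = units.ETA_WATER_MPAS,
                           region: tuple[float, float] = (0.0, math.inf),
                           ) -> PowerLawFit:
    """Fit η_M = a·[mucin]^b + η_W over a concentration region.

    Ordinary least squares of log(η_M − η_W) against log([mucin]) (natural
    logs), restricted to concentrations inside ``region`` (inclusive at both
    ends).  The 0% point is always excluded.  Requires at least 3 usable
    points and η_M > η_W at each of them.
    """
    c = np.asarray(concentrations, dtype=float)
    eta = np.asarray(viscosities, dtype=float)
    if c.shape != eta.shape:
        raise ValueError("concentrations and viscosities must have equal length")
    lo, hi = region
    mask = (c > 0) & (c >= lo) & (c <= hi)
    if mask.sum() < 3:
        raise InsufficientDataError(
            f"need >= 3 nonzero concentrations in region {region}, got {mask.sum()}"
        )
    excess = eta[mask] - eta_water
    if np.any(excess <= 0):
        raise CalibrationDomainError(
            "viscosity must exceed eta_water at every fitted concentration"
        )
    x = np.log(c[mask])
    y = np.log(excess)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return PowerLawFit(
        prefactor_log=float(model.params[0]),
        exponent=float(model.params[1]),
        exponent_stderr=float(model.bse[1]),
        intercept_stderr=float(model.bse[0]),
        r_squared=float(model.rsquared),
        region=(lo, hi),
    )


def ctrw_times_from_diffusivities(row: PhageDiffusivity) -> CTRWParams:
    """Extract CTRW waiting-time parameters from measured diffusivities.

    For 0 < α < 1: τ_D = (D/D_α)^(1/(α−1)), τ₀ = τ_D·sinc(α)^(1/α), ν = α.
    For α ≥ 1 the sticking-time extraction is undefined and the row is
    treated as pure Brownian motion (ν = 1, τ₀ = 0) with a warning; the
    step time then defaults to 0.01 s, the common simulation time step.
    """
    alpha, D_alpha, D = row.alpha, row.D_alpha, row.D
    if alpha >= 1.0:
        warnings.warn(
            f"alpha = {alpha} >= 1 at {row.mucin_concentration}% mucin: "
            "treating as pure diffusion (nu = 1, tau_0 = 0)",
            stacklevel=2,
        )
        return CTRWParams(nu=1.0, tau_0=0.0, tau_D=0.01, D=D)
    tau_D = (D / D_alpha) ** (1.0 / (alpha - 1.0))
    tau_0 = tau_D * normalized_sinc(alpha) ** (1.0 / alpha)
    return CTRWParams(nu=alpha, tau_0=tau_0, tau_D=tau_D, D=D)


def generalized_diffusion_constant(D: float, tau_D: float, nu: float) -> float:
    """D_ν = D / τ_D^(ν−1), in µm²/s^ν.  Inverse of the τ_D extraction."""
    _require_positive(D=D, tau_D=tau_D, nu=nu)
    return D / tau_D ** (nu - 1.0)


def relaxation_time(mass: float, friction: float) -> float:
    """Momentum relaxation time τ_relax = m/γ in seconds.

    ``mass`` in kg, ``friction`` in kg/s.  Used only to justify dropping
    inertia: τ_relax (~0.1 µs for a bacterium, ~0.1 ns for a phage) is
    orders of magnitude below the shortest resolved time scale τ_D.
    """
    _require_positive(mass=mass, friction=friction)
    return mass / friction


# ---------------------------------------------------------------------------
# table-level drivers
# ---------------------------------------------------------------------------

def calibrate_rows(rows: list[PhageDiffusivity]) -> dict:
    """Calibrate every table row; returns a JSON-serializable mapping.

    Keys are ``"{mucin_pct}:{phage_type}"``; values hold the CTRW parameters
    together with the Stokes–Einstein viscosity at that concentration.
    """
    out: dict[str, dict] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row in rows:
            params = ctrw_times_from_diffusivities(row)
            out[f"{row.mucin_concentration:g}:{row.phage_type}"] = {
                "mucin_pct": row.mucin_concentration,
                "phage_type": row.phage_type,
                "nu": params.nu,
                "tau_0": params.tau_0,
                "tau_D": params.tau_D,
                "D": params.D,
                "D_alpha": row.D_alpha,
                "alpha": row.alpha,
                "eta": stokes_einstein_viscosity(row.D),
            }
    return out


def mean_minimum_sticking_time(rows: list[PhageDiffusivity]) -> float:
    """Mean τ₀ (s) over the subdiffusive (α < 1) rows of a table."""
    taus = [
        ctrw_times_from_diffusivities(r).tau_0
        for r in rows
        if r.alpha < 1.0
    ]
    if not taus:
        raise InsufficientDataError("no subdiffusive rows (alpha < 1) in table")
    return float(np.mean(taus))
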