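"""Packaged empirical tables and their loaders.

Two small CSV fixtures ship with the package: the per-concentration
diffusivity parameters of T4 wild type (mucin-adherent, subdiffusive) and
T4Δhoc (non-adherent, diffusive), and the mucus viscosities extracted from
the latter.  ``load_table1`` pairs each wild-type row with the Δhoc
standard diffusion constant measured at the same concentration, since the
CTRW calibration needs both.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .calibration import MucusEnvironment, PhageDiffusivity

TABLE1_COLUMNS = ["mucin_pct", "phage_type", "alpha", "alpha_sd",
                  "diff_coeff", "diff_coeff_sd"]
TABLE2_COLUMNS = ["mucin_pct", "eta_mean", "eta_upper", "eta_lower"]


class TableParseError(ValueError):
    """A fixture CSV is malformed."""


def packaged_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("mucuswalk").joinpath("data", name))


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError as exc:
        raise TableParseError(f"{path}: empty or unreadable CSV") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}")
    return df


def load_table1(path=None) -> list[PhageDiffusivity]:
    """Load the diffusivity table as a list of :class:`PhageDiffusivity`.

    Each wild-type row's ``D`` field is filled with the Δhoc standard
    diffusion constant at the same mucin concentration (the free-diffusion
    reference of the CTRW calibration); for Δhoc rows ``D_alpha`` and ``D``
    coincide (α ≈ 1).
    """
    path = packaged_path("table1.csv") if path is None else path
    df = _read_csv(path, TABLE1_COLUMNS)
    rows: list[PhageDiffusivity] = []
    dhoc = df[df.phage_type == "dhoc"].set_index("mucin_pct")
    for _, r in df.iterrows():
        conc = float(r.mucin_pct)
        if conc not in dhoc.index:
            raise TableParseError(
                f"no dhoc reference row at {conc}% mucin for phage_type={r.phage_type}"
            )
        ref = dhoc.loc[conc]
        rows.append(PhageDiffusivity(
            mucin_concentration=conc,
            alpha=float(r.alpha),
            alpha_sd=float(r.alpha_sd),
            D_alpha=float(r.diff_coeff),
            D_alpha_sd=float(r.diff_coeff_sd),
            D=float(ref.diff_coeff),
            D_sd=float(ref.diff_coeff_sd),
            phage_type=str(r.phage_type),
        ))
    return rows


def load_table2(path=None, kT: float | None = None,
                eta_water: float | None = None) -> list[MucusEnvironment]:
    """Load the viscosity table as a list of :class:`MucusEnvironment`."""
    path = packaged_path("table2.csv") if path is None else path
    df = _read_csv(path, TABLE2_COLUMNS)
    extra = {}
    if kT is not None:
        extra["kT"] = kT
    if eta_water is not None:
        extra["eta_water"] = eta_water
    return [
        MucusEnvironment(
            mucin_concentration=float(r.mucin_pct),
            viscosity=float(r.eta_mean),
            viscosity_upper=float(r.eta_upper),
            viscosity_lower=float(r.eta_lower),
            **extra,
        )
        for _, r in df.iterrows()
    ]


def table1_row(rows: list[PhageDiffusivity], mucin_pct: float,
               phage_type: str) -> PhageDiffusivity:
    """Select one (concentration, phage type) row from a loaded table."""
    for r in rows:
        if r.mucin_concentration == mucin_pct and r.phage_type == phage_type:
            return r
    raise KeyError(f"no row for {mucin_pct}% mucin, phage_type={phage_type}")
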