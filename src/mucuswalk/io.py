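"""Readers and writers for trajectories, kernel series and calibration output.

Formats: trajectories go to CSV (columns t, x, y[, z], one file per track)
or HDF5 (one ``replicate_###`` dataset per track plus model attributes);
kernel series to CSV with a JSON summary; calibration results to JSON.
Every simulation output can be accompanied by a run manifest recording the
configuration, master seed and SHA-256 checksums of the files produced, so
a run can be re-executed and verified bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .encounter import KernelSeries
from .trajectory import Trajectory

_AXES = ("x", "y", "z")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def write_trajectory_csv(traj: Trajectory, path) -> None:
    cols = {"t": traj.times}
    for i in range(traj.dimension):
        cols[_AXES[i]] = traj.positions[:, i]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"# particle_kind={traj.particle_kind} units=um time=s\n")
        df.to_csv(fh, index=False)


def read_trajectory_csv(path) -> Trajectory:
    kind = "phage-wt"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                if tok.startswith("particle_kind="):
                    kind = tok.split("=", 1)[1]
        else:
            fh.seek(0)
        df = pd.read_csv(fh)
    axes = [a for a in _AXES if a in df.columns]
    return Trajectory(df["t"].to_numpy(), df[axes].to_numpy(), len(axes), kind)


def write_ensemble_h5(trajectories: list[Trajectory], path,
                      attrs: dict | None = None) -> None:
    """Write a replicate ensemble to HDF5, one dataset per trajectory."""
    with h5py.File(path, "w") as f:
        f.attrs["n_replicates"] = len(trajectories)
        f.attrs["package_version"] = __version__
        for key, value in (attrs or {}).items():
            f.attrs[key] = value
        for i, tr in enumerate(trajectories):
            ds = f.create_dataset(f"replicate_{i:05d}", data=tr.positions)
            ds.attrs["dimension"] = tr.dimension
            ds.attrs["particle_kind"] = tr.particle_kind
            ds.attrs["dt"] = tr.dt if len(tr) > 1 else 0.0
            ds.attrs["t0"] = float(tr.times[0])


def read_ensemble_h5(path) -> tuple[list[Trajectory], dict]:
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        out = []
        for name in sorted(k for k in f.keys() if k.startswith("replicate_")):
            ds = f[name]
            pos = ds[()]
            dt = float(ds.attrs["dt"]) or 1.0
            t0 = float(ds.attrs.get("t0", 0.0))
            times = t0 + np.arange(len(pos)) * dt
            out.append(Trajectory(times, pos, int(ds.attrs["dimension"]),
                                  str(ds.attrs["particle_kind"])))
    return out, attrs


# ---------------------------------------------------------------------------
# kernel series
# ---------------------------------------------------------------------------

def write_kernel_csv(series: KernelSeries, path, window: int = 100,
                     discard: int = 500) -> None:
    """Kernel series CSV (t, n_enc, n_act, beta in both units, running mean)
    plus a JSON summary next to it (same stem, .json suffix)."""
    cum = np.full(len(series.times), np.nan)
    cum[discard:] = series.cumulative_beta(discard=discard) if discard < len(
        series.times) else np.nan
    df = pd.DataFrame({
        "t_s": series.times,
        "n_enc": series.n_encounters,
        "n_act": series.n_active,
        "beta_um3_s": series.beta_um3_s,
        "beta_ml_h": series.beta_ml_h,
        "beta_cum_um3_s": cum,
        "beta_mavg_um3_s": series.moving_average(window=window),
    })
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# encounter kernel series; moving-average window={window} "
                 f"steps; cumulative mean from step {discard}\n")
        df.to_csv(fh, index=False)
    beta, stderr = series.time_averaged_beta(discard=discard)
    summary = {
        "beta_ml_h": beta,
        "beta_stderr_ml_h": stderr,
        "discarded_steps": discard,
        "n_steps": int(len(series.times)),
        "n_phage": series.config.n_phage,
        "total_encounters": int(series.n_encounters.sum()),
        "units": "mL/h",
    }
    path.with_suffix(".json").write_text(json.dumps(summary, indent=2))


# ---------------------------------------------------------------------------
# calibration and manifests
# ---------------------------------------------------------------------------

def write_calibration_json(calibration: dict, path) -> None:
    Path(path).write_text(json.dumps(calibration, indent=2, sort_keys=True))


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record of one CLI run."""

    command: str
    seed: int | None
    config: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    code_version: str = __version__

    def add_output(self, path) -> None:
        self.outputs[str(path)] = sha256_of(path)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def read_manifest(path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
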