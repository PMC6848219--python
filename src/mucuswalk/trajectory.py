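"""Shared trajectory container for phage and bacterium simulations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Trajectory:
    """A single particle track on a uniform time grid.

    ``times`` are in seconds (strictly increasing, uniform spacing),
    ``positions`` in µm with shape ``(len(times), dimension)``.
    """

    times: np.ndarray
    positions: np.ndarray
    dimension: int
    particle_kind: str = "phage-wt"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")
        if self.positions.ndim != 2 or self.positions.shape[1] != self.dimension:
            raise ValueError("positions must have shape (n_times, dimension)")
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            # uniform up to roundoff of the largest time on the grid
            if not np.allclose(dt, dt[0], rtol=1e-9,
                               atol=4.0 * np.spacing(self.times[-1])):
                raise ValueError("times must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def __len__(self) -> int:
        return len(self.times)
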