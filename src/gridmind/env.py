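"""Synthetic 2-D arenas, foraging trajectories, and self-motion encodings.

The simulated animal forages in a rectangular arena under a simple
correlated random walk: heading follows a wrapped first-order
autoregressive process, per-step speed is drawn from a Rayleigh
distribution rescaled to a target mean, and the walls reflect.  Speed and
allocentric head-direction are then population-encoded the way the
entorhinal inputs of the network models expect them: a ring of
direction-tuned cells with non-negative circular tuning curves, plus a
bank of linear-gain speed cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Arena",
    "MotionParams",
    "Trajectory",
    "SelfMotionSpec",
    "generate_trajectory",
    "generate_trajectory_batch",
    "encode_self_motion",
    "save_trajectory",
    "load_trajectory",
]

#: mean of a unit-scale Rayleigh variate
_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)
#: standard deviation of a unit-scale Rayleigh variate
_RAYLEIGH_STD = math.sqrt(2.0 - math.pi / 2.0)


@dataclass(frozen=True)
class Arena:
    """Rectangular arena ``[0, width) x [0, height)`` cm, origin lower-left.

    ``bin_size`` sets the ratemap discretization; bins are half-open.
    """

    width: float = 150.0
    height: float = 150.0
    bin_size: float = 2.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0 or self.bin_size <= 0:
            raise ValueError("width, height and bin_size must be positive")
        if self.nx < 4 or self.ny < 4:
            raise ValueError("arena must span at least 4 bins per axis")

    @property
    def nx(self) -> int:
        return int(self.width // self.bin_size)

    @property
    def ny(self) -> int:
        return int(self.height // self.bin_size)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Centers of the ratemap bins along each axis (cm)."""
        bx = (np.arange(self.nx) + 0.5) * self.bin_size
        by = (np.arange(self.ny) + 0.5) * self.bin_size
        return bx, by

    def bin_index(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map positions (..., 2) in cm to integer bin indices.

        Raises ``ValueError`` for positions outside the arena.
        """
        p = np.asarray(positions, dtype=float)
        ix = np.floor(p[..., 0] / self.bin_size).astype(int)
        iy = np.floor(p[..., 1] / self.bin_size).astype(int)
        if np.any((ix < 0) | (ix >= self.nx) | (iy < 0) | (iy >= self.ny)):
            raise ValueError("position outside arena bounds")
        return ix, iy

    def contains(self, positions: np.ndarray) -> np.ndarray:
        p = np.asarray(positions, dtype=float)
        return (
            (p[..., 0] >= 0)
            & (p[..., 0] < self.width)
            & (p[..., 1] >= 0)
            & (p[..., 1] < self.height)
        )


@dataclass(frozen=True)
class MotionParams:
    """Parameters of the correlated random-walk foraging model.

    ``heading_persistence`` in [0, 1) controls the angular stiffness of the
    heading process (1 would mean a perfectly straight run); ``speed_scale``
    is the standard deviation of the per-step speed fluctuation in cm/s.
    """

    dt: float = 0.05
    mean_speed: float = 20.0
    speed_scale: float = 10.0
    heading_persistence: float = 0.7
    boundary_mode: str = "reflect"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.mean_speed < 0:
            raise ValueError("mean_speed must be non-negative")
        if not (0 <= self.heading_persistence < 1):
            raise ValueError("heading_persistence must lie in [0, 1)")
        if self.boundary_mode != "reflect":
            raise ValueError(f"unsupported boundary_mode {self.boundary_mode!r}")


@dataclass
class Trajectory:
    """A sampled trajectory: positions (T, 2) cm, headings (T,) rad in
    [0, 2pi), speeds (T,) cm/s, all at fixed timestep ``dt``."""

    positions: np.ndarray
    headings: np.ndarray
    speeds: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.headings = np.mod(np.asarray(self.headings, dtype=float), 2 * np.pi)
        self.speeds = np.asarray(self.speeds, dtype=float)
        if len(self.positions) < 2:
            raise ValueError("trajectory must have at least 2 samples")
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be non-negative")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def duration(self) -> float:
        return len(self) * self.dt

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": np.arange(len(self)) * self.dt,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "heading": self.headings,
                "speed": self.speeds,
            }
        )


@dataclass(frozen=True)
class SelfMotionSpec:
    """Population code for speed and allocentric head direction.

    Direction cells have preferred directions uniformly spaced on [0, 2pi)
    and tuning curve exp((cos(theta - theta_pref) - 1) / width^2): strictly
    positive, ring-shaped, peak 1.  Speed cells are linear with per-cell
    positive gains (units 1/(cm/s)), so typical responses are O(1).
    """

    n_dir_cells: int = 24
    dir_tuning_width: float = 0.5
    n_speed_cells: int = 8
    speed_gains: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_dir_cells < 1 or self.n_speed_cells < 0:
            raise ValueError("cell counts must be positive")
        if self.dir_tuning_width <= 0:
            raise ValueError("dir_tuning_width must be positive")
        if not self.speed_gains:
            gains = np.linspace(0.02, 0.06, max(self.n_speed_cells, 1))
            object.__setattr__(self, "speed_gains", tuple(gains[: self.n_speed_cells]))
        if len(self.speed_gains) != self.n_speed_cells:
            raise ValueError("speed_gains length must equal n_speed_cells")
        if any(g <= 0 for g in self.speed_gains):
            raise ValueError("speed gains must be positive")

    @property
    def n_cells(self) -> int:
        return self.n_dir_cells + self.n_speed_cells

    @property
    def preferred_directions(self) -> np.ndarray:
        return np.arange(self.n_dir_cells) * 2 * np.pi / self.n_dir_cells


def _reflect(coord: np.ndarray, extent: float) -> tuple[np.ndarray, np.ndarray]:
    """Fold a coordinate back into [0, extent) by wall reflection.

    Returns the folded coordinate and a boolean array marking entries that
    were reflected an odd number of times (heading mirror needed).
    """
    period = 2.0 * extent
    folded = np.mod(coord, period)
    odd = folded >= extent
    folded = np.where(odd, period - folded, folded)
    # keep strictly inside the half-open interval
    folded = np.clip(folded, 0.0, np.nextafter(extent, 0.0))
    return folded, odd


def generate_trajectory_batch(
    arena: Arena,
    params: MotionParams,
    duration: float,
    n_traj: int,
    rng: np.random.Generator,
) -> list[Trajectory]:
    """Vectorized batch of independent foraging trajectories.

    The heading evolves as a wrapped AR(1) walk whose per-step turn has
    standard deviation (1 - persistence) * pi * sqrt(dt); reflections off a
    wall mirror the heading for subsequent steps.
    """
    dt = params.dt
    if duration < 2 * dt:
        raise ValueError("duration must cover at least 2 timesteps")
    n_steps = int(math.ceil(duration / dt))

    turn_std = (1.0 - params.heading_persistence) * np.pi * math.sqrt(dt)

    pos = np.column_stack(
        [
            rng.uniform(0, arena.width, size=n_traj),
            rng.uniform(0, arena.height, size=n_traj),
        ]
    )
    heading = rng.uniform(0, 2 * np.pi, size=n_traj)

    raw = rng.rayleigh(scale=1.0, size=(n_steps, n_traj))
    speeds = params.mean_speed + params.speed_scale * (raw - _RAYLEIGH_MEAN) / _RAYLEIGH_STD
    np.clip(speeds, 0.0, None, out=speeds)
    turns = rng.normal(0.0, turn_std, size=(n_steps, n_traj))

    positions = np.empty((n_steps, n_traj, 2))
    headings = np.empty((n_steps, n_traj))

    for t in range(n_steps):
        positions[t] = pos
        headings[t] = heading
        step = speeds[t][:, None] * dt * np.column_stack(
            [np.cos(heading), np.sin(heading)]
        )
        nxt = pos + step
        x, odd_x = _reflect(nxt[:, 0], arena.width)
        y, odd_y = _reflect(nxt[:, 1], arena.height)
        pos = np.column_stack([x, y])
        heading = np.where(odd_x, np.pi - heading, heading)
        heading = np.where(odd_y, -heading, heading)
        heading = np.mod(heading + turns[t], 2 * np.pi)

    return [
        Trajectory(positions[:, i], headings[:, i], speeds[:, i], dt)
        for i in range(n_traj)
    ]


def generate_trajectory(
    arena: Arena, params: MotionParams, duration: float, seed: int
) -> Trajectory:
    """Generate one random foraging trajectory; deterministic per seed."""
    rng = np.random.default_rng(seed)
    return generate_trajectory_batch(arena, params, duration, 1, rng)[0]


def encode_self_motion(traj: Trajectory, spec: SelfMotionSpec) -> np.ndarray:
    """Encode a trajectory into (T, n_dir + n_speed) non-negative responses.

    Columns [0, n_dir) are the head-direction ring, columns [n_dir, ...)
    the speed cells.
    """
    theta = traj.headings[:, None] - spec.preferred_directions[None, :]
    dir_block = np.exp((np.cos(theta) - 1.0) / spec.dir_tuning_width**2)
    gains = np.asarray(spec.speed_gains)
    speed_block = traj.speeds[:, None] * gains[None, :]
    return np.concatenate([dir_block, speed_block], axis=1)


def save_trajectory(path, traj: Trajectory) -> None:
    np.savez_compressed(
        path,
        positions=traj.positions,
        headings=traj.headings,
        speeds=traj.speeds,
        dt=np.array(traj.dt),
    )


def load_trajectory(path) -> Trajectory:
    with np.load(path) as data:
        return Trajectory(
            data["positions"], data["headings"], data["speeds"], float(data["dt"])
        )
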