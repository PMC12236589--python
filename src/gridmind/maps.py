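"""Ground-truth tuning maps: grid modules, spatially modulated cells, masking.

Grid-cell firing fields are sums of Gaussian blobs centered on a triangular
lattice; a module shares period and orientation, and its cells differ only
by a 2-D phase offset drawn uniformly over the unit cell.  Module periods
form a geometric hierarchy ``l_i = l0 * s**i`` with the scale factor s
defaulting to sqrt(e), the theoretically optimal value for 2-D environments
(e is optimal in 1-D).  The smallest spacing defaults to 30 cm and the
spacing-to-field-size ratio to 3.26, field size being the blob diameter at
two standard deviations — hence ``sigma = l / (4 * 3.26)``.

Spatially modulated cells (SMCs) carry synthetic sensory patterns: smoothed
white noise with a configurable correlation length, rectified at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .env import Arena, Trajectory

__all__ = [
    "SPACING_FIELD_RATIO",
    "GridModuleSpec",
    "PhaseHierarchy",
    "Ratemap",
    "SMCSpec",
    "MaskConfig",
    "make_grid_modules",
    "make_smc_map",
    "sample_responses",
    "apply_mask",
]

#: grid spacing divided by field diameter (at 2 sigma) for simulated modules
SPACING_FIELD_RATIO = 3.26


@dataclass(frozen=True)
class PhaseHierarchy:
    """Geometric stack of grid-module spatial periods, ``l_i = l0 * s**i``.

    ``base_period`` is the constant l0 (not itself a module); the smallest
    actual period is ``l0 * s``.
    """

    base_period: float
    scale_factor: float = math.sqrt(math.e)
    n_modules: int = 6

    def __post_init__(self) -> None:
        if self.scale_factor <= 1:
            raise ValueError("scale_factor must exceed 1")
        if self.base_period <= 0 or self.n_modules < 1:
            raise ValueError("base_period must be positive, n_modules >= 1")

    @classmethod
    def from_smallest_period(
        cls,
        smallest: float = 30.0,
        scale_factor: float = math.sqrt(math.e),
        n_modules: int = 6,
    ) -> "PhaseHierarchy":
        return cls(smallest / scale_factor, scale_factor, n_modules)

    @property
    def periods(self) -> np.ndarray:
        i = np.arange(1, self.n_modules + 1)
        return self.base_period * self.scale_factor**i


def _hex_basis(period: float, orientation: float) -> np.ndarray:
    """Lattice basis: columns l*(1,0) and l*(1/2, sqrt(3)/2), rotated."""
    b = period * np.array([[1.0, 0.5], [0.0, math.sqrt(3) / 2]])
    c, s = math.cos(orientation), math.sin(orientation)
    rot = np.array([[c, -s], [s, c]])
    return rot @ b


@dataclass(frozen=True)
class GridModuleSpec:
    """One grid module: shared period/orientation, per-cell phase offsets.

    ``phase_offsets`` has shape (n_cells, 2) with entries in [0, 1): the
    offset in lattice (unit-cell) coordinates.
    """

    period: float
    orientation: float = 0.0
    field_sigma: float | None = None
    phase_offsets: np.ndarray = field(default_factory=lambda: np.zeros((1, 2)))

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.field_sigma is None:
            object.__setattr__(
                self, "field_sigma", self.period / (4.0 * SPACING_FIELD_RATIO)
            )
        if self.field_sigma <= 0:
            raise ValueError("field_sigma must be positive")
        object.__setattr__(
            self, "phase_offsets", np.atleast_2d(np.asarray(self.phase_offsets, float))
        )

    @property
    def n_cells(self) -> int:
        return len(self.phase_offsets)

    @property
    def lattice_basis(self) -> np.ndarray:
        return _hex_basis(self.period, self.orientation)


@dataclass
class Ratemap:
    """Binned non-negative rates, shape (nx, ny, n_cells), over an arena.

    ``valid`` marks bins with defined rates (all bins for generated maps;
    visited bins only for maps aggregated from trajectories).
    """

    rates: np.ndarray
    arena: Arena
    population_tag: str = "GC"
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must have shape (nx, ny, n_cells)")
        if not np.all(np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValueError("rates must be finite and non-negative")
        if self.valid is None:
            self.valid = np.ones(self.rates.shape[:2], dtype=bool)

    @property
    def n_cells(self) -> int:
        return self.rates.shape[2]

    def flattened(self) -> np.ndarray:
        """(nx*ny, n_cells) view used as a nearest-neighbour dictionary."""
        return self.rates.reshape(-1, self.n_cells)


@dataclass(frozen=True)
class SMCSpec:
    """Synthetic sensory-pattern population (stand-in for visual features).

    The default correlation length is comparable to the smallest grid
    fields: visual-feature embeddings carry spatial detail at least that
    fine, and a much smoother field cannot support sensory-to-grid
    pattern completion.
    """

    n_cells: int = 64
    correlation_length: float = 10.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        if self.n_cells < 1 or self.amplitude <= 0:
            raise ValueError("n_cells and amplitude must be positive")


@dataclass(frozen=True)
class MaskConfig:
    """Input occlusion protocol for autoassociative training.

    Per trajectory an effective fraction f ~ Uniform(0, r_mask) is drawn and
    independent Bernoulli(f) entries over (time x cell) are zeroed.
    ``targets`` names the population blocks the mask may touch.
    """

    r_mask: float = 0.5
    targets: frozenset[str] = frozenset({"GC", "SMC", "DIR", "SPD", "initial-state"})

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_mask <= 1.0):
            raise ValueError("r_mask must lie in [0, 1]")
        object.__setattr__(self, "targets", frozenset(self.targets))


def _lattice_points(
    basis: np.ndarray, offset_frac: np.ndarray, arena: Arena, margin: float
) -> np.ndarray:
    """All lattice points B @ (i + u, j + v) within the arena plus margin."""
    corners = np.array(
        [[-margin, -margin], [arena.width + margin, -margin],
         [-margin, arena.height + margin], [arena.width + margin, arena.height + margin]]
    )
    frac_corners = np.linalg.solve(basis, corners.T).T
    lo = np.floor(frac_corners.min(axis=0)).astype(int) - 1
    hi = np.ceil(frac_corners.max(axis=0)).astype(int) + 1
    ii, jj = np.meshgrid(np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1))
    frac = np.column_stack([ii.ravel(), jj.ravel()]) + offset_frac[None, :]
    pts = frac @ basis.T
    keep = (
        (pts[:, 0] >= -margin)
        & (pts[:, 0] <= arena.width + margin)
        & (pts[:, 1] >= -margin)
        & (pts[:, 1] <= arena.height + margin)
    )
    return pts[keep]


def grid_cell_rates(
    positions: np.ndarray, module: GridModuleSpec, arena: Arena, cell: int
) -> np.ndarray:
    """Unnormalized Gaussian-blob rate of one cell at positions (..., 2)."""
    sigma = module.field_sigma
    pts = _lattice_points(
        module.lattice_basis, module.phase_offsets[cell], arena, margin=4 * sigma
    )
    p = np.asarray(positions, float).reshape(-1, 2)
    d2 = ((p[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    r = np.exp(-d2 / (2 * sigma**2)).sum(axis=1)
    return r.reshape(np.asarray(positions).shape[:-1])


def make_grid_modules(
    h: PhaseHierarchy,
    n_cells_per_module: int,
    arena: Arena,
    seed: int,
    orientation: float = 0.0,
) -> list[tuple[GridModuleSpec, Ratemap]]:
    """Simulate grid modules and their ground-truth ratemaps.

    Each cell's map is a sum of Gaussian blobs (std sigma = l/(4*3.26)) on
    the module's triangular lattice shifted by the cell's phase offset,
    peak-normalized to 1 over the arena.  Phase offsets are uniform over
    the unit cell; the first cell of each module sits at offset (0, 0) so a
    field center coincides with the lattice origin.
    """
    if n_cells_per_module < 1:
        raise ValueError("n_cells_per_module must be >= 1")
    rng = np.random.default_rng(seed)
    bx, by = arena.bin_centers()
    gx, gy = np.meshgrid(bx, by, indexing="ij")
    bin_pos = np.stack([gx, gy], axis=-1)

    out: list[tuple[GridModuleSpec, Ratemap]] = []
    for period in h.periods:
        if period > min(arena.width, arena.height):
            warnings.warn(
                f"module period {period:.1f} cm exceeds arena extent; "
                "fields may not repeat",
                stacklevel=2,
            )
        offsets = rng.uniform(0, 1, size=(n_cells_per_module, 2))
        offsets[0] = 0.0
        module = GridModuleSpec(period, orientation, phase_offsets=offsets)
        rates = np.empty((arena.nx, arena.ny, n_cells_per_module))
        for c in range(n_cells_per_module):
            rmap = grid_cell_rates(bin_pos, module, arena, c)
            peak = rmap.max()
            rates[:, :, c] = rmap / peak if peak > 0 else rmap
        out.append((module, Ratemap(rates, arena, "GC")))
    return out


def make_smc_map(spec: SMCSpec, arena: Arena, seed: int) -> Ratemap:
    """Smooth random non-negative spatial fields for SMC ground truth.

    White noise is Gaussian-blurred so that the pre-rectification spatial
    autocorrelation falls to 0.5 at a lag of one correlation length
    (filter sigma = L / (2*sqrt(ln 2))), then rectified at zero and
    peak-scaled to ``amplitude`` per cell.
    """
    rng = np.random.default_rng(seed)
    sigma_bins = spec.correlation_length / (2.0 * math.sqrt(math.log(2))) / arena.bin_size
    noise = rng.standard_normal((arena.nx, arena.ny, spec.n_cells))
    smooth = ndimage.gaussian_filter(noise, sigma=(sigma_bins, sigma_bins, 0), mode="reflect")
    rect = np.clip(smooth, 0.0, None)
    peaks = rect.max(axis=(0, 1), keepdims=True)
    peaks[peaks == 0] = 1.0
    return Ratemap(rect / peaks * spec.amplitude, arena, "SMC")


def sample_responses(ratemap: Ratemap, traj: Trajectory) -> np.ndarray:
    """Ground-truth responses along a trajectory by nearest-bin lookup.

    Returns (T, n_cells); raises for positions outside the map's arena.
    """
    ix, iy = ratemap.arena.bin_index(traj.positions)
    return ratemap.rates[ix, iy, :]


def sample_at_positions(ratemap: Ratemap, positions: np.ndarray) -> np.ndarray:
    """Nearest-bin lookup for arbitrary positions (..., 2) -> (..., n_cells)."""
    ix, iy = ratemap.arena.bin_index(positions)
    return ratemap.rates[ix, iy, :]


def apply_mask(
    batch: np.ndarray, cfg: MaskConfig, seed_or_rng
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly occlude entries of a response array.

    ``batch`` is one trajectory's (T, n_cells) array, or (B, T, n_cells)
    with an independent effective fraction per leading index.  Returns the
    masked copy and the boolean mask (True = zeroed).
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    x = np.asarray(batch, dtype=float)
    if cfg.r_mask == 0.0:
        return x.copy(), np.zeros(x.shape, dtype=bool)
    if x.ndim == 3:
        f = rng.uniform(0, cfg.r_mask, size=(x.shape[0], 1, 1))
    else:
        f = rng.uniform(0, cfg.r_mask)
    mask = rng.uniform(size=x.shape) < f
    out = x.copy()
    out[mask] = 0.0
    return out, mask
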