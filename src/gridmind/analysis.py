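"""Ratemap analysis, population decoding, and recall diagnostics.

Includes the measurement side of the pipeline: occupancy-weighted ratemap
aggregation, exact nearest-neighbour position decoding on a ratemap
dictionary, Skaggs spatial information, place-cell identification, the
sensory-cue recall protocol, grid autocorrelogram metrics, and the
firing-field geometry measurements (field centers, spacing, field size)
used to validate the grid simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from sklearn.decomposition import PCA

from .env import Arena, Trajectory
from .maps import Ratemap
from .network import PopulationLayout, RNNParams, rollout_batch

__all__ = [
    "CellCriteria",
    "RecallTrace",
    "aggregate_ratemaps",
    "collect_network_ratemaps",
    "decode_position",
    "spatial_information",
    "identify_place_cells",
    "recall_query",
    "grid_metrics",
    "project_recall_pca",
    "detect_field_centers",
    "measure_grid_geometry",
]


@dataclass(frozen=True)
class CellCriteria:
    """Thresholds for identifying place-cell-like hidden units.

    ``min_rate`` is a mean activation per timestep in model units;
    ``min_sic`` a Skaggs spatial information threshold in bits per sample.
    The default of 3 bits demands activity concentrated in roughly an
    eighth of the arena — a compact-field criterion; weakly modulated
    units that any recurrent network develops sit well below it.
    """

    min_rate: float = 0.01
    min_sic: float = 3.0
    min_cells_for_decoding: int = 10

    def __post_init__(self) -> None:
        if self.min_rate < 0 or self.min_sic < 0 or self.min_cells_for_decoding < 0:
            raise ValueError("criteria thresholds must be non-negative")


# ---------------------------------------------------------------------------
# Ratemaps and decoding
# ---------------------------------------------------------------------------


def aggregate_ratemaps(
    positions: np.ndarray, activations: np.ndarray, arena: Arena
) -> Ratemap:
    """Occupancy-weighted mean activation per spatial bin.

    positions (N, 2) cm and activations (N, C); unvisited bins are flagged
    invalid (not zero) in the returned map's ``valid`` mask.
    """
    p = np.asarray(positions, float).reshape(-1, 2)
    a = np.asarray(activations, float).reshape(len(p), -1)
    ix, iy = arena.bin_index(p)
    flat = ix * arena.ny + iy
    counts = np.bincount(flat, minlength=arena.nx * arena.ny)
    if counts.sum() == 0:
        raise ValueError("zero total occupancy")
    sums = np.zeros((arena.nx * arena.ny, a.shape[1]))
    np.add.at(sums, flat, a)
    visited = counts > 0
    means = np.zeros_like(sums)
    means[visited] = sums[visited] / counts[visited, None]
    # activations may be signed in principle; ratemaps store rates
    means = np.clip(means, 0.0, None)
    rmap = Ratemap(
        means.reshape(arena.nx, arena.ny, -1), arena, "HPC",
        valid=visited.reshape(arena.nx, arena.ny),
    )
    return rmap


def occupancy_distribution(positions: np.ndarray, arena: Arena) -> np.ndarray:
    """Per-bin occupancy probabilities (nx, ny), summing to 1."""
    ix, iy = arena.bin_index(np.asarray(positions, float).reshape(-1, 2))
    counts = np.zeros((arena.nx, arena.ny))
    np.add.at(counts, (ix, iy), 1.0)
    return counts / counts.sum()


def collect_network_ratemaps(
    params: RNNParams,
    world,
    trajectories: list[Trajectory],
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> dict:
    """Roll the trained network along test trajectories and aggregate
    per-population ratemaps (plus the occupancy distribution).

    Inputs are the unmasked ground-truth encodings; grid coordinates are
    initialized from ground truth at t = 0 of each trajectory.
    """
    from .env import encode_self_motion
    from .models import World  # noqa: F401  (type reference)

    layout = params.layout
    rng = np.random.default_rng(seed)
    all_pos, all_states = [], []
    for traj in trajectories:
        T = len(traj)
        U = np.zeros((1, T, layout.dim))
        sm = encode_self_motion(traj, world.selfmotion)
        sm = sm + rng.normal(0, noise_sigma, sm.shape) if noise_sigma else sm
        n_dir = world.selfmotion.n_dir_cells
        U[0, :, layout.slc("DIR")] = sm[:, :n_dir]
        U[0, :, layout.slc("SPD")] = sm[:, n_dir:]
        if layout.sizes["SMC"]:
            U[0, :, layout.slc("SMC")] = world.smc_pattern(traj.positions)
        z0 = np.zeros((1, layout.dim))
        z0[0, layout.slc("GC")] = world.gc_pattern(traj.positions[0])
        Z, _ = rollout_batch(params, z0, U)
        all_pos.append(traj.positions[1:])
        all_states.append(Z[0, 2:])  # state t aligns with position t
    pos = np.concatenate(all_pos)
    states = np.concatenate(all_states)
    maps = {}
    for name in ("GC", "SMC", "HIDDEN"):
        if layout.sizes[name]:
            maps[name] = aggregate_ratemaps(pos, states[:, layout.slc(name)],
                                            world.arena)
            maps[name].population_tag = "HPC" if name == "HIDDEN" else name
    maps["occupancy"] = occupancy_distribution(pos, world.arena)
    return maps


def decode_position(query: np.ndarray, ratemap: Ratemap) -> np.ndarray:
    """Nearest-neighbour position decoding on a ratemap dictionary.

    Returns the bin-center coordinates (cm) of the valid bin whose rate
    vector is closest in Euclidean distance to the query; exhaustive exact
    search, ties resolved to the lowest flattened bin index.  ``query`` is
    (n_cells,) or (Q, n_cells).
    """
    q = np.atleast_2d(np.asarray(query, float))
    dict_flat = ratemap.flattened()
    valid = ratemap.valid.reshape(-1)
    if not np.any(valid):
        raise ValueError("ratemap has no valid bins")
    if q.shape[1] != ratemap.n_cells:
        raise ValueError("query length must equal the map's cell count")
    d = dict_flat[valid]
    # argmin over ||q - d||^2 = ||d||^2 - 2 q.d (+ const); chunked to keep
    # the score matrix small
    d_norm = np.sum(d**2, axis=1)
    best = np.empty(len(q), dtype=int)
    for lo in range(0, len(q), 512):
        hi = min(lo + 512, len(q))
        scores = d_norm[None, :] - 2.0 * q[lo:hi] @ d.T
        best[lo:hi] = np.argmin(scores, axis=1)
    idx = np.flatnonzero(valid)[best]
    arena = ratemap.arena
    ix, iy = idx // arena.ny, idx % arena.ny
    centers = np.column_stack(
        [(ix + 0.5) * arena.bin_size, (iy + 0.5) * arena.bin_size]
    )
    return centers[0] if np.asarray(query).ndim == 1 else centers


def spatial_information(cell_map: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs spatial information (bits per sample) of one cell's map.

    SIC = sum_i p_i (l_i / L) log2(l_i / L) with L the occupancy-weighted
    mean rate; zero for a silent cell.
    """
    lam = np.asarray(cell_map, float).reshape(-1)
    p = np.asarray(occupancy, float).reshape(-1)
    if np.any(lam < 0):
        raise ValueError("rates must be non-negative")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("occupancy must sum to 1")
    mean_rate = float(np.dot(p, lam))
    if mean_rate == 0:
        return 0.0
    ratio = lam / mean_rate
    mask = (ratio > 0) & (p > 0)
    return float(np.sum(p[mask] * ratio[mask] * np.log2(ratio[mask])))


def identify_place_cells(
    ratemaps: Ratemap, occupancy: np.ndarray, criteria: CellCriteria | None = None
) -> list[int]:
    """Hidden units passing the mean-rate and spatial-information criteria."""
    criteria = criteria or CellCriteria()
    occ = np.asarray(occupancy, float)
    picked = []
    for c in range(ratemaps.n_cells):
        cmap = ratemaps.rates[:, :, c]
        mean_rate = float(np.sum(occ * cmap))
        if mean_rate <= criteria.min_rate:
            continue
        if spatial_information(cmap, occ) > criteria.min_sic:
            picked.append(c)
    return picked


# ---------------------------------------------------------------------------
# Recall protocol
# ---------------------------------------------------------------------------


@dataclass
class RecallTrace:
    """Recorded states and decoded positions during a sensory-cue query."""

    states: np.ndarray                    # (Tq+1, D)
    decoded: dict                         # population -> (Tq, 2) positions
    distances: dict                       # population -> (Tq,) cm to target
    target_position: np.ndarray | None


def recall_query(
    params: RNNParams,
    world,
    smc_pattern: np.ndarray,
    Tq: int = 100,
    target_position=None,
    hpc_map: Ratemap | None = None,
    criteria: CellCriteria | None = None,
) -> RecallTrace:
    """Clamp a sensory pattern on the SMC inputs of a zero-initialized
    network for ``Tq`` steps and decode the population states per step.

    GC and SMC activity is decoded on the ground-truth ratemaps; hidden
    activity on ``hpc_map`` when provided.
    """
    layout = params.layout
    if not layout.sizes["SMC"]:
        raise ValueError("network has no SMC population to query")
    U = np.zeros((1, Tq, layout.dim))
    U[0, :, layout.slc("SMC")] = np.asarray(smc_pattern, float)[None, :]
    z0 = np.zeros((1, layout.dim))
    Z, _ = rollout_batch(params, z0, U)
    states = Z[0]
    decoded, distances = {}, {}
    dictionaries = {"SMC": world.smc_map, "GC": world.gc_map}
    if hpc_map is not None:
        dictionaries["HPC"] = hpc_map
    for name, rmap in dictionaries.items():
        if rmap is None:
            continue
        pop = "HIDDEN" if name == "HPC" else name
        act = states[1:, layout.slc(pop)]
        pos = decode_position(act, rmap)
        decoded[name] = pos
        if target_position is not None:
            distances[name] = np.linalg.norm(
                pos - np.asarray(target_position, float)[None, :], axis=1
            )
    return RecallTrace(states, decoded, distances,
                       None if target_position is None else np.asarray(target_position))


# ---------------------------------------------------------------------------
# Grid metrics and field geometry
# ---------------------------------------------------------------------------


def _pearson_autocorrelogram(m: np.ndarray, min_overlap: int = 20) -> np.ndarray:
    """Per-lag Pearson autocorrelation of a 2-D map (NaN where overlap is
    too small); value 1 at zero lag."""
    m = np.asarray(m, float)
    nx, ny = m.shape
    out = np.full((2 * nx - 1, 2 * ny - 1), np.nan)
    for dx in range(-nx + 1, nx):
        for dy in range(-ny + 1, ny):
            a = m[max(dx, 0): nx + min(dx, 0), max(dy, 0): ny + min(dy, 0)]
            b = m[max(-dx, 0): nx + min(-dx, 0), max(-dy, 0): ny + min(-dy, 0)]
            if a.size < min_overlap:
                continue
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            out[dx + nx - 1, dy + ny - 1] = np.mean(
                (a - a.mean()) * (b - b.mean())
            ) / (sa * sb)
    return out


def grid_metrics(cell_map: np.ndarray, bin_size: float = 1.0) -> dict:
    """Spatial autocorrelogram and the 60-degree-rotation grid score.

    The score contrasts the autocorrelogram's correlation with itself
    rotated by 60/120 degrees against rotations by 30/90/150 degrees,
    evaluated on an annulus around the central peak.  A constant map gets
    ``score = nan`` (undefined).
    """
    m = np.asarray(cell_map, float)
    if m.std() == 0:
        return {"autocorrelogram": None, "grid_score": float("nan")}
    ac = _pearson_autocorrelogram(m)
    acf = np.nan_to_num(ac, nan=0.0)
    cx, cy = (np.array(acf.shape) - 1) // 2
    yy, xx = np.meshgrid(np.arange(acf.shape[1]) - cy, np.arange(acf.shape[0]) - cx)
    r = np.hypot(xx, yy)
    # inner radius: just beyond the central peak (first sub-0.3 crossing)
    radial = [acf[cx + k, cy] for k in range(min(cx, cy))]
    inner = next((k for k, v in enumerate(radial) if v < 0.3), max(2, cx // 8))
    outer = min(cx, cy) * 0.9
    annulus = (r >= inner) & (r <= outer)
    base = acf[annulus]
    if base.std() == 0:
        return {"autocorrelogram": ac, "grid_score": float("nan")}

    def corr_at(angle: float) -> float:
        rot = ndimage.rotate(acf, angle, reshape=False, order=1, mode="constant")
        v = rot[annulus]
        if v.std() == 0:
            return 0.0
        return float(np.corrcoef(base, v)[0, 1])

    on_peak = max(corr_at(60), corr_at(120))
    off_peak = max(corr_at(30), corr_at(90), corr_at(150))
    return {"autocorrelogram": ac, "grid_score": on_peak - off_peak}


def _gaussian2d(coords, amp, x0, y0, sx, sy, base):
    x, y = coords
    return (
        amp * np.exp(-((x - x0) ** 2 / (2 * sx**2) + (y - y0) ** 2 / (2 * sy**2)))
        + base
    ).ravel()


def detect_field_centers(
    cell_map: np.ndarray,
    arena: Arena,
    sigma: float,
    rel_threshold: float = 0.5,
    refine: bool = True,
) -> np.ndarray:
    """Firing-field centers (cm) of one cell's ratemap.

    Local maxima above ``rel_threshold`` of the map peak with a minimum
    separation of two field standard deviations; centers are refined by a
    local 2-D Gaussian fit when ``refine`` is set.  Returns (n_fields, 2).
    """
    m = np.asarray(cell_map, float)
    size = max(3, int(round(2 * sigma / arena.bin_size)))
    local_max = ndimage.maximum_filter(m, size=size, mode="nearest") == m
    peaks = np.argwhere(local_max & (m > rel_threshold * m.max()))
    if len(peaks) == 0:
        return np.empty((0, 2))
    centers = []
    w = max(2, int(round(2 * sigma / arena.bin_size)))
    for px, py in peaks:
        cx = (px + 0.5) * arena.bin_size
        cy = (py + 0.5) * arena.bin_size
        if refine:
            x0, x1 = max(px - w, 0), min(px + w + 1, m.shape[0])
            y0, y1 = max(py - w, 0), min(py + w + 1, m.shape[1])
            patch = m[x0:x1, y0:y1]
            xs = (np.arange(x0, x1) + 0.5) * arena.bin_size
            ys = (np.arange(y0, y1) + 0.5) * arena.bin_size
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            try:
                popt, _ = optimize.curve_fit(
                    _gaussian2d, (gx, gy), patch.ravel(),
                    p0=(patch.max(), cx, cy, sigma, sigma, 0.0),
                    maxfev=2000,
                )
                if abs(popt[1] - cx) < 2 * sigma and abs(popt[2] - cy) < 2 * sigma:
                    cx, cy = popt[1], popt[2]
            except RuntimeError:
                pass
        centers.append((cx, cy))
    return np.asarray(centers)


def measure_grid_geometry(
    cell_map: np.ndarray, arena: Arena, sigma_guess: float
) -> dict:
    """Measure grid spacing and field size from a single-cell ratemap.

    Spacing is the median nearest-neighbour distance between detected
    field centers; field size is the diameter at two standard deviations
    (4 sigma) of a per-field Gaussian fit, averaged over fields fully
    inside the arena.  Returns spacing, field diameter and their ratio.
    """
    m = np.asarray(cell_map, float)
    centers = detect_field_centers(m, arena, sigma_guess)
    if len(centers) < 2:
        raise ValueError("fewer than two firing fields detected")
    diff = centers[:, None, :] - centers[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    np.fill_diagonal(dist, np.inf)
    spacing = float(np.median(dist.min(axis=1)))

    w = max(2, int(round(2.5 * sigma_guess / arena.bin_size)))
    sigmas = []
    for cx, cy in centers:
        margin = 3 * sigma_guess
        if not (margin <= cx <= arena.width - margin
                and margin <= cy <= arena.height - margin):
            continue
        px, py = int(cx / arena.bin_size), int(cy / arena.bin_size)
        x0, x1 = max(px - w, 0), min(px + w + 1, m.shape[0])
        y0, y1 = max(py - w, 0), min(py + w + 1, m.shape[1])
        patch = m[x0:x1, y0:y1]
        xs = (np.arange(x0, x1) + 0.5) * arena.bin_size
        ys = (np.arange(y0, y1) + 0.5) * arena.bin_size
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        try:
            popt, _ = optimize.curve_fit(
                _gaussian2d, (gx, gy), patch.ravel(),
                p0=(patch.max(), cx, cy, sigma_guess, sigma_guess, 0.0),
                maxfev=2000,
            )
            sigmas.append(math.sqrt(abs(popt[3] * popt[4])))
        except RuntimeError:
            continue
    if not sigmas:
        raise ValueError("no field could be fitted")
    field_diameter = 4.0 * float(np.mean(sigmas))
    return {
        "centers": centers,
        "spacing": spacing,
        "field_diameter": field_diameter,
        "ratio": spacing / field_diameter,
    }


# ---------------------------------------------------------------------------
# PCA recall visualization
# ---------------------------------------------------------------------------


def project_recall_pca(ratemap: Ratemap, trace_states: np.ndarray,
                       layout: PopulationLayout | None = None,
                       population: str | None = None) -> dict:
    """Project a subpopulation ratemap and a recall trace to 3 PCs.

    The principal axes are fitted on the flattened (nx*ny, N) ratemap;
    the same linear map projects the per-step states.  Returns the map
    coordinates, trace coordinates, and explained variance ratio.
    """
    if ratemap.n_cells < 3:
        raise ValueError("PCA projection needs at least 3 cells")
    X = ratemap.flattened()
    pca = PCA(n_components=3)
    map_coords = pca.fit_transform(X)
    states = np.asarray(trace_states, float)
    if layout is not None and population is not None:
        states = states[..., layout.slc(population)]
    trace_coords = pca.transform(np.atleast_2d(states))
    return {
        "map_coords": map_coords,
        "trace_coords": trace_coords,
        "explained_variance_ratio": pca.explained_variance_ratio_,
        "pca": pca,
    }
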