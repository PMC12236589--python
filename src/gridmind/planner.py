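"""Analytic planning on the grid-cell phase manifold.

A grid module's population state is summarized by a phase variable on an
n-torus (n = 1 or 2).  Displacements are decoded per module by wrapping the
phase difference into (-pi, pi] along each lattice axis and mapping back to
physical space through the lattice basis; across a geometric hierarchy of
modules, simply averaging the per-module decoded displacements contracts
toward the target whenever enough scales are decodable.  A discretized
transition matrix over phase bins additionally supports sequential
("Markov") planning that stitches local transitions into a path.

Conventions
-----------
* The wrap interval is half-open at +pi: the antipodal tie resolves to the
  positive lattice direction.
* 2-D phases live on the module's two lattice axes (60 degrees apart); each
  axis wraps independently, then the lattice basis maps the wrapped phase
  to a Cartesian displacement.
* The sufficient condition for multi-scale contraction with scale factor s
  and k undercovered modules is m > k + (1 - s**-k)/(s - 1); for s = e in
  1-D this reduces to m > k, and for s = sqrt(e) in 2-D to m > k + 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .maps import GridModuleSpec, PhaseHierarchy

__all__ = [
    "ModulePhase",
    "PhaseDifference",
    "TransitionModel",
    "PlanResult",
    "NavigationResult",
    "wrap_phase",
    "phase_of_position",
    "decode_module_displacement",
    "combine_multiscale",
    "contraction_margin",
    "modules_from_hierarchy",
    "build_transition_matrix",
    "plan_phase_path",
    "vector_navigate",
]


@dataclass(frozen=True)
class ModulePhase:
    """Phase of one grid module: n-vector of radians in [0, 2pi)."""

    phi: np.ndarray
    module_index: int = 0

    def __post_init__(self) -> None:
        phi = np.mod(np.atleast_1d(np.asarray(self.phi, float)), 2 * np.pi)
        object.__setattr__(self, "phi", phi)


@dataclass(frozen=True)
class PhaseDifference:
    """Wrapped phase difference, each component in (-pi, pi]."""

    dphi: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_1d(np.asarray(self.dphi, float))
        if np.any(d <= -np.pi) or np.any(d > np.pi):
            raise ValueError("dphi components must lie in (-pi, pi]")
        object.__setattr__(self, "dphi", d)


def wrap_phase(dphi: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]; the tie at +-pi resolves to +pi."""
    d = np.asarray(dphi, float)
    return np.pi - np.mod(np.pi - d, 2 * np.pi)


def _basis_of(module) -> np.ndarray:
    if isinstance(module, GridModuleSpec):
        return module.lattice_basis
    b = np.atleast_2d(np.asarray(module, float))
    return b


def phase_of_position(pos, module) -> ModulePhase:
    """Map a physical position to the module's torus phase.

    phi = 2*pi * frac(B^-1 @ pos) with B the lattice basis; accepts a
    ``GridModuleSpec`` or an explicit basis matrix (shape (n, n), n = 1, 2).
    """
    basis = _basis_of(module)
    if abs(np.linalg.det(basis)) < 1e-12:
        raise ValueError("lattice basis is singular")
    p = np.atleast_1d(np.asarray(pos, float))
    frac = np.linalg.solve(basis, p) % 1.0
    return ModulePhase(2 * np.pi * frac)


def decode_module_displacement(phi_c, phi_t, module) -> np.ndarray:
    """Shortest-on-torus displacement (cm) from current to target phase.

    Selects the wrapped phase difference in (-pi, pi]^n minimizing the
    per-axis magnitude, then maps it through the lattice basis; each
    component is bounded by half the module period along its lattice axis.
    """
    pc = phi_c.phi if isinstance(phi_c, ModulePhase) else np.atleast_1d(np.asarray(phi_c, float))
    pt = phi_t.phi if isinstance(phi_t, ModulePhase) else np.atleast_1d(np.asarray(phi_t, float))
    dphi = wrap_phase(pt - pc)
    basis = _basis_of(module)
    return basis @ (dphi / (2 * np.pi))


def modules_from_hierarchy(
    h: PhaseHierarchy, dims: int = 2, orientation: float = 0.0
) -> list:
    """Per-module lattice bases for planning (no ratemaps needed).

    For 2-D returns ``GridModuleSpec`` objects; for 1-D returns (1, 1)
    basis matrices [[l_i]].
    """
    if dims == 2:
        return [GridModuleSpec(p, orientation) for p in h.periods]
    if dims == 1:
        return [np.array([[p]]) for p in h.periods]
    raise ValueError("dims must be 1 or 2")


def combine_multiscale(phis_c, phis_t, modules) -> np.ndarray:
    """Average the per-module decoded displacements across scales.

    ``modules`` is the list returned by :func:`modules_from_hierarchy` (or
    any list of module specs/bases ordered by period).  Equivalent to
    d_hat = l0/(2*pi*m) * sum_i s**i * dphi_i along each lattice axis.
    """
    if len(phis_c) != len(phis_t) or len(phis_c) != len(modules):
        raise ValueError("one phase pair per module is required")
    d = [
        decode_module_displacement(pc, pt, mod)
        for pc, pt, mod in zip(phis_c, phis_t, modules)
    ]
    return np.mean(d, axis=0)


def contraction_margin(s: float, k: int, worst_case: bool = False) -> float:
    """Undercoverage penalty of the multi-scale averaged decoder.

    With k undercovered scales out of m, the averaged displacement reduces
    the remaining distance whenever m > k + margin.  The default margin,
    (1 - s**-k)/(s - 1), is the commonly quoted bound (< 1 for s = e, so
    m > k in 1-D; slightly above 1 for s = sqrt(e), so m > k + 1 in 2-D).
    ``worst_case=True`` returns the stricter bound
    (1 - s**-k)/(1 - s**-1), under which contraction holds for every
    displacement in the band, including the adversarial wrap alignments
    that trap the default bound's boundary case (see docs/methods.md).
    """
    if s <= 1:
        raise ValueError("scale factor must exceed 1")
    if k < 0:
        raise ValueError("k must be non-negative")
    num = 1.0 - s ** (-k)
    return num / (1.0 - 1.0 / s) if worst_case else num / (s - 1.0)


# ---------------------------------------------------------------------------
# Markov sequential planning on discretized phase space
# ---------------------------------------------------------------------------


@dataclass
class TransitionModel:
    """Row-stochastic transition matrix over a toroidal phase binning.

    States are ``n_bins**dims`` flattened bins; 1-D uses ring (self + 2
    neighbours) adjacency and 2-D the 8-neighbour torus adjacency.
    """

    n_bins: int
    dims: int
    T: np.ndarray

    def __post_init__(self) -> None:
        n = self.n_bins**self.dims
        self.T = np.asarray(self.T, float)
        if self.T.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        if np.any(self.T < 0) or np.any(np.abs(self.T.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("T must be row-stochastic")

    @property
    def n_states(self) -> int:
        return self.n_bins**self.dims

    def unravel(self, state: int) -> tuple[int, ...]:
        return tuple(int(v) for v in np.unravel_index(state, (self.n_bins,) * self.dims))

    def ravel(self, coords) -> int:
        coords = tuple(int(c) % self.n_bins for c in coords)
        return int(np.ravel_multi_index(coords, (self.n_bins,) * self.dims))

    def neighbors(self, state: int) -> list[int]:
        """Torus-adjacent states, positive directions first (tie-break order)."""
        coords = self.unravel(state)
        if self.dims == 1:
            offs = [(1,), (-1,)]
        else:
            offs = [
                (1, 0), (0, 1), (1, 1), (1, -1),
                (-1, 0), (0, -1), (-1, 1), (-1, -1),
            ]
        return [self.ravel(tuple(c + o for c, o in zip(coords, off))) for off in offs]

    def phase_to_state(self, phi: np.ndarray) -> int:
        phi = np.atleast_1d(np.asarray(phi, float)) % (2 * np.pi)
        coords = np.floor(phi / (2 * np.pi / self.n_bins)).astype(int)
        coords = np.clip(coords, 0, self.n_bins - 1)
        return self.ravel(tuple(coords))


def _ideal_transition(n_bins: int, dims: int) -> np.ndarray:
    n = n_bins**dims
    T = np.zeros((n, n))
    model = TransitionModel.__new__(TransitionModel)
    model.n_bins, model.dims = n_bins, dims
    for i in range(n):
        support = [i] + model.neighbors(i)
        support = sorted(set(support))
        T[i, support] = 1.0 / len(support)
    return T


def build_transition_matrix(
    n_bins: int, dims: int = 1, phase_sequences=None
) -> TransitionModel:
    """Build a phase-bin transition matrix.

    Without ``phase_sequences`` the ideal local topology is used: uniform
    over self plus torus neighbours.  With sequences (each an array of
    phases, shape (T,) in 1-D or (T, 2) in 2-D, radians), transitions are
    counted empirically with add-one smoothing over the torus-adjacent
    support, then row-normalized.
    """
    if n_bins < 3:
        raise ValueError("n_bins must be >= 3")
    if phase_sequences is None:
        return TransitionModel(n_bins, dims, _ideal_transition(n_bins, dims))
    seqs = list(phase_sequences)
    if not seqs:
        raise ValueError("phase_sequences must be non-empty")
    n = n_bins**dims
    counts = np.zeros((n, n))
    model = TransitionModel.__new__(TransitionModel)
    model.n_bins, model.dims = n_bins, dims
    for seq in seqs:
        seq = np.atleast_2d(np.asarray(seq, float).reshape(len(seq), -1))
        states = [model.phase_to_state(s) for s in seq]
        for a, b in zip(states[:-1], states[1:]):
            counts[a, b] += 1.0
    for i in range(n):
        support = sorted(set([i] + model.neighbors(i)))
        counts[i, support] += 1.0  # add-one smoothing on the local topology
    T = counts / counts.sum(axis=1, keepdims=True)
    return TransitionModel(n_bins, dims, T)


@dataclass
class PlanResult:
    path: list[int]
    converged: bool
    v_plan: np.ndarray


def plan_phase_path(
    model: TransitionModel,
    start_bin: int,
    target_bin: int,
    max_iters: int = 2000,
    tie_rtol: float = 1e-9,
    burn_in: int | None = None,
    source_boost: float = 1.0,
) -> PlanResult:
    """Sequential planning by diffusing a plan vector through T.

    v_plan starts with equal mass on the start and target bins.  Each
    iteration applies v <- normalize(T @ v) with the target bin re-clamped
    above the running maximum (``(1 + source_boost) * max(v)``), then
    advances the path to the torus neighbour of the current bin carrying
    the highest value.  The boost keeps the target a persistent source:
    the transition matrix is doubly stochastic, so renormalized diffusion
    alone flattens to the uniform vector and a clamp *at* the maximum
    stops feeding the field.
    Already-visited neighbours are not revisited.  When the best eligible
    neighbours tie (the target's influence has not yet diffused this far,
    or the configuration is genuinely symmetric, e.g. an antipodal
    target), the walker waits for more diffusion; a tie persisting for a
    full mixing period resolves to the first neighbour in
    positive-direction order.

    ``burn_in`` diffusion iterations (default: 5 * n_states) are applied
    before the first move so the clamped target acts as a settled source;
    the transient start blob otherwise locally masks the target's
    gradient.
    """
    n = model.n_states
    if not (0 <= start_bin < n and 0 <= target_bin < n):
        raise ValueError("bin index out of range")
    path = [start_bin]
    if start_bin == target_bin:
        return PlanResult(path, True, np.eye(n)[start_bin])
    v = np.zeros(n)
    v[start_bin] += 0.5
    v[target_bin] += 0.5
    visited = {start_bin}
    current = start_bin
    Tt = model.T.T
    if burn_in is None:
        burn_in = 5 * n
    for _ in range(burn_in):
        v = Tt @ v
        v[target_bin] = (1.0 + source_boost) * v.max()
        v = v / v.sum()
    stall = 0
    stall_limit = n
    for _ in range(max_iters):
        v = Tt @ v
        v[target_bin] = (1.0 + source_boost) * v.max()
        v = v / v.sum()
        eligible = [
            nb for nb in model.neighbors(current)
            if nb == target_bin or nb not in visited
        ]
        if not eligible:
            break
        vals = np.array([v[nb] for nb in eligible])
        order = np.argsort(vals)[::-1]
        best_val = vals[order[0]]
        tied = len(eligible) > 1 and (
            best_val - vals[order[1]] <= tie_rtol * max(best_val, 1e-300)
        )
        if best_val <= 0.0 or (tied and stall < stall_limit):
            stall += 1
            continue
        # strict winner, or a persistent (symmetric) tie broken by
        # positive-direction neighbour order
        best = eligible[int(np.argmax(vals > best_val - tie_rtol * best_val))]
        current = best
        path.append(current)
        visited.add(current)
        stall = 0
        if current == target_bin:
            return PlanResult(path, True, v)
    return PlanResult(path, False, v)


# ---------------------------------------------------------------------------
# Greedy multi-scale vector navigation
# ---------------------------------------------------------------------------


@dataclass
class NavigationResult:
    positions: np.ndarray
    converged: bool
    final_step_norm: float


def vector_navigate(
    start_pos,
    target_phases,
    modules,
    step_fraction: float = 0.5,
    tol: float = 1.0,
    max_steps: int = 200,
) -> NavigationResult:
    """Iteratively follow the averaged multi-scale decoded displacement.

    From the current position the phases of all modules are computed, the
    displacement toward the target phases is decoded and averaged across
    scales, and the position advances by ``step_fraction`` times the
    estimate.  Stops when the decoded displacement estimate falls below
    ``tol`` (cm) — once all modules are decodable the estimate equals the
    true remaining displacement — or after ``max_steps``.
    """
    if not (0 < step_fraction <= 1):
        raise ValueError("step_fraction must lie in (0, 1]")
    pos = np.atleast_1d(np.asarray(start_pos, float))
    out = [pos.copy()]
    converged = False
    step_norm = np.inf
    for _ in range(max_steps):
        phis_c = [phase_of_position(pos, mod) for mod in modules]
        d_hat = combine_multiscale(phis_c, target_phases, modules)
        step_norm = float(np.linalg.norm(d_hat))
        if step_norm < tol:
            converged = True
            break
        pos = pos + step_fraction * d_hat
        out.append(pos.copy())
    return NavigationResult(np.array(out), converged, step_norm)
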