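"""Trainable models of the hippocampal-entorhinal loop.

Three model classes follow a construct-then-fit pattern: build the model
from a simulated :class:`World` (arena, tuning maps, motion statistics),
call :meth:`fit`, and receive a Results object carrying the trained
parameters, the loss history, and evaluation helpers.

* :class:`PathIntegratorModel` — grid, speed and head-direction cells
  only; the network receives the grid pattern at t = 0 and must path-
  integrate noisy self-motion input thereafter.
* :class:`HCMECModel` — adds spatially modulated cells (SMCs) supervised
  to autoencode masked, noisy sensory patterns, and an unsupervised hidden
  population in which place-cell-like units emerge.
* :class:`PlannerModel` — bolts a planner subnetwork onto a pre-trained
  (and frozen) network; the planner sees the goal grid pattern through a
  learned projection plus the current grid state, and acts only by driving
  the speed/direction input coordinates.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .env import (
    Arena,
    MotionParams,
    SelfMotionSpec,
    encode_self_motion,
    generate_trajectory_batch,
)
from .maps import (
    GridModuleSpec,
    MaskConfig,
    PhaseHierarchy,
    Ratemap,
    SMCSpec,
    apply_mask,
    make_grid_modules,
    make_smc_map,
    sample_at_positions,
)
from .network import (
    Adam,
    PopulationLayout,
    RNNParams,
    bptt_gradients,
    rollout_batch,
)

__all__ = [
    "World",
    "TrainConfig",
    "PlannerConfig",
    "FitResults",
    "PathIntegratorModel",
    "PathIntegratorResults",
    "HCMECModel",
    "HCMECResults",
    "PlannerModel",
    "PlannerResults",
    "path_integration_loss",
    "smc_autoencode_loss",
]


# ---------------------------------------------------------------------------
# Study conditions: arena + tuning maps + motion statistics
# ---------------------------------------------------------------------------


@dataclass
class World:
    """The simulated environment a model is built from."""

    arena: Arena
    motion: MotionParams
    selfmotion: SelfMotionSpec
    hierarchy: PhaseHierarchy
    modules: list
    gc_map: Ratemap
    smc_map: Ratemap | None = None

    @classmethod
    def build(
        cls,
        seed: int,
        arena: Arena | None = None,
        n_modules: int = 2,
        cells_per_module: int = 64,
        smc_spec: SMCSpec | None = None,
        motion: MotionParams | None = None,
        selfmotion: SelfMotionSpec | None = None,
        smallest_period: float = 30.0,
        scale_factor: float = math.sqrt(math.e),
    ) -> "World":
        arena = arena or Arena()
        motion = motion or MotionParams()
        selfmotion = selfmotion or SelfMotionSpec()
        hierarchy = PhaseHierarchy.from_smallest_period(
            smallest_period, scale_factor, n_modules
        )
        pairs = make_grid_modules(hierarchy, cells_per_module, arena, seed)
        modules = [m for m, _ in pairs]
        gc_rates = np.concatenate([r.rates for _, r in pairs], axis=2)
        gc_map = Ratemap(gc_rates, arena, "GC")
        smc_map = (
            make_smc_map(smc_spec, arena, seed + 1) if smc_spec is not None else None
        )
        return cls(arena, motion, selfmotion, hierarchy, modules, gc_map, smc_map)

    @property
    def n_gc(self) -> int:
        return self.gc_map.n_cells

    @property
    def n_smc(self) -> int:
        return 0 if self.smc_map is None else self.smc_map.n_cells

    @property
    def sigma1(self) -> float:
        """Field standard deviation of the smallest module (cm)."""
        return self.modules[0].field_sigma

    def gc_pattern(self, positions: np.ndarray) -> np.ndarray:
        return sample_at_positions(self.gc_map, positions)

    def smc_pattern(self, positions: np.ndarray) -> np.ndarray:
        if self.smc_map is None:
            raise ValueError("world has no SMC map")
        return sample_at_positions(self.smc_map, positions)


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule and masking protocol for one training run."""

    variant: str = "GC_ONLY"
    r_mask: float = 0.0
    traj_duration: float = 5.0
    batch_size: int = 16
    n_steps: int = 1500
    learning_rate: float = 1e-3
    seed: int = 0
    noise_sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.variant not in {"GC_ONLY", "HCMEC", "PLANNER_GC", "PLANNER_HCMEC"}:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0.0 <= self.r_mask <= 1.0):
            raise ValueError("r_mask must lie in [0, 1]")
        for name in ("traj_duration", "batch_size", "n_steps", "learning_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class PlannerConfig:
    """Planner subnetwork wiring.

    Projections from SMC and HIDDEN populations into the planner are pinned
    to exactly zero throughout training, so the planner sees only grid
    information; its outputs reach the rest of the network only through
    the speed/direction input coordinates.
    """

    planner_dim: int = 64
    train_horizon: int = 25
    n_pairs: int = 128
    pair_duration: float = 1.0
    planner_alpha0: float = 0.7


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def _states_to_array(states) -> np.ndarray:
    if isinstance(states, np.ndarray):
        return states
    return np.stack([s.z for s in states], axis=-2)


def path_integration_loss(states, gc_truth, layout: PopulationLayout) -> float:
    """MSE between GC output coordinates and ground-truth rates, t >= 1."""
    Z = _states_to_array(states)
    truth = np.asarray(gc_truth, float)
    pred = Z[..., 1:, layout.slc("GC")]
    if pred.shape != truth.shape:
        raise ValueError("states and gc_truth are misaligned")
    return float(np.mean((pred - truth) ** 2))


def smc_autoencode_loss(states, smc_truth, layout: PopulationLayout) -> float:
    """MSE between SMC coordinates and the noiseless, unmasked pattern."""
    Z = _states_to_array(states)
    truth = np.asarray(smc_truth, float)
    pred = Z[..., 1:, layout.slc("SMC")]
    if pred.shape != truth.shape:
        raise ValueError("states and smc_truth are misaligned")
    return float(np.mean((pred - truth) ** 2))


# ---------------------------------------------------------------------------
# Batch construction
# ---------------------------------------------------------------------------


def _make_batch(
    world: World,
    layout: PopulationLayout,
    cfg: TrainConfig,
    rng: np.random.Generator,
    with_smc: bool,
    duration: float | None = None,
):
    """One training batch: injected inputs, initial states, and targets.

    The self-motion encoding at index t describes the step p_t -> p_{t+1},
    so the state after consuming input t corresponds to position t+1;
    supervision targets are therefore the patterns at positions 1..T-1 and
    the rollout takes T-1 update steps.
    """
    duration = duration if duration is not None else cfg.traj_duration
    B = cfg.batch_size
    trajs = generate_trajectory_batch(world.arena, world.motion, duration, B, rng)
    positions = np.stack([t.positions for t in trajs])          # (B, T, 2)
    gc_truth = world.gc_pattern(positions)                      # (B, T, n_gc)
    sm = np.stack([encode_self_motion(t, world.selfmotion) for t in trajs])
    sm_noisy = sm + rng.normal(0, cfg.noise_sigma, sm.shape)

    n_dir = world.selfmotion.n_dir_cells
    mask_cfg = MaskConfig(cfg.r_mask)
    dir_in, _ = apply_mask(sm_noisy[:, :-1, :n_dir], mask_cfg, rng)
    spd_in, _ = apply_mask(sm_noisy[:, :-1, n_dir:], mask_cfg, rng)

    D = layout.dim
    T = positions.shape[1]
    U = np.zeros((B, T - 1, D))
    U[:, :, layout.slc("DIR")] = dir_in
    U[:, :, layout.slc("SPD")] = spd_in

    smc_truth = None
    if with_smc:
        smc_all = world.smc_pattern(positions)
        smc_truth = smc_all[:, 1:]
        smc_noisy = smc_truth + rng.normal(0, cfg.noise_sigma, smc_truth.shape)
        smc_in, _ = apply_mask(smc_noisy, mask_cfg, rng)
        U[:, :, layout.slc("SMC")] = smc_in

    z0 = np.zeros((B, D))
    gc0, _ = apply_mask(gc_truth[:, 0, :], mask_cfg, rng)
    z0[:, layout.slc("GC")] = gc0
    # hidden units start at zero; the initial-state mask is absorbed there
    return U, z0, gc_truth[:, 1:], smc_truth, positions


def _supervision_gradient(
    Z: np.ndarray, layout: PopulationLayout, gc_truth, smc_truth
):
    """dL/dZ for the MSE supervision terms, plus the component losses."""
    B, T1, D = Z.shape
    dLdZ = np.zeros_like(Z)
    gsl = layout.slc("GC")
    diff_gc = Z[:, 1:, gsl] - gc_truth
    loss_gc = float(np.mean(diff_gc**2))
    dLdZ[:, 1:, gsl] = 2.0 * diff_gc / diff_gc.size
    loss_smc = 0.0
    if smc_truth is not None:
        ssl = layout.slc("SMC")
        diff_smc = Z[:, 1:, ssl] - smc_truth
        loss_smc = float(np.mean(diff_smc**2))
        dLdZ[:, 1:, ssl] = 2.0 * diff_smc / diff_smc.size
    return dLdZ, loss_gc, loss_smc


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class FitResults:
    """Trained parameters plus diagnostics from one fit."""

    params: RNNParams
    world: World
    config: TrainConfig
    loss_history: pd.DataFrame
    wall_time: float

    @property
    def layout(self) -> PopulationLayout:
        return self.params.layout

    def final_loss(self, column: str = "loss") -> float:
        return float(self.loss_history[column].iloc[-1])

    def smoothed_loss(self, column: str = "loss", window: int = 100) -> pd.Series:
        return self.loss_history[column].rolling(window, min_periods=1).mean()

    def summary(self) -> str:
        lay = self.layout
        lines = [
            f"{type(self).__name__}",
            "=" * 46,
            f"variant:          {self.config.variant}",
            f"populations:      "
            + ", ".join(f"{k}={v}" for k, v in lay.sizes.items() if v),
            f"trainable params: {self.params.n_trainable()}",
            f"r_mask:           {self.config.r_mask}",
            f"train steps:      {len(self.loss_history)}",
            f"final loss (ma):  {self.smoothed_loss().iloc[-1]:.5f}",
            f"wall time (s):    {self.wall_time:.1f}",
        ]
        return "\n".join(lines)

    # -- shared evaluation -------------------------------------------------

    def _decode_gc(self, gc_activity: np.ndarray) -> np.ndarray:
        from .analysis import decode_position

        return decode_position(gc_activity, self.world.gc_map)

    def evaluate_path_integration(
        self, duration: float = 10.0, n_trials: int = 10, seed: int = 1234,
        noise_sigma: float | None = None,
    ) -> dict:
        """Mean grid-decoded position error (cm) on held-out trajectories.

        The network receives the true grid pattern at t = 0 and noisy,
        unmasked self-motion input thereafter; grid output coordinates are
        decoded by nearest-neighbour search on the ground-truth ratemap.
        """
        world, layout = self.world, self.layout
        ns = self.config.noise_sigma if noise_sigma is None else noise_sigma
        rng = np.random.default_rng(seed)
        cfg = replace(
            self.config, batch_size=n_trials, r_mask=0.0, noise_sigma=ns
        )
        U, z0, gc_truth, _, positions = _make_batch(
            world, layout, cfg, rng, with_smc=layout.sizes["SMC"] > 0,
            duration=duration,
        )
        z0[:, layout.slc("GC")] = world.gc_pattern(positions[:, 0])
        Z, _ = rollout_batch(self.params, z0, U)
        gc_out = Z[:, 1:, layout.slc("GC")]
        B, T, _ = gc_out.shape
        decoded = self._decode_gc(gc_out.reshape(B * T, -1)).reshape(B, T, 2)
        err = np.linalg.norm(decoded - positions[:, 1:], axis=2)
        return {
            "mean_error": float(err.mean()),
            "median_error": float(np.median(err)),
            "final_error": float(err[:, -1].mean()),
            "errors": err,
        }


@dataclass
class PathIntegratorResults(FitResults):
    pass


@dataclass
class HCMECResults(FitResults):
    def recall(self, target_position, Tq: int = 100):
        """Query the trained network with the target's sensory pattern."""
        from .analysis import recall_query

        pattern = self.world.smc_pattern(np.asarray(target_position, float))
        return recall_query(
            self.params, self.world, pattern, Tq=Tq,
            target_position=np.asarray(target_position, float),
        )


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


class _RecurrentModelBase:
    """Shared fit loop for supervised recurrent models."""

    def __init__(self, world: World, layout: PopulationLayout, weight_scale=None,
                 nonlinearity: str = "relu", alpha0: float = 0.9):
        self.world = world
        self.layout = layout
        self.weight_scale = weight_scale
        self.nonlinearity = nonlinearity
        self.alpha0 = alpha0

    #: staged curriculum: (duration fraction, step fraction, learning-rate
    #: multiplier, masking-ratio fraction).  Long-horizon credit assignment
    #: from scratch stalls, and heavy masking blocks the grid association
    #: before it exists; learning the transition operator and the
    #: sensory-grid association on short, unmasked rollouts first, then
    #: lengthening and ramping the mask to its target, converges an order
    #: of magnitude faster.
    CURRICULUM = (
        (0.2, 0.35, 1.0, 0.0),
        (0.5, 0.25, 0.5, 0.5),
        (1.0, 0.40, 0.25, 1.0),
    )

    def _fit_supervised(self, cfg: TrainConfig, with_smc: bool, results_cls):
        t0 = time.time()
        rng = np.random.default_rng(cfg.seed)
        params = RNNParams.init(
            self.layout, cfg.seed, self.weight_scale,
            alpha0=self.alpha0, nonlinearity=self.nonlinearity,
            dtype=np.float32,
        )
        opt = Adam([params.W.shape, params.alpha_raw.shape], lr=cfg.learning_rate)
        records = []
        dt = self.world.motion.dt
        step = 0
        for dur_frac, step_frac, lr_mult, mask_frac in self.CURRICULUM:
            duration = max(2 * dt, dur_frac * cfg.traj_duration)
            n_stage = max(1, int(round(step_frac * cfg.n_steps)))
            opt.lr = cfg.learning_rate * lr_mult
            stage_cfg = replace(cfg, r_mask=cfg.r_mask * mask_frac)
            for _ in range(n_stage):
                U, z0, gc_truth, smc_truth, _ = _make_batch(
                    self.world, self.layout, stage_cfg, rng, with_smc,
                    duration=duration,
                )
                Z, F = rollout_batch(params, z0, U)
                dLdZ, loss_gc, loss_smc = _supervision_gradient(
                    Z, self.layout, gc_truth, smc_truth
                )
                dW, dar, _ = bptt_gradients(params, Z, F, U, dLdZ)
                opt.step([params.W, params.alpha_raw], [dW, dar])
                total = loss_gc + loss_smc
                if not np.isfinite(total):
                    raise FloatingPointError(
                        f"training diverged at step {step} (loss={total})"
                    )
                records.append(
                    {"step": step, "duration": duration, "loss": total,
                     "loss_gc": loss_gc, "loss_smc": loss_smc}
                )
                step += 1
        history = pd.DataFrame(records)
        return results_cls(
            params=params, world=self.world, config=cfg,
            loss_history=history, wall_time=time.time() - t0,
        )


class PathIntegratorModel(_RecurrentModelBase):
    """Grid + speed + head-direction network trained to path-integrate.

    Besides the supervised grid output nodes and the self-motion input
    nodes, the state keeps a pool of plain hidden units; the
    velocity-conditioned update of the grid pattern is nonlinear and the
    conjunctive mixing that implements it forms there.
    """

    def __init__(self, world: World, n_hidden: int = 128, weight_scale=None,
                 nonlinearity="relu", alpha0: float = 0.9):
        layout = PopulationLayout.from_sizes(
            gc=world.n_gc,
            spd=world.selfmotion.n_speed_cells,
            dir=world.selfmotion.n_dir_cells,
            hidden=n_hidden,
        )
        super().__init__(world, layout, weight_scale, nonlinearity, alpha0)

    @classmethod
    def from_world(cls, world: World, **kw) -> "PathIntegratorModel":
        return cls(world, **kw)

    def fit(self, cfg: TrainConfig | None = None, **kw) -> PathIntegratorResults:
        cfg = cfg or TrainConfig(variant="GC_ONLY", **kw)
        if cfg.variant != "GC_ONLY":
            raise ValueError("PathIntegratorModel requires variant GC_ONLY")
        return self._fit_supervised(cfg, with_smc=False,
                                    results_cls=PathIntegratorResults)


class HCMECModel(_RecurrentModelBase):
    """Full loop: grid cells, SMCs, self-motion inputs and hidden units.

    The curriculum keeps final rollouts at half the configured duration
    and spends most steps in the fully-masked stage: the autoassociation
    this model exists for is learned under masking, while the trajectory
    horizon matters less than for the pure path integrator.
    """

    CURRICULUM = (
        (0.2, 0.2, 1.0, 0.0),
        (0.4, 0.2, 0.5, 0.5),
        (0.5, 0.6, 0.25, 1.0),
    )

    def __init__(self, world: World, n_hidden: int = 256, weight_scale=None,
                 nonlinearity="relu", alpha0: float = 0.9):
        if world.smc_map is None:
            raise ValueError("HCMECModel needs a world with an SMC map")
        layout = PopulationLayout.from_sizes(
            gc=world.n_gc,
            smc=world.n_smc,
            spd=world.selfmotion.n_speed_cells,
            dir=world.selfmotion.n_dir_cells,
            hidden=n_hidden,
        )
        super().__init__(world, layout, weight_scale, nonlinearity, alpha0)

    def fit(self, cfg: TrainConfig | None = None, **kw) -> HCMECResults:
        cfg = cfg or TrainConfig(variant="HCMEC", **kw)
        if cfg.variant != "HCMEC":
            raise ValueError("HCMECModel requires variant HCMEC")
        return self._fit_supervised(cfg, with_smc=True, results_cls=HCMECResults)


# ---------------------------------------------------------------------------
# Planner
# ---------------------------------------------------------------------------


@dataclass
class PlannerResults(FitResults):
    W_in: np.ndarray = None
    pcfg: PlannerConfig = None

    def plan(self, start_position, target_position, n_steps: int = 200):
        """Run the planner between two locations; decode the grid path.

        Returns a dict with the decoded position sequence, the terminal
        decoded distance to the target (cm), and (for the full-loop
        variant) the SMC-decoded positions.
        """
        from .analysis import decode_position

        world, layout = self.world, self.layout
        start = np.asarray(start_position, float)
        target = np.asarray(target_position, float)
        g_star = world.gc_pattern(target)
        z0 = np.zeros((1, layout.dim))
        z0[0, layout.slc("GC")] = world.gc_pattern(start)
        with_smc = layout.sizes["SMC"] > 0
        if with_smc:
            z0[0, layout.slc("SMC")] = world.smc_pattern(start)
        U = np.zeros((1, n_steps, layout.dim))
        U[:, :, layout.slc("PLANNER")] = g_star @ self.W_in.T
        Z, _ = rollout_batch(self.params, z0, U)
        gc_path = Z[0, 1:, layout.slc("GC")]
        decoded = decode_position(gc_path, world.gc_map)
        out = {
            "positions": decoded,
            "terminal_distance": float(np.linalg.norm(decoded[-1] - target)),
            "target": target,
            "start": start,
        }
        if with_smc:
            smc_path = Z[0, 1:, layout.slc("SMC")]
            smc_decoded = decode_position(smc_path, world.smc_map)
            out["smc_positions"] = smc_decoded
            out["gc_smc_discrepancy"] = float(
                np.mean(np.linalg.norm(decoded - smc_decoded, axis=1))
            )
        return out

    def evaluate_planning(
        self, pair_duration: float = 10.0, n_pairs: int = 50, seed: int = 99,
        n_steps: int = 200, success_radius: float | None = None,
    ) -> dict:
        """Plan between endpoints of held-out trajectories.

        Success: terminal grid-decoded distance below ``success_radius``
        (default: half the smallest module period).
        """
        world = self.world
        if success_radius is None:
            success_radius = world.modules[0].period / 2.0
        rng = np.random.default_rng(seed)
        trajs = generate_trajectory_batch(
            world.arena, world.motion, pair_duration, n_pairs, rng
        )
        dists, discreps = [], []
        for tr in trajs:
            res = self.plan(tr.positions[0], tr.positions[-1], n_steps=n_steps)
            dists.append(res["terminal_distance"])
            if "gc_smc_discrepancy" in res:
                discreps.append(res["gc_smc_discrepancy"])
        dists = np.asarray(dists)
        out = {
            "terminal_distances": dists,
            "success_rate": float(np.mean(dists < success_radius)),
            "success_radius": success_radius,
        }
        if discreps:
            out["mean_gc_smc_discrepancy"] = float(np.mean(discreps))
        return out


class PlannerModel:
    """Planner subnetwork attached to a frozen pre-trained network.

    The planner's state coordinates receive ``W_in @ g*`` (the goal grid
    pattern through a learned projection) as external input and the
    current grid state through a trainable GC-to-planner block; it drives
    behaviour exclusively through trainable planner-to-SPD/DIR weights.
    All pre-trained weights are frozen; SMC-to-planner and hidden-to-
    planner projections are pinned to zero.
    """

    def __init__(self, pretrained: FitResults, pcfg: PlannerConfig | None = None):
        self.pretrained = pretrained
        self.world = pretrained.world
        self.pcfg = pcfg or PlannerConfig()
        self.base_layout = pretrained.layout
        self.layout = self.base_layout.with_planner(self.pcfg.planner_dim)

    def _build_params(self, seed: int) -> tuple[RNNParams, np.ndarray]:
        rng = np.random.default_rng(seed)
        lay, base = self.layout, self.base_layout
        D, dp = lay.dim, self.pcfg.planner_dim
        W = np.zeros((D, D))
        mask = np.zeros((D, D), dtype=bool)
        # copy frozen pre-trained blocks
        old_names = [n for n in ("GC", "SMC", "SPD", "DIR", "HIDDEN") if base.sizes[n]]
        for a in old_names:
            for b in old_names:
                W[lay.slc(a), lay.slc(b)] = self.pretrained.params.W[
                    base.slc(a), base.slc(b)
                ]
        psl = lay.slc("PLANNER")
        scale = 1.0 / np.sqrt(dp)
        # trainable: planner recurrence, GC -> planner, planner -> SPD/DIR
        W[psl, psl] = rng.normal(0, scale, (dp, dp))
        mask[psl, psl] = True
        gsl = lay.slc("GC")
        W[psl, gsl] = rng.normal(0, scale, (dp, lay.sizes["GC"]))
        mask[psl, gsl] = True
        for name in ("SPD", "DIR"):
            if lay.sizes[name]:
                s = lay.slc(name)
                W[s, psl] = rng.normal(0, scale, (lay.sizes[name], dp))
                mask[s, psl] = True
        # SMC/HIDDEN -> planner stay pinned at exactly zero (mask False)
        alpha_raw = np.empty(D)
        for n in old_names:
            alpha_raw[lay.slc(n)] = self.pretrained.params.alpha_raw[base.slc(n)]
        a0 = self.pcfg.planner_alpha0
        alpha_raw[psl] = np.log(a0 / (1 - a0))
        alpha_mask = np.zeros(D)
        alpha_mask[psl] = 1.0
        params = RNNParams(
            lay, W, alpha_raw, self.pretrained.params.nonlinearity,
            trainable_mask=mask, alpha_trainable=alpha_mask,
        )
        W_in = rng.normal(0, scale, (dp, lay.sizes["GC"]))
        return params, W_in

    def _sample_pairs(self, rng: np.random.Generator, n: int, duration: float):
        trajs = generate_trajectory_batch(
            self.world.arena, self.world.motion, duration, n, rng
        )
        starts = np.stack([t.positions[0] for t in trajs])
        targets = np.stack([t.positions[-1] for t in trajs])
        return starts, targets

    def fit(self, cfg: TrainConfig | None = None, **kw) -> PlannerResults:
        cfg = cfg or TrainConfig(variant="PLANNER_GC", **kw)
        if not cfg.variant.startswith("PLANNER"):
            raise ValueError("PlannerModel requires a PLANNER_* variant")
        t0 = time.time()
        lay = self.layout
        with_smc = lay.sizes["SMC"] > 0
        rng = np.random.default_rng(cfg.seed)
        params, W_in = self._build_params(cfg.seed + 1)
        frozen_before = params.W[~params.trainable_mask].copy()
        opt = Adam(
            [params.W.shape, params.alpha_raw.shape, W_in.shape],
            lr=cfg.learning_rate,
        )
        # fixed pool of start/target pairs from short trajectories
        starts, targets = self._sample_pairs(
            rng, self.pcfg.n_pairs, self.pcfg.pair_duration
        )
        T = self.pcfg.train_horizon
        gsl, psl = lay.slc("GC"), lay.slc("PLANNER")
        records = []
        for step in range(cfg.n_steps):
            idx = rng.integers(0, len(starts), size=cfg.batch_size)
            s_pos, t_pos = starts[idx], targets[idx]
            g_star = self.world.gc_pattern(t_pos)                # (B, n_gc)
            z0 = np.zeros((cfg.batch_size, lay.dim))
            z0[:, gsl] = self.world.gc_pattern(s_pos)
            if with_smc:
                z0[:, lay.slc("SMC")] = self.world.smc_pattern(s_pos)
            U = np.zeros((cfg.batch_size, T, lay.dim))
            U[:, :, psl] = (g_star @ W_in.T)[:, None, :]
            Z, F = rollout_batch(params, z0, U)
            diff = Z[:, 1:, gsl] - g_star[:, None, :]
            loss = float(np.mean(diff**2))
            dLdZ = np.zeros_like(Z)
            dLdZ[:, 1:, gsl] = 2.0 * diff / diff.size
            dW, dar, dU = bptt_gradients(params, Z, F, U, dLdZ, need_dU=True)
            dW_in = np.einsum("btp,bg->pg", dU[:, :, psl], g_star)
            opt.step([params.W, params.alpha_raw, W_in], [dW, dar, dW_in])
            if not np.isfinite(loss):
                raise FloatingPointError(f"planner training diverged at {step}")
            records.append({"step": step, "loss": loss})
        # frozen entries (including the zero-pinned projections) untouched
        if not np.array_equal(params.W[~params.trainable_mask], frozen_before):
            raise AssertionError("frozen projection was modified during training")
        return PlannerResults(
            params=params, world=self.world, config=cfg,
            loss_history=pd.DataFrame(records), wall_time=time.time() - t0,
            W_in=W_in, pcfg=self.pcfg,
        )
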