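"""Recurrent network of the hippocampal-entorhinal loop.

A single recurrent state vector is partitioned into named populations —
grid cells (GC), spatially modulated cells (SMC), speed (SPD) and head
direction (DIR) inputs, unsupervised hidden units (the place-cell
candidates), and an optional planner subnetwork.  The update is

    z[t+1] = alpha * z[t] + (1 - alpha) * (inject(u[t]) + W_rec @ f(z[t]))

where ``inject`` writes raw external inputs into the input-node
coordinates with no learned input projection, ``alpha`` is a per-unit
learnable leak kept in [0, 1] through a sigmoid parameterization, and the
full recurrent matrix ``W_rec`` carries every inter-population block
(surrogate input/output mappings included).  Supervision is applied
directly to output-node coordinates; there is no readout matrix.

The module also provides reverse-mode gradients (backprop through time)
and a small Adam optimizer, so models train without any external deep
learning framework.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationLayout",
    "RNNParams",
    "RNNState",
    "Adam",
    "rnn_step",
    "rollout",
    "rollout_batch",
    "bptt_gradients",
]

_POPULATIONS = ("GC", "SMC", "SPD", "DIR", "HIDDEN", "PLANNER")


@dataclass(frozen=True)
class PopulationLayout:
    """Contiguous index ranges of each population within the state vector.

    SPD/DIR are input-only; SMC is both input and output; GC is an output
    that receives external values only through its initial state; HIDDEN is
    neither; PLANNER (optional) receives the projected goal as input.
    """

    sizes: dict

    def __post_init__(self) -> None:
        for k in self.sizes:
            if k not in _POPULATIONS:
                raise ValueError(f"unknown population {k!r}")
        object.__setattr__(
            self, "sizes", {k: int(self.sizes.get(k, 0)) for k in _POPULATIONS}
        )

    @classmethod
    def from_sizes(
        cls, gc: int, smc: int = 0, spd: int = 0, dir: int = 0,
        hidden: int = 0, planner: int = 0,
    ) -> "PopulationLayout":
        return cls(
            {"GC": gc, "SMC": smc, "SPD": spd, "DIR": dir,
             "HIDDEN": hidden, "PLANNER": planner}
        )

    @property
    def dim(self) -> int:
        return sum(self.sizes.values())

    def slc(self, name: str) -> slice:
        start = 0
        for k in _POPULATIONS:
            n = self.sizes[k]
            if k == name:
                return slice(start, start + n)
            start += n
        raise KeyError(name)

    @property
    def input_populations(self) -> tuple[str, ...]:
        pops = ["SMC", "SPD", "DIR"]
        if self.sizes["PLANNER"]:
            pops.append("PLANNER")
        return tuple(p for p in pops if self.sizes[p])

    @property
    def output_populations(self) -> tuple[str, ...]:
        return tuple(p for p in ("GC", "SMC") if self.sizes[p])

    def inject(self, inputs: dict) -> np.ndarray:
        """Place raw external inputs into their coordinates, zeros elsewhere.

        ``inputs`` maps population name -> array (..., size); all arrays
        must share leading shape.
        """
        lead = ()
        for v in inputs.values():
            lead = np.asarray(v).shape[:-1]
            break
        u = np.zeros(lead + (self.dim,))
        for name, v in inputs.items():
            if name not in self.input_populations:
                raise ValueError(f"{name} is not an input population")
            u[..., self.slc(name)] = v
        return u

    def with_planner(self, planner: int) -> "PopulationLayout":
        sizes = dict(self.sizes)
        sizes["PLANNER"] = planner
        return PopulationLayout(sizes)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


_NONLINEARITIES = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z: 1.0 - np.tanh(z) ** 2),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


@dataclass
class RNNParams:
    """Learnable parameters: full recurrent matrix and leak vector.

    ``alpha_raw`` stores the pre-sigmoid leak so alpha stays in [0, 1];
    ``trainable_mask`` (same shape as W) freezes entries where False, and
    frozen-at-zero entries remain bitwise zero through training.
    """

    layout: PopulationLayout
    W: np.ndarray
    alpha_raw: np.ndarray
    nonlinearity: str = "relu"
    trainable_mask: np.ndarray | None = None
    #: True/False, or a per-unit 0/1 mask on the leak gradient
    alpha_trainable: bool | np.ndarray = True

    def __post_init__(self) -> None:
        d = self.layout.dim
        if self.W.shape != (d, d) or self.alpha_raw.shape != (d,):
            raise ValueError("parameter shapes inconsistent with layout")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    @classmethod
    def init(
        cls,
        layout: PopulationLayout,
        seed: int,
        weight_scale: float | None = None,
        alpha0: float = 0.9,
        nonlinearity: str = "relu",
        dtype=np.float64,
    ) -> "RNNParams":
        """Random initialization: no block structure is imposed on W."""
        rng = np.random.default_rng(seed)
        d = layout.dim
        scale = weight_scale if weight_scale is not None else 1.0 / np.sqrt(d)
        W = rng.normal(0.0, scale, size=(d, d)).astype(dtype)
        a = (np.log(alpha0 / (1 - alpha0)) * np.ones(d)).astype(dtype)
        return cls(layout, W, a, nonlinearity)

    @property
    def alpha(self) -> np.ndarray:
        return _sigmoid(self.alpha_raw)

    def f(self, z: np.ndarray) -> np.ndarray:
        return _NONLINEARITIES[self.nonlinearity][0](z)

    def f_prime(self, z: np.ndarray) -> np.ndarray:
        return _NONLINEARITIES[self.nonlinearity][1](z)

    def copy(self) -> "RNNParams":
        return RNNParams(
            self.layout,
            self.W.copy(),
            self.alpha_raw.copy(),
            self.nonlinearity,
            None if self.trainable_mask is None else self.trainable_mask.copy(),
            self.alpha_trainable,
        )

    def n_trainable(self) -> int:
        nw = self.W.size if self.trainable_mask is None else int(self.trainable_mask.sum())
        return nw + (self.alpha_raw.size if self.alpha_trainable else 0)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            W=self.W,
            alpha_raw=self.alpha_raw,
            nonlinearity=np.array(self.nonlinearity),
            sizes_keys=np.array(list(self.layout.sizes.keys())),
            sizes_vals=np.array(list(self.layout.sizes.values())),
        )

    @classmethod
    def load(cls, path) -> "RNNParams":
        with np.load(path) as d:
            layout = PopulationLayout(
                dict(zip([str(k) for k in d["sizes_keys"]], d["sizes_vals"]))
            )
            return cls(layout, d["W"], d["alpha_raw"], str(d["nonlinearity"]))


@dataclass
class RNNState:
    """State vector over all populations at one timestep."""

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)

    def view(self, layout: PopulationLayout, name: str) -> np.ndarray:
        return self.z[..., layout.slc(name)]


def _check_finite(z: np.ndarray, layout: PopulationLayout) -> None:
    if np.all(np.isfinite(z)):
        return
    bad = ~np.isfinite(z)
    for name in _POPULATIONS:
        if layout.sizes[name] and np.any(bad[..., layout.slc(name)]):
            raise FloatingPointError(
                f"non-finite state in population {name}"
            )


def rnn_step(params: RNNParams, state: RNNState, inputs) -> RNNState:
    """One update of the leaky RNN.

    ``inputs`` is either a full injected vector (dim,) / dict of
    population blocks; external values enter input-node coordinates raw.
    """
    u = params.layout.inject(inputs) if isinstance(inputs, dict) else np.asarray(inputs, float)
    a = params.alpha
    z = state.z
    z_next = a * z + (1.0 - a) * (u + params.f(z) @ params.W.T)
    _check_finite(z_next, params.layout)
    return RNNState(z_next)


def rollout(params: RNNParams, init_state: RNNState, input_sequence) -> list[RNNState]:
    """Iterate ``rnn_step`` over an input sequence, returning all states.

    The initial state carries any ground-truth initialization (e.g. the
    grid-cell pattern at t = 0); a zero-length input returns [init_state].
    """
    states = [init_state]
    for u in input_sequence:
        states.append(rnn_step(params, states[-1], u))
    return states


def rollout_batch(params: RNNParams, z0: np.ndarray, U: np.ndarray):
    """Batched forward pass used by training.

    z0: (B, D) initial states; U: (B, T, D) injected input vectors.
    Returns Z (B, T+1, D) and F = f(Z[:, :-1]) cached for the backward
    pass.
    """
    B, T, D = U.shape
    dt = params.W.dtype
    a = params.alpha.astype(dt)
    U = np.asarray(U, dtype=dt)
    Z = np.empty((B, T + 1, D), dtype=dt)
    F = np.empty((B, T, D), dtype=dt)
    z = np.asarray(z0, dtype=dt)
    Z[:, 0] = z
    for t in range(T):
        fz = params.f(z)
        F[:, t] = fz
        z = a * z + (1.0 - a) * (U[:, t] + fz @ params.W.T)
        Z[:, t + 1] = z
    _check_finite(Z[:, -1], params.layout)
    return Z, F


def bptt_gradients(
    params: RNNParams,
    Z: np.ndarray,
    F: np.ndarray,
    U: np.ndarray,
    dLdZ: np.ndarray,
    need_dU: bool = False,
):
    """Backprop through time for the leaky RNN.

    dLdZ: (B, T+1, D) direct gradient of the loss in each state.  Returns
    (dW, dalpha_raw, dU) where dU is None unless requested.
    """
    B, T1, D = Z.shape
    T = T1 - 1
    a = params.alpha
    one_minus_a = 1.0 - a
    dW = np.zeros_like(params.W)
    dalpha = np.zeros(D)
    dU = np.empty_like(U) if need_dU else None
    g = dLdZ[:, T].copy()
    for t in range(T - 1, -1, -1):
        ga = one_minus_a * g                     # (B, D)
        dW += ga.T @ F[:, t]
        # pre-activation drive recovered from the update equation
        pre = (Z[:, t + 1] - a * Z[:, t]) / one_minus_a
        dalpha += np.sum(g * (Z[:, t] - pre), axis=0)
        if need_dU:
            dU[:, t] = ga
        g = a * g + params.f_prime(Z[:, t]) * (ga @ params.W) + dLdZ[:, t]
    dalpha_raw = dalpha * a * one_minus_a
    if params.trainable_mask is not None:
        dW *= params.trainable_mask
    if isinstance(params.alpha_trainable, np.ndarray):
        dalpha_raw = dalpha_raw * params.alpha_trainable
    elif not params.alpha_trainable:
        dalpha_raw = np.zeros_like(dalpha_raw)
    return dW, dalpha_raw, dU


class Adam:
    """Minimal Adam optimizer over a list of arrays (in-place updates)."""

    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, values, grads) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for x, g, m, v in zip(values, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            x -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
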