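"""Surrogate-gradient training of the spiking network.

The loss is a masked mean-squared error over the batch tensor,

    MSE = sum_{i,l,n} m_il(n) [y_il(n) - yhat_il(n)]^2
          / (N_out * N_batch * N_step * sum_{i,l,n} m_il(n)),

optionally augmented with a firing-rate regulariser
``E = MSE + lambda * E_r`` where ``E_r = sum_i f_i H(f_i - f_th)`` penalises
neurons whose mean rate ``f_i`` (Hz) exceeds the threshold frequency.
Spike thresholds are non-differentiable, so the backward pass substitutes
the SuperSpike pseudo-derivative

    sigma'(v) = (1 + |alpha (v - v_th)|)^-2

for ``dz/dv`` while the forward simulation keeps the hard Heaviside.  The
reset jump is treated as gradient-transparent (no derivative through the
reset), matching the sensitivity recursions, which carry no reset terms.

Two gradient routes over the *identical* surrogate-smoothed graph are
provided:

* :func:`forward_sensitivities` — forward-mode accumulation: per-parameter
  tangents of (v, a, I, y) are propagated through the linearised dynamics,
  including the synaptic-filter pathway and cross-neuron spike propagation.
  Cost O(P * N * T) for P parameters; intended for small instances.
* :func:`bptt_gradients` — reverse-mode backpropagation through time, the
  transpose recursion, used by :func:`train` at full scale.

The two agree to machine precision; a test enforces 1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .network import (NetworkWeights, NeuronParams, _EXP_CAP,
                      readout_kappa, simulate_batch)
from .tasks import BatchTensor, TaskId, TaskTiming, sample_batch


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Loss variant, surrogate and optimiser settings.

    The plain-MSE variant uses mask weights (1, 5) and a fast readout filter
    (tau_out = 2 ms); the rate-regularised variant uses mask weights
    (0.1, 1), tau_out = 50 ms, and (for N = 256) threshold 0.45 mV.
    """

    loss_variant: str = "mse"          # "mse" | "mse_reg"
    lambda_reg: float = 1.0            # weight of E_r (regularised variant)
    f_th: float = 30.0                 # threshold frequency, Hz
    eta: float = 5e-3                  # learning rate
    n_epoch: int = 3000
    n_batch: int = 50                  # 32 for the regularised variant
    alpha: float = 100.0               # surrogate sharpness
    tau_out: float = 2.0               # readout filter time constant, ms
    mask_values: tuple[float, float] = (1.0, 5.0)
    adam: tuple[float, float, float] = (0.9, 0.999, 1e-8)
    optimizer: str = "adam"            # "adam" | "sgd"
    seed: int = 0
    dt: float = 1.0
    noise_sigma: float = 0.05
    mse_denominator: str = "paper"     # "paper" | "masked_mean"
    checkpoint_every: int = 0          # 0 disables periodic checkpoints

    def __post_init__(self):
        if self.eta < 0 or self.alpha <= 0 or self.f_th < 0:
            raise ValueError("eta >= 0, alpha > 0 and f_th >= 0 required")
        if self.loss_variant not in ("mse", "mse_reg"):
            raise ValueError(f"unknown loss variant {self.loss_variant!r}")

    @property
    def kappa(self) -> float:
        return readout_kappa(self.tau_out, self.dt)


#: learning rates explored in the reference protocol; 5e-3 performs best
LEARNING_RATE_SWEEP = (5e-2, 5e-3, 5e-4)


def mse_config(**kw) -> TrainConfig:
    """Plain masked-MSE protocol: mask (1, 5), tau_out = 2 ms, batch 50."""
    base = dict(loss_variant="mse", mask_values=(1.0, 5.0), tau_out=2.0,
                n_batch=50, lambda_reg=0.0)
    base.update(kw)
    return TrainConfig(**base)


def regularized_config(**kw) -> TrainConfig:
    """Rate-regularised protocol: mask (0.1, 1), tau_out = 50 ms, batch 32."""
    base = dict(loss_variant="mse_reg", mask_values=(0.1, 1.0), tau_out=50.0,
                n_batch=32, lambda_reg=1.0)
    base.update(kw)
    return TrainConfig(**base)


# ---------------------------------------------------------------------------
# Loss pieces
# ---------------------------------------------------------------------------


def masked_mse(outputs: np.ndarray, targets: np.ndarray, mask: np.ndarray,
               denominator: str = "paper") -> float:
    """Masked mean-squared error over a ``[T, B, N_out]`` (or 2-D) tensor.

    ``denominator="paper"`` divides by ``N_out*N_batch*N_step*sum(m)`` as
    printed; ``"masked_mean"`` divides by ``sum(m)`` alone (the conventional
    weighted mean — the two differ by a constant factor absorbed by eta).
    """
    outputs, targets, mask = (np.asarray(x, dtype=float)
                              for x in (outputs, targets, mask))
    if outputs.ndim == 2:
        outputs, targets, mask = (x[:, None, :] for x in (outputs, targets, mask))
    msum = mask.sum()
    if msum == 0:
        raise ValueError("mask sums to zero; loss undefined")
    num = float(np.sum(mask * (outputs - targets) ** 2))
    T, B, n_out = outputs.shape
    if denominator == "paper":
        return num / (n_out * B * T * msum)
    elif denominator == "masked_mean":
        return num / msum
    raise ValueError(f"unknown denominator mode {denominator!r}")


def mean_rates_hz(Z: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Per-neuron firing rate in Hz, averaged across time and batch.

    ``Z`` is ``[T, N]`` or ``[T, B, N]`` binary.
    """
    Z = np.asarray(Z, dtype=float)
    axes = tuple(range(Z.ndim - 1))
    return Z.mean(axis=axes) * (1000.0 / dt)


def rate_regularizer(Z: np.ndarray, f_th: float = 30.0,
                     dt: float = 1.0) -> float:
    """``E_r = sum_i f_i H(f_i - f_th)`` with rates in Hz and H(0) = 1."""
    f = mean_rates_hz(Z, dt)
    return float(np.sum(f * (f >= f_th)))


def surrogate_derivative(v: np.ndarray | float, v_th: float,
                         alpha: float = 100.0) -> np.ndarray | float:
    """SuperSpike pseudo-derivative ``(1 + |alpha (v - v_th)|)^-2``."""
    return (1.0 + np.abs(alpha * (np.asarray(v, dtype=float) - v_th))) ** -2


# ---------------------------------------------------------------------------
# Gradients
# ---------------------------------------------------------------------------


@dataclass
class GradientSet:
    """Per-weight gradients; the recurrent diagonal is kept at zero."""

    dw_in: np.ndarray
    dw_rec: np.ndarray
    dw_out: np.ndarray
    db: np.ndarray

    def __post_init__(self):
        np.fill_diagonal(self.dw_rec, 0.0)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"w_in": self.dw_in, "w_rec": self.dw_rec,
                "w_out": self.dw_out, "b": self.db}


def _loss_pieces(trace_Y, trace_Z, batch: BatchTensor, cfg: TrainConfig):
    """Loss value and the local adjoints dL/dy (per step) and dL/dz (rate term)."""
    T, B, n_out = trace_Y.shape
    mask, targets = batch.mask, batch.targets
    msum = mask.sum()
    if msum == 0:
        raise ValueError("mask sums to zero; loss undefined")
    if cfg.mse_denominator == "paper":
        denom = n_out * B * T * msum
    else:
        denom = msum
    err = trace_Y - targets
    mse = float(np.sum(mask * err ** 2) / denom)
    g = 2.0 * mask * err / denom                     # dL/dy_n, [T, B, n_out]

    e_r = 0.0
    r_gate = None
    if cfg.loss_variant == "mse_reg" and cfg.lambda_reg != 0.0:
        f = mean_rates_hz(trace_Z, cfg.dt)           # [N], Hz
        gate = (f >= cfg.f_th).astype(float)
        e_r = float(np.sum(f * gate))
        # dE_r/dz_{n,b,i}: the H gate is piecewise constant and not differentiated
        r_gate = cfg.lambda_reg * gate * (1000.0 / cfg.dt) / (T * B)  # [N]
    loss = mse + cfg.lambda_reg * e_r
    return loss, mse, e_r, g, r_gate


def bptt_gradients(w: NetworkWeights, p: NeuronParams, batch: BatchTensor,
                   cfg: TrainConfig,
                   trace=None) -> tuple[GradientSet, dict]:
    """Reverse-mode gradients of the loss through the full trial (no
    truncation).  Returns the gradients and a dict with the loss parts."""
    if trace is None:
        trace = simulate_batch(w, batch.inputs, p, cfg.kappa, cfg.dt)
    V, Z, Y = trace.V, trace.Z.astype(float), trace.Y
    T, B, N = V.shape
    loss, mse, e_r, g, r_gate = _loss_pieces(Y, trace.Z, batch, cfg)

    dt = cfg.dt
    rho_s = 1.0 - dt / p.tau_s
    c_m = dt / p.tau_m
    c_a = dt / p.tau_a
    sg_all = surrogate_derivative(V, p.v_th, cfg.alpha)

    lam_v = np.zeros((B, N))
    lam_a = np.zeros((B, N))
    lam_I = np.zeros((B, N))
    lam_y = np.zeros((B, w.n_out))
    dw_in = np.zeros_like(w.w_in)
    dw_rec = np.zeros_like(w.w_rec)
    dw_out = np.zeros_like(w.w_out)
    db = np.zeros_like(w.b)
    u = batch.inputs

    for n in range(T - 1, -1, -1):
        z_n = Z[n]
        # post-reset potential drives the next-step Euler factor
        v_hat = np.where(z_n > 0, p.v_reset, V[n])
        D = 1.0 + c_m * (np.exp(np.minimum((v_hat - p.v_th) / p.theta,
                                           _EXP_CAP)) - 1.0)
        lam_y_n = g[n] + cfg.kappa * lam_y
        lam_z = lam_y_n @ w.w_out + lam_I @ w.w_rec
        if r_gate is not None:
            lam_z = lam_z + r_gate
        lam_v_n = D * lam_v + c_a * p.a_current * lam_a + sg_all[n] * lam_z
        lam_a_n = (1.0 - c_a) * lam_a - c_m * lam_v
        lam_I_n = c_m * lam_v + rho_s * lam_I

        dw_out += lam_y_n.T @ z_n
        db += lam_y_n.sum(axis=0)
        if n > 0:
            dw_rec += lam_I_n.T @ Z[n - 1]
        dw_in += lam_I_n.T @ u[n]
        lam_v, lam_a, lam_I, lam_y = lam_v_n, lam_a_n, lam_I_n, lam_y_n

    grads = GradientSet(dw_in, dw_rec, dw_out, db)
    return grads, {"loss": loss, "mse": mse, "e_r": e_r}


def forward_sensitivities(w: NetworkWeights, p: NeuronParams,
                          batch: BatchTensor, cfg: TrainConfig,
                          trace=None) -> tuple[GradientSet, dict]:
    """Forward-mode gradients: tangents of (v, a, I, y) propagated alongside
    the dynamics for every parameter, spikes differentiated through the
    SuperSpike surrogate, resets gradient-transparent.

    The recursion generalises the per-neuron sensitivity equations by keeping
    the synaptic-filter pathway and the cross-neuron spike terms, which makes
    it the exact transpose of :func:`bptt_gradients`.  Cost grows with the
    parameter count; use on small instances.
    """
    if trace is None:
        trace = simulate_batch(w, batch.inputs, p, cfg.kappa, cfg.dt)
    V, Zb, Y = trace.V, trace.Z, trace.Y
    Z = Zb.astype(float)
    T, B, N = V.shape
    n_out = w.n_out
    loss, mse, e_r, g, r_gate = _loss_pieces(Y, Zb, batch, cfg)

    dt = cfg.dt
    rho_s = 1.0 - dt / p.tau_s
    c_m = dt / p.tau_m
    c_a = dt / p.tau_a
    sg_all = surrogate_derivative(V, p.v_th, cfg.alpha)
    u = batch.inputs
    idxN = np.arange(N)
    idxO = np.arange(n_out)

    def propagate(group: str) -> np.ndarray:
        if group == "w_rec":
            P = N * N
        elif group == "w_in":
            P = N * w.n_in
        elif group == "w_out":
            P = n_out * N
        else:
            P = n_out
        tv = np.zeros((P, B, N))
        ta = np.zeros((P, B, N))
        tI = np.zeros((P, B, N))
        ty = np.zeros((P, B, n_out))
        tz_prev = np.zeros((P, B, N))
        dL = np.zeros(P)
        for n in range(T):
            tI = rho_s * tI + tz_prev @ w.w_rec.T
            if group == "w_rec" and n > 0:
                # direct term dI_j/dw_rec[j,k] = z_k(n-1)
                tIr = tI.reshape(N, N, B, N)
                tIr[idxN, :, :, idxN] += Z[n - 1].T
            elif group == "w_in":
                tIr = tI.reshape(N, w.n_in, B, N)
                tIr[idxN, :, :, idxN] += u[n].T
            tz = sg_all[n] * tv
            ty = cfg.kappa * ty + tz @ w.w_out.T
            if group == "w_out":
                tyr = ty.reshape(n_out, N, B, n_out)
                tyr[idxO, :, :, idxO] += Z[n].T
            elif group == "b":
                tyr = ty.reshape(n_out, B, n_out)
                tyr[idxO, :, idxO] += 1.0
            dL += np.einsum("bo,pbo->p", g[n], ty)
            if r_gate is not None:
                dL += np.einsum("n,pbn->p", r_gate, tz)
            # advance tangents through the Euler update (reset-transparent)
            v_hat = np.where(Z[n] > 0, p.v_reset, V[n])
            D = 1.0 + c_m * (np.exp(np.minimum((v_hat - p.v_th) / p.theta,
                                               _EXP_CAP)) - 1.0)
            tv_new = D * tv + c_m * (tI - ta)
            ta = (1.0 - c_a) * ta + c_a * p.a_current * tv
            tv = tv_new
            tz_prev = tz
        return dL

    dw_rec = propagate("w_rec").reshape(N, N)
    dw_in = propagate("w_in").reshape(N, w.n_in)
    dw_out = propagate("w_out").reshape(n_out, N)
    db = propagate("b")
    grads = GradientSet(dw_in, dw_rec, dw_out, db)
    return grads, {"loss": loss, "mse": mse, "e_r": e_r}


# ---------------------------------------------------------------------------
# Optimiser and training loop
# ---------------------------------------------------------------------------


@dataclass
class OptimizerState:
    """Adam first/second-moment accumulators and the step counter."""

    m: dict[str, np.ndarray] = field(default_factory=dict)
    v: dict[str, np.ndarray] = field(default_factory=dict)
    t: int = 0


def apply_update(w: NetworkWeights, g: GradientSet, opt: OptimizerState,
                 cfg: TrainConfig) -> NetworkWeights:
    """One optimiser step (plain SGD or Adam); re-zeros the recurrent
    diagonal afterwards.  The input weights are modified in place and also
    returned."""
    gd = g.as_dict()
    for arr in gd.values():
        if not np.all(np.isfinite(arr)):
            raise FloatingPointError("non-finite gradient; aborting update")
    tensors = {"w_in": w.w_in, "w_rec": w.w_rec, "w_out": w.w_out, "b": w.b}
    if cfg.optimizer == "sgd":
        for k, arr in tensors.items():
            arr -= cfg.eta * gd[k]
    elif cfg.optimizer == "adam":
        b1, b2, eps = cfg.adam
        opt.t += 1
        t = opt.t
        for k, arr in tensors.items():
            if k not in opt.m:
                opt.m[k] = np.zeros_like(arr)
                opt.v[k] = np.zeros_like(arr)
            opt.m[k] = b1 * opt.m[k] + (1 - b1) * gd[k]
            opt.v[k] = b2 * opt.v[k] + (1 - b2) * gd[k] ** 2
            mhat = opt.m[k] / (1 - b1 ** t)
            vhat = opt.v[k] / (1 - b2 ** t)
            arr -= cfg.eta * mhat / (np.sqrt(vhat) + eps)
    else:
        raise ValueError(f"unknown optimizer {cfg.optimizer!r}")
    np.fill_diagonal(w.w_rec, 0.0)
    return w


def train(w: NetworkWeights, p: NeuronParams, cfg: TrainConfig,
          tasks: Sequence[TaskId], rng: np.random.Generator,
          timing: dict[str, TaskTiming] | None = None,
          callback: Callable[[int, dict], None] | None = None,
          checkpoint_dir=None) -> tuple[NetworkWeights, list[dict]]:
    """Train in place for ``cfg.n_epoch`` epochs.

    Each epoch samples ``cfg.n_batch`` trials of randomly selected tasks,
    aligns them into a batch tensor, simulates the network, backpropagates
    the masked loss and applies one optimiser update.  Returns the weights
    and a per-epoch history of loss components.  Fully determined by the
    supplied generator.
    """
    opt = OptimizerState()
    history: list[dict] = []
    for epoch in range(cfg.n_epoch):
        batch = sample_batch(tasks, cfg.n_batch, rng, cfg.noise_sigma,
                             cfg.mask_values, timing, cfg.dt)
        grads, parts = bptt_gradients(w, p, batch, cfg)
        apply_update(w, grads, opt, cfg)
        rec = {"epoch": epoch, **parts}
        history.append(rec)
        if callback is not None:
            callback(epoch, rec)
        if (checkpoint_dir is not None and cfg.checkpoint_every
                and (epoch + 1) % cfg.checkpoint_every == 0):
            from .workbench import Checkpoint, save_checkpoint
            save_checkpoint(
                f"{checkpoint_dir}/ckpt_{epoch + 1:05d}.h5",
                Checkpoint(weights=w, params=p, epoch=epoch + 1))
    return w, history


def history_to_csv(history: list[dict], path) -> None:
    """Write the per-epoch training log as CSV."""
    import pandas as pd

    pd.DataFrame(history).to_csv(path, index=False)
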