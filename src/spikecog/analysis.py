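"""Low-dimensional structure of population trajectories: PCA and demixed PCA.

PCA runs separately on membrane potentials and adaptation variables, since
the two evolve on very different time scales (per-neuron centering, no
variance scaling).  Demixed PCA decomposes a condition-averaged rate tensor
``X[n, s, d, t]`` (neuron, stimulus, decision, time) additively into a
time-only marginal, stimulus- and decision-dependent marginals, and a
residual::

    X = X_t + X_s + X_d + X_noise

where ``X_t(n,t)`` is the mean over conditions (including the grand mean),
``X_s(n,s,t)`` the decision-averaged tensor minus ``X_t``, ``X_d(n,d,t)``
the stimulus-averaged tensor minus ``X_t``, and ``X_noise`` the remainder
(condition interaction plus trial noise).  This is the plain
marginalisation-average decomposition with a per-marginalisation PCA on
top — no reduced-rank regression and no regularisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from sklearn.decomposition import PCA

from .network import SimulationTrace


# ---------------------------------------------------------------------------
# State-matrix PCA
# ---------------------------------------------------------------------------


@dataclass
class StateMatrix:
    """Neurons x time matrix of one dynamic variable over concatenated trials."""

    data: np.ndarray            # [N, N_times]
    variable: str               # "v" | "a"
    boundaries: list[int]       # cumulative trial end columns


@dataclass
class PCAProjection:
    """Top-k loadings, per-trial projected trajectories, variance ratios."""

    components: np.ndarray              # [k, N], orthonormal rows
    trajectories: list[np.ndarray]      # per trial, [T_i, k]
    explained_variance_ratio: np.ndarray


def build_state_matrix(traces: list[SimulationTrace],
                       variable: str = "v") -> StateMatrix:
    """Concatenate one variable of several traces into ``[N, N_times]``."""
    if not traces:
        raise ValueError("need at least one trace")
    if variable not in ("v", "a"):
        raise ValueError(f"variable must be 'v' or 'a', got {variable!r}")
    blocks = [(tr.V if variable == "v" else tr.A).T for tr in traces]
    n = blocks[0].shape[0]
    if any(b.shape[0] != n for b in blocks):
        raise ValueError("traces disagree on network size")
    boundaries = list(np.cumsum([b.shape[1] for b in blocks]))
    return StateMatrix(np.concatenate(blocks, axis=1), variable, boundaries)


def pca_project(m: StateMatrix, k: int = 3) -> PCAProjection:
    """PCA of the row-centered state matrix; trajectories split per trial."""
    n, n_times = m.data.shape
    rank = min(n, n_times)
    if k > rank:
        warnings.warn(f"k={k} exceeds the matrix rank bound {rank}; "
                      f"returning {rank} components")
        k = rank
    pca = PCA(n_components=k)
    proj = pca.fit_transform(m.data.T)          # [N_times, k]
    starts = [0] + m.boundaries[:-1]
    trajectories = [proj[s:e] for s, e in zip(starts, m.boundaries)]
    return PCAProjection(pca.components_, trajectories,
                         pca.explained_variance_ratio_)


# ---------------------------------------------------------------------------
# Instantaneous firing rates
# ---------------------------------------------------------------------------


def smooth_rates(Z: np.ndarray, window: float = 50.0,
                 dt: float = 1.0) -> np.ndarray:
    """Causal boxcar estimate of instantaneous firing rates in Hz.

    ``Z`` is ``[T, N]`` binary; the rate at step t counts spikes in the
    trailing ``window`` ms.  A single spike yields a rectangular bump of
    ``1000/window`` Hz lasting ``window/dt`` samples.
    """
    if window < dt:
        raise ValueError("window must be at least dt")
    w = int(round(window / dt))
    Z = np.asarray(Z, dtype=float)
    counts = lfilter(np.ones(w), [1.0], Z, axis=0)
    return counts * (1000.0 / (w * dt))


# ---------------------------------------------------------------------------
# Demixed PCA
# ---------------------------------------------------------------------------


@dataclass
class ConditionTensor:
    """Trial-averaged rates organised by stimulus and decision condition."""

    rates: np.ndarray                  # [N, S, D, T]
    stimulus_labels: list = field(default_factory=list)
    decision_labels: list = field(default_factory=list)

    def __post_init__(self):
        if self.rates.ndim != 4:
            raise ValueError("rates must be [N, S, D, T]")


@dataclass
class DPCADecomposition:
    """Additive marginals of the condition tensor and their variances."""

    x_t: np.ndarray        # [N, T] condition-independent (includes the mean)
    x_s: np.ndarray        # [N, S, T] stimulus marginal (with its time course)
    x_d: np.ndarray        # [N, D, T] decision marginal
    x_noise: np.ndarray    # [N, S, D, T] residual
    marginal_variance: dict[str, float]
    explained_variance_ratio: dict[str, float]

    def reconstruct(self) -> np.ndarray:
        """Sum of all terms; equals the input tensor exactly."""
        return (self.x_t[:, None, None, :] + self.x_s[:, :, None, :]
                + self.x_d[:, None, :, :] + self.x_noise)


def dpca_decompose(c: ConditionTensor) -> DPCADecomposition:
    """Marginalisation-average decomposition of ``X[n, s, d, t]``."""
    X = np.asarray(c.rates, dtype=float)
    N, S, D, T = X.shape
    if S < 2 and D < 2:
        raise ValueError("need at least two stimulus levels or two decisions")
    if S < 2 or D < 2:
        warnings.warn("a singleton condition axis makes its marginal "
                      "identically zero")
    x_t = X.mean(axis=(1, 2))                       # [N, T]
    x_s = X.mean(axis=2) - x_t[:, None, :]          # [N, S, T]
    x_d = X.mean(axis=1) - x_t[:, None, :]          # [N, D, T]
    x_noise = (X - x_t[:, None, None, :] - x_s[:, :, None, :]
               - x_d[:, None, :, :])

    grand = X.mean(axis=(1, 2, 3))                  # per-neuron mean, [N]
    total = float(np.sum((X - grand[:, None, None, None]) ** 2))
    # sums of squares of each marginal on the broadcast [N, S, D, T] scale;
    # in this complete factorial layout they add up to the total exactly
    mv = {
        "time": S * D * float(np.sum((x_t - grand[:, None]) ** 2)),
        "stimulus": D * float(np.sum(x_s ** 2)),
        "decision": S * float(np.sum(x_d ** 2)),
        "noise": float(np.sum(x_noise ** 2)),
    }
    ratios = {k: (v / total if total > 0 else 0.0) for k, v in mv.items()}
    return DPCADecomposition(x_t, x_s, x_d, x_noise, mv, ratios)


def marginal_components(dec: DPCADecomposition, marginal: str = "stimulus",
                        k: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Per-marginalisation PCA: top-k loadings of one marginal and the
    marginal's trajectories projected onto them.

    For ``marginal="stimulus"`` the decomposition's ``[N, S, T]`` stimulus
    term is reshaped to ``[N, S*T]``; the first component is the leading
    demixed stimulus axis.  Returns ``(components [k, N], projections)``
    where projections keep the marginal's condition-by-time layout.
    """
    term = {"time": dec.x_t[:, None, :], "stimulus": dec.x_s,
            "decision": dec.x_d}[marginal]
    N = term.shape[0]
    flat = term.reshape(N, -1)
    pca = PCA(n_components=min(k, min(flat.shape)))
    pca.fit(flat.T)
    comps = pca.components_                   # [k, N]
    proj = np.tensordot(comps, term, axes=(1, 0))  # [k, *cond_shape, T]
    return comps, proj


def build_condition_tensor(grouped: dict[tuple, list[np.ndarray]],
                           window: float = 50.0,
                           dt: float = 1.0) -> ConditionTensor:
    """Average smoothed rates over trials per (stimulus, decision) condition.

    ``grouped`` maps ``(s_label, d_label)`` to a list of spike matrices
    ``[T, N]`` of equal length.  Missing condition cells are not allowed.
    """
    s_labels = sorted({k[0] for k in grouped})
    d_labels = sorted({k[1] for k in grouped})
    first = next(iter(grouped.values()))[0]
    T, N = first.shape
    X = np.empty((N, len(s_labels), len(d_labels), T))
    for i, s in enumerate(s_labels):
        for j, d in enumerate(d_labels):
            if (s, d) not in grouped:
                raise ValueError(f"missing condition cell {(s, d)}")
            rates = [smooth_rates(Z, window, dt) for Z in grouped[(s, d)]]
            X[:, i, j, :] = np.mean(rates, axis=0).T
    return ConditionTensor(X, s_labels, d_labels)
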