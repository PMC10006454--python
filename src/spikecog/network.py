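"""Discrete-time adaptive-exponential (AdEx) spiking recurrent network.

Neuron ``j`` carries a membrane potential ``v_j``, an adaptation variable
``a_j`` and a synaptic current ``I_j``.  The Euler-discretised dynamics on a
``dt`` grid are::

    v_j(n+1) = v_j(n) + (dt/tau_m) * (-v_j(n) + theta*exp((v_j(n)-v_th)/theta)
                                      + I_j(n) - a_j(n))
    a_j(n+1) = a_j(n) + (dt/tau_a) * (a_current*v_j(n) - a_j(n))
    I_j(n+1) = I_j(n)*(1 - dt/tau_s) + sum_k W_in[j,k]  u_k(n+1)
                                     + sum_k W_rec[j,k] z_k(n)

with spikes ``z_j(n) = H(v_j(n) - v_th)`` (``H(0) = 1``) evaluated from the
pre-reset potential; a spiking neuron is then reset ``v -> v_reset`` and its
adaptation incremented ``a -> a + a_s`` before the Euler update.  Outputs are
exponential filters of the spike trains::

    y_i(n+1) = kappa * y_i(n) + sum_k W_out[i,k] z_k(n) + b_i,
    kappa = exp(-dt / tau_out).

The recurrent matrix keeps an identically zero diagonal (no self-excitation).
All quantities are treated as the dimensionless numbers of the parameter
table; the exponential argument is capped at +20 so transient excursions of
untrained networks cannot overflow (the cap never binds below threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tasks import N_IN, N_OUT, TrialTensor

_EXP_CAP = 20.0


class NumericalBlowupError(RuntimeError):
    """Raised when a state variable becomes non-finite during simulation."""

    def __init__(self, step: int, neuron: int):
        super().__init__(f"non-finite state at step {step}, neuron {neuron}")
        self.step = step
        self.neuron = neuron


@dataclass(frozen=True)
class NeuronParams:
    """AdEx parameters (defaults from the reference parameter table).

    Time constants in ms; ``v_th = 0.65`` except 0.45 for N = 256 networks
    trained with the rate-regularised loss (see :func:`default_params`).
    """

    tau_m: float = 10.0       # membrane time constant, ms
    tau_a: float = 2000.0     # adaptation time constant, ms
    tau_s: float = 5.0        # synaptic time constant, ms
    v_th: float = 0.65        # spike threshold, mV
    v_reset: float = 0.0      # reset potential, mV
    theta: float = 0.5        # sharpness of the exponential nonlinearity, mV
    a_s: float = 0.02         # adaptation increment per spike, nA
    a_current: float = 4.0    # adaptation coupling, nS

    def __post_init__(self):
        if min(self.tau_m, self.tau_a, self.tau_s) <= 0:
            raise ValueError("time constants must be positive")
        if self.theta <= 0:
            raise ValueError("theta must be positive")


def default_params(N: int) -> NeuronParams:
    """Table defaults; the threshold drops to 0.45 mV for N = 256."""
    return NeuronParams(v_th=0.45 if N == 256 else 0.65)


@dataclass
class NetworkWeights:
    """Input, recurrent and readout weights.  ``W_rec`` diagonal is zero."""

    w_in: np.ndarray   # [N, N_in]
    w_rec: np.ndarray  # [N, N]
    w_out: np.ndarray  # [N_out, N]
    b: np.ndarray      # [N_out]

    def __post_init__(self):
        np.fill_diagonal(self.w_rec, 0.0)

    @property
    def n(self) -> int:
        return self.w_rec.shape[0]

    @property
    def n_in(self) -> int:
        return self.w_in.shape[1]

    @property
    def n_out(self) -> int:
        return self.w_out.shape[0]

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.w_in.copy(), self.w_rec.copy(),
                              self.w_out.copy(), self.b.copy())


def init_weights(N: int, n_in: int = N_IN, n_out: int = N_OUT,
                 rng: np.random.Generator | None = None) -> NetworkWeights:
    """Random initial weights: ``W_in``, ``W_rec`` ~ sqrt(2/N) N(0,1) with the
    recurrent diagonal zeroed; ``W_out``, ``b`` ~ U(-sqrt(1/N), sqrt(1/N))."""
    if rng is None:
        rng = np.random.default_rng()
    s = np.sqrt(2.0 / N)
    u = np.sqrt(1.0 / N)
    w = NetworkWeights(
        w_in=s * rng.standard_normal((N, n_in)),
        w_rec=s * rng.standard_normal((N, N)),
        w_out=rng.uniform(-u, u, size=(n_out, N)),
        b=rng.uniform(-u, u, size=n_out),
    )
    return w


@dataclass
class NetworkState:
    """Per-step dynamical state; ``z`` holds the spikes fired this step."""

    v: np.ndarray
    a: np.ndarray
    I: np.ndarray
    z: np.ndarray
    y: np.ndarray

    def copy(self) -> "NetworkState":
        return NetworkState(self.v.copy(), self.a.copy(), self.I.copy(),
                            self.z.copy(), self.y.copy())


def initial_state(N: int, n_out: int = N_OUT) -> NetworkState:
    """All-zero state used at the start of a trial (unless chaining trials)."""
    return NetworkState(np.zeros(N), np.zeros(N), np.zeros(N),
                        np.zeros(N), np.zeros(n_out))


def _exp_term(v: np.ndarray, p: NeuronParams) -> np.ndarray:
    return p.theta * np.exp(np.minimum((v - p.v_th) / p.theta, _EXP_CAP))


def step(state: NetworkState, u_next: np.ndarray, w: NetworkWeights,
         p: NeuronParams, dt: float = 1.0,
         kappa: float | None = None) -> NetworkState:
    """Advance the network by one step.

    Spikes are detected from the pre-reset potential, resets are applied,
    then the Euler update runs from the post-reset state; the synaptic
    current integrates the incoming input row and the previous step's
    spikes.  When ``kappa`` is given the readout filter is advanced too.
    """
    v, a = state.v.copy(), state.a.copy()
    I_new = state.I * (1.0 - dt / p.tau_s) + w.w_in @ u_next + w.w_rec @ state.z
    z = (v >= p.v_th).astype(float)
    v[z > 0] = p.v_reset
    a[z > 0] += p.a_s
    v_next = v + (dt / p.tau_m) * (-v + _exp_term(v, p) + I_new - a)
    a_next = a + (dt / p.tau_a) * (p.a_current * v - a)
    y = state.y
    if kappa is not None:
        y = kappa * y + w.w_out @ z + w.b
    if not (np.all(np.isfinite(v_next)) and np.all(np.isfinite(a_next))
            and np.all(np.isfinite(I_new))):
        bad = int(np.flatnonzero(~(np.isfinite(v_next) & np.isfinite(a_next)
                                   & np.isfinite(I_new)))[0])
        raise NumericalBlowupError(-1, bad)
    return NetworkState(v_next, a_next, I_new, z, y)


def readout_step(y: np.ndarray, z: np.ndarray, w: NetworkWeights,
                 kappa: float) -> np.ndarray:
    """One readout-filter update: ``y' = kappa*y + W_out z + b``."""
    if not 0.0 < kappa < 1.0:
        raise ValueError(f"kappa must lie in (0, 1), got {kappa}")
    return kappa * y + w.w_out @ z + w.b


def readout_kappa(tau_out: float, dt: float = 1.0) -> float:
    """Filter parameter ``kappa = exp(-dt / tau_out)``."""
    return float(np.exp(-dt / tau_out))


@dataclass
class SimulationTrace:
    """Recorded trajectories of one simulation.

    ``V[n]``/``A[n]`` are the pre-reset membrane potential and adaptation at
    step n, ``Z[n]`` the spikes fired at step n, and ``Y[n]`` the readout
    after incorporating ``Z[n]`` (i.e. the Eq.-4 value ``y(n+1)``, compared
    against target row n).  ``final_state`` allows chaining trials.
    """

    V: np.ndarray  # [T, N] (or [T, B, N] for batched runs)
    A: np.ndarray
    Z: np.ndarray
    Y: np.ndarray  # [T, N_out] (or [T, B, N_out])
    final_state: NetworkState | None = None


def simulate_trial(w: NetworkWeights, trial: TrialTensor | np.ndarray,
                   p: NeuronParams, kappa: float,
                   state: NetworkState | None = None,
                   record: bool = True) -> SimulationTrace:
    """Simulate one trial (or a raw ``[T, N_in]`` input array).

    The initial state is zero unless an explicit ``state`` carries over the
    end of a previous trial.  Deterministic given the inputs and weights.
    """
    u = trial.inputs if isinstance(trial, TrialTensor) else np.asarray(trial)
    T = u.shape[0]
    N = w.n
    if state is None:
        state = initial_state(N, w.n_out)
    v, a, I = state.v.copy(), state.a.copy(), state.I.copy()
    z_prev, y = state.z.copy(), state.y.copy()
    dt = trial.spec.dt if isinstance(trial, TrialTensor) else 1.0

    rho_s = 1.0 - dt / p.tau_s
    if record:
        V = np.empty((T, N))
        A = np.empty((T, N))
        Z = np.zeros((T, N), dtype=bool)
        Y = np.empty((T, w.n_out))
    else:
        V = A = Z = Y = np.empty((0,))

    for n in range(T):
        I = rho_s * I + w.w_in @ u[n] + w.w_rec @ z_prev
        z = v >= p.v_th
        if record:
            V[n], A[n], Z[n] = v, a, z
        zf = z.astype(float)
        v = np.where(z, p.v_reset, v)
        a = a + p.a_s * zf
        y = kappa * y + w.w_out @ zf + w.b
        if record:
            Y[n] = y
        v_new = v + (dt / p.tau_m) * (-v + _exp_term(v, p) + I - a)
        a = a + (dt / p.tau_a) * (p.a_current * v - a)
        v = v_new
        z_prev = zf
        if not np.all(np.isfinite(v)):
            raise NumericalBlowupError(n, int(np.flatnonzero(~np.isfinite(v))[0]))

    final = NetworkState(v, a, I, z_prev, y)
    return SimulationTrace(V, A, Z, Y, final)


def simulate_batch(w: NetworkWeights, inputs: np.ndarray, p: NeuronParams,
                   kappa: float, dt: float = 1.0,
                   record_state: bool = False) -> SimulationTrace:
    """Vectorised simulation of a ``[T, B, N_in]`` batch.

    Returns batched traces ``V, A, Z [T, B, N]`` and ``Y [T, B, N_out]``.
    ``V`` holds the pre-reset potentials (for the surrogate derivative); the
    post-reset potentials needed by the backward pass are reconstructed from
    ``V`` and ``Z``.
    """
    T, B, _ = inputs.shape
    N = w.n
    v = np.zeros((B, N))
    a = np.zeros((B, N))
    I = np.zeros((B, N))
    z_prev = np.zeros((B, N))
    y = np.zeros((B, w.n_out))
    rho_s = 1.0 - dt / p.tau_s

    V = np.empty((T, B, N))
    A = np.empty((T, B, N))
    Z = np.zeros((T, B, N), dtype=bool)
    Y = np.empty((T, B, w.n_out))
    w_inT, w_recT, w_outT = w.w_in.T, w.w_rec.T, w.w_out.T

    for n in range(T):
        I = rho_s * I + inputs[n] @ w_inT + z_prev @ w_recT
        z = v >= p.v_th
        V[n], A[n], Z[n] = v, a, z
        zf = z.astype(float)
        v = np.where(z, p.v_reset, v)
        a = a + p.a_s * zf
        y = kappa * y + zf @ w_outT + w.b
        Y[n] = y
        v_new = v + (dt / p.tau_m) * (-v + _exp_term(v, p) + I - a)
        a = a + (dt / p.tau_a) * (p.a_current * v - a)
        v = v_new
        z_prev = zf
    if not np.all(np.isfinite(v)):
        bad = int(np.flatnonzero(~np.isfinite(v).all(axis=0))[0])
        raise NumericalBlowupError(T - 1, bad)
    return SimulationTrace(V, A, Z, Y, None)


def simulate_neuron(p: NeuronParams, i_ext: np.ndarray,
                    dt: float = 1.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Current-clamp protocol for a single neuron.

    The synaptic current is clamped to the injected waveform ``i_ext`` (no
    synaptic filtering), reproducing the classic adaptation experiment: under
    a sustained suprathreshold pulse the adaptation variable grows, the
    firing rate drops until spiking stops, and excitability recovers after
    the input is removed.  Returns ``(v_trace, a_trace, spikes)``.
    """
    T = len(i_ext)
    v = a = 0.0
    V = np.empty(T)
    A = np.empty(T)
    Z = np.zeros(T, dtype=bool)
    for n in range(T):
        z = v >= p.v_th
        V[n], A[n], Z[n] = v, a, z
        if z:
            v = p.v_reset
            a += p.a_s
        e = p.theta * np.exp(min((v - p.v_th) / p.theta, _EXP_CAP))
        v_new = v + (dt / p.tau_m) * (-v + e + i_ext[n] - a)
        a = a + (dt / p.tau_a) * (p.a_current * v - a)
        v = v_new
    return V, A, Z
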