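"""Cognitive task battery: trial sampling, rendering, and batch assembly.

Twelve target tasks — six families, each deliverable through one of two
sensory modalities:

* choice tasks: ``DM`` (perceptual decision), ``CtxDM`` (context-dependent
  decision), ``Romo`` (delayed two-pulse comparison, a working-memory task);
* repeat tasks: ``Go`` (reproduce a held stimulus amplitude), ``GoRt``
  (reaction-time variant, fixation held throughout), ``GoDl`` (delayed
  variant, response cued by fixation offset).

Every trial is rendered on a 1 ms grid as an input matrix ``[T, N_in]`` with
``N_in = 12 + 3`` channels — a binary fixation channel, two noisy sensory
channels, and a constant one-hot task-coding block — plus a target matrix and
loss-mask matrix ``[T, 3]`` over the outputs ``(y_fix, y_1, y_2)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# Task identity
# ---------------------------------------------------------------------------

FAMILIES = ("DM", "CtxDM", "Go", "GoRt", "GoDl", "Romo")
CHOICE_FAMILIES = frozenset({"DM", "CtxDM", "Romo"})
REPEAT_FAMILIES = frozenset({"Go", "GoRt", "GoDl"})

#: discrete amplitude grid for the Go family: {0, 1/7, ..., 6/7, 1}
GO_AMPLITUDES = tuple(i / 7.0 for i in range(8))

N_TASKS = 12
N_OUT = 3
N_IN = N_TASKS + 3  # fixation + two modalities + one-hot task code

# phase codes stored per time step
PHASE_PADDING = 0
PHASE_STIMULUS = 1
PHASE_DELAY = 2
PHASE_RESPONSE = 3

#: when True, a Romo trial whose first pulse is larger targets (y1, y2) = (1, 0)
ROMO_FIRST_LARGER_IS_Y1 = True


@dataclass(frozen=True, order=True)
class TaskId:
    """One of the 12 target tasks: a family plus the sensory modality (1 or 2)."""

    family: str
    modality: int

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown task family {self.family!r}")
        if self.modality not in (1, 2):
            raise ValueError(f"modality must be 1 or 2, got {self.modality}")

    @property
    def name(self) -> str:
        return f"{self.family}{self.modality}"

    @property
    def index(self) -> int:
        """Fixed position of this task in the one-hot task-coding block.

        Ordering: families in ``FAMILIES`` order, modality 1 before 2 —
        DM1, DM2, CtxDM1, CtxDM2, Go1, Go2, GoRt1, GoRt2, GoDl1, GoDl2,
        Romo1, Romo2.
        """
        return FAMILIES.index(self.family) * 2 + (self.modality - 1)

    @property
    def is_choice(self) -> bool:
        return self.family in CHOICE_FAMILIES


ALL_TASKS: tuple[TaskId, ...] = tuple(
    TaskId(f, m) for f in FAMILIES for m in (1, 2)
)


def task_by_name(name: str) -> TaskId:
    for t in ALL_TASKS:
        if t.name == name:
            return t
    raise ValueError(f"unknown task name {name!r}")


def one_hot_task_vector(task: TaskId) -> np.ndarray:
    """One-hot vector of length ``N_TASKS`` marking the current task."""
    v = np.zeros(N_TASKS)
    v[task.index] = 1.0
    return v


# ---------------------------------------------------------------------------
# Trial specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskTiming:
    """Duration distributions (ms) for trial sampling.

    ``stim_range`` is the stimulus-phase range (the pre-stimulus fixation
    range for GoRt, and the per-pulse duration for Romo); ``delay_range``
    applies only to Romo/GoDl; ``t_resp`` is the fixed response duration.
    """

    stim_range: tuple[float, float]
    t_resp: float
    delay_range: tuple[float, float] | None = None


#: default trial-parameter table used for training and testing
DEFAULT_TIMING: dict[str, TaskTiming] = {
    "DM": TaskTiming((300.0, 1800.0), 250.0),
    "CtxDM": TaskTiming((300.0, 1800.0), 250.0),
    "Go": TaskTiming((300.0, 1800.0), 250.0),
    "GoRt": TaskTiming((300.0, 1800.0), 1500.0),
    "GoDl": TaskTiming((200.0, 600.0), 250.0, (200.0, 1700.0)),
    "Romo": TaskTiming((200.0, 600.0), 250.0, (200.0, 1700.0)),
}


def scaled_timing(stim_range=(200.0, 500.0), t_resp=250.0,
                  delay_range=(100.0, 300.0)) -> dict[str, TaskTiming]:
    """A shortened timing table for desk-scale training runs."""
    return {
        f: TaskTiming(stim_range, t_resp,
                      delay_range if DEFAULT_TIMING[f].delay_range else None)
        for f in FAMILIES
    }


@dataclass(frozen=True)
class TrialSpec:
    """A sampled task instance: durations, amplitudes and noise level."""

    task: TaskId
    t_stim: float           # ms; T_fix for GoRt, per-pulse duration for Romo
    t_delay: float          # ms; 0 when the task has no delay period
    t_resp: float           # ms
    a_stim: tuple[float, ...]   # one amplitude, except CtxDM/Romo: two
    noise_sigma: float
    dt: float = 1.0
    u_th: float = 0.5

    def __post_init__(self):
        for d, name in ((self.t_stim, "t_stim"), (self.t_resp, "t_resp")):
            if d <= 0:
                raise ValueError(f"{name} must be positive, got {d}")
        if self.t_delay < 0:
            raise ValueError("t_delay must be non-negative")
        for a in self.a_stim:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"stimulus amplitude {a} outside [0, 1]")

    def _steps(self, duration: float) -> int:
        n = duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"duration {duration} ms is not a multiple of dt={self.dt} ms")
        return int(round(n))

    @property
    def n_steps(self) -> int:
        """Total rendered trial length in steps."""
        ns, nd, nr = (self._steps(self.t_stim),
                      self._steps(self.t_delay) if self.t_delay else 0,
                      self._steps(self.t_resp))
        if self.task.family == "Romo":
            return 2 * ns + nd + nr
        return ns + nd + nr


def _uniform_duration(rng: np.random.Generator, lo: float, hi: float,
                      dt: float) -> float:
    """Draw U(lo, hi) and snap to the dt grid (at least one step)."""
    d = rng.uniform(lo, hi)
    return max(dt, round(d / dt) * dt)


def sample_trial_spec(task: TaskId, rng: np.random.Generator,
                      noise_sigma: float = 0.05, dt: float = 1.0,
                      timing: dict[str, TaskTiming] | None = None) -> TrialSpec:
    """Sample trial durations and amplitudes from the task-parameter table.

    Durations come from continuous uniform ranges (snapped to the ``dt``
    grid); amplitudes come from U(0, 1) for DM/CtxDM/Romo and from the
    discrete eight-level grid for the Go family.
    """
    tm = (timing or DEFAULT_TIMING)[task.family]
    t_stim = _uniform_duration(rng, *tm.stim_range, dt)
    t_delay = _uniform_duration(rng, *tm.delay_range, dt) if tm.delay_range else 0.0

    fam = task.family
    if fam in ("DM",):
        a = (rng.uniform(0.0, 1.0),)
    elif fam == "CtxDM":
        a = (rng.uniform(0.0, 1.0), rng.uniform(0.0, 1.0))
    elif fam == "Romo":
        a = (rng.uniform(0.0, 1.0), rng.uniform(0.0, 1.0))
    else:  # Go family: discrete grid
        a = (GO_AMPLITUDES[rng.integers(len(GO_AMPLITUDES))],)
    return TrialSpec(task, t_stim, t_delay, tm.t_resp, a, noise_sigma, dt)


# ---------------------------------------------------------------------------
# Trial rendering
# ---------------------------------------------------------------------------


@dataclass
class TrialTensor:
    """A rendered trial: inputs, targets, loss mask, and per-step phase codes."""

    inputs: np.ndarray        # [T, N_IN]
    targets: np.ndarray       # [T, N_OUT]
    mask: np.ndarray          # [T, N_OUT]
    phase: np.ndarray         # [T] int8, PHASE_* codes
    spec: TrialSpec

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[0]


def _choice_targets(first_wins: bool) -> tuple[float, float]:
    return (1.0, 0.0) if first_wins else (0.0, 1.0)


def render_trial(spec: TrialSpec, rng: np.random.Generator,
                 mask_values: tuple[float, float] = (1.0, 5.0)) -> TrialTensor:
    """Render a trial on the ``dt`` grid.

    The fixation input is 1 during the stimulus (and delay) phase and 0
    during the response phase; GoRt is the exception, holding fixation at 1
    for the whole trial while the fixation *target* drops to 0 once the
    stimulus appears.  Sensory channels are a deterministic profile plus
    N(0, sigma) noise on every step; the decision ground truth uses the
    deterministic amplitude, which is known at generation time.  The fixation
    target replicates the fixation input.  The mask carries
    ``mask_values[0]`` on stimulus/delay steps and ``mask_values[1]`` on
    response steps.
    """
    task, sig = spec.task, spec.noise_sigma
    ns = spec._steps(spec.t_stim)
    nd = spec._steps(spec.t_delay) if spec.t_delay else 0
    nr = spec._steps(spec.t_resp)
    T = spec.n_steps
    fam, mod = task.family, task.modality
    mcol = 1 + (mod - 1)  # sensory channel column of the trial's modality

    inputs = np.zeros((T, N_IN))
    targets = np.zeros((T, N_OUT))
    phase = np.empty(T, dtype=np.int8)
    inputs[:, 3:] = one_hot_task_vector(task)  # constant over the trial

    # phase layout
    if fam == "Romo":
        bounds = [ns, ns + nd, 2 * ns + nd, T]
        phase[: ns] = PHASE_STIMULUS
        phase[ns: ns + nd] = PHASE_DELAY
        phase[ns + nd: 2 * ns + nd] = PHASE_STIMULUS
        phase[2 * ns + nd:] = PHASE_RESPONSE
        resp0 = 2 * ns + nd
    elif fam == "GoDl":
        phase[: ns] = PHASE_STIMULUS
        phase[ns: ns + nd] = PHASE_DELAY
        phase[ns + nd:] = PHASE_RESPONSE
        resp0 = ns + nd
    else:
        phase[: ns] = PHASE_STIMULUS
        phase[ns:] = PHASE_RESPONSE
        resp0 = ns

    # fixation input: 1 while the network must hold, 0 during response
    if fam == "GoRt":
        inputs[:, 0] = 1.0  # held for the whole trial
    else:
        inputs[: resp0, 0] = 1.0

    # sensory profiles (deterministic part)
    a = spec.a_stim
    if fam == "DM":
        inputs[: resp0, mcol] += a[0]
        first_wins = a[0] < spec.u_th
    elif fam == "CtxDM":
        inputs[: resp0, 1] += a[0]
        inputs[: resp0, 2] += a[1]
        first_wins = a[mod - 1] < spec.u_th
    elif fam == "Romo":
        inputs[: ns, mcol] += a[0]
        inputs[ns + nd: resp0, mcol] += a[1]
        wins = a[0] > a[1]
        first_wins = wins if ROMO_FIRST_LARGER_IS_Y1 else not wins
    elif fam == "Go":
        inputs[:, mcol] += a[0]  # stimulus persists through the response phase
    elif fam == "GoRt":
        inputs[resp0:, mcol] += a[0]  # switches on after the fixation period
    elif fam == "GoDl":
        inputs[: ns, mcol] += a[0]  # short pulse only

    # additive sensory noise on both modality channels, every step
    if sig > 0:
        inputs[:, 1:3] += rng.normal(0.0, sig, size=(T, 2))

    # targets: fixation output replicates the hold requirement
    targets[: resp0, 0] = 1.0
    if task.is_choice:
        y1, y2 = _choice_targets(first_wins)
        targets[resp0:, 1] = y1
        targets[resp0:, 2] = y2
    else:
        targets[resp0:, mcol] = a[0]  # reproduce the stimulus magnitude

    mask = np.empty((T, N_OUT))
    mask[: resp0] = mask_values[0]
    mask[resp0:] = mask_values[1]
    return TrialTensor(inputs, targets, mask, phase, spec)


# ---------------------------------------------------------------------------
# Batch assembly
# ---------------------------------------------------------------------------


@dataclass
class BatchTensor:
    """Trials aligned to the longest by prepending all-zero input steps."""

    inputs: np.ndarray   # [T, B, N_IN]
    targets: np.ndarray  # [T, B, N_OUT]
    mask: np.ndarray     # [T, B, N_OUT]
    phase: np.ndarray    # [T, B] int8
    specs: list[TrialSpec]

    @property
    def n_steps(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_batch(self) -> int:
        return self.inputs.shape[1]


def assemble_batch(trials: Sequence[TrialTensor],
                   mask_values: tuple[float, float] | None = None) -> BatchTensor:
    """Align trials to the longest one; shorter trials get a leading all-zero
    prefix (all input channels, including the task code).  Padding steps carry
    zero mask weight.  If ``mask_values`` is given, masks are rebuilt from the
    phase codes (stimulus/delay -> first value, response -> second)."""
    if not trials:
        raise ValueError("assemble_batch requires at least one trial")
    T = max(t.n_steps for t in trials)
    B = len(trials)
    inputs = np.zeros((T, B, N_IN))
    targets = np.zeros((T, B, N_OUT))
    mask = np.zeros((T, B, N_OUT))
    phase = np.full((T, B), PHASE_PADDING, dtype=np.int8)
    for b, tr in enumerate(trials):
        o = T - tr.n_steps
        inputs[o:, b] = tr.inputs
        targets[o:, b] = tr.targets
        phase[o:, b] = tr.phase
        if mask_values is None:
            mask[o:, b] = tr.mask
        else:
            m = np.where(tr.phase[:, None] == PHASE_RESPONSE,
                         mask_values[1], mask_values[0])
            mask[o:, b] = m
    return BatchTensor(inputs, targets, mask, phase, list(trials))


def sample_batch(tasks: Sequence[TaskId], n_batch: int,
                 rng: np.random.Generator, noise_sigma: float = 0.05,
                 mask_values: tuple[float, float] = (1.0, 5.0),
                 timing: dict[str, TaskTiming] | None = None,
                 dt: float = 1.0) -> BatchTensor:
    """Sample ``n_batch`` trials of randomly selected tasks and align them."""
    trials = []
    for _ in range(n_batch):
        task = tasks[rng.integers(len(tasks))]
        spec = sample_trial_spec(task, rng, noise_sigma, dt, timing)
        trials.append(render_trial(spec, rng, mask_values))
    return assemble_batch(trials)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def save_trials_h5(path, trials: Sequence[TrialTensor]) -> None:
    """Write trials to an HDF5 container, one group per trial."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, tr in enumerate(trials):
            g = f.create_group(f"trial_{i:05d}")
            g.create_dataset("inputs", data=tr.inputs)
            g.create_dataset("targets", data=tr.targets)
            g.create_dataset("mask", data=tr.mask)
            g.create_dataset("phase", data=tr.phase)
            g.attrs["task"] = tr.spec.task.name
            g.attrs["a_stim"] = list(tr.spec.a_stim)
            g.attrs["noise_sigma"] = tr.spec.noise_sigma
            g.attrs["dt"] = tr.spec.dt


def trial_to_csv(trial: TrialTensor, path) -> None:
    """Write a single trial as CSV (one row per time step)."""
    header = (["phase", "u_fix", "u_mod1", "u_mod2"]
              + [f"u_task{i + 1}" for i in range(N_TASKS)]
              + ["y_fix_hat", "y1_hat", "y2_hat", "m_fix", "m1", "m2"])
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(header)
        for t in range(trial.n_steps):
            w.writerow([int(trial.phase[t])]
                       + list(trial.inputs[t]) + list(trial.targets[t])
                       + list(trial.mask[t]))
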