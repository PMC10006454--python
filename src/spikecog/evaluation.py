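"""Trial scoring and task-performance aggregation.

A trial passes the fixation criterion when the fixation output, averaged
over the stimulus (and delay) phase where its target is 1, exceeds 0.5;
otherwise the trial fails outright.  For choice tasks (DM, CtxDM, Romo) the
trial is correct when the response-phase average of the output whose target
is 1 exceeds the other; for repeat tasks (Go, GoRt, GoDl) it is correct when
the response-phase average of the modality output is within 0.15 of the
target amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .network import NetworkWeights, NeuronParams, SimulationTrace, simulate_trial
from .tasks import (PHASE_DELAY, PHASE_RESPONSE, PHASE_STIMULUS, TaskId,
                    TaskTiming, TrialTensor, render_trial, sample_trial_spec)

#: trial fails unless the stimulus-phase mean fixation output exceeds this
FIXATION_THRESHOLD = 0.5
#: repeat tasks: tolerated deviation of the response average from the target
REPEAT_TOLERANCE = 0.15


@dataclass
class TrialOutcome:
    """Scoring result for one trial."""

    task: TaskId
    mean_outputs: tuple[float, float]   # response-phase averages of (y1, y2)
    fixation_mean: float                # stimulus-phase average of y_fix
    fixation_ok: bool
    correct: bool


@dataclass
class PerformanceReport:
    """Per-task accuracy over repeated trials."""

    per_task: dict[str, float]
    n_trials: int

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_task.values())))


#: a simulator maps a rendered trial to an object with .Y (and .Z) traces
Simulator = Callable[[TrialTensor], SimulationTrace]


def network_simulator(w: NetworkWeights, p: NeuronParams,
                      kappa: float) -> Simulator:
    """Simulator closure over trained weights."""
    return lambda trial: simulate_trial(w, trial, p, kappa)


def oracle_simulator(n_neurons: int = 1) -> Simulator:
    """A readout that emits the targets exactly (spikeless); scores 100%."""

    def sim(trial: TrialTensor) -> SimulationTrace:
        T = trial.n_steps
        Z = np.zeros((T, n_neurons), dtype=bool)
        return SimulationTrace(V=np.zeros((T, n_neurons)),
                               A=np.zeros((T, n_neurons)),
                               Z=Z, Y=trial.targets.copy())

    return sim


def score_trial(trace: SimulationTrace | np.ndarray,
                trial: TrialTensor,
                fixation_mode: str = "mean") -> TrialOutcome:
    """Score one trial from its output trace.

    ``fixation_mode="mean"`` tests the stimulus-phase average of the fixation
    output against 0.5 (its target is 1 there); ``"per_step"`` requires every
    stimulus-phase sample to exceed 0.5.
    """
    Y = trace.Y if isinstance(trace, SimulationTrace) else np.asarray(trace)
    phase = trial.phase
    resp = phase == PHASE_RESPONSE
    hold = (phase == PHASE_STIMULUS) | (phase == PHASE_DELAY)
    if not resp.any():
        raise ValueError("trial has an empty response phase")
    y1 = float(Y[resp, 1].mean())
    y2 = float(Y[resp, 2].mean())
    fix_mean = float(Y[hold, 0].mean()) if hold.any() else 1.0
    if fixation_mode == "per_step":
        fix_ok = bool(np.all(Y[hold, 0] > FIXATION_THRESHOLD))
    else:
        fix_ok = fix_mean > FIXATION_THRESHOLD

    task = trial.spec.task
    if task.is_choice:
        target_first = trial.targets[resp, 1].max() > 0.5
        correct = fix_ok and ((y1 > y2) if target_first else (y2 > y1))
    else:
        mcol = task.modality  # output channel 1 or 2
        avg = y1 if mcol == 1 else y2
        target = trial.spec.a_stim[0]
        # small epsilon so the boundary |diff| = 0.15 counts despite rounding
        correct = fix_ok and abs(avg - target) <= REPEAT_TOLERANCE + 1e-12
    return TrialOutcome(task, (y1, y2), fix_mean, fix_ok, correct)


def evaluate(sim: Simulator, tasks: Sequence[TaskId], n_trials: int,
             rng: np.random.Generator, noise_sigma: float = 0.05,
             timing: dict[str, TaskTiming] | None = None,
             dt: float = 1.0) -> PerformanceReport:
    """Accuracy per task over ``n_trials`` freshly sampled trials each."""
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    per_task: dict[str, float] = {}
    for task in tasks:
        n_correct = 0
        for _ in range(n_trials):
            spec = sample_trial_spec(task, rng, noise_sigma, dt, timing)
            trial = render_trial(spec, rng)
            out = score_trial(sim(trial), trial)
            n_correct += out.correct
        per_task[task.name] = n_correct / n_trials
    return PerformanceReport(per_task, n_trials)


def evaluate_network(w: NetworkWeights, p: NeuronParams, kappa: float,
                     tasks: Sequence[TaskId], n_trials: int,
                     rng: np.random.Generator, **kw) -> PerformanceReport:
    """Convenience wrapper: evaluate trained weights directly."""
    return evaluate(network_simulator(w, p, kappa), tasks, n_trials, rng, **kw)


def mean_rate_table(sim: Simulator, tasks: Sequence[TaskId], n_trials: int,
                    rng: np.random.Generator, phase: str = "whole",
                    noise_sigma: float = 0.05,
                    timing: dict[str, TaskTiming] | None = None,
                    dt: float = 1.0) -> tuple[np.ndarray, list[str]]:
    """Neuron x (task, trial) mean firing rates in Hz.

    ``phase`` selects which trial steps enter the average: ``"stimulus"``
    (including delay), ``"response"`` or ``"whole"``.  Returns the raw rate
    matrix ``[N, n_tasks * n_trials]`` and per-column task labels; feed it to
    :class:`spikecog.clustering.RateTable` for normalisation and clustering.
    """
    if phase not in ("stimulus", "response", "whole"):
        raise ValueError(f"unknown phase {phase!r}")
    cols = []
    labels = []
    for task in tasks:
        for _ in range(n_trials):
            spec = sample_trial_spec(task, rng, noise_sigma, dt, timing)
            trial = render_trial(spec, rng)
            tr = sim(trial)
            if phase == "stimulus":
                sel = (trial.phase == PHASE_STIMULUS) | (trial.phase == PHASE_DELAY)
            elif phase == "response":
                sel = trial.phase == PHASE_RESPONSE
            else:
                sel = np.ones(trial.n_steps, dtype=bool)
            cols.append(tr.Z[sel].mean(axis=0) * (1000.0 / dt))
            labels.append(task.name)
    return np.column_stack(cols), labels
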