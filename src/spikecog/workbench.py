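"""Reproducible experiment orchestration.

One master seed spawns named substreams (weights, trials, noise, restarts)
so each component can be re-run in isolation; run configurations round-trip
through JSON; checkpoints are single HDF5 files holding the weight arrays
plus a JSON attribute block with the neuron parameters and configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .network import NetworkWeights, NeuronParams, default_params, init_weights
from .tasks import (ALL_TASKS, TaskId, TaskTiming, render_trial,
                    sample_trial_spec, scaled_timing, task_by_name)
from .training import TrainConfig

SCHEMA_VERSION = 1

#: canonical substream names, spawned in this fixed order
STREAM_NAMES = ("weights", "trials", "noise", "eval", "clustering")


class CheckpointError(RuntimeError):
    """Raised for unreadable, truncated or schema-incompatible checkpoints."""


def seed_streams(master_seed: int,
                 names=STREAM_NAMES) -> dict[str, np.random.Generator]:
    """Independent named generators derived from one master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class RunConfig:
    """Everything needed to reproduce a training run."""

    n_neurons: int = 600
    tasks: list[str] = field(default_factory=lambda: [t.name for t in ALL_TASKS])
    train: TrainConfig = field(default_factory=TrainConfig)
    neuron_overrides: dict = field(default_factory=dict)
    timing_overrides: dict = field(default_factory=dict)  # family -> [lo, hi, resp, dlo, dhi]
    n_eval_trials: int = 100
    master_seed: int = 0

    def task_ids(self) -> list[TaskId]:
        return [task_by_name(n) for n in self.tasks]

    def neuron_params(self) -> NeuronParams:
        p = default_params(self.n_neurons)
        return dataclasses.replace(p, **self.neuron_overrides)

    def timing(self) -> dict[str, TaskTiming] | None:
        if not self.timing_overrides:
            return None
        out = {}
        for fam, row in self.timing_overrides.items():
            lo, hi, resp = row[:3]
            delay = tuple(row[3:5]) if len(row) >= 5 else None
            out[fam] = TaskTiming((lo, hi), resp, delay)
        return out

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "RunConfig":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as f:
                d = json.load(f)
        d.pop("schema_version", None)
        tc = d.pop("train", {})
        tc["mask_values"] = tuple(tc.get("mask_values", (1.0, 5.0)))
        tc["adam"] = tuple(tc.get("adam", (0.9, 0.999, 1e-8)))
        return cls(train=TrainConfig(**tc), **d)


def full_scale_config(loss_variant: str = "mse", seed: int = 0) -> RunConfig:
    """The reference full-scale protocol: all 12 tasks, table timing,
    3000 epochs at eta = 5e-3; N = 600 (plain MSE, batch 50) or N = 256
    (rate-regularised, batch 32, v_th = 0.45, tau_out = 50 ms)."""
    from .training import mse_config, regularized_config

    if loss_variant == "mse":
        return RunConfig(n_neurons=600,
                         train=mse_config(n_epoch=3000, eta=5e-3, seed=seed),
                         master_seed=seed)
    return RunConfig(n_neurons=256,
                     train=regularized_config(n_epoch=3000, eta=5e-3, seed=seed),
                     master_seed=seed)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


@dataclass
class Checkpoint:
    """Self-describing snapshot: weights + neuron parameters + config."""

    weights: NetworkWeights
    params: NeuronParams
    config: RunConfig | None = None
    epoch: int = 0
    seed: int | None = None


def save_checkpoint(path, ckpt: Checkpoint) -> None:
    import h5py

    meta = {
        "schema_version": SCHEMA_VERSION,
        "epoch": ckpt.epoch,
        "seed": ckpt.seed,
        "neuron_params": asdict(ckpt.params),
        "config": json.loads(ckpt.config.to_json()) if ckpt.config else None,
    }
    with h5py.File(path, "w") as f:
        f.create_dataset("W_in", data=ckpt.weights.w_in)
        f.create_dataset("W_rec", data=ckpt.weights.w_rec)
        f.create_dataset("W_out", data=ckpt.weights.w_out)
        f.create_dataset("b", data=ckpt.weights.b)
        f.attrs["meta"] = json.dumps(meta)


def load_checkpoint(path) -> Checkpoint:
    import h5py

    try:
        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["meta"])
            if meta.get("schema_version") != SCHEMA_VERSION:
                raise CheckpointError(
                    f"schema version {meta.get('schema_version')} != {SCHEMA_VERSION}")
            w = NetworkWeights(f["W_in"][()], f["W_rec"][()],
                               f["W_out"][()], f["b"][()])
    except (OSError, KeyError) as e:
        raise CheckpointError(f"cannot read checkpoint {path}: {e}") from e
    params = NeuronParams(**meta["neuron_params"])
    cfg = None
    if meta.get("config"):
        cfg = RunConfig.from_json(json.dumps(meta["config"]))
    return Checkpoint(w, params, cfg, meta.get("epoch", 0), meta.get("seed"))


# ---------------------------------------------------------------------------
# Test fixtures
# ---------------------------------------------------------------------------


def make_fixture(kind: str, seed: int = 0):
    """Deterministic small objects for tests.

    ``tiny_net`` — a 3-neuron network with default parameters;
    ``canned_trials`` — short trials (20-step stimulus) for each family;
    ``planted_rate_table`` — 8 neurons in two well-separated rate blobs.
    """
    rng = np.random.default_rng(seed)
    if kind == "tiny_net":
        return init_weights(3, rng=rng), default_params(3)
    if kind == "canned_trials":
        timing = scaled_timing(stim_range=(20.0, 20.0), t_resp=10.0,
                               delay_range=(10.0, 10.0))
        trials = []
        for task in ALL_TASKS:
            spec = sample_trial_spec(task, rng, noise_sigma=0.05,
                                     timing=timing)
            trials.append(render_trial(spec, rng))
        return trials
    if kind == "planted_rate_table":
        from .clustering import RateTable

        low = rng.uniform(0.0, 5.0, size=(4, 6))
        high = rng.uniform(40.0, 50.0, size=(4, 6))
        rates = np.vstack([low, high])
        labels = [f"task{i % 3}" for i in range(6)]
        return RateTable.from_rates(rates, labels), np.array([0] * 4 + [1] * 4)
    raise ValueError(f"unknown fixture kind {kind!r}")
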