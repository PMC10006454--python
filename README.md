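# spikecog

Multitask spiking recurrent neural networks: a discrete-time adaptive
exponential (AdEx) integrate-and-fire network trained by surrogate-gradient
descent to perform twelve cognitive-neuroscience-inspired tasks, together
with the reverse-engineering battery used to understand *how* it performs
them — an accuracy protocol, PCA and demixed PCA of population dynamics,
k-means/Ward clustering of task-conditioned firing rates, and cluster
lesioning.

The package is for computational neuroscientists who want a transparent,
NumPy-level reference implementation of the "train a recurrent network on
cognitive tasks, then treat it as a dynamical system" workflow, with spiking
neurons instead of rate units.

## The model

The network has `N` AdEx neurons driven through an input matrix `W_in`,
coupled all-to-all by `W_rec` (zero diagonal — no self-excitation), and read
out through `W_out` and a bias `b`. On a `Δt = 1` ms grid:

```
v_j(n+1) = v_j(n) + (Δt/τ_m) [ −v_j(n) + θ·exp((v_j(n)−v_th)/θ) + I_j(n) − a_j(n) ]
a_j(n+1) = a_j(n) + (Δt/τ_a) [ a_current·v_j(n) − a_j(n) ]
I_j(n+1) = I_j(n)(1 − Δt/τ_s) + Σ_k W_in[j,k]·u_k(n+1) + Σ_k W_rec[j,k]·z_k(n)
```

with spikes `z_j(n) = H(v_j(n) − v_th)` (H(0) = 1); a spiking neuron resets
`v → v_reset` and `a → a + a_s`. Outputs are exponential filters of the spike
trains, `y(n+1) = κ·y(n) + W_out·z(n) + b` with `κ = exp(−Δt/τ_out)`. The slow
adaptation variable (`τ_a = 2 s`) is what gives the network enough dynamic
memory for the delayed tasks.

Inputs per trial are `u = (u_fix, u_mod1, u_mod2, u_tasks)`: a binary
fixation channel, two noisy sensory channels (`u_mod = u_0 + N(0, σ)`), and a
constant one-hot task code — `N_in = 12 + 3`. Six task families × two
modalities give 12 tasks: choice tasks (**DM**, **CtxDM**, **Romo**) with a
binary target, and repeat tasks (**Go**, **GoRt**, **GoDl**) that must
reproduce a stimulus amplitude.

Training minimises a masked mean-squared error over the batch tensor
(optionally plus a firing-rate regulariser `λ·Σ_i f_i·H(f_i − f_th)`), with
the SuperSpike pseudo-derivative `σ'(v) = (1 + |α(v − v_th)|)^−2` standing in
for the spike threshold in the backward pass only. Two gradient routes over
the identical surrogate-smoothed graph are provided — forward-mode
sensitivity recursions and reverse-mode backpropagation through time — and a
test pins them to each other at 1e-6 relative error.

## Worked example

Train a 128-neuron network on four tasks at desk scale (shortened stimulus
periods, ~2 minutes on one CPU core), score it with the accuracy protocol,
then cluster and lesion it:

```python
import numpy as np
import spikecog as sc

streams = sc.seed_streams(1)

tasks = [sc.task_by_name(n) for n in ("DM1", "DM2", "Go1", "Go2")]
timing = sc.scaled_timing(stim_range=(200.0, 500.0), t_resp=250.0)
cfg = sc.mse_config(n_batch=16, n_epoch=500, eta=5e-3, seed=1)
w = sc.init_weights(128, rng=streams["weights"])
p = sc.default_params(128)
w, history = sc.train(w, p, cfg, tasks, streams["trials"], timing=timing)
print(f"loss: {history[0]['loss']:.2e} -> {history[-1]['loss']:.2e}")

report = sc.evaluate_network(w, p, cfg.kappa, tasks, 100,
                             streams["eval"], timing=timing)
for name, acc in report.per_task.items():
    print(f"{name}: {acc:.2f}")
print(f"mean accuracy: {report.mean:.4f}")

sim = sc.network_simulator(w, p, cfg.kappa)
rates, labels = sc.mean_rate_table(sim, tasks, 25, streams["clustering"],
                                   timing=timing)
table = sc.RateTable.from_rates(rates, labels)
part = sc.kmeans_cluster(table, 2, streams["clustering"])
big = int(np.bincount(part.labels).argmax())
wl = sc.lesion(w, part, sc.LesionSpec(big, "lesion"))
lesioned = sc.evaluate_network(wl, p, cfg.kappa, tasks, 50,
                               streams["eval"], timing=timing)
print(f"after lesioning cluster {big} "
      f"({np.sum(part.labels == big)} neurons): {lesioned.mean:.4f}")
```

Output:

```
loss: 1.00e-05 -> 6.04e-07
DM1: 0.97
DM2: 0.96
Go1: 0.92
Go2: 1.00
mean accuracy: 0.9625
after lesioning cluster 0 (98 neurons): 0.3800
```

The loss falls by an order of magnitude; the trained network solves each
task on ≥92% of fresh trials; silencing the 98-neuron cluster that carries
most of the activity drops mean accuracy from 0.96 to 0.38, confirming its
causal role.

The full-scale protocol (600 neurons, all 12 tasks, full trial durations,
3000 epochs — several CPU-hours) is exposed unchanged as
`sc.full_scale_config("mse")` / `sc.full_scale_config("mse_reg")` and can be
run with the CLI:

```
spikecog train --config run.json --out ckpt_dir/
spikecog evaluate --ckpt ckpt_dir/final.h5 --n 100 --seed 11 --report report.json
spikecog lesion-screen --ckpt ckpt_dir/final.h5 --clusters auto --n 200 --out screen.csv
```

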