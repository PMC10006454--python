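# Methods

This note documents the model, the numerical choices, and the open design
decisions made in `spikecog`, in the spirit of a model-description appendix.

## Neuron and network model

Each unit is an adaptive exponential (AdEx) integrate-and-fire neuron with
membrane potential `v`, adaptation variable `a`, and synaptic current `I`,
integrated by the forward Euler method on a `Δt = 1 ms` grid (see the README
for the update equations). Default parameters:

| parameter | value | meaning |
|---|---|---|
| `τ_m` | 10 ms | membrane relaxation |
| `τ_a` | 2 s | adaptation time; the slow variable that stores stimulus memory |
| `τ_s` | 5 ms | synaptic current relaxation |
| `v_th` | 0.65 mV (0.45 mV when N = 256) | spike threshold |
| `v_reset` | 0 mV | post-spike reset |
| `θ` | 0.5 mV | sharpness of the exponential spike-initiation term |
| `a_s` | 0.02 nA | adaptation increment per spike |
| `a_current` | 4 nS | adaptation–voltage coupling |

All quantities are treated as the dimensionless numbers above; no unit
conversion is applied inside the update (the nominal units are kept only as
documentation).

Within one step the order of operations is: (1) integrate the synaptic
current with the new input row and the previous step's spikes; (2) detect
spikes from the pre-reset potential, with `H(0) = 1` so a potential exactly
at threshold fires; (3) reset spiking neurons (`v → v_reset`,
`a → a + a_s`); (4) apply the Euler update from the post-reset state. This
ordering produces exactly one spike per threshold crossing per step. A
consequence worth noting: after the first step the exponential term is only
ever evaluated at sub-threshold or reset potentials, so its linearisation
factor is ≤ 1 and the gradient recursions are contractive. The exponential
argument is nevertheless capped at +20 as a guard against transient
excursions in untrained networks; the cap never binds below
`v_th + 10 mV`.

The recorded output sample `Y[n]` is the readout value that first reflects
the spikes `z(n)` (i.e. `y(n+1)` of the filter recursion) and is compared
against target row `n`; this is a deliberate one-sample alignment choice on
the 1 ms grid.

Initial trial state is `v = a = I = y = 0`; traces expose their final state
so trials can be chained (the end state of one trial seeding the next).

## Task battery

Twelve tasks = six families × two sensory modalities, rendered as
`[T, 15]` input tensors (fixation, two noisy sensory channels, constant
one-hot task code). Trial durations are drawn from continuous uniform
ranges (stimulus 300–1800 ms for DM/CtxDM/Go/GoRt, 200–600 ms for
GoDl/Romo; delays 200–1700 ms for GoDl/Romo; responses 250 ms, 1500 ms for
GoRt) and snapped to the `Δt` grid. Amplitudes are U(0, 1) for DM, CtxDM
and Romo, and uniform over the discrete grid {0, 1/7, …, 6/7, 1} for the Go
family.

Decisions in the battery are defined against the *deterministic* stimulus
mean `u_0`, not the realised noisy average: the generator knows `u_0`, and
using it keeps the label noise-free. The sensory noise level σ defaults to
0.05 (≈5% of the full amplitude range) — a level at which a 0.1-wide
amplitude margin is resolvable by temporal averaging over a few hundred
milliseconds, which is what we consider realistic for this kind of
evidence-integration setting; it is exposed in configuration.

Two documented ambiguities are resolved as follows and kept as flags:

* **GoRt fixation.** The task descriptions assign held fixation to GoRt
  (the network must suppress the fixation *output* after stimulus onset
  while the fixation *input* stays 1) and fixation-offset cueing to GoDl;
  one sentence in the training description instead names the delayed task
  as the exception. We follow the task descriptions.
* **Romo polarity.** First pulse larger → target (1, 0), per the methods
  text; the figure caption states the opposite. `ROMO_FIRST_LARGER_IS_Y1`
  flips it.
* **Romo pulse duration.** Both pulses share one duration draw from
  U(200, 600) ms (the wording is ambiguous between one shared draw and two
  independent ones).

Batches align trials to the longest by *prepending* all-zero input steps —
all 15 channels, including the task code, are zeroed in the padding, and
the padding carries zero mask weight (no learning signal).

## Loss and gradients

The masked MSE uses the printed denominator
`N_out · N_batch · N_step · Σm`; a `masked_mean` switch divides by `Σm`
alone. The two differ by a constant factor, which Adam absorbs, so the
choice has no effect on trained behaviour — only on the absolute loss
scale. The rate regulariser `E_r = Σ_i f_i H(f_i − f_th)` (rates in Hz,
threshold 30 Hz, H(0) = 1) treats the indicator as piecewise constant in
the backward pass.

Surrogate-gradient contract: the forward pass uses the hard Heaviside; the
SuperSpike pseudo-derivative `(1 + |α(v − v_th)|)^−2` with α = 100 replaces
`dz/dv` in the backward pass only, evaluated at the pre-reset potential.
The reset jump is gradient-transparent (no derivative through the reset
assignments, including the `a_s` increment), matching sensitivity
recursions that carry no reset terms.

The gradient is computed over the full trial (no truncation) by two
independent routes over the identical graph:

* **Forward mode** (`forward_sensitivities`): per-parameter tangents of
  `(v, a, I, y)` propagated through the linearised dynamics. The published
  per-neuron recursion form is ambiguous about the spike-drive indexing and
  omits the synaptic-filter pathway; we implement the exact forward-mode
  differential of the discrete dynamics — including the `τ_s`-filtered
  current sensitivity and cross-neuron spike propagation through the
  surrogate — which is the unique resolution that makes forward and reverse
  mode agree. Cost is O(P·N·T) for P parameters, so this route is for small
  instances and for the equivalence test.
* **Reverse mode** (`bptt_gradients`): the transpose recursion, O(N²·T),
  used by the training loop. This matches how such networks are trained in
  practice with autodiff frameworks.

A test pins the two routes to < 1e-6 relative error (they agree to machine
precision), and readout gradients are additionally checked against central
finite differences, which are exact for `W_out` because the readout cannot
influence spiking.

Optimisation is Adam with standard coefficients (β₁ = 0.9, β₂ = 0.999,
ε = 1e-8; not specified beyond "standard" in the source protocol), learning
rate 5e-3 by default (the best of the documented {5e-2, 5e-3, 5e-4} sweep,
available as `LEARNING_RATE_SWEEP`). The recurrent diagonal is re-zeroed
after every update. The regulariser weight λ defaults to 1 (never given
numerically; exposed in configuration).

Two loss presets mirror the two training regimes: plain MSE (mask weights
1/5 for stimulus/response, `τ_out = 2 ms`, batch 50) and rate-regularised
(mask 0.1/1, `τ_out = 50 ms`, batch 32, `v_th = 0.45` at N = 256).

## Evaluation protocol

A trial fails outright unless the fixation output, averaged over the steps
where its target is 1 (stimulus + delay), exceeds 0.5; the exact timing of
this check is ambiguous in the source description, so a `per_step` mode is
available. Choice tasks are scored by comparing the response-phase averages
of the two outputs (the one whose target is 1 must be larger); repeat tasks
require the response-phase average of the modality output to lie within
0.15 of the target amplitude ("≈ 0.15" implemented as exactly 0.15, with a
1e-12 guard so the boundary case counts). GoRt is scored on the output
channel only; the fixation trajectory is recorded in the outcome for
inspection.

## Analysis battery

* **PCA** runs separately on membrane potentials and adaptation variables
  (their time scales differ by two orders of magnitude), with per-neuron
  mean removal and no variance scaling.
* **Instantaneous rates** use a causal 50 ms boxcar (kernel shape
  unspecified in the source; configurable).
* **Demixed PCA** is the plain marginalisation-average decomposition
  `X = X_t + X_s + X_d + X_noise` over a complete (neuron × stimulus ×
  decision × time) tensor: `X_t` is the condition mean (including the grand
  mean), `X_s`/`X_d` are the decision-/stimulus-averaged tensors minus
  `X_t` (each marginal keeps its time course), and the residual holds the
  condition interaction plus trial noise. In a complete factorial layout
  the terms are exactly orthogonal and their sums of squares add to the
  total. Per-marginalisation PCA then yields demixed components. The fully
  regularised reduced-rank variant of dPCA is deliberately out of scope:
  only the additive decomposition is specified by the method we follow.
  In deterministic tasks the decision is a function of the stimulus, so a
  genuine 2×2 stimulus-by-decision factorial is not realisable from
  generated trials alone; the shipped analyses therefore vary the stimulus
  axis and leave the decision axis singleton (its marginal is then
  identically zero, with a warning).
* **Clustering**: the rate table is `[N, n_tasks · n_trials]` mean rates
  (100 trials per task in the reference protocol), normalised by its
  maximum entry. k-means is Lloyd's algorithm (scikit-learn backend, best
  of `n_restarts`); Ward linkage comes from scipy with merge heights
  converted to the within-cluster sum-of-squares increase `R = h²/2`, the
  form in which the merge criterion is usually stated. Both are validated
  against hand-written brute-force oracles (exhaustive partition
  enumeration; O(n³) agglomeration). The cluster count is not fixed by the
  protocol (the reference analysis shows ≥13 clusters at full scale);
  the default is chosen by maximum silhouette over k ∈ [2, 20].
* **Lesioning** zeroes a cluster's *outgoing* weights — with
  `I_rec_j = Σ_k w_rec[j,k] z_k`, neuron c's outgoing weights are column c
  of `W_rec`, plus its `W_out` columns. Isolation keeps only the cluster's
  readout columns and cuts recurrent links *into* the cluster from
  non-cluster neurons; external input through `W_in` is left intact (the
  alternative of also cutting `W_in` to non-cluster neurons is noted but
  not what the procedure describes). Both operate on copies.

## Reproducibility and problem sizes

One master seed spawns named substreams (`weights`, `trials`, `noise`,
`eval`, `clustering`), so components are individually re-runnable;
end-to-end determinism (identical weight trajectories and reports for the
same master seed) is covered by a test. Checkpoints are single HDF5 files
with the four weight arrays and a JSON attribute block.

The shipped test suite and the acceptance script use desk-scale problem
sizes chosen so the whole pipeline runs in minutes on one CPU core: a
128-neuron network on the DM₁/DM₂/Go₁/Go₂ subset with stimulus durations
U(200, 500) ms, batch 16, 500 epochs. Under these conditions the trained
network reliably exceeds 80% mean accuracy (≈96% in our runs). The
full-scale protocol (N = 600, 12 tasks, full durations, 3000 epochs, which
reaches >95% at full scale) is exposed verbatim as a run configuration but
is not executed by the tests; several CPU-hours are required.

## Known limitations

* The synthetic battery has noise-free labels and stationary stimulus
  statistics; passing tests therefore demonstrate the training and analysis
  machinery, not robustness to the richer variability of behavioural data.
* Forward-mode sensitivities are exact but scale with the parameter count;
  they are a verification tool, not a training path.
* dPCA here is the additive decomposition only (no regularisation, no
  reduced-rank regression), appropriate for trial-averaged, balanced
  condition tensors.
* No Dale's principle, synaptic delays, or conductance-based synapses: the
  network is deliberately unconstrained so training shapes the structure.
* Chaotic/metastable dynamics of trained networks are reported
  descriptively through projections; no fixed-point analysis or dynamical
  certification is attempted.
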