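# Methods

This note documents the model, the training criterion, the synthetic
tasks, and the numerical and design choices the package makes.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Neuron model

Each hidden unit is a three-compartment spiking neuron: a soma `U_m` and
two point dendrites, one inhibitory (`U_i`) and one excitatory (`U_e`).
All compartments are leaky integrators; the dendrites couple into the
soma through conductances relative to reversal potentials:

    tau_m dU_m/dt = -U_m + R_m I_m + g_i (U_i - theta_i) + g_e (U_e - theta_e) - Gamma z
    tau_i dU_i/dt = -U_i + R_i I_i
    tau_e dU_e/dt = -U_e + R_e I_e

A spike is emitted when `U_m >= Gamma` outside the refractory period;
the `-Gamma z` term implements a soft reset (the threshold value is
subtracted, the neuron is not clamped to rest).  The threshold adapts:

    Gamma(t) = tau0 + alpha * a(t),
    a(t+dt)  = beta a(t) + (1 - beta) z(t),   beta = exp(-dt / tau_a)

With `tau_a = 700 ms` the threshold carries a slow trace of recent
firing — this spike-frequency adaptation is the working-memory substrate
in the store–recall task.

Default parameters: `tau_m = 20 ms`, `R = 1`, `theta_i = theta_e = 0`,
`g_i = g_e = 1`, `alpha = 1.8`, `tau0 = 0.01`, `tau_a = 700 ms`, all
synaptic delays 5 ms.  Choices the reference parameter set leaves open:
dendritic time constants (`tau_i = tau_e = 20 ms`, same as the soma),
refractory period (3 ms), integration scheme (explicit Euler at
`dt = 1 ms`; the contract `dt <= min(tau)/2` is enforced).  Spikes are
stored as `z in {0,1}`; because every update term is already multiplied
by `dt`, the dynamics are invariant to the `{0, 1/dt}` amplitude
convention.

## Network

Three layers.  Input channels project to all three compartments; hidden
neurons are laterally connected (10% sparsity by default); the soma
drives non-spiking leaky-integrator readouts `lambda_i(t)`
(`tau_out = 20 ms` by default).  Six projections exist, one per (source,
compartment) pair.  Every synapse has a fixed sign drawn at
initialization: projections onto the inhibitory dendrite are negative,
onto the excitatory dendrite positive, somatic projections mix both.
Weight magnitudes are Gaussian with scale `w0/sqrt(n_pre)`,
`w0 = dt/R_m`; the three recurrent matrices are jointly rescaled so the
spectral radius of their sum is at most 0.95, which bounds the recurrent
gain and avoids exploding gradients.

Deep rewiring: training updates non-negative magnitudes; a magnitude
crossing zero disconnects its synapse and an equal number of dormant
synapses reconnect at magnitude 0 with their stored sign, so sparsity is
exactly conserved and no sign ever flips.  The L1 pressure is 0.01 and
the rewiring temperature 0 (no exploratory noise).

## Training

Spikes are not differentiable; the backward pass substitutes the
triangular pseudo-derivative `dz/dv = k max(0, 1 - |v|)` with `k = 0.3`
of the normalized potential `v = (U_m - Gamma)/Gamma`, and otherwise
backpropagates exactly through the unrolled dynamics — including the
adaptive-threshold path, the soft reset and the synaptic delays.  The
backward pass is hand-derived (no autodiff framework is used); its
correctness is established against central finite differences of a
smooth "surrogate forward" in which the spike function is replaced by
the pseudo-derivative's primitive — on that graph the chain rule used by
the backward pass is exact, and the test suite requires agreement to a
relative error of 1e-4 (observed ~1e-9).  Refractory-gated steps
contribute no spike gradient.

Optimization is ADAM (`beta = (0.9, 0.999)`, `eps = 1e-8`) applied to
the synapse magnitudes (so the deep-rewiring sign constraint composes
with it) and to the dense readout weights and bias.

### The error-entropy criterion

Minimum-error-entropy learning minimizes the Rényi quadratic entropy
`H2(e) = -log V(e)` of the prediction errors, where the information
potential `V(e) = (1/N^2) sum_ij G_sigma(e_i - e_j)` is a kernel measure
of error concentration.  `V` is shift-invariant, so plain MEE cannot fix
the error distribution's location.  The restricted criterion (RMEE) pins
it to the codebook `C = (0, -1, 1)`: errors are counted into
`Phi = (phi_0, phi_-1, phi_1)` (out-of-range and boundary samples clamp
to the nearest codeword, ties at |e| = 0.5 to the center, so the counts
always sum to N) and the potential becomes

    V_R(e) = (1/N^2) sum_i [phi_0 G(e_i) + phi_-1 G(e_i + 1) + phi_1 G(e_i - 1)].

The half-quadratic reformulation introduces per-sample auxiliaries
`u_i, v_i, s_i in [-1, 0)`; for fixed auxiliaries the objective

    J_R2 = sum_i [phi_0 u_i e_i^2 + phi_-1 v_i (e_i+1)^2 + phi_1 s_i (e_i-1)^2]

is quadratic in the errors, and alternating auxiliary refresh with
quadratic maximization never decreases `V_R` (property-tested over 5000
random alternations).

Sign convention: the trainers minimize losses, so the RMEE contribution
is `-J_R2 / N^2` — minimizing it maximizes `V_R`.  The `1/N^2`
normalization matches `V_R` and keeps the weighting constant `mu`
meaningful across batch sizes.  The kernel bandwidth defaults to
`sigma = 1` (configurable); with errors confined to [-1, 1] by
construction a unit bandwidth keeps all three codeword kernels active.

Supervised tasks use the combined criterion
`mu * RMEE + (1 - mu) * cross-entropy` with errors
`e = label - sigmoid(readout)` at task-defined readout instants and
probabilities clamped to `[1e-12, 1 - 1e-12]` before logs.  `mu`
defaults to 0.8 (the favorable intermediate regime; `mu = 1` is
RMEE-only, `mu = 0` cross-entropy-only).

### Firing-rate regularization

A penalty pulls each hidden neuron's rate toward `f0 = 10 Hz`.  The
standalone operation implements the spike-count form
`mu_f (1/n) sum_j (count_j - f0 K T)^2`.  Inside the trainers the
equivalent per-step-rate normalization is used (identical up to a
`(KT)^2` factor), because the count form's gradient grows with the
episode budget and, at full strength, pins rates to `f0` before the task
can be learned.  The trainer default `mu_f = 20` (supervised; 2 in the
navigation preset) keeps trained networks in the 10–50 Hz range while
learning succeeds.

### Reward learning

Algorithm: per iteration, collect `K` episodes of `T` steps under the
current policy, then update with the clipped PPO surrogate
(`clip_eps = 0.2`) plus a value-error term (coefficient 0.5), the rate
penalty, an optional entropy bonus, and the RMEE term applied to
per-episode value errors `e_n = mean_t(Omega(t) - V(t))` (`N = K`
samples; on iteration 0 the counts are overridden to `(N, 0, 0)`).
Returns are strictly-future discounted sums
`Omega(t) = sum_{t'>t} gamma^{t'-t} r(t')` with `gamma = 0.99`; because
`Omega(t)` excludes the current reward, the advantage of the action at
`t` is `r_t + Omega(t) - V(t)` (otherwise the action that reaches the
goal would receive no credit).  Advantages are normalized per batch.
Replay epochs (2) re-simulate the recorded input streams through the
updated network, the standard treatment for recurrent PPO.

## Tasks

All generators are pure functions of (parameters, seed); no external
data is needed.

**Store–recall.**  40 input channels: two 10-channel value streams
(frames of 10 steps, the active stream firing Poisson at 50 Hz), a
10-channel store-command group and a 10-channel recall-command group
that fire synchronously through their 10-step windows.  The target is
the stream active during the store frame; value streams are silenced
during the recall window so the answer must come from memory.  The label
is read over the last 10 steps of the recall window (replicated per
step), which averages out single-step readout noise.  Chance level is
0.5; untrained networks measure 0.48–0.55 across seeds (the slow
threshold adaptation itself carries a faint stimulus trace).

**Noisy sequential classification.**  Ten procedurally drawn 28x28
binary glyphs stand in for digit images so the repository needs no
download; clean glyphs are exactly template-separable.  Images are
flattened (784 pixels, zero-padded to 800) and streamed at 40 channels x
20 steps per image, five images per trial plus 20 blank steps.  The
label of image n is 1 iff its class lies in the target half of the class
inventory (mirroring a 0–4 vs 5–9 digit split), read at
`t = 20 + 20n` — one image-length after the image ends.  Salt-and-pepper
corruption replaces each pixel independently with 0 or 1 (equal odds)
with the configured probability; robustness runs train on clean streams
and evaluate at 10% corruption.

**2D navigation.**  A point agent in the unit square moves by Gaussian
policy actions: mean `(tanh l1, tanh l2)`, variances
`(sigmoid l3, sigmoid l4)`, samples norm-clipped to a maximum speed of
0.02 per step; `l5` predicts the value.  Positions are Gaussian
population-rate encoded (`rate = 500 exp(-100 (xi_i - xi)^2)` Hz, Poisson
thinned per step).  Reaching the goal disc (radius 0.05) yields reward 1,
a 5-step synchronous burst on the positive-reward input group, and a
teleport to a fresh uniform position.  Two destination regimes exist:
`per_reset` (a fresh goal each time) and `fixed` (one goal per run, the
water-maze setting where the platform stays put across trials).  The
desk-scale experiment uses the fixed regime: at the prescribed budget
(5 episodes x 200 steps x 150 iterations) the per-reset variant yields
on the order of 75 reward events spread over ever-changing goals, too
few for policy-gradient learning to bootstrap, while the fixed-goal
variant learns reliably.  The preset also makes three policy-head
choices dictated by scale analysis: readout weights initialized 8x
larger than the hidden default (so the tanh/sigmoid head has O(1)
dynamic range against unit-scale action noise), a 10 ms readout
integrator (a 20 ms lag corresponds to 0.4 distance units at full speed,
eight times the goal radius), and variance-channel biases initialized to
-2 with an entropy bonus of 0.015 (exploration without collapse).

## What the synthetic data does and does not show

The generators reproduce the *structure* of the benchmark tasks —
Poisson-coded commands, pixel-serialized images with impulsive noise,
sparse-reward navigation — at sizes a single CPU core trains in minutes.
They do not reproduce the statistics of handwritten digits (glyphs are
noise-free templates, so clean-set accuracy ceilings are higher and
class confusability lower than MNIST), nor full-scale episode budgets
(the reference setting is K = 10 episodes of T = 2000 steps; the presets
use 96-episode batches of 100 steps, 5 x 200 for navigation, and
16-trial batches of 120 steps).  Passing tests therefore demonstrate
that the machinery — losses, gradients, rewiring, encoders, trainers —
is correct and that the qualitative findings (learnability of
store-recall, a DRN learning trend, the advantage of intermediate `mu`
under impulsive noise) hold at desk scale; they do not certify
full-scale accuracy figures.

## Numerical choices

- Probability clamp `[1e-12, 1 - 1e-12]` before every log.
- Quantization tie-break: |e| = 0.5 counts to the center codeword.
- Time and sample indices are 0-based half-open internally; the
  sequential readout schedule is exposed as the 1-based formula
  `t = 20 + 20n`.
- The HQ gradient is exposed as the error-side factor
  `dJ_R2/de_i = 2[phi_0 u_i e_i + phi_-1 v_i (e_i+1) + phi_1 s_i (e_i-1)]`
  — each codeword term pairing its own count and auxiliary — and BPTT
  supplies `de/dparameters`; for a logistic readout this subsumes the
  `y(1-y)x` chain factor a direct regression derivation would hard-code.
- Degenerate all-zero codebooks are allowed and give `V_R = 0`.
- ADAM moments are kept per synapse slot across rewiring swaps;
  reactivated synapses inherit the slot's stale moments (second-order
  effect at the observed swap rates).

## Known limitations

- Scalar errors only: each readout contributes one error sample; the
  full covariance-matrix kernel is out of scope.
- Homogeneous 5 ms delays per projection; no per-synapse delay learning.
- The PPO auxiliary coefficients (value 0.5, entropy 0-0.015) are
  conventional defaults, not derived quantities.
- Reward learning replays rollouts under the updated policy without
  importance-correcting the *inputs* (the recorded spike streams were
  generated under the old policy's trajectory); this is the standard
  recurrent-PPO approximation and is exact for the first epoch.
- The IDX reader enables runs on real digit images but no shipped test
  exercises the network on them.
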