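"""Surrogate-gradient BPTT training.

The forward simulation is non-differentiable at the spike threshold;
training replaces dz/dv with the triangular pseudo-derivative
k*max(0, 1-|v|) and otherwise backpropagates exactly through the unrolled
dynamics (compartments, adaptive threshold, soft reset, delays, leaky
readouts).  The backward pass here is hand-derived; its correctness is
checked against central finite differences of the smooth "surrogate
forward" (spike function replaced by the pseudo-derivative's primitive),
on which the chain rule used here is exact.

Two trainers are provided:

* ``train_supervised`` — minimizes the combined criterion
  mu * RMEE + (1 - mu) * cross-entropy at task-defined readout times,
  with errors e = label - sigmoid(readout).
* ``train_reward`` — proximal-policy-optimization (clipped surrogate)
  reward learning; per-episode value errors e_n = mean_t(Omega - V)
  feed the RMEE term, with the quantization counts overridden to
  (N, 0, 0) on the first iteration.

Both add a firing-rate regularizer pulling hidden rates toward the target
f0 = 10 Hz, optimize with ADAM, and apply sign-preserving deep rewiring
to the sparse projections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np

from . import itl_losses as itl
from .itl_losses import (ErrorBatch, KernelSpec, hq_auxiliaries, quantize_errors,
                         rmee_gradient, rmee_hq_objective)
from .neuron import pseudo_derivative
from .network import (NetworkConfig, NetworkStepper, SpikingNetwork, Trace,
                      init_network, rewire_step, PROJECTIONS)
from .tasks import discounted_returns, NavigationTask

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "Adam",
    "bptt_gradients",
    "firing_rate_regularizer",
    "ppo_loss",
    "train_supervised",
    "train_reward",
    "evaluate_supervised",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite; carries the iteration index."""

    def __init__(self, iteration: int):
        super().__init__(f"training diverged at iteration {iteration}")
        self.iteration = iteration


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    ``mu`` weights the RMEE term against cross-entropy (supervised) or
    against the PPO loss (reward learning); ``mu_f`` scales the
    firing-rate regularizer (applied on spikes-per-step rate units);
    ``f0`` is the target rate in Hz.  ``K`` episodes of ``T`` steps are
    generated per iteration in reward learning; the desk-scale experiment
    presets shrink both.
    """

    mu: float = 0.8
    mu_f: float = 20.0
    f0: float = 10.0            # Hz
    sigma: float = 1.0          # RMEE kernel bandwidth
    lr: float = 1e-3
    K: int = 10
    T: int = 2000
    gamma: float = 0.99
    clip_eps: float = 0.2
    n_iterations: int = 100
    batch_size: int = 32        # supervised episodes per iteration
    value_coef: float = 0.5
    entropy_coef: float = 0.0
    ppo_epochs: int = 2
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.f0 <= 0:
            raise ValueError("target firing rate must be positive")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("discount factor must lie in [0, 1)")


@dataclass
class TrainHistory:
    """Per-iteration training records (loss terms, rates, task metric)."""

    records: list = field(default_factory=list)

    def append(self, **kwargs) -> None:
        rec = {k: (float(v) if np.isscalar(v) or isinstance(v, np.floating) else v)
               for k, v in kwargs.items()}
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def column(self, key: str) -> np.ndarray:
        return np.array([r[key] for r in self.records])

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


class Adam:
    """ADAM optimizer over a dict of named parameter arrays."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t: dict = {}

    def step(self, key: str, grad: np.ndarray) -> np.ndarray:
        """Return the additive update (to be subtracted from the parameter)."""
        if key not in self.m:
            self.m[key] = np.zeros_like(grad)
            self.v[key] = np.zeros_like(grad)
            self.t[key] = 0
        self.t[key] += 1
        t = self.t[key]
        self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
        self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad**2
        mhat = self.m[key] / (1 - self.beta1**t)
        vhat = self.v[key] / (1 - self.beta2**t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the backward pass


def bptt_gradients(net: SpikingNetwork, trace: Trace, g_lam: np.ndarray,
                   g_z_direct: Optional[np.ndarray] = None) -> dict:
    """Backpropagate through a stored simulation.

    ``g_lam`` is dL/dlambda over (B, T, n_out); ``g_z_direct`` an optional
    dL/dz over (B, T, H) (e.g. the firing-rate regularizer).  Returns
    gradients of the signed weights of all six projections plus the
    readout weights and bias.  At every spike nonlinearity dz/dv is the
    pseudo-derivative (exact when the trace came from a surrogate-mode
    forward); refractory-gated steps contribute no spike gradient.
    """
    if trace.z.size == 0:
        raise ValueError("trace has no stored steps")
    cfg = net.config
    p = cfg.neuron
    B, T, H = trace.z.shape
    g_lam = np.asarray(g_lam, dtype=float)
    if g_lam.shape != trace.lam.shape:
        raise ValueError(f"g_lam shape {g_lam.shape} != readout shape {trace.lam.shape}")

    W = {k: w.weights for k, w in net.wirings.items()}
    d = {k: w.delay for k, w in net.wirings.items()}
    rho_m, rho_i, rho_e = 1 - p.dt / p.tau_m, 1 - p.dt / p.tau_i, 1 - p.dt / p.tau_e
    rho_o = 1 - cfg.dt / cfg.tau_out
    beta = p.beta

    GL = g_lam.copy()
    Gz = np.zeros((B, T, H)) if g_z_direct is None else np.array(g_z_direct, dtype=float)
    GUm = np.zeros((B, T, H))
    GUi = np.zeros((B, T, H))
    GUe = np.zeros((B, T, H))
    Ga = np.zeros((B, T, H))
    GG = np.zeros((B, T, H))

    grads = {k: np.zeros_like(W[k]) for k in PROJECTIONS}
    gW_out = np.zeros_like(net.W_out)
    gb_out = np.zeros_like(net.b_out)

    psi = pseudo_derivative(trace.v, p.k_pseudo)
    if not trace.surrogate:
        psi = psi * trace.gate

    for t in range(T - 1, -1, -1):
        if t + 1 < T:
            GL[:, t] += rho_o * GL[:, t + 1]
        gdrive = (1 - rho_o) * GL[:, t]                      # (B, O)
        gW_out += np.einsum("bo,bh->oh", gdrive, trace.z[:, t])
        gb_out += gdrive.sum(axis=0)
        Gz[:, t] += gdrive @ net.W_out

        gv = Gz[:, t] * psi[:, t]
        GUm[:, t] += gv / trace.Gamma[:, t]
        GG[:, t] += -gv * trace.U_m[:, t] / trace.Gamma[:, t] ** 2
        Ga[:, t] += p.alpha * GG[:, t]

        if t > 0:
            GUm[:, t - 1] += rho_m * GUm[:, t]
            GUi[:, t - 1] += (p.dt / p.tau_m) * p.g_i * GUm[:, t] + rho_i * GUi[:, t]
            GUe[:, t - 1] += (p.dt / p.tau_m) * p.g_e * GUm[:, t] + rho_e * GUe[:, t]
            Gz[:, t - 1] += -trace.Gamma[:, t - 1] * GUm[:, t]
            GG[:, t - 1] += -trace.z[:, t - 1] * GUm[:, t]
            Ga[:, t - 1] += beta * Ga[:, t]
            Gz[:, t - 1] += (1 - beta) * Ga[:, t]

        gI_m = (p.dt / p.tau_m) * p.R_m * GUm[:, t]
        gI_i = (p.dt / p.tau_i) * p.R_i * GUi[:, t]
        gI_e = (p.dt / p.tau_e) * p.R_e * GUe[:, t]

        for proj, gI in (("in_m", gI_m), ("in_i", gI_i), ("in_e", gI_e)):
            lag = d[proj]
            if t >= lag:
                grads[proj] += np.einsum("bh,bi->hi", gI, trace.x[:, t - lag])
        for proj, gI in (("rec_m", gI_m), ("rec_i", gI_i), ("rec_e", gI_e)):
            lag = d[proj]
            if lag >= 1 and t >= lag:
                grads[proj] += np.einsum("bh,bj->hj", gI, trace.z[:, t - lag])
                Gz[:, t - lag] += gI @ W[proj]

    grads["W_out"] = gW_out
    grads["b_out"] = gb_out
    return grads


# ---------------------------------------------------------------------------
# loss assemblies


def firing_rate_regularizer(spikes: np.ndarray, f0: float, mu_f: float,
                            K: int, T: int, dt: float = 1.0) -> float:
    """Firing-rate penalty mu_f * (1/n) * sum_j (count_j - f0*K*T)^2.

    ``spikes`` covers K episodes of T steps (any shape with the last axis
    as neurons); ``f0`` is given in Hz and converted to expected spikes
    per step via dt (ms).
    """
    z = np.asarray(spikes, dtype=float)
    counts = z.reshape(-1, z.shape[-1]).sum(axis=0)
    if counts.size == 0:
        return 0.0
    target = (f0 * dt / 1000.0) * K * T
    return float(mu_f * np.mean((counts - target) ** 2))


def _rate_reg_grad(z: np.ndarray, f0_step: float, mu_f: float) -> tuple[float, np.ndarray]:
    """Rate penalty on spikes-per-step units and its dL/dz.

    penalty = mu_f * mean_j (rate_j - f0_step)^2 with rate_j averaged over
    batch and time; equivalent to the count form up to a (K*T)^2 factor,
    which keeps mu_f meaningful across episode lengths.
    """
    B, T, H = z.shape
    rates = z.mean(axis=(0, 1))
    dev = rates - f0_step
    penalty = float(mu_f * np.mean(dev**2))
    g = np.broadcast_to(mu_f * 2.0 * dev / (H * B * T), z.shape)
    return penalty, np.array(g)


def _sigmoid(x):
    return itl._sigmoid(x)


def supervised_loss_grads(trace: Trace, labels: np.ndarray, times: np.ndarray,
                          cfg: TrainConfig, first_iteration: bool = False) -> tuple:
    """Combined-criterion value and readout/spike gradients for one batch.

    ``labels`` is (B, R) binary; ``times`` is (B, R) 0-based readout step
    indices (channel 0 of the readout is the decision output).  Errors
    e = label - sigmoid(lambda) at the readout instants feed the RMEE
    term; the same instants feed the cross-entropy term.
    """
    B, T, O = trace.lam.shape
    labels = np.asarray(labels, dtype=float)
    times = np.asarray(times, dtype=int)
    if times.ndim == 1:
        times = np.broadcast_to(times, (B, times.size))
    R = times.shape[1]
    bidx = np.repeat(np.arange(B), R)
    tidx = times.ravel()
    y = trace.lam[bidx, tidx, 0]                     # pre-sigmoid readouts
    l = labels.ravel()
    pr = _sigmoid(y)
    e = l - pr
    N = e.size

    eb = ErrorBatch(e)
    spec = KernelSpec(cfg.sigma)
    cb = quantize_errors(eb, first_iteration=first_iteration)
    aux = hq_auxiliaries(eb, spec)
    rmee_term = -rmee_hq_objective(eb, cb, aux) / N**2
    drmee_de = -rmee_gradient(eb, cb, aux) / N**2

    ce_term = float(np.sum(
        -(l * np.log(np.clip(pr, 1e-12, None))
          + (1 - l) * np.log(np.clip(1 - pr, 1e-12, None))))) / B

    sig_prime = pr * (1 - pr)
    # de/dy = -sigmoid'(y); dCE/dy = (p - l)
    gy = cfg.mu * drmee_de * (-sig_prime) + (1 - cfg.mu) * (pr - l) / B

    g_lam = np.zeros_like(trace.lam)
    np.add.at(g_lam, (bidx, tidx, np.zeros_like(bidx)), gy)

    penalty, g_z = _rate_reg_grad(trace.z, cfg.f0 * net_dt(trace) / 1000.0, cfg.mu_f)
    combined = cfg.mu * rmee_term + (1 - cfg.mu) * ce_term + penalty
    acc = float(np.mean((pr > 0.5) == (l > 0.5)))
    metrics = {"rmee_term": rmee_term, "ce_term": ce_term, "rate_penalty": penalty,
               "combined": combined, "accuracy": acc,
               "mean_rate_hz": float(trace.z.mean() * 1000.0 / net_dt(trace))}
    return g_lam, g_z, metrics


def net_dt(trace: Trace) -> float:
    # dt is not stored on the trace; the package uses 1 ms throughout
    return 1.0


def ppo_loss(logp: np.ndarray, logp_old: np.ndarray, advantages: np.ndarray,
             values: np.ndarray, returns: np.ndarray, clip_eps: float,
             value_coef: float = 0.5, entropy: float = 0.0,
             entropy_coef: float = 0.0) -> dict:
    """Clipped-surrogate PPO loss over flattened (K*T,) per-step arrays.

    Returns the surrogate objective mean(min(r*A, clip(r)*A)), the value
    error term, and the total loss
    -surrogate + value_coef * value_term - entropy_coef * entropy.
    With identical policies (logp == logp_old) the ratio is 1 everywhere
    and the surrogate equals mean(A).
    """
    logp = np.asarray(logp, dtype=float).ravel()
    logp_old = np.asarray(logp_old, dtype=float).ravel()
    advantages = np.asarray(advantages, dtype=float).ravel()
    values = np.asarray(values, dtype=float).ravel()
    returns = np.asarray(returns, dtype=float).ravel()
    if not (logp.size == logp_old.size == advantages.size):
        raise ValueError("logp, logp_old and advantages must have equal length")
    if values.size != returns.size:
        raise ValueError("values and returns must have equal length")
    ratio = np.exp(logp - logp_old)
    clipped = np.clip(ratio, 1.0 - clip_eps, 1.0 + clip_eps)
    surrogate = float(np.mean(np.minimum(ratio * advantages, clipped * advantages)))
    value_term = float(np.mean((returns - values) ** 2))
    total = -surrogate + value_coef * value_term - entropy_coef * entropy
    return {"surrogate": surrogate, "value_term": value_term, "loss": total}


# ---------------------------------------------------------------------------
# parameter updates


class _Updater:
    """ADAM + deep rewiring applied to a network's parameters."""

    def __init__(self, net: SpikingNetwork, cfg: TrainConfig,
                 rng: np.random.Generator):
        self.net = net
        self.cfg = cfg
        self.rng = rng
        self.adam = Adam(cfg.lr, cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps)

    def apply(self, grads: dict) -> None:
        net, cfg = self.net, self.cfg
        ncfg = net.config
        lr_safe = cfg.lr if cfg.lr > 0 else 1.0
        for k in PROJECTIONS:
            w = net.wirings[k]
            grad_theta = w.signs * grads[k]
            update = self.adam.step(k, grad_theta)
            # rewire_step computes lr*(signs*g + l1); feed it the ADAM
            # direction so that signs*g reproduces update/lr
            pseudo_grad = w.signs * update / lr_safe
            net.wirings[k] = rewire_step(
                w, pseudo_grad, cfg.lr, l1=ncfg.l1_reg,
                temperature=ncfg.rewiring_temperature, rng=self.rng)
        net.W_out = net.W_out - self.adam.step("W_out", grads["W_out"])
        net.b_out = net.b_out - self.adam.step("b_out", grads["b_out"])


# ---------------------------------------------------------------------------
# supervised training


def train_supervised(config: TrainConfig, task, net: Optional[SpikingNetwork] = None,
                     network_config: Optional[NetworkConfig] = None) -> tuple:
    """Iterate simulate -> combined loss -> BPTT -> ADAM -> rewiring.

    ``task`` must provide ``sample_batch(rng, batch_size) ->
    (inputs (B,T,n_in), labels (B,R), times (R,) or (B,R))`` plus ``n_in``
    and ``T`` attributes.  Returns ``(net, TrainHistory)``; reproducible
    under a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    if net is None:
        if network_config is None:
            network_config = NetworkConfig(
                n_in=task.n_in, n_hidden=100, n_out=1, seed=config.seed)
        net = init_network(network_config)
    updater = _Updater(net, config, rng)
    history = TrainHistory()

    for it in range(config.n_iterations):
        inputs, labels, times = task.sample_batch(rng, config.batch_size)
        trace = net.forward(inputs)
        g_lam, g_z, metrics = supervised_loss_grads(trace, labels, times, config)
        if not np.isfinite(metrics["combined"]):
            raise TrainingDivergedError(it)
        grads = bptt_gradients(net, trace, g_lam, g_z)
        updater.apply(grads)
        history.append(iteration=it, **metrics)
    return net, history


def evaluate_supervised(net: SpikingNetwork, task, n_episodes: int,
                        seed: int = 12345) -> float:
    """Frozen-weight accuracy over freshly sampled held-out episodes."""
    rng = np.random.default_rng(seed)
    inputs, labels, times = task.sample_batch(rng, n_episodes)
    trace = net.forward(inputs)
    times = np.asarray(times, dtype=int)
    if times.ndim == 1:
        times = np.broadcast_to(times, (n_episodes, times.size))
    bidx = np.repeat(np.arange(n_episodes), times.shape[1])
    y = trace.lam[bidx, times.ravel(), 0]
    pred = _sigmoid(y) > 0.5
    return float(np.mean(pred == (np.asarray(labels, float).ravel() > 0.5)))


# ---------------------------------------------------------------------------
# reward learning (PPO + RMEE, per-episode value errors)


def _gaussian_logp(actions_raw: np.ndarray, lam: np.ndarray) -> tuple:
    """Log-density of the raw action samples under the policy head.

    Policy: mean = (tanh l1, tanh l2), variance = (sigmoid l3, sigmoid l4).
    Returns (logp (B,T), cached intermediates for the backward pass).
    """
    mx, my = np.tanh(lam[..., 0]), np.tanh(lam[..., 1])
    vx, vy = _sigmoid(lam[..., 2]), _sigmoid(lam[..., 3])
    ax, ay = actions_raw[..., 0], actions_raw[..., 1]
    logp = (-0.5 * ((ax - mx) ** 2 / vx + np.log(2 * np.pi * vx))
            - 0.5 * ((ay - my) ** 2 / vy + np.log(2 * np.pi * vy)))
    cache = (mx, my, vx, vy, ax, ay)
    return logp, cache


def _policy_backward(dlogp: np.ndarray, cache, lam: np.ndarray) -> np.ndarray:
    """dL/dlambda for channels 0..3 given dL/dlogp."""
    mx, my, vx, vy, ax, ay = cache
    g = np.zeros_like(lam)
    for (m, var, a, im, iv) in ((mx, vx, ax, 0, 2), (my, vy, ay, 1, 3)):
        dl_dm = (a - m) / var
        dl_dv = 0.5 * ((a - m) ** 2 / var**2 - 1.0 / var)
        g[..., im] += dlogp * dl_dm * (1.0 - m**2)        # tanh'
        g[..., iv] += dlogp * dl_dv * var * (1.0 - var)   # sigmoid'
    return g


def train_reward(config: TrainConfig, arena_factory: Callable,
                 net: Optional[SpikingNetwork] = None,
                 network_config: Optional[NetworkConfig] = None) -> tuple:
    """Reward learning: collect K episodes under the current policy, then
    update with the clipped PPO surrogate plus the RMEE term on
    per-episode value errors (counts overridden to (N,0,0) on iteration 0).

    ``arena_factory(rng)`` must return a closed-loop environment with the
    interface of ``tasks.NavigationTask``.  Returns ``(net, TrainHistory)``.
    """
    rng = np.random.default_rng(config.seed)
    task: NavigationTask = arena_factory(rng)
    if net is None:
        if network_config is None:
            network_config = NetworkConfig(
                n_in=task.n_in, n_hidden=64, n_out=5, seed=config.seed)
        net = init_network(network_config)
    updater = _Updater(net, config, rng)
    history = TrainHistory()
    spec = KernelSpec(config.sigma)
    K, T = config.K, config.T

    for it in range(config.n_iterations):
        # -- rollout under the current (old) policy -------------------------
        roll = task.rollout(net, K, T, rng)
        x_stream = roll["inputs"]                  # (K, T, n_in)
        actions_raw = roll["actions_raw"]          # (K, T, 2)
        rewards = roll["rewards"]                  # (K, T)
        reaches = float(roll["reaches"])

        returns = np.stack([discounted_returns(rewards[k], config.gamma)
                            for k in range(K)])    # (K, T)
        lam_old = roll["lam"]                      # (K, T, 5)
        logp_old, _ = _gaussian_logp(actions_raw, lam_old)
        # the value head predicts the strictly-future return Omega(t); the
        # advantage of the action taken at t must include the reward that
        # action itself produced, hence r_t + Omega(t)
        adv = rewards + returns - lam_old[..., 4]
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)

        # per-episode value errors for the RMEE term
        e = (returns - lam_old[..., 4]).mean(axis=1)
        eb = ErrorBatch(e)
        cb = quantize_errors(eb, first_iteration=(it == 0))
        aux = hq_auxiliaries(eb, spec)
        rmee_term = -rmee_hq_objective(eb, cb, aux) / K**2
        last = {}

        for epoch in range(config.ppo_epochs):
            trace = net.forward(x_stream)
            lam = trace.lam
            logp, cache = _gaussian_logp(actions_raw, lam)
            ratio = np.exp(np.clip(logp - logp_old, -20, 20))
            clipped = np.clip(ratio, 1 - config.clip_eps, 1 + config.clip_eps)
            surrogate = float(np.mean(np.minimum(ratio * adv, clipped * adv)))
            active = np.where(adv >= 0, ratio <= 1 + config.clip_eps,
                              ratio >= 1 - config.clip_eps)
            dlogp = -(active * ratio * adv) / (K * T)

            g_lam = _policy_backward(dlogp, cache, lam)
            # entropy bonus keeps the Gaussian policy from collapsing:
            # H = sum_dims 0.5 log(2 pi e var), dH/dl3 = 0.5 (1 - var)
            if config.entropy_coef > 0:
                for ch in (2, 3):
                    var_ch = _sigmoid(lam[..., ch])
                    g_lam[..., ch] += -config.entropy_coef * 0.5 * (1 - var_ch) / (K * T)
            # value head: value_coef * mean (Omega - V)^2
            vdiff = returns - lam[..., 4]
            value_term = float(np.mean(vdiff**2))
            g_lam[..., 4] += -2.0 * config.value_coef * vdiff / (K * T)

            # RMEE on per-episode errors e_n = mean_t(Omega - V)
            e_now = vdiff.mean(axis=1)
            eb_now = ErrorBatch(e_now)
            aux_now = hq_auxiliaries(eb_now, spec)
            rmee_now = -rmee_hq_objective(eb_now, cb, aux_now) / K**2
            drmee_de = -rmee_gradient(eb_now, cb, aux_now) / K**2
            g_lam[..., 4] += config.mu * (-drmee_de[:, None] / T)

            penalty, g_z = _rate_reg_grad(
                trace.z, config.f0 * net.config.dt / 1000.0, config.mu_f)

            total = (-surrogate + config.value_coef * value_term
                     + config.mu * rmee_now + penalty)
            if not np.isfinite(total):
                raise TrainingDivergedError(it)
            grads = bptt_gradients(net, trace, g_lam, g_z)
            updater.apply(grads)
            last = {"ppo_surrogate": surrogate, "value_term": value_term,
                    "rmee_term": rmee_now, "rate_penalty": penalty,
                    "total_loss": total}

        history.append(iteration=it, reaches=reaches,
                       mean_rate_hz=float(roll["mean_rate_hz"]),
                       rmee_term_rollout=rmee_term, **last)
    return net, history
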