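"""Desk-scale experiment presets.

Each function runs one complete, self-contained experiment at sizes that
finish in minutes on a single CPU core and returns the quantities of
interest.  The same presets back the command-line interface, the
end-to-end tests and the reproduction script, so every reported number
comes from exactly this code.

Problem sizes (deliberate down-scalings of the full-size experiments):

* store-recall — 100 hidden neurons, 100-step episodes, 200 training
  iterations of 96 episodes; held-out accuracy over 400 fresh episodes.
* navigation — 64 hidden neurons, 5 episodes x 200 steps per iteration,
  150 iterations; metric is destinations reached per iteration (DRN).
* noisy-sequence mu sweep — 80 hidden neurons, 150 iterations of 16
  trials, trained clean and tested at 10% salt-and-pepper noise for each
  requested RMEE weight mu.
"""

from __future__ import annotations

import numpy as np

from .network import NetworkConfig
from .tasks import NavigationTask, NoisySequenceTask, StoreRecallTask
from .training import (TrainConfig, train_reward, train_supervised,
                       evaluate_supervised)

__all__ = ["run_store_recall", "run_navigation", "run_mu_sweep"]


def run_store_recall(seed: int = 1, n_hidden: int = 100, n_iterations: int = 200,
                     batch_size: int = 96, T: int = 100,
                     n_eval: int = 400) -> dict:
    """Train on the store-recall task and report held-out recall accuracy.

    Also reports the accuracy of the untrained network on the same
    held-out generator (the chance level is 0.5).
    """
    task = StoreRecallTask(T=T)
    cfg = TrainConfig(mu=0.8, lr=3e-3, n_iterations=n_iterations,
                      batch_size=batch_size, seed=seed)
    ncfg = NetworkConfig(n_in=task.n_in, n_hidden=n_hidden, n_out=1, seed=seed)
    from .network import init_network

    net = init_network(ncfg)
    baseline = evaluate_supervised(net, task, n_eval, seed=seed + 10_000)
    net, history = train_supervised(cfg, task, net=net)
    accuracy = evaluate_supervised(net, task, n_eval, seed=seed + 20_000)
    return {
        "accuracy": accuracy,
        "baseline_accuracy": baseline,
        "final_rate_hz": history.records[-1]["mean_rate_hz"],
        "history": history,
        "net": net,
    }


def run_navigation(seed: int = 1, n_hidden: int = 100, n_iterations: int = 150,
                   K: int = 5, T: int = 200) -> dict:
    """Reward learning in the 2D arena; reports the DRN learning trend.

    Water-maze setting: the destination is fixed for the run (drawn from
    the seed) and the agent teleports to a fresh random position after
    each reach.  The policy network uses a fast (10 ms) readout
    integrator and an O(1) readout dynamic range so the tanh/sigmoid
    policy head is expressive at initialization; the variance channels
    start low (bias -2) so the action noise does not drown the policy
    mean.  The trend statistic compares mean destinations reached over
    the last 10 iterations against the first 10.
    """
    task = NavigationTask(dest_mode="fixed", seed=seed)
    cfg = TrainConfig(mu=0.8, mu_f=2.0, lr=5e-3, K=K, T=T,
                      n_iterations=n_iterations, ppo_epochs=2,
                      entropy_coef=0.015, seed=seed)
    ncfg = NetworkConfig(n_in=task.n_in, n_hidden=n_hidden, n_out=5, seed=seed,
                         readout_gain=8.0, tau_out=10.0)
    from .network import init_network

    net = init_network(ncfg)
    net.b_out[2:4] = -2.0
    net, history = train_reward(cfg, lambda rng: task, net=net)
    reaches = history.column("reaches")
    return {
        "reaches": reaches,
        "first10_mean": float(reaches[:10].mean()),
        "last10_mean": float(reaches[-10:].mean()),
        "improved": bool(reaches[-10:].mean() > reaches[:10].mean()),
        "history": history,
        "net": net,
    }


def run_mu_sweep(seeds=(1, 2, 3, 4, 5), mu_values=(0.8, 1.0),
                 n_hidden: int = 80, n_iterations: int = 150,
                 batch_size: int = 16, test_noise: float = 0.10,
                 n_eval: int = 200) -> dict:
    """Train the noisy-sequence task at each mu; test at salt-and-pepper noise.

    Training uses clean glyph streams; evaluation corrupts ``test_noise``
    of the pixels.  Returns per-(mu, seed) test accuracies and the mean
    per mu.
    """
    train_task = NoisySequenceTask(noise_fraction=0.0)
    test_task = NoisySequenceTask(noise_fraction=test_noise)
    acc = {mu: [] for mu in mu_values}
    for mu in mu_values:
        for seed in seeds:
            cfg = TrainConfig(mu=mu, lr=3e-3, n_iterations=n_iterations,
                              batch_size=batch_size, seed=seed)
            ncfg = NetworkConfig(n_in=train_task.n_in, n_hidden=n_hidden,
                                 n_out=1, seed=seed)
            net, _ = train_supervised(cfg, train_task, network_config=ncfg)
            acc[mu].append(evaluate_supervised(net, test_task, n_eval,
                                               seed=seed + 30_000))
    return {
        "accuracies": acc,
        "means": {mu: float(np.mean(a)) for mu, a in acc.items()},
    }
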