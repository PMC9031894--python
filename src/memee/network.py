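"""Recurrent three-layer spiking network: construction, rewiring, simulation.

Architecture.  Input channels project to the hidden layer's three
compartments; hidden neurons are laterally connected by sparse recurrent
synapses; somatic spikes drive non-spiking leaky-integrator readouts
lambda_i(t).  Six synaptic projections exist, one per (source, target
compartment) pair:

    in_m / in_i / in_e   : input -> soma / inhibitory dendrite / excitatory dendrite
    rec_m / rec_i / rec_e: hidden -> soma / inhibitory dendrite / excitatory dendrite

Every synapse carries a fixed sign drawn at initialization (Dale-like:
the sign never changes during training).  Projections onto the
inhibitory dendrite are all-negative, onto the excitatory dendrite
all-positive; somatic projections mix both signs.  All synapses have a
homogeneous conduction delay (5 ms at dt = 1 ms).

Initialization.  Weight magnitudes are Gaussian with scale w0/sqrt(n_pre),
w0 = dt/R_m; recurrent matrices are jointly rescaled so the spectral
radius of their sum is below 1 (target 0.95), which avoids exploding
gradients through the recurrence.

Deep rewiring.  Training updates the non-negative magnitude theta of each
active synapse (signed weight = sign * theta).  A synapse whose magnitude
would cross zero is disconnected, and an equal number of dormant synapses
are reconnected at magnitude 0+ with their stored sign, so the sparsity
level is exactly conserved and no sign ever flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .neuron import NeuronParams, pseudo_derivative_primitive

__all__ = [
    "LayerWiring",
    "NetworkConfig",
    "SpikeRaster",
    "Trace",
    "SpikingNetwork",
    "init_network",
    "rewire_step",
    "simulate_forward",
]

PROJECTIONS = ("in_m", "in_i", "in_e", "rec_m", "rec_i", "rec_e")


@dataclass
class LayerWiring:
    """One synaptic projection: magnitudes, fixed signs, mask, delay.

    ``theta`` holds non-negative magnitudes; the effective signed weight
    matrix is ``signs * theta * mask``.  ``delay`` is a homogeneous integer
    step delay for the whole projection.
    """

    theta: np.ndarray      # (n_post, n_pre), >= 0
    signs: np.ndarray      # (n_post, n_pre), entries in {-1, +1}
    mask: np.ndarray       # (n_post, n_pre), bool
    delay: int = 5

    def __post_init__(self) -> None:
        if self.theta.shape != self.signs.shape or self.theta.shape != self.mask.shape:
            raise ValueError("theta, signs and mask must share one shape")
        if np.any(self.theta < 0):
            raise ValueError("synaptic magnitudes must be non-negative")
        if not np.all(np.isin(self.signs, (-1, 1))):
            raise ValueError("synaptic signs must be -1 or +1")
        if self.delay < 0:
            raise ValueError("delay must be non-negative")

    @property
    def weights(self) -> np.ndarray:
        """Effective signed weight matrix."""
        return self.signs * self.theta * self.mask

    @property
    def n_active(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "LayerWiring":
        return LayerWiring(self.theta.copy(), self.signs.copy(), self.mask.copy(), self.delay)


@dataclass(frozen=True)
class NetworkConfig:
    """Sizes, sparsity and initialization constants of one network."""

    n_in: int
    n_hidden: int
    n_out: int
    sparsity: float = 0.1          # fraction of active lateral synapses
    input_sparsity: float = 1.0    # input projections are dense by default
    dt: float = 1.0
    l1_reg: float = 0.01           # deep-rewiring L1 penalty
    rewiring_temperature: float = 0.0
    spectral_target: float = 0.95  # recurrent spectral radius after rescale
    delay_steps: int = 5           # 5 ms at dt = 1 ms, all synapse classes
    tau_out: float = 20.0          # readout leaky-integrator time constant
    readout_gain: float = 1.0      # scales the readout weight init (policy
                                   # heads need O(1) readout dynamic range)
    seed: int = 0
    neuron: NeuronParams = field(default_factory=NeuronParams)

    def __post_init__(self) -> None:
        if min(self.n_in, self.n_hidden, self.n_out) < 1:
            raise ValueError("layer sizes must be >= 1")
        if not 0.0 < self.sparsity <= 1.0 or not 0.0 < self.input_sparsity <= 1.0:
            raise ValueError("sparsity must lie in (0, 1]")

    @property
    def w0(self) -> float:
        """Weight-scaling factor w0 = dt / R_m."""
        return self.dt / self.neuron.R_m


@dataclass(frozen=True)
class SpikeRaster:
    """Binary spike matrix (T x n_hidden) plus readout traces (T x n_out)."""

    spikes: np.ndarray
    readouts: np.ndarray

    def to_events(self) -> np.ndarray:
        """(time, neuron_id) event list, one row per spike."""
        t, j = np.nonzero(self.spikes)
        return np.column_stack([t, j])


@dataclass
class Trace:
    """Full state record of one batched simulation, as needed by BPTT.

    All arrays have leading dims (B, T).  In surrogate mode (smooth
    forward) ``z`` holds the continuous surrogate spike values.
    """

    x: np.ndarray        # (B, T, n_in) input stream
    z: np.ndarray        # (B, T, H) spikes
    U_m: np.ndarray
    U_i: np.ndarray
    U_e: np.ndarray
    a: np.ndarray        # threshold deviation tau_j
    Gamma: np.ndarray
    v: np.ndarray        # normalized potential
    gate: np.ndarray     # 1 where the neuron was free to spike
    lam: np.ndarray      # (B, T, n_out) readout traces
    surrogate: bool = False

    @property
    def raster(self) -> SpikeRaster:
        if self.z.shape[0] != 1:
            raise ValueError("raster export expects a single-episode trace")
        return SpikeRaster(self.z[0], self.lam[0])


class SpikingNetwork:
    """A wired network: six sign-constrained projections plus dense readout."""

    def __init__(self, config: NetworkConfig, wirings: dict, W_out: np.ndarray,
                 b_out: np.ndarray):
        self.config = config
        self.wirings = wirings
        self.W_out = W_out
        self.b_out = b_out

    # -- forward simulation -------------------------------------------------

    def forward(self, inputs: np.ndarray, surrogate: bool = False) -> Trace:
        """Simulate the network over a batch of input streams.

        ``inputs`` has shape (B, T, n_in) and may be binary spikes or
        analog currents.  Deterministic given wiring and inputs.  With
        ``surrogate=True`` the hard spike function is replaced by the
        smooth primitive of the pseudo-derivative and refractoriness is
        disabled, yielding a differentiable forward pass (used to validate
        gradients); training uses the hard forward with the surrogate
        derivative only in the backward pass.
        """
        inputs = np.asarray(inputs, dtype=float)
        if inputs.ndim == 2:
            inputs = inputs[None]
        B, T, _ = inputs.shape
        stepper = NetworkStepper(self, B, surrogate=surrogate)
        for t in range(T):
            stepper.step(inputs[:, t])
        return stepper.trace()

    # -- parameter plumbing --------------------------------------------------

    def save(self, path) -> None:
        """Checkpoint weights/signs/masks/delays and a config echo (npz archive)."""
        arrays = {"W_out": self.W_out, "b_out": self.b_out}
        for k, w in self.wirings.items():
            arrays[f"{k}_theta"] = w.theta
            arrays[f"{k}_signs"] = w.signs
            arrays[f"{k}_mask"] = w.mask
            arrays[f"{k}_delay"] = np.array(w.delay)
        cfg = self.config
        arrays["config"] = np.array([cfg.n_in, cfg.n_hidden, cfg.n_out, cfg.seed])
        arrays["config_floats"] = np.array(
            [cfg.sparsity, cfg.input_sparsity, cfg.dt, cfg.l1_reg, cfg.tau_out])
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, config: Optional[NetworkConfig] = None) -> "SpikingNetwork":
        with np.load(path) as data:
            n_in, n_hidden, n_out, seed = (int(x) for x in data["config"])
            sp, isp, dt, l1, tau_out = (float(x) for x in data["config_floats"])
            if config is None:
                config = NetworkConfig(
                    n_in=n_in, n_hidden=n_hidden, n_out=n_out, sparsity=sp,
                    input_sparsity=isp, dt=dt, l1_reg=l1, tau_out=tau_out, seed=seed)
            wirings = {
                k: LayerWiring(
                    data[f"{k}_theta"], data[f"{k}_signs"],
                    data[f"{k}_mask"].astype(bool), int(data[f"{k}_delay"]))
                for k in PROJECTIONS
            }
            return cls(config, wirings, data["W_out"], data["b_out"])


class NetworkStepper:
    """Incremental simulator: one call per time step, with full recording.

    Both the batched ``SpikingNetwork.forward`` and the closed-loop RL
    rollout drive the network through this class, so the offline replay
    used by BPTT reproduces the rollout dynamics exactly.
    """

    def __init__(self, net: SpikingNetwork, batch: int, surrogate: bool = False):
        cfg = net.config
        if cfg.n_in < 1:
            raise ValueError("invalid network")
        self.net = net
        self.B = batch
        self.surrogate = surrogate
        self.W = {k: w.weights for k, w in net.wirings.items()}
        self.d = {k: w.delay for k, w in net.wirings.items()}
        p = cfg.neuron
        self.p = p
        self.rho = (1 - p.dt / p.tau_m, 1 - p.dt / p.tau_i, 1 - p.dt / p.tau_e)
        self.rho_o = 1 - cfg.dt / cfg.tau_out
        self.t = 0
        self.refrac = np.zeros((batch, cfg.n_hidden), dtype=int)
        # recorded histories, one (B, .) array per step
        self.hist: dict[str, list] = {k: [] for k in
                                      ("x", "z", "U_m", "U_i", "U_e", "a",
                                       "Gamma", "v", "gate", "lam")}

    def step(self, x_t: np.ndarray):
        """Advance one time step with input ``x_t`` (B, n_in); returns (z_t, lam_t)."""
        net, p, cfg = self.net, self.p, self.net.config
        B, H, O = self.B, cfg.n_hidden, cfg.n_out
        x_t = np.asarray(x_t, dtype=float).reshape(B, cfg.n_in)
        if not np.all(np.isfinite(x_t)):
            raise ValueError("input currents must be finite")
        t = self.t
        # recurrent lookups require delay >= 1 (same-step spikes do not exist
        # yet when the currents are formed); input lookups allow delay 0
        self.hist["x"].append(x_t)
        xm = self.hist["x"][t - self.d["in_m"]] if t >= self.d["in_m"] else None
        xi = self.hist["x"][t - self.d["in_i"]] if t >= self.d["in_i"] else None
        xe = self.hist["x"][t - self.d["in_e"]] if t >= self.d["in_e"] else None
        zm = self.hist["z"][t - self.d["rec_m"]] if t >= self.d["rec_m"] >= 1 else None
        zi = self.hist["z"][t - self.d["rec_i"]] if t >= self.d["rec_i"] >= 1 else None
        ze = self.hist["z"][t - self.d["rec_e"]] if t >= self.d["rec_e"] >= 1 else None

        I_m = (xm @ self.W["in_m"].T if xm is not None else 0.0) + (
            zm @ self.W["rec_m"].T if zm is not None else 0.0)
        I_i = (xi @ self.W["in_i"].T if xi is not None else 0.0) + (
            zi @ self.W["rec_i"].T if zi is not None else 0.0)
        I_e = (xe @ self.W["in_e"].T if xe is not None else 0.0) + (
            ze @ self.W["rec_e"].T if ze is not None else 0.0)

        prev = lambda key, fill=0.0: (self.hist[key][t - 1] if t > 0
                                      else np.full((B, H), fill))
        Um_p, Ui_p, Ue_p = prev("U_m"), prev("U_i"), prev("U_e")
        a_p, z_p = prev("a"), prev("z")
        G_p = self.hist["Gamma"][t - 1] if t > 0 else np.full((B, H), p.tau0)

        rho_m, rho_i, rho_e = self.rho
        U_i = rho_i * Ui_p + (p.dt / p.tau_i) * p.R_i * I_i
        U_e = rho_e * Ue_p + (p.dt / p.tau_e) * p.R_e * I_e
        U_m = (
            rho_m * Um_p
            + (p.dt / p.tau_m)
            * (p.R_m * I_m + p.g_i * (Ui_p - p.theta_i) + p.g_e * (Ue_p - p.theta_e))
            - G_p * z_p
        )
        a = p.beta * a_p + (1 - p.beta) * z_p
        Gamma = p.tau0 + p.alpha * a
        v = (U_m - Gamma) / Gamma

        if self.surrogate:
            gate = np.ones((B, H))
            z = pseudo_derivative_primitive(v, p.k_pseudo)
        else:
            free = self.refrac == 0
            gate = free.astype(float)
            z = (free & (v >= 0.0)).astype(float)
            self.refrac = np.where(z > 0, p.refractory_steps,
                                   np.maximum(self.refrac - 1, 0))

        lam_p = self.hist["lam"][t - 1] if t > 0 else np.zeros((B, O))
        lam = self.rho_o * lam_p + (1 - self.rho_o) * (z @ net.W_out.T + net.b_out)

        for key, val in (("z", z), ("U_m", U_m), ("U_i", U_i), ("U_e", U_e),
                         ("a", a), ("Gamma", Gamma), ("v", v), ("gate", gate),
                         ("lam", lam)):
            self.hist[key].append(val)
        self.t += 1
        return z, lam

    def trace(self) -> Trace:
        h = {k: np.stack(v, axis=1) for k, v in self.hist.items()}
        return Trace(h["x"], h["z"], h["U_m"], h["U_i"], h["U_e"], h["a"],
                     h["Gamma"], h["v"], h["gate"], h["lam"], self.surrogate)


def _spectral_radius(M: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def init_network(config: NetworkConfig) -> SpikingNetwork:
    """Build a network with Gaussian weights, fixed signs and sparse masks.

    Magnitudes are |N(0, (w0/sqrt(n_pre))^2)|.  Somatic projections sample
    their sign from the weight draw itself (Bernoulli +-1), so the signed
    somatic weights are exactly Gaussian; dendritic projections have their
    sign forced by compartment (inhibitory negative, excitatory positive).
    The three recurrent matrices are jointly rescaled so the spectral
    radius of their sum is at most ``spectral_target`` < 1.
    """
    rng = np.random.default_rng(config.seed)
    H, n_in = config.n_hidden, config.n_in

    def make(n_post, n_pre, sign_mode, sparsity, lateral=False):
        w = rng.normal(0.0, config.w0 / np.sqrt(n_pre), size=(n_post, n_pre))
        if sign_mode == "mixed":
            signs = np.where(w >= 0, 1, -1)
        else:
            signs = np.full((n_post, n_pre), 1 if sign_mode == "pos" else -1)
        mask = rng.random((n_post, n_pre)) < sparsity
        if lateral:
            np.fill_diagonal(mask, False)
        if not mask.any():  # degenerate tiny nets: keep at least one synapse
            mask[rng.integers(n_post), rng.integers(n_pre)] = True
        return LayerWiring(np.abs(w), signs.astype(float), mask, config.delay_steps)

    wirings = {
        "in_m": make(H, n_in, "mixed", config.input_sparsity),
        "in_i": make(H, n_in, "neg", config.input_sparsity),
        "in_e": make(H, n_in, "pos", config.input_sparsity),
        "rec_m": make(H, H, "mixed", config.sparsity, lateral=True),
        "rec_i": make(H, H, "neg", config.sparsity, lateral=True),
        "rec_e": make(H, H, "pos", config.sparsity, lateral=True),
    }

    total = wirings["rec_m"].weights + wirings["rec_i"].weights + wirings["rec_e"].weights
    rho = _spectral_radius(total)
    if rho > config.spectral_target:
        scale = config.spectral_target / rho
        for k in ("rec_m", "rec_i", "rec_e"):
            wirings[k].theta *= scale

    W_out = rng.normal(0.0, config.readout_gain * config.w0 / np.sqrt(H),
                       size=(config.n_out, H))
    b_out = np.zeros(config.n_out)
    return SpikingNetwork(config, wirings, W_out, b_out)


def recurrent_spectral_radius(net: SpikingNetwork) -> float:
    """Spectral radius of the summed recurrent weight matrix."""
    return _spectral_radius(
        net.wirings["rec_m"].weights
        + net.wirings["rec_i"].weights
        + net.wirings["rec_e"].weights
    )


def rewire_step(
    wiring: LayerWiring,
    gradients: np.ndarray,
    lr: float,
    l1: float = 0.01,
    temperature: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> LayerWiring:
    """One deep-rewiring update of a projection.

    ``gradients`` is dL/dW for the signed weights; the magnitude update is
    theta <- theta - lr * (sign * grad + l1) + sqrt(2 lr temperature) * noise.
    Active synapses whose magnitude would cross below zero are
    disconnected; the same number of dormant synapses are reconnected at
    magnitude 0 with their stored sign, so sparsity is exactly conserved
    and signs never flip.
    """
    if rng is None:
        rng = np.random.default_rng()
    w = wiring.copy()
    grad_theta = w.signs * np.asarray(gradients, dtype=float)
    step = lr * (grad_theta + l1)
    if temperature > 0:
        step = step - np.sqrt(2.0 * lr * temperature) * rng.standard_normal(w.theta.shape)
    theta_new = np.where(w.mask, w.theta - step, w.theta)

    crossed = w.mask & (theta_new < 0)
    n_cross = int(crossed.sum())
    w.theta = np.where(crossed, 0.0, np.maximum(theta_new, 0.0))
    if n_cross:
        w.mask = w.mask & ~crossed
        dormant = np.flatnonzero(~w.mask.ravel())
        pick = rng.choice(dormant, size=n_cross, replace=False)
        flat_mask = w.mask.ravel()
        flat_mask[pick] = True
        w.mask = flat_mask.reshape(w.mask.shape)
        w.theta.ravel()[pick] = 0.0
    return w


def simulate_forward(net: SpikingNetwork, input_spikes: np.ndarray,
                     T: Optional[int] = None) -> SpikeRaster:
    """Simulate one episode and return its spike raster and readout traces."""
    inputs = np.asarray(input_spikes, dtype=float)
    if T is not None:
        if inputs.shape[0] < T:
            raise ValueError(f"input stream of length {inputs.shape[0]} shorter than T={T}")
        inputs = inputs[:T]
    return net.forward(inputs[None]).raster
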