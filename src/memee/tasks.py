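"""Synthetic task generators and encoders/decoders.

Three task families exercise the networks:

* **Store–recall** (working memory): 40 input channels; channels 1-10 and
  11-20 carry two alternating Poisson-coded value streams, channels 21-30
  and 31-40 carry synchronous store and recall command bursts.  The
  network must report, during the recall window, which value stream was
  active when the store command arrived.
* **Noisy sequential classification**: procedurally drawn 28x28 glyphs
  (ten distinguishable classes) flattened into a 40-channel pixel stream
  at 20 steps per image, five images per trial; binary per-image labels
  mark whether an image matches the class of the first (reference) image.
  Salt-and-pepper corruption flips a configurable fraction of pixels to
  0 or 1.
* **2D navigation**: a point agent in the unit square must reach a
  destination disc; positions (and the destination) are Gaussian
  population-rate encoded into Poisson spike trains, a dedicated input
  group bursts for 5 steps after each reward, and five leaky readouts
  parameterize a Gaussian action policy plus a value estimate.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .itl_losses import readout_times, N_IMAGES, STEPS_PER_IMAGE

__all__ = [
    "StoreRecallEpisode",
    "StoreRecallTask",
    "gen_store_recall",
    "NoisySequenceBatch",
    "NoisySequenceTask",
    "gen_noisy_sequences",
    "salt_pepper",
    "glyph",
    "GLYPH_CLASSES",
    "PopulationCode",
    "population_encode",
    "poisson_spikes",
    "Arena",
    "arena_reset",
    "arena_step",
    "decode_action",
    "discounted_returns",
    "NavigationTask",
    "read_idx",
]


# ---------------------------------------------------------------------------
# store-recall


@dataclass(frozen=True)
class StoreRecallEpisode:
    """One store-recall episode: T x 40 binary inputs and the stored bit."""

    input_spikes: np.ndarray    # (T, 40)
    target: int                 # 0 = stream A stored, 1 = stream B
    store_t: int                # first step of the store window
    recall_t: int               # first step of the recall window


def gen_store_recall(n_episodes: int, T: int = 100, seed: int = 0,
                     frame_len: int = 10, value_rate_hz: float = 50.0,
                     dt: float = 1.0) -> list[StoreRecallEpisode]:
    """Generate store-recall episodes.

    Time is partitioned into frames of ``frame_len`` steps; in each frame
    one of the two value streams is active and fires Poisson at
    ``value_rate_hz``.  One early frame carries the store command burst
    (channels 21-30 at every step), one late frame the recall burst
    (channels 31-40); value streams are silenced during recall so the
    answer must come from memory.  The target is the stream that was
    active during the store frame.
    """
    n_frames = T // frame_len
    if n_frames < 4:
        raise ValueError(f"T={T} too small: need at least 4 frames of {frame_len} steps")
    rng = np.random.default_rng(seed)
    p_fire = value_rate_hz * dt / 1000.0
    episodes = []
    for _ in range(n_episodes):
        active = rng.integers(0, 2, size=n_frames)          # per-frame stream
        store_f = int(rng.integers(0, n_frames // 2 - 1))
        recall_f = int(rng.integers(n_frames // 2 + 1, n_frames))
        x = np.zeros((T, 40))
        for f in range(n_frames):
            s = slice(f * frame_len, (f + 1) * frame_len)
            if f == recall_f:
                x[s, 30:40] = 1.0
                continue
            ch = slice(0, 10) if active[f] == 0 else slice(10, 20)
            x[s, ch] = (rng.random((frame_len, 10)) < p_fire)
            if f == store_f:
                x[s, 20:30] = 1.0
        episodes.append(StoreRecallEpisode(
            x, int(active[store_f]), store_f * frame_len, recall_f * frame_len))
    return episodes


class StoreRecallTask:
    """Batch adapter of the store-recall generator for the trainer.

    The stored bit is read out over the last ``readout_window`` steps of
    the recall window (the label is replicated across those instants),
    which averages out single-step readout noise.
    """

    n_in = 40

    def __init__(self, T: int = 100, frame_len: int = 10,
                 value_rate_hz: float = 50.0, readout_window: int = 10):
        if not 1 <= readout_window <= frame_len:
            raise ValueError("readout_window must lie in [1, frame_len]")
        self.T = T
        self.frame_len = frame_len
        self.value_rate_hz = value_rate_hz
        self.readout_window = readout_window

    def sample_batch(self, rng: np.random.Generator, batch_size: int):
        eps = gen_store_recall(batch_size, self.T, seed=int(rng.integers(2**31)),
                               frame_len=self.frame_len,
                               value_rate_hz=self.value_rate_hz)
        W = self.readout_window
        inputs = np.stack([e.input_spikes for e in eps])
        labels = np.array([[e.target] * W for e in eps], dtype=float)
        times = np.array([
            [e.recall_t + self.frame_len - W + i for i in range(W)] for e in eps])
        return inputs, labels, times


# ---------------------------------------------------------------------------
# glyphs and noisy sequential classification

GLYPH_CLASSES = 10
_GLYPH_CACHE: dict[int, np.ndarray] = {}


def glyph(cls: int) -> np.ndarray:
    """A 28x28 binary template for class ``cls`` (0-9), drawn from strokes."""
    if cls in _GLYPH_CACHE:
        return _GLYPH_CACHE[cls]
    g = np.zeros((28, 28))

    def hbar(r, c0=4, c1=24):
        g[r:r + 3, c0:c1] = 1

    def vbar(c, r0=4, r1=24):
        g[r0:r1, c:c + 3] = 1

    if cls == 0:
        hbar(4); hbar(21); vbar(4, 4, 24); vbar(21, 4, 24)
    elif cls == 1:
        vbar(13)
    elif cls == 2:
        hbar(4); hbar(21)
        rr = np.arange(7, 21)
        g[rr, 24 - rr] = 1; g[rr, 23 - rr] = 1
    elif cls == 3:
        hbar(4); hbar(12); hbar(21); vbar(21, 4, 24)
    elif cls == 4:
        vbar(6, 4, 14); hbar(12); vbar(19, 4, 24)
    elif cls == 5:
        hbar(4); vbar(4, 4, 13); hbar(12); vbar(21, 12, 22); hbar(21)
    elif cls == 6:
        vbar(4, 4, 24); hbar(12); hbar(21); vbar(21, 12, 22)
    elif cls == 7:
        hbar(4)
        rr = np.arange(7, 24)
        g[rr, 25 - (rr * 18) // 24] = 1; g[rr, 24 - (rr * 18) // 24] = 1
    elif cls == 8:
        hbar(4); hbar(12); hbar(21); vbar(4, 4, 24); vbar(21, 4, 24)
    elif cls == 9:
        hbar(4); vbar(4, 4, 13); hbar(12); vbar(21, 4, 24)
    else:
        raise ValueError(f"glyph class must be 0-9, got {cls}")
    _GLYPH_CACHE[cls] = g
    return g


def salt_pepper(image: np.ndarray, fraction: float,
                rng: Optional[np.random.Generator] = None,
                seed: Optional[int] = None) -> np.ndarray:
    """Replace each pixel independently with 0 or 1 (equal odds) with
    probability ``fraction``; other pixels are untouched."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"noise fraction must lie in [0, 1], got {fraction}")
    if rng is None:
        rng = np.random.default_rng(seed)
    image = np.asarray(image, dtype=float)
    hit = rng.random(image.shape) < fraction
    vals = (rng.random(image.shape) < 0.5).astype(float)
    return np.where(hit, vals, image)


#: glyph classes whose images are labelled 1 (the first half of the class
#: inventory, mirroring a 0-4 vs 5-9 digit split)
TARGET_CLASSES = frozenset({0, 1, 2, 3, 4})


@dataclass(frozen=True)
class NoisySequenceBatch:
    """Per-trial pixel streams with five binary class-membership labels."""

    sequences: np.ndarray       # (B, T, n_channels)
    labels: np.ndarray          # (B, 5) binary
    classes: np.ndarray         # (B, 5) glyph classes (generator metadata)
    noise_fraction: float


def gen_noisy_sequences(n_trials: int, noise_fraction: float = 0.0,
                        seed: int = 0, n_channels: int = 40,
                        classes: Optional[np.ndarray] = None,
                        target_classes=TARGET_CLASSES) -> NoisySequenceBatch:
    """Five-image trials of flattened glyphs with salt-and-pepper noise.

    Each 28x28 glyph is flattened (784 pixels, zero-padded to 800) and
    streamed over 20 steps of 40 channels; five glyphs make one trial and
    l_n = 1 iff image n belongs to the target class set (half the classes,
    so labels are balanced).  Twenty blank steps follow the last image so
    every readout instant t = 20 + 20n exists.
    """
    if not 0.0 <= noise_fraction <= 1.0:
        raise ValueError(f"noise fraction must lie in [0, 1], got {noise_fraction}")
    rng = np.random.default_rng(seed)
    steps = STEPS_PER_IMAGE
    T = steps * (N_IMAGES + 1)
    if classes is None:
        classes = rng.integers(0, GLYPH_CLASSES, size=(n_trials, N_IMAGES))
    labels = np.isin(classes, list(target_classes)).astype(float)

    seqs = np.zeros((n_trials, T, n_channels))
    pad = steps * n_channels - 28 * 28
    for b in range(n_trials):
        for n in range(N_IMAGES):
            img = salt_pepper(glyph(int(classes[b, n])), noise_fraction, rng)
            flat = np.concatenate([img.ravel(), np.zeros(pad)])
            seqs[b, n * steps:(n + 1) * steps] = flat.reshape(steps, n_channels)
    return NoisySequenceBatch(seqs, labels, classes, noise_fraction)


class NoisySequenceTask:
    """Batch adapter of the glyph-sequence generator for the trainer."""

    n_in = 40
    T = STEPS_PER_IMAGE * (N_IMAGES + 1)

    def __init__(self, noise_fraction: float = 0.0):
        self.noise_fraction = noise_fraction

    def sample_batch(self, rng: np.random.Generator, batch_size: int):
        batch = gen_noisy_sequences(batch_size, self.noise_fraction,
                                    seed=int(rng.integers(2**31)))
        return batch.sequences, batch.labels, readout_times()


# ---------------------------------------------------------------------------
# population coding and the navigation arena


@dataclass(frozen=True)
class PopulationCode:
    """Gaussian population rate code: rate_i = r_max * exp(-width (xi_i - xi)^2)."""

    preferred: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 1.0, 8))
    r_max: float = 500.0        # Hz
    width: float = 100.0        # exponent coefficient

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")


def population_encode(value: float, code: PopulationCode) -> np.ndarray:
    """Firing rates (Hz) of the population for a scalar coordinate value."""
    d = code.preferred - float(value)
    return code.r_max * np.exp(-code.width * d * d)


def poisson_spikes(rates_hz: np.ndarray, dt: float,
                   rng: np.random.Generator) -> np.ndarray:
    """One step of Bernoulli-thinned Poisson spikes at the given rates."""
    p = np.clip(np.asarray(rates_hz, dtype=float) * dt / 1000.0, 0.0, 1.0)
    return (rng.random(p.shape) < p).astype(float)


@dataclass(frozen=True)
class Arena:
    """Point agent in the unit square with a destination disc."""

    pos: np.ndarray
    dest: np.ndarray
    radius: float = 0.05
    max_speed: float = 0.02


def arena_reset(rng: np.random.Generator, radius: float = 0.05,
                max_speed: float = 0.02) -> Arena:
    """Uniformly random agent and destination positions."""
    return Arena(rng.random(2), rng.random(2), radius, max_speed)


def arena_step(arena: Arena, action: np.ndarray) -> tuple[Arena, float, bool]:
    """Apply an action (clipped to max speed and walls); reward 1 at the goal."""
    action = np.asarray(action, dtype=float)
    norm = float(np.linalg.norm(action))
    if norm > arena.max_speed:
        action = action * (arena.max_speed / norm)
    pos = np.clip(arena.pos + action, 0.0, 1.0)
    reached = bool(np.linalg.norm(pos - arena.dest) <= arena.radius)
    return replace(arena, pos=pos), (1.0 if reached else 0.0), reached


def decode_action(lams: np.ndarray, rng: np.random.Generator,
                  max_speed: float = 0.02) -> tuple:
    """Sample an action from the Gaussian policy head.

    mean = (tanh l1, tanh l2), variances = (sigmoid l3, sigmoid l4);
    the raw sample is norm-clipped to ``max_speed``; l5 is the value
    estimate.  Returns (action, raw_sample, value).
    """
    lams = np.asarray(lams, dtype=float)
    if lams.shape[-1] < 5:
        raise ValueError("five readout traces are required")
    mean = np.stack([np.tanh(lams[..., 0]), np.tanh(lams[..., 1])], axis=-1)
    var = np.stack([_sigm(lams[..., 2]), _sigm(lams[..., 3])], axis=-1)
    raw = mean + np.sqrt(var) * rng.standard_normal(mean.shape)
    norm = np.linalg.norm(raw, axis=-1, keepdims=True)
    scale = np.minimum(1.0, max_speed / np.maximum(norm, 1e-12))
    return raw * scale, raw, lams[..., 4]


def _sigm(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def discounted_returns(rewards: np.ndarray, gamma: float) -> np.ndarray:
    """Strictly-future discounted returns Omega(t) = sum_{t'>t} gamma^(t'-t) w(t')."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError(f"discount factor must lie in [0, 1), got {gamma}")
    r = np.asarray(rewards, dtype=float).ravel()
    out = np.zeros_like(r)
    acc = 0.0
    for t in range(r.size - 2, -1, -1):
        acc = gamma * (r[t + 1] + acc)
        out[t] = acc
    return out


class NavigationTask:
    """Closed-loop navigation environment with population-coded inputs.

    The environment state is Gaussian population-rate encoded into
    Poisson spike trains: ``n_pos`` neurons per coordinate for the agent
    position and, when the destination varies (``dest_mode='per_reset'``),
    ``n_dest`` neurons per coordinate for the destination.  A 4-neuron
    positive-reward group and a 4-neuron negative-reward group each burst
    synchronously for 5 steps after the respective reward (no negative
    rewards occur in this arena).

    ``dest_mode``: ``'fixed'`` (default) keeps one destination for the
    whole run, as in the water-maze paradigm where the platform stays put
    across trials — the agent is teleported to a fresh uniform position
    after each reach and must relocate the same goal; ``'per_reset'``
    resamples the destination (and encodes it) on every reach.  In both
    modes the per-iteration metric is the number of destinations reached
    (DRN).
    """

    reward_window = 5

    def __init__(self, radius: float = 0.05, max_speed: float = 0.02,
                 dt: float = 1.0, dest_mode: str = "fixed",
                 n_pos: int = 16, n_dest: int = 8,
                 dest: Optional[np.ndarray] = None, seed: int = 0):
        if dest_mode not in ("fixed", "per_reset"):
            raise ValueError("dest_mode must be 'fixed' or 'per_reset'")
        self.radius = radius
        self.max_speed = max_speed
        self.dt = dt
        self.dest_mode = dest_mode
        self.n_pos = n_pos
        self.n_dest = n_dest if dest_mode == "per_reset" else 0
        self.pos_code = PopulationCode(np.linspace(0.0, 1.0, n_pos))
        self.dest_code = PopulationCode(np.linspace(0.0, 1.0, max(n_dest, 2)))
        if dest is None:
            # keep the fixed goal away from the walls
            dest = 0.1 + 0.8 * np.random.default_rng(seed + 500).random(2)
        self.fixed_dest = np.asarray(dest, dtype=float)
        self.n_in = 2 * self.n_pos + 2 * self.n_dest + 8

    def encode(self, pos: np.ndarray, dest: np.ndarray, reward_timer: np.ndarray,
               rng: np.random.Generator) -> np.ndarray:
        """One step of input spikes for a batch of agents (B, n_in)."""
        B = pos.shape[0]
        x = np.zeros((B, self.n_in))
        n_coded = 2 * self.n_pos + 2 * self.n_dest
        for b in range(B):
            parts = [population_encode(pos[b, 0], self.pos_code),
                     population_encode(pos[b, 1], self.pos_code)]
            if self.n_dest:
                parts += [population_encode(dest[b, 0], self.dest_code),
                          population_encode(dest[b, 1], self.dest_code)]
            x[b, :n_coded] = poisson_spikes(np.concatenate(parts), self.dt, rng)
        x[:, n_coded:n_coded + 4] = (reward_timer > 0)[:, None]
        return x

    def rollout(self, net, K: int, T: int, rng: np.random.Generator) -> dict:
        """Run K closed-loop episodes of T steps under the current policy."""
        from .network import NetworkStepper

        stepper = NetworkStepper(net, K)
        pos = rng.random((K, 2))
        if self.dest_mode == "fixed":
            dest = np.tile(self.fixed_dest, (K, 1))
        else:
            dest = rng.random((K, 2))
        reward_timer = np.zeros(K, dtype=int)
        actions_raw = np.zeros((K, T, 2))
        rewards = np.zeros((K, T))
        reaches = 0

        for t in range(T):
            x_t = self.encode(pos, dest, reward_timer, rng)
            z_t, lam_t = stepper.step(x_t)
            action, raw, _ = decode_action(lam_t, rng, self.max_speed)
            actions_raw[:, t] = raw
            pos = np.clip(pos + action, 0.0, 1.0)
            reached = np.linalg.norm(pos - dest, axis=1) <= self.radius
            rewards[:, t] = reached.astype(float)
            reaches += int(reached.sum())
            reward_timer = np.where(reached, self.reward_window,
                                    np.maximum(reward_timer - 1, 0))
            if reached.any():
                idx = np.flatnonzero(reached)
                pos[idx] = rng.random((idx.size, 2))
                if self.dest_mode == "per_reset":
                    dest[idx] = rng.random((idx.size, 2))

        trace = stepper.trace()
        return {
            "inputs": trace.x,
            "lam": trace.lam,
            "actions_raw": actions_raw,
            "rewards": rewards,
            "reaches": reaches,
            "mean_rate_hz": trace.z.mean() * 1000.0 / self.dt,
        }


# ---------------------------------------------------------------------------
# optional IDX (MNIST container) reader


def read_idx(path) -> np.ndarray:
    """Read an array in IDX format (the MNIST container); optional utility."""
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic[:2] != b"\x00\x00":
            raise ValueError("not an IDX file")
        dtype = {0x08: np.uint8, 0x09: np.int8, 0x0B: np.int16,
                 0x0C: np.int32, 0x0D: np.float32, 0x0E: np.float64}[magic[2]]
        ndim = magic[3]
        shape = tuple(int.from_bytes(fh.read(4), "big") for _ in range(ndim))
        data = np.frombuffer(fh.read(), dtype=np.dtype(dtype).newbyteorder(">"))
    return data.reshape(shape)
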