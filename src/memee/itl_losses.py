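"""Information-theoretic loss machinery.

Implements the error-entropy toolbox used to train the spiking networks in
this package: Gaussian kernels, kernel density estimates of the error
distribution, the Rényi quadratic entropy and its information potential,
the quantized / restricted variants (QMEE / RMEE), the half-quadratic (HQ)
auxiliary formulation that turns the RMEE objective into a tractable
weighted quadratic, plus the cross-entropy term and the combined training
criterion.

Background.  Minimum-error-entropy (MEE) learning minimizes the Rényi
quadratic entropy H2(e) = -log V(e) of the prediction errors, where

    V(e) = (1/N^2) sum_ij G_sigma(e_i - e_j)

is the *information potential* (a kernel-smoothed measure of how
concentrated the error samples are).  MEE is shift-invariant: adding a
constant to every error leaves H2 unchanged, so the error distribution can
converge away from zero.  The *restricted* MEE criterion (RMEE) cures this
by maximizing the similarity between the error density and a fixed
three-peak target at the codebook C = (0, -1, 1): errors are quantized to
the codebook and the potential becomes

    V_R(e) = (1/N^2) sum_i [phi_0 G(e_i) + phi_-1 G(e_i + 1) + phi_1 G(e_i - 1)]

with Phi = (phi_0, phi_-1, phi_1) the per-codeword sample counts.  A
half-quadratic reformulation with auxiliaries u_i, v_i, s_i < 0 makes the
objective quadratic in the errors for fixed auxiliaries, which is what the
gradient-based trainer uses.

Sign convention: the trainer *minimizes* losses, so the RMEE contribution
to the combined criterion is the negated, N^2-normalized HQ objective
(-J_R2 / N^2); minimizing it maximizes the information potential V_R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KernelSpec",
    "ErrorBatch",
    "RestrictedCodebook",
    "HQAuxiliaries",
    "LossBreakdown",
    "gaussian_kernel",
    "information_potential",
    "renyi_quadratic_entropy",
    "parzen_instantaneous_ip",
    "quantize_errors",
    "quantized_information_potential",
    "hq_auxiliaries",
    "rmee_potential",
    "rmee_hq_objective",
    "rmee_gradient",
    "cross_entropy",
    "sequence_readout_loss",
    "combined_loss",
    "STEPS_PER_IMAGE",
    "N_IMAGES",
    "readout_times",
]

#: probability clamp applied before any log
_EPS = 1e-12

#: presentation schedule of the sequential-classification task: each image is
#: rendered for 20 simulation steps and the readout for image n is taken at
#: step 20 + 20*n (1-based), i.e. one image-length after the image ends.
STEPS_PER_IMAGE = 20
N_IMAGES = 5


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel bandwidth for density estimation over scalar errors."""

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError(f"kernel bandwidth must be positive, got {self.sigma}")


@dataclass(frozen=True)
class ErrorBatch:
    """An ordered batch of scalar error samples e_i, i = 1..N."""

    errors: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.errors, dtype=float).ravel()
        if e.size < 1:
            raise ValueError("error batch must contain at least one sample")
        if not np.all(np.isfinite(e)):
            raise ValueError("error batch contains non-finite samples")
        object.__setattr__(self, "errors", e)

    @property
    def n(self) -> int:
        return int(self.errors.size)


#: fixed RMEE codebook: the target error density has peaks at exactly these values
CODEBOOK_CENTERS = (0.0, -1.0, 1.0)


@dataclass(frozen=True)
class RestrictedCodebook:
    """Quantization counts Phi = (phi_0, phi_-1, phi_1) over the codebook (0, -1, 1)."""

    counts: tuple[int, int, int]
    centers: tuple[float, float, float] = CODEBOOK_CENTERS

    def __post_init__(self) -> None:
        if tuple(self.centers) != CODEBOOK_CENTERS:
            raise ValueError("restricted codebook centers are fixed at (0, -1, 1)")
        c = tuple(int(x) for x in self.counts)
        if any(x < 0 for x in c):
            raise ValueError("quantization counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return sum(self.counts)


@dataclass(frozen=True)
class HQAuxiliaries:
    """Half-quadratic auxiliary variables (u_i, v_i, s_i), all strictly negative."""

    u: np.ndarray
    v: np.ndarray
    s: np.ndarray

    def __post_init__(self) -> None:
        for name in ("u", "v", "s"):
            a = np.asarray(getattr(self, name), dtype=float).ravel()
            if np.any(a >= 0) or np.any(a < -1):
                raise ValueError(f"HQ auxiliary {name} must lie in [-1, 0)")
            object.__setattr__(self, name, a)
        if not (self.u.size == self.v.size == self.s.size):
            raise ValueError("HQ auxiliary components must have equal length")

    @property
    def n(self) -> int:
        return int(self.u.size)


@dataclass(frozen=True)
class LossBreakdown:
    """The combined training criterion and its two components."""

    rmee_term: float
    ce_term: float
    mu: float
    combined: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError(f"weighting constant mu must be in [0, 1], got {self.mu}")
        object.__setattr__(
            self, "combined", self.mu * self.rmee_term + (1.0 - self.mu) * self.ce_term
        )


# ---------------------------------------------------------------------------
# kernels, KDE, entropy


def gaussian_kernel(x, spec: KernelSpec):
    """Gaussian kernel G_sigma(x) = exp(-x^2 / 2 sigma^2) / (sqrt(2 pi) sigma)."""
    x = np.asarray(x, dtype=float)
    s = spec.sigma
    return np.exp(-(x * x) / (2.0 * s * s)) / (np.sqrt(2.0 * np.pi) * s)


def information_potential(e: ErrorBatch, spec: KernelSpec) -> float:
    """Full O(N^2) information potential V(e) = (1/N^2) sum_ij G(e_i - e_j)."""
    d = e.errors[:, None] - e.errors[None, :]
    return float(gaussian_kernel(d, spec).sum() / e.n**2)


def renyi_quadratic_entropy(e: ErrorBatch, spec: KernelSpec) -> float:
    """Rényi quadratic entropy H2(e) = -log V(e) of the error sample."""
    return float(-np.log(information_potential(e, spec)))


def parzen_instantaneous_ip(
    e: ErrorBatch, window: int, k: int, spec: KernelSpec = KernelSpec()
) -> float:
    """Instantaneous information potential over a trailing Parzen window.

    J1 = (1/W) sum_{i=k-W+1..k} G(e_k - e_i), with 0-based index ``k`` and
    window length ``W`` not exceeding the available history k+1.
    """
    window = int(window)
    k = int(k)
    if not (1 <= window <= k + 1 <= e.n):
        raise ValueError(
            f"need 1 <= window <= k+1 <= N, got window={window}, k={k}, N={e.n}"
        )
    seg = e.errors[k - window + 1 : k + 1]
    return float(gaussian_kernel(e.errors[k] - seg, spec).sum() / window)


# ---------------------------------------------------------------------------
# quantization / RMEE


def quantize_errors(e: ErrorBatch, first_iteration: bool = False) -> RestrictedCodebook:
    """Quantize errors onto the fixed codebook (0, -1, 1).

    Counting rule: phi_0 = #{e in (-0.5, 0.5)}, phi_-1 = #{e in (-1, -0.5)},
    phi_1 = #{e in (0.5, 1)}.  Samples outside these bins (|e| >= 1) and
    samples on a bin boundary are clamped to the nearest codeword (ties at
    |e| = 0.5 go to the center 0) so that the counts always sum to N.

    On the very first training iteration of reward learning the counts are
    overridden to (N, 0, 0), before any error statistics exist.
    """
    if first_iteration:
        return RestrictedCodebook((e.n, 0, 0))
    x = e.errors
    phi0 = int(np.count_nonzero(np.abs(x) <= 0.5))
    phim = int(np.count_nonzero(x < -0.5))
    phip = int(np.count_nonzero(x > 0.5))
    return RestrictedCodebook((phi0, phim, phip))


def quantized_information_potential(
    e: ErrorBatch, centers: np.ndarray, counts: np.ndarray, spec: KernelSpec
) -> float:
    """General QMEE potential V_Q = (1/N^2) sum_i sum_j phi_j G(e_i - c_j).

    With the codebook equal to the distinct sample values and counts equal
    to their multiplicities this reduces exactly to the full potential V.
    """
    centers = np.asarray(centers, dtype=float).ravel()
    counts = np.asarray(counts, dtype=float).ravel()
    if centers.size != counts.size:
        raise ValueError("codebook centers and counts must have equal length")
    d = e.errors[:, None] - centers[None, :]
    return float((gaussian_kernel(d, spec) * counts[None, :]).sum() / e.n**2)


def hq_auxiliaries(e: ErrorBatch, spec: KernelSpec) -> HQAuxiliaries:
    """Half-quadratic auxiliaries for the current errors.

    u_i = -exp(-e_i^2 / 2 sigma^2),
    v_i = -exp(-(e_i + 1)^2 / 2 sigma^2),
    s_i = -exp(-(e_i - 1)^2 / 2 sigma^2);  all strictly negative.
    """
    s2 = 2.0 * spec.sigma**2
    x = e.errors
    return HQAuxiliaries(
        u=-np.exp(-(x**2) / s2),
        v=-np.exp(-((x + 1.0) ** 2) / s2),
        s=-np.exp(-((x - 1.0) ** 2) / s2),
    )


def _check_counts(e: ErrorBatch, cb: RestrictedCodebook) -> None:
    # the all-zero codebook is allowed as a degenerate empty weighting
    if cb.n != e.n and cb.n != 0:
        raise ValueError(f"codebook counts sum to {cb.n} but batch has {e.n} samples")


def rmee_potential(e: ErrorBatch, cb: RestrictedCodebook, spec: KernelSpec) -> float:
    """Restricted information potential

    V_R = (1/N^2) sum_i [phi_0 G(e_i) + phi_-1 G(e_i+1) + phi_1 G(e_i-1)].
    """
    _check_counts(e, cb)
    phi0, phim, phip = cb.counts
    x = e.errors
    total = (
        phi0 * gaussian_kernel(x, spec)
        + phim * gaussian_kernel(x + 1.0, spec)
        + phip * gaussian_kernel(x - 1.0, spec)
    ).sum()
    return float(total / e.n**2)


def rmee_hq_objective(e: ErrorBatch, cb: RestrictedCodebook, aux: HQAuxiliaries) -> float:
    """HQ surrogate J_R2 = sum_i [phi_0 u_i e_i^2 + phi_-1 v_i (e_i+1)^2 + phi_1 s_i (e_i-1)^2].

    For fixed auxiliaries this is a concave quadratic in the errors (the
    coefficients are negative); alternating auxiliary refresh and quadratic
    maximization never decreases V_R.
    """
    if aux.n != e.n:
        raise ValueError(f"auxiliaries have length {aux.n} but batch has {e.n}")
    phi0, phim, phip = cb.counts
    x = e.errors
    return float(
        (phi0 * aux.u * x**2 + phim * aux.v * (x + 1.0) ** 2 + phip * aux.s * (x - 1.0) ** 2).sum()
    )


def rmee_gradient(e: ErrorBatch, cb: RestrictedCodebook, aux: HQAuxiliaries) -> np.ndarray:
    """Per-sample derivative dJ_R2/de_i = 2[phi_0 u_i e_i + phi_-1 v_i (e_i+1) + phi_1 s_i (e_i-1)].

    Only the error-side factor is computed here; the derivative of the
    errors with respect to network parameters is supplied by the trainer's
    backpropagation-through-time pass.
    """
    if aux.n != e.n:
        raise ValueError(f"auxiliaries have length {aux.n} but batch has {e.n}")
    phi0, phim, phip = cb.counts
    x = e.errors
    return 2.0 * (phi0 * aux.u * x + phim * aux.v * (x + 1.0) + phip * aux.s * (x - 1.0))


# ---------------------------------------------------------------------------
# cross-entropy and the combined criterion


def cross_entropy(yhat, y) -> float:
    """Binary cross-entropy -[y log yhat + (1-y) log(1-yhat)] with probability clamp."""
    yhat = np.asarray(yhat, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(yhat < 0) or np.any(yhat > 1):
        raise ValueError("predicted probabilities must lie in [0, 1]")
    p = np.clip(yhat, _EPS, 1.0 - _EPS)
    return float(np.sum(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def _sigmoid(x):
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def readout_times(n_images: int = N_IMAGES, steps_per_image: int = STEPS_PER_IMAGE) -> np.ndarray:
    """0-based readout indices for the schedule t = 20 + 20*n (1-based), n = 1..5."""
    n = np.arange(1, n_images + 1)
    return steps_per_image + steps_per_image * n - 1


def sequence_readout_loss(readout_trace: np.ndarray, labels: np.ndarray) -> float:
    """Cross-entropy of the sequential-classification readout.

    ``readout_trace`` holds pre-sigmoid outputs y_t over time; only the five
    readout instants t = 20 + 20*n (1-based, n = 1..5) enter the loss:

        J2 = sum_n -[l_n log sigma(y_t) + (1 - l_n) log(1 - sigma(y_t))].
    """
    trace = np.asarray(readout_trace, dtype=float).ravel()
    labels = np.asarray(labels, dtype=float).ravel()
    if labels.size != N_IMAGES:
        raise ValueError(f"expected {N_IMAGES} binary labels, got {labels.size}")
    t_idx = readout_times()
    if trace.size <= t_idx[-1]:
        raise ValueError(
            f"readout trace of length {trace.size} too short for readout at step {t_idx[-1] + 1}"
        )
    return cross_entropy(_sigmoid(trace[t_idx]), labels)


def combined_loss(
    e: ErrorBatch,
    cb: RestrictedCodebook,
    aux: HQAuxiliaries,
    readout_trace: np.ndarray,
    labels: np.ndarray,
    mu: float,
) -> LossBreakdown:
    """Combined criterion: mu * RMEE term + (1 - mu) * cross-entropy term.

    The RMEE term is -J_R2 / N^2 (negated so that minimizing the combined
    loss maximizes the restricted information potential, and normalized like
    V_R so mu keeps its meaning across batch sizes).
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError(f"weighting constant mu must be in [0, 1], got {mu}")
    rmee_term = -rmee_hq_objective(e, cb, aux) / e.n**2
    ce_term = sequence_readout_loss(readout_trace, labels)
    return LossBreakdown(rmee_term=rmee_term, ce_term=ce_term, mu=mu)
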