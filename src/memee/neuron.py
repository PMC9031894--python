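"""Three-compartment adaptive-threshold spiking neuron.

The neuron has a somatic compartment U_m and two point dendrites: an
inhibitory compartment U_i and an excitatory compartment U_e.  Each
compartment is a leaky integrator of its input current; the dendrites
additionally couple into the soma through conductances g_i, g_e relative
to reversal potentials theta_i, theta_e:

    tau_m dU_m/dt = -U_m + R_m I_m + g_i (U_i - theta_i) + g_e (U_e - theta_e) - Gamma_j z_j
    tau_i dU_i/dt = -U_i + R_i I_i
    tau_e dU_e/dt = -U_e + R_e I_e

A spike (z_j = 1) is emitted when U_m crosses the adaptive threshold
Gamma_j = tau0 + alpha * tau_j and the neuron is not refractory; the
-Gamma_j z_j term implements a soft reset.  The threshold deviation tau_j
relaxes with the adaptation time constant tau_a:

    tau_j(t + dt) = beta tau_j(t) + (1 - beta) z_j(t),   beta = exp(-dt / tau_a)

which produces spike-frequency adaptation (the threshold climbs with each
spike and decays slowly back to the baseline tau0).

Training uses a surrogate gradient: the non-existent derivative of the
spike function is replaced by the triangular pseudo-derivative
dz/dv = k * max(0, 1 - |v|) of the normalized potential
v = (U_m - Gamma_j) / Gamma_j.

Integration is explicit Euler with dt = 1 ms by default.  Spikes are
stored as z in {0, 1}; the update terms are already multiplied by dt so
the dynamics do not depend on the {0, 1} vs {0, 1/dt} amplitude
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NeuronParams",
    "NeuronState",
    "step_neuron",
    "update_threshold",
    "emit_spike",
    "normalized_potential",
    "pseudo_derivative",
    "pseudo_derivative_primitive",
]


@dataclass(frozen=True)
class NeuronParams:
    """Constants of the neuron model (defaults: the reference parameter set).

    Time constants in ms, resistances in Ohm, reversal potentials in mV,
    conductances in nS; all dynamics are asserted on the dimensionless
    discretized system so the units are nominal.
    """

    tau_m: float = 20.0       # somatic membrane time constant
    tau_i: float = 20.0       # inhibitory dendrite time constant
    tau_e: float = 20.0       # excitatory dendrite time constant
    R_m: float = 1.0
    R_i: float = 1.0
    R_e: float = 1.0
    theta_i: float = 0.0      # inhibitory dendritic reversal potential
    theta_e: float = 0.0
    g_i: float = 1.0
    g_e: float = 1.0
    alpha: float = 1.8        # threshold-deviation scale
    tau0: float = 0.01        # baseline threshold
    tau_a: float = 700.0      # threshold adaptation time constant
    dt: float = 1.0
    refractory_steps: int = 3
    k_pseudo: float = 0.3     # pseudo-derivative amplitude

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_i", "tau_e", "R_m", "R_i", "R_e", "dt",
                     "tau_a", "tau0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt > min(self.tau_m, self.tau_i, self.tau_e) / 2.0:
            raise ValueError("dt must satisfy dt <= min(tau)/2 for Euler stability")
        if self.refractory_steps < 0:
            raise ValueError("refractory_steps must be non-negative")

    @property
    def beta(self) -> float:
        """Threshold-adaptation decay factor beta = exp(-dt / tau_a)."""
        return float(np.exp(-self.dt / self.tau_a))


@dataclass(frozen=True)
class NeuronState:
    """Evolving variables of one neuron (or an array of neurons)."""

    U_m: float = 0.0
    U_i: float = 0.0
    U_e: float = 0.0
    tau_j: float = 0.0        # threshold deviation
    Gamma_j: float = 0.01     # current threshold, = tau0 + alpha * tau_j
    z_j: int = 0              # spike emitted this step
    refrac_count: int = 0     # refractory steps remaining


def step_neuron(state: NeuronState, I_m: float, I_i: float, I_e: float,
                params: NeuronParams) -> NeuronState:
    """One explicit-Euler step of the compartment potentials.

    Uses the state at time t throughout (dendritic coupling and the soft
    reset -Gamma_j z_j both read the pre-step values); the spike flag and
    threshold are left untouched — ``update_threshold`` and ``emit_spike``
    complete the step.
    """
    for cur in (I_m, I_i, I_e):
        if not np.all(np.isfinite(cur)):
            raise ValueError("input currents must be finite")
    p = params
    U_i = state.U_i + (p.dt / p.tau_i) * (-state.U_i + p.R_i * I_i)
    U_e = state.U_e + (p.dt / p.tau_e) * (-state.U_e + p.R_e * I_e)
    U_m = (
        state.U_m
        + (p.dt / p.tau_m)
        * (
            -state.U_m
            + p.R_m * I_m
            + p.g_i * (state.U_i - p.theta_i)
            + p.g_e * (state.U_e - p.theta_e)
        )
        - state.Gamma_j * state.z_j
    )
    return replace(state, U_m=U_m, U_i=U_i, U_e=U_e)


def update_threshold(state: NeuronState, params: NeuronParams) -> NeuronState:
    """Advance the adaptive threshold using the spike emitted last step."""
    b = params.beta
    tau_j = b * state.tau_j + (1.0 - b) * state.z_j
    return replace(state, tau_j=tau_j, Gamma_j=params.tau0 + params.alpha * tau_j)


def emit_spike(state: NeuronState, params: NeuronParams) -> NeuronState:
    """Spike iff U_m >= Gamma_j and the neuron is not refractory.

    On a spike the refractory counter is armed; the soft reset is applied
    by the *next* ``step_neuron`` call through the -Gamma_j z_j term.
    """
    if state.refrac_count > 0:
        return replace(state, z_j=0, refrac_count=state.refrac_count - 1)
    if state.U_m >= state.Gamma_j:
        return replace(state, z_j=1, refrac_count=params.refractory_steps)
    return replace(state, z_j=0)


def normalized_potential(U_m, Gamma_j):
    """Normalized membrane potential v = (U_m - Gamma_j) / Gamma_j."""
    Gamma_j = np.asarray(Gamma_j, dtype=float)
    if np.any(Gamma_j <= 0):
        raise ValueError("threshold Gamma_j must be positive")
    return (np.asarray(U_m, dtype=float) - Gamma_j) / Gamma_j


def pseudo_derivative(v, k: float = 0.3):
    """Surrogate spike derivative dz/dv = k * max(0, 1 - |v|)."""
    return k * np.maximum(0.0, 1.0 - np.abs(np.asarray(v, dtype=float)))


def pseudo_derivative_primitive(v, k: float = 0.3):
    """Antiderivative of the pseudo-derivative (the smooth surrogate spike).

    Piecewise quadratic rising from 0 (v <= -1) to k (v >= 1), with exact
    derivative ``pseudo_derivative``.  Used by the smooth "surrogate
    forward" mode in which finite differences validate the BPTT pass.
    """
    v = np.asarray(v, dtype=float)
    vc = np.clip(v, -1.0, 1.0)
    # integral of k*(1-|s|) ds from -1 to vc; equals k*(vc+1)^2/2 on [-1,0]
    # and k*(1/2 + vc - vc^2/2) on [0,1], which share the closed form below
    return k * (0.5 + vc - np.sign(vc) * vc * vc / 2.0)
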