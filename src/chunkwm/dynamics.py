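"""Rate-coded point-neuron dynamics shared by every layer in the circuit.

Each unit integrates excitatory, inhibitory, and leak conductances into a
membrane potential on a normalized 0-1 scale, and communicates a rate-code
activation that is a thresholded sigmoidal function of its excitatory drive
relative to the drive that would put the equilibrium potential exactly at
the firing threshold.  Layer-level sparsity is regulated by pooled lateral
inhibition with a feedforward term (driven by the layer's mean net input)
and a leaky-integrated feedback term (driven by the layer's mean firing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NeuronParams",
    "FFFBParams",
    "LayerState",
    "excitatory_conductance",
    "threshold_conductance",
    "rate_activation",
    "integrate_vm",
    "fffb_inhibition",
    "settle",
]


@dataclass(frozen=True)
class NeuronParams:
    """Point-neuron biophysics on a normalized potential scale.

    The ordering ``E_i < E_l < theta < E_e`` is required: inhibition and leak
    pull the membrane below threshold while excitation pulls it above.
    """

    Cm: float = 1.0
    E_e: float = 1.0
    E_i: float = 0.25
    E_l: float = 0.3
    theta: float = 0.5
    gamma: float = 40.0
    gbar_e: float = 1.0
    gbar_i: float = 1.0
    gbar_l: float = 1.0
    g_l: float = 0.1

    def __post_init__(self) -> None:
        if not (self.E_i < self.E_l < self.theta < self.E_e):
            raise ValueError(
                "reversal potentials must satisfy E_i < E_l < theta < E_e"
            )
        if self.gamma <= 0:
            raise ValueError("activation gain gamma must be > 0")
        if self.Cm <= 0:
            raise ValueError("membrane capacitance Cm must be > 0")
        for name in ("gbar_e", "gbar_i", "gbar_l", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"conductance {name} must be >= 0")


@dataclass(frozen=True)
class FFFBParams:
    """Pooled feedforward/feedback lateral inhibition parameters."""

    Gi: float = 1.9
    ff_gain: float = 1.0
    fb_gain: float = 1.0
    ff_floor: float = 0.1
    fb_tau: float = 1.4

    def __post_init__(self) -> None:
        if self.Gi < 0 or self.ff_gain < 0 or self.fb_gain < 0:
            raise ValueError("inhibitory gains must be >= 0")
        if self.fb_tau < 1:
            raise ValueError("fb_tau must be >= 1 (cycles)")


@dataclass
class LayerState:
    """Per-neuron state of one layer after (partial) settling."""

    size: int
    y: np.ndarray = field(default=None)  # type: ignore[assignment]
    vm: np.ndarray = field(default=None)  # type: ignore[assignment]
    ge: np.ndarray = field(default=None)  # type: ignore[assignment]
    gi: float = 0.0
    fb: float = 0.0

    def __post_init__(self) -> None:
        if self.y is None:
            self.y = np.zeros(self.size)
        if self.vm is None:
            self.vm = np.zeros(self.size)
        if self.ge is None:
            self.ge = np.zeros(self.size)


def excitatory_conductance(sender_groups) -> np.ndarray:
    """Net excitatory conductance from one or more sending projections.

    Parameters
    ----------
    sender_groups : sequence of (activities, weights, relative_scale)
        ``activities`` is the sending layer's rate vector, ``weights`` the
        synaptic matrix with shape ``(n_receivers, n_senders)``, and
        ``relative_scale`` a non-negative projection-level multiplier (the
        mechanism by which, e.g., bottom-up sensory input outweighs top-down
        cortical feedback).

    Returns
    -------
    ndarray
        Per-receiver conductance: the scale-weighted sum over projections of
        the mean sender-activity-times-weight.
    """
    ge = None
    for activities, weights, scale in sender_groups:
        x = np.asarray(activities, dtype=float)
        w = np.asarray(weights, dtype=float)
        if scale < 0:
            raise ValueError("projection relative_scale must be >= 0")
        if w.ndim == 1:
            if w.shape != x.shape:
                raise ValueError("activities and weights shapes differ")
            contrib = scale * float(x @ w) / x.size
        else:
            if w.shape[1] != x.size:
                raise ValueError("activities and weights shapes differ")
            contrib = scale * (w @ x) / x.size
        ge = contrib if ge is None else ge + contrib
    if ge is None:
        raise ValueError("at least one sender group required")
    return ge


def threshold_conductance(g_i_val, g_l_val, params: NeuronParams):
    """Excitatory conductance putting the equilibrium potential at threshold.

    Solves the equilibrium of the membrane equation for ``ge`` with the
    potential pinned at ``theta``; this is the quantity the rate activation
    subtracts from the actual excitatory drive.
    """
    if params.theta == params.E_e:
        raise ValueError("theta == E_e leaves the threshold conductance undefined")
    num = (
        g_i_val * params.gbar_i * (params.E_i - params.theta)
        + g_l_val * params.gbar_l * (params.E_l - params.theta)
    )
    return num / ((params.theta - params.E_e) * params.gbar_e)


def rate_activation(ge, ge_theta, gamma: float):
    """Thresholded sigmoidal rate code: ``1 / (1 + 1/(gamma*[ge-ge_theta]+))``.

    Zero at or below threshold, strictly increasing above it, asymptoting to 1.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    drive = np.maximum(np.asarray(ge, dtype=float) - ge_theta, 0.0)
    safe = np.maximum(drive, 1e-300)
    out = np.where(drive > 0, 1.0 / (1.0 + 1.0 / (gamma * safe)), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def integrate_vm(vm, ge, gi, params: NeuronParams, dt: float):
    """One explicit-Euler step of the membrane-potential equation.

    The fixed point is the conductance-weighted mean of the reversal
    potentials; with only leak active the potential decays to ``E_l``.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    p = params
    dv = (
        ge * p.gbar_e * (p.E_e - vm)
        + gi * p.gbar_i * (p.E_i - vm)
        + p.g_l * p.gbar_l * (p.E_l - vm)
    )
    return vm + (dt / p.Cm) * dv


def fffb_inhibition(mean_net_input, mean_activation, fb_state, params: FFFBParams):
    """Pooled inhibitory conductance ``gi = Gi*(ff + fb)`` and new fb state.

    ``ff`` is thresholded-linear in the layer's mean net input; ``fb`` is a
    leaky integration of the layer's mean activation.
    """
    ff = params.ff_gain * max(0.0, mean_net_input - params.ff_floor)
    fb_new = fb_state + (1.0 / params.fb_tau) * (
        params.fb_gain * mean_activation - fb_state
    )
    gi = params.Gi * (ff + fb_new)
    return gi, fb_new


def settle(
    ge: np.ndarray,
    neuron: NeuronParams,
    fffb: FFFBParams,
    n_cycles: int = 30,
    state: LayerState | None = None,
) -> LayerState:
    """Iterate the layer equations to an approximate attractor state.

    The excitatory drive ``ge`` is held fixed (sender activities do not change
    within a settling window), so each cycle updates the pooled inhibition
    from the layer's own activity, recomputes the threshold conductance, and
    re-applies the rate activation.  Deterministic; a state that is already a
    fixed point is left unchanged by further cycles.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    ge = np.asarray(ge, dtype=float)
    if state is None:
        state = LayerState(size=ge.size)
    mean_net = float(ge.mean())
    y = state.y
    fb = state.fb
    gi = state.gi
    for _ in range(n_cycles):
        gi, fb = fffb_inhibition(mean_net, float(y.mean()), fb, fffb)
        ge_theta = threshold_conductance(gi, neuron.g_l, neuron)
        y = rate_activation(ge * neuron.gbar_e, ge_theta, neuron.gamma)
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("layer dynamics diverged (non-finite activations)")
    vm = integrate_vm(state.vm, ge, gi, neuron, dt=0.3 * neuron.Cm)
    return LayerState(size=ge.size, y=y, vm=vm, ge=ge, gi=gi, fb=fb)
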