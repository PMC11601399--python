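"""Dopaminergic reinforcement learning and error-driven report learning.

A scalar Rescorla-Wagner critic turns each recall reward into a reward
prediction error (RPE); positive RPEs become dopamine bursts and negative
RPEs dopamine dips, each scaled by its own gain.  Gating decisions leave
synaptic eligibility tags on the striatal Go/NoGo weights that drove them,
and the dopamine signal converts those tags into opponent weight changes
(bursts strengthen tagged Go weights and weaken NoGo; dips do the reverse).
The color-report mappings (input->output and PFC-output->output) learn by a
supervised delta rule against the presented or probed target bump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CriticState",
    "DopamineParams",
    "SynapticTagStore",
    "critic_rpe",
    "dopamine_signal",
    "update_tags",
    "striatal_three_factor_update",
    "report_mapping_update",
]


@dataclass
class CriticState:
    """Per-state reward expectations updated by the delta rule.

    One value per probe state (orientation): rewards differ systematically
    across probes (an orientation bound to a merged chunk earns slightly
    less than one held alone, and a given-up orientation earns chance), so
    a state-conditioned baseline is required for the prediction error to
    vanish at equilibrium instead of perpetually punishing correct but
    lower-reward policies.
    """

    n_states: int = 1
    lr_v: float = 0.05

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValueError("critic needs at least one state")
        self.values = np.zeros(self.n_states)

    @property
    def v(self) -> float:
        """Mean expectation across states (summary statistic)."""
        return float(self.values.mean())


@dataclass(frozen=True)
class DopamineParams:
    """Gains applied to positive (burst) and negative (dip) RPEs."""

    burst_gain: float = 0.6
    dip_gain: float = 0.6

    def __post_init__(self) -> None:
        if not (np.isfinite(self.burst_gain) and np.isfinite(self.dip_gain)):
            raise ValueError("dopamine gains must be finite")
        if self.burst_gain < 0 or self.dip_gain < 0:
            raise ValueError("dopamine gains must be >= 0")


@dataclass
class SynapticTagStore:
    """Per-synapse eligibility tags for each gating channel.

    Each gating competition has a winning pool per stripe: Go when the gate
    opened, NoGo when it stayed closed.  The tag matrices mirror the
    striatal weight matrices, shape ``(n_drive, n_stripes)``, one pair per
    channel: ``*_go`` flags open decisions and ``*_nogo`` flags closed
    decisions.  All tags are non-negative, decay multiplicatively each
    trial, and are incremented by pre x post activity (one-hot drive times
    the winning pool's activity) when their pool wins.
    """

    n_drive: int
    n_stripes: int
    decay: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("tag decay must lie in [0, 1]")
        shape = (self.n_drive, self.n_stripes)
        self.input_go = np.zeros(shape)
        self.input_nogo = np.zeros(shape)
        self.output_go = np.zeros(shape)
        self.output_nogo = np.zeros(shape)

    @property
    def input(self) -> np.ndarray:
        """Signed eligibility on the input channel (Go minus NoGo tags)."""
        return self.input_go - self.input_nogo

    @property
    def output(self) -> np.ndarray:
        """Signed eligibility on the output channel (Go minus NoGo tags)."""
        return self.output_go - self.output_nogo

    def reset(self) -> None:
        self.input_go[:] = 0.0
        self.input_nogo[:] = 0.0
        self.output_go[:] = 0.0
        self.output_nogo[:] = 0.0


def critic_rpe(reward: float, critic: CriticState, state: int = 0) -> float:
    """Delta-rule RPE for one state: ``delta = r - v[state]``; that state's
    expectation moves toward the reward."""
    delta = reward - critic.values[state]
    critic.values[state] += critic.lr_v * delta
    return float(delta)


def dopamine_signal(delta: float, params: DopamineParams) -> float:
    """Gain-scaled phasic dopamine: bursts for delta>0, dips for delta<0."""
    if delta > 0:
        return params.burst_gain * delta
    return params.dip_gain * delta


def update_tags(
    tags: SynapticTagStore,
    channel: str,
    drive_input: np.ndarray,
    gate_open: np.ndarray,
    closed_gain: float = 0.5,
) -> None:
    """Decay all tags, then flag this trial's gating decisions.

    ``drive_input`` is the control-input activity vector (one-hot orientation)
    and ``gate_open`` the per-stripe open flags on ``channel``.  The Go tag
    of each (drive, stripe) synapse whose gate opened grows by pre x post;
    the NoGo tag grows instead where the gate stayed closed (the suppression
    was the winning decision there).  ``closed_gain`` scales the closed-gate
    (NoGo) eligibility relative to the open-gate one: a phasically selected
    Go pool leaves a stronger trace than a tonically suppressing NoGo pool,
    which is what lets maladaptive "give up" states persist instead of being
    punished straight back open.
    """
    opened = np.asarray(gate_open, dtype=float)
    pre = np.asarray(drive_input, dtype=float)
    tags.input_go *= tags.decay
    tags.input_nogo *= tags.decay
    tags.output_go *= tags.decay
    tags.output_nogo *= tags.decay
    if channel == "input":
        tags.input_go += np.outer(pre, opened)
        tags.input_nogo += closed_gain * np.outer(pre, 1.0 - opened)
    elif channel == "output":
        tags.output_go += np.outer(pre, opened)
        tags.output_nogo += closed_gain * np.outer(pre, 1.0 - opened)
    else:
        raise ValueError(f"unknown gating channel {channel!r}")


def striatal_three_factor_update(
    go_w: np.ndarray,
    nogo_w: np.ndarray,
    tags: np.ndarray,
    da: float,
    lr_w: float = 0.1,
    w_max: float = 1.0,
) -> None:
    """Opponent dopamine-gated update of tagged Go/NoGo weights, in place.

    ``tags`` is the signed eligibility (Go-tag minus NoGo-tag).  A burst
    shifts open-tagged synapses toward Go and closed-tagged synapses toward
    NoGo (the winning pool, whichever it was, is reinforced); a dip does the
    opposite, punishing whichever decision was taken.  Untagged synapses are
    untouched; weights stay in [0, w_max].
    """
    if da == 0.0:
        return
    step = lr_w * da * np.asarray(tags, dtype=float)
    go_w += step
    nogo_w -= step
    np.clip(go_w, 0.0, w_max, out=go_w)
    np.clip(nogo_w, 0.0, w_max, out=nogo_w)


def report_mapping_update(
    projection_weights: np.ndarray,
    pre_activity: np.ndarray,
    produced: np.ndarray,
    target: np.ndarray,
    lr: float = 0.05,
) -> None:
    """Supervised delta-rule step on a plastic report projection, in place.

    ``dW = lr * (target - produced) x pre``; a perfect report leaves the
    weights unchanged, and repeated training on a fixed pair drives the
    produced pattern to the target.
    """
    projection_weights += lr * np.outer(
        np.asarray(target, dtype=float) - np.asarray(produced, dtype=float),
        np.asarray(pre_activity, dtype=float),
    )
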