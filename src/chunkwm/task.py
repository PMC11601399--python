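"""Continuous-report color task: stimuli, population codes, and scoring.

Each episode presents a sequence of (continuous color angle, discrete
orientation) pairs followed by a recall probe showing one of the stored
orientations alone; the circuit must reproduce the color bound to that
orientation.  Colors are coded as circular Gaussian activity bumps over a
ring of neurons with evenly spaced preferred angles; responses are decoded
as the activity-weighted circular mean and scored by the signed shortest-arc
error in degrees.  Reward falls off linearly with absolute error, crossing
zero at 90 degrees so that chance-level responding is reward-neutral in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ColorStimulus",
    "TrialSpec",
    "EpisodeSpec",
    "RecallResult",
    "preferred_angles",
    "encode_color",
    "decode_population",
    "signed_circular_error",
    "make_episode",
    "reward_from_error",
]

TWO_PI = 2.0 * np.pi

#: Activity level below which a unit does not count as participating in a bump.
ACTIVITY_FLOOR = 0.1


def preferred_angles(ring_size: int) -> np.ndarray:
    """Preferred angles 2*pi*k/ring_size of a ring layer, in radians."""
    return TWO_PI * np.arange(ring_size) / ring_size


def _wrap_angle(angle: float) -> float:
    return float(np.mod(angle, TWO_PI))


def encode_color(
    angle: float, ring_size: int = 20, tuning_width: float = 0.7
) -> np.ndarray:
    """Circular Gaussian bump centered on ``angle``, peak normalized to 1.

    With the default width and a 20-unit ring, about 10 units sit above the
    activity floor, giving the coarse population code used throughout the
    circuit.
    """
    if ring_size < 4:
        raise ValueError("ring_size must be >= 4")
    if tuning_width <= 0:
        raise ValueError("tuning_width must be > 0")
    prefs = preferred_angles(ring_size)
    d = np.angle(np.exp(1j * (prefs - angle)))  # circular distance in [-pi, pi]
    return np.exp(-0.5 * (d / tuning_width) ** 2)


def decode_population(
    activities: np.ndarray,
    prefs: np.ndarray | None = None,
    floor: float = 0.0,
) -> float:
    """Activity-weighted circular mean (resultant-vector angle), in radians.

    Returns ``nan`` when no unit is above ``floor`` (no-decode; the caller
    treats this as a non-response).
    """
    a = np.asarray(activities, dtype=float)
    if prefs is None:
        prefs = preferred_angles(a.size)
    w = np.where(a > floor, a, 0.0)
    if not np.any(w > 0):
        return float("nan")
    vec = np.sum(w * np.exp(1j * np.asarray(prefs)))
    if np.abs(vec) < 1e-12:
        return float("nan")
    return _wrap_angle(np.angle(vec))


def signed_circular_error(response_angle: float, target_angle: float) -> float:
    """Signed shortest-arc error (response minus target) in [-180, 180) deg."""
    diff = np.angle(np.exp(1j * (response_angle - target_angle)))
    deg = float(np.degrees(diff))
    if deg >= 180.0:  # np.angle returns (-pi, pi]; fold +180 onto -180
        deg -= 360.0
    return deg


def reward_from_error(error_deg: float) -> float:
    """Linear reward 1 - |error|/90, clipped to [-1, 1].

    Maximal at zero error, zero at 90 degrees, negative beyond; a uniform
    guesser therefore earns zero reward in expectation.
    """
    return float(np.clip(1.0 - abs(error_deg) / 90.0, -1.0, 1.0))


@dataclass
class ColorStimulus:
    """A continuous color angle bound to a discrete orientation."""

    color_angle: float
    orientation_id: int
    bump: np.ndarray = field(repr=False)

    def __init__(self, color_angle, orientation_id, ring_size=20, tuning_width=0.7):
        self.color_angle = _wrap_angle(color_angle)
        self.orientation_id = int(orientation_id)
        self.bump = encode_color(self.color_angle, ring_size, tuning_width)


@dataclass
class TrialSpec:
    """One trial of an episode: a store, an ignore, or a recall probe."""

    kind: str  # "store" | "ignore" | "recall"
    stimulus: ColorStimulus | None = None
    probe_orientation: int | None = None
    target_angle: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("store", "ignore", "recall"):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if self.kind in ("store", "ignore") and self.stimulus is None:
            raise ValueError(f"{self.kind} trial requires a stimulus")
        if self.kind == "recall" and (
            self.probe_orientation is None or self.target_angle is None
        ):
            raise ValueError("recall trial requires probe_orientation and target")


@dataclass
class EpisodeSpec:
    """An ordered sequence of store trials followed by one recall probe."""

    set_size: int
    trials: list
    seed: int | None = None

    @property
    def store_trials(self):
        return [t for t in self.trials if t.kind == "store"]

    @property
    def item_angles(self) -> list:
        return [t.stimulus.color_angle for t in self.store_trials]

    @property
    def item_orientations(self) -> list:
        return [t.stimulus.orientation_id for t in self.store_trials]


@dataclass
class RecallResult:
    """Outcome of one recall probe."""

    target_angle: float
    error_deg: float
    responded: bool
    n_output_gated: int
    lag: int
    response_angle: float | None = None
    probe_orientation: int | None = None
    episode_id: int = -1
    other_item_angles: tuple = ()
    reward: float = 0.0


def make_episode(
    set_size: int,
    n_orientations: int,
    rng: np.random.Generator,
    ring_size: int = 20,
    tuning_width: float = 0.7,
) -> EpisodeSpec:
    """Draw one episode: ``set_size`` store trials then a single recall probe.

    Orientations are sampled without replacement from the inventory of
    ``n_orientations``; colors are iid uniform on [0, 2*pi); the probe targets
    a uniformly chosen stored orientation.
    """
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    if set_size > n_orientations:
        raise ValueError(
            f"set_size ({set_size}) exceeds orientation inventory "
            f"({n_orientations}); orientations are sampled without replacement"
        )
    orients = rng.choice(n_orientations, size=set_size, replace=False)
    colors = rng.uniform(0.0, TWO_PI, size=set_size)
    trials = [
        TrialSpec(
            "store",
            stimulus=ColorStimulus(c, o, ring_size, tuning_width),
        )
        for c, o in zip(colors, orients)
    ]
    probe_idx = int(rng.integers(set_size))
    trials.append(
        TrialSpec(
            "recall",
            probe_orientation=int(orients[probe_idx]),
            target_angle=float(colors[probe_idx]),
        )
    )
    return EpisodeSpec(set_size=set_size, trials=trials)
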