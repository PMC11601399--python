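"""The gated working-memory circuit: stripes, chunk layer, BG gating.

The network holds a set of independently gateable prefrontal "stripes".
Each stripe's superficial layer transiently mirrors its source (the sensory
ring or the chunking ring); its deep layer robustly maintains whatever bump
was last input-gated into it.  A basal-ganglia module per stripe and per
channel (input gating on store trials, output gating at recall) opens its
gate when striatal Go activity exceeds NoGo activity plus exploration noise;
both pools are driven by the discrete orientation control input through
learned weights, so the gating policy is role-addressable: the orientation
bound to a color decides where it is stored and where it is read out from.

The chunking ring receives convergent excitation from the sensory input
(strong) and from every occupied deep stripe (weaker, top-down).  Pooled
lateral inhibition lets only the most excited units survive settling, so the
ring either mirrors the input (when no maintained item is nearby) or forms a
merged bump attracted toward the nearest maintained item.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import FFFBParams, NeuronParams, settle
from .learning import (
    CriticState,
    DopamineParams,
    SynapticTagStore,
    critic_rpe,
    dopamine_signal,
    report_mapping_update,
    striatal_three_factor_update,
    update_tags,
)
from .task import (
    ACTIVITY_FLOOR,
    EpisodeSpec,
    RecallResult,
    TrialSpec,
    decode_population,
    encode_color,
    reward_from_error,
    signed_circular_error,
)

__all__ = ["StripeConfig", "StripeState", "GatingRecord", "Network"]


@dataclass(frozen=True)
class StripeConfig:
    """Wiring of one stripe: its id and whether it sees the raw input or
    the chunking layer."""

    stripe_id: int
    source: str  # "input" | "chunk"

    def __post_init__(self) -> None:
        if self.source not in ("input", "chunk"):
            raise ValueError(f"unknown stripe source {self.source!r}")


@dataclass
class StripeState:
    """One stripe's transient (superficial) and maintained (deep) content."""

    superficial: np.ndarray | None = None
    deep: np.ndarray | None = None
    last_update_trial: int = -1

    @property
    def occupied(self) -> bool:
        return self.deep is not None and bool(np.any(self.deep > ACTIVITY_FLOOR))


@dataclass
class GatingRecord:
    """Per-trial log of one gating competition (one channel)."""

    trial_index: int
    channel: str  # "input" | "output"
    go: np.ndarray
    nogo: np.ndarray
    noise: np.ndarray
    open: np.ndarray  # boolean per stripe


class Network:
    """Chunk-augmented PFC-BG working-memory network.

    Parameters
    ----------
    n_stripes : int
        Number of independently gateable PFC stripes.
    n_orientations : int
        Size of the discrete orientation inventory driving the striatum.
    chunk_enabled : bool
        If True, stripe 0 is wired to the chunking ring and the remaining
        stripes to the sensory input; if False all stripes are input-linked.
    """

    def __init__(
        self,
        n_stripes: int = 2,
        n_orientations: int = 2,
        chunk_enabled: bool = True,
        ring_size: int = 20,
        tuning_width: float = 0.7,
        noise_sd: float = 0.1,
        lr_w: float = 0.2,
        lr_sup: float = 0.05,
        w_max: float = 1.0,
        tag_decay: float = 0.7,
        closed_tag_gain: float = 0.5,
        lr_v: float = 0.05,
        dopamine: DopamineParams | None = None,
        neuron: NeuronParams | None = None,
        fffb: FFFBParams | None = None,
        input_scale: float = 1.0,
        top_down_scale: float = 0.4,
        n_cycles: int = 30,
        maintenance_leak: float = 1.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        if n_stripes < 1:
            raise ValueError("need at least one stripe")
        if rng is None:
            rng = np.random.default_rng()
        self.ring_size = ring_size
        self.tuning_width = tuning_width
        self.n_orientations = n_orientations
        self.noise_sd = noise_sd
        self.lr_w = lr_w
        self.lr_sup = lr_sup
        self.w_max = w_max
        self.closed_tag_gain = closed_tag_gain
        self.input_scale = input_scale
        self.top_down_scale = top_down_scale
        self.n_cycles = n_cycles
        self.maintenance_leak = maintenance_leak
        self.chunk_enabled = chunk_enabled

        sources = (
            ["chunk"] + ["input"] * (n_stripes - 1) if chunk_enabled
            else ["input"] * n_stripes
        )
        self.stripe_configs = [StripeConfig(i, s) for i, s in enumerate(sources)]
        self.stripes = [StripeState() for _ in range(n_stripes)]

        K, n = n_orientations, n_stripes
        self.go_in = np.zeros((K, n))
        self.nogo_in = np.zeros((K, n))
        self.go_out = np.zeros((K, n))
        self.nogo_out = np.zeros((K, n))
        self.W_in_out = rng.uniform(0.0, 0.05, size=(ring_size, ring_size))
        self.W_pfc_out = rng.uniform(0.0, 0.05, size=(ring_size, ring_size))

        self.tags = SynapticTagStore(K, n, decay=tag_decay)
        self.critic = CriticState(n_states=n_orientations, lr_v=lr_v)
        self.dopamine = dopamine if dopamine is not None else DopamineParams()
        self.neuron = neuron if neuron is not None else NeuronParams()
        self.fffb = fffb if fffb is not None else FFFBParams()
        self.trial_counter = 0

    # ------------------------------------------------------------------ #
    # circuit pieces
    # ------------------------------------------------------------------ #

    @property
    def n_stripes(self) -> int:
        return len(self.stripes)

    def occupied_deep_bumps(self) -> list:
        return [s.deep for s in self.stripes if s.occupied]

    def chunk_layer_step(self, input_bump: np.ndarray) -> np.ndarray:
        """Settle the chunking ring under convergent input + top-down drive.

        One-to-one topographic projections at relative scales
        ``input_scale`` (sensory) and ``top_down_scale`` (each occupied deep
        stripe); pooled FFFB inhibition leaves at most one coherent bump.
        """
        ge = self.input_scale * input_bump
        for deep in self.occupied_deep_bumps():
            ge = ge + self.top_down_scale * deep
        state = settle(ge, self.neuron, self.fffb, self.n_cycles)
        return state.y

    def bg_gate_competition(
        self,
        channel: str,
        orientation: int,
        rng: np.random.Generator,
        trial_index: int = -1,
    ) -> GatingRecord:
        """Per-stripe Go/NoGo competition on one channel.

        A gate opens iff Go - NoGo + Gaussian exploration noise > 0; the
        decisions are independent across stripes.
        """
        if channel == "input":
            go_w, nogo_w = self.go_in, self.nogo_in
        elif channel == "output":
            go_w, nogo_w = self.go_out, self.nogo_out
        else:
            raise ValueError(f"unknown gating channel {channel!r}")
        go = go_w[orientation].copy()
        nogo = nogo_w[orientation].copy()
        if self.noise_sd > 0:
            noise = rng.normal(0.0, self.noise_sd, size=self.n_stripes)
        else:
            noise = np.zeros(self.n_stripes)
        gate_open = (go - nogo + noise) > 0
        return GatingRecord(trial_index, channel, go, nogo, noise, gate_open)

    def apply_input_gating(
        self,
        gate_open: np.ndarray,
        input_bump: np.ndarray,
        chunk_bump: np.ndarray | None,
    ) -> None:
        """Latch each opened stripe's source bump into its deep layer.

        Closed gates leave the maintained content exactly unchanged (perfect
        latch by default; a leak factor < 1 enables decay for sensitivity
        analysis).  Opening an occupied stripe overwrites its prior content.
        """
        for cfg, stripe, is_open in zip(
            self.stripe_configs, self.stripes, gate_open
        ):
            source = input_bump if cfg.source == "input" else chunk_bump
            stripe.superficial = source
            if is_open and source is not None:
                peak = float(source.max())
                stripe.deep = source / peak if peak > 0 else source.copy()
                stripe.last_update_trial = self.trial_counter
            elif stripe.deep is not None and self.maintenance_leak < 1.0:
                stripe.deep = stripe.deep * self.maintenance_leak
                if not np.any(stripe.deep > ACTIVITY_FLOOR):
                    stripe.deep = None

    def apply_output_gating(self, gate_open: np.ndarray):
        """Route opened, occupied stripes to the response pathway.

        Returns (output drive = mean of opened deep bumps or None,
        responded flag, count of opened gates).
        """
        opened = [
            s.deep
            for s, o in zip(self.stripes, gate_open)
            if o and s.occupied
        ]
        n_gated = int(np.count_nonzero(gate_open))
        if not opened:
            return None, False, n_gated
        drive = np.mean(opened, axis=0)
        return drive, True, n_gated

    # ------------------------------------------------------------------ #
    # trial execution
    # ------------------------------------------------------------------ #

    def reset_memory(self) -> None:
        """Clear maintained content (weights and critic are untouched)."""
        for s in self.stripes:
            s.superficial = None
            s.deep = None
            s.last_update_trial = -1

    def run_trial(
        self,
        trial: TrialSpec,
        rng: np.random.Generator,
        learn: bool = True,
    ):
        """Execute one trial; returns (result, gating record).

        Store trials run the chunk layer (if wired), the input-gating
        competition, the latch update, and a supervised step on the
        input->output report mapping.  Recall trials run the output-gating
        competition, decode and score the response, and (if learning)
        dispatch the reward through the critic and dopamine to the tagged
        striatal weights and the PFC->output report mapping.
        """
        self.trial_counter += 1
        if trial.kind in ("store", "ignore"):
            return self._run_store(trial, rng, learn)
        return self._run_recall(trial, rng, learn)

    def _run_store(self, trial: TrialSpec, rng, learn):
        stim = trial.stimulus
        input_bump = stim.bump
        chunk_bump = (
            self.chunk_layer_step(input_bump) if self.chunk_enabled else None
        )
        record = self.bg_gate_competition(
            "input", stim.orientation_id, rng, self.trial_counter
        )
        if trial.kind == "store":
            self.apply_input_gating(record.open, input_bump, chunk_bump)
            drive = np.zeros(self.n_orientations)
            drive[stim.orientation_id] = 1.0
            update_tags(self.tags, "input", drive, record.open,
                        self.closed_tag_gain)
        if learn:
            produced = self.W_in_out @ input_bump
            report_mapping_update(
                self.W_in_out, input_bump, produced, input_bump, self.lr_sup
            )
        return None, record

    def _run_recall(self, trial: TrialSpec, rng, learn):
        probe = trial.probe_orientation
        record = self.bg_gate_competition(
            "output", probe, rng, self.trial_counter
        )
        drive, responded, n_gated = self.apply_output_gating(record.open)
        response_angle = None
        if responded:
            out = np.maximum(self.W_pfc_out @ drive, 0.0)
            decoded = decode_population(out)
            if np.isnan(decoded):
                responded = False
            else:
                response_angle = decoded
        if responded:
            error_deg = signed_circular_error(response_angle, trial.target_angle)
        else:
            error_deg = float(rng.uniform(-180.0, 180.0))
        reward = reward_from_error(error_deg)

        one_hot = np.zeros(self.n_orientations)
        one_hot[probe] = 1.0
        update_tags(self.tags, "output", one_hot, record.open,
                    self.closed_tag_gain)

        if learn:
            delta = critic_rpe(reward, self.critic, probe)
            da = dopamine_signal(delta, self.dopamine)
            striatal_three_factor_update(
                self.go_in, self.nogo_in, self.tags.input, da,
                self.lr_w, self.w_max,
            )
            striatal_three_factor_update(
                self.go_out, self.nogo_out, self.tags.output, da,
                self.lr_w, self.w_max,
            )
            if responded:
                target_bump = encode_color(
                    trial.target_angle, self.ring_size, self.tuning_width
                )
                produced = np.maximum(self.W_pfc_out @ drive, 0.0)
                report_mapping_update(
                    self.W_pfc_out, drive, produced, target_bump, self.lr_sup
                )
        self.tags.reset()  # episode boundary

        result = RecallResult(
            target_angle=trial.target_angle,
            error_deg=error_deg,
            responded=responded,
            n_output_gated=n_gated,
            lag=-1,
            response_angle=response_angle,
            probe_orientation=probe,
            reward=reward,
        )
        return result, record

    def run_episode(
        self,
        episode: EpisodeSpec,
        rng: np.random.Generator,
        learn: bool = True,
        collect_records: bool = False,
    ):
        """Run a full episode; returns (RecallResult, occupancy, records).

        ``occupancy`` is the per-stripe occupied flag measured immediately
        after the final store trial.  Memory is cleared at episode start.
        """
        stored = {}
        for t in episode.store_trials:
            stored[t.stimulus.orientation_id] = t.stimulus.color_angle
        recalls = [t for t in episode.trials if t.kind == "recall"]
        for t in recalls:
            if t.probe_orientation not in stored:
                raise ValueError(
                    "malformed episode: recall probes an orientation that "
                    "was never stored"
                )
        self.reset_memory()
        self.tags.reset()
        records = [] if collect_records else None
        result = None
        occupancy = None
        n_store = len(episode.store_trials)
        store_seen = 0
        for t in episode.trials:
            res, rec = self.run_trial(t, rng, learn)
            if collect_records:
                records.append(rec)
            if t.kind == "store":
                store_seen += 1
                if store_seen == n_store:
                    occupancy = np.array([s.occupied for s in self.stripes])
            if t.kind == "recall":
                result = res
                orients = episode.item_orientations
                idx = max(
                    i for i, o in enumerate(orients)
                    if o == t.probe_orientation
                )
                result.lag = n_store - 1 - idx
                result.other_item_angles = tuple(
                    a for i, a in enumerate(episode.item_angles) if i != idx
                )
        return result, occupancy, records
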