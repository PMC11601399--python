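"""Unit tests for the gated working-memory circuit."""

import numpy as np
import pytest

from chunkwm.circuit import GatingRecord, Network, StripeConfig, StripeState
from chunkwm.task import (
    TrialSpec,
    decode_population,
    encode_color,
    make_episode,
    signed_circular_error,
)


def make_network(**kw):
    kw.setdefault("n_stripes", 2)
    kw.setdefault("n_orientations", 2)
    kw.setdefault("chunk_enabled", False)
    kw.setdefault("rng", np.random.default_rng(0))
    return Network(**kw)


class TestWiring:
    def test_chunk_model_has_one_chunk_stripe(self):
        net = make_network(chunk_enabled=True, n_stripes=3)
        assert [c.source for c in net.stripe_configs] == [
            "chunk", "input", "input",
        ]

    def test_no_chunk_model_is_all_input(self):
        net = make_network(chunk_enabled=False, n_stripes=3)
        assert all(c.source == "input" for c in net.stripe_configs)

    def test_invalid_source_rejected(self):
        with pytest.raises(ValueError):
            StripeConfig(0, "thalamus")

    def test_weight_shapes(self):
        net = make_network(n_stripes=4, n_orientations=3)
        assert net.go_in.shape == (3, 4)
        assert net.go_out.shape == (3, 4)
        assert net.W_in_out.shape == (20, 20)


class TestGating:
    def test_zero_weights_zero_noise_keeps_gates_closed(self):
        net = make_network(noise_sd=0.0)
        rec = net.bg_gate_competition("input", 0, np.random.default_rng(0))
        assert isinstance(rec, GatingRecord)
        assert not rec.open.any()

    def test_go_above_nogo_opens_deterministically(self):
        net = make_network(noise_sd=0.0)
        net.go_in[0, 1] = 0.6
        rec = net.bg_gate_competition("input", 0, np.random.default_rng(0))
        assert list(rec.open) == [False, True]

    def test_unknown_channel_rejected(self):
        net = make_network()
        with pytest.raises(ValueError):
            net.bg_gate_competition("lateral", 0, np.random.default_rng(0))

    def test_orientation_selects_weight_row(self):
        net = make_network(noise_sd=0.0)
        net.go_in[1, 0] = 0.9
        rec0 = net.bg_gate_competition("input", 0, np.random.default_rng(0))
        rec1 = net.bg_gate_competition("input", 1, np.random.default_rng(0))
        assert not rec0.open.any()
        assert rec1.open[0] and not rec1.open[1]


class TestMaintenance:
    def test_latch_stores_and_holds(self):
        net = make_network(noise_sd=0.0)
        bump = encode_color(1.0)
        net.apply_input_gating(np.array([True, False]), bump, None)
        assert net.stripes[0].occupied
        assert not net.stripes[1].occupied
        held = net.stripes[0].deep.copy()
        # closed gates on later trials leave the content exactly unchanged
        for _ in range(10):
            net.apply_input_gating(
                np.array([False, False]), encode_color(4.0), None
            )
        assert np.array_equal(net.stripes[0].deep, held)

    def test_open_gate_overwrites(self):
        net = make_network(noise_sd=0.0)
        net.apply_input_gating(np.array([True, False]), encode_color(1.0), None)
        net.apply_input_gating(np.array([True, False]), encode_color(4.0), None)
        decoded = decode_population(net.stripes[0].deep)
        assert abs(signed_circular_error(decoded, 4.0)) < 10.0

    def test_stored_bump_renormalized_to_unit_peak(self):
        net = make_network(noise_sd=0.0)
        net.apply_input_gating(
            np.array([True, False]), 0.3 * encode_color(2.0), None
        )
        assert net.stripes[0].deep.max() == pytest.approx(1.0)

    def test_maintenance_leak_eventually_clears(self):
        net = make_network(noise_sd=0.0, maintenance_leak=0.7)
        net.apply_input_gating(np.array([True, False]), encode_color(1.0), None)
        for _ in range(20):
            net.apply_input_gating(
                np.array([False, False]), encode_color(1.0), None
            )
        assert not net.stripes[0].occupied

    def test_reset_memory_clears_stripes_not_weights(self):
        net = make_network()
        net.go_in[:] = 0.5
        net.apply_input_gating(np.array([True, True]), encode_color(0.5), None)
        net.reset_memory()
        assert not any(s.occupied for s in net.stripes)
        assert np.all(net.go_in == 0.5)


class TestChunkLayer:
    def probe_deviation(self, separation_deg):
        """Chunk-bump deviation toward a maintained item at the given
        separation from the input."""
        net = make_network(chunk_enabled=True, noise_sd=0.0)
        base = 2.0
        other = base + np.radians(separation_deg)
        net.stripes[1].deep = encode_color(other)
        y = net.chunk_layer_step(encode_color(base))
        decoded = decode_population(y)
        if np.isnan(decoded):
            return np.nan
        return signed_circular_error(decoded, base)

    def test_mirrors_input_when_memory_empty(self):
        net = make_network(chunk_enabled=True, noise_sd=0.0)
        y = net.chunk_layer_step(encode_color(2.0))
        decoded = decode_population(y)
        assert abs(signed_circular_error(decoded, 2.0)) < 10.0

    def test_nearby_item_attracts_the_bump(self):
        dev = self.probe_deviation(60.0)
        assert 5.0 < dev < 60.0  # pulled toward the neighbor, not onto it

    def test_far_item_does_not_attract(self):
        dev = self.probe_deviation(180.0)
        assert np.isnan(dev) or abs(dev) < 10.0

    def test_attraction_rises_then_falls_with_separation(self):
        devs = {s: self.probe_deviation(s) for s in (20, 70, 160)}
        assert devs[70] > devs[20] - 1e-9
        assert (np.isnan(devs[160])) or devs[160] < devs[70]


class TestOutputGating:
    def test_counts_opened_gates(self):
        net = make_network(noise_sd=0.0)
        net.stripes[0].deep = encode_color(1.0)
        drive, responded, n = net.apply_output_gating(np.array([True, True]))
        assert responded and n == 2
        assert np.array_equal(drive, net.stripes[0].deep)

    def test_empty_stripes_do_not_respond(self):
        net = make_network(noise_sd=0.0)
        drive, responded, n = net.apply_output_gating(np.array([True, True]))
        assert drive is None and not responded and n == 2

    def test_multiple_open_stripes_average(self):
        net = make_network(noise_sd=0.0)
        net.stripes[0].deep = encode_color(1.0)
        net.stripes[1].deep = encode_color(2.0)
        drive, responded, _ = net.apply_output_gating(np.array([True, True]))
        expected = 0.5 * (net.stripes[0].deep + net.stripes[1].deep)
        assert np.allclose(drive, expected)


class TestEpisodes:
    def test_run_episode_outputs(self):
        net = make_network()
        rng = np.random.default_rng(3)
        ep = make_episode(2, 2, rng)
        result, occupancy, records = net.run_episode(
            ep, rng, learn=True, collect_records=True
        )
        assert occupancy.shape == (2,)
        assert len(records) == len(ep.trials)
        assert result.lag in (0, 1)
        assert len(result.other_item_angles) == 1
        assert -180.0 <= result.error_deg < 180.0

    def test_closed_gates_mean_nonresponse(self):
        net = make_network(noise_sd=0.0)  # zero weights: everything closed
        rng = np.random.default_rng(0)
        ep = make_episode(2, 2, rng)
        result, occupancy, _ = net.run_episode(ep, rng, learn=False)
        assert not occupancy.any()
        assert not result.responded
        assert result.response_angle is None

    def test_malformed_episode_rejected(self):
        net = make_network()
        ep = make_episode(2, 2, np.random.default_rng(0))
        ep.trials[-1] = TrialSpec(
            "recall", probe_orientation=99, target_angle=1.0
        )
        with pytest.raises(ValueError):
            net.run_episode(ep, np.random.default_rng(0))

    def test_tags_reset_at_episode_boundary(self):
        net = make_network()
        rng = np.random.default_rng(5)
        net.run_episode(make_episode(2, 2, rng), rng, learn=True)
        assert not np.any(net.tags.input) and not np.any(net.tags.output)

    def test_learning_changes_weights(self):
        net = make_network(noise_sd=0.5)
        rng = np.random.default_rng(7)
        before = net.go_in.copy()
        for _ in range(20):
            net.run_episode(make_episode(2, 2, rng), rng, learn=True)
        assert not np.array_equal(net.go_in, before)

    def test_learn_false_freezes_weights_and_critic(self):
        net = make_network(noise_sd=0.5)
        rng = np.random.default_rng(9)
        snapshot = (net.go_in.copy(), net.W_pfc_out.copy(), net.critic.v)
        for _ in range(10):
            net.run_episode(make_episode(2, 2, rng), rng, learn=False)
        assert np.array_equal(net.go_in, snapshot[0])
        assert np.array_equal(net.W_pfc_out, snapshot[1])
        assert net.critic.v == snapshot[2]

    def test_stripe_state_occupancy_floor(self):
        s = StripeState()
        assert not s.occupied
        s.deep = np.full(20, 0.05)
        assert not s.occupied
        s.deep = np.full(20, 0.5)
        assert s.occupied
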