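"""Continuous attractor bubbles, mixed object-place memories, traversal
recall and ring path integration."""

import math

import numpy as np
import pytest

from hipposim.cann import (
    Bubble,
    CannConfig,
    MixedCannConfig,
    RingSystem,
    build_cann,
    recall_object_from_place,
    recall_place_from_object,
    ring_path_integration,
    settle_bubble,
    standard_object_place_fixture,
    store_mixed,
    traverse_recall,
)
from hipposim.metrics import pattern_overlap
from hipposim.patterns import degrade_cue, make_gaussian_bump, make_mixed_memory


@pytest.fixture(scope="module")
def ring_net():
    cfg = CannConfig(n_units=1000, sigma=20.0, steps=100)
    return cfg, build_cann(cfg)


@pytest.fixture(scope="module")
def two_memory_net():
    """The canonical mixed fixture: memories at locations 300 and 500."""
    memories, cfg, W = standard_object_place_fixture((300.0, 500.0), seed=3)
    return memories, cfg, W


def circ_dist(a, b, n=1000):
    return abs((a - b + n / 2) % n - n / 2)


class TestWeights:
    def test_identical_tuning_maximal_weight(self, ring_net):
        cfg, W = ring_net
        offd = W + np.diag(np.full(cfg.n_units, -np.inf))
        i, j = np.unravel_index(np.argmax(offd), W.shape)
        assert circ_dist(i, j) == 1  # nearest neighbours (self excluded)

    def test_weight_decays_with_distance(self, ring_net):
        """The Gaussian-overlap weight profile decays monotonically out
        to 3 sigma, following exp(-d^2/(4 sigma^2))."""
        cfg, W = ring_net
        d = np.arange(1, int(3 * cfg.sigma))
        profile = W[0, d]
        assert np.all(np.diff(profile) < 0)
        expected = np.exp(-(d**2) / (4 * cfg.sigma**2))
        expected = (expected - expected * 0)  # shape only
        prof_n = (profile - profile.min()) / (profile.max() - profile.min())
        exp_n = (expected - expected.min()) / (expected.max() - expected.min())
        assert np.allclose(prof_n, exp_n, atol=0.02)

    def test_ring_translation_symmetry(self, ring_net):
        cfg, W = ring_net
        assert W[10, 40] == pytest.approx(W[110, 140], abs=1e-9)
        assert W[0, 990] == pytest.approx(W[500, 490], abs=1e-9)


class TestBubble:
    def test_settles_at_cued_location(self, ring_net):
        cfg, W = ring_net
        b = settle_bubble(W, 300.0, cfg)
        assert circ_dist(b.center, 300.0) <= 1.0

    def test_zero_noise_persistence(self, ring_net):
        cfg, W = ring_net
        b = settle_bubble(W, 300.0, cfg)
        long_cfg = CannConfig(n_units=1000, sigma=20.0, steps=1000)
        b2 = settle_bubble(W, b.pattern, long_cfg)
        assert circ_dist(b2.center, b.center) <= 2.0

    def test_two_cues_single_survivor(self, ring_net):
        cfg, W = ring_net
        cue = make_gaussian_bump(1000, 200, 20.0) + 0.95 * make_gaussian_bump(1000, 700, 20.0)
        b = settle_bubble(W, cue, cfg)
        active = np.flatnonzero(b.pattern)
        # all activity within one sigma-scale neighbourhood of the winner
        assert all(circ_dist(u, b.center) < 4 * cfg.sigma for u in active)

    def test_translation_equivariance(self, ring_net):
        cfg, W = ring_net
        for d in (55, 137, 402):
            b1 = settle_bubble(W, 100.0, cfg)
            b2 = settle_bubble(W, 100.0 + d, cfg)
            assert circ_dist(b2.center - b1.center, d) <= 1.0

    def test_single_contiguous_packet(self, ring_net):
        """At default inhibition the active set is contiguous (mod ring)
        in >= 95% of settles over random cue positions."""
        cfg, W = ring_net
        rng = np.random.default_rng(0)
        good = 0
        n_trials = 40
        for _ in range(n_trials):
            b = settle_bubble(W, float(rng.uniform(0, 1000)), cfg)
            active = np.sort(np.flatnonzero(b.pattern))
            gaps = np.diff(np.concatenate([active, [active[0] + 1000]]))
            good += int((gaps > 1).sum() <= 1)  # one wrap gap only
        assert good / n_trials >= 0.95

    def test_zero_cue_flagged(self, ring_net):
        cfg, W = ring_net
        b = settle_bubble(W, np.zeros(1000), cfg)
        assert not b.exists


class TestMixedMemories:
    def test_object_cue_recalls_place(self, two_memory_net):
        memories, cfg, W = two_memory_net
        b1 = recall_place_from_object(W, memories[0].discrete, cfg)
        b2 = recall_place_from_object(W, memories[1].discrete, cfg)
        assert circ_dist(b1.center, 300.0) <= 2.0
        assert circ_dist(b2.center, 500.0) <= 2.0

    def test_partial_object_cue_still_completes(self, two_memory_net):
        memories, cfg, W = two_memory_net
        half = degrade_cue(memories[0].discrete, 0.5, seed=1)
        b = recall_place_from_object(W, half, cfg)
        assert circ_dist(b.center, 300.0) <= 2.0

    def test_place_cue_recalls_object(self, two_memory_net):
        memories, cfg, W = two_memory_net
        for mem in memories:
            disc = recall_object_from_place(W, mem.center, cfg)
            assert pattern_overlap(disc, mem.discrete) >= 0.9

    def test_midway_cue_picks_exactly_one_winner(self, two_memory_net):
        """A noisy cue at location 400 (between the two stored memories)
        retrieves exactly one object code, never a mixture."""
        memories, cfg, W = two_memory_net
        winners = set()
        for s in range(10):
            disc = recall_object_from_place(W, 400.0, cfg, noise_sd=0.05, seed=s)
            ovs = [pattern_overlap(disc, m.discrete) for m in memories]
            assert sum(o > 0.5 for o in ovs) == 1
            winners.add(int(np.argmax(ovs)))
        assert winners == {0, 1}  # the noise really does pick either

    def test_full_mixed_cue_consistency(self):
        """Cueing with a complete memory returns a state whose continuous
        and discrete parts both match it, at a load of 5 memories."""
        memories, cfg, W = standard_object_place_fixture(
            (100.0, 300.0, 500.0, 700.0, 900.0), seed=4)
        for mem in memories:
            b = recall_place_from_object(W, mem.discrete, cfg)
            disc = recall_object_from_place(W, mem.center, cfg)
            assert pattern_overlap(b.pattern, mem.continuous) >= 0.95
            assert pattern_overlap(disc, mem.discrete) >= 0.95

    def test_zero_memories_zero_weights(self):
        cfg = MixedCannConfig()
        assert not store_mixed([], cfg).any()

    def test_weights_respect_mask(self):
        cfg = MixedCannConfig(n_units=20, n_disc=10, sigma=3.0, disc_k=2)
        mem = make_mixed_memory(5, [1, 2], N_cont=20, N_disc=10, sigma=3.0)
        rng = np.random.default_rng(0)
        mask = rng.random((30, 30)) < 0.5
        W = store_mixed([mem], cfg, mask=mask)
        assert not W[~mask].any()


class TestTraversal:
    def test_items_recalled_in_path_order(self):
        memories, cfg, W = standard_object_place_fixture(
            (100.0, 300.0, 500.0, 700.0, 900.0), seed=4)
        path = list(np.arange(50.0, 1000.0, 25.0))
        order = traverse_recall(W, path, memories, cfg)
        assert order == [m.label for m in memories]  # none missing, in order

    def test_reverse_path_reverses_order(self):
        memories, cfg, W = standard_object_place_fixture(
            (100.0, 300.0, 500.0, 700.0, 900.0), seed=4)
        path = list(np.arange(975.0, 0.0, -25.0))
        order = traverse_recall(W, path, memories, cfg)
        assert order == [m.label for m in reversed(memories)]

    def test_unpopulated_territory_yields_nothing(self):
        memories, cfg, W = standard_object_place_fixture((300.0,), seed=4)
        empty_net = store_mixed([], cfg)
        assert traverse_recall(empty_net, [100.0, 200.0], memories, cfg) == []


class TestRingPathIntegration:
    def test_full_cycle_returns_phase(self):
        rings = RingSystem([7.0, 11.0])
        ring_path_integration(rings, [7.0])
        assert rings.phases[0] == pytest.approx(0.0, abs=1e-9)
        assert rings.phases[1] == pytest.approx(7 / 11)

    def test_zero_velocity_leaves_phases(self):
        rings = RingSystem([7.0, 11.0], phases=[0.3, 0.6])
        ring_path_integration(rings, [0.0, 0.0])
        assert rings.phases == [0.3, 0.6]

    def test_decoding_matches_brute_force_oracle(self):
        """Displacements summing to 23 on rings {7, 11} decode to 23
        (checked against an independent exhaustive decoder)."""
        rings = RingSystem([7.0, 11.0])
        decoded = ring_path_integration(rings, [10.0, 8.0, 5.0])
        # independent oracle: coarse exhaustive search over positions
        best, best_cost = None, np.inf
        for pos in np.arange(0, 77, 0.01):
            cost = 0.0
            for s, ph in zip(rings.sizes, rings.phases):
                d = abs((pos / s - ph + 0.5) % 1.0 - 0.5)
                cost += d * d
            if cost < best_cost:
                best, best_cost = pos, cost
        assert decoded == pytest.approx(best, abs=0.05)
        assert decoded == pytest.approx(23.0, abs=0.05)

    def test_duplicate_ring_sizes_rejected(self):
        with pytest.raises(ValueError):
            RingSystem([7.0, 7.0])
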