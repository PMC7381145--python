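"""Local and global single-sample node entropy, checked against a brute-force oracle."""

import math
import random

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snetropy.entropy import (
    global_sne,
    local_p_vector,
    local_sne,
    sample_entropy_profile,
)
from snetropy.network import TemplateNetwork

# ---------------------------------------------------------------------------
# Brute-force oracle: a from-scratch re-evaluation of the three formulas with
# plain Python loops, independent of the package's vectorized code path.
# ---------------------------------------------------------------------------


def oracle_local_sne(states):
    total = sum(states)
    m_plus_1 = len(states)
    if total == 0:
        return 0.0
    h = 0.0
    for s in states:
        p = s / total
        if p > 0:
            h -= p * math.log(p)
    return h / m_plus_1


def oracle_global(graph, state_of, top_fraction):
    per_center = {}
    for center in graph.nodes:
        members = [center] + list(graph.neighbors(center))
        per_center[center] = oracle_local_sne([state_of[g] for g in members])
    q = graph.number_of_nodes()
    l = math.ceil(top_fraction * q)
    ranked = sorted(per_center.items(), key=lambda kv: (-kv[1], kv[0]))
    return sum(v for _, v in ranked[:l]), per_center


def random_connected_graph(rng, n_nodes):
    while True:
        g = nx.gnp_random_graph(n_nodes, 0.4, seed=rng.randrange(2**31))
        g.remove_nodes_from(list(nx.isolates(g)))
        if g.number_of_nodes() >= 2:
            return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})


class TestLocalPVector:
    def test_single_deviation_is_degenerate(self):
        assert local_p_vector([1, 0, 0]).tolist() == [1.0, 0.0, 0.0]

    def test_two_deviations_split_mass(self):
        assert local_p_vector([1, 1, 0, 0]).tolist() == [0.5, 0.5, 0.0, 0.0]

    def test_no_deviation_returns_sentinel(self):
        assert local_p_vector([0, 0, 0]).tolist() == [0.0, 0.0, 0.0]

    def test_too_short_vector_rejected(self):
        with pytest.raises(ValueError):
            local_p_vector([1])


class TestLocalSne:
    def test_degenerate_distribution_has_zero_entropy(self):
        assert local_sne([1.0, 0.0, 0.0]) == 0.0

    def test_uniform_p_over_four(self):
        assert local_sne([0.25] * 4) == pytest.approx(math.log(4) / 4, abs=1e-12)

    def test_half_half(self):
        assert local_sne([0.5, 0.5, 0.0, 0.0]) == pytest.approx(
            math.log(2) / 4, abs=1e-12
        )

    def test_sentinel_maps_to_zero(self):
        assert local_sne([0.0, 0.0, 0.0]) == 0.0

    def test_invalid_sum_rejected(self):
        with pytest.raises(ValueError):
            local_sne([0.4, 0.4])

    @given(states=st.lists(st.integers(0, 1), min_size=2, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_bound_with_equality_iff_all_deviate(self, states):
        """0 <= H <= ln(m+1)/(m+1), equality iff every member deviates."""
        h = local_sne(local_p_vector(states))
        bound = math.log(len(states)) / len(states)
        assert 0.0 <= h <= bound + 1e-12
        if all(states):
            assert h == pytest.approx(bound, abs=1e-12)
        else:
            assert h < bound


class TestSampleEntropyProfile:
    def _states(self, mapping):
        return pd.Series(mapping)

    def test_all_zero_states_give_zero_everywhere(self, star_net):
        states = self._states({n: 0 for n in star_net.nodes})
        profile = sample_entropy_profile(star_net, states)
        assert (profile.sne == 0).all()

    def test_center_deviating_alone_on_star(self, star_net):
        states = self._states({"H": 1, "L1": 0, "L2": 0, "L3": 0, "L4": 0})
        profile = sample_entropy_profile(star_net, states)
        # center's P is degenerate; each leaf sees a single deviating member
        assert (profile.sne == 0).all()
        assert profile.n_deviating["L1"] == 1

    def test_fully_deviating_star_k13(self):
        g = nx.star_graph(3)
        net = TemplateNetwork.from_graph(
            nx.relabel_nodes(g, {0: "H", 1: "a", 2: "b", 3: "c"})
        )
        states = self._states({"H": 1, "a": 1, "b": 1, "c": 1})
        profile = sample_entropy_profile(net, states)
        assert profile.sne["H"] == pytest.approx(math.log(4) / 4, abs=1e-12)
        assert profile.sne["a"] == pytest.approx(math.log(2) / 2, abs=1e-12)

    def test_missing_state_raises(self, star_net):
        with pytest.raises(KeyError):
            sample_entropy_profile(star_net, self._states({"H": 1}))


class TestGlobalSne:
    def _profile(self, net, states):
        return sample_entropy_profile(net, pd.Series(states))

    def test_top_fraction_selects_single_max_for_q20(self):
        g = nx.cycle_graph(20)
        net = TemplateNetwork.from_graph(
            nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
        )
        states = {n: 1 if n in ("n00", "n01", "n02") else 0 for n in net.nodes}
        profile = self._profile(net, states)
        score = global_sne(profile, top_fraction=0.05)
        assert score.l == 1 and score.q == 20
        assert score.h == pytest.approx(profile.sne.max())

    def test_all_zero_profile_gives_zero(self, k4_net):
        profile = self._profile(k4_net, {n: 0 for n in k4_net.nodes})
        assert global_sne(profile).h == 0.0

    def test_full_fraction_sums_everything(self, path_net):
        profile = self._profile(path_net, {"A": 1, "B": 1, "C": 0})
        score = global_sne(profile, top_fraction=1.0)
        assert score.h == pytest.approx(profile.sne.sum())
        assert score.l == 3

    def test_tie_break_is_lexicographic(self, k4_net):
        profile = self._profile(k4_net, {n: 1 for n in k4_net.nodes})
        score = global_sne(profile, top_fraction=0.25)
        assert score.selected_centers == ("A",)

    def test_monotone_in_top_fraction(self, k4_net):
        profile = self._profile(k4_net, {"A": 1, "B": 1, "C": 0, "D": 1})
        hs = [global_sne(profile, f).h for f in (0.05, 0.3, 0.6, 1.0)]
        assert hs == sorted(hs)

    def test_bad_fraction_rejected(self, k4_net):
        profile = self._profile(k4_net, {n: 0 for n in k4_net.nodes})
        with pytest.raises(ValueError):
            global_sne(profile, top_fraction=0.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("trial_block", range(4))
    def test_random_instances_match_brute_force(self, trial_block):
        """Pipeline agrees with the independent loop-based oracle to 1e-12."""
        rng = random.Random(100 + trial_block)
        for _ in range(50):
            g = random_connected_graph(rng, rng.randint(4, 12))
            net = TemplateNetwork.from_graph(g)
            state_of = {n: rng.randint(0, 1) for n in g.nodes}
            top = rng.choice([0.05, 0.1, 0.5, 1.0])
            profile = sample_entropy_profile(net, pd.Series(state_of))
            score = global_sne(profile, top_fraction=top)
            h_oracle, per_center = oracle_global(g, state_of, top)
            assert score.h == pytest.approx(h_oracle, abs=1e-12)
            for center, expected in per_center.items():
                assert profile.sne[center] == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_leaves_h_unchanged(self):
        rng = random.Random(5)
        g = random_connected_graph(rng, 10)
        state_of = {n: rng.randint(0, 1) for n in g.nodes}
        mapping = {n: f"z{i}" for i, n in enumerate(sorted(g.nodes, key=hash))}
        g2 = nx.relabel_nodes(g, mapping)
        states2 = {mapping[n]: s for n, s in state_of.items()}
        h1 = global_sne(
            sample_entropy_profile(TemplateNetwork.from_graph(g), pd.Series(state_of))
        ).h
        h2 = global_sne(
            sample_entropy_profile(TemplateNetwork.from_graph(g2), pd.Series(states2))
        ).h
        assert h1 == pytest.approx(h2, abs=1e-12)
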