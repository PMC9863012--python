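"""Normalization, Welch screening, the low-correlation graph and clique
sampling, with an exhaustive subset-search oracle for the clique enumerator."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from actipheno.selection import (build_low_correlation_graph, enumerate_cliques,
                                 sample_combinations, standard_normalize,
                                 welch_filter)
from actipheno.types import FeatureTable, Group


def table_from(values: dict, labels=None) -> FeatureTable:
    df = pd.DataFrame(values)
    df.index = [f"S{i}" for i in range(len(df))]
    if labels is None:
        labels = [Group.C] * len(df)
    return FeatureTable(df, pd.Series(labels, index=df.index))


class TestNormalize:
    def test_center_and_unit_population_sd(self):
        t, flagged = standard_normalize(table_from({"a": [1.0, 2.0, 3.0]}))
        assert t.frame["a"].mean() == pytest.approx(0.0)
        assert t.frame["a"].std(ddof=0) == pytest.approx(1.0)
        assert flagged == []

    def test_constant_column_flagged_and_centered(self):
        t, flagged = standard_normalize(table_from({"a": [4.0, 4.0, 4.0],
                                                    "b": [1.0, 2.0, 3.0]}))
        assert flagged == ["a"]
        assert np.all(t.frame["a"] == 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        t0 = table_from({"a": rng.normal(5, 2, 20), "b": rng.uniform(0, 9, 20)})
        once, _ = standard_normalize(t0)
        twice, _ = standard_normalize(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)


class TestWelch:
    def _two_class(self, a, b, name="f"):
        labels = [Group.CTF] * len(a) + [Group.C] * len(b)
        return table_from({name: list(a) + list(b)}, labels)

    def test_textbook_example_retained(self):
        t = self._two_class([1, 2, 3, 4, 5], [11, 12, 13, 14, 15])
        assert welch_filter(t, Group.CTF, alpha=0.001) == ["f"]

    def test_identical_samples_dropped(self):
        t = self._two_class([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert welch_filter(t, Group.CTF) == []

    def test_degenerate_zero_variance_dropped(self):
        t = self._two_class([2, 2, 2], [2, 2, 2])
        assert welch_filter(t, Group.CTF) == []

    def test_monotone_in_alpha(self):
        rng = np.random.default_rng(1)
        vals = {f"f{i}": rng.normal(0, 1, 20) for i in range(10)}
        labels = [Group.CTF] * 10 + [Group.C] * 10
        t = table_from(vals, labels)
        kept_low = welch_filter(t, Group.CTF, alpha=1e-12)
        kept_all = welch_filter(t, Group.CTF, alpha=1.0)
        assert kept_low == []
        assert kept_all == list(t.feature_names)


class TestGraph:
    def test_identical_columns_have_no_edge(self):
        x = [1.0, 2.0, 3.0, 4.0]
        g = build_low_correlation_graph(table_from({"a": x, "b": x}))
        assert not g.has_edge("a", "b")

    def test_independent_noise_connected(self):
        rng = np.random.default_rng(2)
        g = build_low_correlation_graph(
            table_from({"a": rng.normal(0, 1, 100), "b": rng.normal(0, 1, 100)}))
        assert g.has_edge("a", "b")

    def test_boundary_rule_threshold_is_inclusive(self):
        # "exceeds the threshold" is strict: |r| equal to the threshold keeps
        # the edge, anything above loses it
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 40)
        t = table_from({"a": a, "b": 0.4 * a + rng.normal(0, 1, 40)})
        r = float(abs(t.frame.corr().loc["a", "b"]))
        assert build_low_correlation_graph(t, threshold=r).has_edge("a", "b")
        assert not build_low_correlation_graph(
            t, threshold=r * (1 - 1e-9)).has_edge("a", "b")


def brute_force_maximal_cliques(graph, min_size):
    nodes = sorted(graph.nodes)
    cliques = []
    for k in range(min_size, len(nodes) + 1):
        for subset in itertools.combinations(nodes, k):
            if all(graph.has_edge(a, b)
                   for a, b in itertools.combinations(subset, 2)):
                others = set(nodes) - set(subset)
                maximal = not any(
                    all(graph.has_edge(o, m) for m in subset) for o in others)
                if maximal:
                    cliques.append(tuple(sorted(subset)))
    return sorted(cliques)


class TestCliques:
    def test_complete_graph(self):
        g = nx.complete_graph(8)
        combos = enumerate_cliques(g, min_size=8)
        assert len(combos) == 1 and len(combos[0].features) == 8

    def test_isolated_nodes_excluded(self):
        g = nx.complete_graph(8)
        g.add_nodes_from([8, 9])
        combos = enumerate_cliques(g, min_size=8)
        assert [sorted(c.features) for c in combos] == [list(range(8))]

    def test_undersized_max_clique_gives_nothing(self):
        assert enumerate_cliques(nx.complete_graph(7), min_size=8) == []

    def test_matches_exhaustive_subset_search(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            g = nx.gnp_random_graph(12, 0.6, seed=int(rng.integers(1 << 30)))
            got = sorted(tuple(c.features) for c in enumerate_cliques(g, min_size=4))
            assert got == brute_force_maximal_cliques(g, 4), f"trial {trial}"


class TestSampling:
    def test_sample_is_reproducible_and_capped(self):
        from actipheno.selection import FeatureCombination
        g = nx.complete_graph(9)  # maximal clique of 9: one combination
        combos = enumerate_cliques(g, min_size=8)
        assert len(sample_combinations(combos, n=1600, seed=0)) == len(combos)
        many = [FeatureCombination(features=(f"f{i}", f"g{i}"), origin_clique=i)
                for i in range(50)]
        s1 = sample_combinations(many, n=10, seed=5)
        s2 = sample_combinations(many, n=10, seed=5)
        assert [c.origin_clique for c in s1] == [c.origin_clique for c in s2]
        assert len({c.origin_clique for c in s1}) == 10

    def test_every_emitted_combination_is_a_clique(self):
        rng = np.random.default_rng(4)
        frame = {f"f{i}": rng.normal(0, 1, 60) for i in range(14)}
        t = table_from(frame, [Group.C] * 60)
        g = build_low_correlation_graph(t, threshold=0.3)
        combos = enumerate_cliques(g, min_size=4)
        corr = t.frame.corr().abs()
        sampled = sample_combinations(combos, n=20, seed=1)
        assert sampled
        for c in sampled:
            for a, b in itertools.combinations(c.features, 2):
                assert corr.loc[a, b] <= 0.3
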