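"""Contribution Decision Rate: coverage, greedy ranking, KFC selection."""

import math

import numpy as np
import pytest

import kfcnet as k
from kfcnet.cdr import coverage, rank_cdr, select_kfc

from oracles import best_coverage_of_size


def _key_net(comp_targets: dict, extra_nodes=()) -> k.CTPNetwork:
    """Build a toy key network straight from component->target sets."""
    net = k.CTPNetwork()
    for c in comp_targets:
        net.add_node(c, {"component"})
    targets = set().union(*comp_targets.values()) if comp_targets else set()
    for t in sorted(targets | set(extra_nodes)):
        net.add_node(t, {"target"})
    for c, ts in comp_targets.items():
        for t in ts:
            net.add_edge(c, t, "ct")
    return net


def _random_instance(rng, n_comp, n_targets):
    return {
        f"c{i}": {f"t{j}" for j in rng.choice(n_targets, size=rng.integers(1, 6), replace=False)}
        for i in range(n_comp)
    }


class TestCoverage:
    def test_empty_set_covers_nothing(self):
        net = _key_net({"a": {"t1"}})
        assert coverage(set(), net) == 0.0

    def test_all_components_cover_everything(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            net = _key_net(_random_instance(rng, 5, 12))
            assert coverage(net.components, net) == 1.0

    def test_unknown_ids_are_named(self):
        net = _key_net({"a": {"t1"}})
        with pytest.raises(ValueError, match="ghost"):
            coverage({"ghost"}, net)

    def test_matches_neighbourhood_union_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            sets = _random_instance(rng, 6, 14)
            net = _key_net(sets)
            universe = set().union(*sets.values())
            S = set(rng.choice(sorted(sets), size=rng.integers(1, 5), replace=False))
            expected = len(set().union(*(sets[c] for c in S))) / len(universe)
            assert coverage(S, net) == pytest.approx(expected)

    def test_monotone_in_the_component_set(self):
        rng = np.random.default_rng(8)
        sets = _random_instance(rng, 8, 20)
        net = _key_net(sets)
        comps = sorted(sets)
        for _ in range(20):
            S = set(rng.choice(comps, size=rng.integers(0, 5), replace=False))
            T = S | set(rng.choice(comps, size=rng.integers(0, 4), replace=False))
            assert coverage(S, net) <= coverage(T, net) + 1e-12


class TestRankCDR:
    def test_worked_greedy_trace(self):
        """a covers {t1,t2}, b {t2}, c {t3}: order a (2/3), c (1/3), b (0)."""
        net = _key_net({"a": {"t1", "t2"}, "b": {"t2"}, "c": {"t3"}})
        ranking = rank_cdr(net)
        assert ranking.order == ["a", "c", "b"]
        assert [e.marginal for e in ranking.entries] == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert ranking.entries[-1].cumulative == pytest.approx(1.0)

    def test_single_component_has_cdr_one(self):
        net = _key_net({"only": {"t1", "t2"}})
        ranking = rank_cdr(net)
        assert ranking.entries[0].marginal == pytest.approx(1.0)

    def test_no_components_is_an_error(self):
        with pytest.raises(ValueError, match="component"):
            rank_cdr(_key_net({}))

    def test_marginals_never_increase_and_sum_to_final(self):
        rng = np.random.default_rng(33)
        for _ in range(25):
            net = _key_net(_random_instance(rng, 8, 18))
            ranking = rank_cdr(net)
            marginals = [e.marginal for e in ranking.entries]
            assert all(a >= b - 1e-12 for a, b in zip(marginals, marginals[1:]))
            assert sum(marginals) == pytest.approx(ranking.entries[-1].cumulative)
            cums = [e.cumulative for e in ranking.entries]
            assert all(a <= b + 1e-12 for a, b in zip(cums, cums[1:]))

    def test_deterministic_under_input_permutation(self):
        rng = np.random.default_rng(2)
        sets = _random_instance(rng, 7, 15)
        net = _key_net(sets)
        shuffled = _key_net({c: sets[c] for c in rng.permutation(sorted(sets))})
        assert rank_cdr(net).order == rank_cdr(shuffled).order

    def test_greedy_equals_optimum_on_disjoint_target_sets(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            sizes = rng.integers(1, 6, size=6)
            sets, start = {}, 0
            for i, s in enumerate(sizes):
                sets[f"c{i}"] = {f"t{j}" for j in range(start, start + int(s))}
                start += int(s)
            net = _key_net(sets)
            ranking = rank_cdr(net)
            universe = set().union(*sets.values())
            for prefix in range(1, len(sets) + 1):
                opt = best_coverage_of_size(sets, universe, prefix)
                assert ranking.cumulative_at(prefix) == pytest.approx(opt / len(universe))

    def test_greedy_respects_classical_bound_on_small_instances(self):
        """Cumulative coverage at every prefix >= (1 - 1/e) x exhaustive optimum."""
        rng = np.random.default_rng(77)
        bound = 1 - 1 / math.e
        for _ in range(8):
            sets = _random_instance(rng, 8, 16)
            net = _key_net(sets)
            ranking = rank_cdr(net)
            universe = set().union(*sets.values())
            for prefix in range(1, len(sets) + 1):
                opt = best_coverage_of_size(sets, universe, prefix) / len(universe)
                assert ranking.cumulative_at(prefix) >= bound * opt - 1e-12

    def test_static_mode_sorts_by_individual_coverage(self):
        net = _key_net({"a": {"t1", "t2"}, "b": {"t1", "t2", "t3"}, "c": {"t4"}})
        ranking = rank_cdr(net, static=True)
        assert ranking.order[0] == "b"


class TestSelectKFC:
    def test_shortest_prefix_reaching_threshold(self):
        net = _key_net({"a": {"t1", "t2", "t3", "t4", "t5"},
                        "b": {"t6", "t7", "t8"},
                        "c": {"t9"},
                        "d": {"t10"}})
        ranking = rank_cdr(net)
        assert len(select_kfc(ranking, 0.90)) == 3
        assert len(select_kfc(ranking, 0.80)) == 2

    def test_unreachable_threshold_warns_and_returns_positive_prefix(self):
        # universe mode "all" keeps a node no component touches
        net = _key_net({"a": {"t1"}}, extra_nodes=["orphan"])
        ranking = rank_cdr(net, universe_mode="all")
        with pytest.warns(UserWarning, match="unreachable"):
            kfc = select_kfc(ranking, 1.0)
        assert kfc == ["a"]

    @pytest.mark.parametrize("thr", [0.0, -0.2, 1.5])
    def test_threshold_must_be_in_unit_interval(self, thr):
        net = _key_net({"a": {"t1"}})
        with pytest.raises(ValueError):
            select_kfc(rank_cdr(net), thr)


class TestRecoveryOnPlantedNetworks:
    def test_kfc_prefix_recovers_planted_components(self, seed_runs):
        """Median recovery of planted key components at threshold 0.90 >= 80%."""
        rates = []
        for run in seed_runs:
            truth = run.dataset.truth_key_components
            rates.append(len(set(run.kfc) & truth) / len(truth))
        assert float(np.median(rates)) >= 0.80
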