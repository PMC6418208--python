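"""The diversity function: exact DP, greedy ordering, reduction curve."""

from __future__ import annotations

import numpy as np
import pytest

from multidiv import (
    FixtureSpec,
    MultiplexNetwork,
    PairwiseDistanceMatrix,
    diversity,
    diversity_exact,
    diversity_greedy,
    element_set_distance,
    er_multiplex,
    global_diversity,
    layer_distance_matrix,
    node_distance_matrix,
    node_diversity,
    node_diversity_all,
    reduction_curve,
)
from multidiv.diversity_core import CapacityError

from conftest import (
    diversity_recursive_oracle,
    random_distance_matrix,
    random_ultrametric_matrix,
)


def singleton_matrix() -> PairwiseDistanceMatrix:
    return PairwiseDistanceMatrix(("solo",), np.zeros((1, 1)))


class TestElementSetDistance:
    def test_reference_example(self, ref_matrix):
        assert element_set_distance(ref_matrix, "c", ["a", "b", "d"]) == (
            pytest.approx(0.214, abs=1e-12)
        )

    def test_singleton_set(self, ref_matrix):
        assert element_set_distance(ref_matrix, "a", ["d"]) == pytest.approx(0.786)

    def test_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(5)
        dm = random_distance_matrix(rng, 6)
        labels = dm.element_labels
        for g in labels:
            members = [l for l in labels if l != g]
            expected = min(dm[(g, s)] for s in members)
            assert element_set_distance(dm, g, members) == pytest.approx(
                expected, abs=0
            )

    def test_membership_and_empty_errors(self, ref_matrix):
        with pytest.raises(ValueError):
            element_set_distance(ref_matrix, "a", ["a", "b"])
        with pytest.raises(ValueError):
            element_set_distance(ref_matrix, "a", [])

    def test_unknown_label(self, ref_matrix):
        with pytest.raises(KeyError):
            element_set_distance(ref_matrix, "z", ["a"])


class TestExactDiversity:
    def test_reference_worked_example(self, ref_matrix):
        rep = diversity_exact(ref_matrix)
        assert rep.value == pytest.approx(1.692, abs=1e-9)
        assert rep.increments == pytest.approx((0.214, 0.692, 0.786), abs=1e-9)
        assert rep.elimination_order[:2] == ("c", "b")
        assert rep.final_pair == frozenset({"a", "d"})
        assert rep.method == "dp"

    def test_singleton_is_zero(self):
        rep = diversity_exact(singleton_matrix())
        assert rep.value == 0.0
        assert rep.elimination_order == ()
        assert rep.increments == ()

    def test_pair_is_its_distance(self, ref_matrix):
        rep = diversity_exact(ref_matrix.submatrix(["a", "d"]))
        assert rep.value == pytest.approx(0.786, abs=1e-12)

    def test_matches_recursive_oracle(self):
        rng = np.random.default_rng(11)
        for k in range(2, 8):
            dm = random_distance_matrix(rng, k)
            assert diversity_exact(dm).value == pytest.approx(
                diversity_recursive_oracle(dm), abs=1e-9
            )

    def test_capacity_error_above_limit(self, ref_matrix):
        with pytest.raises(CapacityError, match="greedy"):
            diversity_exact(ref_matrix, dp_limit=3)

    def test_increments_sum_to_value(self):
        rng = np.random.default_rng(3)
        dm = random_distance_matrix(rng, 7)
        rep = diversity_exact(dm)
        assert sum(rep.increments) == pytest.approx(rep.value, abs=1e-9)


class TestGreedyDiversity:
    def test_reference_worked_example(self, ref_matrix):
        rep = diversity_greedy(ref_matrix)
        assert rep.value == pytest.approx(1.692, abs=1e-9)
        assert rep.increments == pytest.approx((0.214, 0.692, 0.786), abs=1e-9)
        assert rep.elimination_order[:2] == ("c", "b")
        assert rep.final_pair == frozenset({"a", "d"})
        assert rep.method == "greedy"

    def test_all_equal_offdiagonals(self):
        k, delta = 5, 0.3
        vals = np.full((k, k), delta)
        np.fill_diagonal(vals, 0.0)
        labels = tuple("vwxyz")
        rep = diversity_greedy(PairwiseDistanceMatrix(labels, vals))
        assert rep.value == pytest.approx((k - 1) * delta, abs=1e-12)
        # pure label tie-breaking: remove ascending, largest label survives
        assert rep.elimination_order == ("v", "w", "x", "y")
        assert rep.survivor == "z"

    def test_never_exceeds_dp_on_many_random_matrices(self):
        # every removal order lower-bounds the max-over-orders recursion
        rng = np.random.default_rng(2024)
        for trial in range(1000):
            k = 3 + trial % 6
            dm = random_distance_matrix(rng, k)
            assert diversity_greedy(dm).value <= diversity_exact(dm).value + 1e-9

    def test_agrees_with_dp_on_triples(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            dm = random_distance_matrix(rng, 3)
            assert diversity_greedy(dm).value == pytest.approx(
                diversity_exact(dm).value, abs=1e-9
            )

    def test_agrees_with_dp_on_ultrametric_matrices(self):
        rng = np.random.default_rng(29)
        for _ in range(300):
            k = int(rng.integers(3, 9))
            dm = random_ultrametric_matrix(rng, k)
            assert diversity_greedy(dm).value == pytest.approx(
                diversity_exact(dm).value, abs=1e-9
            )

    def test_contributions_sum_to_one(self, ref_matrix):
        rep = diversity_greedy(ref_matrix)
        assert sum(rep.contributions.values()) == pytest.approx(1.0, abs=1e-9)
        assert rep.contributions[rep.survivor] == 0.0

    def test_ordering_is_reversed_elimination(self, ref_matrix):
        rep = diversity_greedy(ref_matrix)
        assert rep.ordering == (rep.survivor,) + tuple(
            reversed(rep.elimination_order)
        )


class TestDiversityProperties:
    def test_superset_inequality(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            k = int(rng.integers(3, 8))
            dm = random_distance_matrix(rng, k)
            u_full = diversity_exact(dm).value
            for g in dm.element_labels:
                rest = [l for l in dm.element_labels if l != g]
                u_rest = diversity_exact(dm.submatrix(rest)).value
                d_g = element_set_distance(dm, g, rest)
                assert u_full >= u_rest + d_g - 1e-9

    def test_monotonicity_under_inclusion(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = int(rng.integers(3, 8))
            dm = random_distance_matrix(rng, k)
            u_full = diversity_exact(dm).value
            size = int(rng.integers(1, k))
            subset = list(
                rng.choice(dm.element_labels, size=size, replace=False)
            )
            assert diversity_exact(dm.submatrix(subset)).value <= u_full + 1e-9

    def test_duplicate_element_invariance(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            k = int(rng.integers(2, 7))
            dm = random_distance_matrix(rng, k)
            twin_of = int(rng.integers(0, k))
            vals = np.zeros((k + 1, k + 1))
            vals[:k, :k] = dm.values
            vals[k, :k] = dm.values[twin_of]
            vals[:k, k] = dm.values[twin_of]
            bigger = PairwiseDistanceMatrix(dm.element_labels + ("twin",), vals)
            assert diversity_exact(bigger).value == pytest.approx(
                diversity_exact(dm).value, abs=1e-9
            )

    def test_scale_equivariance(self):
        rng = np.random.default_rng(21)
        for lam in (0.25, 0.5, 2.0, 7.5):
            dm = random_distance_matrix(rng, 6)
            scaled = PairwiseDistanceMatrix(dm.element_labels, dm.values * lam)
            assert diversity_exact(scaled).value == pytest.approx(
                lam * diversity_exact(dm).value, rel=1e-9
            )
            assert diversity_greedy(scaled).value == pytest.approx(
                lam * diversity_greedy(dm).value, rel=1e-9
            )


class TestDispatch:
    def test_auto_uses_dp_when_feasible(self, ref_matrix):
        assert diversity(ref_matrix, method="auto").method == "dp"

    def test_auto_falls_back_to_greedy(self, ref_matrix):
        assert diversity(ref_matrix, method="auto", dp_limit=3).method == "greedy"

    def test_unknown_method(self, ref_matrix):
        with pytest.raises(ValueError):
            diversity(ref_matrix, method="magic")


class TestNetworkLevelDiversity:
    def test_identical_layers_zero(self):
        edges = {("a", "b"), ("b", "c")}
        net = MultiplexNetwork(("a", "b", "c"), ("p", "q", "r"),
                               {"p": edges, "q": edges, "r": edges})
        assert global_diversity(net).value == 0.0

    def test_complete_vs_empty_is_one(self):
        nodes = tuple("abcde")
        complete = {(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]}
        net = MultiplexNetwork(nodes, ("full", "void"),
                               {"full": complete, "void": set()})
        assert global_diversity(net).value == pytest.approx(1.0, abs=1e-15)

    def test_composition_with_layer_matrix(self):
        net = er_multiplex(FixtureSpec(12, 5, 0.25, 77))
        assert global_diversity(net).value == pytest.approx(
            diversity_exact(layer_distance_matrix(net)).value, abs=1e-12
        )

    def test_node_diversity_extremes(self):
        net = MultiplexNetwork(
            ("a", "b", "c"), ("p", "q"),
            {"p": set(), "q": {("a", "b"), ("a", "c")}},
        )
        assert node_diversity(net, "a").value == pytest.approx(1.0, abs=1e-15)

    def test_node_isolated_everywhere_zero(self):
        net = MultiplexNetwork(
            ("a", "b", "c"), ("p", "q"),
            {"p": {("a", "b")}, "q": {("a", "b")}},
        )
        assert node_diversity(net, "c").value == 0.0

    def test_node_diversity_composition(self, er_net):
        node = er_net.node_labels[3]
        assert node_diversity(er_net, node).value == pytest.approx(
            diversity_exact(node_distance_matrix(er_net, node)).value, abs=1e-12
        )

    def test_node_diversity_all_consistency(self):
        net = er_multiplex(FixtureSpec(8, 3, 0.3, 5))
        all_vals = node_diversity_all(net)
        assert list(all_vals) == list(net.node_labels)
        for node, val in all_vals.items():
            assert val == node_diversity(net, node).value

    def test_node_diversity_all_zero_for_identical_layers(self):
        edges = {("a", "b")}
        net = MultiplexNetwork(("a", "b"), ("p", "q"), {"p": edges, "q": edges})
        assert set(node_diversity_all(net).values()) == {0.0}

    def test_layer_duplication_leaves_node_diversity_unchanged(self):
        net = er_multiplex(FixtureSpec(7, 3, 0.3, 9))
        doubled_layers = tuple(
            f"{l}{suffix}" for l in net.layer_labels for suffix in ("x", "y")
        )
        doubled = MultiplexNetwork(
            net.node_labels,
            doubled_layers,
            {f"{l}{s}": net.edges[l] for l in net.layer_labels for s in ("x", "y")},
        )
        base = node_diversity_all(net)
        dup = node_diversity_all(doubled)
        for node in net.node_labels:
            assert dup[node] == pytest.approx(base[node], abs=1e-9)


class TestReductionCurve:
    def test_reference_example_values(self, ref_matrix):
        curve = reduction_curve(ref_matrix)
        assert [s.retained_size for s in curve] == [4, 3, 2, 1]
        assert curve[0].value == pytest.approx(1.692, abs=1e-9)
        assert curve[1].removed == "c"
        assert curve[1].value == pytest.approx(1.478, abs=1e-9)
        assert curve[2].removed == "b"
        assert curve[2].value == pytest.approx(0.786, abs=1e-9)
        assert curve[3].value == 0.0
        assert curve[3].loss_fraction == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            dm = random_distance_matrix(rng, int(rng.integers(3, 8)))
            values = [s.value for s in reduction_curve(dm)]
            assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_loss_fraction_definition(self, ref_matrix):
        curve = reduction_curve(ref_matrix)
        full = curve[0].value
        for step in curve:
            assert step.loss_fraction == pytest.approx(1 - step.value / full,
                                                       abs=1e-12)

    def test_rejects_singleton(self):
        with pytest.raises(ValueError):
            reduction_curve(singleton_matrix())
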