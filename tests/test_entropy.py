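"""Transition matrices, local entropies, stationary distributions, and the
two global entropy rates, checked against hand arithmetic and closed forms."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import sigentropy as sg
from sigentropy.entropy import entropy_profile

from conftest import make_uniform_system, random_connected_system


# ---------------------------------------------------------------------------
# Integration


class TestIntegrate:
    def test_restricts_to_common_genes(self):
        net = sg.InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D")])
        expr = sg.ExpressionMatrix(pd.DataFrame({"s": [1.0, 1.0, 1.0]}, index=["A", "B", "C"]))
        system = sg.integrate(net, expr)
        assert set(system.node_order) == {"A", "B", "C"}

    def test_isolated_after_restriction_removed(self):
        net = sg.InteractionNetwork.from_edges([("A", "B"), ("C", "D")])
        expr = sg.ExpressionMatrix(
            pd.DataFrame({"s": [1.0, 1.0, 1.0]}, index=["A", "B", "C"])
        )
        system = sg.integrate(net, expr)
        assert set(system.node_order) == {"A", "B"}

    def test_zero_replaced_by_tenth_of_min_positive(self):
        net = sg.InteractionNetwork.from_edges([("A", "B"), ("B", "C")])
        expr = sg.ExpressionMatrix(pd.DataFrame({"s": [0.0, 2.0, 5.0]}, index=["A", "B", "C"]))
        system = sg.integrate(net, expr)
        assert system.expression.loc["A", "s"] == pytest.approx(0.2)
        assert system.epsilon["s"] == pytest.approx(0.2)

    def test_disjoint_gene_sets_rejected(self):
        net = sg.InteractionNetwork.from_edges([("X", "Y")])
        expr = sg.ExpressionMatrix(pd.DataFrame({"s": [1.0]}, index=["A"]))
        with pytest.raises(ValueError, match="no genes"):
            sg.integrate(net, expr)

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            sg.ExpressionMatrix(pd.DataFrame({"s": [-1.0]}, index=["A"]))


# ---------------------------------------------------------------------------
# Transition matrix and local entropies


class TestTransitionMatrix:
    def test_path_example_probabilities(self, path_system):
        P = sg.transition_matrix(path_system, "s1")
        assert P.row("A") == pytest.approx({"B": 1.0})
        assert P.row("B") == pytest.approx({"A": 0.25, "C": 0.75})
        assert P.row("C") == pytest.approx({"B": 1.0})

    def test_star_uniform_rows(self, star5_system):
        P = sg.transition_matrix(star5_system, "s1")
        hub_row = P.row("HUB")
        assert all(v == pytest.approx(0.2) for v in hub_row.values())

    def test_row_sums_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            system = random_connected_system(rng)
            P = sg.transition_matrix(system, "s1")
            sums = np.asarray(P.matrix.sum(axis=1)).ravel()
            assert np.max(np.abs(sums - 1.0)) < 1e-12


class TestLocalEntropies:
    def test_degree_one_node_zero(self, path_system):
        prof = entropy_profile(path_system, "s1")
        by = dict(zip(prof.nodes, prof.s))
        assert by["A"] == 0.0 and by["C"] == 0.0

    def test_path_centre_value(self, path_system):
        prof = entropy_profile(path_system, "s1")
        s_b = dict(zip(prof.nodes, prof.s))["B"]
        assert s_b == pytest.approx(-(0.25 * math.log(0.25) + 0.75 * math.log(0.75)), abs=1e-12)
        assert s_b == pytest.approx(0.5623, abs=1e-4)

    def test_star_centre_log_k(self, star5_system):
        prof = entropy_profile(star5_system, "s1")
        assert dict(zip(prof.nodes, prof.s))["HUB"] == pytest.approx(math.log(5), abs=1e-12)

    def test_normalized_path_centre(self, path_system):
        prof = entropy_profile(path_system, "s1")
        assert dict(zip(prof.nodes, prof.s_norm))["B"] == pytest.approx(0.8113, abs=1e-4)

    def test_normalized_uniform_is_one_and_leaves_zero(self, star5_system):
        prof = entropy_profile(star5_system, "s1")
        by = dict(zip(prof.nodes, prof.s_norm))
        assert by["HUB"] == pytest.approx(1.0, abs=1e-12)
        assert all(by[f"L{i}"] == 0.0 for i in range(5))

    def test_entropy_bounded_by_log_degree(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            system = random_connected_system(rng)
            prof = entropy_profile(system, "s1")
            assert np.all(prof.s <= np.log(np.maximum(prof.degrees, 1)) + 1e-12)
            assert np.all((prof.s_norm >= 0) & (prof.s_norm <= 1))


# ---------------------------------------------------------------------------
# Stationary distribution


def _power_iteration_pi(P, tol=1e-14, max_iter=200_000):
    """Independent fixed-point oracle for the stationary distribution.

    Iterates the lazy chain (I + P)/2, which shares P's stationary
    distribution but cannot oscillate on bipartite graphs.
    """
    n = len(P.nodes)
    pi = np.full(n, 1.0 / n)
    M = 0.5 * (np.eye(n) + P.matrix.toarray())
    for _ in range(max_iter):
        new = pi @ M
        if np.max(np.abs(new - pi)) < tol:
            return new / new.sum()
        pi = new
    return pi / pi.sum()


class TestStationaryDistribution:
    def test_path_closed_form(self, path_system):
        pi = sg.stationary_distribution(path_system, "s1")
        assert pi == pytest.approx([0.125, 0.5, 0.375], abs=1e-12)

    def test_regular_graph_uniform(self):
        system = make_uniform_system(nx.cycle_graph(6))
        pi = sg.stationary_distribution(system, "s1")
        assert pi == pytest.approx(np.full(6, 1 / 6), abs=1e-12)

    def test_sums_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            system = random_connected_system(rng)
            assert sg.stationary_distribution(system, "s1").sum() == pytest.approx(1.0, abs=1e-12)

    def test_disconnected_rejected_with_guidance(self):
        net = sg.InteractionNetwork.from_edges([("A", "B"), ("C", "D")])
        expr = sg.ExpressionMatrix(
            pd.DataFrame({"s": np.ones(4)}, index=["A", "B", "C", "D"])
        )
        system = sg.integrate(net, expr)
        with pytest.raises(ValueError, match="largest connected component"):
            sg.stationary_distribution(system, "s")

    def test_matches_power_iteration(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            system = random_connected_system(rng)
            P = sg.transition_matrix(system, "s1")
            pi = sg.stationary_distribution(system, "s1", transition=P)
            assert np.max(np.abs(pi - _power_iteration_pi(P))) < 1e-8


# ---------------------------------------------------------------------------
# Rates


class TestMaxEntropyRate:
    def test_complete_graph(self):
        system = make_uniform_system(nx.complete_graph(4))
        assert sg.max_entropy_rate(system.network) == pytest.approx(math.log(3), abs=1e-9)

    def test_star_half_log_k(self, star5_system):
        assert sg.max_entropy_rate(star5_system.network) == pytest.approx(
            0.5 * math.log(5), abs=1e-9
        )

    def test_path_log_sqrt2(self, path_system):
        assert sg.max_entropy_rate(path_system.network) == pytest.approx(
            math.log(math.sqrt(2)), abs=1e-9
        )

    def test_single_edge_rejected(self):
        net = sg.InteractionNetwork.from_edges([("A", "B")])
        with pytest.raises(ValueError, match="nonpositive"):
            sg.max_entropy_rate(net)


class TestRates:
    def test_equilibrium_path_uniform_is_one(self):
        system = make_uniform_system(nx.path_graph(3))
        prof = entropy_profile(system, "s1")
        pi = sg.stationary_distribution(system, "s1")
        m_r = sg.max_entropy_rate(system.network)
        assert sg.equilibrium_rate(prof, pi, m_r) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 7, 12])
    def test_equilibrium_complete_graph_is_one(self, n):
        system = make_uniform_system(nx.complete_graph(n))
        prof = entropy_profile(system, "s1")
        pi = sg.stationary_distribution(system, "s1")
        m_r = sg.max_entropy_rate(system.network)
        assert sg.equilibrium_rate(prof, pi, m_r) == pytest.approx(1.0, abs=1e-9)

    def test_nonequilibrium_path_third(self):
        system = make_uniform_system(nx.path_graph(3))
        assert sg.nonequilibrium_rate(entropy_profile(system, "s1")) == pytest.approx(1 / 3)

    def test_nonequilibrium_star(self, star5_system):
        assert sg.nonequilibrium_rate(entropy_profile(star5_system, "s1")) == pytest.approx(1 / 6)

    def test_nonequilibrium_regular_graph_is_one(self):
        system = make_uniform_system(nx.cycle_graph(8))
        assert sg.nonequilibrium_rate(entropy_profile(system, "s1")) == pytest.approx(1.0)

    def test_mr_nonpositive_rejected(self, path_system):
        prof = entropy_profile(path_system, "s1")
        with pytest.raises(ValueError):
            sg.equilibrium_rate(prof, np.array([0.3, 0.4, 0.3]), 0.0)


# ---------------------------------------------------------------------------
# Entropy table


class TestEntropyTable:
    def _two_sample_system(self):
        net = sg.InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])
        expr = sg.ExpressionMatrix(
            pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
        )
        return sg.integrate(net, expr)

    def test_one_row_per_sample(self):
        table = sg.entropy_table(self._two_sample_system())
        assert list(table.index) == ["s1", "s2"]
        assert {"sr_neq", "sr_eq", "m_r", "n_nodes", "n_edges_used"} <= set(table.columns)

    def test_identical_samples_identical_rows(self):
        table = sg.entropy_table(self._two_sample_system())
        assert table.loc["s1"].equals(table.loc["s2"])

    def test_sample_order_only_permutes_rows(self):
        net = sg.InteractionNetwork.from_edges([("A", "B"), ("B", "C")])
        df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [3.0, 1.0, 2.0]}, index=["A", "B", "C"])
        t1 = sg.entropy_table(sg.integrate(net, sg.ExpressionMatrix(df)))
        t2 = sg.entropy_table(sg.integrate(net, sg.ExpressionMatrix(df[["s2", "s1"]])))
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())

    def test_scale_invariance_per_sample(self):
        """Multiplying a sample by a positive constant changes nothing."""
        net = sg.InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "D"), ("D", "B")])
        base = pd.DataFrame({"s1": [1.0, 2.0, 3.0, 4.0]}, index=["A", "B", "C", "D"])
        t1 = sg.entropy_table(sg.integrate(net, sg.ExpressionMatrix(base)))
        t2 = sg.entropy_table(sg.integrate(net, sg.ExpressionMatrix(base * 37.5)))
        assert t1["sr_neq"].iloc[0] == pytest.approx(t2["sr_neq"].iloc[0], abs=1e-14)
        assert t1["sr_eq"].iloc[0] == pytest.approx(t2["sr_eq"].iloc[0], abs=1e-14)

    def test_eq_uses_largest_component(self):
        net = sg.InteractionNetwork.from_edges([("A", "B"), ("B", "C"), ("X", "Y")])
        expr = sg.ExpressionMatrix(
            pd.DataFrame({"s": np.ones(5)}, index=["A", "B", "C", "X", "Y"])
        )
        table = sg.entropy_table(sg.integrate(net, expr))
        # eq on the LCC (path A-B-C, uniform -> 1.0); neq over all 5 nodes
        assert table["sr_eq"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert table["sr_neq"].iloc[0] == pytest.approx(1 / 5)
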