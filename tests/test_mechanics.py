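"""Cluster-graph mechanics: residuals, force balance, strain energy."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from jforce.fields import SubstrateModel, VectorField2D
from jforce.mechanics import (
    ClusterGraph,
    build_cluster_graph,
    cell_force_summaries,
    junction_force_balance,
    residual_traction,
    strain_energy,
)


class FakeInterface:
    def __init__(self, jid, a, b):
        self.junction_id = jid
        self.cell_a = a
        self.cell_b = b
        self.points = np.zeros((2, 2))


def graph_with_residuals(edges, residuals):
    """Cluster graph directly from per-cell residuals (unit masks)."""
    n = len(residuals)
    # one grid cell per cell footprint; traction = -residual per unit area
    vals = np.zeros((1, n, 2))
    for i, r in enumerate(residuals):
        vals[0, i] = -np.asarray(r)
    fld = VectorField2D((0.0, 0.0), 1.0, vals)
    masks = []
    for i in range(n):
        m = np.zeros((1, n), dtype=bool)
        m[0, i] = True
        masks.append(m)
    interfaces = [FakeInterface(k, a, b) for k, (a, b) in enumerate(edges)]
    return build_cluster_graph(masks, interfaces, fld, 1.0)


class TestResidualTraction:
    def test_zero_traction(self):
        fld = VectorField2D((0.0, 0.0), 1.0, np.zeros((8, 8, 2)))
        mask = np.ones((8, 8), dtype=bool)
        np.testing.assert_array_equal(residual_traction(mask, fld), [0.0, 0.0])

    def test_single_pixel(self):
        vals = np.zeros((4, 4, 2))
        vals[1, 2] = (2.0, 0.0)  # Pa over a 1 um^2 cell
        fld = VectorField2D((0.0, 0.0), 1.0, vals)
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 2] = True
        np.testing.assert_allclose(residual_traction(mask, fld), [-2.0, 0.0])

    def test_matches_direct_double_loop(self, rng):
        vals = rng.normal(0, 100, (20, 20, 2))
        fld = VectorField2D((0.0, 0.0), 0.5, vals)
        mask = rng.random((20, 20)) > 0.4
        expected = np.zeros(2)
        for iy in range(20):
            for ix in range(20):
                if mask[iy, ix]:
                    expected -= vals[iy, ix] * 0.25
        np.testing.assert_allclose(residual_traction(mask, fld), expected, rtol=1e-12)

    def test_empty_footprint_raises(self):
        fld = VectorField2D((0.0, 0.0), 1.0, np.zeros((4, 4, 2)))
        with pytest.raises(ValueError):
            residual_traction(np.zeros((4, 4), dtype=bool), fld)


class TestGraph:
    def test_chain_edges_are_bridges(self):
        g = graph_with_residuals([(0, 1), (1, 2)], [(1, 0), (0, 0), (-1, 0)])
        assert all(d["is_bridge"] for _, _, d in g.graph.edges(data=True))

    def test_triangle_has_no_bridges(self):
        g = graph_with_residuals(
            [(0, 1), (1, 2), (0, 2)], [(1, 0), (0, 1), (-1, -1)]
        )
        assert not any(d["is_bridge"] for _, _, d in g.graph.edges(data=True))

    def test_closing_a_loop_removes_bridges(self):
        """Adding one edge to a 3-chain turns the loop edges non-bridge,
        disabling the force-balancing calculation there."""
        chain = graph_with_residuals([(0, 1), (1, 2)], [(1, 0), (0, 0), (-1, 0)])
        looped = graph_with_residuals(
            [(0, 1), (1, 2), (0, 2)], [(1, 0), (0, 0), (-1, 0)]
        )
        assert all(d["is_bridge"] for _, _, d in chain.graph.edges(data=True))
        assert not any(d["is_bridge"] for _, _, d in looped.graph.edges(data=True))
        with pytest.raises(ValueError, match="bridge"):
            junction_force_balance(looped, (0, 1))

    def test_unknown_cell_id_raises(self):
        with pytest.raises(ValueError, match="unknown cell"):
            graph_with_residuals([(0, 5)], [(1, 0), (-1, 0)])


class TestForceBalance:
    def test_balanced_pair(self):
        g = graph_with_residuals([(0, 1)], [(-5.0, 0.0), (5.0, 0.0)])
        np.testing.assert_allclose(junction_force_balance(g, (0, 1)), [-5.0, 0.0])

    def test_noisy_pair_takes_symmetrized_mean(self):
        # residual integrals int T = (5,0) and (-4,0): the two cut
        # estimates are -5 and -4; their mean is -4.5
        g = graph_with_residuals([(0, 1)], [(-5.0, 0.0), (4.0, 0.0)])
        np.testing.assert_allclose(junction_force_balance(g, (0, 1)), [-4.5, 0.0])

    def test_antisymmetry_exact(self):
        g = graph_with_residuals(
            [(0, 1), (1, 2), (1, 3)],
            [(3.0, 1.0), (-1.0, 2.0), (-1.0, -2.0), (-1.0, -1.0)],
        )
        for a, b in g.graph.edges:
            f_ab = junction_force_balance(g, (a, b))
            f_ba = junction_force_balance(g, (b, a))
            np.testing.assert_array_equal(f_ab, -f_ba)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_tree_partition_oracle(self, seed):
        """Balance forces on random trees equal brute-force partition
        sums of the residuals over every cut."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        tree = nx.random_labeled_tree(n, seed=int(rng.integers(0, 2**31)))
        residuals = rng.normal(0, 10, (n, 2))
        residuals -= residuals.mean(axis=0)
        g = graph_with_residuals(list(tree.edges), residuals)
        for a, b in tree.edges:
            cut = tree.copy()
            cut.remove_edge(a, b)
            side = sorted(nx.node_connected_component(cut, a))
            expected = residuals[side].sum(axis=0)
            np.testing.assert_allclose(
                junction_force_balance(g, (a, b)), expected, atol=1e-9
            )


class TestSummaries:
    def test_star_sums(self):
        g = graph_with_residuals(
            [(0, 1), (0, 2), (0, 3)],
            [(0.0, 0.0), (1.0, 0.0), (-2.0, 0.0), (1.0, 0.0)],
        )
        for a, b, d in g.graph.edges(data=True):
            d["f_balance"] = junction_force_balance(g, (a, b))
            d["length_um"] = 16.0
        s = cell_force_summaries(g, source="f_balance")
        mags = sorted(v["magnitude_pN"] for v in s["per_edge"].values())
        np.testing.assert_allclose(mags, [1.0, 1.0, 2.0])
        assert s["per_cell"][0] == pytest.approx(4.0)  # hub
        assert s["cluster_total_pN"] == pytest.approx(4.0)

    def test_edge_stress_is_force_over_length(self):
        g = graph_with_residuals([(0, 1)], [(-32.0, 0.0), (32.0, 0.0)])
        g.graph.edges[0, 1]["f_balance"] = junction_force_balance(g, (0, 1))
        g.graph.edges[0, 1]["length_um"] = 16.0
        s = cell_force_summaries(g, source="f_balance")
        assert s["per_edge"][0]["stress_pN_per_um"] == pytest.approx(2.0)

    def test_missing_force_raises(self):
        g = graph_with_residuals([(0, 1)], [(-1.0, 0.0), (1.0, 0.0)])
        with pytest.raises(ValueError, match="junction ids"):
            cell_force_summaries(g, source="f_fem")


class TestStrainEnergy:
    sub = SubstrateModel(5000.0, 0.5)

    def test_zero_traction_zero_energy(self):
        fld = VectorField2D((0.0, 0.0), 1.0, np.zeros((16, 16, 2)))
        mask = np.ones((16, 16), dtype=bool)
        assert strain_energy(mask, fld, self.sub) == 0.0

    def test_quadratic_form_oracle(self):
        from jforce.evaluation import strain_energy_check

        res = strain_energy_check(seed=0, n_random=5)
        assert res["oracle_rel_diff"] < 1e-6
        assert res["min_energy_aJ"] >= 0.0

    def test_contractile_dipole_positive_and_scales_inversely_with_E(self):
        vals = np.zeros((32, 32, 2))
        vals[16, 10, 0] = 100.0
        vals[16, 22, 0] = -100.0
        fld = VectorField2D((0.0, 0.0), 1.0, vals)
        mask = np.ones((32, 32), dtype=bool)
        u1 = strain_energy(mask, fld, self.sub)
        u2 = strain_energy(
            mask, fld, SubstrateModel(2 * self.sub.youngs_modulus, 0.5)
        )
        assert u1 > 0
        assert u2 == pytest.approx(u1 / 2, rel=1e-12)

    def test_invariant_under_frame_translation(self, rng):
        vals = np.zeros((24, 24, 2))
        mask = np.zeros((24, 24), dtype=bool)
        mask[6:18, 6:18] = True
        vals[mask] = rng.normal(0, 50, (mask.sum(), 2))
        f1 = VectorField2D((0.0, 0.0), 1.0, vals)
        f2 = VectorField2D((123.4, -55.0), 1.0, vals)
        assert strain_energy(mask, f1, self.sub) == pytest.approx(
            strain_energy(mask, f2, self.sub), rel=1e-14
        )

    def test_uses_cell_own_displacement_only(self, rng):
        """The energy of a cell must not change when a neighbouring
        cell's traction is added outside its footprint."""
        vals = np.zeros((32, 32, 2))
        mask = np.zeros((32, 32), dtype=bool)
        mask[4:16, 4:16] = True
        vals[mask] = rng.normal(0, 50, (mask.sum(), 2))
        base = strain_energy(mask, VectorField2D((0, 0), 1.0, vals), self.sub)
        vals2 = vals.copy()
        vals2[20:30, 20:30] = rng.normal(0, 200, (10, 10, 2))
        with_neighbor = strain_energy(
            mask, VectorField2D((0, 0), 1.0, vals2), self.sub
        )
        assert with_neighbor == pytest.approx(base, rel=1e-12)
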