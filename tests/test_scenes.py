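"""Synthetic scene generator: geometry, traction truth, image rendering."""

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

from jforce.fields import VectorField2D
from jforce.scenes import (
    SceneConfig,
    generate_cluster_geometry,
    make_scene,
    render_bead_images,
    render_junction_intensity,
    smooth_arc_noise,
    synthesize_traction_field,
)
from jforce.tfm import boussinesq_displacement
import networkx as nx


class TestGeometry:
    def test_single_cell_has_no_junctions(self):
        geo = generate_cluster_geometry(SceneConfig(n_cells=1, topology="chain"))
        assert len(geo.cell_polygons) == 1
        assert geo.interfaces == []

    def test_minimal_loop_is_a_triangle(self):
        geo = generate_cluster_geometry(SceneConfig(n_cells=3, topology="loop", seed=2))
        assert len(geo.interfaces) == 3
        cycles = nx.cycle_basis(geo.adjacency)
        assert len(cycles) >= 1

    @pytest.mark.parametrize("topo,n", [("pair", 2), ("chain", 4), ("tree", 5)])
    def test_tree_like_topologies_are_acyclic(self, topo, n):
        geo = generate_cluster_geometry(SceneConfig(n_cells=n, topology=topo, seed=4))
        assert nx.is_tree(geo.adjacency)
        assert len(geo.interfaces) == n - 1

    def test_determinism_under_fixed_seed(self):
        a = generate_cluster_geometry(SceneConfig(n_cells=4, topology="tree", seed=7))
        b = generate_cluster_geometry(SceneConfig(n_cells=4, topology="tree", seed=7))
        for pa, pb in zip(a.cell_polygons, b.cell_polygons):
            np.testing.assert_array_equal(pa, pb)
        for ia, ib in zip(a.interfaces, b.interfaces):
            np.testing.assert_array_equal(ia.points, ib.points)

    def test_impossible_topologies_raise(self):
        with pytest.raises(ValueError):
            generate_cluster_geometry(SceneConfig(n_cells=2, topology="loop"))
        with pytest.raises(ValueError):
            generate_cluster_geometry(SceneConfig(n_cells=3, topology="pair"))

    def test_interfaces_shared_between_cells(self):
        geo = generate_cluster_geometry(SceneConfig(n_cells=2, topology="pair", seed=1))
        itf = geo.interfaces[0]
        assert {itf.cell_a, itf.cell_b} == {0, 1}
        assert len(itf.points) > 10


class TestTractionTruth:
    def test_single_cell_balances_to_zero(self):
        cfg = SceneConfig(n_cells=1, topology="chain", seed=0)
        geo = generate_cluster_geometry(cfg)
        truth = synthesize_traction_field(geo, config=cfg)
        net = truth.true_traction.integral()
        assert np.abs(net).max() < 1e-9

    def test_global_balance_all_scenes(self, pair_scene, chain4_scene, triangle_scene):
        for truth in (pair_scene, chain4_scene, triangle_scene):
            assert np.abs(truth.true_traction.integral()).max() < 1e-9
            assert np.abs(truth.true_residuals.sum(axis=0)).max() < 1e-9

    def test_pair_junction_force_equals_prescribed_residual(self):
        cfg = SceneConfig(n_cells=2, topology="pair", seed=9)
        geo = generate_cluster_geometry(cfg)
        residuals = np.array([[-5.0, 0.0], [5.0, 0.0]])
        truth = synthesize_traction_field(geo, residuals=residuals, config=cfg)
        np.testing.assert_allclose(
            truth.true_junction_forces[0]
            if truth.geometry.interfaces[0].cell_a == 0
            else -truth.true_junction_forces[0],
            [-5.0, 0.0],
            atol=1e-9,
        )

    def test_chain_partition_sums(self):
        """Edge forces of a 4-chain equal the brute-force cut sums."""
        cfg = SceneConfig(n_cells=4, topology="chain", seed=11)
        geo = generate_cluster_geometry(cfg)
        residuals = np.array([[-4.0, 0], [1.0, 0], [1.0, 0], [2.0, 0]])
        truth = synthesize_traction_field(geo, residuals=residuals, config=cfg)
        # brute-force oracle: enumerate the three cuts of the path graph
        for itf in geo.interfaces:
            g = geo.adjacency.copy()
            g.remove_edge(itf.cell_a, itf.cell_b)
            side = nx.node_connected_component(g, itf.cell_a)
            expected = residuals[sorted(side)].sum(axis=0)
            np.testing.assert_allclose(
                truth.true_junction_forces[itf.junction_id], expected, atol=1e-9
            )

    def test_prescribed_residuals_must_balance(self):
        cfg = SceneConfig(n_cells=2, topology="pair", seed=9)
        geo = generate_cluster_geometry(cfg)
        with pytest.raises(ValueError, match="sum to zero"):
            synthesize_traction_field(
                geo, residuals=np.array([[1.0, 0.0], [1.0, 0.0]]), config=cfg
            )

    def test_emergent_residuals_match_field_integrals(self, chain4_scene):
        truth = chain4_scene
        masks = truth.geometry.masks_on_grid(truth.true_traction)
        for i, m in enumerate(masks):
            measured = -truth.true_traction.integral(m)
            np.testing.assert_allclose(measured, truth.true_residuals[i], atol=1e-8)

    def test_node_wise_balance_on_tree(self, chain4_scene):
        truth = chain4_scene
        g = truth.geometry.adjacency
        for i in g.nodes:
            tot = np.zeros(2)
            for itf in truth.geometry.interfaces:
                f = truth.true_junction_forces[itf.junction_id]
                if itf.cell_a == i:
                    tot += f
                elif itf.cell_b == i:
                    tot -= f
            np.testing.assert_allclose(tot, truth.true_residuals[i], atol=1e-8)


class TestBeadImages:
    def test_zero_displacement_identity(self):
        cfg = SceneConfig(n_cells=1, seed=3, topology="chain")
        u = VectorField2D((0.0, 0.0), 2.0, np.zeros((40, 40, 2)))
        rng = np.random.default_rng(5)
        ref, defo = render_bead_images(u, cfg, (200, 200), rng)
        np.testing.assert_array_equal(ref, defo)

    def test_uniform_shift_recovered_by_phase_correlation(self):
        cfg = SceneConfig(n_cells=1, seed=3, topology="chain")
        vals = np.zeros((60, 60, 2))
        vals[:, :, 0] = 0.5  # um
        u = VectorField2D((0.0, 0.0), 2.0, vals)
        rng = np.random.default_rng(5)
        ref, defo = render_bead_images(u, cfg, (300, 300), rng)
        # Hann window suppresses the periodic-boundary bias of the
        # Fourier shift estimate
        w = np.outer(np.hanning(300), np.hanning(300))
        shift, _, _ = phase_cross_correlation(
            (ref - ref.mean()) * w, (defo - defo.mean()) * w, upsample_factor=50
        )
        # image shifts by -u in (row, col); 0.5 um = 3.125 px
        assert abs(-shift[1] * cfg.pixel_size - 0.5) < 0.05
        assert abs(shift[0]) < 0.3

    def test_seeded_rendering_is_deterministic(self):
        cfg = SceneConfig(n_cells=1, seed=3, topology="chain")
        u = VectorField2D((0.0, 0.0), 2.0, np.zeros((40, 40, 2)))
        imgs = [
            render_bead_images(u, cfg, (150, 150), np.random.default_rng(9))
            for _ in range(2)
        ]
        np.testing.assert_array_equal(imgs[0][0], imgs[1][0])
        np.testing.assert_array_equal(imgs[0][1], imgs[1][1])


class TestJunctionIntensity:
    def test_exact_linear_coupling_gives_unit_correlation(self):
        truth = make_scene(
            SceneConfig(n_cells=2, topology="pair", seed=21,
                        intensity_coupling=1.0, intensity_noise_sd=0.0)
        )
        prof = truth.junction_profiles[0]
        r = np.corrcoef(prof["intensity"], prof["stress_mag"])[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_decoupled_intensity_uncorrelated(self):
        pooled_i, pooled_s = [], []
        for seed in range(8):
            truth = make_scene(
                SceneConfig(n_cells=2, topology="pair", seed=100 + seed,
                            cell_radius=14.0, intensity_coupling=0.0,
                            intensity_noise_sd=100.0)
            )
            prof = truth.junction_profiles[0]
            pooled_i.extend(prof["intensity"])
            pooled_s.extend(prof["stress_mag"])
        r = np.corrcoef(pooled_i, pooled_s)[0, 1]
        # samples along an arc are correlated over ~corr_length, so the
        # null threshold uses the effective (decorrelated) sample count
        spacing = 1.6  # um between profile samples
        n_eff = len(pooled_i) * spacing / 10.0
        assert abs(r) < 2 / np.sqrt(n_eff)

    def test_arc_noise_autocorrelation_length(self):
        """Correlated arc noise drops below 0.5 autocorrelation at the
        configured length (checked on a long series)."""
        rng = np.random.default_rng(0)
        g = smooth_arc_noise(20000, 1.6, 10.0, rng)
        lags = np.arange(1, 12)
        ac = [np.corrcoef(g[:-m], g[m:])[0, 1] for m in lags]
        crossing = lags[np.argmax(np.array(ac) < 0.5)] * 1.6
        assert 7.0 <= crossing <= 13.0

    def test_marker_image_bright_on_cluster(self, pair_scene):
        img = render_junction_intensity(
            pair_scene.geometry, pair_scene.junction_profiles, pair_scene.config
        )
        body = np.zeros(pair_scene.geometry.field_size_px, dtype=bool)
        for m in pair_scene.geometry.footprint_masks():
            body |= m
        assert img[body].mean() > 3 * img[~body].mean()


def test_forward_displacement_magnitude_reasonable(pair_scene):
    """Substrate displacements for default scenes are in the um range
    block matching can resolve."""
    u = boussinesq_displacement(pair_scene.true_traction, pair_scene.config.substrate)
    umax = np.abs(u.values).max()
    assert 0.3 < umax < 3.0
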