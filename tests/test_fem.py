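"""Thin-plate FEM: meshing, solving, stress profiles, junction forces."""

import numpy as np
import pytest

from jforce.fields import VectorField2D
from jforce.fem import (
    JunctionProfile,
    ThinPlateModel,
    ThinPlateSolution,
    build_mesh,
    integrate_interface_force,
    interface_stress_profile,
    modulus_field,
    separating_cut_polyline,
    solve_thin_plate,
)


def disk_mask(radius_um: float, pixel_size: float, pad_px: int = 20):
    n = int(2 * radius_um / pixel_size) + 2 * pad_px
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2
    return ((xx - c) ** 2 + (yy - c) ** 2) * pixel_size**2 < radius_um**2


class TestMesh:
    def test_disk_area(self):
        mesh = build_mesh(disk_mask(20.0, 0.3), 0.3)
        assert mesh.areas.sum() == pytest.approx(np.pi * 400, rel=0.02)

    def test_refinement_quadruples_elements(self):
        m2 = build_mesh(disk_mask(20.0, 0.3), 0.3, target_edge=2.0)
        m1 = build_mesh(disk_mask(20.0, 0.3), 0.3, target_edge=1.0)
        assert len(m1.triangles) == pytest.approx(4 * len(m2.triangles), rel=0.25)

    def test_mask_hole_gives_interior_ring(self):
        mask = disk_mask(20.0, 0.3)
        n = mask.shape[0]
        yy, xx = np.mgrid[0:n, 0:n]
        hole = ((xx - n / 2) ** 2 + (yy - n / 2) ** 2) * 0.09 < 6.0**2
        mesh = build_mesh(mask & ~hole, 0.3)
        assert len(mesh.rings) == 2
        expected = np.pi * (400 - 36)
        assert mesh.areas.sum() == pytest.approx(expected, rel=0.03)

    def test_element_quality(self):
        mesh = build_mesh(disk_mask(15.0, 0.3), 0.3)
        assert mesh.min_angles_deg().min() >= 20.0


class TestSolve:
    def test_zero_traction_zero_stress(self):
        mesh = build_mesh(disk_mask(10.0, 0.3), 0.3)
        t = VectorField2D((0.0, 0.0), 2.0, np.zeros((40, 40, 2)))
        sol = solve_thin_plate(mesh, ThinPlateModel(), t)
        assert np.abs(sol.element_stress).max() < 1e-12

    def test_opposing_strips_cross_section_force(self):
        """Two opposing traction strips of +-50 pN: the stress integral
        over any full vertical cross-section between them carries the
        whole 50 pN."""
        px = 0.3
        mask = np.zeros((120, 300), dtype=bool)
        mask[10:110, 10:290] = True
        mesh = build_mesh(mask, px)
        gs = 1.0
        ny, nx = 40, 95
        xs = np.arange(nx) * gs
        ys = np.arange(ny) * gs
        XX, YY = np.meshgrid(xs, ys)
        T = np.zeros((ny, nx, 2))
        left = (XX > 8) & (XX < 14) & (YY > 6) & (YY < 30)
        right = (XX > 72) & (XX < 78) & (YY > 6) & (YY < 30)
        T[left, 0] = -50.0 / (left.sum() * gs**2)
        T[right, 0] = 50.0 / (right.sum() * gs**2)
        sol = solve_thin_plate(mesh, ThinPlateModel(), VectorField2D((0, 0), gs, T))
        from matplotlib.tri import LinearTriInterpolator

        tri = sol.mesh.triangulation()
        ip = LinearTriInterpolator(tri, sol.nodal_stress[:, 0])
        ysec = np.linspace(10 * px, 110 * px, 500)
        sxx = np.ma.filled(ip(np.full_like(ysec, 45.0), ysec), 0.0)
        assert abs(np.trapezoid(sxx, ysec)) == pytest.approx(50.0, rel=0.03)

    def test_zero_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            ThinPlateModel(kappa_ratio=0.0)

    def test_modulus_decays_outside_tight_mask(self):
        mask = disk_mask(10.0, 0.3)
        from jforce.segmentation import dilate_cluster_mask

        dil = dilate_cluster_mask(mask, 30)
        mesh = build_mesh(dil, 0.3)
        model = ThinPlateModel()
        E = modulus_field(mesh, mask, 0.3, model)
        assert E.max() == pytest.approx(model.E0, rel=1e-6)
        assert E.min() < 0.1 * model.E0


class TestProfiles:
    @pytest.fixture(scope="class")
    def uniform_solution(self):
        mask = np.zeros((100, 200), dtype=bool)
        mask[10:90, 10:190] = True
        mesh = build_mesh(mask, 0.3)
        s = 2.0  # pN/um
        nodal = np.zeros((len(mesh.nodes), 3))
        nodal[:, 0] = s
        elem = np.zeros((len(mesh.triangles), 3))
        elem[:, 0] = s
        return ThinPlateSolution(mesh, np.zeros_like(mesh.nodes), elem, nodal)

    def test_uniform_stress_constant_profile(self, uniform_solution):
        line = np.column_stack([np.full(161, 100.0), np.arange(40.0, 201.0)])
        prof = interface_stress_profile(
            uniform_solution, line, 0.3, np.array([150.0, 120.0])
        )
        np.testing.assert_allclose(prof.stress_vectors[:, 0], 2.0, rtol=1e-9)
        np.testing.assert_allclose(prof.stress_vectors[:, 1], 0.0, atol=1e-12)

    def test_flipping_orientation_negates_profile(self, uniform_solution):
        line = np.column_stack([np.full(161, 100.0), np.arange(40.0, 201.0)])
        p1 = interface_stress_profile(
            uniform_solution, line, 0.3, np.array([150.0, 120.0])
        )
        p2 = interface_stress_profile(
            uniform_solution, line, 0.3, np.array([50.0, 120.0])
        )
        np.testing.assert_allclose(p1.stress_vectors, -p2.stress_vectors)

    def test_constant_profile_integral(self):
        """Constant (2, 0) pN/um over 16 um integrates to (-32, 0) pN
        with the sign convention that the force is exerted on cell n."""
        s = np.linspace(0.0, 16.0, 11)
        prof = JunctionProfile(
            0, np.zeros((11, 2)), np.zeros((11, 2)),
            np.tile([1.0, 0.0], (11, 1)),
            np.tile([2.0, 0.0], (11, 1)), s,
        )
        np.testing.assert_allclose(integrate_interface_force(prof), [-32.0, 0.0])

    def test_stretch_additivity(self):
        rng = np.random.default_rng(0)
        s = np.linspace(0.0, 20.0, 41)
        sv = rng.normal(0, 3, (41, 2))
        whole = JunctionProfile(0, None, None, None, sv, s)
        first = JunctionProfile(0, None, None, None, sv[:21], s[:21])
        second = JunctionProfile(0, None, None, None, sv[20:], s[20:])
        np.testing.assert_allclose(
            integrate_interface_force(first) + integrate_interface_force(second),
            integrate_interface_force(whole),
            atol=1e-10,
        )


class TestSceneForces:
    def test_pair_fem_matches_truth(self, pair_scene):
        from jforce.evaluation import scene_forces

        df = scene_forces(pair_scene)
        r = df.iloc[0]
        rel = np.linalg.norm(r.f_fem - r.f_true) / np.linalg.norm(r.f_true)
        assert rel < 0.05

    def test_e0_invariance(self):
        from jforce.evaluation import e0_invariance

        assert e0_invariance(seed=1) < 0.01

    def test_kappa_insensitivity(self, pair_scene):
        """Halving the stabilization ratio leaves junction forces
        essentially unchanged when the traction is well balanced."""
        from jforce.evaluation import scene_forces
        from tests.conftest import pipeline_config_for

        forces = {}
        for kr in (1e-7, 5e-8):
            cfg = pipeline_config_for(pair_scene)
            cfg.plate = ThinPlateModel(kappa_ratio=kr)
            df = scene_forces(pair_scene, config=cfg)
            forces[kr] = df.iloc[0].f_fem
        change = np.linalg.norm(forces[5e-8] - forces[1e-7]) / np.linalg.norm(
            forces[1e-7]
        )
        assert change < 0.001

    def test_mesh_convergence(self, pair_scene):
        from jforce.evaluation import scene_forces
        from tests.conftest import pipeline_config_for

        forces = {}
        for edge in (1.5, 0.75):
            cfg = pipeline_config_for(pair_scene)
            cfg.mesh_edge_um = edge
            df = scene_forces(pair_scene, config=cfg)
            forces[edge] = df.iloc[0].f_fem
        change = np.linalg.norm(forces[0.75] - forces[1.5]) / np.linalg.norm(
            forces[1.5]
        )
        assert change < 0.02

    def test_loop_refusal_and_fem_balance(self):
        from jforce.evaluation import loop_capability

        res = loop_capability(seed=2)
        assert res["n_refusals"] == res["n_edges"] == 3
        assert not res["any_bridge"]
        assert res["worst_cell_balance_rel_err"] < 0.05


class TestSeparatingCut:
    def test_cut_follows_interface_inside_cluster(self, pair_scene):
        geo = pair_scene.geometry
        masks = geo.footprint_masks()
        tight = masks[0] | masks[1]
        from jforce.segmentation import dilate_cluster_mask

        dil = dilate_cluster_mask(tight, 30)
        cut, side = separating_cut_polyline(masks, {0}, {1}, dil)
        # the drawn interface midpoint must lie on (near) the cut
        itf = geo.interfaces[0]
        mid = itf.points[len(itf.points) // 2]
        d = np.min(np.linalg.norm(cut - mid, axis=1))
        assert d < 3.0  # px
        # side function separates the two centroids
        c0 = np.array(np.nonzero(masks[0])).mean(axis=1)[::-1]
        c1 = np.array(np.nonzero(masks[1])).mean(axis=1)[::-1]
        assert side(c0[None])[0] * side(c1[None])[0] < 0
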