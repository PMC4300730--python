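"""Thin-plate finite-element model for cluster-internal stress.

The ventral cortex of the cluster is modelled as a 2-D linear elastic
plate whose internal stress field balances the sign-inverted tractions:

    d(sigma_ik)/dx_k - T_i + kappa u_i = 0   in the dilated cluster mask
    sigma_ik n_k = 0                         on its outer boundary

with a plane-stress constitutive law sigma = E(x)/(1+nu) (eps +
nu/(1-nu) tr(eps) I), which stays finite at the incompressible limit
nu = 0.5 used for cell cortices.  E(x) equals a reference modulus E0
inside the tight mask and decays as E0 exp(-d/lambda) outside, so
tractions in the dilated band are penalized with distance from the
detected cluster edge.  Junction forces are line integrals of sigma . n
along interface polylines; because the constitutive scale E0 cancels
between loading and stress recovery, they are invariant to E0.

The small kappa u term (kappa/E0 = 1e-7 by default, with a 1 um
reference length) removes the rigid-body null space that would make the
system singular when the measured tractions do not balance exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from matplotlib.tri import LinearTriInterpolator, Triangulation
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve
from scipy.spatial import Delaunay
from shapely.geometry import Polygon
from skimage import measure

from .fields import VectorField2D

__all__ = [
    "TriMesh",
    "ThinPlateModel",
    "ThinPlateSolution",
    "JunctionProfile",
    "build_mesh",
    "solve_thin_plate",
    "interface_stress_profile",
    "integrate_interface_force",
    "extend_interface_to_boundary",
]


@dataclass
class TriMesh:
    """Linear triangular mesh; node coordinates in um."""

    nodes: np.ndarray = field(repr=False)  # (N, 2)
    triangles: np.ndarray = field(repr=False)  # (M, 3) int
    boundary_nodes: np.ndarray = field(repr=False)  # bool (N,)
    rings: list = field(default_factory=list, repr=False)  # per-ring node index arrays

    def boundary_normals(self) -> np.ndarray:
        """Outward unit normals at boundary nodes (zero rows elsewhere).

        Normals come from the ring tangents; outwardness is fixed by
        pointing away from the ring centroid (rings are star-shaped
        enough for cluster masks).
        """
        out = np.zeros_like(self.nodes)
        for ring in self.rings:
            pts = self.nodes[ring]
            tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
            tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
            nrm = np.column_stack([-tang[:, 1], tang[:, 0]])
            cen = pts.mean(axis=0)
            flip = np.einsum("ij,ij->i", nrm, cen - pts) > 0
            nrm[flip] *= -1
            out[ring] = nrm
        return out

    @property
    def areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def min_angles_deg(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        angs = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.sum(a * b, axis=1) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angs.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
        return np.min(angs, axis=0)

    def triangulation(self) -> Triangulation:
        return Triangulation(self.nodes[:, 0], self.nodes[:, 1], self.triangles)


@dataclass
class ThinPlateModel:
    """Material model of the thin plate.

    ``E0`` is an arbitrary reference modulus (junction forces do not
    depend on it); ``decay_length`` is the exponential decay scale of
    E(x) outside the tight mask (1.6 um, i.e. 10 px at 0.16 um/px);
    ``kappa_ratio`` is kappa/E0 of the stabilization term.
    """

    E0: float = 1.0e4
    nu_plate: float = 0.5
    decay_length: float = 1.6
    kappa_ratio: float = 1.0e-7

    def __post_init__(self) -> None:
        if self.kappa_ratio <= 0:
            raise ValueError(
                "kappa_ratio must be > 0: with kappa = 0 the boundary value "
                "problem is singular for any unbalanced traction field"
            )


@dataclass
class ThinPlateSolution:
    mesh: TriMesh
    displacement: np.ndarray = field(repr=False)  # (N, 2) model-internal
    element_stress: np.ndarray = field(repr=False)  # (M, 3) sxx, syy, sxy pN/um
    nodal_stress: np.ndarray = field(repr=False)  # (N, 3)
    model: ThinPlateModel | None = None
    residual_norm: float = 0.0

    def stress_interpolators(self):
        tri = self.mesh.triangulation()
        return [LinearTriInterpolator(tri, self.nodal_stress[:, c]) for c in range(3)]

    def write_csv(self, outdir) -> None:
        """Dump mesh and solution as plain CSV (nodes, triangles, stress)."""
        import pandas as pd
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "x_um": self.mesh.nodes[:, 0],
                "y_um": self.mesh.nodes[:, 1],
                "ux": self.displacement[:, 0],
                "uy": self.displacement[:, 1],
                "sxx_pN_per_um": self.nodal_stress[:, 0],
                "syy_pN_per_um": self.nodal_stress[:, 1],
                "sxy_pN_per_um": self.nodal_stress[:, 2],
                "boundary": self.mesh.boundary_nodes.astype(int),
            }
        ).to_csv(out / "mesh_nodes.csv", index=False)
        pd.DataFrame(
            {
                "n0": self.mesh.triangles[:, 0],
                "n1": self.mesh.triangles[:, 1],
                "n2": self.mesh.triangles[:, 2],
                "sxx_pN_per_um": self.element_stress[:, 0],
                "syy_pN_per_um": self.element_stress[:, 1],
                "sxy_pN_per_um": self.element_stress[:, 2],
            }
        ).to_csv(out / "mesh_elements.csv", index=False)


@dataclass
class JunctionProfile:
    """Sub-junctional stress profile sampled every 10th interface pixel."""

    junction_id: int
    points_px: np.ndarray = field(repr=False)  # (S, 2)
    points_um: np.ndarray = field(repr=False)
    normals: np.ndarray = field(repr=False)  # unit, toward cell_n
    stress_vectors: np.ndarray = field(repr=False)  # sigma . n, pN/um
    arc_um: np.ndarray = field(repr=False)
    cell_m: int = -1
    cell_n: int = -1
    intensity: np.ndarray | None = None


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


def _mask_polygon(mask: np.ndarray, pixel_size: float, subsample: int = 10) -> Polygon:
    """Boundary polygon (with holes) of a binary mask, every 10th px kept."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no boundary contour")
    rings = []
    for c in contours:
        ring = (c[:, ::-1] - 1.0) * pixel_size  # rc -> xy, un-pad
        ring = ring[:: max(1, subsample)]
        if len(ring) >= 4:
            rings.append(Polygon(ring))
    rings.sort(key=lambda p: abs(p.area), reverse=True)
    outer = rings[0]
    holes = [r.exterior.coords for r in rings[1:] if outer.contains(r.representative_point())]
    poly = Polygon(outer.exterior.coords, holes)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.geom_type != "Polygon":
            poly = max(poly.geoms, key=lambda g: g.area)
    return poly


def _ring_points(ring, spacing: float) -> np.ndarray:
    n = max(int(np.ceil(ring.length / spacing)), 8)
    return np.array(
        [ring.interpolate(d).coords[0] for d in np.linspace(0, ring.length, n, endpoint=False)]
    )


def build_mesh(
    dilated_mask: np.ndarray,
    pixel_size: float,
    target_edge: float = 2.0,
    smooth_iters: int = 4,
) -> TriMesh:
    """Quality triangulation of the dilated cluster mask.

    The boundary polygon is traced from the mask (every 10th boundary
    pixel); interior nodes come from a triangular lattice at the target
    edge length, boundary nodes from arc-length resampling of the rings.
    Delaunay triangulation restricted to the polygon, with a few rounds
    of Laplacian smoothing of interior nodes to improve element quality.
    """
    poly = _mask_polygon(np.asarray(dilated_mask, dtype=bool), pixel_size)
    for attempt in range(2):
        h = target_edge
        rings = [poly.exterior, *poly.interiors]
        ring_pts = [_ring_points(r, h) for r in rings]
        ring_idx = []
        start = 0
        for rp in ring_pts:
            ring_idx.append(np.arange(start, start + len(rp)))
            start += len(rp)
        bpts = np.vstack(ring_pts)
        xmin, ymin, xmax, ymax = poly.bounds
        xs = np.arange(xmin, xmax + h, h)
        ys = np.arange(ymin, ymax + h, h * np.sqrt(3) / 2)
        XX, YY = np.meshgrid(xs, ys)
        XX[1::2] += h / 2  # staggered rows: near-equilateral lattice
        lattice = np.column_stack([XX.ravel(), YY.ravel()])
        inside = shapely.contains_xy(poly, lattice[:, 0], lattice[:, 1])
        # drop lattice nodes hugging the boundary
        eroded = poly.buffer(-0.55 * h)
        if not eroded.is_empty:
            keep = shapely.intersects(
                shapely.points(lattice[inside]), eroded
            )
        else:
            keep = np.zeros(inside.sum(), dtype=bool)
        nodes = np.vstack([bpts, lattice[inside][keep]])
        nb = len(bpts)
        tri, tris = _delaunay_in_polygon(nodes, poly)
        # Laplacian smoothing of interior nodes
        for _ in range(smooth_iters):
            neigh: dict[int, set[int]] = {}
            for t in tris:
                for i in range(3):
                    neigh.setdefault(t[i], set()).update(t[[(i + 1) % 3, (i + 2) % 3]])
            new = nodes.copy()
            for i, ns in neigh.items():
                if i >= nb and ns:
                    new[i] = nodes[sorted(ns)].mean(axis=0)
            nodes = new
            tri, tris = _delaunay_in_polygon(nodes, poly)
        boundary = np.zeros(len(nodes), dtype=bool)
        boundary[:nb] = True
        mesh = TriMesh(nodes, tris, boundary, ring_idx)
        # drop degenerate slivers
        good = mesh.areas > 1e-6 * h**2
        mesh = TriMesh(nodes, tris[good], boundary, ring_idx)
        if len(mesh.triangles) > 0:
            return mesh
        target_edge *= 0.7  # densify and retry
    raise RuntimeError("mesh generation failed (self-intersecting boundary?)")


def _delaunay_in_polygon(nodes: np.ndarray, poly: Polygon):
    dela = Delaunay(nodes)
    cent = nodes[dela.simplices].mean(axis=1)
    keep = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
    return dela, dela.simplices[keep]


# ---------------------------------------------------------------------------
# FEM solve
# ---------------------------------------------------------------------------


def _element_matrices(mesh: TriMesh):
    """Per-element shape-function gradients and areas for P1 triangles."""
    p = mesh.nodes[mesh.triangles]
    x1, y1 = p[:, 0, 0], p[:, 0, 1]
    x2, y2 = p[:, 1, 0], p[:, 1, 1]
    x3, y3 = p[:, 2, 0], p[:, 2, 1]
    det = (x2 - x1) * (y3 - y1) - (x3 - x1) * (y2 - y1)
    area = 0.5 * np.abs(det)
    b = np.stack([y2 - y3, y3 - y1, y1 - y2], axis=1) / det[:, None]
    c = np.stack([x3 - x2, x1 - x3, x2 - x1], axis=1) / det[:, None]
    return b, c, area


def modulus_field(
    mesh: TriMesh,
    tight_mask: np.ndarray,
    pixel_size: float,
    model: ThinPlateModel,
) -> np.ndarray:
    """Nodal Young's modulus: E0 inside the tight mask, exponential decay
    E0 exp(-d / decay_length) outside."""
    dist_px = ndimage.distance_transform_edt(~np.asarray(tight_mask, dtype=bool))
    d_um = dist_px * pixel_size
    H, W = tight_mask.shape
    ix = np.clip(np.round(mesh.nodes[:, 0] / pixel_size).astype(int), 0, W - 1)
    iy = np.clip(np.round(mesh.nodes[:, 1] / pixel_size).astype(int), 0, H - 1)
    return model.E0 * np.exp(-d_um[iy, ix] / model.decay_length)


def solve_thin_plate(
    mesh: TriMesh,
    model: ThinPlateModel,
    traction: VectorField2D,
    E_nodes: np.ndarray | None = None,
) -> ThinPlateSolution:
    """Solve the stabilized thin-plate boundary value problem.

    Weak form of div(sigma) - T + kappa u = 0 with natural (zero normal
    stress) boundary conditions: (K + kappa M_L) u = f, where f is the
    lumped load of the sign-inverted traction interpolated to the nodes,
    and M_L the lumped mass matrix.  Stress is recovered per element and
    area-averaged to the nodes for sampling.
    """
    nu = model.nu_plate
    E_nodes = np.full(len(mesh.nodes), model.E0) if E_nodes is None else E_nodes
    E_elem = E_nodes[mesh.triangles].mean(axis=1)
    b, c, area = _element_matrices(mesh)
    nmesh = len(mesh.nodes)
    # plane-stress D matrix per element (factor E/(1-nu^2))
    d11 = E_elem / (1 - nu**2)
    d12 = d11 * nu
    d33 = E_elem / (2 * (1 + nu))
    tris = mesh.triangles
    rows, cols, vals = [], [], []
    # K_ab(ij) = A * Bi^T D Bj ; assembled blockwise, vectorized over elements
    for i in range(3):
        for j in range(3):
            kxx = area * (d11 * b[:, i] * b[:, j] + d33 * c[:, i] * c[:, j])
            kxy = area * (d12 * b[:, i] * c[:, j] + d33 * c[:, i] * b[:, j])
            kyx = area * (d12 * c[:, i] * b[:, j] + d33 * b[:, i] * c[:, j])
            kyy = area * (d11 * c[:, i] * c[:, j] + d33 * b[:, i] * b[:, j])
            for (blk, rr, cc) in (
                (kxx, 2 * tris[:, i], 2 * tris[:, j]),
                (kxy, 2 * tris[:, i], 2 * tris[:, j] + 1),
                (kyx, 2 * tris[:, i] + 1, 2 * tris[:, j]),
                (kyy, 2 * tris[:, i] + 1, 2 * tris[:, j] + 1),
            ):
                rows.append(rr)
                cols.append(cc)
                vals.append(blk)
    # lumped mass (kappa stabilization, 1 um reference length)
    kappa = model.kappa_ratio * model.E0
    lump = np.zeros(nmesh)
    for i in range(3):
        np.add.at(lump, tris[:, i], area / 3.0)
    rows.append(2 * np.arange(nmesh))
    cols.append(2 * np.arange(nmesh))
    vals.append(kappa * lump)
    rows.append(2 * np.arange(nmesh) + 1)
    cols.append(2 * np.arange(nmesh) + 1)
    vals.append(kappa * lump)
    K = coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(2 * nmesh, 2 * nmesh),
    ).tocsr()
    # load: sign-inverted traction; edge-midpoint quadrature (exact for
    # quadratic integrands, markedly more accurate than nodal lumping for
    # the smooth but structured traction fields this model is fed)
    p = mesh.nodes[tris]
    mids = 0.5 * (p + np.roll(p, -1, axis=1))  # midpoints opposite node i+2
    T_mid = traction.sample(mids.reshape(-1, 2)).reshape(len(tris), 3, 2)
    f = np.zeros(2 * nmesh)
    for i in range(3):
        # node i touches the midpoints of edges (i, i+1) and (i+2, i)
        contrib = (area[:, None] / 6.0) * (T_mid[:, i] + T_mid[:, (i + 2) % 3])
        np.add.at(f, 2 * tris[:, i], -contrib[:, 0])
        np.add.at(f, 2 * tris[:, i] + 1, -contrib[:, 1])
    u = spsolve(K, f)
    resid = float(np.linalg.norm(K @ u - f) / (np.linalg.norm(f) or 1.0))
    if resid > 1e-8:
        warnings.warn(f"thin-plate solve residual {resid:.2e}")
    U = u.reshape(-1, 2)
    # element strain and stress
    ue = U[tris]  # (M, 3, 2)
    exx = np.sum(b * ue[:, :, 0], axis=1)
    eyy = np.sum(c * ue[:, :, 1], axis=1)
    gxy = np.sum(c * ue[:, :, 0] + b * ue[:, :, 1], axis=1)
    sxx = d11 * exx + d12 * eyy
    syy = d12 * exx + d11 * eyy
    sxy = d33 * gxy
    elem_stress = np.stack([sxx, syy, sxy], axis=1)
    nodal = np.zeros((nmesh, 3))
    wsum = np.zeros(nmesh)
    for i in range(3):
        np.add.at(wsum, tris[:, i], area)
        for comp in range(3):
            np.add.at(nodal[:, comp], tris[:, i], area * elem_stress[:, comp])
    nodal /= np.maximum(wsum, 1e-300)[:, None]
    # enforce the zero-normal-stress boundary condition on the recovered
    # field: a free surface carries only tangential stress, so project
    # boundary-node stress onto the tangential space t (x) t
    if mesh.rings:
        nrm = mesh.boundary_normals()
        bidx = np.flatnonzero(mesh.boundary_nodes)
        nx_, ny_ = nrm[bidx, 0], nrm[bidx, 1]
        tx, ty = -ny_, nx_
        s = nodal[bidx]
        s_tt = (
            s[:, 0] * tx**2 + s[:, 1] * ty**2 + 2 * s[:, 2] * tx * ty
        )
        nodal[bidx, 0] = s_tt * tx**2
        nodal[bidx, 1] = s_tt * ty**2
        nodal[bidx, 2] = s_tt * tx * ty
    return ThinPlateSolution(mesh, U, elem_stress, nodal, model, resid)


# ---------------------------------------------------------------------------
# interface profiles and forces
# ---------------------------------------------------------------------------


def extend_interface_to_boundary(
    points_px: np.ndarray,
    dilated_mask: np.ndarray,
    tight_mask: np.ndarray | None = None,
    step_px: float = 2.0,
    max_steps: int = 300,
) -> np.ndarray:
    """Extend interface endpoints outward to the dilated-mask boundary.

    Interfaces drawn on the tight mask end at the cluster edge; the
    thin-plate domain extends further.  For force integration the cut
    must span the whole plate, so each endpoint lying at the cluster
    boundary is continued along its end tangent until it leaves the
    dilated mask.  Endpoints at interior triple junctions (still deep in
    the tight mask) are left untouched.
    """
    pts = np.asarray(points_px, dtype=float)
    H, W = dilated_mask.shape
    tight = (
        np.asarray(tight_mask, dtype=bool)
        if tight_mask is not None
        else np.asarray(dilated_mask, dtype=bool)
    )

    def inside(mask, p):
        y, x = int(round(p[1])), int(round(p[0]))
        return 0 <= y < H and 0 <= x < W and mask[y, x]

    out = [pts]
    for end, tangent_from in ((0, min(len(pts) - 1, 8)), (-1, max(0, len(pts) - 9))):
        p_end = pts[end]
        tang = p_end - pts[tangent_from]
        nt = np.linalg.norm(tang)
        if nt == 0:
            continue
        tang /= nt
        probe = p_end + 3.0 * tang
        if inside(tight, probe):
            continue  # interior endpoint (triple junction)
        ext = []
        p = p_end.copy()
        for _ in range(max_steps):
            p = p + step_px * tang
            if not inside(np.asarray(dilated_mask, dtype=bool), p):
                ext.append(p)  # one step beyond, clipped by the sampler
                break
            ext.append(p.copy())
        if ext:
            if end == 0:
                out.insert(0, np.array(ext[::-1]))
            else:
                out.append(np.array(ext))
    return np.vstack(out)


def separating_cut_polyline(
    cell_masks: list[np.ndarray],
    group_a: set[int] | list[int],
    group_b: set[int] | list[int],
    dilated_mask: np.ndarray,
    step_px: int = 2,
) -> tuple[np.ndarray, "callable"]:
    """Full plate cut separating two cell groups, as a sub-pixel polyline.

    The cut is the equidistance contour between the footprint unions of
    the two groups (d_a(x) = d_b(x)), clipped to the dilated mask.
    Inside the cluster this coincides with the drawn interface (the
    footprints tile the tight mask); in the dilated band it continues
    through the middle of the gap between the groups' territories, so
    the line integral of sigma . n over it captures the entire
    transmitted force, also in pinched cluster geometries.  For edges in
    loops pass only the two incident cells and the contour is trimmed
    where a third cell's territory takes over.

    Returns the cut points (px, xy) and a side function mapping (N, 2)
    px points to the signed distance difference (positive on the group_b
    side), used to orient normals.
    """
    from scipy.ndimage import distance_transform_edt
    from scipy.interpolate import RegularGridInterpolator

    H, W = dilated_mask.shape
    sub = slice(None, None, step_px)
    ua = np.zeros((H, W), dtype=bool)
    ub = np.zeros((H, W), dtype=bool)
    for i in group_a:
        ua |= cell_masks[i]
    for i in group_b:
        ub |= cell_masks[i]
    da = distance_transform_edt(~ua[sub, sub]) * step_px
    db = distance_transform_edt(~ub[sub, sub]) * step_px
    phi = da - db
    others = [i for i in range(len(cell_masks)) if i not in set(group_a) | set(group_b)]
    trim_mask = None
    if others:
        uo = np.zeros((H, W), dtype=bool)
        for i in others:
            uo |= cell_masks[i]
        do = distance_transform_edt(~uo[sub, sub]) * step_px
        trim_mask = do < np.minimum(da, db)
    contours = measure.find_contours(phi, 0.0)
    if not contours:
        raise ValueError("groups are not separated by any contour")
    dmask = np.asarray(dilated_mask, dtype=bool)

    def keep(c):
        pts = c * step_px  # rc full-res
        iy = np.clip(np.round(pts[:, 0]).astype(int), 0, H - 1)
        ix = np.clip(np.round(pts[:, 1]).astype(int), 0, W - 1)
        ok = dmask[iy, ix]
        if trim_mask is not None:
            cy = np.clip(np.round(c[:, 0]).astype(int), 0, phi.shape[0] - 1)
            cx = np.clip(np.round(c[:, 1]).astype(int), 0, phi.shape[1] - 1)
            ok &= ~trim_mask[cy, cx]
        return ok

    best = None
    for c in contours:
        ok = keep(c)
        if not ok.any():
            continue
        # longest contiguous run of valid points
        idx = np.flatnonzero(ok)
        splits = np.split(idx, np.where(np.diff(idx) > 1)[0] + 1)
        run = max(splits, key=len)
        if best is None or len(run) > len(best):
            best = c[run]
    if best is None or len(best) < 2:
        raise ValueError("no valid separating cut inside the dilated mask")
    cut_px = best[:, ::-1] * step_px  # rc -> xy, full-res px

    ys = np.arange(phi.shape[0]) * step_px
    xs = np.arange(phi.shape[1]) * step_px
    itp = RegularGridInterpolator(
        (ys, xs), phi, bounds_error=False, fill_value=0.0
    )

    def side(points_xy_px: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points_xy_px)
        return np.asarray(itp(p[:, ::-1]))

    return cut_px, side


def interface_stress_profile(
    solution: ThinPlateSolution,
    points_px: np.ndarray,
    pixel_size: float,
    toward_point_px: np.ndarray,
    junction_id: int = -1,
    cell_m: int = -1,
    cell_n: int = -1,
    step: int = 10,
) -> JunctionProfile:
    """Sample sigma . n every ``step`` pixels along an interface.

    The local normal is computed from the tangent (central difference
    over +-5 px) and oriented toward ``toward_point_px`` (a point inside
    cell n, typically its centroid): the resulting stress vectors are
    the force per unit length that cell m side exerts across the cut.
    Samples outside the mesh are dropped with a warning.
    """
    pts = np.asarray(points_px, dtype=float)
    idx = np.arange(0, len(pts), step)
    if idx[-1] != len(pts) - 1:
        idx = np.r_[idx, len(pts) - 1]
    samples = pts[idx]
    side_fn = toward_point_px if callable(toward_point_px) else None
    normals = np.zeros((len(idx), 2))
    for k, i in enumerate(idx):
        lo = max(0, i - 5)
        hi = min(len(pts) - 1, i + 5)
        tang = pts[hi] - pts[lo]
        nt = np.linalg.norm(tang)
        if nt == 0:
            normals[k] = np.array([1.0, 0.0])
            continue
        n = np.array([-tang[1], tang[0]]) / nt
        if side_fn is not None:
            probe = side_fn(np.vstack([pts[i] + 3 * n, pts[i] - 3 * n]))
            if probe[0] < probe[1]:
                n = -n
        elif np.dot(n, np.asarray(toward_point_px) - pts[i]) < 0:
            n = -n
        normals[k] = n
    pum = samples * pixel_size
    interp = solution.stress_interpolators()
    sxx = np.asarray(interp[0](pum[:, 0], pum[:, 1]))
    syy = np.asarray(interp[1](pum[:, 0], pum[:, 1]))
    sxy = np.asarray(interp[2](pum[:, 0], pum[:, 1]))
    ok = ~(np.ma.getmaskarray(interp[0](pum[:, 0], pum[:, 1])))
    ok &= np.isfinite(sxx) & np.isfinite(syy) & np.isfinite(sxy)
    if not np.all(ok):
        warnings.warn(f"{np.sum(~ok)} profile samples outside mesh dropped")
    samples, pum, normals = samples[ok], pum[ok], normals[ok]
    sv = np.stack(
        [
            sxx[ok] * normals[:, 0] + sxy[ok] * normals[:, 1],
            sxy[ok] * normals[:, 0] + syy[ok] * normals[:, 1],
        ],
        axis=1,
    )
    d = np.diff(pum, axis=0)
    arc = np.r_[0, np.cumsum(np.hypot(d[:, 0], d[:, 1]))]
    return JunctionProfile(
        junction_id, samples, pum, normals, sv, arc, cell_m, cell_n
    )


def integrate_interface_force(profile: JunctionProfile) -> np.ndarray:
    """Junction force f_m,n (pN): minus the trapezoidal line integral of
    sigma . n along the (possibly partial) interface, normals toward
    cell n.  Additive over sub-interface stretches."""
    if len(profile.arc_um) < 2:
        raise ValueError("profile needs at least 2 samples")
    return -np.array(
        [
            np.trapezoid(profile.stress_vectors[:, 0], profile.arc_um),
            np.trapezoid(profile.stress_vectors[:, 1], profile.arc_um),
        ]
    )
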