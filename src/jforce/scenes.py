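"""Synthetic contractile cell clusters with exact mechanical ground truth.

A scene emulates the study system: a small adherent epithelial cluster
(1-6 cells) contracting on a soft elastic substrate.  The generator
provides everything the downstream analysis would obtain from microscopy
-- bead images before/after deformation, a junction-marker image, cell
footprints and interface polylines -- together with quantities that are
unobservable in experiments: the exact traction field, the per-cell
residual traction forces, and the junction forces that follow from them.

Geometry is a perturbed-seed Voronoi partition of a smooth blob.
Traction is a sum of inward-pointing Gaussian patches along each cell's
free (cluster-exterior) boundary, plus a low-order correction field that
makes each cell's traction integral equal exactly minus its prescribed
residual force and zeroes the net torque.  For tree-topology clusters the
true junction forces are the partition sums of the prescribed residuals:
cutting the junction graph at an edge splits the cluster into two groups
g1, g2 and the force transmitted is f_g1,g2 = sum_{i in g1} f_res,i.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import shapely
from scipy.ndimage import gaussian_filter1d
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import linemerge, unary_union, voronoi_diagram
from skimage.draw import polygon as draw_polygon

from .fields import SubstrateModel, VectorField2D, grid_covering

__all__ = [
    "SceneConfig",
    "SyntheticGroundTruth",
    "ClusterGeometry",
    "generate_cluster_geometry",
    "synthesize_traction_field",
    "render_bead_images",
    "render_junction_intensity",
    "make_scene",
    "smooth_arc_noise",
]


@dataclass
class SceneConfig:
    """All tunable knobs of the synthetic scene generator.

    Defaults describe a small epithelial cluster on an 8 kPa gel imaged
    at 0.3 um/px, with ~18 um cells, dark-red marker beads at
    0.4 beads/um^2 and a junction marker whose intensity tracks local
    junction stress with a 10 um correlation length.
    """

    n_cells: int = 2
    topology: str = "chain"  # pair | chain | tree | loop
    field_size_px: tuple[int, int] | None = None
    pixel_size: float = 0.16  # um/px
    substrate_modulus: float = 8000.0  # Pa
    substrate_poisson: float = 0.5
    bead_density: float = 0.4  # beads/um^2
    bead_psf_sigma: float = 0.3  # um
    displacement_noise_sd: float = 0.0  # um, per-bead
    intensity_coupling: float = 1.0  # a.u. per (pN/um)
    intensity_corr_length: float = 10.0  # um
    intensity_noise_sd: float = 0.0  # a.u.
    cell_radius: float = 9.0  # um, typical half lateral extent
    traction_amplitude: float = 600.0  # Pa, peripheral patch scale
    residual_scale: float = 20000.0  # pN, sd of prescribed residuals
    clearance: float = 7.0  # um, min gap between non-adjacent cells
    traction_spacing_px: int = 4  # traction grid step in px
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.topology not in {"pair", "chain", "tree", "loop"}:
            raise ValueError(f"unknown topology {self.topology!r}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if not self.substrate_modulus > 0:
            raise ValueError("substrate modulus must be > 0")
        if not 0 <= self.substrate_poisson <= 0.5:
            raise ValueError("substrate poisson must be in [0, 0.5]")
        for name in ("displacement_noise_sd", "intensity_noise_sd", "bead_psf_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def substrate(self) -> SubstrateModel:
        return SubstrateModel(self.substrate_modulus, self.substrate_poisson)


@dataclass
class Interface:
    """A cell-cell interface polyline in pixel coordinates."""

    junction_id: int
    cell_a: int
    cell_b: int
    points: np.ndarray = field(repr=False)  # (N, 2) xy px

    def length_um(self, pixel_size: float) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.sum(np.hypot(d[:, 0], d[:, 1]))) * pixel_size


@dataclass
class ClusterGeometry:
    """Cell polygons, interfaces and adjacency of a synthetic cluster."""

    cell_polygons: list[np.ndarray]  # (N_i, 2) xy px, closed
    interfaces: list[Interface]
    adjacency: nx.Graph
    field_size_px: tuple[int, int]  # (height, width)
    pixel_size: float

    def footprint_masks(self) -> list[np.ndarray]:
        """Rasterized boolean footprint per cell, shape (H, W)."""
        H, W = self.field_size_px
        masks = []
        for poly in self.cell_polygons:
            rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(H, W))
            m = np.zeros((H, W), dtype=bool)
            m[rr, cc] = True
            masks.append(m)
        return masks

    def cluster_polygon(self) -> Polygon:
        return unary_union([Polygon(p) for p in self.cell_polygons])

    def masks_on_grid(self, fld: VectorField2D) -> list[np.ndarray]:
        """Per-cell boolean masks on a vector-field grid.

        A grid cell belongs to a cell footprint when its centre lies
        inside the cell polygon; the same rule is used by the traction
        synthesizer, so residual integrals computed through these masks
        reproduce the prescribed values to float precision.
        """
        XX, YY = np.meshgrid(fld.x, fld.y)
        out = []
        for poly_px in self.cell_polygons:
            cell = Polygon(poly_px * self.pixel_size)
            out.append(
                shapely.contains_xy(cell, XX.ravel(), YY.ravel()).reshape(XX.shape)
            )
        return out


@dataclass
class SyntheticGroundTruth:
    """Exact mechanical truth for one synthetic scene."""

    geometry: ClusterGeometry
    true_traction: VectorField2D  # Pa
    true_residuals: np.ndarray  # (n_cells, 2) pN
    true_junction_forces: dict[int, np.ndarray]  # junction_id -> (2,) pN, a on b
    junction_profiles: dict[int, dict]  # junction_id -> sampled truth profile
    config: SceneConfig
    seed: int


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _seed_layout(config: SceneConfig, rng: np.random.Generator) -> tuple[np.ndarray, nx.Graph]:
    """Seed positions (um) and intended junction graph for the topology."""
    n = config.n_cells
    d0 = 2.0 * config.cell_radius
    topo = config.topology
    if topo == "pair" and n != 2:
        raise ValueError("pair topology requires n_cells == 2")
    if topo == "loop" and n < 3:
        raise ValueError("loop topology requires n_cells >= 3")
    target = nx.Graph()
    target.add_nodes_from(range(n))
    if n == 1:
        return np.zeros((1, 2)), target
    if topo in ("pair", "chain") or (topo == "tree" and n <= 2):
        pts = np.column_stack(
            [np.arange(n) * d0, rng.normal(0, 0.05 * d0, n)]
        )
        target.add_edges_from((i, i + 1) for i in range(n - 1))
        return pts, target
    if topo == "loop":
        R = d0 / (2 * np.sin(np.pi / n))
        ang = 2 * np.pi * np.arange(n) / n + rng.normal(0, 0.03, n)
        rad = R * (1 + rng.normal(0, 0.03, n))
        pts = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
        target.add_edges_from((i, (i + 1) % n) for i in range(n))
        return pts, target
    # random labelled tree (degree capped at 3 so neighbours of a cell can
    # be spread >= ~105 degrees apart, keeping non-adjacent cells clear of
    # each other), embedded breadth-first with wide wedges
    tree = None
    for _ in range(50):
        cand = (
            nx.from_prufer_sequence(list(rng.integers(0, n, size=n - 2)))
            if n > 2
            else nx.path_graph(n)
        )
        if max(dict(cand.degree).values()) <= 3:
            tree = cand
            break
    if tree is None:
        tree = nx.path_graph(n)
    pts = np.zeros((n, 2))
    order = list(nx.bfs_edges(tree, 0))
    incoming = {0: 0.0}
    children: dict[int, list[int]] = {}
    for a, b in order:
        children.setdefault(a, []).append(b)
    for parent, kids in children.items():
        base = incoming[parent]
        k = len(kids)
        if parent == 0 and 0 not in incoming or parent == 0:
            # root: no incoming edge constraint, spread kids evenly
            offsets = np.linspace(0, 2 * np.pi, k, endpoint=False)
        else:
            # keep kids within +-60 deg of the outgoing direction and
            # >= ~110 deg apart from each other and from the parent edge
            offsets = np.array([0.0]) if k == 1 else np.linspace(-0.96, 0.96, k)
        for kid, s in zip(kids, offsets):
            theta = base + s + rng.normal(0, 0.06)
            pts[kid] = pts[parent] + d0 * np.array([np.cos(theta), np.sin(theta)])
            incoming[kid] = theta
    return pts, tree


def _voronoi_partition(
    seeds_um: np.ndarray, blob: Polygon, pixel_size: float
) -> tuple[list[Polygon], dict[tuple[int, int], shapely.LineString]]:
    """Clip the Voronoi diagram of the seeds to the blob.

    Returns per-seed polygons and shared-boundary polylines per cell pair.
    """
    n = len(seeds_um)
    if n == 1:
        return [blob], {}
    env = blob.buffer(4 * pixel_size).envelope
    vor = voronoi_diagram(MultiPoint(seeds_um.tolist()), envelope=env)
    cells: list[Polygon | None] = [None] * n
    for region in vor.geoms:
        for i, s in enumerate(seeds_um):
            if region.contains(shapely.Point(s)):
                cells[i] = region
                break
    if any(c is None for c in cells):
        raise RuntimeError("voronoi region association failed")
    clipped = [c.intersection(blob) for c in cells]
    for i, c in enumerate(clipped):
        if c.geom_type != "Polygon" or c.is_empty:
            raise RuntimeError(f"degenerate cell footprint for seed {i}")
    shared: dict[tuple[int, int], shapely.LineString] = {}
    for i in range(n):
        for j in range(i + 1, n):
            inter = clipped[i].boundary.intersection(clipped[j].boundary)
            if inter.is_empty or inter.length < 2 * pixel_size:
                continue
            if inter.geom_type == "MultiLineString":
                merged = linemerge(inter)
                if merged.geom_type == "MultiLineString":
                    merged = max(merged.geoms, key=lambda g: g.length)
                inter = merged
            if inter.geom_type != "LineString":
                continue
            shared[(i, j)] = inter
    return clipped, shared


def _resample_line(line: shapely.LineString, step: float) -> np.ndarray:
    n = max(int(np.ceil(line.length / step)), 2)
    dists = np.linspace(0.0, line.length, n + 1)
    return np.array([line.interpolate(d).coords[0] for d in dists])


def generate_cluster_geometry(config: SceneConfig) -> ClusterGeometry:
    """Generate cell polygons, interfaces and the junction adjacency graph.

    The cluster footprint is a smooth blob (union of per-seed disks,
    holes filled) partitioned by the Voronoi diagram of jittered seeds.
    The requested topology is enforced on the realized adjacency: trees
    must come out acyclic and exactly matching the drawn tree, loops must
    contain a cycle; the layout is re-jittered on failure.  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    last_err: Exception | None = None
    for attempt in range(25):
        seeds, target = _seed_layout(config, rng)
        blob_raw = unary_union(
            [shapely.Point(s).buffer(1.25 * config.cell_radius, quad_segs=32) for s in seeds]
        )
        if blob_raw.geom_type != "Polygon":
            continue
        blob = Polygon(blob_raw.exterior)  # fill any enclosed holes
        blob = blob.buffer(2.0).buffer(-2.0)  # smooth scallops a little
        if blob.geom_type != "Polygon":
            continue
        try:
            cells, shared = _voronoi_partition(seeds, blob, config.pixel_size)
        except RuntimeError as err:
            last_err = err
            continue
        realized = nx.Graph()
        realized.add_nodes_from(range(config.n_cells))
        realized.add_edges_from(shared.keys())
        if config.topology in ("pair", "chain", "tree"):
            if set(realized.edges) != set(map(tuple, map(sorted, target.edges))):
                last_err = RuntimeError("realized adjacency does not match target tree")
                continue
            # non-adjacent cells must stay geometrically clear of each
            # other, otherwise mask dilation bridges the gap and couples
            # cells that share no junction
            clear_ok = True
            for i in range(config.n_cells):
                for j in range(i + 1, config.n_cells):
                    if realized.has_edge(i, j):
                        continue
                    if cells[i].distance(cells[j]) < config.clearance:
                        clear_ok = False
            if not clear_ok:
                last_err = RuntimeError("non-adjacent cells closer than clearance")
                continue
        else:  # loop
            if not nx.is_connected(realized) or nx.is_forest(realized):
                last_err = RuntimeError("loop topology without a cycle")
                continue
        # place into a pixel field with margin
        allx = np.concatenate([np.asarray(c.exterior.coords)[:, 0] for c in cells])
        ally = np.concatenate([np.asarray(c.exterior.coords)[:, 1] for c in cells])
        margin_px = 40
        px = config.pixel_size
        if config.field_size_px is None:
            W = int(np.ceil((allx.max() - allx.min()) / px)) + 2 * margin_px
            H = int(np.ceil((ally.max() - ally.min()) / px)) + 2 * margin_px
            side = max(H, W)
            H = W = side
        else:
            H, W = config.field_size_px
        span_x = allx.max() - allx.min()
        span_y = ally.max() - ally.min()
        if (W - 2 * 20) * px < span_x or (H - 2 * 20) * px < span_y:
            raise ValueError("field_size_px too small to hold cluster with 20 px margin")
        offset = np.array(
            [
                (W * px - span_x) / 2 - allx.min(),
                (H * px - span_y) / 2 - ally.min(),
            ]
        )
        polys_px = [
            (np.asarray(c.exterior.coords) + offset) / px for c in cells
        ]
        interfaces = []
        for jid, ((i, j), line) in enumerate(sorted(shared.items())):
            pts_um = _resample_line(line, px) + offset
            pts_px = pts_um / px
            # orientation convention: cell_a lies on the left of the
            # polyline traversal (y-down image coordinates), so label
            # maps are recoverable from the interface file alone
            mid = len(pts_px) // 2
            tang = pts_px[min(mid + 3, len(pts_px) - 1)] - pts_px[max(mid - 3, 0)]
            left = np.array([tang[1], -tang[0]])
            nl = np.linalg.norm(left)
            a, b = i, j
            if nl > 0:
                probe = (pts_px[mid] + 4.0 * left / nl) * px - offset
                if shapely.contains_xy(cells[j], probe[0], probe[1]):
                    a, b = j, i
            interfaces.append(Interface(jid, a, b, pts_px))
        graph = nx.Graph()
        graph.add_nodes_from(range(config.n_cells))
        for itf in interfaces:
            graph.add_edge(itf.cell_a, itf.cell_b, junction_id=itf.junction_id)
        return ClusterGeometry(polys_px, interfaces, graph, (H, W), px)
    raise RuntimeError(f"could not realize topology {config.topology!r}: {last_err}")


# ---------------------------------------------------------------------------
# traction synthesis
# ---------------------------------------------------------------------------


def _partition_force(
    graph: nx.Graph, residuals: np.ndarray, edge: tuple[int, int]
) -> np.ndarray:
    """Force exerted by the component containing edge[0] on the other.

    Cutting a bridge edge splits the cluster into groups g1 (containing
    cell a) and g2; the transmitted force is sum_{i in g1} f_res,i.
    """
    g = graph.copy()
    g.remove_edge(*edge)
    comp_a = nx.node_connected_component(g, edge[0])
    return residuals[sorted(comp_a)].sum(axis=0)


def draw_random_residuals(
    n_cells: int, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Random per-cell residual forces (pN) summing exactly to zero."""
    r = rng.normal(0.0, scale, size=(n_cells, 2))
    return r - r.mean(axis=0, keepdims=True)


def synthesize_traction_field(
    geometry: ClusterGeometry,
    contraction_strengths: np.ndarray | None = None,
    residuals: np.ndarray | None = None,
    config: SceneConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticGroundTruth:
    """Build a traction field with exactly known residual forces.

    Each cell carries inward-pointing Gaussian traction patches anchored
    along its cluster-exterior boundary (peripheral traction
    localization).  In the default *emergent* mode (``residuals=None``)
    the patch amplitudes are smoothly polarized around each cell, giving
    it a natural net traction imbalance of order ``residual_scale``; the
    field is then projected so the cluster's net force and torque vanish
    to float precision, and the true residuals are measured from the
    final field.  In the *prescribed* mode the per-cell integrals are
    pinned to exactly ``-f_res,i`` by a minimal-change adjustment of the
    patch amplitudes plus tapered interior corrections (prescribing
    residuals that the peripheral patch layout cannot supply smoothly
    concentrates traction near junction ends, which real reconstructed
    fields do not show; prefer the emergent mode for benchmark scenes).
    """
    config = config or SceneConfig(n_cells=len(geometry.cell_polygons))
    rng = rng or np.random.default_rng(config.seed + 1)
    n = len(geometry.cell_polygons)
    prescribed = residuals is not None
    if prescribed:
        residuals = np.asarray(residuals, dtype=float)
        if residuals.shape != (n, 2):
            raise ValueError("residuals must have shape (n_cells, 2)")
        if not np.allclose(residuals.sum(axis=0), 0.0, atol=1e-6):
            raise ValueError("prescribed residuals must sum to zero over the cluster")
    if contraction_strengths is None:
        contraction_strengths = 1.0 + 0.3 * rng.uniform(-1, 1, size=n)
    strengths = np.broadcast_to(np.asarray(contraction_strengths, float), (n,))

    px = geometry.pixel_size
    H, W = geometry.field_size_px
    step = config.traction_spacing_px
    spacing = step * px
    nyx = (H // step, W // step)
    xs = (np.arange(nyx[1]) + 0.5) * spacing
    ys = (np.arange(nyx[0]) + 0.5) * spacing
    XX, YY = np.meshgrid(xs, ys)
    pts = np.column_stack([XX.ravel(), YY.ravel()])

    cluster_poly = geometry.cluster_polygon()
    exterior = shapely.prepared.prep(
        Polygon(cluster_poly.exterior).exterior.buffer(1.5)
    )
    # the traction must be smooth everywhere (real reconstructed fields
    # are): patches are not clipped; a smooth window confines them to a
    # few um around the cluster, per-cell corrections taper to zero at
    # footprint boundaries, and a smooth band term zeroes the spill that
    # falls outside all footprints.
    T = np.zeros(nyx + (2,))
    cell_masks_grid = []
    sigma = 1.5  # um, patch width
    inset = 4.0  # um, anchor depth behind the boundary
    endpoint_pts_um = (
        np.array(
            [itf.points[k] * px for itf in geometry.interfaces for k in (0, -1)]
        )
        if geometry.interfaces
        else None
    )
    for i, poly_px in enumerate(geometry.cell_polygons):
        poly_um = poly_px * px
        cell = Polygon(poly_um)
        inside = shapely.contains_xy(cell, pts[:, 0], pts[:, 1]).reshape(nyx)
        cell_masks_grid.append(inside)
        centroid = np.asarray(cell.centroid.coords[0])
        # patch anchor points: boundary vertices on the cluster exterior,
        # inset toward the centroid
        bnd = poly_um[:-1] if np.allclose(poly_um[0], poly_um[-1]) else poly_um
        keep = [p for p in bnd if exterior.intersects(shapely.Point(p))]
        if len(keep) < 3:
            keep = list(bnd)
        keep = np.asarray(keep)
        # avoid focal traction right at junction endpoints: anchors stay
        # clear of the corners where interfaces meet the cluster boundary
        if endpoint_pts_um is not None and len(endpoint_pts_um):
            d2 = np.min(
                np.sum(
                    (keep[:, None, :] - endpoint_pts_um[None, :, :]) ** 2, axis=2
                ),
                axis=1,
            )
            far = keep[d2 > 6.0**2]
            if len(far) >= 3:
                keep = far
        # subsample anchors every ~3 um of boundary
        d = np.r_[0, np.cumsum(np.linalg.norm(np.diff(keep, axis=0), axis=1))]
        sel = keep[np.searchsorted(d, np.arange(0, d[-1], 3.0))]
        anchors, dirs, amps = [], [], []
        for p0 in sel:
            direction = centroid - p0
            nd = np.linalg.norm(direction)
            if nd < 1e-9:
                continue
            direction = direction / nd
            anchors.append(p0 + inset * direction)
            dirs.append(direction)
            amps.append(
                config.traction_amplitude
                * strengths[i]
                * (1.0 + 0.3 * rng.uniform(-1, 1))
            )
        anchors = np.asarray(anchors)
        dirs = np.asarray(dirs)
        amps = np.asarray(amps, dtype=float)
        mass = 2 * np.pi * sigma**2  # continuous mass of a unit patch
        if prescribed:
            # adjust amplitudes (least squares, minimal change) so the
            # patch field itself integrates to ~ -f_res for this cell;
            # the exact numeric projection below then only removes a
            # small remainder, keeping interior corrections weak
            A = (dirs * mass).T  # (2, K)
            P0 = A @ amps
            rhs = -residuals[i] - P0
            try:
                amps = amps + A.T @ np.linalg.solve(A @ A.T, rhs)
            except np.linalg.LinAlgError:
                pass
        elif n > 1:
            # emergent mode: polarize the contraction smoothly around the
            # cell so it develops a net traction imbalance of order
            # residual_scale without focal hot spots
            target = abs(rng.normal(0.0, config.residual_scale))
            theta_b = rng.uniform(0, 2 * np.pi)
            gross = 0.5 * float(np.sum(amps)) * mass
            gamma = min(0.85, target / max(gross, 1e-9))
            ang = np.arctan2(
                anchors[:, 1] - centroid[1], anchors[:, 0] - centroid[0]
            )
            amps = amps * (1.0 + gamma * np.cos(ang - theta_b))
        for anchor, direction, amp in zip(anchors, dirs, amps):
            g = np.exp(
                -((XX - anchor[0]) ** 2 + (YY - anchor[1]) ** 2) / (2 * sigma**2)
            )
            T[:, :, 0] += amp * g * direction[0]
            T[:, :, 1] += amp * g * direction[1]

    # smooth window: 1 inside the cluster, rolling to 0 within ~3 um outside
    from scipy.ndimage import distance_transform_edt

    union_mask = np.zeros(nyx, dtype=bool)
    for m in cell_masks_grid:
        union_mask |= m
    d_out = distance_transform_edt(~union_mask) * spacing
    window = np.clip(1.0 - d_out / 3.0, 0.0, 1.0)
    T *= window[:, :, None]

    area = spacing**2
    cluster_centroid = np.asarray(cluster_poly.centroid.coords[0])
    # tapered correction weights: vanish at footprint boundaries, so the
    # corrected field stays continuous across interfaces
    weights = []
    for inside in cell_masks_grid:
        if not inside.any():
            raise RuntimeError("a cell footprint misses the traction grid")
        d_in = distance_transform_edt(inside) * spacing
        weights.append(np.clip(d_in / 4.0, 0.0, 1.0) * inside)
    band = union_mask == False  # noqa: E712  (band = outside all footprints)
    band_w = np.clip(1.0 - np.abs(d_out - 1.5) / 1.5, 0.0, 1.0) * band

    def _zero_torque(w_field, sel):
        """Add a tapered rotational field to zero the torque over `sel`."""
        rx = XX[sel] - cluster_centroid[0]
        ry = YY[sel] - cluster_centroid[1]
        tau = (rx * T[sel][:, 1] - ry * T[sel][:, 0]).sum() * area
        cx = (XX * w_field).sum() / w_field.sum()
        cy = (YY * w_field).sum() / w_field.sum()
        bx = -(YY - cy) * w_field
        by = (XX - cx) * w_field
        tau_basis = (
            (XX - cluster_centroid[0]) * by - (YY - cluster_centroid[1]) * bx
        )[sel].sum() * area
        if abs(tau_basis) > 1e-12:
            coef = -tau / tau_basis
            T[:, :, 0] += coef * bx
            T[:, :, 1] += coef * by

    if prescribed:
        # two-pass exact projection: per-cell force and torque, band spill
        for _pass in range(2):
            for i, (inside, w) in enumerate(zip(cell_masks_grid, weights)):
                cur = T[inside].sum(axis=0) * area
                corr = (-residuals[i] - cur) / (w.sum() * area)
                T[:, :, 0] += corr[0] * w
                T[:, :, 1] += corr[1] * w
                _zero_torque(w, inside)
            if band_w.sum() > 0:
                spill = T[band].sum(axis=0) * area
                T[:, :, 0] -= spill[0] * band_w / (band_w.sum() * area)
                T[:, :, 1] -= spill[1] * band_w / (band_w.sum() * area)
    else:
        # emergent mode: only global force/torque balance is enforced;
        # the per-cell residuals are whatever the polarized patches give
        w_all = np.sum(weights, axis=0)
        everything = np.ones_like(union_mask, dtype=bool)
        for _pass in range(2):
            if band_w.sum() > 0:
                spill = T[band].sum(axis=0) * area
                T[:, :, 0] -= spill[0] * band_w / (band_w.sum() * area)
                T[:, :, 1] -= spill[1] * band_w / (band_w.sum() * area)
            total = T.sum(axis=(0, 1)) * area
            corr = -total / (w_all.sum() * area)
            T[:, :, 0] += corr[0] * w_all
            T[:, :, 1] += corr[1] * w_all
            _zero_torque(w_all, everything)
        residuals = np.array(
            [-T[inside].sum(axis=0) * area for inside in cell_masks_grid]
        )

    traction = VectorField2D((float(xs[0]), float(ys[0])), spacing, T)

    junction_forces: dict[int, np.ndarray] = {}
    if nx.is_forest(geometry.adjacency):
        for itf in geometry.interfaces:
            junction_forces[itf.junction_id] = _partition_force(
                geometry.adjacency, residuals, (itf.cell_a, itf.cell_b)
            )
    profiles = _truth_stress_profiles(geometry, junction_forces, config, rng)
    return SyntheticGroundTruth(
        geometry, traction, residuals, junction_forces, profiles, config, config.seed
    )


# ---------------------------------------------------------------------------
# junction stress / intensity truth
# ---------------------------------------------------------------------------


def smooth_arc_noise(
    n: int, spacing_um: float, corr_length_um: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance noise along an arc whose autocorrelation drops to 0.5
    at a lag of ``corr_length_um``.

    White noise filtered with a Gaussian kernel of sd
    ell = corr_length / (2 sqrt(ln 2)) has autocorrelation
    exp(-lag^2 / (4 ell^2)), which equals 1/2 at lag = corr_length.
    """
    if corr_length_um <= 0:
        return rng.standard_normal(n)
    ell = corr_length_um / (2 * np.sqrt(np.log(2.0)))
    sig = ell / spacing_um
    pad = int(np.ceil(6 * sig)) + 1
    w = rng.standard_normal(n + 2 * pad)
    sm = gaussian_filter1d(w, sig, mode="constant")[pad:-pad]
    # renormalize to unit variance using the theoretical filtered-noise sd
    norm = 1.0 / np.sqrt(2 * np.sqrt(np.pi) * sig) if sig > 0.3 else np.std(sm) or 1.0
    return sm / norm


def _truth_stress_profiles(
    geometry: ClusterGeometry,
    junction_forces: dict[int, np.ndarray],
    config: SceneConfig,
    rng: np.random.Generator,
) -> dict[int, dict]:
    """Ground-truth sub-junctional stress/intensity samples per interface.

    Stress magnitude along a junction is its mean transmitted stress
    |f|/L modulated by a smooth +-50% variation with the configured
    correlation length; intensity is baseline + coupling * stress plus
    spatially correlated noise.  Samples sit at every 10th interface
    pixel, mirroring the analysis-side profile sampling.
    """
    px = geometry.pixel_size
    profiles: dict[int, dict] = {}
    for itf in geometry.interfaces:
        pts = itf.points[::10]
        if len(pts) < 3:
            pts = itf.points[:: max(1, len(itf.points) // 3)]
        d = np.diff(pts * px, axis=0)
        s = np.r_[0, np.cumsum(np.hypot(d[:, 0], d[:, 1]))]
        spacing = s[-1] / max(len(s) - 1, 1)
        L = itf.length_um(px)
        f = junction_forces.get(itf.junction_id)
        base = (np.linalg.norm(f) / L) if f is not None else 100.0
        base = max(base, 20.0)
        mod = smooth_arc_noise(len(s), spacing, config.intensity_corr_length, rng)
        stress = np.clip(base * (1.0 + 0.5 * mod), 0.05 * base, None)
        noise = smooth_arc_noise(len(s), spacing, config.intensity_corr_length, rng)
        intensity = (
            600.0
            + config.intensity_coupling * stress
            + config.intensity_noise_sd * noise
        )
        profiles[itf.junction_id] = {
            "points_px": pts,
            "arc_um": s,
            "stress_mag": stress,
            "intensity": intensity,
        }
    return profiles


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def _splat_gaussians(
    shape: tuple[int, int],
    centers_px: np.ndarray,
    sigma_px: float,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Accumulate Gaussian spots onto an image (windowed at +-4 sigma)."""
    img = np.zeros(shape)
    H, W = shape
    r = max(int(np.ceil(4 * sigma_px)), 2)
    for (cx, cy), a in zip(centers_px, amplitudes):
        ix, iy = int(round(cx)), int(round(cy))
        x0, x1 = max(ix - r, 0), min(ix + r + 1, W)
        y0, y1 = max(iy - r, 0), min(iy + r + 1, H)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        img[y0:y1, x0:x1] += a * np.exp(
            -(xs[None, :] ** 2 + ys[:, None] ** 2) / (2 * sigma_px**2)
        )
    return img


def render_bead_images(
    displacement: VectorField2D,
    config: SceneConfig,
    field_size_px: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the unstrained reference and deformed bead image pair.

    Beads are placed by a seeded uniform point process; each bead is a
    Gaussian spot.  In the deformed frame each bead is shifted by the
    local displacement (bilinear interpolation of the field at the bead),
    optionally plus per-bead Gaussian positional noise
    (``displacement_noise_sd``).
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    H, W = field_size_px
    px = config.pixel_size
    area = H * W * px**2
    n_beads = rng.poisson(config.bead_density * area)
    pos_um = rng.uniform([0, 0], [W * px, H * px], size=(n_beads, 2))
    sigma_px = config.bead_psf_sigma / px
    if config.bead_density * np.pi * (2 * config.bead_psf_sigma) ** 2 > 1.0:
        warnings.warn("bead density so high that spots merge everywhere")
    amps = 1000.0 * (0.6 + 0.8 * rng.random(n_beads))
    ref = _splat_gaussians((H, W), pos_um / px, sigma_px, amps)
    u = displacement.sample(pos_um)
    if config.displacement_noise_sd > 0:
        u = u + rng.normal(0, config.displacement_noise_sd, u.shape)
    defo = _splat_gaussians((H, W), (pos_um + u) / px, sigma_px, amps)
    background = 100.0
    return ref + background, defo + background


def render_junction_intensity(
    geometry: ClusterGeometry,
    profiles: dict[int, dict],
    config: SceneConfig,
) -> np.ndarray:
    """Render the junction-marker image from ground-truth profiles.

    The cluster footprint gets a uniform plateau above background (the
    cytoplasmic marker pool); each interface is drawn as a bright line
    whose local brightness follows the profile intensity; everything else
    stays at a background level below the cluster-detection threshold.
    """
    H, W = geometry.field_size_px
    img = np.full((H, W), 100.0)
    body = np.zeros((H, W), dtype=bool)
    for m in geometry.footprint_masks():
        body |= m
    img[body] = 500.0
    line_sigma = 2.0  # px, junction cross-section
    for itf in geometry.interfaces:
        prof = profiles[itf.junction_id]
        # per-pixel arc positions along the full-resolution polyline
        pts = itf.points
        d = np.diff(pts * geometry.pixel_size, axis=0)
        s_full = np.r_[0, np.cumsum(np.hypot(d[:, 0], d[:, 1]))]
        vals = np.interp(s_full, prof["arc_um"], prof["intensity"])
        # stamps at 1-px arc steps sum to ~a*sqrt(2*pi)*sigma across the
        # line, so divide amplitudes accordingly to hit `vals` on-centre
        img += _splat_gaussians(
            (H, W), pts, line_sigma, vals / (np.sqrt(2 * np.pi) * line_sigma)
        )
    return img


def make_scene(config: SceneConfig) -> SyntheticGroundTruth:
    """Full scene: geometry + traction + ground-truth profiles."""
    geometry = generate_cluster_geometry(config)
    rng = np.random.default_rng(config.seed + 1)
    return synthesize_traction_field(geometry, None, None, config, rng)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def scene_to_json(truth: SyntheticGroundTruth) -> str:
    geo = truth.geometry
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(truth.config),
        "seed": truth.seed,
        "field_size_px": list(geo.field_size_px),
        "pixel_size": geo.pixel_size,
        "cell_polygons": [p.tolist() for p in geo.cell_polygons],
        "interfaces": [
            {
                "junction_id": i.junction_id,
                "cell_a": i.cell_a,
                "cell_b": i.cell_b,
                "points": i.points.tolist(),
            }
            for i in geo.interfaces
        ],
        "true_residuals": truth.true_residuals.tolist(),
        "true_junction_forces": {
            str(k): v.tolist() for k, v in truth.true_junction_forces.items()
        },
    }
    return json.dumps(payload)
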