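"""End-to-end orchestration: images (or synthetic scenes) -> bead
displacements -> traction -> cluster graph -> junction forces (force
balance + thin-plate FEM) -> profiles and time-resolved analytics."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import analysis, fem, mechanics, segmentation, tfm, tracking
from .fields import SubstrateModel, VectorField2D, grid_covering
from .scenes import SceneConfig, SyntheticGroundTruth, make_scene

log = logging.getLogger("jforce")

__all__ = ["PipelineConfig", "FrameResult", "process_frame", "process_scene",
           "process_timelapse", "mechanics_from_traction"]


@dataclass
class PipelineConfig:
    """All knobs of a full per-frame analysis."""

    pixel_size: float = 0.16  # um/px
    substrate_modulus: float = 8000.0  # Pa
    substrate_poisson: float = 0.5
    fttc: tfm.FttcConfig = field(default_factory=tfm.FttcConfig)
    plate: fem.ThinPlateModel = field(default_factory=fem.ThinPlateModel)
    dilation_radius_px: int = 30
    mesh_edge_um: float = 1.5
    profile_step_px: int = 10  # sub-junctional sampling for profiles
    force_step_px: int = 5  # finer sampling for force integration
    seed: int = 0

    @property
    def substrate(self) -> SubstrateModel:
        return SubstrateModel(self.substrate_modulus, self.substrate_poisson)

    def hash(self) -> str:
        payload = {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(self).items()
        }
        return hashlib.sha1(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class FrameResult:
    """Everything one frame of the pipeline produces."""

    tight_mask: np.ndarray = field(repr=False)
    dilated_mask: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    traction: VectorField2D = field(repr=False)
    displacement: VectorField2D | None = field(repr=False, default=None)
    graph: mechanics.ClusterGraph | None = None
    solution: fem.ThinPlateSolution | None = None
    profiles: dict[int, fem.JunctionProfile] = field(default_factory=dict)
    strain_energies: dict[int, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Dump frame products as plain CSV/JSON (+ TIFF masks)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        import tifffile

        tifffile.imwrite(out / "tight_mask.tif", self.tight_mask.astype("uint8") * 255)
        tifffile.imwrite(out / "dilated_mask.tif", self.dilated_mask.astype("uint8") * 255)
        self.traction.to_dataframe().rename(
            columns={"vx": "tx_Pa", "vy": "ty_Pa"}
        ).to_csv(out / "traction.csv", index=False)
        if self.graph is not None:
            (out / "graph.json").write_text(self.graph.to_json())
            self.graph.to_dataframe().to_csv(out / "junctions.csv", index=False)
        if self.profiles:
            rows = []
            for jid, p in self.profiles.items():
                for k in range(len(p.arc_um)):
                    rows.append(
                        dict(junction_id=jid, s_um=p.arc_um[k],
                             px_x=p.points_px[k, 0], px_y=p.points_px[k, 1],
                             nx=p.normals[k, 0], ny=p.normals[k, 1],
                             sx_pN_per_um=p.stress_vectors[k, 0],
                             sy_pN_per_um=p.stress_vectors[k, 1])
                    )
            pd.DataFrame(rows).to_csv(out / "profiles.csv", index=False)
        if self.strain_energies:
            (out / "strain_energy.json").write_text(
                json.dumps({str(k): v for k, v in self.strain_energies.items()})
            )
        if self.solution is not None:
            self.solution.write_csv(out)
        (out / "provenance.json").write_text(json.dumps(self.provenance, default=str))


def _masks_from_labels(labels: np.ndarray, n_cells: int, fld: VectorField2D,
                       pixel_size: float) -> list[np.ndarray]:
    """Per-cell boolean masks on a vector-field grid from a label image."""
    XX, YY = np.meshgrid(fld.x / pixel_size, fld.y / pixel_size)
    iy = np.clip(np.round(YY).astype(int), 0, labels.shape[0] - 1)
    ix = np.clip(np.round(XX).astype(int), 0, labels.shape[1] - 1)
    lab = labels[iy, ix]
    return [lab == i + 1 for i in range(n_cells)]


def mechanics_from_traction(
    traction: VectorField2D,
    tight_mask: np.ndarray,
    dilated_mask: np.ndarray,
    cell_masks_px: list[np.ndarray],
    interfaces: list,
    config: PipelineConfig,
    traction_masks: list[np.ndarray] | None = None,
) -> tuple[mechanics.ClusterGraph, fem.ThinPlateSolution | None, dict]:
    """Graph + balance forces + FEM forces from a traction field.

    ``cell_masks_px`` are per-cell boolean masks at image resolution
    (index = cell id); ``traction_masks`` optionally provides masks
    aligned with the traction grid (otherwise derived from the label
    image).  FEM junction forces integrate sigma . n along the full
    separating cut between the two cell groups (tree edges) or the two
    cells' territories (loop edges).
    """
    n = len(cell_masks_px)
    labels = np.zeros(tight_mask.shape, dtype=int)
    for i, m in enumerate(cell_masks_px):
        labels[m] = i + 1
    if traction_masks is None:
        traction_masks = _masks_from_labels(labels, n, traction, config.pixel_size)
    lengths = {
        itf.junction_id: segmentation.interface_length(
            itf.points, tight_mask, config.pixel_size
        )
        for itf in interfaces
    }
    centers = np.array(
        [np.array(np.nonzero(m)).mean(axis=1)[::-1] if m.any() else (np.nan, np.nan)
         for m in cell_masks_px]
    )
    graph = mechanics.build_cluster_graph(
        traction_masks, interfaces, traction, config.pixel_size, lengths, centers
    )
    mechanics.balance_all_bridges(graph)

    solution = None
    profiles: dict[int, fem.JunctionProfile] = {}
    if interfaces:
        mesh = fem.build_mesh(dilated_mask, config.pixel_size, config.mesh_edge_um)
        E_nodes = fem.modulus_field(mesh, tight_mask, config.pixel_size, config.plate)
        solution = fem.solve_thin_plate(mesh, config.plate, traction, E_nodes)
        g = graph.graph
        for a, b, d in g.edges(data=True):
            if d["is_bridge"]:
                h = g.copy()
                h.remove_edge(a, b)
                g1 = nx.node_connected_component(h, a)
                g2 = nx.node_connected_component(h, b)
            else:
                g1, g2 = {a}, {b}
            cut, side = fem.separating_cut_polyline(
                cell_masks_px, g1, g2, dilated_mask
            )
            prof = fem.interface_stress_profile(
                solution, cut, config.pixel_size, side,
                d["junction_id"], a, b, step=config.force_step_px,
            )
            d["f_fem"] = fem.integrate_interface_force(prof)
            # the reported sub-junctional profile samples the drawn
            # interface at the conventional every-10th-pixel density
            itf = next(i for i in interfaces if i.junction_id == d["junction_id"])
            profiles[d["junction_id"]] = fem.interface_stress_profile(
                solution, itf.points, config.pixel_size, side,
                d["junction_id"], a, b, step=config.profile_step_px,
            )
    return graph, solution, profiles


def process_frame(
    config: PipelineConfig,
    bead_reference: np.ndarray,
    bead_deformed: np.ndarray,
    marker_image: np.ndarray,
    interfaces: list,
) -> FrameResult:
    """Full single-frame analysis from raw images.

    Stages: bead tracking -> displacement gridding -> regularized FTTC
    -> marker segmentation -> cell partition -> residual forces and
    balance forces on bridge edges -> thin-plate FEM forces on all edges
    -> junction stress profiles -> per-cell strain energies.
    """
    t0 = time.time()
    sub = config.substrate
    pos, disp = tfm.track_bead_displacements(
        bead_reference, bead_deformed, config.fttc, config.pixel_size
    )
    if len(pos) < 4:
        raise RuntimeError("bead tracking produced too few displacements")
    H, W = marker_image.shape
    side = max(H, W) * config.pixel_size
    origin, shape = grid_covering((0.0, 0.0, side, side), config.fttc.output_spacing)
    ufield = tfm.interpolate_to_grid(
        pos, disp, config.fttc.output_spacing, origin, shape
    )
    traction = tfm.fttc_reconstruct(ufield, sub, config.fttc.regularization)
    log.info("tfm stage done in %.2fs (%d beads)", time.time() - t0, len(pos))

    tight = segmentation.segment_cluster_mask(marker_image)
    dilated = segmentation.dilate_cluster_mask(tight, config.dilation_radius_px)
    if interfaces:
        labels, _ = segmentation.partition_cells(tight, interfaces)
        mapping = segmentation.labels_for_cell_ids(labels, interfaces)
        n_cells = max(mapping) + 1
        cell_masks = [labels == mapping.get(i, -1) for i in range(n_cells)]
        relabeled = np.zeros_like(labels)
        for i, m in enumerate(cell_masks):
            relabeled[m] = i + 1
    else:
        relabeled = tight.astype(int)
        cell_masks = [tight]

    graph, solution, profiles = mechanics_from_traction(
        traction, tight, dilated, cell_masks, interfaces, config
    )
    energies = {}
    tmasks = _masks_from_labels(relabeled, len(cell_masks), traction, config.pixel_size)
    for i, m in enumerate(tmasks):
        if m.any():
            energies[i] = mechanics.strain_energy(m, traction, sub)
    return FrameResult(
        tight, dilated, relabeled, traction, ufield, graph, solution, profiles,
        energies,
        provenance={"config_hash": config.hash(), "seed": config.seed,
                    "n_beads": len(pos), "elapsed_s": time.time() - t0},
    )


def process_scene(
    config: PipelineConfig, truth: SyntheticGroundTruth, use_true_traction: bool = False
) -> FrameResult:
    """Run the pipeline on a synthetic scene.

    With ``use_true_traction`` the TFM stages are bypassed and the
    generator's exact traction field is fed to the mechanics stages
    (useful to isolate method errors from reconstruction errors).
    """
    geo = truth.geometry
    scfg: SceneConfig = truth.config
    masks_px = geo.footprint_masks()
    tight = np.zeros(geo.field_size_px, dtype=bool)
    for m in masks_px:
        tight |= m
    dilated = segmentation.dilate_cluster_mask(tight, config.dilation_radius_px)
    if use_true_traction:
        traction = truth.true_traction
        graph, solution, profiles = mechanics_from_traction(
            traction, tight, dilated, masks_px, geo.interfaces, config,
            traction_masks=geo.masks_on_grid(traction),
        )
        energies = {
            i: mechanics.strain_energy(m, traction, scfg.substrate)
            for i, m in enumerate(geo.masks_on_grid(traction))
        }
        labels = np.zeros(tight.shape, dtype=int)
        for i, m in enumerate(masks_px):
            labels[m] = i + 1
        return FrameResult(
            tight, dilated, labels, traction, None, graph, solution, profiles,
            energies, provenance={"config_hash": config.hash(), "seed": scfg.seed,
                                  "mode": "true-traction"},
        )
    from .scenes import render_bead_images, render_junction_intensity
    from .tfm import boussinesq_displacement

    u_true = boussinesq_displacement(truth.true_traction, scfg.substrate)
    rng = np.random.default_rng(scfg.seed + 2)
    ref, defo = render_bead_images(u_true, scfg, geo.field_size_px, rng)
    marker = render_junction_intensity(geo, truth.junction_profiles, scfg)
    return process_frame(config, ref, defo, marker, geo.interfaces)


def process_timelapse(
    config: PipelineConfig,
    frames: list[FrameResult],
    frame_interval_s: float = 60.0,
) -> dict:
    """Track entities across processed frames and build time analytics.

    Returns cell and interface track sets, per-junction force series,
    per-cell residual and strain-energy series (resampled to the 240-s
    analysis rate and variance-normalized for pooling), and the
    force-transmission table for every cell with >= 2 junctions.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 processed frames")
    centers = []
    for fr in frames:
        g = fr.graph.graph
        centers.append(
            np.array([g.nodes[i].get("center", (np.nan, np.nan))
                      for i in sorted(g.nodes)]) * config.pixel_size
        )
    cell_tracks = tracking.track_cells(centers)
    iface_feats = []
    for fr in frames:
        feats = []
        for jid, p in sorted(fr.profiles.items()):
            feats.append({"end1": p.points_um[0], "end2": p.points_um[-1],
                          "com": p.points_um.mean(axis=0), "junction_id": jid})
        iface_feats.append(feats)
    iface_tracks = tracking.track_interfaces(iface_feats)

    times = np.arange(len(frames)) * frame_interval_s
    force_series: dict[int, np.ndarray] = {}
    for tid, tr in iface_tracks.tracks.items():
        if len(tr) != len(frames):
            continue  # analytics use complete tracks only
        series = []
        for f, idx in sorted(tr.items()):
            jid = iface_feats[f][idx]["junction_id"]
            _, _, d = frames[f].graph.edge_by_junction(jid)
            fvec = d.get("f_fem") if d.get("f_fem") is not None else d.get("f_balance")
            series.append(fvec if fvec is not None else (np.nan, np.nan))
        force_series[tid] = np.asarray(series, dtype=float)
    residual_series: dict[int, np.ndarray] = {}
    energy_series: dict[int, np.ndarray] = {}
    for tid, tr in cell_tracks.tracks.items():
        if len(tr) != len(frames):
            continue
        residual_series[tid] = np.array(
            [frames[f].graph.graph.nodes[idx]["f_res"] for f, idx in sorted(tr.items())]
        )
        energy_series[tid] = np.array(
            [frames[f].strain_energies.get(idx, np.nan) for f, idx in sorted(tr.items())]
        )
    cluster_sum = np.array(
        [sum(np.linalg.norm(v[f]) for v in force_series.values())
         for f in range(len(frames))]
    )
    transmission = []
    # map cells to their incident junction tracks via frame 0
    g0 = frames[0].graph.graph
    for tid, tr in cell_tracks.tracks.items():
        if len(tr) != len(frames):
            continue
        cell0 = tr[0]
        incident = {}
        for a, b, d in g0.edges(data=True):
            if cell0 in (a, b):
                for jt, jtr in iface_tracks.tracks.items():
                    if len(jtr) == len(frames) and \
                       iface_feats[0][jtr[0]]["junction_id"] == d["junction_id"]:
                        fv = force_series[jt]
                        incident[jt] = fv if cell0 == b else -fv
        if len(incident) < 2:
            continue
        norm_inc = {}
        for jt, fv in incident.items():
            _, v = analysis.resample_and_normalize(times, fv)
            norm_inc[jt] = v
        _, res_n = analysis.resample_and_normalize(times, residual_series[tid])
        transmission.append(
            analysis.transmission_analysis(norm_inc, res_n, cell_id=tid)
        )
    return {
        "cell_tracks": cell_tracks,
        "interface_tracks": iface_tracks,
        "times_s": times,
        "junction_force_series": force_series,
        "residual_series": residual_series,
        "strain_energy_series": energy_series,
        "cluster_force_sum": cluster_sum,
        "transmission": (
            pd.concat(transmission, ignore_index=True) if transmission else pd.DataFrame()
        ),
    }
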