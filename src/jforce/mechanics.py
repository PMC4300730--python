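"""Cluster graph mechanics: residual forces, junction force balance,
strain energy.

A cluster is a graph with cells as nodes and junctions as edges.  The
force-balancing principle states that the traction of the whole cluster
integrates to zero, so the residual traction force of any connected cell
group equals the force its complement exerts on it through the junctions
crossing the cut.  For bridge edges (edges whose removal disconnects the
graph) this determines the transmitted junction force; edges inside
loops are statically indeterminate here and require the thin-plate model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .fields import SubstrateModel, VectorField2D
from .tfm import boussinesq_displacement

__all__ = [
    "ClusterGraph",
    "residual_traction",
    "build_cluster_graph",
    "junction_force_balance",
    "cell_force_summaries",
    "strain_energy",
]


@dataclass
class ClusterGraph:
    """Cells (nodes) and junctions (edges) with their mechanical state.

    Node attributes: ``f_res`` (pN), ``degree`` k, ``strain_energy`` (aJ,
    optional), ``center`` (px).  Edge attributes: ``junction_id``,
    ``is_bridge``, ``f_balance``/``f_fem`` (pN, force exerted by
    ``cell_a`` on ``cell_b`` -- the single stored orientation from which
    every report derives), ``length_um``, ``min_k``.
    """

    graph: nx.Graph
    traction: VectorField2D | None = None
    pixel_size: float = 1.0

    def edge_by_junction(self, junction_id: int):
        for a, b, data in self.graph.edges(data=True):
            if data.get("junction_id") == junction_id:
                return a, b, data
        raise KeyError(f"no edge with junction_id {junction_id}")

    def residuals(self) -> np.ndarray:
        return np.array(
            [self.graph.nodes[i]["f_res"] for i in sorted(self.graph.nodes)]
        )

    def to_json(self) -> str:
        nodes = [
            {
                "cell_id": int(i),
                "f_res_pN": np.asarray(d["f_res"]).tolist(),
                "degree": int(self.graph.degree[i]),
                "strain_energy_aJ": d.get("strain_energy"),
                "center_px": np.asarray(d.get("center", (np.nan, np.nan))).tolist(),
            }
            for i, d in sorted(self.graph.nodes(data=True))
        ]
        edges = []
        for a, b, d in self.graph.edges(data=True):
            rec = {
                "junction_id": int(d["junction_id"]),
                "cell_a": int(a),
                "cell_b": int(b),
                "is_bridge": bool(d["is_bridge"]),
                "length_um": d.get("length_um"),
                "min_k": int(d["min_k"]),
            }
            for key in ("f_balance", "f_fem"):
                v = d.get(key)
                rec[f"{key}_pN"] = None if v is None else np.asarray(v).tolist()
            edges.append(rec)
        return json.dumps({"nodes": nodes, "edges": edges})

    def to_dataframe(self, frame: int | None = None) -> pd.DataFrame:
        rows = []
        for a, b, d in self.graph.edges(data=True):
            f = d.get("f_fem") if d.get("f_fem") is not None else d.get("f_balance")
            mag = np.nan if f is None else float(np.linalg.norm(f))
            length = d.get("length_um")
            rows.append(
                {
                    "frame": frame,
                    "junction_id": d["junction_id"],
                    "cell_a": a,
                    "cell_b": b,
                    "fx_pN": np.nan if f is None else float(f[0]),
                    "fy_pN": np.nan if f is None else float(f[1]),
                    "f_mag_pN": mag,
                    "length_um": length,
                    "stress_pN_per_um": (
                        np.nan if f is None or not length else mag / length
                    ),
                    "min_k": d["min_k"],
                    "is_bridge": d["is_bridge"],
                }
            )
        return pd.DataFrame(rows)


def residual_traction(
    footprint: np.ndarray, traction: VectorField2D
) -> np.ndarray:
    """Residual traction force f_res = -integral of T over one footprint.

    ``footprint`` is a boolean mask aligned with the traction grid.  With
    traction in Pa and grid spacing in um the result is in pN.  f_res is
    the net force the cell's neighbours exert on it through junctions.
    """
    mask = np.asarray(footprint, dtype=bool)
    if not mask.any():
        raise ValueError("empty footprint")
    return -traction.integral(mask)


def build_cluster_graph(
    cell_masks: list[np.ndarray],
    interfaces: list,
    traction: VectorField2D,
    pixel_size: float = 1.0,
    interface_lengths_um: dict[int, float] | None = None,
    centers_px: np.ndarray | None = None,
) -> ClusterGraph:
    """Assemble the cluster graph with residual forces and bridge flags.

    ``cell_masks`` are per-cell boolean masks on the traction grid
    (index = cell id); ``interfaces`` carry ``junction_id``, ``cell_a``,
    ``cell_b``.  An edge is a bridge iff its removal disconnects the
    graph; ``min_k`` is the smaller connectivity degree of its two cells.
    """
    n = len(cell_masks)
    g = nx.Graph()
    for i, mask in enumerate(cell_masks):
        g.add_node(i, f_res=residual_traction(mask, traction))
        if centers_px is not None:
            g.nodes[i]["center"] = np.asarray(centers_px[i])
    for itf in interfaces:
        a, b = itf.cell_a, itf.cell_b
        if a >= n or b >= n or a < 0 or b < 0:
            raise ValueError(
                f"interface {itf.junction_id} references unknown cell id ({a},{b})"
            )
        length = None
        if interface_lengths_um is not None:
            length = interface_lengths_um.get(itf.junction_id)
        g.add_edge(
            a,
            b,
            junction_id=itf.junction_id,
            f_balance=None,
            f_fem=None,
            length_um=length,
        )
    bridges = set(map(frozenset, nx.bridges(g))) if g.number_of_edges() else set()
    for a, b in g.edges:
        g.edges[a, b]["is_bridge"] = frozenset((a, b)) in bridges
        g.edges[a, b]["min_k"] = min(g.degree[a], g.degree[b])
    return ClusterGraph(g, traction, pixel_size)


def junction_force_balance(cgraph: ClusterGraph, edge: tuple[int, int]) -> np.ndarray:
    """Junction force on a bridge edge by the force-balancing principle.

    Removing the edge splits the cluster into groups g1 (containing
    ``edge[0]``) and g2.  Each group's summed residual is an independent
    estimate of the transmitted force; the returned value is their
    symmetrized mean <f_g1,g2> = (f_g1,g2 - f_g2,g1)/2, i.e. the force
    exerted by the ``edge[0]`` side on the other, antisymmetric under
    edge reversal by construction.
    """
    g = cgraph.graph
    a, b = edge
    if not g.has_edge(a, b):
        raise KeyError(f"no edge {edge}")
    if not g.edges[a, b]["is_bridge"]:
        raise ValueError(
            f"edge {edge} is not a bridge: loop topology prevents the "
            "force-balancing calculation; use the thin-plate FEM instead"
        )
    h = g.copy()
    h.remove_edge(a, b)
    g1 = nx.node_connected_component(h, a)
    g2 = nx.node_connected_component(h, b)
    f_12 = np.sum([g.nodes[i]["f_res"] for i in g1], axis=0)
    f_21 = np.sum([g.nodes[j]["f_res"] for j in g2], axis=0)
    return 0.5 * (f_12 - f_21)


def balance_all_bridges(cgraph: ClusterGraph) -> None:
    """Store the balance force (cell_a on cell_b) on every bridge edge."""
    for a, b, d in cgraph.graph.edges(data=True):
        if d["is_bridge"]:
            d["f_balance"] = junction_force_balance(cgraph, (a, b))


def cell_force_summaries(cgraph: ClusterGraph, source: str = "auto") -> dict:
    """Per-cell, per-cluster and per-edge junction force summaries.

    Per cell: sum of |f| over incident edges; per cluster: sum over all
    edges; per edge: interfacial stress |f| / length (pN/um).  ``source``
    selects ``"f_balance"``, ``"f_fem"`` or ``"auto"`` (FEM when present,
    balance otherwise).
    """
    g = cgraph.graph
    per_edge = {}
    missing = []
    for a, b, d in g.edges(data=True):
        if source == "auto":
            f = d.get("f_fem") if d.get("f_fem") is not None else d.get("f_balance")
        else:
            f = d.get(source)
        if f is None:
            missing.append(d["junction_id"])
            continue
        per_edge[d["junction_id"]] = {
            "cells": (a, b),
            "magnitude_pN": float(np.linalg.norm(f)),
            "length_um": d.get("length_um"),
            "stress_pN_per_um": (
                float(np.linalg.norm(f)) / d["length_um"] if d.get("length_um") else None
            ),
            "min_k": d["min_k"],
        }
    if missing:
        raise ValueError(f"undefined force on edges (junction ids): {missing}")
    per_cell = {
        i: float(
            sum(
                per_edge[g.edges[e]["junction_id"]]["magnitude_pN"]
                for e in g.edges(i)
            )
        )
        for i in g.nodes
    }
    cluster_total = float(sum(v["magnitude_pN"] for v in per_edge.values()))
    return {"per_edge": per_edge, "per_cell": per_cell, "cluster_total_pN": cluster_total}


def strain_energy(
    footprint: np.ndarray,
    traction: VectorField2D,
    substrate: SubstrateModel,
) -> float:
    """Strain energy (aJ) a cell stores in the substrate.

    U_j = 1/2 int_{Omega_j} T . u_j dA, where u_j is the displacement
    generated by the cell's own traction alone (traction restricted to
    the footprint, forward Boussinesq map).  Using the full measured
    displacement instead would be wrong: elastic deformations are
    long-ranged, so the displacement under a cell contains contributions
    from its neighbours.  Non-negative because the Boussinesq kernel is
    positive semi-definite.
    """
    mask = np.asarray(footprint, dtype=bool)
    if not mask.any():
        raise ValueError("empty footprint")
    masked = traction.copy()
    masked.values[~mask] = 0.0
    u_own = boussinesq_displacement(masked, substrate)
    if not np.all(np.isfinite(u_own.values)):
        raise FloatingPointError("non-finite displacement in strain-energy map")
    dens = np.sum(masked.values * u_own.values, axis=-1)
    return float(0.5 * dens[mask].sum() * traction.pixel_area)
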