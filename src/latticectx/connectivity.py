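"""Lattice connectivity: pair criteria and maximum-connectivity networks.

A pair of candidate units is connected when its spacing, curvature (from
both tangential planes) and normal-vector difference all fall inside the
acceptance windows; connected components of the resulting graph are the
candidate particles, and only networks with more than ``min_network_size``
members are retained as genuine closed/extended lattices.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .geometry import UnitAnnotation, pair_geometry
from .synthetic import DEFAULT_SPACING, LatticeGraph

__all__ = ["ConnectivityCriteria", "pair_passes", "build_networks"]


@dataclass(frozen=True)
class ConnectivityCriteria:
    """Acceptance windows for unit-pair connectivity.

    Defaults are the operational values for a retroviral CA lattice:
    spacing 60-110 A, curvature -15..40 deg, normal difference <= 45 deg,
    and networks must exceed 20 units (strict) to count as particles.
    """

    min_spacing: float = 60.0
    max_spacing: float = 110.0
    min_curvature: float = -15.0
    max_curvature: float = 40.0
    max_normal_diff: float = 45.0
    min_network_size: int = 20

    def __post_init__(self):
        if not self.min_spacing < self.max_spacing:
            raise ValueError("min_spacing must be < max_spacing")
        if not self.min_curvature < self.max_curvature:
            raise ValueError("min_curvature must be < max_curvature")
        if not 0 < self.max_normal_diff <= 180:
            raise ValueError("max_normal_diff out of range")


def pair_passes(a: UnitAnnotation, b: UnitAnnotation,
                crit: ConnectivityCriteria = ConnectivityCriteria(),
                voxel_size: float = 1.0) -> tuple[bool, list[str]]:
    """Evaluate all pair criteria; returns (passed, failed-criterion labels).

    Boundary values are inclusive.  Curvature is checked from both units'
    tangential planes (stricter than a one-sided check, and symmetric).
    """
    g = pair_geometry(a, b, voxel_size)
    failed = []
    if g.distance < crit.min_spacing:
        failed.append("min_spacing")
    if g.distance > crit.max_spacing:
        failed.append("max_spacing")
    for c in (g.curvature, g.curvature_ba):
        if c < crit.min_curvature:
            failed.append("min_curvature")
            break
    for c in (g.curvature, g.curvature_ba):
        if c > crit.max_curvature:
            failed.append("max_curvature")
            break
    if g.normal_diff > crit.max_normal_diff:
        failed.append("max_normal_diff")
    return (not failed, failed)


def build_networks(units: list[UnitAnnotation],
                   crit: ConnectivityCriteria = ConnectivityCriteria(),
                   voxel_size: float = 1.0,
                   spacing_hint: float | None = None,
                   ) -> list[LatticeGraph]:
    """Connected components of the pair-criteria graph, size-filtered.

    Components with <= ``min_network_size`` units are discarded (strict
    ``>`` retention).  Each retained component becomes a LatticeGraph with
    a fresh ``network_id``; unit annotations are copied, not shared.
    """
    from scipy.spatial import cKDTree

    n = len(units)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    if n:
        pos = np.array([u.position for u in units]) * voxel_size
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(crit.max_spacing):
            ok, _ = pair_passes(units[i], units[j], crit, voxel_size)
            if ok:
                G.add_edge(i, j)
    out = []
    for comp in sorted(nx.connected_components(G), key=min):
        if len(comp) <= crit.min_network_size:
            continue
        idx = sorted(comp)
        remap = {k: r for r, k in enumerate(idx)}
        net_id = len(out)
        members = []
        for k in idx:
            u = units[k].copy()
            u.network_id = net_id
            members.append(u)
        edges = sorted((remap[i], remap[j]) if remap[i] < remap[j]
                       else (remap[j], remap[i])
                       for i, j in G.subgraph(comp).edges)
        g = LatticeGraph(members, edges, closed=False,
                         voxel_size=voxel_size,
                         spacing=spacing_hint or DEFAULT_SPACING,
                         network_id=net_id)
        # a component is a closed surface when every unit is fully ringed
        degs = [len(g.neighbors(i)) for i in range(len(g))]
        g.closed = all(
            d == (5 if g.units[i].is_pentamer else 6)
            for i, d in enumerate(degs)
        )
        out.append(g)
    return out
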