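"""Context classification of unit pairs.

Every pair of adjacent lattice units (a "dimer") is sorted into one of six
general groups by the positions of pentamers around the pair and, where no
pentamer constrains the geometry, by the orientation of the pair with
respect to the local tube axis.

Position numbering: the neighbor slots of unit A are numbered 1'..6'
counterclockwise (viewed from outside the particle), starting with the
partner unit B at slot 1; unit B is numbered 1''..6'' the same way.  A
pentamer at slot 1 means the partner itself is a pentamer; slots 2 and 6
are the two neighbors shared by A and B (so 2' names the same unit as 6''
and vice versa); slots 3-5 touch only one unit of the pair.

Groups:
  1  one or both units are pentamers
  2  hexamer pair sharing one or two pentamer neighbors (slots 2/6)
  3  both hexamers have pentamer(s) at slots 3-5
  4  exactly one hexamer has pentamer(s) at slots 3-5; subclassed by
     tube-orientation class
  5  no pentamers at slots 2-6 on either side (regular-tube context);
     three orientation subclasses
  6  one hexamer has pentamers at two of slots {3,4,5}, the other has none
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import signed_inplane_angle
from .synthetic import LatticeGraph

__all__ = [
    "PairContext",
    "ring_order",
    "number_positions",
    "classify_from_positions",
    "classify_pair",
    "classify_pairs",
    "orientation_class",
    "local_symmetry",
    "symmetry_independent_monomers",
    "enumerate_context_sweep",
]


@dataclass
class PairContext:
    """Classification result for one unit pair."""

    edge: tuple[int, int]
    group: int
    subclass: int
    positions_a: frozenset[int]
    positions_b: frozenset[int]
    orientation_class: int | None = None


def ring_order(g: LatticeGraph, i: int, first: int | None = None) -> list[int]:
    """Neighbors of unit i ordered counterclockwise viewed from outside.

    Projected into the unit's tangential plane and sorted by signed angle
    about the outward normal; if ``first`` is given the cycle starts there.
    """
    u = g.units[i]
    nbrs = g.neighbors(i)
    max_deg = 5 if u.is_pentamer else 6
    if len(nbrs) > max_deg:
        raise ValueError(
            f"unit {i} ({u.unit_type}) has {len(nbrs)} neighbors, "
            f"more than its {max_deg} slots"
        )
    n = u.normal
    if first is None:
        first = nbrs[0]
    ref = g.units[first].position - u.position
    def angle(j):
        if j == first:
            return 0.0
        a = signed_inplane_angle(ref, g.units[j].position - u.position, n)
        return a % 360.0
    return sorted(nbrs, key=angle)


def number_positions(g: LatticeGraph, edge: tuple[int, int]
                     ) -> tuple[frozenset[int], frozenset[int]]:
    """Pentamer-occupied neighbor slots of both units of an edge.

    Slot 1 is the partner unit; slots proceed counterclockwise viewed from
    outside.  For shared neighbors the identities 2' = 6'' and 6' = 2''
    hold by construction.
    """
    a, b = edge
    out = []
    for i, j in ((a, b), (b, a)):
        ring = ring_order(g, i, first=j)
        occ = {slot + 1 for slot, k in enumerate(ring)
               if g.units[k].is_pentamer}
        out.append(frozenset(occ))
    return out[0], out[1]


def classify_from_positions(pos_a: frozenset[int], pos_b: frozenset[int],
                            orientation: int | None = None
                            ) -> tuple[int, int]:
    """Pure group/subclass rule given pentamer slot sets of both units.

    Total over all consistent configurations; evaluated most-constrained
    first (1, 2, 6, 3, 4, 5).
    """
    a35 = pos_a & {3, 4, 5}
    b35 = pos_b & {3, 4, 5}
    if 1 in pos_a or 1 in pos_b:
        return 1, 0
    shared = pos_a & {2, 6}
    if shared:
        return 2, len(shared)
    if (len(a35) >= 2 and not b35) or (len(b35) >= 2 and not a35):
        two = a35 if len(a35) >= 2 else b35
        return 6, sum(two)  # {3,4}=7 {3,5}=8 {4,5}=9 {3,4,5}=12
    if a35 and b35:
        return 3, min(min(a35), min(b35))
    if a35 or b35:
        return 4, orientation if orientation else 0
    return 5, orientation if orientation else 0


def orientation_class(g: LatticeGraph, edge: tuple[int, int]
                      ) -> int | None:
    """Orientation of a pair w.r.t. the local tube geometry: class 1-3.

    The local cylinder axis is the near-null direction of the neighborhood
    normals (all cylinder normals are perpendicular to the axis).  The
    edge's in-plane angle to the axis, folded by the hexagonal symmetry,
    falls into one of three lattice edge families: circumferential
    (class 1) and the two oblique families (classes 2 and 3 by sign).
    Returns None where no axis is estimable (spherical neighborhood).
    """
    a, b = edge
    ua, ub = g.units[a], g.units[b]
    mid = 0.5 * (ua.position + ub.position)
    cutoff = 2.0 * g.spacing / g.voxel_size
    nearby = [u for u in g.units
              if np.linalg.norm(u.position - mid) <= cutoff]
    if len(nearby) < 5:
        return None
    N = np.array([u.normal for u in nearby])
    _, s, vt = np.linalg.svd(N, full_matrices=False)
    if s[2] / s[0] > 0.2:  # normals span 3D: no cylinder axis
        return None
    axis = vt[2]
    n = ua.normal + ub.normal
    n /= np.linalg.norm(n)

    def folded_beta(e):
        i, j = e
        d = g.units[j].position - g.units[i].position
        beta = signed_inplane_angle(axis, d, n)
        beta = (beta + 90.0) % 180.0 - 90.0  # edge and axis are undirected
        return beta

    # family offset from all edges incident to the pair (period 60 deg)
    incident = [e for e in g.edges if a in e or b in e]
    ang = np.deg2rad(np.array([folded_beta(e) for e in incident]) * 6.0)
    mu = np.rad2deg(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean())) / 6.0
    centers = [((mu + k * 60.0) + 90.0) % 180.0 - 90.0 for k in (-1, 0, 1)]
    # canonical labels: largest |center| = circumferential family (class 1),
    # then positive (class 2) / negative (class 3)
    order = sorted(centers, key=lambda c: (-abs(c)))
    rest = sorted(order[1:], reverse=True)
    labels = {order[0]: 1, rest[0]: 2, rest[1]: 3}
    beta = folded_beta(edge)
    dist = {c: min(abs(beta - c), 180.0 - abs(beta - c)) for c in centers}
    return labels[min(centers, key=lambda c: dist[c])]


def classify_pair(g: LatticeGraph, edge: tuple[int, int]) -> PairContext:
    """Assign a unit pair to its general group and subclass."""
    a, b = edge
    pos_a, pos_b = number_positions(g, edge)
    a35, b35 = pos_a & {3, 4, 5}, pos_b & {3, 4, 5}
    needs_orient = (not (1 in pos_a or 1 in pos_b)
                    and not (pos_a & {2, 6})
                    and not (a35 and b35)
                    and not (len(a35) >= 2 or len(b35) >= 2))
    orient = orientation_class(g, edge) if needs_orient else None
    group, subclass = classify_from_positions(pos_a, pos_b, orient)
    return PairContext(edge=edge, group=group, subclass=subclass,
                       positions_a=pos_a, positions_b=pos_b,
                       orientation_class=orient)


def classify_pairs(g: LatticeGraph) -> list[PairContext]:
    return [classify_pair(g, e) for e in g.edges]


def local_symmetry(g: LatticeGraph, i: int) -> str:
    """Local symmetry of a hexamer from its pentamer arrangement.

    C3 for pentamers alternating at three slots, C2_pentamer for two
    antipodal pentamers, C2_tube for a pentamer-free (tube-like) ring;
    any other arrangement breaks the symmetry (C1).
    """
    u = g.units[i]
    if u.is_pentamer:
        raise ValueError("local_symmetry is defined for hexamers")
    nbrs = g.neighbors(i)
    if len(nbrs) != 6:
        raise ValueError(f"hexamer {i} has {len(nbrs)} neighbors, need 6")
    ring = ring_order(g, i)
    slots = [s for s, k in enumerate(ring) if g.units[k].is_pentamer]
    if not slots:
        return "C2_tube"
    if len(slots) == 3:
        gaps = {(slots[1] - slots[0]) % 6, (slots[2] - slots[1]) % 6,
                (slots[0] - slots[2]) % 6}
        if gaps == {2}:
            return "C3"
    if len(slots) == 2 and (slots[1] - slots[0]) % 6 == 3:
        return "C2_pentamer"
    return "C1"


def symmetry_independent_monomers(unit_type: str, symmetry: str) -> int:
    """Number of symmetry-independent protein monomers in a unit.

    A hexamer has 6 monomers, a pentamer 5; local Cn symmetry reduces the
    independent count by the group order.
    """
    n = 5 if unit_type == "pentamer_C5" else 6
    order = {"C1": 1, "C2_tube": 2, "C2_pentamer": 2, "C3": 3,
             "C2": 2, "C5": 5, "C6": 6}[symmetry]
    if n % order:
        raise ValueError(f"{symmetry} is not a symmetry of a {n}-mer")
    return n // order


def enumerate_context_sweep() -> list[tuple[frozenset, frozenset, int, int]]:
    """Exhaustive sweep over consistent pentamer-position configurations.

    Slot 1 mirrors the partner's identity on both sides; slots 2/6 are the
    shared neighbors (2' = 6''); slots 3-5 are free per side.  Returns
    (pos_a, pos_b, group, subclass) for every configuration with every
    orientation class, using orientation class 1 where required.
    """
    out = []
    for a_is_pent in (False, True):
        for b_is_pent in (False, True):
            for s2 in (False, True):      # shared neighbor at 2'/6''
                for s6 in (False, True):  # shared neighbor at 6'/2''
                    free_a = [] if a_is_pent else [3, 4, 5]
                    free_b = [] if b_is_pent else [3, 4, 5]
                    for ka in range(2 ** len(free_a)):
                        for kb in range(2 ** len(free_b)):
                            pos_a = set()
                            pos_b = set()
                            if b_is_pent:
                                pos_a.add(1)
                            if a_is_pent:
                                pos_b.add(1)
                            if s2:
                                pos_a.add(2)
                                pos_b.add(6)
                            if s6:
                                pos_a.add(6)
                                pos_b.add(2)
                            for m, slot in enumerate(free_a):
                                if ka >> m & 1:
                                    pos_a.add(slot)
                            for m, slot in enumerate(free_b):
                                if kb >> m & 1:
                                    pos_b.add(slot)
                            pa, pb = frozenset(pos_a), frozenset(pos_b)
                            grp, sub = classify_from_positions(pa, pb, 1)
                            out.append((pa, pb, grp, sub))
    return out
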