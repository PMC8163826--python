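"""Ground-truth lattice generators and density simulation.

The generators emulate the morphologies a pleomorphic retroviral
capsid-protein assembly adopts in vitro: regular tubes (hexamers only),
T=1 and T=3 icosahedra, and closed fullerene-type polyhedrons (hexamer
bodies closed by exactly 12 pentamers, as any closed hexagonal surface
must be).  Each generator returns a :class:`LatticeGraph` whose unit
positions are in Angstrom (``voxel_size == 1``); rendering converts to
voxel coordinates and emits the matching ground-truth table.

Default unit spacing is 80 A, the middle of the 60-110 A neighbor-spacing
regime accepted by the connectivity criteria.  Density is a sum of
Gaussian pseudo-atom templates; acquisition is emulated by a binary
missing-wedge mask in Fourier space (default +/-60 degrees about x) and
additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft

from .geometry import (
    EulerTriplet,
    UnitAnnotation,
    euler_from_normal,
    pair_geometry,
    rotation_from_euler,
    signed_inplane_angle,
)
from .io_formats import DensityVolume

__all__ = [
    "LatticeGraph",
    "UnitTemplate",
    "WedgeSpec",
    "default_templates",
    "build_tube",
    "build_icosahedron",
    "build_polyhedron",
    "render_density",
    "render_unit_template",
    "mesh_faces",
    "mesh_vertex_normals",
    "wedge_mask",
    "apply_missing_wedge",
    "add_noise",
]

DEFAULT_SPACING = 80.0


# ---------------------------------------------------------------------------
# graph container

@dataclass
class LatticeGraph:
    """Units plus validated neighbor edges; the connectivity network."""

    units: list[UnitAnnotation]
    edges: list[tuple[int, int]]
    closed: bool = False
    voxel_size: float = 1.0
    spacing: float = DEFAULT_SPACING
    network_id: int = 0

    def __post_init__(self):
        n = len(self.units)
        for i, j in self.edges:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) references missing unit")
        for k, u in enumerate(self.units):
            u.unit_id = k

    def __len__(self) -> int:
        return len(self.units)

    @property
    def pentamer_count(self) -> int:
        return sum(u.is_pentamer for u in self.units)

    @property
    def hexamer_count(self) -> int:
        return sum(not u.is_pentamer for u in self.units)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.edges:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)

    def edge_geometry(self, edge: tuple[int, int]):
        i, j = edge
        return pair_geometry(self.units[i], self.units[j], self.voxel_size)

    def positions(self) -> np.ndarray:
        return np.array([u.position for u in self.units])


def mesh_faces(points: np.ndarray, edges: list[tuple[int, int]]
               ) -> list[tuple[int, int, int]]:
    """Triangular faces of a closed triangulated surface (3-cliques)."""
    nbrs = {i: set() for i in range(len(points))}
    for i, j in edges:
        nbrs[i].add(j)
        nbrs[j].add(i)
    faces = []
    for i, j in edges:
        for k in nbrs[i] & nbrs[j]:
            if k > j > i:
                faces.append((i, j, k))
    return faces


def mesh_vertex_normals(points: np.ndarray, edges: list[tuple[int, int]]
                        ) -> np.ndarray:
    """Outward vertex normals: area-weighted incident-face normals."""
    centroid = points.mean(axis=0)
    normals = np.zeros_like(points)
    for f in mesh_faces(points, edges):
        a, b, c = points[list(f)]
        n = np.cross(b - a, c - a)  # length = 2 * area
        if np.dot(n, (a + b + c) / 3.0 - centroid) < 0:
            n = -n
        for v in f:
            normals[v] += n
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("degenerate vertex normal; mesh is not a closed surface")
    return normals / norms


def _edges_by_cutoff(points: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    from scipy.spatial import cKDTree

    tree = cKDTree(points)
    return sorted(tuple(sorted(p)) for p in tree.query_pairs(cutoff))


def _assign_units(points, normals, unit_types, x_ref=None) -> list[UnitAnnotation]:
    """Build UnitAnnotations with outward normals and a tangent in-plane axis."""
    units = []
    for k, (p, n, t) in enumerate(zip(points, normals, unit_types)):
        n = n / np.linalg.norm(n)
        e0 = euler_from_normal(n, 0.0)
        # choose psi so the unit-local x axis points along a tangent
        # reference direction (deterministic, geometry-derived)
        ref = np.array([0.0, 0.0, 1.0]) if x_ref is None else x_ref(k)
        x0 = rotation_from_euler(e0) @ np.array([1.0, 0.0, 0.0])
        try:
            psi = signed_inplane_angle(x0, ref, n)
        except ValueError:
            psi = 0.0
        units.append(
            UnitAnnotation(position=np.array(p, dtype=float),
                           euler=EulerTriplet(e0.phi, e0.theta, psi),
                           cc=1.0, unit_type=t, unit_id=k)
        )
    return units


# ---------------------------------------------------------------------------
# tube

def build_tube(n_around: int = 12, n_rings: int = 10,
               spacing: float = DEFAULT_SPACING) -> LatticeGraph:
    """Hexagonal lattice rolled on a cylinder along z; hexamers only.

    Rings of ``n_around`` units, consecutive rings offset by half a step
    (triangular packing), axial pitch spacing*sqrt(3)/2.  Normals point
    radially outward; the unit-local x axis points along the tube axis.
    """
    if n_around < 6:
        raise ValueError("n_around must be >= 6")
    if n_rings < 3:
        raise ValueError("n_rings must be >= 3")
    if not (60.0 <= spacing <= 110.0):
        raise ValueError("spacing must be in the 60-110 A regime")
    r = n_around * spacing / (2.0 * np.pi)
    dz = spacing * np.sqrt(3.0) / 2.0
    dphi = 2.0 * np.pi / n_around
    pts, normals = [], []
    for k in range(n_rings):
        for j in range(n_around):
            phi = (j + 0.5 * (k % 2)) * dphi
            pts.append([r * np.cos(phi), r * np.sin(phi), k * dz])
            normals.append([np.cos(phi), np.sin(phi), 0.0])
    pts = np.array(pts)
    normals = np.array(normals)
    units = _assign_units(pts, normals, ["hexamer_C2"] * len(pts))
    edges = _edges_by_cutoff(pts, 1.3 * spacing)
    return LatticeGraph(units, edges, closed=False, spacing=spacing)


# ---------------------------------------------------------------------------
# icosahedra

_GOLD = (1.0 + np.sqrt(5.0)) / 2.0


def _icosahedron_vertices() -> np.ndarray:
    v = []
    for a in (-1.0, 1.0):
        for b in (-_GOLD, _GOLD):
            v += [[0, a, b], [a, b, 0], [b, 0, a]]
    v = np.array(v)
    return v / np.linalg.norm(v[0])


def _icosahedron_faces(verts: np.ndarray) -> list[tuple[int, int, int]]:
    # faces = triples of mutually adjacent vertices (edge = shortest distance)
    d = np.linalg.norm(verts[:, None] - verts[None, :], axis=-1)
    edge = d[d > 1e-6].min()
    adj = (d < edge * 1.1) & (d > 1e-6)
    faces = []
    n = len(verts)
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i, j]:
                continue
            for k in range(j + 1, n):
                if adj[i, k] and adj[j, k]:
                    faces.append((i, j, k))
    return faces


def build_icosahedron(T: int = 1, spacing: float = DEFAULT_SPACING) -> LatticeGraph:
    """Caspar-Klug icosahedral lattice: T=1 (12 pentamers) or T=3 (+20 hexamers).

    T=1 places pentamers at the icosahedron vertices; T=3 adds hexamers at
    the face centers (soccer-ball arrangement), all on a common sphere
    scaled so the hexamer-hexamer separation equals ``spacing``.
    """
    if T not in (1, 3):
        raise ValueError("only T=1 and T=3 lattices are supported")
    verts = _icosahedron_vertices()
    if T == 1:
        edge_chord = np.linalg.norm(verts[:, None] - verts[None, :], axis=-1)
        edge_chord = edge_chord[edge_chord > 1e-6].min()  # ~1.0515 R
        R = spacing / edge_chord
        pts = verts * R
        types = ["pentamer_C5"] * 12
    else:
        faces = _icosahedron_faces(verts)
        centers = np.array([verts[list(f)].mean(axis=0) for f in faces])
        centers /= np.linalg.norm(centers, axis=1, keepdims=True)
        # hexamer-hexamer chord (adjacent face centers) for unit sphere
        dc = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        hh = dc[dc > 1e-6].min()  # ~0.7136
        R = spacing / hh
        pts = np.vstack([verts, centers]) * R
        types = ["pentamer_C5"] * 12 + ["hexamer_C6"] * 20
    normals = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    units = _assign_units(pts, normals, types)
    edges = _edges_by_cutoff(pts, 1.15 * spacing)
    return LatticeGraph(units, edges, closed=True, spacing=spacing)


# ---------------------------------------------------------------------------
# random closed polyhedron (capped-tube fullerene)

def build_polyhedron(n_units: int = 42, elongation: float = 0.0,
                     seed: int = 0,
                     spacing: float = DEFAULT_SPACING) -> LatticeGraph:
    """Closed fullerene-type polyhedron: tube body capped by two 6-pentamer caps.

    The body is a stack of 10-unit rings; each cap is an apex pentamer plus
    a 5-hexamer ring, leaving 5 pentamers alternating in the boundary body
    ring (the classic capped-armchair-nanotube combinatorics).  Exactly 12
    pentamers always; achievable sizes are 32, 42, 52, ... units, and
    ``n_units`` is rounded to the nearest one.  ``seed`` fixes the ring
    twists and a small positional jitter; ``elongation`` stretches the
    body pitch (fraction, clipped to keep edges within the lattice regime).
    """
    if n_units < 12:
        raise ValueError("n_units must be >= 12")
    rng = np.random.default_rng(seed)
    m = max(2, round((n_units - 12) / 10))  # number of 10-unit body rings
    elong = float(np.clip(elongation, -0.15, 0.25))

    r10 = spacing / (2.0 * np.sin(np.pi / 10.0))     # body ring radius
    h = 0.863 * spacing * (1.0 + elong)              # body ring pitch
    rho = 1.8 * spacing                              # cap sphere radius
    theta0 = np.arcsin(min(r10 / rho, 1.0))          # polar angle of body ring
    theta5 = theta0 - spacing / rho                  # polar angle of hexamer ring
    z_top = (m - 1) * h / 2.0
    z_bot = -z_top

    pts, types, ring_index = [], [], []
    # body rings, top to bottom; ring k twisted by k*18 deg + jitter
    twists = [np.deg2rad(18.0 * k) + rng.uniform(-0.06, 0.06) for k in range(m)]
    base_twist = rng.uniform(0.0, 2.0 * np.pi)
    ring_ids = []
    for k in range(m):
        ids = []
        for j in range(10):
            phi = base_twist + twists[k] + j * np.pi / 5.0
            pts.append([r10 * np.cos(phi), r10 * np.sin(phi), z_top - k * h])
            # boundary rings carry 5 alternating pentamers at odd slots
            if (k == 0 or k == m - 1) and j % 2 == 1:
                types.append("pentamer_C5")
            else:
                types.append("hexamer_C6")
            ids.append(len(pts) - 1)
        ring_ids.append(ids)

    def add_cap(ring, z_ring, sign):
        """sign=+1: cap above ring; returns (ring5 ids, apex id)."""
        zc = z_ring - sign * rho * np.cos(theta0)
        r5 = rho * np.sin(theta5)
        z5 = zc + sign * rho * np.cos(theta5)
        ids5 = []
        for i in range(5):
            # hexamer above each odd (pentamer) slot of the boundary ring
            p = pts[ring[2 * i + 1]]
            phi = np.arctan2(p[1], p[0])
            pts.append([r5 * np.cos(phi), r5 * np.sin(phi), z5])
            types.append("hexamer_C6")
            ids5.append(len(pts) - 1)
        pts.append([0.0, 0.0, zc + sign * rho])
        types.append("pentamer_C5")
        return ids5, len(pts) - 1

    top5, top_apex = add_cap(ring_ids[0], z_top, +1)
    bot5, bot_apex = add_cap(ring_ids[-1], z_bot, -1)

    # explicit edge list (combinatorics fixed by construction)
    edges = set()

    def add(i, j):
        edges.add((min(i, j), max(i, j)))

    for k in range(m):
        ids = ring_ids[k]
        for j in range(10):
            add(ids[j], ids[(j + 1) % 10])
        if k + 1 < m:
            nxt = ring_ids[k + 1]
            # connect to the two angularly nearest of the next ring
            for j in range(10):
                p = pts[ids[j]]
                phi = np.arctan2(p[1], p[0])
                angdiff = []
                for jj in range(10):
                    q = pts[nxt[jj]]
                    d = np.arctan2(q[1], q[0]) - phi
                    angdiff.append((abs((d + np.pi) % (2 * np.pi) - np.pi), jj))
                for _, jj in sorted(angdiff)[:2]:
                    add(ids[j], nxt[jj])
    for ids5, apex, ring in ((top5, top_apex, ring_ids[0]),
                             (bot5, bot_apex, ring_ids[-1])):
        for i in range(5):
            add(ids5[i], ids5[(i + 1) % 5])
            add(ids5[i], apex)
            # three consecutive boundary-ring units under each cap hexamer
            add(ids5[i], ring[2 * i])
            add(ids5[i], ring[2 * i + 1])
            add(ids5[i], ring[(2 * i + 2) % 10])

    pts = np.array(pts)
    # small jitter, kept well inside the connectivity tolerances
    pts = pts + rng.normal(0.0, 0.015 * spacing, size=pts.shape)

    normals = mesh_vertex_normals(pts, sorted(edges))

    units = _assign_units(pts, normals, types)
    return LatticeGraph(units, sorted(edges), closed=True, spacing=spacing)


# ---------------------------------------------------------------------------
# templates and rendering

@dataclass
class UnitTemplate:
    """Coarse Gaussian pseudo-atom footprint of a hexamer or pentamer."""

    points: np.ndarray        # (n, 3) A, unit-local frame, normal = +z
    weights: np.ndarray
    sigma: float              # Gaussian width, A
    symmetry: str             # C2 / C5 / C6
    name: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.points) != len(self.weights):
            raise ValueError("points/weights length mismatch")

    @property
    def order(self) -> int:
        return int(self.symmetry[1:])

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.points, axis=1).max() + 3 * self.sigma)

    def check_symmetry(self, tol: float = 1e-6) -> bool:
        """The point set maps onto itself under rotation by 360/n about z."""
        ang = 2 * np.pi / self.order
        c, s = np.cos(ang), np.sin(ang)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
        rotated = self.points @ R.T
        for p, w in zip(rotated, self.weights):
            d = np.linalg.norm(self.points - p, axis=1)
            k = int(np.argmin(d))
            if d[k] > tol or abs(self.weights[k] - w) > tol:
                return False
        return True


def _ring(n: int, radius: float) -> np.ndarray:
    ang = 2 * np.pi * np.arange(n) / n
    return np.stack([radius * np.cos(ang), radius * np.sin(ang),
                     np.zeros(n)], axis=1)


def default_templates(sigma: float = 7.0) -> dict[str, UnitTemplate]:
    """Blob templates emulating hexamer/pentamer footprints.

    Each unit is an outer ring of C-terminal-domain-like blobs plus an
    inner ring of weaker N-terminal-domain-like blobs (the inner density
    distinguishes a unit center from the empty three-fold holes of the
    blob honeycomb).  The C2 hexamer carries a two-fold weight modulation.
    """
    def two_rings(n, r_out, r_in, w_out, z_in=12.0):
        inner = _ring(n, r_in) @ _rotz(180.0 / n)
        inner[:, 2] = z_in  # polar unit: inner lobes sit above the base ring
        pts = np.vstack([_ring(n, r_out), inner])
        w = np.concatenate([w_out, 0.5 * np.ones(n)])
        return pts, w

    w6 = np.ones(6)
    w2 = np.array([1.4, 0.8, 0.8, 1.4, 0.8, 0.8])
    p6, v6 = two_rings(6, 30.0, 13.0, w6)
    p2, v2 = two_rings(6, 30.0, 13.0, w2)
    p5, v5 = two_rings(5, 24.0, 10.0, np.ones(5))
    return {
        "hexamer_C6": UnitTemplate(p6, v6, sigma, "C6", "hexamer_C6"),
        "hexamer_C2": UnitTemplate(p2, v2, sigma, "C2", "hexamer_C2"),
        "pentamer_C5": UnitTemplate(p5, v5, sigma, "C5", "pentamer_C5"),
    }


def _rotz(deg: float) -> np.ndarray:
    a = np.deg2rad(deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, s, 0], [-s, c, 0], [0, 0, 1]])


def render_unit_template(tmpl: UnitTemplate, voxel_size: float,
                         box: int) -> DensityVolume:
    """Render a single template, identity pose, centered in a cubic box."""
    grid = np.zeros((box, box, box), dtype=np.float32)
    center = np.full(3, (box - 1) / 2.0)
    _splat(grid, tmpl.points / voxel_size + center, tmpl.weights,
           tmpl.sigma / voxel_size)
    return DensityVolume(grid, voxel_size)


def _splat(grid: np.ndarray, centers_vox: np.ndarray, weights: np.ndarray,
           sigma_vox: float) -> None:
    r = int(np.ceil(3.5 * sigma_vox))
    shape = grid.shape
    for c, w in zip(centers_vox, weights):
        lo = np.maximum(np.floor(c).astype(int) - r, 0)
        hi = np.minimum(np.floor(c).astype(int) + r + 1, shape)
        if np.any(lo >= hi):
            continue
        xs = [np.arange(lo[d], hi[d]) for d in range(3)]
        dx = [(x - c[d]) ** 2 for d, x in enumerate(xs)]
        g = np.exp(-(dx[0][:, None, None] + dx[1][None, :, None]
                     + dx[2][None, None, :]) / (2 * sigma_vox ** 2))
        grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += (w * g).astype(grid.dtype)


def render_density(g: LatticeGraph, voxel_size: float, box,
                   templates: dict[str, UnitTemplate] | None = None,
                   ) -> tuple[DensityVolume, LatticeGraph]:
    """Render a lattice (positions in A) into a density volume.

    Returns the volume and a copy of the graph with unit positions in the
    volume's voxel coordinates (the ground truth for the rendered scene).
    """
    if templates is None:
        templates = default_templates()
    box = np.array([box] * 3 if np.isscalar(box) else box, dtype=int)
    pts = g.positions() * g.voxel_size  # A
    centroid = pts.mean(axis=0)
    box_center = (box - 1) / 2.0
    margin = max(t.radius for t in templates.values())
    extent = np.abs(pts - centroid).max(axis=0) + margin
    room = box_center * voxel_size
    if np.any(extent > room):
        over = extent - room
        raise ValueError(
            f"lattice exceeds box by {np.maximum(over, 0).round(1)} A per axis"
        )
    grid = np.zeros(tuple(box), dtype=np.float32)
    truth_units = []
    for u in g.units:
        tmpl = templates[u.unit_type]
        R = u.rotation
        world = (u.position * g.voxel_size - centroid) + (tmpl.points @ R.T)
        _splat(grid, world / voxel_size + box_center, tmpl.weights,
               tmpl.sigma / voxel_size)
        v = u.copy()
        v.position = (u.position * g.voxel_size - centroid) / voxel_size + box_center
        truth_units.append(v)
    truth = LatticeGraph(truth_units, list(g.edges), closed=g.closed,
                         voxel_size=voxel_size, spacing=g.spacing)
    return DensityVolume(grid, voxel_size), truth


# ---------------------------------------------------------------------------
# acquisition model

@dataclass(frozen=True)
class WedgeSpec:
    """Single-axis tilt geometry: covered tilt range about ``tilt_axis``."""

    tilt_axis: str = "x"
    min_angle: float = -60.0
    max_angle: float = 60.0

    def __post_init__(self):
        if self.tilt_axis not in ("x", "y", "z"):
            raise ValueError("tilt_axis must be x, y or z")
        if not self.min_angle < self.max_angle:
            raise ValueError("min_angle must be < max_angle")


def wedge_mask(shape, w: WedgeSpec, rfft: bool = True) -> np.ndarray:
    """Boolean Fourier mask of the sampled region (True = acquired).

    A voxel k is sampled iff some tilt t in the covered range satisfies
    k . beam(t) = 0, with the beam rotating about the tilt axis from the
    z direction; equivalently arctan(k_b / k_a) lies in the range, where
    (a, b) are the in-plane-of-rotation axes.
    """
    axes = {"x": (1, 2), "y": (0, 2), "z": (0, 1)}[w.tilt_axis]
    freqs = []
    for d in range(3):
        if d == 2 and rfft:
            freqs.append(np.fft.rfftfreq(shape[2]))
        else:
            freqs.append(np.fft.fftfreq(shape[d]))
    ka = freqs[axes[0]]
    kb = freqs[axes[1]]
    sh = [1, 1, 1]
    sh[axes[0]] = -1
    a = ka.reshape(sh)
    sh = [1, 1, 1]
    sh[axes[1]] = -1
    b = kb.reshape(sh)
    t = np.rad2deg(np.arctan2(b, a))  # tilt angle solving the plane condition
    keep = np.zeros(np.broadcast(a, b).shape, dtype=bool)
    for off in (-180.0, 0.0, 180.0):  # beam directions t and t+180 coincide
        keep |= (t + off >= w.min_angle) & (t + off <= w.max_angle)
    keep = keep | ((np.abs(a) < 1e-12) & (np.abs(b) < 1e-12))
    full = np.zeros([s if (d != 2 or not rfft) else len(freqs[2])
                     for d, s in enumerate(shape)], dtype=bool)
    full |= keep
    return full


def apply_missing_wedge(vol: DensityVolume, w: WedgeSpec) -> DensityVolume:
    """Zero Fourier coefficients outside the sampled wedge (idempotent)."""
    ft = scipy.fft.rfftn(vol.grid.astype(np.float32))
    ft *= wedge_mask(vol.grid.shape, w, rfft=True)
    out = scipy.fft.irfftn(ft, s=vol.grid.shape).astype(np.float32)
    return DensityVolume(out, vol.voxel_size, vol.origin)


def add_noise(vol: DensityVolume, sigma: float, seed: int = 0) -> DensityVolume:
    """Additive white Gaussian noise, reproducible per seed."""
    rng = np.random.default_rng(seed)
    noisy = vol.grid + rng.normal(0.0, sigma, size=vol.grid.shape)
    return DensityVolume(noisy.astype(np.float32), vol.voxel_size, vol.origin)
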