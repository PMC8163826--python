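"""Consensus alignment of lattice units from neighbor-specific measurements.

Instead of refining each hexamer/pentamer in isolation, every unit is
aligned once per direct neighbor (masking the central unit and that one
neighbor), yielding N position/orientation measurements with correlation
scores.  The consensus position is the cc-weighted mean of the measured
positions

    (X, Y, Z) = sum_i cc_i (x_i, y_i, z_i) / sum_i cc_i

and the consensus orientation is the cc-weighted, renormalized sum of the
measured normal vectors

    n = sum_i cc_i n_i / | sum_i cc_i n_i |.

The normal fixes only two of three rotational degrees of freedom; the
in-plane angle is combined as a cc-weighted circular mean after parallel
transport of each measured frame onto the consensus normal (a switch
selects carrying the best single measurement's in-plane angle instead).

Class-geometry optimization then nudges unit poses to reduce the z-scored
deviation of each pair's tilt/twist/distance from its class mean, by a
greedy pattern search that only ever accepts improving steps (the
objective is non-increasing by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .geometry import (
    EulerTriplet,
    UnitAnnotation,
    _transport_rotation,
    euler_from_normal,
    normal_from_euler,
    rotation_from_euler,
    signed_inplane_angle,
)
from .io_formats import DensityVolume
from .synthetic import LatticeGraph, UnitTemplate, default_templates, _splat
from .classify import PairContext, classify_pairs

__all__ = [
    "ConsensusMeasurement",
    "consensus_schedule",
    "ConsensusResult",
    "ClassGeometryStats",
    "consensus_position",
    "consensus_orientation",
    "consensus_unit",
    "align_unit_pair",
    "consensus_pass",
    "compute_class_geometry",
    "optimize_class_geometry",
    "interface_refinement",
    "simulate_consensus_recovery",
]


@dataclass
class ConsensusMeasurement:
    """One neighbor-specific alignment result."""

    position: np.ndarray       # voxels
    euler: EulerTriplet
    cc: float
    flagged: bool = False

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not np.isfinite(self.cc):
            raise ValueError("cc must be finite")

    @property
    def normal(self) -> np.ndarray:
        return normal_from_euler(self.euler)


@dataclass
class ConsensusResult:
    position: np.ndarray
    normal: np.ndarray
    in_plane: float            # degrees
    n_measurements: int

    @property
    def euler(self) -> EulerTriplet:
        e0 = euler_from_normal(self.normal, 0.0)
        x0 = rotation_from_euler(e0) @ np.array([1.0, 0.0, 0.0])
        # in_plane is measured from the zero-psi frame's x axis
        return EulerTriplet(e0.phi, e0.theta, self.in_plane)


def _positive_cc(ms: list[ConsensusMeasurement]) -> list[ConsensusMeasurement]:
    return [m for m in ms if m.cc > 0]


def consensus_position(ms: list[ConsensusMeasurement]) -> np.ndarray:
    """cc-weighted mean of measured positions; cc <= 0 measurements dropped."""
    kept = _positive_cc(ms)
    if not kept:
        raise ValueError("no measurements with positive cc")
    w = np.array([m.cc for m in kept])
    P = np.array([m.position for m in kept])
    return (w[:, None] * P).sum(axis=0) / w.sum()


def consensus_orientation(ms: list[ConsensusMeasurement],
                          inplane: str = "weighted_circular",
                          ) -> tuple[np.ndarray, float]:
    """cc-weighted normal-vector consensus plus in-plane angle.

    ``inplane``: "weighted_circular" (default) combines in-plane angles by
    a cc-weighted circular mean after transporting each measured frame
    onto the consensus normal; "best" carries the highest-cc measurement's
    in-plane angle.
    """
    kept = _positive_cc(ms)
    if not kept:
        raise ValueError("no measurements with positive cc")
    w = np.array([m.cc for m in kept])
    N = np.array([m.normal for m in kept])
    resultant = (w[:, None] * N).sum(axis=0)
    norm = np.linalg.norm(resultant)
    if norm < 1e-9 * w.sum():
        raise ValueError("degenerate consensus: normal resultant vanishes")
    nbar = resultant / norm
    e0 = euler_from_normal(nbar, 0.0)
    x0 = rotation_from_euler(e0) @ np.array([1.0, 0.0, 0.0])
    angles = []
    for m in kept:
        t = _transport_rotation(m.normal, nbar)
        xm = t @ (rotation_from_euler(m.euler) @ np.array([1.0, 0.0, 0.0]))
        angles.append(signed_inplane_angle(x0, xm, nbar))
    angles = np.deg2rad(np.array(angles))
    if inplane == "best":
        psi = float(np.rad2deg(angles[int(np.argmax(w))]))
    elif inplane == "weighted_circular":
        s = (w * np.sin(angles)).sum()
        c = (w * np.cos(angles)).sum()
        psi = float(np.rad2deg(np.arctan2(s, c)))
    else:
        raise ValueError(f"unknown inplane mode {inplane!r}")
    return nbar, psi % 360.0


def consensus_unit(ms: list[ConsensusMeasurement],
                   inplane: str = "weighted_circular") -> ConsensusResult:
    pos = consensus_position(ms)
    nbar, psi = consensus_orientation(ms, inplane)
    return ConsensusResult(position=pos, normal=nbar, in_plane=psi,
                           n_measurements=len(_positive_cc(ms)))


# ---------------------------------------------------------------------------
# volume-based pair alignment

def _extract_cube(vol: DensityVolume, center_vox: np.ndarray, box: int
                  ) -> np.ndarray | None:
    c = np.round(center_vox).astype(int)
    half = box // 2
    lo = c - half
    hi = lo + box
    if np.any(lo < 0) or np.any(hi > np.array(vol.grid.shape)):
        return None
    return vol.grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].astype(np.float64)


def _soft_sphere(box: int, center: np.ndarray, radius: float,
                 soft: float = 2.0) -> np.ndarray:
    ax = [np.arange(box) - c for c in center]
    r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2)
    return 1.0 / (1.0 + np.exp((r - radius) / soft))


def _small_rotations(max_deg: float, step_deg: float) -> list[np.ndarray]:
    """Deterministic net of small rotations (rotation-vector grid)."""
    vals = np.arange(-max_deg, max_deg + 1e-9, step_deg)
    out = []
    for ax in np.deg2rad(vals):
        for ay in np.deg2rad(vals):
            for az in np.deg2rad(vals):
                out.append(Rotation.from_rotvec([ax, ay, az]).as_matrix())
    return out


def render_pair_reference(unit: UnitAnnotation, neighbor: UnitAnnotation,
                          voxel_size: float, box: int,
                          templates: dict[str, UnitTemplate] | None = None,
                          rel_override: np.ndarray | None = None,
                          ) -> tuple[DensityVolume, np.ndarray]:
    """Render the expected pair density in the unit's canonical frame.

    The central unit sits at the box center with identity orientation; the
    neighbor is placed at the current relative position (rotated into the
    unit frame), with its relative orientation preserved.  Returns the
    reference volume and the canonical-frame neighbor offset (voxels).
    """
    if templates is None:
        templates = default_templates()
    Ra = unit.rotation
    rel = (neighbor.position - unit.position) if rel_override is None \
        else np.asarray(rel_override, dtype=float)
    rel_canon = Ra.T @ rel  # voxels, canonical frame
    Rb_canon = Ra.T @ neighbor.rotation
    grid = np.zeros((box, box, box), dtype=np.float32)
    bc = np.full(3, box // 2, dtype=float)
    ta = templates[unit.unit_type]
    tb = templates[neighbor.unit_type]
    _splat(grid, ta.points / voxel_size + bc, ta.weights,
           ta.sigma / voxel_size)
    _splat(grid, (tb.points @ Rb_canon.T) / voxel_size + bc + rel_canon,
           tb.weights, tb.sigma / voxel_size)
    return DensityVolume(grid, voxel_size), rel_canon


def align_unit_pair(vol: DensityVolume, unit: UnitAnnotation,
                    neighbor: UnitAnnotation,
                    reference: DensityVolume | None = None,
                    box: int = 33,
                    trans_range: float = 4.0,
                    rot_range: float = 8.0,
                    rot_step: float = 4.0,
                    mask_radius: float | None = None,
                    min_cc: float = 0.1,
                    templates: dict[str, UnitTemplate] | None = None,
                    ) -> ConsensusMeasurement:
    """Refine one unit's pose against a two-unit masked reference.

    Searches a bounded net of rotations about the current pose crossed
    with translations (FFT correlation, parabolic sub-voxel refinement),
    maximizing masked normalized correlation.  If no candidate exceeds
    ``min_cc`` the input pose is returned flagged.
    """
    box |= 1  # odd box: integer center
    if reference is None:
        reference, rel_canon = render_pair_reference(
            unit, neighbor, vol.voxel_size, box, templates)
    else:
        rel_canon = unit.rotation.T @ (neighbor.position - unit.position)
    sub = _extract_cube(vol, unit.position, box)
    if sub is None:
        return ConsensusMeasurement(unit.position.copy(), unit.euler,
                                    cc=0.0, flagged=True)
    c0 = np.round(unit.position).astype(float)
    bc = np.full(3, box // 2, dtype=float)
    if mask_radius is None:
        mask_radius = 0.45 * np.linalg.norm(rel_canon) + 30.0 / vol.voxel_size
    ref_grid = reference.grid.astype(np.float64)

    best = (-2.0, None, None)  # cc, shift, rotation
    R_center = unit.rotation
    stages = [(rot_range, rot_step), (rot_step, rot_step / 2.0)]
    for stage_range, stage_step in stages:
        best = _search_rotations(
            sub, ref_grid, rel_canon, R_center, stage_range, stage_step,
            box, bc, mask_radius, trans_range, best)
        if best[2] is not None:
            R_center = best[2]
    cc_val, shift, R_c = best
    if R_c is None or cc_val < min_cc:
        return ConsensusMeasurement(unit.position.copy(), unit.euler,
                                    cc=max(cc_val, 0.0), flagged=True)
    from .geometry import euler_from_rotation

    return ConsensusMeasurement(position=c0 + shift,
                                euler=euler_from_rotation(R_c),
                                cc=cc_val, flagged=False)


def _search_rotations(sub, ref_grid, rel_canon, R_center, rot_range,
                      rot_step, box, bc, mask_radius, trans_range, best):
    for dR in _small_rotations(rot_range, rot_step):
        R_c = R_center @ dR
        # reference and mask in the volume frame under candidate pose
        M = _rotmat_resample(ref_grid, R_c)
        nb_off = R_c @ rel_canon
        mask = _soft_sphere(box, bc, mask_radius) \
            + _soft_sphere(box, bc + nb_off, mask_radius)
        mask = np.clip(mask, 0.0, 1.0)
        r = (M - M[mask > 0.5].mean()) * mask
        rn = np.sqrt((r ** 2).sum())
        if rn < 1e-12:
            continue
        s = (sub - sub[mask > 0.5].mean()) * mask
        sn = np.sqrt((s ** 2).sum())
        if sn < 1e-12:
            continue
        cc3 = scipy.fft.irfftn(
            scipy.fft.rfftn(s) * np.conj(scipy.fft.rfftn(r)),
            s=s.shape) / (rn * sn)
        cc3 = np.fft.fftshift(cc3)
        half = box // 2
        t = min(int(np.ceil(trans_range)), half - 1)
        win = cc3[half - t:half + t + 1, half - t:half + t + 1,
                  half - t:half + t + 1]
        k = np.unravel_index(np.argmax(win), win.shape)
        cc_val = float(win[k])
        shift = np.array(k, dtype=float) - t
        shift += _parabolic_offset(win, k)
        if cc_val > best[0]:
            best = (cc_val, shift, R_c)
    return best


def _rotmat_resample(grid: np.ndarray, R: np.ndarray) -> np.ndarray:
    c = (np.array(grid.shape) - 1) / 2.0
    Rinv = R.T
    return ndimage.affine_transform(grid, Rinv, offset=c - Rinv @ c,
                                    order=1, mode="constant", cval=0.0)


def _parabolic_offset(win: np.ndarray, k: tuple) -> np.ndarray:
    out = np.zeros(3)
    for d in range(3):
        i = k[d]
        if 0 < i < win.shape[d] - 1:
            idx = list(k)
            idx[d] = i - 1
            lo = win[tuple(idx)]
            idx[d] = i + 1
            hi = win[tuple(idx)]
            denom = 2 * win[k] - lo - hi
            if abs(denom) > 1e-12:
                out[d] = np.clip(0.5 * (hi - lo) / denom, -0.5, 0.5)
    return out


def consensus_pass(g: LatticeGraph, vol: DensityVolume,
                   templates: dict[str, UnitTemplate] | None = None,
                   inplane: str = "weighted_circular",
                   **align_kw) -> LatticeGraph:
    """One round of per-neighbor alignment + consensus for every unit.

    Each unit is aligned once per neighbor (masking the unit and that
    neighbor) and the measurements are combined with the consensus
    equations.  Units whose measurements are all flagged keep their pose.
    Returns a new graph; the input is not modified.
    """
    out_units = [u.copy() for u in g.units]
    for i, u in enumerate(g.units):
        ms = []
        for j in g.neighbors(i):
            m = align_unit_pair(vol, u, g.units[j], templates=templates,
                                **align_kw)
            if not m.flagged:
                ms.append(m)
        if not ms:
            continue
        try:
            res = consensus_unit(ms, inplane=inplane)
        except ValueError:
            continue
        out_units[i].position = res.position
        out_units[i].euler = res.euler
        out_units[i].cc = float(np.mean([m.cc for m in ms]))
    return LatticeGraph(out_units, list(g.edges), closed=g.closed,
                        voxel_size=g.voxel_size, spacing=g.spacing,
                        network_id=g.network_id)


def consensus_schedule(g: LatticeGraph, vol: DensityVolume,
                       schedule: list[tuple[int, int]] | None = None,
                       templates: dict[str, UnitTemplate] | None = None,
                       **align_kw) -> LatticeGraph:
    """Multi-round consensus alignment over a binning schedule.

    ``schedule`` is a list of (binning, n_passes); the default mirrors the
    coarse-to-fine discipline of four passes at bin 4, two at bin 2, and a
    final subclass-resolved pass at bin 2 (pair references are rendered
    from each pair's own context, so the final pass differs only in
    starting from the refined poses).  Volumes are binned by Fourier
    cropping; unit coordinates scale with the binning.
    """
    from .averaging import bin_volume

    if schedule is None:
        schedule = [(4, 4), (2, 2), (2, 1)]
    work = g
    for binning, n_passes in schedule:
        wvol = bin_volume(vol, binning) if binning > 1 else vol
        scale = 1.0 / binning
        scaled_units = []
        for u in work.units:
            v = u.copy()
            v.position = u.position * scale
            scaled_units.append(v)
        wg = LatticeGraph(scaled_units, list(work.edges), closed=work.closed,
                          voxel_size=work.voxel_size / scale,
                          spacing=work.spacing, network_id=work.network_id)
        for _ in range(n_passes):
            wg = consensus_pass(wg, wvol, templates=templates, **align_kw)
        out_units = []
        for u in wg.units:
            v = u.copy()
            v.position = u.position / scale
            out_units.append(v)
        work = LatticeGraph(out_units, list(work.edges), closed=work.closed,
                            voxel_size=work.voxel_size, spacing=work.spacing,
                            network_id=work.network_id)
    return work


# ---------------------------------------------------------------------------
# class geometry

@dataclass
class ClassGeometryStats:
    """Mean/std of tilt, twist, distance per (group, subclass) class."""

    stats: dict[tuple[int, int], dict[str, tuple[float, float]]]
    std_floor: dict[str, float] = field(default_factory=lambda: {
        "tilt": 0.5, "twist": 0.5, "distance": 0.5,
    })

    def z2(self, key: tuple[int, int], tilt: float, twist: float,
           distance: float) -> float:
        s = self.stats[key]
        tot = 0.0
        for name, q in (("tilt", tilt), ("twist", twist),
                        ("distance", distance)):
            mean, std = s[name]
            std = max(std, self.std_floor[name])
            tot += ((q - mean) / std) ** 2
        return tot


def compute_class_geometry(g: LatticeGraph,
                           contexts: list[PairContext] | None = None
                           ) -> ClassGeometryStats:
    """Per-class mean and std of pair tilt/twist/distance.

    std requires >= 2 members; singleton classes get std 0 (floored in the
    objective).
    """
    if contexts is None:
        contexts = classify_pairs(g)
    buckets: dict[tuple[int, int], list[tuple[float, float, float]]] = {}
    for pc in contexts:
        pg = g.edge_geometry(pc.edge)
        buckets.setdefault((pc.group, pc.subclass), []).append(
            (pg.tilt, pg.twist, pg.distance))
    stats = {}
    for key, rows in buckets.items():
        arr = np.array(rows)
        mean = arr.mean(axis=0)
        std = arr.std(axis=0, ddof=1) if len(rows) >= 2 else np.zeros(3)
        stats[key] = {
            "tilt": (float(mean[0]), float(std[0])),
            "twist": (float(mean[1]), float(std[1])),
            "distance": (float(mean[2]), float(std[2])),
        }
    return ClassGeometryStats(stats)


def _pair_objective(g: LatticeGraph, contexts, stats: ClassGeometryStats,
                    unit: int | None = None) -> float:
    tot = 0.0
    for pc in contexts:
        if unit is not None and unit not in pc.edge:
            continue
        pg = g.edge_geometry(pc.edge)
        tot += stats.z2((pc.group, pc.subclass), pg.tilt, pg.twist,
                        pg.distance)
    return tot


def optimize_class_geometry(g: LatticeGraph,
                            stats: ClassGeometryStats | None = None,
                            contexts: list[PairContext] | None = None,
                            n_iter: int = 3,
                            trans_step: float = 0.5,
                            rot_step: float = 2.0,
                            ) -> tuple[LatticeGraph, list[float]]:
    """Greedy pattern-search pose optimization toward class-mean geometry.

    Per unit, translations of +/- ``trans_step`` voxels along each axis and
    rotations of +/- ``rot_step`` degrees about each axis are trialled; a
    step is kept only if the summed z-scored deviation of that unit's
    pairs decreases, so the global objective is non-increasing.  Pairs at
    their class mean are fixed points.  Returns (new graph, per-iteration
    objective history including the initial value).
    """
    if contexts is None:
        contexts = classify_pairs(g)
    if stats is None:
        stats = compute_class_geometry(g, contexts)
    work = LatticeGraph([u.copy() for u in g.units], list(g.edges),
                        closed=g.closed, voxel_size=g.voxel_size,
                        spacing=g.spacing, network_id=g.network_id)
    history = [_pair_objective(work, contexts, stats)]
    axes = np.eye(3)
    for _ in range(n_iter):
        for i in range(len(work.units)):
            u = work.units[i]
            base = _pair_objective(work, contexts, stats, unit=i)
            if base < 1e-12:
                continue
            for ax in axes:
                for sgn in (+1.0, -1.0):
                    cand = u.position + sgn * trans_step * ax
                    old = u.position
                    u.position = cand
                    val = _pair_objective(work, contexts, stats, unit=i)
                    if val < base - 1e-12:
                        base = val
                    else:
                        u.position = old
            R0 = u.rotation
            from .geometry import euler_from_rotation

            for ax in axes:
                for sgn in (+1.0, -1.0):
                    dR = Rotation.from_rotvec(
                        np.deg2rad(sgn * rot_step) * ax).as_matrix()
                    old = u.euler
                    u.euler = euler_from_rotation(R0 @ dR)
                    val = _pair_objective(work, contexts, stats, unit=i)
                    if val < base - 1e-12:
                        base = val
                        R0 = u.rotation
                    else:
                        u.euler = old
        history.append(_pair_objective(work, contexts, stats))
    return work, history


# ---------------------------------------------------------------------------
# interface-centered class averages

def interface_refinement(g: LatticeGraph, vol: DensityVolume,
                         contexts: list[PairContext] | None = None,
                         box: int = 33, min_members: int = 3,
                         ) -> dict[tuple[int, int], DensityVolume]:
    """Average subtomograms re-extracted at pair midpoints, per class.

    Boxes are centered at the dimer interface and rotated into the pair
    frame (z = mean normal, x = A->B direction projected); classes with
    fewer than ``min_members`` pairs are skipped with a warning.
    """
    if contexts is None:
        contexts = classify_pairs(g)
    box |= 1
    by_class: dict[tuple[int, int], list[PairContext]] = {}
    for pc in contexts:
        by_class.setdefault((pc.group, pc.subclass), []).append(pc)
    out = {}
    for key, pcs in sorted(by_class.items()):
        if len(pcs) < min_members:
            warnings.warn(f"class {key}: only {len(pcs)} pairs, skipped")
            continue
        acc = np.zeros((box, box, box))
        n = 0
        for pc in pcs:
            a, b = pc.edge
            ua, ub = g.units[a], g.units[b]
            mid = 0.5 * (ua.position + ub.position)
            R = _pair_frame(ua, ub)
            cube = _extract_rotated_cube(vol, mid, R, box)
            if cube is None:
                continue
            acc += cube
            n += 1
        if n:
            out[key] = DensityVolume((acc / n).astype(np.float32),
                                     vol.voxel_size)
    return out


def _pair_frame(ua: UnitAnnotation, ub: UnitAnnotation) -> np.ndarray:
    """Rotation whose columns are the pair frame axes (x: A->B, z: mean n)."""
    z = ua.normal + ub.normal
    z /= np.linalg.norm(z)
    d = ub.position - ua.position
    x = d - np.dot(d, z) * z
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)


def _extract_rotated_cube(vol: DensityVolume, center: np.ndarray,
                          R: np.ndarray, box: int) -> np.ndarray | None:
    bc = np.full(3, box // 2, dtype=float)
    offset = center - R @ bc
    ext = np.abs(R).sum(axis=1) * (box // 2)
    if np.any(center - ext < -1) or np.any(center + ext
                                           > np.array(vol.grid.shape)):
        return None
    return ndimage.affine_transform(vol.grid.astype(np.float64), R,
                                    offset=offset, output_shape=(box,) * 3,
                                    order=1, mode="constant", cval=0.0)


# ---------------------------------------------------------------------------
# statistical recovery study

def simulate_consensus_recovery(g: LatticeGraph, sigma_pos: float = 1.5,
                                sigma_angle: float = 8.0,
                                n_trials: int = 50, seed: int = 0,
                                ) -> dict:
    """Monte-Carlo check of the 1/sqrt(N) error reduction of the consensus.

    Per trial and unit, each of the N neighbor-specific measurements is
    the true pose plus isotropic Gaussian noise (sigma_pos voxels per
    coordinate, sigma_angle degrees rotation magnitude), with equal cc.
    Reports the RMS consensus position error, the single-measurement RMS
    error, and the ratio to the 1/sqrt(N) expectation.
    """
    from .geometry import euler_from_rotation

    rng = np.random.default_rng(seed)
    errs, single_errs, expected = [], [], []
    for _ in range(n_trials):
        for i, u in enumerate(g.units):
            nbrs = g.neighbors(i)
            N = len(nbrs)
            if N == 0:
                continue
            ms = []
            for _j in range(N):
                dpos = rng.normal(0.0, sigma_pos, size=3)
                rv = rng.normal(0.0, np.deg2rad(sigma_angle), size=3)
                R = Rotation.from_rotvec(rv).as_matrix() @ u.rotation
                ms.append(ConsensusMeasurement(u.position + dpos,
                                               euler_from_rotation(R),
                                               cc=1.0))
            res = consensus_unit(ms)
            errs.append(np.linalg.norm(res.position - u.position) ** 2)
            single_errs.append(
                np.linalg.norm(ms[0].position - u.position) ** 2)
            expected.append(3.0 * sigma_pos ** 2 / N)
    rms = float(np.sqrt(np.mean(errs)))
    rms_single = float(np.sqrt(np.mean(single_errs)))
    rms_expected = float(np.sqrt(np.mean(expected)))
    return {
        "rms_consensus": rms,
        "rms_single": rms_single,
        "rms_expected": rms_expected,
        "ratio_to_expected": rms / rms_expected,
        "reduction": rms / rms_single,
    }
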