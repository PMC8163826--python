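"""Subtomogram extraction, iterative alignment, symmetrization, FSC.

The tube pipeline mirrors conventional iterative subtomogram averaging:
seed poses from the cylinder parametrization of the tube (oversampled),
align each subtomogram to the current reference over a bounded angular
net, remove duplicates that converged onto the same lattice position
(greedy, keep highest correlation), drop non-aligning particles by a
correlation threshold, apply C2 symmetry, and estimate resolution by
mask-corrected Fourier shell correlation of independent half-set averages
at the 0.143 criterion.

Anisotropy from preferred particle orientations is compensated by
wedge-mask-weighted averaging: each subtomogram contributes its Fourier
spectrum only inside its (pose-rotated) sampled wedge, and the sum is
divided by the accumulated coverage.
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
    clean_rotation,
    UnitAnnotation,
    euler_from_normal,
    euler_from_rotation,
    rotation_from_euler,
    signed_inplane_angle,
)
from .io_formats import DensityVolume
from .synthetic import LatticeGraph, WedgeSpec

__all__ = [
    "AlignmentRound",
    "AlignmentSchedule",
    "FSCCurve",
    "extract_subtomograms",
    "remove_duplicates",
    "threshold_cc",
    "bin_volume",
    "apply_symmetry",
    "weighted_average",
    "fsc",
    "fsc_shell_counts",
    "soft_mask",
    "resolution_at",
    "seed_tube_poses",
    "split_half_sets",
    "run_tube_average",
]


@dataclass(frozen=True)
class AlignmentRound:
    binning: int = 1
    rot_range: float = 8.0      # degrees
    rot_step: float = 4.0
    trans_range: float = 4.0    # voxels (at the round's binning)
    lowpass: float = 32.0       # A; >= 32 until half-sets are independent
    dup_cutoff: float = 40.0    # A
    cc_threshold: float = 0.1


@dataclass
class AlignmentSchedule:
    rounds: list[AlignmentRound] = field(default_factory=lambda: [
        AlignmentRound(binning=2, rot_range=12, rot_step=6, trans_range=6),
        AlignmentRound(binning=2, rot_range=12, rot_step=6, trans_range=4),
        AlignmentRound(binning=2, rot_range=8, rot_step=4, trans_range=3),
        AlignmentRound(binning=1, rot_range=6, rot_step=3, trans_range=3),
        AlignmentRound(binning=1, rot_range=3, rot_step=1.5, trans_range=2),
    ])

    def __post_init__(self):
        bins = [r.binning for r in self.rounds]
        if any(b2 > b1 for b1, b2 in zip(bins, bins[1:])):
            raise ValueError("binning must be non-increasing across rounds")
        if any(r.lowpass < 32.0 for r in self.rounds):
            raise ValueError(
                "low-pass limits below 32 A are reserved for independent "
                "half-set refinement")


@dataclass
class FSCCurve:
    frequencies: np.ndarray   # 1/A, shell centers
    values: np.ndarray
    nyquist_flagged: bool = False


# ---------------------------------------------------------------------------
# stack handling

def extract_subtomograms(vol: DensityVolume, units: list[UnitAnnotation],
                         box: int) -> list[tuple[np.ndarray, UnitAnnotation]]:
    """One cube per unit, centered at its voxel position (center box//2).

    Out-of-bounds boxes are skipped with a warning.
    """
    out = []
    half = box // 2
    shape = np.array(vol.grid.shape)
    for u in units:
        c = np.round(u.position).astype(int)
        lo, hi = c - half, c - half + box
        if np.any(lo < 0) or np.any(hi > shape):
            warnings.warn(f"unit {u.unit_id} at {c} exceeds volume; skipped")
            continue
        out.append((vol.grid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
                    .astype(np.float64), u))
    return out


def remove_duplicates(units: list[UnitAnnotation], cutoff: float,
                      voxel_size: float = 1.0) -> list[UnitAnnotation]:
    """Greedy duplicate removal: keep the highest-cc unit within cutoff (A).

    Deterministic: candidates visited by descending cc, ties by list index.
    """
    order = sorted(range(len(units)),
                   key=lambda i: (-units[i].cc, i))
    kept: list[int] = []
    for i in order:
        p = units[i].position
        if any(np.linalg.norm((p - units[j].position) * voxel_size) < cutoff
               for j in kept):
            continue
        kept.append(i)
    return [units[i] for i in sorted(kept)]


def threshold_cc(units: list[UnitAnnotation], min_cc: float
                 ) -> list[UnitAnnotation]:
    """Remove units with cc strictly below the threshold."""
    return [u for u in units if u.cc >= min_cc]


def bin_volume(vol: DensityVolume, factor: int) -> DensityVolume:
    """Bin by Fourier cropping (the tomography convention)."""
    if factor == 1:
        return vol.copy()
    s = np.array(vol.grid.shape)
    if np.any(s % (2 * factor)):
        raise ValueError("volume dimensions must be divisible by 2*factor")
    ns = s // factor
    ft = scipy.fft.fftshift(scipy.fft.fftn(vol.grid.astype(np.float64)))
    c = s // 2
    sl = tuple(slice(ci - ni // 2, ci + ni // 2) for ci, ni in zip(c, ns))
    cropped = scipy.fft.ifftshift(ft[sl])
    out = np.real(scipy.fft.ifftn(cropped)) / factor ** 3
    return DensityVolume(out.astype(np.float32), vol.voxel_size * factor,
                         vol.origin)


# ---------------------------------------------------------------------------
# symmetrization and weighted averaging

def apply_symmetry(vol: DensityVolume, n: int) -> DensityVolume:
    """Average over the Cn group about the box z axis (center (N-1)/2)."""
    if n < 1:
        raise ValueError("symmetry order must be >= 1")
    if n == 1:
        return vol.copy()
    acc = np.zeros(vol.grid.shape)
    g = vol.grid.astype(np.float64)
    c = (np.array(vol.grid.shape) - 1) / 2.0
    for k in range(n):
        ang = 2 * np.pi * k / n
        R = clean_rotation(Rotation.from_rotvec([0, 0, ang]).as_matrix())
        acc += ndimage.affine_transform(g, R.T, offset=c - R.T @ c, order=1,
                                        mode="constant", cval=0.0)
    return DensityVolume((acc / n).astype(np.float32), vol.voxel_size,
                         vol.origin)


def rotated_wedge_mask(shape, w: WedgeSpec, R: np.ndarray) -> np.ndarray:
    """Binary wedge support after rotating a subtomogram by R (rfft grid)."""
    fx = np.fft.fftfreq(shape[0])[:, None, None]
    fy = np.fft.fftfreq(shape[1])[None, :, None]
    fz = np.fft.rfftfreq(shape[2])[None, None, :]
    k = np.stack(np.broadcast_arrays(fx, fy, fz), axis=-1)
    # a point k of the rotated spectrum came from R^T k in the original
    k0 = np.einsum("ij,...j->...i", R.T, k)
    axes = {"x": (1, 2), "y": (0, 2), "z": (0, 1)}[w.tilt_axis]
    a, b = k0[..., axes[0]], k0[..., axes[1]]
    t = np.rad2deg(np.arctan2(b, a))
    keep = np.zeros(a.shape, dtype=bool)
    for off in (-180.0, 0.0, 180.0):
        keep |= (t + off >= w.min_angle) & (t + off <= w.max_angle)
    keep |= (np.abs(a) < 1e-12) & (np.abs(b) < 1e-12)
    return keep


def weighted_average(cubes: list[np.ndarray],
                     masks: list[np.ndarray],
                     coverage_floor: float = 0.5,
                     ) -> tuple[DensityVolume | np.ndarray, float]:
    """Fourier-space wedge-weighted average.

    Sums mask-weighted spectra and divides by accumulated coverage
    (floored at ``coverage_floor`` to avoid amplifying unsampled voxels);
    voxels with zero coverage are zeroed.  Returns (average grid, covered
    fraction of Fourier space).
    """
    if not cubes:
        raise ValueError("empty stack")
    shape = cubes[0].shape
    num = np.zeros(scipy.fft.rfftn(np.zeros(shape)).shape, dtype=complex)
    cov = np.zeros(num.shape)
    for cube, mask in zip(cubes, masks):
        num += scipy.fft.rfftn(cube) * mask
        cov += mask
    covered = cov > 0
    denom = np.maximum(cov, coverage_floor)
    avg_ft = np.where(covered, num / denom, 0.0)
    avg = scipy.fft.irfftn(avg_ft, s=shape)
    return avg, float(covered.mean())


# ---------------------------------------------------------------------------
# FSC

def _shell_index(shape, voxel_size):
    fx = np.fft.fftfreq(shape[0])[:, None, None]
    fy = np.fft.fftfreq(shape[1])[None, :, None]
    fz = np.fft.rfftfreq(shape[2])[None, None, :]
    k = np.sqrt(fx ** 2 + fy ** 2 + fz ** 2)
    n_shells = shape[0] // 2
    idx = np.minimum((k * shape[0]).astype(int), n_shells)
    freqs = (np.arange(n_shells) + 0.5) / (shape[0] * voxel_size)
    return idx, n_shells, freqs


def soft_mask(shape, radius_frac: float = 0.4, soft_vox: float = 3.0
              ) -> np.ndarray:
    """Gaussian-filtered spherical mask for mask-corrected FSC."""
    c = (np.array(shape) - 1) / 2.0
    ax = [np.arange(s) - ci for s, ci in zip(shape, c)]
    r = np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                + ax[2][None, None, :] ** 2)
    radius = radius_frac * min(shape)
    hard = (r <= radius).astype(float)
    return ndimage.gaussian_filter(hard, min(soft_vox, max(1.0, 0.3 * radius)))


def fsc(a: DensityVolume, b: DensityVolume,
        mask: np.ndarray | None = None) -> FSCCurve:
    """Fourier shell correlation of two (soft-masked) maps."""
    if a.grid.shape != b.grid.shape:
        raise ValueError("maps must have equal shapes")
    if abs(a.voxel_size - b.voxel_size) > 1e-6:
        raise ValueError("maps must have equal voxel sizes")
    ga = a.grid.astype(np.float64)
    gb = b.grid.astype(np.float64)
    if mask is not None:
        ga = ga * mask
        gb = gb * mask
    fa = scipy.fft.rfftn(ga)
    fb = scipy.fft.rfftn(gb)
    idx, n_shells, freqs = _shell_index(a.grid.shape, a.voxel_size)
    flat = idx.ravel()
    num = np.bincount(flat, weights=np.real(fa * np.conj(fb)).ravel(),
                      minlength=n_shells + 1)[:n_shells]
    pa = np.bincount(flat, weights=(np.abs(fa) ** 2).ravel(),
                     minlength=n_shells + 1)[:n_shells]
    pb = np.bincount(flat, weights=(np.abs(fb) ** 2).ravel(),
                     minlength=n_shells + 1)[:n_shells]
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = num / np.sqrt(pa * pb)
    vals = np.nan_to_num(vals, nan=0.0)
    return FSCCurve(frequencies=freqs, values=np.clip(vals, -1.0, 1.0))


def fsc_shell_counts(shape) -> np.ndarray:
    """Independent-sample count per shell (full-FFT voxels per shell)."""
    fx = np.fft.fftfreq(shape[0])[:, None, None]
    fy = np.fft.fftfreq(shape[1])[None, :, None]
    fz = np.fft.fftfreq(shape[2])[None, None, :]
    k = np.sqrt(fx ** 2 + fy ** 2 + fz ** 2)
    n_shells = shape[0] // 2
    idx = np.minimum((k * shape[0]).astype(int), n_shells)
    return np.bincount(idx.ravel(), minlength=n_shells + 1)[:n_shells]


def resolution_at(curve: FSCCurve, threshold: float = 0.143
                  ) -> tuple[float, bool]:
    """Resolution (A) at the first crossing below threshold.

    Linear interpolation between shells; if the curve never drops below
    the threshold, returns the Nyquist resolution flagged True.
    """
    f, v = curve.frequencies, curve.values
    above = np.where(v >= threshold)[0]
    if len(above) == 0:
        return float(1.0 / f[0]), True
    # first downward crossing after the curve has been above threshold
    # (the near-DC shell of mean-free maps carries no signal and is noisy)
    below = np.where(v < threshold)[0]
    below = below[below > above[0]]
    if len(below) == 0:
        return float(1.0 / f[-1]), True
    i = below[0]
    f_cross = f[i - 1] + (f[i] - f[i - 1]) * (v[i - 1] - threshold) \
        / (v[i - 1] - v[i])
    return float(1.0 / f_cross), False


# ---------------------------------------------------------------------------
# tube pipeline

def seed_tube_poses(g: LatticeGraph, oversample: float = 4.0
                    ) -> list[UnitAnnotation]:
    """Initial poses from the cylinder parametrization of a tube lattice.

    Axis and radius are estimated from the annotated positions (PCA);
    seeds are laid out on the cylinder surface with a grid ~``oversample``
    times denser (in area) than the lattice, normals radial, in-plane x
    axis along the tube axis.
    """
    P = g.positions() * g.voxel_size
    centroid = P.mean(axis=0)
    _, _, vt = np.linalg.svd(P - centroid, full_matrices=False)
    axis = vt[0]
    radial = P - centroid - np.outer((P - centroid) @ axis, axis)
    radius = np.linalg.norm(radial, axis=1).mean()
    zs = (P - centroid) @ axis
    lin = np.sqrt(oversample)
    step = g.spacing / lin
    n_phi = max(3, int(round(2 * np.pi * radius / step)))
    z_grid = np.arange(zs.min(), zs.max() + 0.5 * step, step)
    # basis perpendicular to the axis
    e1 = np.eye(3)[np.argmin(np.abs(axis))]
    e1 = e1 - np.dot(e1, axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    seeds = []
    for z in z_grid:
        for j in range(n_phi):
            phi = 2 * np.pi * j / n_phi
            n = np.cos(phi) * e1 + np.sin(phi) * e2
            pos = (centroid + z * axis + radius * n) / g.voxel_size
            e0 = euler_from_normal(n, 0.0)
            x0 = rotation_from_euler(e0) @ np.array([1.0, 0.0, 0.0])
            psi = signed_inplane_angle(x0, axis, n)
            seeds.append(UnitAnnotation(
                position=pos, euler=EulerTriplet(e0.phi, e0.theta, psi),
                cc=0.0, unit_type="hexamer_C2", unit_id=len(seeds)))
    return seeds


def split_half_sets(graphs: list[LatticeGraph]
                    ) -> tuple[list[LatticeGraph], list[LatticeGraph]]:
    """Split whole particles into two half-sets of comparable size.

    The split is at the particle (lattice) level so no structure
    contributes to both halves; greedy balance by unit count.
    """
    order = sorted(range(len(graphs)), key=lambda i: (-len(graphs[i]), i))
    halves: tuple[list, list] = ([], [])
    sizes = [0, 0]
    for i in order:
        h = 0 if sizes[0] <= sizes[1] else 1
        halves[h].append(graphs[i])
        sizes[h] += len(graphs[i])
    return halves


def _align_to_ref(cube, ref, mask, R0, rot_range, rot_step, trans_range=4):
    """Bounded rotation/translation search of a cube against a reference."""
    best = (-2.0, np.zeros(3), R0)
    box = cube.shape[0]
    half = box // 2
    t = min(int(trans_range), half - 1)
    c = (np.array(ref.shape) - 1) / 2.0
    m = mask
    m_sel = m > 0.5 * m.max()
    s = (cube - cube[m_sel].mean()) * m
    sn = np.sqrt((s ** 2).sum())
    if sn < 1e-12:
        return best
    sft = scipy.fft.rfftn(s)
    vals = np.arange(-rot_range, rot_range + 1e-9, rot_step)
    for ax_ in np.deg2rad(vals):
        for ay in np.deg2rad(vals):
            for az in np.deg2rad(vals):
                dR = Rotation.from_rotvec([ax_, ay, az]).as_matrix()
                R = R0 @ dR
                Rt = R.T
                ref_rot = ndimage.affine_transform(
                    ref, Rt, offset=c - Rt @ c, order=1, mode="constant")
                r = (ref_rot - ref_rot[m_sel].mean()) * m
                rn = np.sqrt((r ** 2).sum())
                if rn < 1e-12:
                    continue
                cc3 = scipy.fft.irfftn(sft * np.conj(scipy.fft.rfftn(r)),
                                       s=s.shape) / (rn * sn)
                cc3 = np.fft.fftshift(cc3)
                win = cc3[half - t:half + t + 1, half - t:half + t + 1,
                          half - t:half + t + 1]
                k = np.unravel_index(np.argmax(win), win.shape)
                if win[k] > best[0]:
                    shift = np.array(k, dtype=float) - t
                    best = (float(win[k]), shift, R)
    return best


def _average_stack(vol, units, box, symmetry, wedge=None):
    """Rotate subtomograms into the reference frame and average."""
    stack = extract_subtomograms(vol, units, box)
    if not stack:
        raise ValueError("no subtomograms inside the volume")
    c = (np.array((box, box, box)) - 1) / 2.0
    cubes, masks = [], []
    for cube, u in stack:
        R = clean_rotation(u.rotation)
        # unit frame -> volume frame is R; resample so the unit appears
        # in its canonical orientation
        sub = ndimage.affine_transform(cube, R, offset=c - R @ c, order=1,
                                       mode="constant", cval=0.0)
        cubes.append(sub)
        if wedge is not None:
            masks.append(rotated_wedge_mask((box, box, box), wedge, R.T))
    if wedge is None:
        avg = np.mean(cubes, axis=0)
    else:
        avg, _ = weighted_average(cubes, masks)
    out = DensityVolume(avg.astype(np.float32), vol.voxel_size)
    return apply_symmetry(out, symmetry)


def run_tube_average(vol: DensityVolume, g: LatticeGraph,
                     schedule: AlignmentSchedule | None = None,
                     box: int = 32, symmetry: int = 2,
                     oversample: float = 4.0,
                     wedge: WedgeSpec | None = None,
                     mask_radius_frac: float = 0.35,
                     rel_cc_min: float = 0.75,
                     seed_from_truth: bool = False,
                     ) -> dict:
    """Full tube subtomogram-averaging pipeline.

    Seeds poses from the cylinder parametrization (or the annotation
    itself), runs the alignment schedule with duplicate and cc filtering,
    applies Cn symmetry, splits even/odd half-sets, and reports the
    final average, half-maps, FSC curve and 0.143 resolution.
    """
    if schedule is None:
        schedule = AlignmentSchedule()
    box |= 1  # odd boxes: rotation center and extraction center coincide
    units = [u.copy() for u in g.units] if seed_from_truth \
        else seed_tube_poses(g, oversample)
    results: dict = {}
    for rnd in schedule.rounds:
        wvol = bin_volume(vol, rnd.binning) if rnd.binning > 1 else vol
        scale = 1.0 / rnd.binning
        rbox = max(9, (box // rnd.binning) | 1)  # fixed physical extent
        mask = soft_mask((rbox, rbox, rbox), mask_radius_frac)
        scaled = []
        for u in units:
            v = u.copy()
            v.position = u.position * scale
            scaled.append(v)
        ref = _average_stack(wvol, scaled, rbox, symmetry)
        if rnd.lowpass > 2.0 * wvol.voxel_size:
            from .matching import bandpass_filter

            ref = bandpass_filter(ref, 1e6, rnd.lowpass)
        stack = extract_subtomograms(wvol, scaled, rbox)
        new_units = []
        for cube, u in stack:
            cc, shift, R = _align_to_ref(cube, ref.grid.astype(np.float64),
                                         mask, u.rotation, rnd.rot_range,
                                         rnd.rot_step,
                                         trans_range=rnd.trans_range)
            v = u.copy()
            # shift is the object displacement in the volume frame
            v.position = u.position + shift
            v.euler = euler_from_rotation(R)
            v.cc = cc
            new_units.append(v)
        new_units = threshold_cc(new_units, rnd.cc_threshold)
        if rel_cc_min > 0 and new_units:
            med = float(np.median([u.cc for u in new_units]))
            new_units = threshold_cc(new_units, rel_cc_min * med)
        new_units = remove_duplicates(new_units, rnd.dup_cutoff,
                                      wvol.voxel_size)
        units = []
        for u in new_units:
            v = u.copy()
            v.position = u.position / scale
            units.append(v)
    results["units"] = units
    results["average"] = _average_stack(vol, units, box, symmetry,
                                        wedge=wedge)
    mask = soft_mask((box, box, box), mask_radius_frac)
    halves = ([u for i, u in enumerate(units) if i % 2 == 0],
              [u for i, u in enumerate(units) if i % 2 == 1])
    if min(len(h) for h in halves) >= 1:
        h1 = _average_stack(vol, halves[0], box, symmetry, wedge=wedge)
        h2 = _average_stack(vol, halves[1], box, symmetry, wedge=wedge)
        curve = fsc(h1, h2, soft_mask((box, box, box), mask_radius_frac))
        res, flagged = resolution_at(curve)
        results.update(half_maps=(h1, h2), fsc=curve,
                       resolution_A=res, at_nyquist=flagged)
    return results
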