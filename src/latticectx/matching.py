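"""Template matching: locate hexamer/pentamer candidates in a volume.

Constrained cross-correlation search: both volume and template are
band-pass filtered (default 425-30 A), the template is scanned over a
near-uniform net of normal directions (arc step ~15 deg) crossed with
in-plane rotations (10 deg steps, reduced by template symmetry), and at
every voxel the maximum locally-normalized correlation over orientations
and templates is retained.  Peaks are local maxima separated by at least
one unit spacing.

Normalization is zero-mean / unit-variance under a spherical mask around
the template footprint (the field norm for tomogram matching); the
correlation is therefore invariant to local intensity scale and offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy import ndimage

from .geometry import EulerTriplet, UnitAnnotation, euler_from_normal
from .io_formats import DensityVolume
from .synthetic import UnitTemplate, default_templates, render_unit_template

__all__ = [
    "MatchConfig",
    "CCPeak",
    "bandpass_filter",
    "orientation_net",
    "rotate_volume",
    "cc_map",
    "scan_orientations",
    "peaks_to_units",
]


@dataclass(frozen=True)
class MatchConfig:
    """Angular sampling, band-pass and peak criteria for the search."""

    phi_step: float = 10.0            # in-plane step, degrees
    other_step: float = 15.0          # direction-net arc step, degrees
    bandpass: tuple[float, float] = (425.0, 30.0)   # (low, high) in A
    mask_radius: float = 55.0         # normalization mask radius, A
    peak_min_separation: float = 60.0  # A, the minimum lattice spacing
    min_cc: float = 0.1

    def __post_init__(self):
        if not (360.0 / self.phi_step) % 1 < 1e-9:
            raise ValueError("phi_step must divide 360")
        lo, hi = self.bandpass
        if not lo > hi > 0:
            raise ValueError("bandpass must be (low A, high A) with low > high")


@dataclass
class CCPeak:
    """One candidate unit: position, best orientation, score, template."""

    position: np.ndarray     # voxels
    euler: EulerTriplet
    cc: float
    unit_type: str

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if not -1.0 - 1e-6 <= self.cc <= 1.0 + 1e-6:
            raise ValueError(f"cc out of [-1, 1]: {self.cc}")


def bandpass_filter(vol: DensityVolume, low_A: float, high_A: float,
                    soft: float = 2.0) -> DensityVolume:
    """Fourier band-pass between resolutions low_A and high_A (low > high).

    Edges are softened with a Gaussian of ``soft`` Fourier pixels to avoid
    ringing.
    """
    shape = vol.grid.shape
    fx = np.fft.fftfreq(shape[0])[:, None, None]
    fy = np.fft.fftfreq(shape[1])[None, :, None]
    fz = np.fft.rfftfreq(shape[2])[None, None, :]
    k = np.sqrt(fx ** 2 + fy ** 2 + fz ** 2) / vol.voxel_size
    k_lo, k_hi = 1.0 / low_A, 1.0 / high_A
    dk = soft / (shape[0] * vol.voxel_size)
    win = _soft_step(k, k_lo, dk) * (1.0 - _soft_step(k, k_hi, dk))
    ft = scipy.fft.rfftn(vol.grid) * win
    return DensityVolume(
        scipy.fft.irfftn(ft, s=shape).astype(np.float32), vol.voxel_size,
        vol.origin,
    )


def _soft_step(k, k0, dk):
    return 0.5 * (1.0 + np.tanh((k - k0) / max(dk, 1e-9)))


def orientation_net(other_step: float, phi_step: float,
                    symmetry_order: int = 1) -> list[EulerTriplet]:
    """Near-uniform orientation sampling.

    Normal directions on a Fibonacci sphere with arc spacing ~``other_step``,
    crossed with in-plane angles every ``phi_step`` over 360/symmetry
    (template Cn symmetry makes the rest redundant).  Deterministic.
    """
    n_dirs = max(1, int(np.ceil(4.0 * 180.0 ** 2 / np.pi
                                / other_step ** 2)))
    i = np.arange(n_dirs)
    z = 1.0 - (2.0 * i + 1.0) / n_dirs
    phi_g = np.pi * (3.0 - np.sqrt(5.0)) * i
    dirs = np.stack([np.sqrt(1 - z ** 2) * np.cos(phi_g),
                     np.sqrt(1 - z ** 2) * np.sin(phi_g), z], axis=1)
    out = []
    inplane = np.arange(0.0, 360.0 / symmetry_order, phi_step)
    for d in dirs:
        base = euler_from_normal(d)
        for psi in inplane:
            out.append(EulerTriplet(base.phi, base.theta, psi))
    return out


def rotate_volume(vol: np.ndarray, euler: EulerTriplet, order: int = 1) -> np.ndarray:
    """Resample a cubic volume under the rotation of ``euler`` about its center."""
    from .geometry import clean_rotation, rotation_from_euler

    R = clean_rotation(rotation_from_euler(euler))
    c = (np.array(vol.shape) - 1) / 2.0
    Rinv = R.T
    offset = c - Rinv @ c
    return ndimage.affine_transform(vol, Rinv, offset=offset, order=order,
                                    mode="constant", cval=0.0)


def _bandpass_window(shape, voxel_size, low_A, high_A, soft=2.0):
    fx = np.fft.fftfreq(shape[0])[:, None, None]
    fy = np.fft.fftfreq(shape[1])[None, :, None]
    fz = np.fft.rfftfreq(shape[2])[None, None, :]
    k = np.sqrt(fx ** 2 + fy ** 2 + fz ** 2) / voxel_size
    dk = soft / (shape[0] * voxel_size)
    return _soft_step(k, 1.0 / low_A, dk) * (1.0 - _soft_step(k, 1.0 / high_A, dk))


class _VolumeContext:
    """Cached FFT and local statistics of the search volume."""

    def __init__(self, vol: DensityVolume, cfg: MatchConfig):
        self.shape = vol.grid.shape
        self.voxel_size = vol.voxel_size
        self.window = _bandpass_window(self.shape, self.voxel_size,
                                       *cfg.bandpass)
        g = scipy.fft.irfftn(scipy.fft.rfftn(vol.grid.astype(np.float64))
                             * self.window, s=self.shape)
        # small template workspace: band-pass once (isotropic, commutes with
        # rotation), rotate and mask per orientation
        self.tbox = min(2 * int(np.ceil(cfg.mask_radius / self.voxel_size)) + 5,
                        min(self.shape))
        c = (self.tbox - 1) / 2.0
        ax = np.arange(self.tbox) - c
        self.tmask = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
                      + ax[None, None, :] ** 2) <= (cfg.mask_radius
                                                    / self.voxel_size) ** 2
        self.cfg = cfg
        self.ft = scipy.fft.rfftn(g)
        # spherical normalization mask centered at the origin voxel
        r_vox = cfg.mask_radius / vol.voxel_size
        grids = np.meshgrid(*[np.minimum(np.arange(n), n - np.arange(n))
                              for n in self.shape], indexing="ij")
        mask = (grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2) <= r_vox ** 2
        self.m = int(mask.sum())
        mft = scipy.fft.rfftn(mask.astype(np.float64))
        s1 = scipy.fft.irfftn(self.ft * np.conj(mft), s=self.shape)
        s2 = scipy.fft.irfftn(scipy.fft.rfftn(g ** 2) * np.conj(mft),
                              s=self.shape)
        var = np.maximum(s2 - s1 ** 2 / self.m, 0.0)
        sigma = np.sqrt(var)
        # floor the local deviation to suppress spurious correlations in
        # (near-)empty regions of noise-free synthetic volumes
        self.degenerate = sigma <= 0.02 * sigma.max()
        self.sigma = np.maximum(sigma, 0.02 * sigma.max() + 1e-300)


def _prepared_template(ctx: "_VolumeContext", tmpl) -> np.ndarray:
    """Band-pass-filtered template in the context's template box."""
    key = id(tmpl)
    cache = getattr(ctx, "_tcache", None)
    if cache is None:
        cache = ctx._tcache = {}
    if key in cache:
        return cache[key]
    box = ctx.tbox
    if isinstance(tmpl, UnitTemplate):
        tv = render_unit_template(tmpl, ctx.voxel_size, box)
    else:
        if any(s > v for s, v in zip(tmpl.grid.shape, ctx.shape)):
            raise ValueError("template box exceeds volume box")
        g = np.zeros((box, box, box), dtype=np.float64)
        src = tmpl.grid
        off = [(box - min(s, box)) // 2 for s in src.shape]
        sl_src = tuple(slice(max(0, (s - box) // 2),
                             max(0, (s - box) // 2) + min(s, box))
                       for s in src.shape)
        sl_dst = tuple(slice(o, o + min(s, box))
                       for o, s in zip(off, src.shape))
        g[sl_dst] = src[sl_src]
        tv = DensityVolume(g, ctx.voxel_size)
    win = _bandpass_window(tv.grid.shape, ctx.voxel_size, *ctx.cfg.bandpass)
    out = scipy.fft.irfftn(scipy.fft.rfftn(tv.grid.astype(np.float64)) * win,
                           s=tv.grid.shape)
    cache[key] = out
    return out


def cc_map(vol: DensityVolume | _VolumeContext, template, e: EulerTriplet,
           cfg: MatchConfig = MatchConfig()) -> np.ndarray:
    """Normalized cross-correlation of the template at orientation ``e``
    against the volume, at every (circular) voxel shift.

    ``template`` may be a :class:`UnitTemplate` (rendered at the volume's
    voxel size) or a :class:`DensityVolume` no larger than the volume.
    Degenerate locations (zero local variance, e.g. an all-zero volume)
    score 0.
    """
    ctx = vol if isinstance(vol, _VolumeContext) else _VolumeContext(vol, cfg)
    t = _prepared_template(ctx, template)
    t = rotate_volume(t, e, order=1)
    # mask and zero-mean within the mask: with the same mask in the
    # denominator this bounds |cc| by 1 (Cauchy-Schwarz)
    t = np.where(ctx.tmask, t, 0.0)
    t[ctx.tmask] -= t[ctx.tmask].mean()
    norm = np.sqrt((t ** 2).sum())
    if norm < 1e-12:
        raise ValueError("template is zero after filtering")
    # embed with the template center at the origin voxel
    pad = np.zeros(ctx.shape)
    pad[: t.shape[0], : t.shape[1], : t.shape[2]] = t
    c = [(s - 1) // 2 for s in t.shape]
    pad = np.roll(pad, [-ci for ci in c], axis=(0, 1, 2))
    num = scipy.fft.irfftn(ctx.ft * np.conj(scipy.fft.rfftn(pad)),
                           s=ctx.shape) / norm
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = num / ctx.sigma
    cc[ctx.degenerate] = 0.0
    return np.clip(cc, -1.0, 1.0)


def scan_orientations(vol: DensityVolume, templates=None,
                      cfg: MatchConfig = MatchConfig()) -> list[CCPeak]:
    """Exhaustive orientation/template scan; returns separated CC peaks.

    For each voxel the maximum cc over all scanned orientations and
    templates is retained; peaks are local maxima with minimum separation
    ``cfg.peak_min_separation`` (greedy by descending cc; ties broken by
    linear voxel index).
    """
    if templates is None:
        templates = {k: v for k, v in default_templates().items()
                     if k in ("hexamer_C6", "pentamer_C5")}
    ctx = _VolumeContext(vol, cfg)
    best = np.full(ctx.shape, -2.0)
    best_orient = np.zeros(ctx.shape, dtype=np.int32)
    best_tmpl = np.zeros(ctx.shape, dtype=np.int8)
    names = list(templates)
    all_orients = []
    for ti, name in enumerate(names):
        tmpl = templates[name]
        order = tmpl.order if isinstance(tmpl, UnitTemplate) else 1
        net = orientation_net(cfg.other_step, cfg.phi_step, order)
        for e in net:
            cc = cc_map(ctx, tmpl, e, cfg)
            take = cc > best
            best[take] = cc[take]
            best_orient[take] = len(all_orients)
            best_tmpl[take] = ti
            all_orients.append(e)
    return _extract_peaks(best, best_orient, best_tmpl, all_orients, names,
                          ctx.voxel_size, cfg)


def _extract_peaks(best, best_orient, best_tmpl, orients, names,
                   voxel_size, cfg) -> list[CCPeak]:
    sep_vox = max(1, int(round(cfg.peak_min_separation / voxel_size)))
    footprint = min(2 * (sep_vox // 2) + 1, min(best.shape))
    local_max = best >= ndimage.maximum_filter(best, size=footprint,
                                               mode="nearest")
    cand = np.argwhere(local_max & (best > cfg.min_cc))
    scores = best[tuple(cand.T)]
    lin = np.ravel_multi_index(tuple(cand.T), best.shape)
    order = np.lexsort((lin, -scores))  # descending cc, ties by voxel index
    kept: list[np.ndarray] = []
    peaks: list[CCPeak] = []
    for idx in order:
        p = cand[idx]
        if any(np.linalg.norm((p - q) * voxel_size) < cfg.peak_min_separation
               for q in kept):
            continue
        kept.append(p)
        peaks.append(CCPeak(
            position=p.astype(float),
            euler=orients[best_orient[tuple(p)]],
            cc=float(best[tuple(p)]),
            unit_type=names[best_tmpl[tuple(p)]],
        ))
    return peaks


def peaks_to_units(peaks: list[CCPeak]) -> list[UnitAnnotation]:
    return [
        UnitAnnotation(position=p.position.copy(), euler=p.euler, cc=p.cc,
                       unit_type=p.unit_type, unit_id=i)
        for i, p in enumerate(peaks)
    ]
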