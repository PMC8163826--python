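"""Pose mathematics for lattice units.

Orientations are intrinsic ZXZ Euler triplets (phi, theta, psi) in degrees,
R = Rz(phi) @ Rx(theta) @ Rz(psi), the convention common in subtomogram
averaging packages.  A unit's outward normal is R @ (0, 0, 1); psi is the
in-plane spin about that normal.  Positions are stored in voxels; every
physical threshold is in Angstrom, with the voxel size carried explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EulerTriplet",
    "UnitAnnotation",
    "PairGeometry",
    "rotation_from_euler",
    "euler_from_rotation",
    "normal_from_euler",
    "euler_from_normal",
    "pair_geometry",
    "UNIT_TYPES",
]

UNIT_TYPES = ("hexamer_C2", "hexamer_C6", "pentamer_C5")


@dataclass(frozen=True)
class EulerTriplet:
    """Intrinsic ZXZ Euler angles in degrees, canonicalized on creation.

    theta is folded into [0, 180]; phi and psi into [0, 360).
    """

    phi: float
    theta: float
    psi: float

    def __post_init__(self):
        phi, theta, psi = float(self.phi), float(self.theta), float(self.psi)
        theta = theta % 360.0
        if theta > 180.0:
            # (phi, theta, psi) and (phi+180, 360-theta, psi+180) are the
            # same rotation in ZXZ
            theta = 360.0 - theta
            phi += 180.0
            psi += 180.0
        def wrap(v):
            v = v % 360.0
            return 0.0 if v == 360.0 else v  # (-eps) % 360 rounds to 360.0

        object.__setattr__(self, "phi", wrap(phi))
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "psi", wrap(psi))

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi, self.theta, self.psi)


@dataclass
class UnitAnnotation:
    """One lattice unit (hexamer or pentamer): the atom of all analysis."""

    position: np.ndarray          # (x, y, z) in voxels
    euler: EulerTriplet
    cc: float = 1.0               # correlation score in [-1, 1]
    unit_type: str = "hexamer_C6"
    unit_id: int = -1
    network_id: int = -1
    group: int = 0
    subclass: int = 0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if self.unit_type not in UNIT_TYPES:
            raise ValueError(
                f"unit_type must be one of {UNIT_TYPES}, got {self.unit_type!r}"
            )
        if not np.isfinite(self.cc):
            raise ValueError("cc must be finite")

    @property
    def is_pentamer(self) -> bool:
        return self.unit_type == "pentamer_C5"

    @property
    def rotation(self) -> np.ndarray:
        return rotation_from_euler(self.euler)

    @property
    def normal(self) -> np.ndarray:
        return normal_from_euler(self.euler)

    def copy(self) -> "UnitAnnotation":
        out = replace(self)
        out.position = self.position.copy()
        return out


@dataclass(frozen=True)
class PairGeometry:
    """Pairwise descriptors of two adjacent units.

    distance    center separation in Angstrom
    tilt        angle between the two outward normals, degrees in [0, 180]
    twist       signed in-plane rotation offset of B relative to A after
                parallel transport of B's frame onto A's tangential plane,
                degrees in (-180, 180]
    curvature   angle of the A->B vector below A's tangential plane, degrees;
                positive = convex-outward surface (B on the inner side)
    normal_diff alias of tilt under its connectivity-criterion name
    """

    distance: float
    tilt: float
    twist: float
    curvature: float
    curvature_ba: float = field(default=np.nan)

    @property
    def normal_diff(self) -> float:
        return self.tilt


def rotation_from_euler(e: EulerTriplet | tuple) -> np.ndarray:
    """3x3 proper rotation matrix for an intrinsic ZXZ triplet (degrees)."""
    if isinstance(e, EulerTriplet):
        e = e.as_tuple()
    return Rotation.from_euler("ZXZ", e, degrees=True).as_matrix()


def euler_from_rotation(m: np.ndarray) -> EulerTriplet:
    """Inverse of :func:`rotation_from_euler`, canonicalized."""
    phi, theta, psi = Rotation.from_matrix(np.asarray(m, dtype=float)).as_euler(
        "ZXZ", degrees=True
    )
    return EulerTriplet(phi, theta, psi)


def normal_from_euler(e: EulerTriplet | tuple) -> np.ndarray:
    """Outward normal R @ z; unit length; independent of psi."""
    if not isinstance(e, EulerTriplet):
        e = EulerTriplet(*e)
    phi, theta = np.deg2rad(e.phi), np.deg2rad(e.theta)
    st = np.sin(theta)
    return np.array([st * np.sin(phi), -st * np.cos(phi), np.cos(theta)])


def euler_from_normal(n: np.ndarray, psi: float = 0.0) -> EulerTriplet:
    """An Euler triplet whose normal is n (psi chosen by the caller)."""
    n = np.asarray(n, dtype=float)
    n = n / np.linalg.norm(n)
    theta = np.rad2deg(np.arccos(np.clip(n[2], -1.0, 1.0)))
    if np.hypot(n[0], n[1]) < 1e-12:
        phi = 0.0
    else:
        phi = np.rad2deg(np.arctan2(n[0], -n[1]))
    return EulerTriplet(phi, theta, psi)


def clean_rotation(R: np.ndarray) -> np.ndarray:
    """Snap numerical noise in near-axis-aligned rotation matrices.

    Entries within 1e-12 of 0 or +/-1 are snapped so that exact 90/180
    degree rotations resample grids exactly (floating-point residue can
    push border samples out of bounds).
    """
    R = np.asarray(R, dtype=float).copy()
    R[np.abs(R) < 1e-12] = 0.0
    R[np.abs(R - 1.0) < 1e-12] = 1.0
    R[np.abs(R + 1.0) < 1e-12] = -1.0
    return R


def _angle_between(u: np.ndarray, v: np.ndarray) -> float:
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    return float(np.rad2deg(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def _transport_rotation(n_from: np.ndarray, n_to: np.ndarray) -> np.ndarray:
    """Minimal rotation taking n_from onto n_to (parallel transport)."""
    n_from = n_from / np.linalg.norm(n_from)
    n_to = n_to / np.linalg.norm(n_to)
    axis = np.cross(n_from, n_to)
    s = np.linalg.norm(axis)
    c = float(np.dot(n_from, n_to))
    if s < 1e-12:
        if c > 0:
            return np.eye(3)
        # antipodal: transport undefined; pick any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(n_from[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(n_from, perp)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(axis * np.pi).as_matrix()
    axis = axis / s
    ang = np.arctan2(s, c)
    return Rotation.from_rotvec(axis * ang).as_matrix()


def signed_inplane_angle(v_ref: np.ndarray, v: np.ndarray, normal: np.ndarray) -> float:
    """Signed angle (degrees, (-180, 180]) from v_ref to v about normal."""
    n = normal / np.linalg.norm(normal)
    a = v_ref - np.dot(v_ref, n) * n
    b = v - np.dot(v, n) * n
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("vector is (anti)parallel to the normal")
    a, b = a / na, b / nb
    ang = np.rad2deg(np.arctan2(np.dot(np.cross(a, b), n), np.dot(a, b)))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def pair_geometry(
    a: UnitAnnotation, b: UnitAnnotation, voxel_size: float
) -> PairGeometry:
    """Tilt / twist / distance / curvature geometry of a unit pair.

    Curvature is reported from both sides: ``curvature`` w.r.t. A's
    tangential plane and ``curvature_ba`` w.r.t. B's.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be positive")
    delta = (b.position - a.position) * voxel_size
    dist = float(np.linalg.norm(delta))
    if dist < 1e-9:
        raise ValueError("coincident unit positions")
    n_a, n_b = a.normal, b.normal
    tilt = _angle_between(n_a, n_b)
    # positive curvature: neighbor lies below the tangential plane,
    # i.e. the surface is convex as seen from outside
    curv_ab = _angle_between(n_a, delta) - 90.0
    curv_ba = _angle_between(n_b, -delta) - 90.0
    # twist: transport B's frame onto A's tangential plane, then compare
    # in-plane x axes about n_a
    x_a = a.rotation @ np.array([1.0, 0.0, 0.0])
    x_b = b.rotation @ np.array([1.0, 0.0, 0.0])
    t = _transport_rotation(n_b, n_a)
    twist = signed_inplane_angle(x_a, t @ x_b, n_a)
    return PairGeometry(
        distance=dist, tilt=tilt, twist=twist, curvature=curv_ab,
        curvature_ba=curv_ba,
    )
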