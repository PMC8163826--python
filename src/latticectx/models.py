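"""Rigid-body superposition and interface RMSD analysis of atomic models.

Class averages yield one rigid-body-fitted model per class; differences
between classes are quantified by pairwise interface RMSD: superpose two
models on a fixed domain selection, then measure the C-alpha RMSD of the
domain(s) across the interface without re-fitting.  Superposition is the
least-squares rigid transform (Kabsch, via scipy's align_vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import AtomModel

__all__ = [
    "InterfaceSpec",
    "Selection",
    "superpose",
    "rmsd_between",
    "interface_rmsd_matrix",
    "pentamer_model_rmsd",
]


@dataclass(frozen=True)
class Selection:
    """Atom selection by chain(s), residue range and atom name."""

    chain: tuple[str, ...] | None = None
    res_range: tuple[int, int] | None = None
    atom_name: str = "CA"

    def apply(self, m: AtomModel) -> AtomModel:
        out = m.select(chain=list(self.chain) if self.chain else None,
                       res_range=self.res_range, atom_name=self.atom_name)
        if len(out) == 0:
            raise ValueError(f"empty selection {self}")
        return out


@dataclass(frozen=True)
class InterfaceSpec:
    """Fixed-domain and measured-domain selections of an interface.

    kind is one of NTD-NTD, NTD-CTD, CTD-dimer, CTD-trimer; the fixed and
    measured selections must not overlap.
    """

    kind: str
    fixed: Selection
    measured: tuple[Selection, ...]

    def __post_init__(self):
        if self.kind not in ("NTD-NTD", "NTD-CTD", "CTD-dimer", "CTD-trimer"):
            raise ValueError(f"unknown interface kind {self.kind!r}")
        if not self.measured:
            raise ValueError("at least one measured selection required")


def _paired_coords(a: AtomModel, b: AtomModel
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Match atoms 1:1 by (chain, residue, atom name); order from a."""
    key_a = list(zip(a.chain, a.res_id, a.atom_name))
    key_b = {k: i for i, k in enumerate(zip(b.chain, b.res_id, b.atom_name))}
    missing = [k for k in key_a if k not in key_b]
    if missing:
        raise ValueError(
            f"{len(missing)} atoms unmatched between models, e.g. {missing[:3]}"
        )
    if len(set(key_a)) != len(key_a):
        raise ValueError("duplicate atom keys; pairing is ambiguous")
    idx = [key_b[k] for k in key_a]
    return a.coords, b.coords[idx]


def superpose(mobile: AtomModel, target: AtomModel,
              selection: Selection | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (rotation, translation, rmsd) where the transform maps mobile
    coordinates as ``x @ R.T + t``.  Atoms are paired by chain/residue/
    atom-name over the selection (default: all C-alpha).
    """
    sel = selection or Selection()
    ma, tb = sel.apply(mobile), sel.apply(target)
    X, Y = _paired_coords(ma, tb)
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Y - yc, X - xc)
    R = rot.as_matrix()
    t = yc - R @ xc
    rmsd = float(rssd / np.sqrt(len(X)))
    return R, t, rmsd


def rmsd_between(a: AtomModel, b: AtomModel) -> float:
    """Plain coordinate RMSD of 1:1 paired atoms (no fitting)."""
    X, Y = _paired_coords(a, b)
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))


def interface_rmsd_matrix(models: list[AtomModel], spec: InterfaceSpec
                          ) -> np.ndarray:
    """Pairwise interface RMSD across class models.

    For each model pair: superpose on the fixed-domain selection, then
    RMSD over the measured domain(s) without re-fitting.  Symmetric, zero
    diagonal.
    """
    n = len(models)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            R, t, _ = superpose(models[i], models[j], spec.fixed)
            moved = models[i].transformed(R, t)
            vals = []
            for sel in spec.measured:
                vals.append(rmsd_between(sel.apply(moved),
                                         sel.apply(models[j])) ** 2
                            * len(sel.apply(moved)))
            ntot = sum(len(sel.apply(moved)) for sel in spec.measured)
            out[i, j] = out[j, i] = float(np.sqrt(sum(vals) / ntot))
    return out


def pentamer_model_rmsd(model_a: AtomModel, model_b: AtomModel) -> float:
    """C-alpha RMSD of two pentamer models after global superposition."""
    R, t, rmsd = superpose(model_a, model_b, Selection(atom_name="CA"))
    return rmsd
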