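"""On-disk formats: MRC volumes, particle tables, PDB models, YAML config.

Volumes are MRC2014 (via gemmi), mode 2 float32, with an isotropic voxel
size in Angstrom taken from the cell parameters.  Particle tables are plain
tab-separated text with a fixed, order-independent column schema — diffable
and adequate at desk scale.  Header origins are recorded for provenance but
ignored by all processing (volumes start at index 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .geometry import EulerTriplet, UnitAnnotation

__all__ = [
    "FormatError",
    "DensityVolume",
    "read_volume",
    "write_volume",
    "AtomModel",
    "read_model",
    "write_model",
    "TABLE_COLUMNS",
    "units_to_table",
    "table_to_units",
    "read_table",
    "write_table",
    "read_config",
    "write_config",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass
class DensityVolume:
    """3D density grid, indexed ``grid[x, y, z]``, with voxel size in A."""

    grid: np.ndarray
    voxel_size: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        self.voxel_size = float(self.voxel_size)
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy(self) -> "DensityVolume":
        return DensityVolume(self.grid.copy(), self.voxel_size, self.origin)


def read_volume(path) -> DensityVolume:
    """Read an MRC/CCP4 volume; voxel size from the header cell."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"not a valid MRC map ({path.name}): {exc}") from exc
    grid = np.array(m.grid, copy=True, dtype=np.float32)
    sp = m.grid.spacing
    if max(sp) <= 0:
        raise FormatError(f"non-positive voxel size in header: {sp}")
    if (max(sp) - min(sp)) / max(sp) > 1e-3:
        raise FormatError(f"anisotropic voxel size unsupported: {sp}")
    try:
        origin = tuple(
            float(m.header_float(w)) for w in (50, 51, 52)
        )  # ORIGIN words of MRC2014
    except Exception:
        origin = (0.0, 0.0, 0.0)
    return DensityVolume(grid, float(np.mean(sp)), origin)


def write_volume(vol: DensityVolume, path) -> None:
    """Write mode-2 (float32) MRC with the volume's voxel size."""
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(vol.grid, dtype=np.float32))
    nx, ny, nz = vol.grid.shape
    v = vol.voxel_size
    m.grid.unit_cell = gemmi.UnitCell(nx * v, ny * v, nz * v, 90, 90, 90)
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for word, val in zip((50, 51, 52), vol.origin):
        m.set_header_float(word, float(val))
    m.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# particle tables

TABLE_COLUMNS = (
    "x", "y", "z", "phi", "theta", "psi", "cc",
    "unit_type", "network_id", "group", "subclass",
)
_NUMERIC = ("x", "y", "z", "phi", "theta", "psi", "cc")
_INT = ("network_id", "group", "subclass")


def units_to_table(units: list[UnitAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "x": u.position[0], "y": u.position[1], "z": u.position[2],
            "phi": u.euler.phi, "theta": u.euler.theta, "psi": u.euler.psi,
            "cc": u.cc, "unit_type": u.unit_type,
            "network_id": u.network_id, "group": u.group,
            "subclass": u.subclass,
        }
        for u in units
    ]
    return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))


def table_to_units(df: pd.DataFrame) -> list[UnitAnnotation]:
    _validate_columns(df)
    units = []
    for i, row in enumerate(df.itertuples(index=False)):
        units.append(
            UnitAnnotation(
                position=np.array([row.x, row.y, row.z], dtype=float),
                euler=EulerTriplet(row.phi, row.theta, row.psi),
                cc=float(row.cc),
                unit_type=str(row.unit_type),
                unit_id=i,
                network_id=int(row.network_id),
                group=int(row.group),
                subclass=int(row.subclass),
            )
        )
    return units


def _validate_columns(df: pd.DataFrame) -> None:
    unknown = set(df.columns) - set(TABLE_COLUMNS)
    if unknown:
        raise FormatError(
            f"unknown columns {sorted(unknown)}; accepted columns are "
            f"{list(TABLE_COLUMNS)}"
        )
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"missing columns {sorted(missing)}")


def write_table(df: pd.DataFrame, path) -> None:
    _validate_columns(df)
    df = df[list(TABLE_COLUMNS)]
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ("," if "," in header else r"\s+")
    df = pd.read_csv(path, sep=sep, comment="#",
                     float_precision="round_trip")
    _validate_columns(df)
    df = df[list(TABLE_COLUMNS)]
    for c in _NUMERIC:
        df[c] = df[c].astype(float)
    for c in _INT:
        df[c] = df[c].astype(int)
    return df


# ---------------------------------------------------------------------------
# atomic models

@dataclass
class AtomModel:
    """Minimal atomic coordinate model for superposition/RMSD analysis."""

    chain: np.ndarray      # str array
    res_id: np.ndarray     # int array, 1-based
    atom_name: np.ndarray  # str array
    element: np.ndarray    # str array
    coords: np.ndarray     # (n, 3) float, Angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        for arr in (self.chain, self.res_id, self.atom_name, self.element):
            if len(arr) != n:
                raise ValueError("field length mismatch")

    def __len__(self) -> int:
        return len(self.coords)

    def select(self, chain=None, res_range=None, atom_name=None) -> "AtomModel":
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            chains = {chain} if isinstance(chain, str) else set(chain)
            mask &= np.isin(self.chain, list(chains))
        if res_range is not None:
            lo, hi = res_range
            mask &= (self.res_id >= lo) & (self.res_id <= hi)
        if atom_name is not None:
            names = {atom_name} if isinstance(atom_name, str) else set(atom_name)
            mask &= np.isin(self.atom_name, list(names))
        return AtomModel(
            self.chain[mask], self.res_id[mask], self.atom_name[mask],
            self.element[mask], self.coords[mask],
        )

    def ca(self) -> "AtomModel":
        out = self.select(atom_name="CA")
        if len(out) == 0:
            raise ValueError("no C-alpha atoms in selection")
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "AtomModel":
        return AtomModel(
            self.chain, self.res_id, self.atom_name, self.element,
            self.coords @ np.asarray(rotation).T + np.asarray(translation),
        )


def read_model(path) -> AtomModel:
    """Read ATOM/HETATM records from a PDB file (via biotite)."""
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(str(path))
        arr = pdb.get_structure(model=1)
    except Exception as exc:
        raise FormatError(f"not a valid PDB file ({Path(path).name}): {exc}") from exc
    if arr.array_length() == 0:
        raise FormatError(f"no atoms in {Path(path).name}")
    return AtomModel(
        chain=np.asarray(arr.chain_id, dtype=object),
        res_id=np.asarray(arr.res_id, dtype=int),
        atom_name=np.asarray(arr.atom_name, dtype=object),
        element=np.asarray(arr.element, dtype=object),
        coords=np.asarray(arr.coord, dtype=float),
    )


def write_model(model: AtomModel, path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arr = struc.AtomArray(len(model))
    arr.chain_id = np.asarray(model.chain, dtype="U4")
    arr.res_id = np.asarray(model.res_id, dtype=int)
    arr.res_name = np.full(len(model), "ALA", dtype="U3")
    arr.atom_name = np.asarray(model.atom_name, dtype="U6")
    arr.element = np.asarray(model.element, dtype="U2")
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# configuration

def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError("run configuration must be a YAML mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
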