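"""End-to-end pipeline: simulate -> match -> network -> classify -> report.

One configuration mapping drives all stages; every run writes its
resolved configuration and a machine-readable summary next to the stage
outputs, and a single seed fans out to per-stage seeds through a counter
so each stage is reproducible in isolation.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path

from . import io_formats
from .classify import classify_pairs, local_symmetry
from .connectivity import ConnectivityCriteria, build_networks
from .geometry import UnitAnnotation
from .io_formats import write_config
from .matching import MatchConfig, peaks_to_units, scan_orientations
from .synthetic import (
    WedgeSpec,
    add_noise,
    apply_missing_wedge,
    build_icosahedron,
    build_polyhedron,
    build_tube,
    default_templates,
    render_density,
)

__all__ = ["RunConfig", "default_config", "run_pipeline"]

_KNOWN_KEYS = {
    "seed", "out_dir", "log_level",
    "simulate", "match", "network", "classify",
}
_SIM_KEYS = {"kind", "spacing", "voxel", "box", "noise_sigma", "wedge",
             "n_around", "n_rings", "T", "n_units", "elongation"}
_MATCH_KEYS = {"phi_step", "other_step", "bandpass", "mask_radius",
               "peak_min_separation", "min_cc", "templates"}
_NET_KEYS = {"min_spacing", "max_spacing", "min_curvature", "max_curvature",
             "max_normal_diff", "min_network_size"}


class RunConfig(dict):
    """Validated pipeline configuration (rejects unknown keys)."""

    def __init__(self, data: dict):
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}; "
                             f"accepted: {sorted(_KNOWN_KEYS)}")
        for section, keys in (("simulate", _SIM_KEYS), ("match", _MATCH_KEYS),
                              ("network", _NET_KEYS)):
            extra = set(data.get(section, {})) - keys
            if extra:
                raise ValueError(
                    f"unknown keys {sorted(extra)} in section {section!r}")
        net = data.get("network", {})
        if ("min_spacing" in net and "max_spacing" in net
                and not net["min_spacing"] < net["max_spacing"]):
            raise ValueError("min_spacing must be < max_spacing")
        super().__init__(data)


def default_config(kind: str = "polyhedron", seed: int = 0) -> RunConfig:
    return RunConfig({
        "seed": seed,
        "out_dir": "run_out",
        "simulate": {
            "kind": kind, "spacing": 80.0, "voxel": 4.0, "box": 160,
            "noise_sigma": 0.0, "wedge": None, "n_units": 42,
            "elongation": 0.0, "n_around": 12, "n_rings": 10, "T": 3,
        },
        "match": {"phi_step": 30.0, "other_step": 20.0,
                  "peak_min_separation": 60.0, "min_cc": 0.3,
                  "mask_radius": 45.0},
        "network": {},
    })


def _stage_seed(seed: int, stage: int) -> int:
    return (int(seed) * 1000 + stage) % (2 ** 31 - 1)


def simulate_stage(cfg: dict, seed: int):
    kind = cfg.get("kind", "polyhedron")
    spacing = float(cfg.get("spacing", 80.0))
    if kind == "tube":
        g = build_tube(int(cfg.get("n_around", 12)),
                       int(cfg.get("n_rings", 10)), spacing)
    elif kind in ("t1", "t3"):
        g = build_icosahedron(1 if kind == "t1" else 3, spacing)
    elif kind == "icosahedron":
        g = build_icosahedron(int(cfg.get("T", 3)), spacing)
    elif kind == "polyhedron":
        g = build_polyhedron(int(cfg.get("n_units", 42)),
                             float(cfg.get("elongation", 0.0)),
                             seed, spacing)
    else:
        raise ValueError(f"unknown lattice kind {kind!r}")
    vol, truth = render_density(g, float(cfg.get("voxel", 4.0)),
                                int(cfg.get("box", 160)))
    if cfg.get("wedge"):
        w = cfg["wedge"]
        vol = apply_missing_wedge(vol, WedgeSpec(
            w.get("tilt_axis", "x"), float(w.get("min_angle", -60)),
            float(w.get("max_angle", 60))))
    sigma = float(cfg.get("noise_sigma", 0.0))
    if sigma > 0:
        vol = add_noise(vol, sigma, seed)
    return vol, truth


def run_pipeline(config: dict | RunConfig, out_dir=None) -> Path:
    """Run simulate -> match -> network -> classify and write a summary.

    Returns the output directory.  All tabular outputs use the particle
    table schema; volumes are MRC; the summary is JSON.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(config)
    out = Path(out_dir or cfg.get("out_dir", "run_out"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    write_config(dict(cfg), out / "resolved_config.yaml")

    vol, truth = simulate_stage(cfg.get("simulate", {}),
                                _stage_seed(seed, 0))
    io_formats.write_volume(vol, out / "volume.mrc")
    io_formats.write_table(io_formats.units_to_table(truth.units),
                           out / "truth.tsv")

    mcfg_kw = {k: v for k, v in cfg.get("match", {}).items()
               if k != "templates"}
    if "bandpass" in mcfg_kw:
        mcfg_kw["bandpass"] = tuple(mcfg_kw["bandpass"])
    mcfg = MatchConfig(**mcfg_kw)
    templates = {k: v for k, v in default_templates().items()
                 if k in ("hexamer_C6", "pentamer_C5")}
    peaks = scan_orientations(vol, templates, mcfg)
    peak_units = peaks_to_units(peaks)
    io_formats.write_table(io_formats.units_to_table(peak_units),
                           out / "peaks.tsv")

    crit = ConnectivityCriteria(**cfg.get("network", {}))
    networks = build_networks(peak_units, crit, vol.voxel_size,
                              spacing_hint=cfg.get("simulate", {})
                              .get("spacing", None))
    annotated: list[UnitAnnotation] = []
    summary_networks = []
    for g in networks:
        contexts = classify_pairs(g)
        group_census = Counter(pc.group for pc in contexts)
        sym_census = Counter()
        for i, u in enumerate(g.units):
            if not u.is_pentamer and len(g.neighbors(i)) == 6:
                sym_census[local_symmetry(g, i)] += 1
        for i, u in enumerate(g.units):
            incident = [pc.group for pc in contexts if i in pc.edge]
            u.group = min(incident) if incident else 0
        annotated.extend(g.units)
        summary_networks.append({
            "network_id": g.network_id,
            "n_units": len(g),
            "n_pentamers": g.pentamer_count,
            "n_hexamers": g.hexamer_count,
            "closed": bool(g.closed),
            "group_census": {str(k): int(v)
                             for k, v in sorted(group_census.items())},
            "local_symmetry": {k: int(v)
                               for k, v in sorted(sym_census.items())},
        })
    io_formats.write_table(io_formats.units_to_table(annotated),
                           out / "classified.tsv")

    summary = {
        "seed": seed,
        "n_truth_units": len(truth.units),
        "n_truth_pentamers": truth.pentamer_count,
        "n_peaks": len(peaks),
        "n_networks": len(networks),
        "networks": summary_networks,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return out
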