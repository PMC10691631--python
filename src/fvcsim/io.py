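"""File formats: YAML presets and plans, CSV planar maps, voxel grids.

Planar maps are CSV matrices with a ``#``-prefixed header block carrying the
coordinates and provenance (version, seed, config hash) so QA comparisons are
reproducible. Dose grids are written either as long-format CSV
(x, y, z, dose) or as a small binary voxel format with a self-describing text
header (dims, spacing, origin, units, then float32 values in C order).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .beam_model import BeamPreset, MLCField
from .dose_engine import DoseGrid, PlanarDose
from .exceptions import ValidationError
from .planning import ArcSpec, PlanSpec

__all__ = ["load_preset", "get_preset", "save_plan", "load_plan",
           "write_planar_csv", "read_planar_csv", "write_grid_csv",
           "write_grid_voxels", "read_grid_voxels", "config_hash"]

_BUILTIN_PRESETS = {"6FFF": "6fff.yaml", "10FFF": "10fff.yaml"}


def load_preset(path) -> BeamPreset:
    """Load a beam preset from a YAML file (see the packaged presets for the
    schema; lengths in mm, dose in cGy)."""
    with open(path) as f:
        doc = yaml.safe_load(f)
    try:
        tmr = np.asarray(doc["tmr"], dtype=float)
        of = np.asarray(doc["of_table"], dtype=float)
        return BeamPreset(
            energy_label=str(doc["energy_label"]),
            sigma_penumbra=float(doc["sigma_penumbra_mm"]),
            mlc_transmission=float(doc["mlc_transmission"]),
            jaw_transmission=float(doc["jaw_transmission"]),
            sigma_lcpe=float(doc["sigma_lcpe_mm"]),
            leaf_end_offset=float(doc["leaf_end_offset_mm"]),
            leaf_side_offset=float(doc["leaf_side_offset_mm"]),
            tmr_depths=tmr[:, 0], tmr_values=tmr[:, 1],
            of_sizes=of[:, 0], of_values=of[:, 1],
            dmu_cal=float(doc["dmu_cal_cgy_per_mu"]),
            max_dose_rate=float(doc.get("max_dose_rate_mu_per_min", 2400.0)),
        )
    except KeyError as e:
        raise ValidationError(f"preset file {path} missing key {e}") from e


def get_preset(name: str) -> BeamPreset:
    """One of the packaged presets: '6FFF' or '10FFF'."""
    key = name.upper()
    if key not in _BUILTIN_PRESETS:
        raise ValidationError(f"unknown preset {name!r}; available: {list(_BUILTIN_PRESETS)}")
    ref = resources.files("fvcsim").joinpath("presets", _BUILTIN_PRESETS[key])
    with resources.as_file(ref) as p:
        return load_preset(p)


def _field_to_dict(f: MLCField) -> dict:
    return dict(x1=f.x1, x2=f.x2, y1=f.y1, y2=f.y2,
                jaw_x=f.jaw_x, jaw_y=f.jaw_y, leaf_shift=f.leaf_shift)


def save_plan(plan: PlanSpec, path) -> None:
    doc = dict(
        preset_ref=plan.preset_ref, total_mu=plan.total_mu,
        prescription_cgy=plan.prescription,
        normalization_mode=plan.normalization_mode,
        field=_field_to_dict(plan.field),
        arcs=[dict(couch_angle=a.couch_angle, collimator_angle=a.collimator_angle,
                   gantry_start=a.gantry_start, gantry_stop=a.gantry_stop,
                   direction=a.direction, weight=a.weight) for a in plan.arcs],
    )
    with open(path, "w") as f:
        yaml.safe_dump(doc, f, sort_keys=False)


def load_plan(path) -> PlanSpec:
    with open(path) as f:
        doc = yaml.safe_load(f)
    try:
        arcs = tuple(ArcSpec(**a) for a in doc["arcs"])
        return PlanSpec(arcs=arcs, field=MLCField(**doc["field"]),
                        preset_ref=doc["preset_ref"], total_mu=float(doc["total_mu"]),
                        prescription=float(doc["prescription_cgy"]),
                        normalization_mode=doc["normalization_mode"])
    except (KeyError, TypeError) as e:
        raise ValidationError(f"malformed plan file {path}: {e}") from e


def _header_lines(meta: dict | None) -> list[str]:
    lines = [f"# fvcsim {__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def write_planar_csv(plane: PlanarDose, path, meta: dict | None = None) -> None:
    """CSV matrix: header block, then an x-coordinate header row and one row
    per y coordinate (y value first). Doses in cGy."""
    lines = _header_lines(meta)
    lines.append("y_mm\\x_mm," + ",".join(f"{v:.6g}" for v in plane.x))
    for j, yv in enumerate(plane.y):
        row = ",".join(f"{plane.values[i, j]:.8g}" for i in range(plane.x.size))
        lines.append(f"{yv:.6g}," + row)
    Path(path).write_text("\n".join(lines) + "\n")


def read_planar_csv(path) -> PlanarDose:
    rows = []
    x = None
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split(",")
        if x is None:
            x = np.array([float(v) for v in parts[1:]])
            y = []
            continue
        y.append(float(parts[0]))
        rows.append([float(v) for v in parts[1:]])
    if x is None or not rows:
        raise ValidationError(f"no planar data found in {path}")
    vals = np.asarray(rows).T  # rows are y, columns x -> values[i, j] at (x_i, y_j)
    return PlanarDose(x=x, y=np.asarray(y), values=vals)


def write_grid_csv(grid: DoseGrid, path, meta: dict | None = None) -> None:
    """Long-format CSV: one (x_mm, y_mm, z_mm, dose_cgy) row per voxel."""
    lines = _header_lines(meta)
    lines.append("x_mm,y_mm,z_mm,dose_cgy")
    pts = grid.points()
    vals = grid.values.ravel()
    for p, v in zip(pts, vals):
        lines.append(f"{p[0]:.6g},{p[1]:.6g},{p[2]:.6g},{v:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_grid_voxels(grid: DoseGrid, path, meta: dict | None = None) -> None:
    """Binary voxel format: UTF-8 text header terminated by a blank line,
    then float32 dose values (cGy) in C order."""
    header = _header_lines(meta)
    header += [
        "format: fvcsim-voxels-1",
        f"dims: {grid.dims[0]} {grid.dims[1]} {grid.dims[2]}",
        f"spacing_mm: {grid.spacing[0]:.6g} {grid.spacing[1]:.6g} {grid.spacing[2]:.6g}",
        f"origin_mm: {grid.origin[0]:.6g} {grid.origin[1]:.6g} {grid.origin[2]:.6g}",
        "units: cGy",
        "dtype: float32 C-order",
        "", "",
    ]
    with open(path, "wb") as f:
        f.write("\n".join(header).encode())
        f.write(grid.values.astype(np.float32).tobytes())


def read_grid_voxels(path) -> DoseGrid:
    raw = Path(path).read_bytes()
    end = raw.index(b"\n\n") + 2
    fields = {}
    for line in raw[:end].decode().splitlines():
        if ":" in line and not line.startswith("#"):
            k, v = line.split(":", 1)
            fields[k.strip()] = v.strip()
    dims = tuple(int(v) for v in fields["dims"].split())
    spacing = np.array([float(v) for v in fields["spacing_mm"].split()])
    origin = np.array([float(v) for v in fields["origin_mm"].split()])
    vals = np.frombuffer(raw[end:], dtype=np.float32).reshape(dims).astype(float)
    return DoseGrid(origin=origin, spacing=spacing, dims=dims, values=vals)


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
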