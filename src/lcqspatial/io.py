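"""Readers and writers for the centroid / alveolus / adjacency / mask dialects.

All tables are comma-separated UTF-8 text with a mandatory header, decimal
points, and no quoting of numeric fields.  Lengths are serialised in um with
3 decimal places (the generator itself works on a 1 nm grid, so round trips
are lossless); quotients and p-values with 6 significant digits.  The mask is
a single-channel PNG with 0 = tissue, 255 = void; its pixel size lives in the
config sidecar.
"""

from __future__ import annotations

import csv
import dataclasses
import math
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import yaml

from .errors import ConfigError, SchemaError
from .lcq_core import COMPARTMENTS, CellRecord, LCQResult, PointPattern
from .synthetic_tissue import Alveolus, LobuleAdjacency, SimConfig, VoidMask

__all__ = [
    "CELLS_HEADER",
    "read_cells",
    "write_cells",
    "read_alveoli",
    "write_alveoli",
    "read_adjacency",
    "write_adjacency",
    "read_mask",
    "write_mask",
    "read_sim_config",
    "write_sim_config",
    "write_simulation",
    "read_simulation",
    "write_lcq_results",
]

CELLS_HEADER = ["cell_id", "x_um", "y_um", "label", "compartment", "alveolus_id"]
ALVEOLI_HEADER = [
    "alveolus_id",
    "lobule_id",
    "centre_x_um",
    "centre_y_um",
    "lumen_major_um",
    "lumen_minor_um",
    "orientation_rad",
    "committed",
]
ADJACENCY_HEADER = ["alveolus_a", "alveolus_b", "distance_um"]

_LABELS = {"pos": True, "neg": False}


def _fmt_len(v: float) -> str:
    return f"{v:.3f}"


def _fmt_q(v: float) -> str:
    return f"{v:.6g}"


def write_cells(pattern: PointPattern, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CELLS_HEADER)
        for c in pattern.cells:
            w.writerow(
                [
                    c.cell_id,
                    _fmt_len(c.x),
                    _fmt_len(c.y),
                    c.label,
                    c.compartment,
                    "" if c.alveolus_id is None else c.alveolus_id,
                ]
            )
    return path


def read_cells(path: str | Path, domain: Optional[tuple[float, float]] = None) -> PointPattern:
    """Read a centroid table into a validated :class:`PointPattern`.

    Rows with unparseable coordinates or labels are rejected with their line
    numbers; a missing or reordered header is a schema error.  When ``domain``
    is not given, the bounding box of the cells (padded by 1 um) is used.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cells file not found: {path}")
    errors: list[str] = []
    cells: list[CellRecord] = []
    seen_ids: set[int] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file; expected header {','.join(CELLS_HEADER)}")
        if header != CELLS_HEADER:
            raise SchemaError(
                f"{path}: bad header {header}; expected {CELLS_HEADER}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CELLS_HEADER):
                errors.append(f"line {lineno}: expected {len(CELLS_HEADER)} fields, got {len(row)}")
                continue
            cid_s, x_s, y_s, label_s, comp_s, alv_s = row
            try:
                cid = int(cid_s)
            except ValueError:
                errors.append(f"line {lineno}: bad cell_id {cid_s!r}")
                continue
            try:
                x, y = float(x_s), float(y_s)
                if not (math.isfinite(x) and math.isfinite(y)):
                    raise ValueError
            except ValueError:
                errors.append(f"line {lineno}: unparseable coordinates ({x_s!r}, {y_s!r})")
                continue
            if label_s not in _LABELS:
                errors.append(f"line {lineno}: bad label {label_s!r} (expected 'pos' or 'neg')")
                continue
            if comp_s not in COMPARTMENTS:
                errors.append(
                    f"line {lineno}: bad compartment {comp_s!r} (expected one of {COMPARTMENTS})"
                )
                continue
            alv: Optional[int] = None
            if alv_s != "":
                try:
                    alv = int(alv_s)
                except ValueError:
                    errors.append(f"line {lineno}: bad alveolus_id {alv_s!r}")
                    continue
            if cid in seen_ids:
                errors.append(f"line {lineno}: duplicate cell_id {cid}")
                continue
            seen_ids.add(cid)
            cells.append(CellRecord(cid, x, y, _LABELS[label_s], comp_s, alv))
    if errors:
        shown = "; ".join(errors[:10])
        more = f" (+{len(errors) - 10} more)" if len(errors) > 10 else ""
        raise SchemaError(f"{path}: {shown}{more}")
    if not cells:
        raise SchemaError(f"{path}: empty pattern (header only, no cell rows)")
    if domain is None:
        xs = [c.x for c in cells]
        ys = [c.y for c in cells]
        domain = (max(xs) + 1.0, max(ys) + 1.0)
    return PointPattern(cells=cells, domain=domain)


def write_alveoli(alveoli: Sequence[Alveolus], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ALVEOLI_HEADER)
        for a in alveoli:
            w.writerow(
                [
                    a.id,
                    a.lobule_id,
                    _fmt_len(a.lumen_centre[0]),
                    _fmt_len(a.lumen_centre[1]),
                    _fmt_len(a.lumen_major_axis),
                    _fmt_len(a.lumen_minor_axis),
                    f"{a.orientation:.6f}",
                    "true" if a.committed else "false",
                ]
            )
    return path


def read_alveoli(path: str | Path) -> list[Alveolus]:
    path = Path(path)
    alveoli = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ALVEOLI_HEADER:
            raise SchemaError(f"{path}: bad header {header}; expected {ALVEOLI_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                alveoli.append(
                    Alveolus(
                        id=int(row[0]),
                        lobule_id=int(row[1]),
                        lumen_centre=(float(row[2]), float(row[3])),
                        lumen_major_axis=float(row[4]),
                        lumen_minor_axis=float(row[5]),
                        orientation=float(row[6]),
                        committed={"true": True, "false": False}[row[7]],
                    )
                )
            except (ValueError, KeyError, IndexError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
    if not alveoli:
        raise SchemaError(f"{path}: no alveoli")
    return alveoli


def link_members(alveoli: Sequence[Alveolus], pattern: PointPattern) -> None:
    """Rebuild epithelial membership lists from the cell table, in cell order."""
    by_id = {a.id: a for a in alveoli}
    for a in alveoli:
        a.member_cell_ids.clear()
    for c in pattern.cells:
        if c.compartment == "epithelial" and c.alveolus_id is not None:
            if c.alveolus_id not in by_id:
                raise SchemaError(
                    f"cell {c.cell_id} references unknown alveolus {c.alveolus_id}"
                )
            by_id[c.alveolus_id].member_cell_ids.append(c.cell_id)


def write_adjacency(adjacency: LobuleAdjacency, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(ADJACENCY_HEADER)
        for a, b, data in sorted(adjacency.graph.edges(data=True)):
            w.writerow([a, b, _fmt_len(data.get("distance", float("nan")))])
    return path


def read_adjacency(path: str | Path, alveoli: Sequence[Alveolus]) -> LobuleAdjacency:
    path = Path(path)
    graph = nx.Graph()
    for a in alveoli:
        graph.add_node(a.id, lobule_id=a.lobule_id)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ADJACENCY_HEADER:
            raise SchemaError(f"{path}: bad header {header}; expected {ADJACENCY_HEADER}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                a, b, d = int(row[0]), int(row[1]), float(row[2])
            except (ValueError, IndexError) as exc:
                raise SchemaError(f"{path}: line {lineno}: {exc}") from exc
            if a not in graph or b not in graph:
                raise SchemaError(f"{path}: line {lineno}: edge references unknown alveolus")
            graph.add_edge(a, b, distance=d)
    return LobuleAdjacency(graph=graph)


def write_mask(mask: VoidMask, path: str | Path) -> Path:
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, mask.raster.astype(np.uint8))
    return path


def read_mask(path: str | Path, pixel_size: float, origin=(0.0, 0.0)) -> VoidMask:
    import imageio.v3 as iio

    raster = np.asarray(iio.imread(Path(path)))
    if raster.ndim == 3:
        raster = raster[..., 0]
    return VoidMask(raster=raster.astype(np.uint8), pixel_size=pixel_size,
                    origin=(float(origin[0]), float(origin[1])))


def sim_config_to_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["seed"] = int(d["seed"])
    return {k: (float(v) if isinstance(v, (np.floating,)) else v) for k, v in d.items()}


def sim_config_from_dict(d: dict) -> SimConfig:
    fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(d) - fields
    if unknown:
        raise ConfigError(f"unknown SimConfig keys: {sorted(unknown)}")
    missing = fields - set(d)
    if missing:
        raise ConfigError(f"missing SimConfig keys: {sorted(missing)}")
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg


def write_sim_config(config: SimConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(sim_config_to_dict(config), fh, sort_keys=True)
    return path


def read_sim_config(path: str | Path) -> SimConfig:
    with open(Path(path), encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ConfigError(f"{path}: expected a flat key-value mapping")
    return sim_config_from_dict(d)


def write_simulation(
    pattern: PointPattern,
    alveoli: Sequence[Alveolus],
    adjacency: LobuleAdjacency,
    mask: VoidMask,
    out_dir: str | Path,
    config: Optional[SimConfig] = None,
) -> dict[str, Path]:
    """Write the full simulation file set; a round-trip read reproduces the objects."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {
        "cells": write_cells(pattern, out_dir / "cells.csv"),
        "alveoli": write_alveoli(alveoli, out_dir / "alveoli.csv"),
        "adjacency": write_adjacency(adjacency, out_dir / "adjacency.csv"),
        "mask": write_mask(mask, out_dir / "mask.png"),
    }
    if config is not None:
        files["config"] = write_sim_config(config, out_dir / "config.yaml")
    return files


def read_simulation(
    in_dir: str | Path,
) -> tuple[PointPattern, list[Alveolus], LobuleAdjacency, VoidMask, Optional[SimConfig]]:
    in_dir = Path(in_dir)
    config = None
    pixel_size = 2.0
    domain = None
    cfg_path = in_dir / "config.yaml"
    if cfg_path.exists():
        config = read_sim_config(cfg_path)
        pixel_size = config.mask_pixel_size
        domain = (config.field_width, config.field_height)
    pattern = read_cells(in_dir / "cells.csv", domain=domain)
    alveoli = read_alveoli(in_dir / "alveoli.csv")
    link_members(alveoli, pattern)
    adjacency = read_adjacency(in_dir / "adjacency.csv", alveoli)
    mask = read_mask(in_dir / "mask.png", pixel_size=pixel_size)
    pattern.void_mask = mask
    return pattern, alveoli, adjacency, mask, config


def write_lcq_results(
    result: LCQResult, pattern: PointPattern, path: str | Path
) -> Path:
    """Per-cell results table: cell_id,x_um,y_um,label,h_um,lcq,p_raw,q_fdr,significant."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        cols = ["cell_id", "x_um", "y_um", "label", "h_um", "lcq"]
        has_p = result.p_raw is not None
        if has_p:
            cols += ["p_raw", "q_fdr", "significant"]
        w.writerow(cols)
        for i, c in enumerate(pattern.cells):
            row = [
                c.cell_id,
                _fmt_len(c.x),
                _fmt_len(c.y),
                c.label,
                _fmt_len(result.h[i]),
                _fmt_q(result.lcq[i]),
            ]
            if has_p:
                row += [
                    _fmt_q(result.p_raw[i]),
                    _fmt_q(result.q_fdr[i]),
                    "true" if result.significant[i] else "false",
                ]
            w.writerow(row)
    return path
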