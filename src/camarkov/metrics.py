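"""Landscape-pattern metrics on categorical rasters.

Patches (maximal connected same-class regions, 8-neighbour by default)
are the atomic unit. Class-scale indices: patch count NP, mean patch
size MPS (ha), largest patch index LPI (% of landscape), patch-size
coefficient of variation PSCV (%, population sd), landscape division
DIVISION, aggregation index AI (%). Landscape scale adds Shannon
diversity SHDI. Conventions follow the standard raster landscape-metric
definitions: 8-connectivity for patches, rook single-count adjacencies
for AI, population standard deviation for PSCV, LPI normalized by total
landscape area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import measure

from .raster import LandCoverGrid


@dataclass
class PatchLabelling:
    """Connected-component labelling of a land-cover map.

    ``labels`` is 0 on nodata; patch ids are 1..n in row-major order of
    each patch's first cell. ``patches`` has one row per patch: label,
    code, cells, area_ha.
    """

    labels: np.ndarray
    patches: pd.DataFrame
    connectivity: int


def label_patches(grid: LandCoverGrid, connectivity: int = 8) -> PatchLabelling:
    """Delineate single-class connected patches (4- or 8-neighbour)."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    skc = 1 if connectivity == 4 else 2
    labels = np.zeros(grid.shape, dtype=np.int32)
    next_label = 0
    for k in grid.classes:
        mask = (grid.codes == k) & grid.valid_mask
        if not mask.any():
            continue
        lab = measure.label(mask, connectivity=skc)
        labels[mask] = lab[mask] + next_label
        next_label = int(labels.max())
    # relabel in row-major first-cell order for determinism
    flat = labels.ravel()
    vals, first_idx, counts = np.unique(flat, return_index=True, return_counts=True)
    keep = vals != 0
    vals, first_idx, counts = vals[keep], first_idx[keep], counts[keep]
    order = np.argsort(first_idx, kind="stable")
    remap = np.zeros(next_label + 1, dtype=np.int32)
    remap[vals[order]] = np.arange(1, len(vals) + 1)
    labels = remap[labels]
    patches = pd.DataFrame({
        "label": np.arange(1, len(vals) + 1),
        "code": grid.codes.ravel()[first_idx[order]].astype(int),
        "cells": counts[order].astype(int),
        "area_ha": counts[order] * grid.cell_area_ha,
    }).set_index("label")
    return PatchLabelling(labels=labels, patches=patches, connectivity=connectivity)


def _like_adjacencies(mask: np.ndarray) -> int:
    """Rook (4-neighbour) like adjacencies, each pair counted once."""
    horiz = int((mask[:, :-1] & mask[:, 1:]).sum())
    vert = int((mask[:-1, :] & mask[1:, :]).sum())
    return horiz + vert


def _max_like_adjacencies(n_cells: int) -> int:
    """Largest achievable rook adjacency count for n cells (square-fill bound)."""
    n = int(np.floor(np.sqrt(n_cells)))
    m = n_cells - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def aggregation_index(grid: LandCoverGrid, class_code: int) -> float:
    """AI = 100 * like adjacencies / square-fill bound; 100 for a single cell."""
    mask = (grid.codes == class_code) & grid.valid_mask
    n_cells = int(mask.sum())
    if n_cells == 0:
        raise ValueError(f"class {class_code} absent")
    max_g = _max_like_adjacencies(n_cells)
    if max_g == 0:
        return 100.0
    return 100.0 * _like_adjacencies(mask) / max_g


def class_metrics(grid: LandCoverGrid, connectivity: int = 8) -> pd.DataFrame:
    """Class-scale metric rows (NP, MPS, LPI, PSCV, DIVISION, AI).

    Absent classes are omitted. Areas in hectares; LPI and AI in percent.
    """
    labelling = label_patches(grid, connectivity)
    patches = labelling.patches
    total_area = grid.n_valid * grid.cell_area_ha
    rows = []
    for k in grid.classes:
        pk = patches[patches["code"] == k]
        if pk.empty:
            continue
        areas = pk["area_ha"].to_numpy()
        np_k = len(areas)
        mps = areas.sum() / np_k
        lpi = 100.0 * areas.max() / total_area
        pscv = 100.0 * areas.std() / mps  # population sd
        division = 1.0 - float(((areas / total_area) ** 2).sum())
        rows.append({"code": k, "NP": np_k, "MPS": mps, "LPI": lpi,
                     "PSCV": pscv, "DIVISION": division,
                     "AI": aggregation_index(grid, k)})
    return pd.DataFrame(rows).set_index("code")


def landscape_metrics(grid: LandCoverGrid, connectivity: int = 8) -> pd.Series:
    """Landscape-scale metric row (NP, MPS, LPI, PSCV, AI, SHDI).

    AI is the class-area-weighted mean of class AIs; SHDI the Shannon
    entropy of class-area proportions.
    """
    if grid.n_valid == 0:
        raise ValueError("empty landscape")
    labelling = label_patches(grid, connectivity)
    areas = labelling.patches["area_ha"].to_numpy()
    total_area = grid.n_valid * grid.cell_area_ha
    np_all = len(areas)
    mps = areas.sum() / np_all
    cm = class_metrics(grid, connectivity)
    counts = grid.class_counts()
    props = np.array([counts[k] for k in cm.index], dtype=float)
    props /= props.sum()
    ai = float((props * cm["AI"].to_numpy()).sum())
    shdi = float(-(props * np.log(props)).sum())
    return pd.Series({
        "NP": np_all,
        "MPS": mps,
        "LPI": 100.0 * areas.max() / total_area,
        "PSCV": 100.0 * areas.std() / mps,
        "AI": ai,
        "SHDI": shdi,
    })


def metrics_report(grid: LandCoverGrid, connectivity: int = 8) -> dict:
    """Class rows and landscape row for one map, as plain tables."""
    return {
        "label": grid.label,
        "class": class_metrics(grid, connectivity),
        "landscape": landscape_metrics(grid, connectivity),
    }


def change_table(grids: list[LandCoverGrid], connectivity: int = 8) -> pd.DataFrame:
    """Landscape-scale change between the first and last dated maps.

    Reports each index at both dates plus absolute and percent change.
    """
    if len(grids) < 2:
        raise ValueError("need at least two dated maps")
    first, last = grids[0], grids[-1]
    a = landscape_metrics(first, connectivity)
    b = landscape_metrics(last, connectivity)
    out = pd.DataFrame({first.label or "first": a, last.label or "last": b})
    out["change"] = b - a
    with np.errstate(divide="ignore", invalid="ignore"):
        out["change_pct"] = 100.0 * (b - a) / a
    return out
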