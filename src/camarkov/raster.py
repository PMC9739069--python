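"""Core raster data model: categorical land-cover grids and driver stacks.

The package works on plain 2-D numpy lattices. A :class:`LandCoverGrid`
holds one dated categorical map (codes 1-6, 0 = nodata); a
:class:`DriverStack` holds named continuous layers congruent with it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Nodata code for categorical rasters. Cells with this code are excluded
#: from every statistic in the package.
NODATA = 0

#: Land-cover legend: 6-class scheme for agro-pastoral landscapes.
DEFAULT_LEGEND: dict[int, str] = {
    1: "Cultivated land",
    2: "Forest",
    3: "Grassland",
    4: "Water",
    5: "Built up",
    6: "Deserted land",
}

#: Globeland30 code -> 6-class code. Shrub land and wetland fold into
#: grassland; bare land and permanent snow/ice fold into deserted land.
GLOBELAND30_MAP: dict[int, int] = {
    10: 1,  # Cultivated land
    20: 2,  # Forest
    30: 3,  # Grassland
    40: 3,  # Shrub land
    50: 3,  # Wetland
    60: 4,  # Water bodies
    80: 5,  # Artificial surfaces
    90: 6,  # Bare land
    100: 6,  # Permanent snow and ice
}

#: Canonical driver-layer taxonomy (4 categories, 13 layers).
DRIVER_NAMES: tuple[str, ...] = (
    # physical geography
    "elevation", "aspect", "slope",
    # climate
    "precipitation", "temperature",
    # accessibility
    "dist_builtup", "dist_road",
    # socio-economic
    "pop_density", "gdp",
    "livestock_density", "agri_output", "husbandry_output", "eco_investment",
)


def _default_geotransform(cell_size_m: float) -> tuple[float, ...]:
    # GDAL-style affine: (x0, dx, 0, y0, 0, -dy); row 0 is north.
    return (0.0, float(cell_size_m), 0.0, 0.0, 0.0, -float(cell_size_m))


@dataclass
class LandCoverGrid:
    """A dated categorical land-cover raster.

    Parameters
    ----------
    codes
        2-D integer lattice; values are legend keys or ``NODATA`` (0).
    cell_size_m
        Side length of the square cell, metres (default 500).
    label
        Free-text date/epoch tag, e.g. ``"2020"``.
    legend
        Mapping code -> class name.
    geotransform
        GDAL-style 6-tuple; row-major, row 0 = north, cell (0, 0) top-left.
    """

    codes: np.ndarray
    cell_size_m: float = 500.0
    label: str = ""
    legend: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LEGEND))
    geotransform: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.size == 0:
            raise ValueError("codes must be a non-empty 2-D lattice")
        if not np.issubdtype(self.codes.dtype, np.integer):
            raise ValueError("codes must be integer-valued")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        present = set(np.unique(self.codes).tolist()) - {NODATA}
        unknown = present - set(self.legend)
        if unknown:
            raise ValueError(f"codes outside legend: {sorted(unknown)}")
        if self.geotransform is None:
            self.geotransform = _default_geotransform(self.cell_size_m)

    # -- basic geometry ---------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.codes != NODATA

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def classes(self) -> list[int]:
        """Legend codes, sorted."""
        return sorted(self.legend)

    @property
    def cell_area_ha(self) -> float:
        return self.cell_size_m**2 / 1e4

    def class_counts(self) -> dict[int, int]:
        """Valid-cell count per legend class (zero for absent classes)."""
        vals, cnt = np.unique(self.codes[self.valid_mask], return_counts=True)
        tally = dict(zip(vals.tolist(), cnt.tolist()))
        return {k: tally.get(k, 0) for k in self.classes}

    def with_codes(self, codes: np.ndarray, label: str | None = None) -> "LandCoverGrid":
        """A copy of this grid carrying new codes (same geometry/legend)."""
        return LandCoverGrid(
            codes=np.asarray(codes),
            cell_size_m=self.cell_size_m,
            label=self.label if label is None else label,
            legend=dict(self.legend),
            geotransform=self.geotransform,
        )


@dataclass
class DriverStack:
    """Named continuous layers congruent with a reference land-cover grid."""

    layers: dict[str, np.ndarray]
    standardized: bool = False
    standardization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers are not congruent: shapes {shapes}")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def subset(self, names: list[str]) -> "DriverStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"unknown driver layer(s): {missing}")
        return DriverStack(
            layers={n: self.layers[n] for n in names},
            standardized=self.standardized,
            standardization={n: self.standardization[n]
                             for n in names if n in self.standardization},
        )

    def design_matrix(self, rows: np.ndarray, cols: np.ndarray,
                      names: list[str] | None = None) -> np.ndarray:
        """Stack driver values at the given cell coordinates, column per layer."""
        names = names or self.names
        return np.column_stack([self.layers[n][rows, cols] for n in names])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def reclassify_globeland30(raw: np.ndarray, cell_size_m: float = 500.0,
                           label: str = "") -> LandCoverGrid:
    """Reclassify a Globeland30-coded lattice to the 6-class scheme.

    Nodata (0) is preserved; any code outside the Globeland30 system is
    rejected with the offending code and its cell count.
    """
    raw = np.asarray(raw)
    if not np.issubdtype(raw.dtype, np.integer):
        raise ValueError("raw codes must be integer-valued")
    out = np.full(raw.shape, NODATA, dtype=np.int32)
    known = raw == NODATA
    for src, dst in GLOBELAND30_MAP.items():
        hit = raw == src
        out[hit] = dst
        known |= hit
    if not known.all():
        bad, bad_n = np.unique(raw[~known], return_counts=True)
        detail = ", ".join(f"{c} ({n} cells)" for c, n in zip(bad, bad_n))
        raise ValueError(f"unmapped Globeland30 code(s): {detail}")
    return LandCoverGrid(out, cell_size_m=cell_size_m, label=label)


def class_areas(grid: LandCoverGrid) -> pd.DataFrame:
    """Per-class area table (ha and % of valid area), nodata excluded.

    Returns a DataFrame indexed by class code with columns
    ``name, cells, area_ha, percent``; only classes present appear.
    """
    counts = grid.class_counts()
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty landscape: all cells are nodata")
    rows = []
    for k, n in counts.items():
        if n == 0:
            continue
        rows.append({
            "code": k,
            "name": grid.legend[k],
            "cells": n,
            "area_ha": n * grid.cell_area_ha,
            "percent": 100.0 * n / total,
        })
    return pd.DataFrame(rows).set_index("code")


def _nearest_resample(layer: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resample of a 2-D layer to the target shape."""
    src_r, src_c = layer.shape
    dst_r, dst_c = shape
    # centre-of-cell mapping: target cell i covers fraction (i+0.5)/dst of extent
    rr = np.minimum((np.arange(dst_r) + 0.5) * src_r / dst_r, src_r - 1).astype(int)
    cc = np.minimum((np.arange(dst_c) + 0.5) * src_c / dst_c, src_c - 1).astype(int)
    return layer[np.ix_(rr, cc)]


def align_and_stack(layers: dict[str, np.ndarray], reference: LandCoverGrid,
                    standardize: bool = False) -> DriverStack:
    """Align driver layers to the reference grid and optionally z-score them.

    Layers whose shape differs from the reference are resampled by nearest
    neighbour. Standardization uses the mean/sd over valid reference cells
    only, and the parameters are recorded on the stack.
    """
    mask = reference.valid_mask
    aligned: dict[str, np.ndarray] = {}
    params: dict[str, tuple[float, float]] = {}
    for name, layer in layers.items():
        arr = np.asarray(layer, dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"layer {name!r} is not 2-D")
        if arr.shape != reference.shape:
            arr = _nearest_resample(arr, reference.shape)
        if standardize:
            mu = float(arr[mask].mean())
            sd = float(arr[mask].std())
            if sd == 0.0:
                raise ValueError(f"layer {name!r} has zero variance; cannot standardize")
            arr = (arr - mu) / sd
            params[name] = (mu, sd)
        aligned[name] = arr
    return DriverStack(layers=aligned, standardized=standardize, standardization=params)
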