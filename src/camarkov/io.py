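"""Raster and model I/O.

Land-cover grids are written as single-band integer TIFFs, drivers as
single-band float32 TIFFs; the legend, cell size, nodata convention and
geotransform travel in a JSON sidecar next to each file (``<file>.json``).
Round-tripping a grid reproduces its codes bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .raster import NODATA, DriverStack, LandCoverGrid


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_grid(grid: LandCoverGrid, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, grid.codes.astype(np.int32))
    meta = {
        "kind": "landcover",
        "cell_size_m": grid.cell_size_m,
        "label": grid.label,
        "legend": {str(k): v for k, v in grid.legend.items()},
        "geotransform": list(grid.geotransform),
        "nodata": NODATA,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_grid(path: str | Path) -> LandCoverGrid:
    path = Path(path)
    codes = tifffile.imread(path)
    meta = json.loads(_sidecar(path).read_text())
    return LandCoverGrid(
        codes=np.asarray(codes, dtype=np.int32),
        cell_size_m=float(meta["cell_size_m"]),
        label=meta.get("label", ""),
        legend={int(k): v for k, v in meta["legend"].items()},
        geotransform=tuple(meta["geotransform"]),
    )


def write_driver_stack(stack: DriverStack, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, layer in stack.layers.items():
        tifffile.imwrite(directory / f"{name}.tif", layer.astype(np.float32))
    meta = {
        "kind": "drivers",
        "names": stack.names,
        "standardized": stack.standardized,
        "standardization": {k: list(v) for k, v in stack.standardization.items()},
    }
    (directory / "stack.json").write_text(json.dumps(meta, indent=2))
    return directory


def read_driver_stack(directory: str | Path) -> DriverStack:
    directory = Path(directory)
    meta = json.loads((directory / "stack.json").read_text())
    layers = {
        name: np.asarray(tifffile.imread(directory / f"{name}.tif"), dtype=float)
        for name in meta["names"]
    }
    return DriverStack(
        layers=layers,
        standardized=meta["standardized"],
        standardization={k: tuple(v) for k, v in meta["standardization"].items()},
    )


def write_float_map(array: np.ndarray, path: str | Path, meta: dict | None = None) -> Path:
    """Write a continuous raster (suitability layer, per-pixel biocapacity)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    if meta is not None:
        _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def read_float_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)
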