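"""Biocapacity accounting from land-cover composition.

BC = sum_i A_i * YF_i * EQF_i, with A_i the class area in hectares,
YF_i the dimensionless yield factor and EQF_i the equivalence factor in
global hectares per hectare. Built-up and deserted land carry YF = 0 in
the bundled defaults (negligible natural productivity).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import LandCoverGrid, class_areas

# Bundled decadal factor table (GFN/WWF-style accounting factors for a
# temperate agro-pastoral region); 2030 factors equal 2020 by assumption.
_DEFAULT_ROWS = [
    # (code, epoch, YF, EQF)
    (1, "2000", 2.12, 2.11), (1, "2010", 2.21, 2.39),
    (1, "2020", 2.02, 2.50), (1, "2030", 2.02, 2.50),
    (2, "2000", 1.18, 1.35), (2, "2010", 1.18, 1.24),
    (2, "2020", 1.18, 1.28), (2, "2030", 1.18, 1.28),
    (3, "2000", 0.81, 0.47), (3, "2010", 0.81, 0.51),
    (3, "2020", 0.81, 0.46), (3, "2030", 0.81, 0.46),
    (4, "2000", 1.27, 0.35), (4, "2010", 1.27, 0.41),
    (4, "2020", 1.27, 0.37), (4, "2030", 1.27, 0.37),
] + [
    (code, epoch, 0.0, 0.0)
    for code in (5, 6) for epoch in ("2000", "2010", "2020", "2030")
]


@dataclass
class BCFactorTable:
    """Yield and equivalence factors per class and epoch (BF = YF * EQF)."""

    table: pd.DataFrame  # columns: code, epoch, yf, eqf

    def __post_init__(self) -> None:
        required = {"code", "epoch", "yf", "eqf"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"factor table needs columns {sorted(required)}")
        if (self.table[["yf", "eqf"]] < 0).any().any():
            raise ValueError("YF and EQF must be non-negative")
        self.table = self.table.assign(epoch=self.table["epoch"].astype(str))

    @classmethod
    def default(cls) -> "BCFactorTable":
        return cls(pd.DataFrame(_DEFAULT_ROWS, columns=["code", "epoch", "yf", "eqf"]))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BCFactorTable":
        return cls(pd.read_csv(path, dtype={"epoch": str}))

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)
        return path

    @property
    def epochs(self) -> list[str]:
        return sorted(self.table["epoch"].unique())

    def factors(self, class_code: int, epoch: str) -> tuple[float, float]:
        """(YF, EQF) for one class and epoch; raises if absent."""
        hit = self.table[(self.table["code"] == class_code)
                         & (self.table["epoch"] == str(epoch))]
        if hit.empty:
            raise KeyError(f"no biocapacity factors for class {class_code} "
                           f"in epoch {epoch!r}")
        row = hit.iloc[0]
        return float(row["yf"]), float(row["eqf"])


@dataclass
class BCReport:
    """Biocapacity of one dated map: per-class table, total, per-pixel map."""

    epoch: str
    table: pd.DataFrame  # index code; columns name, area_ha, yf, eqf, bf, bc_gha
    per_pixel: np.ndarray | None = field(default=None, repr=False)

    @property
    def total_gha(self) -> float:
        return float(self.table["bc_gha"].sum())

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps({
            "epoch": self.epoch,
            "total_gha": self.total_gha,
            "classes": self.table.reset_index().to_dict(orient="records"),
        }, indent=2))
        return path


def biocapacity_report(grid: LandCoverGrid, factors: BCFactorTable | None = None,
                       epoch: str | None = None,
                       per_pixel: bool = False) -> BCReport:
    """Biocapacity of one land-cover map under the given factor epoch.

    The epoch defaults to the grid label. Every class present in the
    grid must have factors for the epoch.
    """
    factors = factors or BCFactorTable.default()
    epoch = str(epoch if epoch is not None else grid.label)
    areas = class_areas(grid)
    rows = []
    for code, r in areas.iterrows():
        yf, eqf = factors.factors(int(code), epoch)
        rows.append({"code": int(code), "name": r["name"], "area_ha": r["area_ha"],
                     "yf": yf, "eqf": eqf, "bf": yf * eqf,
                     "bc_gha": r["area_ha"] * yf * eqf})
    table = pd.DataFrame(rows).set_index("code")
    pix = None
    if per_pixel:
        pix = np.zeros(grid.shape, dtype=float)
        for code, r in table.iterrows():
            pix[grid.codes == code] = r["bf"] * grid.cell_area_ha
        pix[~grid.valid_mask] = np.nan
    return BCReport(epoch=epoch, table=table, per_pixel=pix)


def bc_timeseries(grids: list[LandCoverGrid],
                  factors: BCFactorTable | None = None,
                  years: list[float] | None = None
                  ) -> tuple[pd.DataFrame, pd.Series | None]:
    """Biocapacity by class and date, with least-squares annual trends.

    Grid labels must be (or ``years`` must supply) numeric years. Returns
    the BC table (classes + total as rows, dates as columns, gha) and a
    Series of slopes in gha per year (None with a single date, with a
    warning).
    """
    factors = factors or BCFactorTable.default()
    if years is None:
        years = [float(g.label) for g in grids]
    if len(years) != len(grids):
        raise ValueError("years must match grids")
    reports = [biocapacity_report(g, factors) for g in grids]
    cols = {}
    for g, yr, rep in zip(grids, years, reports):
        col = rep.table["bc_gha"].reindex(sorted(g.legend), fill_value=0.0)
        col.loc["total"] = rep.total_gha
        cols[yr] = col
    bc = pd.DataFrame(cols)
    bc.index.name = "code"
    if len(grids) < 2:
        warnings.warn("single date: trend omitted")
        return bc, None
    order = np.argsort(years)
    x = np.asarray(years, dtype=float)[order]
    slopes = pd.Series(
        {idx: float(np.polyfit(x, bc.loc[idx].to_numpy()[order], 1)[0])
         for idx in bc.index},
        name="trend_gha_per_year")
    return bc, slopes
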