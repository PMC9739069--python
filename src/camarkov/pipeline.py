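"""End-to-end orchestration: validation and forecast legs.

Validation leg: calibrate on (t0, t1), simulate t2, compare with the
observed t2 (Kappa, per-class ROC, confusion matrix). Forecast leg:
calibrate on (t1, t2), simulate t3, then account biocapacity and
landscape metrics across all dates.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import io as _io
from .biocapacity import BCFactorTable, bc_timeseries, biocapacity_report
from .ca import CAConfig
from .metrics import change_table, class_metrics, landscape_metrics
from .model import CAMarkov
from .raster import DriverStack, LandCoverGrid


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_validation_leg(t0: LandCoverGrid, t1: LandCoverGrid, t2: LandCoverGrid,
                       drivers: DriverStack, *, n_per_class: int = 5000,
                       ca_config: CAConfig | None = None, seed: int = 0) -> dict:
    """Calibrate on t0->t1, simulate t2, score against the observed t2."""
    for g in (t1, t2):
        if g.shape != t0.shape:
            raise ValueError("the three dated maps must be congruent")
    model = CAMarkov(t0, t1, drivers, n_per_class=n_per_class,
                     ca_config=ca_config or CAConfig(seed=seed))
    res = model.fit(seed=seed)
    simulated = res.simulate(steps=1, labels=[t2.label])
    report = res.validate(t2, simulated)
    report.update({
        "per_class_roc": {str(k): float(v) for k, v in res.roc.items()},
        "transition_P": res.P.tolist(),
        "seed": seed,
    })
    return report


def run_forecast_leg(t1: LandCoverGrid, t2: LandCoverGrid,
                     drivers: DriverStack, *,
                     factors: BCFactorTable | None = None,
                     forecast_label: str | None = None,
                     n_per_class: int = 5000,
                     ca_config: CAConfig | None = None,
                     seed: int = 0,
                     earlier: list[LandCoverGrid] | None = None) -> dict:
    """Calibrate on t1->t2, forecast t3, account BC and pattern metrics.

    ``earlier`` maps (e.g. t0) are prepended to the BC/metrics time
    series. If the forecast epoch is missing from the factor table the
    latest available epoch is used (factors held constant forward).
    """
    factors = factors or BCFactorTable.default()
    if forecast_label is None:
        try:
            forecast_label = str(int(t2.label) + int(float(t2.label)
                                                     - float(t1.label)))
        except ValueError:
            forecast_label = f"{t2.label}+1"
    model = CAMarkov(t1, t2, drivers, n_per_class=n_per_class,
                     ca_config=ca_config or CAConfig(seed=seed))
    res = model.fit(seed=seed)
    forecast = res.simulate(steps=1, labels=[forecast_label])

    dated = list(earlier or []) + [t1, t2, forecast]
    epochs = factors.epochs
    bc_reports = {}
    for g in dated:
        epoch = g.label if g.label in epochs else epochs[-1]
        bc_reports[g.label] = biocapacity_report(g, factors, epoch=epoch)
    years = [float(g.label) for g in dated]
    bc_table, bc_trend = bc_timeseries(dated, factors=_constant_forward(factors, dated),
                                       years=years)
    metrics_by_date = {g.label: {"class": class_metrics(g),
                                 "landscape": landscape_metrics(g)} for g in dated}
    return {
        "forecast": forecast,
        "results": res,
        "areas": {g.label: g.class_counts() for g in dated},
        "bc_reports": bc_reports,
        "bc_table": bc_table,
        "bc_trend": bc_trend,
        "metrics": metrics_by_date,
        "metrics_change": change_table(dated),
        "seed": seed,
    }


def _constant_forward(factors: BCFactorTable, grids: list[LandCoverGrid]) -> BCFactorTable:
    """Extend the factor table so every grid label has an epoch.

    Missing epochs inherit the latest available one (constant-factor
    extrapolation).
    """
    table = factors.table
    epochs = set(table["epoch"])
    latest = sorted(epochs)[-1]
    add = []
    for g in grids:
        if g.label not in epochs:
            block = table[table["epoch"] == latest].assign(epoch=g.label)
            add.append(block)
    if add:
        table = pd.concat([table, *add], ignore_index=True)
    return BCFactorTable(table)


def write_bundle(bundle: dict, directory: str | Path, seed: int,
                 config: dict | None = None) -> Path:
    """Persist a forecast bundle: forecast map, tables, run log."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = dict(config or {})
    cfg["seed"] = seed
    run_meta = {"config": cfg, "config_hash": _config_hash(cfg)}
    _io.write_grid(bundle["forecast"], directory / "forecast.tif")
    bundle["results"].transition.to_json(directory / "transition.json")
    bundle["results"].suitability.to_json(directory / "suitability.json")
    bundle["bc_table"].to_csv(directory / "biocapacity.csv")
    if bundle["bc_trend"] is not None:
        bundle["bc_trend"].to_csv(directory / "biocapacity_trend.csv")
    rows = []
    for label, rep in bundle["metrics"].items():
        row = rep["landscape"].copy()
        row["date"] = label
        rows.append(row)
    pd.DataFrame(rows).set_index("date").to_csv(directory / "metrics.csv")
    bundle["metrics_change"].to_csv(directory / "metrics_change.csv")
    (directory / "run.json").write_text(json.dumps(run_meta, indent=2))
    return directory
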