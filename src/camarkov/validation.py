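"""Map agreement: cross-tabulation, observed/chance agreement, Kappa.

Chance agreement is Cohen's: the product of the row and column
marginal proportions summed over classes. The qualitative banding used
for simulation acceptance is poor (< 0.4), general (0.4-0.75), very
good (>= 0.75).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .raster import LandCoverGrid


@dataclass
class ConfusionMatrix:
    """Cross-tabulation of a reference map (rows) vs a simulated map (columns)."""

    classes: list[int]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def observed_agreement(self) -> float:
        return float(np.trace(self.counts) / self.total)

    @property
    def chance_agreement(self) -> float:
        row = self.counts.sum(axis=1) / self.total
        col = self.counts.sum(axis=0) / self.total
        return float(row @ col)


def cross_tabulate(reference: LandCoverGrid, simulated: LandCoverGrid) -> ConfusionMatrix:
    """Count cells per (reference, simulated) class pair, nodata excluded."""
    if reference.shape != simulated.shape:
        raise ValueError("grids are not congruent")
    if set(reference.legend) != set(simulated.legend):
        raise ValueError("grids do not share a legend")
    classes = reference.classes
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    mask = reference.valid_mask & simulated.valid_mask
    a = np.vectorize(idx.get)(reference.codes[mask])
    b = np.vectorize(idx.get)(simulated.codes[mask])
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(classes=classes, counts=counts)


def kappa(cm: ConfusionMatrix) -> float:
    """Cohen's chance-corrected agreement, (P0 - Pc) / (1 - Pc)."""
    if cm.total <= 0:
        raise ValueError("empty confusion matrix")
    p0 = cm.observed_agreement
    pc = cm.chance_agreement
    if pc >= 1.0:
        warnings.warn("both maps are constant and identical; Kappa defined as 1")
        return 1.0
    return (p0 - pc) / (1.0 - pc)


def kappa_band(value: float) -> str:
    """Qualitative agreement band for a Kappa value."""
    if value < 0.4:
        return "poor"
    if value < 0.75:
        return "general"
    return "very good"


def agreement_report(reference: LandCoverGrid, simulated: LandCoverGrid) -> dict:
    """Full agreement report as a plain dict (JSON-serializable)."""
    cm = cross_tabulate(reference, simulated)
    k = kappa(cm)
    return {
        "classes": cm.classes,
        "counts": cm.counts.astype(int).tolist(),
        "observed_agreement": cm.observed_agreement,
        "chance_agreement": cm.chance_agreement,
        "kappa": k,
        "band": kappa_band(k),
    }


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=2))
    return path
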