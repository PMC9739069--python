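"""Markov transition estimation and class-quantity projection.

The quantity model of CA-Markov: cross-tabulate two dated maps to get
class transition counts, normalize rows to a row-stochastic matrix P,
and project class areas forward one observed interval per step
(areas_{t+1} = areas_t P).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .raster import NODATA, LandCoverGrid


@dataclass
class TransitionModel:
    """Class transition counts and row-stochastic probability matrix.

    Rows index the origin class at t, columns the destination at t+1.
    Rows with zero origin count are identity rows.
    """

    classes: list[int]
    counts: np.ndarray
    step_years: float = 10.0
    P: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        row = self.counts.sum(axis=1, keepdims=True).astype(float)
        P = np.where(row > 0, self.counts / np.where(row == 0, 1, row), 0.0)
        empty = row[:, 0] == 0
        P[empty] = np.eye(k)[empty]
        self.P = P

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps({
            "classes": self.classes,
            "counts": self.counts.astype(int).tolist(),
            "P": self.P.tolist(),
            "step_years": self.step_years,
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TransitionModel":
        d = json.loads(Path(path).read_text())
        return cls(classes=list(d["classes"]), counts=np.asarray(d["counts"]),
                   step_years=d.get("step_years", 10.0))


def estimate_transition(grid_t0: LandCoverGrid, grid_t1: LandCoverGrid,
                        step_years: float = 10.0) -> TransitionModel:
    """Cross-tabulate two dated maps into a TransitionModel.

    Cells that are nodata at either date are excluded. Both maps must be
    congruent and share a legend.
    """
    if grid_t0.shape != grid_t1.shape:
        raise ValueError(f"shape mismatch: {grid_t0.shape} vs {grid_t1.shape}")
    if set(grid_t0.legend) != set(grid_t1.legend):
        raise ValueError("grids do not share a legend")
    classes = grid_t0.classes
    k = len(classes)
    code_to_idx = {c: i for i, c in enumerate(classes)}
    mask = grid_t0.valid_mask & grid_t1.valid_mask
    if not mask.any():
        raise ValueError("no valid overlapping cells")
    a = np.vectorize(code_to_idx.get)(grid_t0.codes[mask])
    b = np.vectorize(code_to_idx.get)(grid_t1.codes[mask])
    counts = np.bincount(a * k + b, minlength=k * k).reshape(k, k)
    return TransitionModel(classes=classes, counts=counts, step_years=step_years)


def project_class_areas(model: TransitionModel, areas_t: np.ndarray,
                        steps: int = 1) -> np.ndarray:
    """Project a per-class quantity vector forward ``steps`` intervals.

    One step corresponds to one observed inter-map interval. Total
    quantity is conserved because P is row-stochastic.
    """
    v = np.asarray(areas_t, dtype=float)
    if v.shape != (len(model.classes),):
        raise ValueError("areas_t length must match model classes")
    if (v < 0).any():
        raise ValueError("areas must be non-negative")
    if steps < 1:
        raise ValueError("steps must be >= 1")
    for _ in range(steps):
        v = v @ model.P
    return v


def largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative real quotas to integers summing exactly to ``total``.

    Floors each quota, then hands the remaining units to the largest
    fractional parts (ties broken by position). Used to turn projected
    areas into feasible CA cell-count targets.
    """
    t = np.asarray(targets, dtype=float)
    if (t < 0).any():
        raise ValueError("targets must be non-negative")
    scale = total / t.sum() if t.sum() > 0 else 0.0
    t = t * scale
    base = np.floor(t).astype(int)
    short = total - int(base.sum())
    if short > 0:
        frac = t - base
        # stable argsort on -frac: largest remainders first, index order on ties
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base
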