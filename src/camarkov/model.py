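"""Statsmodels-style facade over the Logistic-CA-Markov pipeline.

``CAMarkov`` is built from two dated land-cover maps and a driver
stack; ``fit()`` estimates the Markov transition matrix from the map
pair and the per-class logistic suitability models at the later date,
returning a :class:`CAMarkovResults` that can ``simulate()`` forward
steps, ``validate()`` against a reference map, and print a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ca import CAConfig, simulate_ca
from .markov import TransitionModel, estimate_transition
from .raster import DriverStack, LandCoverGrid
from .suitability import (LogisticModelSet, SuitabilityAtlas,
                          fit_suitability_models, predict_suitability)
from .validation import agreement_report


class CAMarkov:
    """Logistic-CA-Markov land-change model.

    Parameters
    ----------
    grid_start, grid_end
        Two dated, congruent land-cover maps; their cross-tabulation
        calibrates the transition matrix, and occurrence at ``grid_end``
        is the logistic response.
    drivers
        Driver stack congruent with the grids (standardized recommended).
    driver_subset
        Optional list of driver names to fit on (default: all).
    n_per_class
        Stratified sample size per class for the logistic fits.
    ca_config
        Allocation parameters (window size, cycles, seed).
    """

    def __init__(self, grid_start: LandCoverGrid, grid_end: LandCoverGrid,
                 drivers: DriverStack, *, driver_subset: list[str] | None = None,
                 n_per_class: int = 5000, ca_config: CAConfig | None = None):
        if grid_start.shape != grid_end.shape:
            raise ValueError("grids are not congruent")
        if drivers.shape != grid_end.shape:
            raise ValueError("drivers are not congruent with the grids")
        self.grid_start = grid_start
        self.grid_end = grid_end
        self.drivers = drivers
        self.driver_subset = driver_subset
        self.n_per_class = n_per_class
        self.ca_config = ca_config or CAConfig()

    @classmethod
    def from_scenario(cls, scenario, *, use: tuple[str, str] = ("t0", "t1"),
                      **kwargs) -> "CAMarkov":
        """Build the model from a synthetic scenario's dated maps."""
        a, b = use
        return cls(scenario.grids[a], scenario.grids[b], scenario.drivers,
                   **kwargs)

    def fit(self, seed: int = 0) -> "CAMarkovResults":
        transition = estimate_transition(self.grid_start, self.grid_end)
        suitability = fit_suitability_models(
            self.grid_end, self.drivers, subset=self.driver_subset,
            n_per_class=self.n_per_class, seed=seed)
        atlas = predict_suitability(suitability, self.drivers,
                                    reference=self.grid_end)
        return CAMarkovResults(model=self, transition=transition,
                               suitability=suitability, atlas=atlas, seed=seed)


@dataclass
class CAMarkovResults:
    """Fitted transition matrix, suitability models and atlas."""

    model: CAMarkov
    transition: TransitionModel
    suitability: LogisticModelSet
    atlas: SuitabilityAtlas
    seed: int
    _forecasts: list[LandCoverGrid] = field(default_factory=list, repr=False)

    @property
    def roc(self) -> pd.Series:
        """Training ROC area per class."""
        return self.suitability.roc_table

    @property
    def P(self) -> np.ndarray:
        return self.transition.P

    def simulate(self, steps: int = 1, start: LandCoverGrid | None = None,
                 labels: list[str] | None = None) -> LandCoverGrid:
        """Allocate the Markov-projected quantities ``steps`` intervals ahead.

        Starts from ``grid_end`` by default; with ``steps > 1`` each step
        re-applies the same transition matrix and atlas.
        """
        current = start or self.model.grid_end
        self._forecasts = []
        for s in range(steps):
            label = (labels[s] if labels else f"{current.label}+1step")
            current = simulate_ca(current.with_codes(current.codes, label=label),
                                  self.atlas, self.transition,
                                  self.model.ca_config)
            self._forecasts.append(current)
        return current

    def validate(self, reference: LandCoverGrid,
                 simulated: LandCoverGrid | None = None) -> dict:
        """Agreement report (confusion matrix, P0, Pc, Kappa, band)."""
        if simulated is None:
            simulated = self.simulate(steps=1)
        return agreement_report(reference, simulated)

    def summary(self) -> str:
        classes = self.transition.classes
        legend = self.model.grid_end.legend
        lines = ["Logistic-CA-Markov model fit",
                 "=" * 64,
                 f"maps: {self.model.grid_start.label or 't'} -> "
                 f"{self.model.grid_end.label or 't+1'}   "
                 f"lattice: {self.model.grid_end.shape[0]} x "
                 f"{self.model.grid_end.shape[1]}   seed: {self.seed}",
                 "",
                 "Transition probability matrix (rows = origin):"]
        header = "          " + " ".join(f"{legend[c][:8]:>9}" for c in classes)
        lines.append(header)
        for i, c in enumerate(classes):
            row = " ".join(f"{p:9.4f}" for p in self.transition.P[i])
            lines.append(f"{legend[c][:9]:<10}{row}")
        lines += ["", "Per-class suitability fits (training ROC area):"]
        for c in self.suitability.classes:
            m = self.suitability[c]
            top = sorted(m.coefficients.items(), key=lambda kv: -abs(kv[1]))[:3]
            top_str = ", ".join(f"{n}={b:+.2f}" for n, b in top)
            lines.append(f"  {legend[c]:<16} ROC = {m.roc:.3f}   "
                         f"main drivers: {top_str}")
        return "\n".join(lines)
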