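"""Per-class logistic suitability models and ROC evaluation.

For each land class k a binary logistic regression of occurrence
(logit p = b0 + b1 X1 + ... + bn Xn) is fitted on a stratified cell
sample; applying the fitted model across the lattice yields the class's
suitability layer, and the set of layers forms the suitability atlas
used to rank cells during CA allocation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .raster import DriverStack, LandCoverGrid

#: Inverse of the mild L2 penalty used to keep estimates finite under
#: separation or exact collinearity.
_RIDGE_C = 1e6


@dataclass
class ClassLogit:
    """One fitted per-class logistic model."""

    class_code: int
    intercept: float
    coefficients: dict[str, float]
    roc: float
    subset: list[str]
    converged: bool = True

    def linear_predictor(self, drivers: DriverStack) -> np.ndarray:
        missing = [n for n in self.subset if n not in drivers]
        if missing:
            raise KeyError(f"missing driver layer(s): {missing}")
        eta = np.full(drivers.shape, self.intercept, dtype=float)
        for name in self.subset:
            eta += self.coefficients[name] * drivers[name]
        return eta


@dataclass
class LogisticModelSet:
    """Fitted per-class logistic models keyed by class code."""

    models: dict[int, ClassLogit] = field(default_factory=dict)

    def __getitem__(self, code: int) -> ClassLogit:
        return self.models[code]

    @property
    def classes(self) -> list[int]:
        return sorted(self.models)

    @property
    def roc_table(self) -> pd.Series:
        return pd.Series({k: m.roc for k, m in sorted(self.models.items())},
                         name="roc")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps({
            str(k): {
                "intercept": m.intercept,
                "coefficients": m.coefficients,
                "roc": m.roc,
                "subset": m.subset,
                "converged": m.converged,
            } for k, m in sorted(self.models.items())
        }, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LogisticModelSet":
        d = json.loads(Path(path).read_text())
        return cls(models={
            int(k): ClassLogit(class_code=int(k), intercept=v["intercept"],
                               coefficients=v["coefficients"], roc=v["roc"],
                               subset=v["subset"],
                               converged=v.get("converged", True))
            for k, v in d.items()
        })


@dataclass
class SuitabilityAtlas:
    """Per-class occurrence-probability lattices congruent with the grid.

    Nodata cells carry NaN.
    """

    probabilities: dict[int, np.ndarray]

    def __getitem__(self, code: int) -> np.ndarray:
        return self.probabilities[code]

    @property
    def classes(self) -> list[int]:
        return sorted(self.probabilities)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.probabilities.values())).shape


# ---------------------------------------------------------------------------
# sampling and fitting
# ---------------------------------------------------------------------------

def sample_observations(grid: LandCoverGrid, drivers: DriverStack,
                        n_per_class: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Stratified random cell sample for logistic fitting.

    Draws up to ``n_per_class`` cells per present class without
    replacement (classes with fewer cells contribute all of them, with a
    warning). The returned table has ``row, col, code`` plus one column
    per driver; the binary response for class k is ``code == k``.
    """
    if n_per_class < 30:
        raise ValueError("n_per_class must be >= 30")
    rng = np.random.default_rng(seed)
    rows_all, cols_all = np.nonzero(grid.valid_mask)
    codes_all = grid.codes[rows_all, cols_all]
    take_r, take_c = [], []
    for k in grid.classes:
        idx = np.nonzero(codes_all == k)[0]
        if idx.size == 0:
            continue
        if idx.size < n_per_class:
            warnings.warn(f"class {k} has only {idx.size} cells "
                          f"(< {n_per_class}); sampling all of them")
            chosen = idx
        else:
            chosen = rng.choice(idx, size=n_per_class, replace=False)
        take_r.append(rows_all[chosen])
        take_c.append(cols_all[chosen])
    rr = np.concatenate(take_r)
    cc = np.concatenate(take_c)
    table = pd.DataFrame({"row": rr, "col": cc, "code": grid.codes[rr, cc]})
    for name in drivers.names:
        table[name] = drivers[name][rr, cc]
    return table


def fit_class_logistic(observations: pd.DataFrame, class_code: int,
                       subset: list[str] | None = None) -> ClassLogit:
    """Maximum-likelihood logistic fit of occurrence of one class.

    Presences and absences are weight-balanced so rare classes are not
    swamped. A mild ridge penalty keeps estimates finite under complete
    separation or duplicated drivers; non-convergence is reported on the
    result, not raised.
    """
    names = subset or [c for c in observations.columns
                       if c not in ("row", "col", "code")]
    y = (observations["code"].to_numpy() == class_code).astype(int)
    if y.min() == y.max():
        raise ValueError(f"degenerate response for class {class_code}: "
                         "both presences and absences are required")
    X = observations[names].to_numpy(dtype=float)
    clf = LogisticRegression(C=_RIDGE_C, class_weight="balanced",
                             solver="lbfgs", max_iter=500)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y)
        except ConvergenceWarning:
            converged = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X, y)
            warnings.warn(f"logistic fit for class {class_code} stopped at the "
                          "iteration cap (separable or near-separable data)")
    scores = clf.decision_function(X)
    return ClassLogit(
        class_code=class_code,
        intercept=float(clf.intercept_[0]),
        coefficients={n: float(b) for n, b in zip(names, clf.coef_[0])},
        roc=roc_area(scores, y),
        subset=list(names),
        converged=converged,
    )


def fit_suitability_models(grid: LandCoverGrid, drivers: DriverStack,
                           subset: list[str] | None = None,
                           n_per_class: int = 5000, seed: int = 0,
                           classes: list[int] | None = None) -> LogisticModelSet:
    """Fit the full per-class model set on one stratified sample."""
    subset = subset or drivers.names
    missing = [n for n in subset if n not in drivers]
    if missing:
        raise KeyError(f"unknown driver layer(s): {missing}")
    obs = sample_observations(grid, drivers, n_per_class=n_per_class, seed=seed)
    present = sorted(set(obs["code"]))
    wanted = classes or present
    return LogisticModelSet(models={
        k: fit_class_logistic(obs, k, subset=subset)
        for k in wanted if k in present
    })


def predict_suitability(models: LogisticModelSet, drivers: DriverStack,
                        reference: LandCoverGrid | None = None) -> SuitabilityAtlas:
    """Apply fitted models across the lattice: p = 1 / (1 + exp(-eta)).

    Nodata cells of the reference grid (if given) propagate as NaN.
    """
    probs: dict[int, np.ndarray] = {}
    for k, m in models.models.items():
        with np.errstate(over="ignore"):
            p = 1.0 / (1.0 + np.exp(-m.linear_predictor(drivers)))
        if reference is not None:
            p = np.where(reference.valid_mask, p, np.nan)
        probs[k] = p
    return SuitabilityAtlas(probabilities=probs)


def roc_area(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC area: P(random positive outscores random negative).

    Ties count one half; equals the trapezoidal area under the empirical
    ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both label values must be present")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compare_driver_subsets(grid: LandCoverGrid, drivers: DriverStack,
                           subsets: dict[str, list[str]],
                           n_per_class: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Per-class ROC for each driver subset on one common sample.

    Returns a class-by-subset ROC table; with exactly two subsets a
    ``difference`` column (first minus second) is appended.
    """
    for name, subset in subsets.items():
        if not subset:
            raise ValueError(f"subset {name!r} is empty")
        missing = [n for n in subset if n not in drivers]
        if missing:
            raise KeyError(f"subset {name!r} references unknown driver(s): {missing}")
    obs = sample_observations(grid, drivers, n_per_class=n_per_class, seed=seed)
    present = sorted(set(obs["code"]))
    table = pd.DataFrame(index=present)
    table.index.name = "class"
    for name, subset in subsets.items():
        table[name] = [fit_class_logistic(obs, k, subset=subset).roc
                       for k in present]
    if len(subsets) == 2:
        a, b = table.columns
        table["difference"] = table[a] - table[b]
    return table
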