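"""Synthetic study regions with known generating process.

Builds fully synthetic driver stacks, an initial 6-class land-cover map
drawn from a softmax of known logistic coefficients, and forward-evolved
later dates governed by a known row-stochastic transition matrix — so
every downstream stage (suitability fitting, Markov estimation, CA
allocation, validation, accounting, metrics) can be checked against
ground truth.

The default configuration emulates a temperate agro-pastoral zone:
cultivated land ~38%, grassland ~46%, forest ~11%, built-up ~3%,
deserted ~2%, water ~0.5%; smooth terrain and climate gradients;
distance-to-built-up/road accessibility surfaces; and county-constant
socio-economic layers on a rectangular partition. All stochasticity
flows through one seeded generator: same seed + config gives a
bit-identical scenario.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io as _io
from .raster import DEFAULT_LEGEND, DRIVER_NAMES, DriverStack, LandCoverGrid

#: Target class composition (fractions of valid area, normalized).
DEFAULT_COMPOSITION: dict[int, float] = {
    1: 0.38,   # cultivated
    2: 0.11,   # forest
    3: 0.46,   # grassland
    4: 0.005,  # water
    5: 0.03,   # built-up
    6: 0.02,   # deserted
}

#: Decadal transition matrix used to evolve the map forward (rows sum to 1).
DEFAULT_TRUE_P = np.array([
    # cult    forest  grass   water   built   desert
    [0.950, 0.008, 0.020, 0.002, 0.015, 0.005],
    [0.010, 0.960, 0.025, 0.001, 0.002, 0.002],
    [0.030, 0.015, 0.935, 0.002, 0.008, 0.010],
    [0.010, 0.002, 0.010, 0.960, 0.003, 0.015],
    [0.005, 0.001, 0.004, 0.000, 0.990, 0.000],
    [0.010, 0.005, 0.040, 0.002, 0.003, 0.940],
])

#: Structural (non-intercept) logistic loadings per class on standardized
#: drivers. Signs follow the physical expectations of an agro-pastoral
#: region (cropland in warm wet lowlands near settlements, forest on wet
#: slopes, desert where dry, built-up near roads/towns); every class has
#: enough signal that occurrence is well separated from the background.
DEFAULT_TRUE_BETA: dict[int, dict[str, float]] = {
    1: {"precipitation": 2.6, "temperature": 1.8, "slope": -3.2,
        "dist_builtup": -1.8, "dist_road": -1.4, "agri_output": 3.2,
        "livestock_density": -1.4},
    2: {"elevation": 2.2, "slope": 3.8, "precipitation": 3.2,
        "husbandry_output": -2.6},
    3: {"precipitation": -2.6, "temperature": -2.6, "livestock_density": 4.6,
        "dist_road": 2.2, "elevation": 1.4, "slope": 1.4},
    4: {"elevation": -3.2, "slope": -2.6, "precipitation": 1.8},
    5: {"dist_builtup": -5.2, "dist_road": -3.2, "pop_density": 3.2,
        "gdp": 2.2},
    6: {"precipitation": -2.6, "temperature": 2.2, "eco_investment": -2.6,
        "livestock_density": -2.2, "slope": -1.8},
}

DEFAULT_PARAMS: dict = {
    "autocorr_sigma": 8.0,     # cells; low-pass filter width for smooth fields
    "elevation_amplitude": 1.0,
    "county_block": None,      # cells per rectangular "county"; None = auto
    "n_builtup_seeds": 12,
    "n_roads": 6,
    "smoothing_passes": 2,
    "cell_size_m": 500.0,
}


@dataclass
class SyntheticScenario:
    """Drivers, three dated maps, and the generating truth."""

    grids: dict[str, LandCoverGrid]
    drivers: DriverStack
    true_beta: dict[int, dict[str, float]]
    true_P: np.ndarray
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def t0(self) -> LandCoverGrid:
        return self.grids["t0"]

    @property
    def t1(self) -> LandCoverGrid:
        return self.grids["t1"]

    @property
    def t2(self) -> LandCoverGrid:
        return self.grids["t2"]

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for key, grid in self.grids.items():
            _io.write_grid(grid, directory / f"{key}.tif")
        _io.write_driver_stack(self.drivers, directory / "drivers")
        (directory / "truth.json").write_text(json.dumps({
            "true_beta": {str(k): v for k, v in self.true_beta.items()},
            "true_P": self.true_P.tolist(),
            "seed": self.seed,
            "config": {k: v for k, v in self.config.items()
                       if isinstance(v, (int, float, str, bool, list, dict))},
        }, indent=2))
        return directory


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return field_


def _line_mask(rng: np.random.Generator, shape, n_lines: int) -> np.ndarray:
    """Mask of a few random straight transects (roads)."""
    mask = np.zeros(shape, dtype=bool)
    nr, nc = shape
    for _ in range(n_lines):
        kind = rng.integers(3)
        if kind == 0:           # horizontal
            mask[rng.integers(nr), :] = True
        elif kind == 1:         # vertical
            mask[:, rng.integers(nc)] = True
        else:                   # diagonal through a random offset
            off = int(rng.integers(-nr // 2, nr // 2))
            rr = np.arange(nr)
            cc = rr + off
            ok = (cc >= 0) & (cc < nc)
            mask[rr[ok], cc[ok]] = True
    return mask


def generate_drivers(shape: tuple[int, int], seed: int = 0,
                     params: dict | None = None,
                     standardize: bool = True) -> DriverStack:
    """Generate the 13-layer synthetic driver stack.

    Terrain: smooth elevation (low-pass filtered noise), slope =
    finite-difference gradient magnitude, aspect = gradient direction.
    Climate: directional gradients plus smooth noise. Accessibility:
    Euclidean distance transforms from seeded built-up points and random
    road transects. Socio-economic: two smooth population/economy fields
    tied to settlement proximity and four county-constant layers on a
    rectangular partition.
    """
    p = {**DEFAULT_PARAMS, **(params or {})}
    if min(shape) < 32:
        raise ValueError("shape must be at least 32 x 32")
    if p["county_block"] is None:
        # several counties per axis regardless of grid size
        p["county_block"] = max(4, min(32, min(shape) // 8))
    if p["county_block"] > min(shape):
        raise ValueError("county_block larger than the grid")
    rng = np.random.default_rng(seed)
    nr, nc = shape
    sigma = p["autocorr_sigma"]

    elevation = p["elevation_amplitude"] * _smooth_noise(rng, shape, sigma)
    gy, gx = np.gradient(elevation)
    slope = np.hypot(gx, gy)
    aspect = np.arctan2(gy, gx)

    rows = np.linspace(0, 1, nr)[:, None]
    cols = np.linspace(0, 1, nc)[None, :]
    precipitation = (cols - rows) + 0.5 * _smooth_noise(rng, shape, sigma)
    temperature = (rows + 0.3 * cols) + 0.5 * _smooth_noise(rng, shape, sigma)

    builtup = np.zeros(shape, dtype=bool)
    n_seeds = int(p["n_builtup_seeds"])
    builtup[rng.integers(nr, size=n_seeds), rng.integers(nc, size=n_seeds)] = True
    dist_builtup = ndimage.distance_transform_edt(~builtup)
    roads = _line_mask(rng, shape, int(p["n_roads"]))
    dist_road = ndimage.distance_transform_edt(~roads)

    pop_density = -0.02 * dist_builtup + 0.5 * _smooth_noise(rng, shape, sigma)
    gdp = 0.8 * pop_density + 0.5 * _smooth_noise(rng, shape, sigma)

    block = int(p["county_block"])
    county_row = np.minimum(np.arange(nr) // block, nr // block - 1)
    county_col = np.minimum(np.arange(nc) // block, nc // block - 1)
    n_cr, n_cc = county_row.max() + 1, county_col.max() + 1

    def county_layer() -> np.ndarray:
        values = rng.standard_normal((n_cr, n_cc))
        return values[np.ix_(county_row, county_col)]

    layers = {
        "elevation": elevation, "aspect": aspect, "slope": slope,
        "precipitation": precipitation, "temperature": temperature,
        "dist_builtup": dist_builtup, "dist_road": dist_road,
        "pop_density": pop_density, "gdp": gdp,
        "livestock_density": county_layer(), "agri_output": county_layer(),
        "husbandry_output": county_layer(), "eco_investment": county_layer(),
    }
    assert tuple(layers) == DRIVER_NAMES
    if not standardize:
        return DriverStack(layers=layers, standardized=False)
    std_layers, std_params = {}, {}
    for name, arr in layers.items():
        mu, sd = float(arr.mean()), float(arr.std())
        if sd == 0.0:
            raise ValueError(f"layer {name!r} has zero variance; cannot standardize")
        std_layers[name] = (arr - mu) / sd
        std_params[name] = (mu, sd)
    return DriverStack(layers=std_layers, standardized=True,
                       standardization=std_params)


# ---------------------------------------------------------------------------
# maps
# ---------------------------------------------------------------------------

def _linear_predictors(drivers: DriverStack,
                       beta: dict[int, dict[str, float]]) -> dict[int, np.ndarray]:
    etas = {}
    for k, coefs in beta.items():
        eta = np.full(drivers.shape, float(coefs.get("intercept", 0.0)))
        for name, b in coefs.items():
            if name == "intercept":
                continue
            eta += b * drivers[name]
        etas[k] = eta
    return etas


def _majority_smooth(codes: np.ndarray, classes: list[int], passes: int) -> np.ndarray:
    kernel = np.ones((3, 3))
    out = codes
    for _ in range(passes):
        counts = np.stack([
            ndimage.correlate((out == k).astype(float), kernel, mode="constant")
            for k in classes
        ])
        out = np.asarray(classes, dtype=np.int32)[np.argmax(counts, axis=0)]
    return out


def generate_initial_map(drivers: DriverStack,
                         true_beta: dict[int, dict[str, float]],
                         seed: int = 0, smoothing_passes: int = 2,
                         cell_size_m: float = 500.0, label: str = "t0",
                         max_retries: int = 5,
                         require_all_classes: bool = True) -> LandCoverGrid:
    """Draw a class map from the softmax of the true linear predictors.

    Sampling uses the Gumbel-argmax trick (exactly softmax-distributed,
    deterministic given the seed), followed by 3x3 majority smoothing to
    form contiguous patches. If smoothing erases a class the draw is
    retried with a perturbed stream, up to ``max_retries``.
    """
    classes = sorted(true_beta)
    etas = _linear_predictors(drivers, true_beta)
    eta_stack = np.stack([etas[k] for k in classes])
    for attempt in range(max_retries):
        rng = np.random.default_rng((seed, attempt))
        gumbel = rng.gumbel(size=eta_stack.shape)
        codes = np.asarray(classes, dtype=np.int32)[
            np.argmax(eta_stack + gumbel, axis=0)]
        codes = _majority_smooth(codes, classes, smoothing_passes)
        if not require_all_classes or all((codes == k).any() for k in classes):
            return LandCoverGrid(codes, cell_size_m=cell_size_m, label=label,
                                 legend=dict(DEFAULT_LEGEND))
    raise RuntimeError(
        f"class(es) missing after smoothing in {max_retries} attempts; "
        "the coefficient set is too degenerate for the requested composition")


def calibrate_intercepts(drivers: DriverStack,
                         beta: dict[int, dict[str, float]],
                         targets: dict[int, float], seed: int = 0,
                         smoothing_passes: int = 2, inner_iters: int = 40,
                         outer_iters: int = 6, outer_step: float = 0.6) -> dict[int, dict[str, float]]:
    """Choose intercepts so the generated composition hits the targets.

    Inner loop: iterative proportional fitting on the expected softmax
    composition. Outer loop: corrects for the (rare-class-eroding) bias
    of majority smoothing by sampling a map and nudging intercepts
    toward the realized composition; updates are damped and clipped
    because erosion responds nonlinearly to the intercepts.
    Deterministic given the seed.
    """
    classes = sorted(beta)
    tgt = np.array([targets[k] for k in classes], dtype=float)
    tgt = tgt / tgt.sum()
    beta = {k: dict(v) for k, v in beta.items()}
    for k in classes:
        beta[k].setdefault("intercept", 0.0)
    base = np.stack([
        _linear_predictors(drivers, {k: {n: b for n, b in beta[k].items()
                                         if n != "intercept"}})[k]
        for k in classes
    ])
    b = np.array([beta[k]["intercept"] for k in classes])
    n_cells = base[0].size
    floor = 1.0 / n_cells
    for _ in range(inner_iters):
        eta = base + b[:, None, None]
        eta -= eta.max(axis=0, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=0, keepdims=True)
        realized = p.reshape(len(classes), -1).mean(axis=1)
        b += np.log(tgt / np.maximum(realized, floor))
    for it in range(outer_iters):
        for k, bi in zip(classes, b):
            beta[k]["intercept"] = float(bi)
        grid = generate_initial_map(drivers, beta, seed=(seed + 1000 + it),
                                    smoothing_passes=smoothing_passes)
        counts = grid.class_counts()
        realized = np.array([counts[k] for k in classes], dtype=float)
        realized = np.maximum(realized, 1.0) / realized.sum()
        b += np.clip(outer_step * np.log(tgt / realized), -1.5, 1.5)
    for k, bi in zip(classes, b):
        beta[k]["intercept"] = float(bi)
    return beta


def evolve_map(grid: LandCoverGrid, drivers: DriverStack,
               true_beta: dict[int, dict[str, float]], true_P: np.ndarray,
               seed: int = 0, label: str = "t1") -> LandCoverGrid:
    """Advance the map one interval under the true transition matrix.

    Each cell's destination is drawn i.i.d. from its origin row of
    ``true_P``; within each origin class the drawn moves to class j land
    on the cells ranked most suitable for j (by the true linear
    predictor), so aggregate transition frequencies converge to the
    matrix while the spatial pattern tracks suitability.
    """
    true_P = np.asarray(true_P, dtype=float)
    classes = sorted(grid.legend)
    k = len(classes)
    if true_P.shape != (k, k) or not np.allclose(true_P.sum(axis=1), 1.0, atol=1e-9) \
            or (true_P < 0).any():
        raise ValueError("true_P must be a row-stochastic k x k matrix")
    rng = np.random.default_rng(seed)
    etas = _linear_predictors(drivers, true_beta)
    flat_codes = grid.codes.ravel().copy()
    valid = grid.valid_mask.ravel()
    new_codes = flat_codes.copy()
    for i, code_i in enumerate(classes):
        cells = np.nonzero(valid & (flat_codes == code_i))[0]
        if cells.size == 0:
            continue
        dest = rng.choice(k, size=cells.size, p=true_P[i] / true_P[i].sum())
        remaining = cells
        for j, code_j in enumerate(classes):
            if code_j == code_i:
                continue
            n_move = int((dest == j).sum())
            if n_move == 0 or remaining.size == 0:
                continue
            eta_j = etas[code_j].ravel()[remaining]
            top = np.argsort(-eta_j, kind="stable")[:n_move]
            new_codes[remaining[top]] = code_j
            remaining = np.delete(remaining, top)
    return grid.with_codes(new_codes.reshape(grid.shape), label=label)


def generate_scenario(size: int = 256, seed: int = 0,
                      config: dict | None = None) -> SyntheticScenario:
    """Full synthetic study region: drivers + t0/t1/t2 with known truth.

    The three dates are labelled "2000", "2010", "2020" so the bundled
    biocapacity factor epochs apply directly.
    """
    cfg = {
        "composition": dict(DEFAULT_COMPOSITION),
        "true_beta": {k: dict(v) for k, v in DEFAULT_TRUE_BETA.items()},
        "true_P": DEFAULT_TRUE_P,
        "labels": ("2000", "2010", "2020"),
        **DEFAULT_PARAMS,
        **(config or {}),
    }
    shape = (size, size)
    root = np.random.default_rng(seed)
    sub = root.integers(2**31, size=4)
    drivers = generate_drivers(shape, seed=int(sub[0]), params=cfg)
    beta = calibrate_intercepts(drivers, cfg["true_beta"], cfg["composition"],
                                seed=int(sub[1]),
                                smoothing_passes=cfg["smoothing_passes"])
    labels = cfg["labels"]
    t0 = generate_initial_map(drivers, beta, seed=int(sub[1]),
                              smoothing_passes=cfg["smoothing_passes"],
                              cell_size_m=cfg["cell_size_m"], label=labels[0])
    true_P = np.asarray(cfg["true_P"], dtype=float)
    t1 = evolve_map(t0, drivers, beta, true_P, seed=int(sub[2]), label=labels[1])
    t2 = evolve_map(t1, drivers, beta, true_P, seed=int(sub[3]), label=labels[2])
    return SyntheticScenario(
        grids={"t0": t0, "t1": t1, "t2": t2},
        drivers=drivers, true_beta=beta, true_P=true_P,
        seed=seed, config={k: v for k, v in cfg.items() if k != "true_P"},
    )
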