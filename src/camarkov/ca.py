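"""Cellular-automaton allocation of Markov class quantities.

Quantity comes from the Markov projection (hard per-class cell-count
targets); pattern comes from ranking cells by transition potential,
the product of logistic suitability and a neighborhood weight computed
with an odd square filter (default 5 x 5, 10 cycles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .markov import TransitionModel, largest_remainder, project_class_areas
from .raster import LandCoverGrid
from .suitability import SuitabilityAtlas


@dataclass
class CAConfig:
    """Allocation parameters: window width, cycle count, tie handling."""

    filter_size: int = 5
    cycles: int = 10
    seed: int = 0
    neighbor_floor: float = 0.01
    tiebreak: str = "deterministic"  # or "random"

    def __post_init__(self) -> None:
        if self.filter_size < 3 or self.filter_size % 2 == 0:
            raise ValueError("filter_size must be an odd integer >= 3")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if not (0.0 < self.neighbor_floor < 1.0):
            raise ValueError("neighbor_floor must be in (0, 1)")
        if self.tiebreak not in ("deterministic", "random"):
            raise ValueError("tiebreak must be 'deterministic' or 'random'")


def neighborhood_weight(grid: LandCoverGrid, class_code: int,
                        filter_size: int = 5,
                        floor: float = 0.01) -> np.ndarray:
    """Fraction of valid cells of the class within the square window.

    Windows are truncated at the lattice edge (no wraparound); the
    result is floored at ``floor`` so absent neighborhoods keep a small
    positive weight.
    """
    if filter_size < 3 or filter_size % 2 == 0:
        raise ValueError("filter_size must be an odd integer >= 3")
    kernel = np.ones((filter_size, filter_size))
    valid = grid.valid_mask.astype(float)
    like = ((grid.codes == class_code) & grid.valid_mask).astype(float)
    n_like = ndimage.correlate(like, kernel, mode="constant", cval=0.0)
    n_valid = ndimage.correlate(valid, kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, n_like / n_valid, 0.0)
    return np.maximum(frac, floor)


def simulate_ca(grid_t: LandCoverGrid, atlas: SuitabilityAtlas,
                model: TransitionModel, cfg: CAConfig | None = None) -> LandCoverGrid:
    """One CA-Markov step: allocate projected quantities on the lattice.

    Per-class targets are the largest-remainder rounding of the Markov
    projection of current counts. Each cycle interpolates an interim
    quota, recomputes neighborhood weights from the current map, and
    lets deficit classes claim the best-ranked cells (suitability x
    neighborhood) from surplus classes; a cell moves at most once per
    cycle and never into a class whose suitability there is zero.
    """
    cfg = cfg or CAConfig()
    if atlas.shape != grid_t.shape:
        raise ValueError("atlas and grid are not congruent")
    classes = model.classes
    if set(classes) != set(grid_t.legend):
        raise ValueError("transition model classes do not match grid legend")
    missing = [k for k in classes if k not in atlas.probabilities]
    if missing:
        raise KeyError(f"atlas lacks suitability layer(s) for class(es) {missing}")

    codes = grid_t.codes.copy()
    valid = grid_t.valid_mask
    n_valid = int(valid.sum())
    counts0 = np.array([grid_t.class_counts()[k] for k in classes], dtype=int)
    projected = project_class_areas(model, counts0.astype(float), steps=1)
    targets = largest_remainder(projected, n_valid)

    rng = np.random.default_rng(cfg.seed)
    flat_valid = valid.ravel()
    code_pos = {k: i for i, k in enumerate(classes)}

    for cycle in range(1, cfg.cycles + 1):
        frac = cycle / cfg.cycles
        quota = largest_remainder(counts0 + frac * (targets - counts0), n_valid)
        cur = np.array([int(((codes == k) & valid).sum()) for k in classes])
        deficit = quota - cur
        if not (deficit > 0).any():
            continue
        surplus = np.maximum(cur - quota, 0)

        # transition potential per class, computed on the cycle-start map
        weights = {k: neighborhood_weight(
            grid_t.with_codes(codes), k, cfg.filter_size, cfg.neighbor_floor)
            for k in classes}
        reassigned = np.zeros(codes.size, dtype=bool)
        flat_codes = codes.ravel()

        for ki in np.argsort(-deficit, kind="stable"):
            need = int(deficit[ki])
            if need <= 0:
                continue
            k = classes[ki]
            p_k = np.nan_to_num(atlas[k], nan=0.0)
            tp = (p_k * weights[k]).ravel()
            cand = np.nonzero(flat_valid & (flat_codes != k) & (tp.ravel() > 0)
                              & (p_k.ravel() > 0) & ~reassigned)[0]
            if cfg.tiebreak == "random":
                cand = rng.permutation(cand)
            # descending potential; stable sort keeps row-major order on ties
            cand = cand[np.argsort(-tp[cand], kind="stable")]
            taken = 0
            for idx in cand:
                src = code_pos[int(flat_codes[idx])]
                if surplus[src] <= 0:
                    continue
                flat_codes[idx] = k
                reassigned[idx] = True
                surplus[src] -= 1
                taken += 1
                if taken == need:
                    break
        codes = flat_codes.reshape(codes.shape)

    final = np.array([int(((codes == k) & valid).sum()) for k in classes])
    if not np.array_equal(final, targets):
        raise RuntimeError(
            "allocation failed to meet Markov targets "
            f"(got {final.tolist()}, want {targets.tolist()}); "
            "zero-suitability cells may have blocked reassignment")
    return grid_t.with_codes(codes)
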