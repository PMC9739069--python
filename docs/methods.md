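# Methods

## The model chain

The package simulates categorical land-cover change on a square lattice
by separating *how much* changes from *where* it changes.

**Quantity.** Cross-tabulating two dated maps gives transition counts
n(i→j); dividing each row by its total yields the row-stochastic matrix
P. Class quantities are projected forward by S·P per step, where one
step equals one observed inter-map interval (a decade in the bundled
defaults). Rows whose origin class is absent are set to the identity so
that projection is always defined. The projection is a first-order,
time-homogeneous Markov assumption: transition rates estimated in the
calibration interval are held constant into the forecast interval.

**Pattern.** Per-class binary logistic regressions of occurrence on
standardized drivers give, at every cell, the probability that class k
occurs there — the suitability atlas. The cellular automaton multiplies
suitability by a neighborhood weight (the fraction of same-class cells
in an odd square window, floored at a small ε) and lets classes whose
Markov quota exceeds their current count claim the best-ranked cells
from classes in surplus. Quotas are interpolated linearly over the
configured cycles so change accrues gradually and the neighborhood term
can respond to the evolving map; final counts equal the Markov targets
exactly by construction.

**Validation.** Simulated vs observed maps are compared with Cohen's
Kappa (chance agreement from marginal products), reported together with
the qualitative banding poor < 0.4 ≤ general < 0.75 ≤ very good.
Suitability fits are judged by the rank-based ROC area (ties counted
one half), with 0.7 the conventional usability bar.

**Accounting.** Biocapacity is composition-linear:
BC = Σᵢ Aᵢ·YFᵢ·EQFᵢ (gha), with a bundled decadal factor table in which
built-up and deserted land carry zero yield and the forecast epoch
inherits the latest factors (constant-factor extrapolation). Because BC
is invariant to spatial rearrangement, the landscape-metric suite (NP,
MPS, LPI, PSCV, DIVISION, AI, SHDI) is computed alongside it to capture
configuration: fragmentation and aggregation changes that composition
metrics cannot see.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| cell size | 500 | m | working resolution; cell area 25 ha |
| nodata code | 0 | – | excluded from every statistic |
| CA filter | 5 × 5 | cells | square contiguity window |
| CA cycles | 10 | – | gradual quota interpolation |
| neighbor floor ε | 0.01 | – | keeps isolated colonization possible |
| sample per class | 5 000 | cells | stratified without replacement; smaller classes contribute all cells with a warning |
| L2 penalty | 1e-6 | – | finiteness under separation/collinearity only; C = 1e6 in the solver |
| patch connectivity | 8 | – | queen-case patch delineation |
| AI adjacency | rook, single-count | – | largest-square normalization bound |
| step length | 10 | years | one observed interval per projection step |

Class imbalance in the logistic fits is handled by inverse-frequency
observation weights (equivalent to balancing presences and absences),
which stabilizes rare-class models such as water at ~0.5% of the area.

## The synthetic generator

The generator emulates the structure of an agro-pastoral study region:

- **Drivers (13 layers, 4 families).** Smooth elevation (low-pass
  filtered Gaussian noise) with finite-difference slope and aspect;
  precipitation and temperature as directional gradients plus smooth
  noise; Euclidean distance transforms from seeded settlement points
  and random road transects; two smooth population/economy fields tied
  to settlement proximity; and four county-constant socio-economic
  layers on a rectangular partition (auto-sized to keep several
  counties per axis).
- **Initial map.** Cell classes are drawn from the softmax of known
  per-class linear predictors (Gumbel-argmax sampling), then majority-
  smoothed (3 × 3, 2 passes) into contiguous patches. Intercepts are
  calibrated so the realized composition matches the target mix
  (cultivated ≈ 38%, grassland ≈ 46%, forest ≈ 11%, built-up ≈ 3%,
  deserted ≈ 2%, water ≈ 0.5%): an inner iterative-proportional-fitting
  loop on the expected softmax composition, then a damped, clipped
  outer loop that corrects the rare-class erosion caused by smoothing.
- **Forward evolution.** Each cell's destination is drawn i.i.d. from
  its origin row of the known transition matrix; within an origin
  class, the drawn moves to class j land on the cells ranked most
  suitable for j, so aggregate frequencies converge to the matrix while
  the pattern tracks suitability.
- **Loadings.** The default coefficient table gives every class a
  monotone-extreme signature on dedicated driver axes (e.g. grassland:
  high livestock density, dry/cool, far from roads; desert separated
  from grassland by livestock and investment rather than by being "even
  drier"). This matters because the fitted suitability models are
  linear one-vs-rest scorers: a class occupying the *middle* of a
  shared gradient has hump-shaped occurrence that no linear score can
  rank well, whereas extremes are linearly separable. The default
  construction keeps every class's occurrence ROC above 0.9.

What the generator does **not** emulate: real geography or county
shapes, classification error in the input maps, temporal driver change
(drivers are held fixed across dates), anisotropic or long-range
spatial dependence, and sub-cell mixed cover. Passing tests on
synthetic scenarios therefore demonstrate the *internal correctness*
of estimation, allocation and accounting — matrix recovery, exact
quota satisfaction, coefficient recovery, agreement scores — not the
predictive skill of the model chain on any real landscape.

## Numerical choices

- **Quota rounding.** Projected class areas are converted to integer
  cell targets by largest-remainder rounding (ties to the lower class
  index), which conserves the total exactly and guarantees the CA a
  feasible target vector.
- **Allocation order and ties.** Deficit classes are processed in
  descending-deficit order; candidate cells in descending transition
  potential with row-major index as the deterministic tie-break (an
  optional seeded random tie order is available). A cell is reassigned
  at most once per cycle, donors are capped at their surplus, and cells
  with zero suitability for a class are never assigned to it.
- **Windows at edges.** Neighborhood fractions use truncated windows
  (no wraparound): the denominator is the number of in-grid valid cells.
- **Degenerate cases.** Kappa of two identical constant maps is defined
  as 1 with a warning; the aggregation index of a single-cell class is
  defined as 100 (a 1 × 1 patch attains its own largest-square bound);
  zero-variance layers cannot be standardized and are rejected by name;
  a single-date biocapacity series omits the trend with a warning.
- **Logistic fitting.** Maximum likelihood via lbfgs with a ridge
  penalty of 1e-6 so separable or duplicated-driver designs return
  finite coefficients and unchanged predictions; hitting the iteration
  cap is reported as non-convergence on the result rather than raised.
- **PSCV** uses the population standard deviation; **LPI** is
  normalized by total landscape area, not class area; landscape-scale
  **AI** is the class-area-weighted mean of class AIs.

## Design choices where the design was open

- Occurrence (not change-event) response for the suitability models:
  the probability being modelled is "class k occurs here", which is
  what the atlas must rank for allocation.
- Drivers are z-scored before fitting so coefficient magnitudes are
  comparable across layers with wildly different native scales, and a
  "main influencing factor" cut at |β| > 0.5 is meaningful.
- Competitive ranking allocation (hard Markov quotas, suitability ×
  neighborhood ranking) rather than an opaque multi-objective solver:
  the mechanism is fully specified, deterministic under a fixed seed,
  and auditable cell by cell.
- The forecast refits suitability at the latest observed date rather
  than reusing the validation-leg fit, mirroring the calibrate→validate
  →forecast sequencing.
- The most recent observed interval calibrates the forecast interval.
- Raster I/O uses single-band TIFF plus a JSON metadata sidecar
  (legend, nodata, cell size, geotransform); coordinate reference
  systems and reprojection are out of scope.

## Problem sizes

Default synthetic scenarios are 256 × 256 cells (65 536 cells ≈ 1.6 M ha
at 500 m), which the full pipeline — generation, fitting, allocation,
validation, accounting — processes in a few seconds on one CPU; unit
tests use 64 × 64 scenes. These sizes were chosen as the package's own
desk-scale defaults; all operations scale linearly in cell count except
patch labelling, which is near-linear.

## Known limitations

- Time-homogeneous, first-order Markov quantities; no annualization or
  interval-mismatch correction.
- Suitability is static over a simulation (drivers do not evolve), and
  spatial autocorrelation of residuals is not modelled.
- No per-class persistence or protection constraints (e.g. water
  immutability) — none are assumed by default.
- Biocapacity factors are user-overridable but the bundled table is a
  four-productive-class scheme; demand-side (footprint) accounting is
  out of scope.
- Kappa is reported whole-map only; location/quantity decompositions
  and fuzzy comparison are not implemented.
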