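# camarkov

Logistic-CA-Markov land-use/land-cover (LULC) change simulation, with
biocapacity accounting and landscape-pattern metrics — the modelling
chain used to forecast the evolution of agro-pastoral transition zones,
where cultivated land, grassland and forest interleave and small shifts
in land cover change both the region's biological productivity and the
fragmentation of its landscape.

## What it computes

The pipeline couples three classical components:

1. **Logistic suitability models.** For each land class *i*, occurrence
   is regressed on a stack of standardized driver rasters (terrain,
   climate, accessibility, socio-economic layers):

   logit *p*ᵢ = β₀ + β₁X₁ + β₂X₂ + ⋯ + βₙXₙ

   Applying the fitted model over the lattice gives a per-class
   *suitability atlas*; fit quality is judged by rank-based ROC area.

2. **Markov quantity projection.** Cross-tabulating two dated maps
   yields the transition count matrix and the row-stochastic probability
   matrix *P* (*p*ᵢⱼ = probability class *i* becomes class *j* over one
   interval); class quantities propagate as *S*ₜ₊₁ = *S*ₜ·*P*, with one
   step per observed inter-map interval.

3. **CA allocation.** A cellular automaton places the projected
   quantities on the lattice: cells are ranked by transition potential
   (suitability × neighborhood weight from an odd square filter,
   default 5 × 5 over 10 cycles), growing classes claim the best-ranked
   cells from shrinking ones, and final class counts match the Markov
   targets exactly.

Agreement between a simulated and an observed map is scored with
Cohen's Kappa (poor < 0.4 ≤ general < 0.75 ≤ very good). On top of the
simulated maps the package computes:

- **Biocapacity** (BC = Σᵢ Aᵢ·YFᵢ·EQFᵢ, in global hectares), from a
  bundled yield-factor/equivalence-factor table in which built-up and
  deserted land have zero yield, plus least-squares annual trends; and
- **Landscape metrics** at class and landscape scale: NP, MPS, LPI,
  PSCV, DIVISION, AI and SHDI, with 8-neighbour patch delineation and
  rook adjacency counting for AI.

Because real continental-scale land-cover archives cannot ship with a
package, a first-class synthetic-scenario generator produces study
regions with *known* ground truth — known logistic coefficients, known
transition matrix — so every stage is testable end to end.

## Worked example

```python
import camarkov as cm

sc = cm.generate_scenario(size=128, seed=42)        # maps for 2000/2010/2020
model = cm.CAMarkov.from_scenario(sc, use=("t0", "t1"))
res = model.fit(seed=42)
print(res.summary())

forecast = res.simulate(steps=1, labels=["2020"])
report = res.validate(sc.t2, forecast)
print(f"validation Kappa vs observed 2020 map: {report['kappa']:.3f} ({report['band']})")

bc, trend = cm.bc_timeseries([sc.t0, sc.t1, sc.t2])
print(f"biocapacity trend: {trend['total']:+.4g} gha/a")
```

prints

```
Logistic-CA-Markov model fit
================================================================
maps: 2000 -> 2010   lattice: 128 x 128   seed: 42

Transition probability matrix (rows = origin):
           Cultivat    Forest  Grasslan     Water  Built up  Deserted
Cultivate    0.9471    0.0090    0.0189    0.0018    0.0173    0.0059
Forest       0.0114    0.9539    0.0273    0.0006    0.0034    0.0034
Grassland    0.0333    0.0143    0.9327    0.0020    0.0083    0.0095
Water        0.0112    0.0000    0.0112    0.9775    0.0000    0.0000
Built up     0.0000    0.0021    0.0021    0.0000    0.9958    0.0000
Deserted     0.0095    0.0000    0.0536    0.0095    0.0000    0.9274

Per-class suitability fits (training ROC area):
  Cultivated land  ROC = 0.949   main drivers: slope=-2.43, agri_output=+1.96, gdp=+1.95
  Forest           ROC = 0.981   main drivers: dist_builtup=+4.44, slope=+4.03, pop_density=+3.90
  Grassland        ROC = 0.964   main drivers: livestock_density=+3.04, precipitation=-2.96, gdp=-2.74
  Water            ROC = 1.000   main drivers: slope=-14.64, elevation=-14.28, gdp=-6.84
  Built up         ROC = 0.994   main drivers: gdp=+12.51, dist_road=-5.60, pop_density=+3.29
  Deserted land    ROC = 0.997   main drivers: livestock_density=-6.56, eco_investment=-6.49, precipitation=-5.57

validation Kappa vs observed 2020 map: 0.909 (very good)
biocapacity trend: +3434 gha/a
```

The diagonal of the estimated matrix shows decadal persistence around
0.93–0.99; every suitability model clears the ROC > 0.7 usability bar
comfortably; the simulated 2020 map agrees with the withheld observed
map in the "very good" Kappa band, so the calibration is fit for
forecasting one interval ahead.

The same stages are available from the shell:

```bash
camarkov synth --out scenario/ --seed 1 --size 256
camarkov markov scenario/t0.tif scenario/t1.tif --out P.json
camarkov forecast --t1 scenario/t1.tif --t2 scenario/t2.tif \
    --drivers scenario/drivers --seed 1 --out bundle/
```

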