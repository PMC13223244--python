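# urban330

Assessment of the **3-30-300 urban greening rule** on gridded city data:
every dwelling should have a view of **3** trees, every neighborhood at
least **30%** tree-canopy cover, and every resident a public green space of
at least 1 ha within **300 m**. `urban330` turns these three benchmarks
into population-weighted, per-city metrics computed from raster layers —
building heights, tree counts, tree-cover density, residential population
(all on a common 100 m grid) and categorical land use (50 m) — plus a city
boundary polygon.

It is written for urban ecologists, geographers and planners who want a
reproducible, testable implementation of the rule rather than a one-off
GIS workflow, and it ships a synthetic-city generator so the whole
pipeline can be exercised and validated without downloading any data.

## The three metrics

For a city with total population POP_city:

- **Rule 3 (visibility).** Observation points are scattered over the city
  by dart throwing with a minimum Euclidean spacing *d* ∈ {100, 250, 500} m.
  From each point, a viewshed of radius *r* ∈ {100, 250} m is computed
  against the building-height obstacle layer with observer and target at
  1.6 m above flat ground; the line-of-sight test is exact (the sight
  segment is clipped cell by cell, and an obstacle blocks when it reaches
  the sight line anywhere on its traversed interval). A cell complies when
  it is visible from at least one point and contains ≥ 3 trees, and

  POP_R3 = Σ POP_green / POP_city.

- **Rule 30 (canopy).** Neighborhoods are square blocks (1 km by default;
  500/250/100 m for sensitivity) anchored at the raster origin. A block
  complies when its mean tree-cover density is ≥ 30%, and

  POP_R30 = Σ POP_in_30 / POP_city.

- **Rule 300 (proximity).** Green land-use patches inside the urban area
  are polygonized (4-connectivity), filtered to ≥ 1 ha, and buffered by a
  Euclidean 300 m radius; a cell complies when its center falls in the
  buffer union, and

  POP_R300 = Σ POP_in_300 / POP_city.

The three boolean grids are intersected at the 100 m cell level into a
0–3 **score** (number of rules met), summarized as population shares per
score; the *full-rule share* is the population at score 3. An equity
module averages the score over a coarser income grid (the *Green Space
Category*), summarizes income by compliance category, and computes seeded
permutation Spearman correlations and bivariate quartile classes of
per-city covariates.

## Worked example

```python
from urban330 import SyntheticCitySpec, generate_city, ThreeThirtyThree, ViewshedConfig

bundle = generate_city(SyntheticCitySpec(seed=7))          # 6 x 6 km, 100k people
res = ThreeThirtyThree(bundle, viewshed_config=ViewshedConfig(seed=7)).fit()
print(res.summary())
```

```
          3-30-300 urban greening assessment
============================================================
City:            synthetic-7
Viewpoints:      2263  (d = 100.0 m, r = 100.0 m)
Green spaces:    2  (>= 1 ha)
Neighborhood:    1000.0 m blocks, threshold 30.0%
------------------------------------------------------------
POP_R3   (3 trees visible)          28.7 %
POP_R30  (30% neighborhood cover)   25.4 %
POP_R300 (park within 300 m)         8.1 %
------------------------------------------------------------
Population share by number of rules met:
    0 rules:   57.4 %
    1 rules:   24.1 %
    2 rules:   17.6 %
    3 rules:    1.0 %
------------------------------------------------------------
Full 3-30-300 compliance:            1.0 %
```

Reading: 28.7% of this synthetic city's residents live in cells that see
at least three trees, 25.4% in neighborhoods with ≥ 30% canopy, but only
8.1% within 300 m of a ≥ 1 ha park (this city has just two parks) — so
only 1.0% of the population satisfies all three benchmarks at once, while
57.4% satisfies none. `res.sensitivity()` sweeps (d, r, block size), and
`res.plot_score(ax)` maps the per-cell score.

The same pipeline runs from the shell on a city directory:

```sh
urban330 synth --seed 7 --out demo_city
urban330 assess --city demo_city --seed 7 --out demo_out
urban330 sweep --city demo_city --d 100,250,500 --r 100,250 --block 1000,500,250,100 --out demo_sweep
```

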