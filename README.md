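# canopyfuse

Classification of individual tree specimens from **fused mobile laser
scanning (MLS) and hyperspectral line-camera data**, as collected by a
vehicle-borne survey driving past an urban experimental garden. A
side-view laser scanner delivers a dense, nearly occlusion-free vertical
point cloud per tree; a co-mounted line spectrometer (659 pixels over a
44.4° vertical opening, binned to 123 channels spanning 397–1,086 nm, with
10 pixels viewing a Spectralon™ white-reference panel) delivers
panel-normalized reflectance. Fusing the two answers two questions: can we
separate **coniferous from deciduous** trees, and can we identify
**individual species**, better than either sensor alone?

The package implements the complete analysis as a reusable, tested
pipeline, together with a synthetic-scene generator so every stage runs
and is validated without any field data:

- **`synthetic_scene`** — parametric garden scenes: conifers as uniform
  cones, deciduous trees as trunk + offset ellipsoid crowns; per-species
  123-channel reflectance curves under strong multiplicative
  (lognormal) illumination noise; a straight constant-speed trajectory;
  truncated spectral coverage of tall near trees.
- **`fusion`** — pixel/point overlap tests (time window along track,
  elevation-angle interval widened by the laser footprint), Spectralon
  normalization `ρ = DN_target / mean(DN_reference)`, per-point pixel
  averaging, and the ≥5-specimens-per-species dataset rule.
- **`features`** — the 34 canopy height-distribution features
  (point ratios PR over normalized-height intervals h_N, skewness,
  kurtosis, height quantiles hq10…hq90, Max, Mean, CV) and the 123
  per-tree mean reflectance features.
- **`classify`** — features scaled to [−1, 1]; RBF-SVM (one-vs-one, grid-
  tuned C and γ by seeded inner CV) and an LDA reference; leave-one-out
  cross-validation; exhaustive single/pair searches; top-10% pair
  selection (ties included); structural-pair × spectral-pair feature
  quadruples; greedy four-iteration forward selection.
- **`report`** — ranked tables, per-class producer/user accuracy
  summaries, the five-way four-feature mode comparison, and the published
  census/error-matrix fixtures used by the tests.

## Worked example

```python
from canopyfuse import (
    generate_scene, fuse, build_feature_table, build_datasets,
    scale_features, exhaustive_search, ClassifierSpec,
)
from canopyfuse.synthetic_scene import small_garden_config

config = small_garden_config(specimens_per_species=7)   # 6 species, 42 trees
scene = generate_scene(config, seed=42)
fused = fuse(scene.specimens, scene.frames, scene.band_set)
separation_set, species_set = build_datasets(fused, min_count=5)
table = build_feature_table(separation_set, scene.band_set)

scaled = scale_features(
    table, label="habit",
    feature_cols=[c for c in table.columns if c.startswith("PR")],
)
pool = ["PR(hN>0.5)", "PR(hN>0.3)", "PR(hN<0.33)", "PR(0.5<hN<0.6)"]
pairs = exhaustive_search(scaled, pool, 2, ClassifierSpec(seed=0))
best = pairs.best()
print(f"{len(scene.specimens)} specimens, {len(scene.frames)} spectrometer frames")
print(f"separation set: {len(separation_set)}   species set: {len(species_set)}")
print(f"best structural pair: {' + '.join(best.subset)}  "
      f"LOOCV accuracy {best.accuracy:.1f}%  (C, gamma) = {best.params}")
```

prints

```
42 specimens, 48 spectrometer frames
separation set: 42   species set: 42
best structural pair: PR(0.5<hN<0.6) + PR(hN<0.33)  LOOCV accuracy 100.0%  (C, gamma) = (1.0, 0.125)
```

Point ratios split the two habits cleanly because the generated conifers
concentrate their returns low in the crown (cone: mean h_N = 1/4) while
deciduous crowns sit high (ellipsoid centred at h_N = 0.7) — the shape
contrast the structural features were designed to capture. On the species
task the single-sensor pairs are much weaker, and fused four-feature sets
(one structural pair + one spectral pair) recover most of the gap; see the
mode comparison in `canopyfuse.report`.

A thin CLI wraps the same pipeline:

```sh
canopyfuse generate --seed 1 --out scene/
canopyfuse classify --table scene/features.csv --task species --mode pair --out results/
```

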