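# cordmap

Spatial cell-distribution analysis for developing spinal-cord
hemi-sections: normalized coordinate mapping of counted cells, pooled
density maps, two-sample Hotelling T² comparison of positional
distributions with per-axis annotation, a per-animal cell-count
comparison workflow, and a synthetic cohort generator for testing and
calibrating the whole pipeline.

## What it does

Counted cells arrive as a per-cell CSV (animal, genotype, section,
marker, position in µm — polar or Cartesian — plus each section's
measured maximal width and height). The package:

1. **geometry** — converts polar positions (distance/angle from the
   ventral-most point; 90° = straight dorsal) to Cartesian, normalizes
   x by section width and y by section height, and superimposes all
   sections of one marker × genotype into a pooled sample.
2. **stats** — compares pooled positions between genotypes with a
   two-sample Hotelling T² (exact F transform by default; χ²
   approximation and a label-permutation variant available), annotates
   each axis with an independent pooled-variance t-test and star
   strings, averages counts per hemi-section within each animal and
   compares per-animal means with an unpaired Student t-test (one- or
   two-tailed as declared), and runs Monte-Carlo type-I-error / power
   calibration.
3. **density** — Gaussian-kernel 2D density maps on the unit square
   (integral 1, Scott's-rule bandwidth with a floor), 1D
   dorsoventral/mediolateral marginal projections, and signed
   control-vs-mutant difference maps.
4. **synthetic** — simulates cohorts (genotypes × animals × sections)
   with Poisson counts, a lognormal per-animal count effect, and
   truncated Gaussian-mixture positions; mutant arms can scale counts
   (cell-loss phenotype), shift cluster centers (displacement
   phenotype), or rescale spreads.
5. **pipeline / CLI** — ties everything into reproducible `simulate`,
   `analyze`, and `calibrate` commands with a TSV + JSON report bundle.

## CLI

```sh
# generate a synthetic cohort (CSV + section inventory + truth log)
cordmap simulate --config cohort.yaml --out sim/ --seed 17

# run the full analysis on a per-cell CSV
cordmap analyze --input sim/cells.csv --sections sim/sections.csv \
    --out report/ --seed 17 --unit cells --test f

# Monte-Carlo calibration over a grid of cohort settings
cordmap calibrate --config grid.yaml --out calib.tsv --n-reps 500 --seed 1
```

`analyze` writes `report.tsv` / `report.json` (one row per marker:
n, T², F, df, p, Δx, Δy, per-axis t/p/stars, count test), per-genotype
density matrices as TSV, marginal projections, and a run log. Reports
are byte-identical across reruns with the same inputs, config, and
seed. `--unit animals` switches the positional test to per-animal
centroids (the default pools individual cells; calibration quantifies
the clustering-induced type-I inflation of that choice).

Example cohort config (YAML):

```yaml
seed: 17
n_animals_per_genotype: 3
n_sections_per_animal: 4
mean_cells_per_section: 40
mixture:
  - {center: [0.45, 0.6], sd: [0.12, 0.1], weight: 1.0}
effect:
  count_ratio: 0.6        # mutant cell loss
  shift: [0.0, -0.1]      # mutant dorsoventral displacement
```

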