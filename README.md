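# cropclim

County-level climate analog analysis for specialty-crop agriculture.

The pipeline answers: *which counties' current climates most resemble a
target county's projected mid-century climate, and do those analog counties
grow similar specialty crops?* It works in five stages:

1. **Derived climate variables** (`cropclim.metrics`) — from daily
   Tmax/Tmin/precipitation it computes a context-specific vector (annual
   growing degree days with a 0–29.44 °C band, longest frost-free run,
   summer heat degree hours above 32 °C via sine-curve hourly
   disaggregation, Oct–Mar chill hours in the 0–7.22 °C band, and the
   wettest-minus-driest-month precipitation range) and a generic vector
   (seasonal mean temperature and precipitation totals for JFM/AMJ/JAS/OND).
2. **County aggregation** (`cropclim.aggregation`) — cells with at least
   1/8 agricultural land fraction are kept; per-cell yearly vectors are
   averaged over each county's agricultural cells; each county gets a
   multi-year climate normal plus an interannual-variability covariance of
   linearly detrended yearly values (ridge-regularized when degenerate).
3. **Analog identification** (`cropclim.analogs`) — Mahalanobis distance
   between a target's future normal and each candidate's historical normal,
   scaled by the candidate's interannual variability, re-expressed as sigma
   dissimilarity through the chi distribution (2σ = 95th percentile,
   4σ = 99.994th). Candidates within 2σ are acceptable analogs; targets
   beyond 4σ of everything are novel climates. Per-GCM acceptable sets are
   merged with an at-least-m-models consensus rule (5 of 19, scaled as
   ⌊n/4⌋+1 for smaller ensembles).
4. **Crop-mix similarity** (`cropclim.cropmix`) — counties are coded
   specialty/non-specialty from a census, targets are the top producers
   covering 99% of specialty acreage, and target–analog pairs are scored by
   the Jaccard fraction of shared specialty crops.
5. **Synthetic data** (`cropclim.synthetic`) — a seeded generator emulating
   gridded daily weather (sinusoidal annual cycle, north–south gradient,
   winter-wet vs. uniform precipitation regimes), a pseudo-GCM warming
   ensemble, land use, a county partition with regions, and a heavy-tailed
   crop census. Known target→analog ground truths can be planted and
   recovered through the full pipeline, which is how the system is tested
   offline end to end.

## CLI

Every stage is a subcommand working against a directory of plain CSVs;
`run-all` does everything in memory:

```bash
cropclim run-all --seed 1 --variable-mode both --out runs/demo
# or stage by stage (each stage reads the previous stage's files):
cropclim synth     --config run.cfg --out runs/demo
cropclim metrics   --config run.cfg --out runs/demo
cropclim analogs   --config run.cfg --out runs/demo
cropclim consensus --config run.cfg --out runs/demo --sensitivity
cropclim cropmatch --config run.cfg --out runs/demo
cropclim report    --config run.cfg --out runs/demo
```

The config file is flat `key: value` text, e.g.

```
seed: 13
grid_rows: 20
grid_cols: 20
n_counties: 40
n_years_hist: 30
n_gcms: 6
variable_mode: both
planted_pairs: 3->30
```

Outputs are `distances_<mode>.csv`, `consensus_<mode>.csv`, `matches.csv`,
`overlap.csv` (when `variable_mode: both`), `summary.json`, and
`manifest.json`. Identical configs produce byte-identical outputs.

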