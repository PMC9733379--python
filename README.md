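# uavcanopy

Estimation of crop canopy height and leaf area index (LAI) from
UAV-photogrammetry point clouds, implemented as a tested, reusable pipeline:

- **geodesy** — WGS84 → ECEF → local east-north-up (ENU) transforms, with the
  frame anchored at the field's southwest low corner and stored alongside the
  cloud so every product is invertible back to geodetic coordinates.
- **terrain** — orthogonal-least-squares terrain planes between adjacent
  sampling regions, per-point relative heights, and ground-elevation
  inversion from sampled plant heights plus the surface model
  (`h_ground = P99 − h_measured`, averaged per plot).
- **canopy_height** — max-value DSM rasterization and 99th-percentile upper
  boundaries per plot/quadrat; `h = P99 − h_ground`.
- **canopy_density** — above-ground segmentation, 2-D point-density matrices
  on an ε grid, the occupancy-ratio statistic g (fraction of cells with
  density ≥ 0.2 × the grid mean), and the maximum canopy diameter.
- **lai_model** — the published three-descriptor linear LAI model
  `LAI = (1.37618·g + 0.66738·d_t − 0.02035·h_e − 0.51087)/0.76`,
  prediction, and bidirectional stepwise OLS fitting (AIC or p-value mode).
- **evaluation** — MAE, RMSE, and two determination coefficients: the
  variance-ratio form (`r2_paper`, can exceed 1) and the conventional
  `1 − SSres/SStot` (`r2_standard`). Both are reported everywhere.
- **synthetic_field** — a seeded generator for georeferenced synthetic cotton
  fields (sloped terrain, row-planted Gaussian-blob plants with a
  defoliation-stage parameter, 32 plots × 4 quadrats, measured heights and
  LAI from a known linear model) so the whole chain is testable offline with
  full ground truth.
- **pipeline / io / cli** — end-to-end orchestration, plain-text formats
  (XYZ-CSV, ASCII PLY, ESRI ASCII grid, GeoJSON layouts, CSV/JSON reports);
  LAS and GeoTIFF are available when the optional `laspy` / `rasterio`
  packages are installed.

## CLI

```bash
# Generate a synthetic field with ground truth
uavcanopy simulate --seed 1 --out sim/

# Full analysis: localize -> ground -> heights -> densities -> LAI -> metrics
uavcanopy run sim/cloud.csv --layout sim/layout.geojson \
    --measurements sim/measurements.csv --out results/

# Individual stages compose to the same results
uavcanopy localize sim/cloud.csv --out local.csv
uavcanopy ground sim/cloud.csv --layout sim/layout.geojson \
    --measurements sim/measurements.csv --out ground.csv
uavcanopy height sim/cloud.csv --layout sim/layout.geojson \
    --ground ground.csv --out heights.csv
uavcanopy density local.csv --eps 1.0 --out density.csv
uavcanopy lai-fit features.csv --out model.json
uavcanopy lai-predict features.csv --out predictions.csv
uavcanopy evaluate pairs.csv --measured measured --estimated estimated
```

`uavcanopy run` accepts `--config config.yaml` with any pipeline option
(cell size, percentile, ε, ground-model mode `inverted`/`as-printed`, row
spacing, stepwise criterion, …); explicit flags override file values.
Every output table carries the config hash for provenance.

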