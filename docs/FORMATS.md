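# File formats

All pipeline artifacts are plain text (CSV, JSON/GeoJSON, YAML) written into
the config's `output_dir`. Coordinates are planar meters; grid indices
`(i, j)` are (row, column) from the lower-left grid origin.

## Landscape (written by `antrisk simulate`)

- `landuse_a.geojson`, `landuse_b.geojson` — polygon `FeatureCollection`s
  for land-cover years A and B; each feature has a `category` property
  (`agriculture | transportation | artificial | natural`). The two layers
  tile the same extent; the derived fifth category *change* is where they
  disagree.
- `roads.geojson` — `LineString` features for road centerlines.
- `landscape_meta.json` — extent, CRS note, generator parameters and the
  realised changed-area fraction.
- `config.yaml` — the validated run configuration, re-serialized.

## Survey tubes

`tubes_wave1.csv`, `tubes_wave2.csv`:

| column  | type  | meaning                                  |
|---------|-------|------------------------------------------|
| tube_id | str   | unique per tube and wave                 |
| x, y    | float | tube position (m)                        |
| period  | str   | survey wave label                        |
| scale   | int   | severity 0–3 (validated on read)         |

`cell_truth.csv` — simulator-only ground truth per sampled cell:
representative covariates, `p_true`, the drawn `label` and the consistent
severity pair `s1, s2`.

## Quantification (written by `antrisk quantify`)

- `cells.csv` — one row per cell sampled in either wave: `i, j, max_s1,
  max_s2, label` (`SIRH | USIRL | undefined`; absent wave maxima are empty).
- `labelled_tubes.csv` — wave-2 tubes in defined cells: original tube
  columns with the coordinate renamed `y_coord`, plus binary `y`
  (1 = SIRH) and `cell_i, cell_j`.
- `quantify_report.json` — cell label counts, labelled-tube count, and the
  number of tubes excluded for undefined cells.

## Model table (written by `antrisk covariates`)

`model_table.csv`: `tube_id, y, landuse5, road_dist, x, y_coord`.
`landuse5` is one of the five categories; `road_dist` is centerline distance
in meters. Validated on read (binary `y`, finite distances).

## Fits and comparison (written by `antrisk fit` / `antrisk compare`)

- `fit_<model>.json` — n, deviance, AIC, total and per-term EDF, selected
  λ, convergence, the odds-ratio table (`param, odds_ratio, se_or, z, p,
  beta, se_beta`) and smooth-term tests (`term, edf, chi2, df, p`).
- `fit_<model>.txt` — the human-readable `summary()`.
- `comparison.json` — per-model AIC/EDF/deviance, `selected` (AIC
  minimizer), and the nested ANOVA chain `GLM_vs_GAM1`, `GAM1_vs_GAM2`
  (`ddf, ddeviance, chi2, p_chi2, F, p_F`).

## Report (written by `antrisk report`)

- `report.json` — severity summaries per wave, the land-use × label
  contingency table with Pearson χ², change-transition percentages, and
  distance thresholds `d*` at the requested p₀.
- `distance_curve_<category>.csv` — `distance, p` at 1 m resolution.
- `risk_surface.csv` — one row per grid cell: `i, j, x_center, y_center,
  p, lp0, lp_landuse, lp_dist, lp_spatial`. The four `lp*` columns are the
  component-wise linear-predictor contributions (intercept, land use,
  distance, spatial) and sum exactly to `logit(p)`.
- `distance_curves.png`, `risk_surface.png` — matplotlib figures.

## Acceptance script output

`python scripts/acceptance.py --seed <int> --out <path>` writes a flat JSON
object `{"<name>": {"value": <number>, "n": <size>}}` where `n` is the
sample or replicate count behind each value.
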