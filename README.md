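# tercab

Terrestrial ecosystem carbon-balance analysis on co-registered annual
raster stacks. The package chains six analysis stages:

1. **Carbon storage** (`tercab.storage`) — per-pixel carbon density from a
   land-use map and a per-class four-pool density table (aboveground,
   belowground, soil organic, dead organic matter; Mg/hm²); regional
   totals in Tg; class-by-class land-use **transfer matrices** (km²).
2. **Net ecosystem productivity** (`tercab.nep`) — annual soil respiration
   `Rs = 1.55·e^(0.031T)·P/(P+0.68)·SOC/(SOC+2.23)` (kg C m⁻² yr⁻¹,
   with T in °C, P in **metres**, SOC in kg C m⁻²), heterotrophic
   respiration `Rh = 0.6163·Rs^0.7918`, and `NEP = NPP − Rh` (g C m⁻²
   yr⁻¹); positive NEP = carbon sink.
3. **Carbon balance** (`tercab.balance`) — `CB = CS + 0.01·NEP·Δt`
   (Mg/hm²) with per-year/per-class interannual summaries and windowed
   rates of change.
4. **Trend analysis** (`tercab.trend`) — per-pixel least-squares slope
   against the year index, F-test significance with df (1, n−2), and the
   five-way ESI/SI/NSC/SD/ESD classification with area summaries.
5. **Correlation screening** (`tercab.correlation`) — per-pixel partial
   correlation of the balance with temperature (controlling
   precipitation) and vice versa, t-test with n−m−1 df (m = 2 by
   default), six-way classification.
6. **Driver attribution** (`tercab.attribution`) — per-pixel regression
   `CB_CC = a·T + b·P + c`, residual `CB_HA = CB_obs − CB_CC`, six driver
   scenarios from the slope signs, contribution rates as slope ratios
   (clipped to [0, 100]%), and five 20-%-wide contribution levels.
7. **Factor detection** (`tercab.geodetector`) — stratified-variance
   q statistic `q = 1 − ΣN_h·σ_h²/(N·σ²)` with quantile/equal-interval
   discretisation of continuous drivers, and pairwise interaction
   detection on overlay stratifications.

A synthetic-scene generator (`tercab.synthetic`) produces multi-year
stacks with known ground truth — Markov land-cover transitions,
deterministic "human disturbance" patches, smooth climate fields with
configurable trends/noise, climate-responsive NPP, and static covariate
grids — so every stage is testable without external data. Published
reference tables (the default carbon-density table, a 2000–2022
transfer matrix and three five-class trend-area tables from a tropical
island study region) ship under `tercab.reference_tables`.

## CLI

Each stage runs from a JSON config, e.g.

```json
{
  "scene": {"shape": [48, 64], "seed": 1,
            "human_patches": [{"year": 2010, "row0": 4, "col0": 6,
                               "height": 10, "width": 10, "target_class": 7}]},
  "stages": ["report"]
}
```

```bash
tercab simulate  --config scene.json --outdir out/   # scene + truth.json
tercab trend     --config scene.json --outdir out/ --seed 7
tercab report    --config scene.json --outdir out/   # all stages
```

Stages: `simulate storage nep balance trend corr attribute geodetect
transfer report`. Instead of `"scene"`, a config may name real raster
inputs per variable (`"inputs"` with `{year}` path patterns plus
`"years"` and `"pixel_area_hm2"`). Every run writes `run_log.json` with
the seed and versions; identical config + seed reproduces identical
outputs bit for bit.

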