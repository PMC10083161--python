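# gwtrend

Spatially varying temporal trends for monitoring networks that are dense in
space but sparse in time.

National environmental surveys often visit thousands of stations but only
once every few years, in a *rotating panel* design: stations are split into
panels revisited on a fixed cycle, so each series holds just two or three
observations.  Station-wise trend tests (Mann–Kendall, Sen slopes) are
useless at that length, and a single country-wide regression hides regional
differences.  `gwtrend` closes the gap by adapting geographically weighted
regression (GWR) to time: at every station a local weighted least squares
line is fitted, borrowing observations from a spatial neighbourhood, so
that trends vary smoothly over space while each local fit pools enough data
to be estimable.  The intended users are biostatisticians and environmental
agencies analysing water-chemistry panels (the motivating variable is lake
total organic carbon, mg/L), but nothing is specific to that variable.

## Model

For station *i* with observations *j*:

```
Y_ij = β_i0 + β_i · t_ij + ε_ij,        ε_ij ~ N(0, σ²)
```

where `Y` is the log10 value (station-wise mean-centered), `t` the
observation year, and `(β_i0, β_i)` vary by location.  The local fit at
station *i* weights every observation by a bisquare kernel

```
w_ij = (1 − (d_ij/b)²)²   if d_ij < b,   else 0
```

with adaptive bandwidth `b` = distance to the k-th nearest observation.
`k` is chosen by leave-one-out cross-validation.  Standard errors follow
the weighted-least-squares convention with a global residual variance
`σ̂² = RSS / (n − 2·tr(S) + tr(SᵀS))`, and per-station two-sided t
p-values are left unadjusted — they delineate regions with trends, they
are not confirmatory tests.

Supporting stages: log10 transform, a ≥2-observations filter, a
log-normal coefficient-of-variation screen
(`CV = sqrt(exp(s_ln²) − 1)`, `s_ln = s10·ln 10`) for suspicious series,
Moran's I of the per-station change-per-year as a clustering diagnostic,
multi-program merging, and moving 10-year windows to expose nonlinearity.
A synthetic rotating-panel generator with known trend surfaces makes every
stage testable without any external data.

## Worked example

```python
import numpy as np
from gwtrend import *

config = SyntheticConfig(n_stations=400, seed=3)        # 6 panels, 2008-2021
surface = two_region_surface(config.bounds)             # +0.015 west, -0.02 east
stations = generate_network(config)
schedule = assign_panels(stations, config)
table = simulate_observations(schedule, stations, surface, config)
print("observations:", table.n_obs, "stations:", table.n_stations)

summ = station_summaries(table)
print("stations with CV > 0.8:", len(flag_high_cv(summ, 0.8)))

ok = summ.dropna(subset=["change_per_year"])
moran = morans_i(ok["change_per_year"].to_numpy(), ok[["x", "y"]].to_numpy())
print(f"Moran's I of change/yr: {moran.observed_i:.3f} (p = {moran.p_value:.2e})")

centered = center_by_station(table)
sel = select_bandwidth(centered, k_grid=[30, 60, 100, 200])
print("CV-selected k:", sel.selected_k)

result = fit_gwr(centered, k=sel.selected_k)
classes = significance_classes(result, alpha=0.05)
print(classes.value_counts().to_dict())
west = result.fits["x"] < 250_000
print(f"mean slope west: {result.fits.loc[west,'slope'].mean():+.4f} log10/yr")
print(f"mean slope east: {result.fits.loc[~west,'slope'].mean():+.4f} log10/yr")
```

prints

```
observations: 934 stations: 400
stations with CV > 0.8: 5
Moran's I of change/yr: 0.135 (p = 7.11e-102)
CV-selected k: 200
{'down': 204, 'up': 165, 'none': 31}
mean slope west: +0.0103 log10/yr
mean slope east: -0.0156 log10/yr
```

Reading the output: each station has 2–3 visits, far too few for
station-wise trend tests, yet the crude change-per-year statistic is
strongly spatially clustered (Moran's I ≫ its null expectation −1/(n−1)),
so a geographically differentiated model is warranted.  Cross-validation
picks the largest candidate neighbourhood, and the fitted slope field
recovers the sign structure of the truth: predominantly significant
upward trends west of the split, downward east of it, with means close to
the true ±0.015/−0.02 log10 units per year (slightly attenuated toward the
boundary, where neighbourhoods mix the two regimes).

The same pipeline is available from a shell:

```sh
gwtrend simulate --seed 3 --n-stations 400 --out synth.csv --truth truth.csv
gwtrend preprocess --input synth.csv --scale log10 --center --out centered.csv --moran
gwtrend bandwidth  --input centered.csv --k-grid 30:200:30
gwtrend fit        --input centered.csv --k 200 --out fit.csv --geojson fit.geojson
gwtrend windows    --input synth.csv --length 10 --k 60 --out-dir windows/
gwtrend compare    --a fit_a.csv --b fit_b.csv --out diff.csv
```

Observation CSVs are long-format (`station_id,x,y,year,value[,program,month]`,
headers remappable via `--col logical=actual`); coordinates must be planar
projected metres.  Results are written as CSV or GeoJSON Points for any GIS.

## Layout

- `gwtrend.table` / `gwtrend.io` — observation containers, CSV/GeoJSON I/O
- `gwtrend.preprocess` — transforms, summaries, CV screen, Moran's I
- `gwtrend.gwr` — kernel, adaptive bandwidth, local WLS, CV selection
- `gwtrend.analysis` — significance maps, fit comparison, program merging,
  moving windows
- `gwtrend.synthetic` — rotating-panel generator with known truth
- `docs/methods.md` — modelling assumptions, defaults and limitations
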