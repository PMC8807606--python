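# vegclim

Sensitivity of near-surface air temperature to leaf-area-index (LAI) change:
an end-to-end pipeline that

1. isolates the vegetation-driven temperature signal from gridded monthly
   observations by a space-for-time decomposition (stable-LAI reference
   cells within a search radius, inverse-distance weighting of their
   between-year temperature change),
2. expresses the resulting per-record sensitivities as two bivariate
   quadratic response surfaces in background-climate drivers — a snow
   regime driven by snow cover and shortwave radiation (response per
   m²/m² of LAI) and a snow-free regime driven by evaporation and
   shortwave radiation (response per unit ln LAI),
3. projects vegetation-driven biophysical temperature change under
   multi-model scenario ensembles, factors it into LAI-only /
   climate-change / per-driver contributions, and adds the biochemical
   (vegetation carbon) term at 2.2 °C per Tt C.

A synthetic-data module stands in for the satellite and climate-model
archives: it generates observation-like baselines with a **known injected
sensitivity model** and CMIP6-like scenario ensembles with known ordering,
so every stage is testable at desk scale without downloads.

## Layout

| module | role |
|---|---|
| `vegclim.grid_core` | grid geometry, area weights, zonal means, bilinear regridding, season alignment, great-circle distance, NetCDF I/O |
| `vegclim.synthetic_data` | baseline-observation and scenario-ensemble generators with ground truth |
| `vegclim.local_signal` | year-pair enumeration, reference-cell search, IDW residual, record building, regime samples, σ-filter, LAI-transition bins, sensitivity maps |
| `vegclim.sensitivity` | quadratic surfaces, published coefficient sets, OLS fitting, map building and comparison |
| `vegclim.projection` | scenario ΔT, factorial attribution, biochemical term, trends, ensemble statistics, zone aggregation, mitigation summary |
| `vegclim.cli_io` | configuration, manifests, NetCDF run round-trip, `vegclim` CLI |

## CLI

```sh
vegclim simulate --kind baseline --nlat 24 --nlon 48 --seed 1 --out sim/
vegclim decompose --obs sim/obs.nc --radius-km 700 --out dec/
vegclim fit --samples dec/samples.csv --out model.yaml
vegclim apply --model model.yaml --drivers sim/obs.nc --out sensmap.nc
vegclim compare --a sensmap.nc --b sensmap.nc

vegclim simulate --kind scenario --n-models 3 --year-step 5 --seed 1 --out runs/
vegclim project   --model model.yaml --runs runs/ --out proj/
vegclim attribute --model model.yaml --runs runs/ --out att/
vegclim report    --model model.yaml --runs runs/ --out rep/
```

Note on the radius: the physical default is 50 km (suited to the 0.05°
grids of real products); synthetic grids are far coarser, so pass a radius
that spans at least one cell (the simulate manifest records a suitable
value, and `vegclim.synthetic_data.auto_radius_km` computes it).

## Conventions

- Grids are cell-center registered, latitude ascending, longitude in
  [−180, 180); missing data are NaN and never imputed.
- All between-year deltas are later-minus-earlier; negative ΔT is cooling.
- NetCDF files are written through xarray's scipy backend (classic
  format), so no binary NetCDF-4 dependency is required.
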