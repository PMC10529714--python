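# coldspot

Transient heat-transfer simulation of cylindrical food products moving
through a multistage convective process line — drying, smoking, steam
cooking, water cooling, air cooling, and the ambient transfers in
between — with cold-/hot-spot tracking for food-safety assessment,
composition-based thermophysical property estimation, least-squares
calibration of heat-transfer coefficients against centre-probe logger
data, and a synthetic-data generator that emulates a 16-probe (4 pallets
x 4 layers) industrial logging campaign.

The packaged default scenario is the production of a salted-smoked pork
loin ("Hamburgerryg"): a D = 85 mm, L = 540 mm cylinder starting at
280.65 K and passing through seven scheduled stages over 84 120 s.

## What it does

* **`properties`** — effective density (mass-fraction harmonic rule),
  specific heat (mass-fraction arithmetic rule) and thermal conductivity
  (g-weighted blend of the volume-fraction parallel/series bounds) from
  proximate composition; constants for the five food components at 20 degC
  are shipped and overridable.
* **`schedule`** — the process as data: ordered stages, each with a
  duration, medium temperature and heat-transfer coefficient; exact
  stage-boundary times and piecewise-constant `h(t)`, `Tp(t)` lookups.
* **`solver`** — conservative finite-volume discretization of
  axisymmetric conduction on the (r, z) half-domain with scheduled Robin
  boundaries; implicit theta-scheme stepping (backward-Euler ramp at
  every stage restart, Crank-Nicolson after) with cached sparse
  factorizations; exact discrete energy balance; plus an independent
  analytic finite-cylinder series oracle for verification.
* **`summaries`** — volume-average / min / max temperature series with
  cold- and hot-spot locations, and R^2 / RMSE validation metrics.
* **`calibration`** — bounded trust-region least squares for unknown
  stage coefficients (e.g. `h_w`, `h_air`) with prefix-simulation
  caching and identifiability guards.
* **`synthetic_data`** — seeded 16-probe logger bundles with per-layer
  water-temperature offsets, per-pallet drying offsets and Gaussian
  measurement noise, written as plain CSV.
* **`cli` / `config`** — a YAML-driven command line
  (`simulate`, `synth`, `fit`, `report`) with schema validation,
  Celsius/Kelvin normalization and reproducibility manifests.

## Command line

```bash
# forward simulation of the default scenario, snapshot at 20 000 s
coldspot simulate --out runs/base --snapshot 20000

# synthetic 16-probe logger bundle (sigma = 0.5 K, +/-5 K water offsets)
coldspot synth --seed 7 --out runs/loggers

# estimate h_w and h_air from the calibration probe
coldspot fit --loggers runs/loggers/T11.csv --free h_w,h_air --out runs/fit

# per-probe R^2 / RMSE validation report
coldspot report --sim runs/base --loggers runs/loggers --out runs/report
```

All commands accept `--config <file>`; a minimal config is

```yaml
default: hamburgerryg       # load the packaged scenario...
grid: {nr: 45, nz: 90}      # ...then override anything
solver: {dt_max_s: 30.0}
```

Outputs are CSV (probe series `time_s,temperature_K`, summary series,
snapshot matrices) plus a `manifest.json` with the config hash, seed and
package version.

## Numerical notes

* Grid: uniform vertex-centred 45 x 90 nodes by default; second-order
  spatial accuracy (verified against the analytic series oracle with a
  mesh-halving convergence test).
* The axis r = 0 needs no special handling: the finite-volume flux form
  with cylindrical metric gives the correct singular limit.
* Time steps never cross a stage boundary or a 60 s recording mark, so
  boundary-condition jumps are resolved exactly and probe series align
  with logger cadence without interpolation error.
* Internally everything is Kelvin; degC appears only in reports.
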