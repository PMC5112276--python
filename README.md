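# isochamber

A pipeline for chamber-based CO₂-isotopologue flux experiments: it turns raw
valve-switched ¹²C¹⁶O₂/¹³C¹⁶O₂ streams from paired shoot/soil chambers into
gas-exchange fluxes (net assimilation, transpiration, stomatal conductance,
soil respiration), on-line photosynthetic ¹³C discrimination, the δ¹³C of
soil-respired CO₂, and treatment-level drought/recovery statistics. Because
raw data of this kind are rarely deposited, the package ships a first-class
synthetic chamber simulator whose outputs invert the pipeline's mass balances
exactly, so the whole chain can be validated closed-loop.

## Modules

| module | role |
|---|---|
| `isochamber.synthetic` | drivers (PAR/SMC/VPD/temperatures), ground-truth plant fluxes, 0.5 Hz raw streams with Allan-scaled noise, optional gain drift + hourly cal-gas blocks |
| `isochamber.ingest` | valve-block parsing (134 s inlet / 136 s outlet, first 20 s discarded), cycle averaging, linear gain calibration |
| `isochamber.engine` | per-cycle fluxes and isotope quantities (open-system mass balances, discrimination with ξ, two-member mixing) |
| `isochamber.metrics` | day/night masks, plant-first aggregation, drought effect `(100·treatment/control)−100`, SD propagation, recovery days, exact rank-sum test, mixed-model contracts |
| `isochamber.cli` | `simulate` / `process` / `analyze` / `all` commands over a YAML config |
| `isochamber.config` | pydantic models for the simulator, masks, QC thresholds and constants |

All tabular I/O is plain CSV with a one-line versioned schema comment
(`# isochamber:<name>:v1`).

## CLI

```bash
# full chain with defaults (3 control + 3 drought plants, 31 days):
isochamber all --out-dir run_out --seed 1 --no-plots

# or stage by stage, with a custom configuration:
isochamber simulate --config config.yaml
isochamber process  --config config.yaml
isochamber analyze  --config config.yaml --no-plots
```

`simulate` writes `raw_stream.csv` (one row per 2 s sample), `truth.csv` and
`chambers.csv`; `process` writes `cycles.csv` and `fluxes.csv`; `analyze`
writes `results/summary.csv` (drought-window treatment means ± SD and percent
effects), `results/effects.csv` (daily effect series with propagated SDs and
recovery days) and optional time-series figures. Identical config + seed
reproduces every file byte for byte.

A minimal `config.yaml`:

```yaml
out_dir: run_out
sim:
  days: 10
  drought_start_day: 2
  rewater_day: 8
  seed: 7
  noise_delta13c: 0.25   # permil at 1 s averaging
```

## Conventions

- δ¹³C on the V-PDB scale (R = 0.0111802, configurable); inside the
  discrimination formula deltas are dimensionless fractions (‰/1000).
- δ of a cycle is computed from cycle-averaged isotopologue mole fractions
  (ratio of means).
- Total CO₂ = x626 + x636; mole fractions are used as measured (wet), with an
  optional dry-air correction (off by default).
- Flows in l min⁻¹ are converted to mol s⁻¹ at 298.15 K / 1013.25 hPa.
- Day mask: PAR > 500 µmol m⁻² s⁻¹; night: PAR < 20; in between is excluded.
- Saturation vapour pressure: Magnus form, 6.112·exp(17.62·T/(243.12+T)) hPa.
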