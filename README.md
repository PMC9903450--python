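# edstack

Long-term forecasting of regional emergency-department (ED) demand with a
multi-granularity regression stack.

Two random-forest level-0 models are fit at different temporal resolutions —
a **capacity model** on monthly service-capacity rates (GP appointments,
111 calls offered, ambulance calls answered, each per 10,000 people) and a
**population-health model** on annual covariates (population, % over 65 and
the People/Places/Lives health-index domains). A level-1 ordinary
least-squares combiner turns their predictions (the annual prediction
broadcast to every month of its region-year) into a monthly forecast of ED
attendances per 10,000 people. The stack supports repeated 5-fold
cross-validation, Gini and stack-wide permutation importance, and
multi-year what-if forecasts (capacity uplifts, health-inequality ramp).

## Layout

| module                | what it does |
|-----------------------|--------------|
| `edstack.curation`    | raw provider/contract/region CSVs → one complete region-month panel, with a full accounting log |
| `edstack.synthetic`   | seeded generators for raw inputs with known ground truth (latent capacity + health components) |
| `edstack.models`      | the two level-0 forests, hyper-parameter selection (1-sd parsimony rule) |
| `edstack.stack`       | nested 70/10/20 splits, level-1 combiner, fitted-stack archive |
| `edstack.evaluation`  | R², MAPE, repeated CV, permutation importance |
| `edstack.scenarios`   | future-panel construction, scenario transforms, rolling-average series |
| `edstack.cli`         | `edstack` command line; `edstack.pipeline` orchestrates end-to-end runs |

## Command line

```sh
# generate synthetic raw inputs (emits the curation-schema CSVs + ground truth)
edstack simulate --config config.yaml --out raw/

# curate them into the panel
edstack curate --in raw/ --panel panel.csv --log curation_log.json

# fit, evaluate, importance
edstack fit --panel panel.csv --out model.archive
edstack evaluate --panel panel.csv --report report.json
edstack importance --panel panel.csv --out importance.json

# forecast 4 years under a scenario
edstack forecast --model model.archive --panel panel.csv \
    --projections raw/projections.csv --scenario health_ramp --out series.csv

# or everything at once (writes a manifest with config digest and seeds)
edstack run --config config.yaml --out run/
```

A config file is optional; every section has defaults. Example:

```yaml
seed: 7
generator: {n_regions: 76, n_months: 24, seed: 7}
cv: {repeats: 5, folds: 5}
hp_capacity: {n_trees: 100}
hp_health: {n_trees: 100}
scenario: {horizon_years: 4, uplift_fraction: 0.10, ramp_step: 0.2}
```

Raw input schema (UTF-8 CSVs with headers, months as `YYYY-MM`):
`providers.csv` (provider_id, region_id, month, count), `contracts.csv`
(contract_id, month, count, service ∈ {111, ambulance}), `contract_map.csv`
(contract_id, region_id), `gp.csv` (region_id, month, count), `regions.csv`
(region_id, year, population, population_over_65, people, places, lives,
merger_group), and for forecasting `projections.csv` (region_id, year,
population, population_over_65). Missing records are absent rows.

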