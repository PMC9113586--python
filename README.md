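# freshprior

Systematic conservation prioritization of freshwater catchments:
Red-List-driven representation targets, simulated-annealing minimum-set
reserve selection with boundary or river-connectivity penalties, selection
frequency (irreplaceability), and three ways of scoring how well
conservation priority corresponds to existing protection.

## Who this is for

Conservation planners and quantitative ecologists who work with catchments
as planning units — the ecologically meaningful unit for rivers and lakes —
and want a scriptable, testable implementation of the classic
reserve-selection workflow (the Marxan family) with freshwater-specific
extras: longitudinal (upstream) connectivity instead of shared boundaries,
status- and range-based target rules, endemism-based lock-ins, and
protected-area gap diagnostics. The package reads and writes the
Marxan input dialect (`pu.dat`, `spec.dat`, `puvspr.dat`, `bound.dat`), so
results can be cross-checked against the reference tool.

## The model

Select a set *S* of catchments minimizing

    cost(S) + Σ_s spf_s · max(0, t_s − c_s(S)) / t_s + structure(S) + cap(S)

where cost is total selected area (km²), *t_s* is the representation target
of species *s* (CR: 100% of occurrences, EN: 75%, VU: 50%, range-restricted:
25%, otherwise 2, ceiling-rounded and capped at the occurrence count),
*c_s(S)* its occurrences inside *S*, and `structure` is either
`BLM × exposed boundary` or `CP × broken upstream river connections`. The
solution's area is softly capped at 17% of the planning region. Three
protection scenarios (ignore / lock in / lock out well-protected catchments,
i.e. >70% protected) plus endemism-based lock-ins define the problems; a
portfolio of annealing runs yields the best network and per-catchment
selection frequencies, the irreplaceability proxy. Full details and all
defaults: [docs/methods.md](docs/methods.md).

A synthetic-world generator (`freshprior.synth`) produces dendritic
catchment forests with hotspot-clustered, network-contiguous species
ranges, Red List status mixtures and spatially structured protection, so
the entire pipeline runs and is tested without any data downloads.

## Worked example

```python
import freshprior as fp
from freshprior import ScenarioConfig, WorldConfig, generate_world

bundle, truth = generate_world(WorldConfig(seed=42))
targets = fp.build_target_table(bundle)
problem = fp.build_problem(bundle, targets,
                           ScenarioConfig.preset(1, n_runs=50, base_seed=0))
result = fp.run_portfolio(problem)

print(fp.coverage_by_status(result.coverage))
```

With seed 42 this prints a world of 200 catchments, 300 species and 6061
occurrences whose best network uses 41 catchments (87,448 km² of the
111,975 km² cap) and meets every representation target:

```
                met  unmet
redlist_status
CR               26      0
EN               21      0
VU               51      0
NT               21      0
LC              167      0
DD               14      0
Total           300      0
```

Correspondence between selection frequency and protected fraction on the
same world:

```python
res = fp.analyze_correspondence(
    result.selection_frequency[bundle.catchments.index].astype(float),
    bundle.catchments["protected_fraction"], n_runs=50)
```

gives `slope 12.7 ± 7.84; r = 0.115; n = 200; p = 0.11` — a weak positive
association, i.e. protection is only loosely aligned with priority — and
the quadrant split `lowP_lowI: 75, highP_highI: 60, highP_lowI: 40,
lowP_highI: 25`; the 25 `lowP_highI` catchments are the under-protected
priorities a planner would look at first.

The same pipeline from a shell:

```bash
freshprior synth --seed 42 --out world/
freshprior run --world world/ --scenario 1 --connectivity river \
               --runs 50 --seed 0 --out results/
freshprior correspond --frequencies results/selection_frequency.csv \
               --catchments world/catchments.csv --out corr/
freshprior sweep --world world/ --parameter cp --values 0,1,10,100 \
               --runs 10 --seed 0 --out sweep.csv
```

`run` writes `selection_frequency.csv`, `coverage.csv`,
`best_solution.csv`, `objective_log.csv` and a `marxan_inputs/` directory
for cross-checking against the reference tool.

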