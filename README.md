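# phenomapper

Topological phenogrouping and survival-guided risk stratification for
clinical cohorts, built around the workflow used to study patients
upgraded to cardiac resynchronization therapy (CRT): who benefits from a
defibrillator-capable device (CRT-D) over a pacemaker-only one (CRT-P)?

The package is aimed at biostatisticians and cardiology researchers who
want a fully open, tested implementation of that workflow:

1. **Patient-similarity network (Mapper).** Sixteen pre-procedure clinical
   features (demographics, device type, NYHA class, comorbidity history,
   renal function, echo measurements) are mean-imputed and Z-scored.
   Patients are compared by normalized-correlation distance,
   `d(i,j) = 1 − r(x_i, x_j)`, projected to a 2-D lens with classical
   multidimensional scaling, and covered by 25×25 overlapping,
   quantile-equalized cells with gain 2.1. Single-linkage clusters within
   each cell become network nodes; nodes sharing a patient are joined by
   an edge; minor components are removed as outliers.
2. **Phenogroups.** Louvain community detection partitions the network
   into ~14 autogroups, which are greedily merged — always the adjacent
   pair with the most similar crude mortality, under a group-size balance
   cap — down to exactly three phenogroups labeled low / intermediate /
   high risk. Each patient gets a unique label (majority node group, ties
   to the riskier group) with dual membership tracked.
3. **Survival analysis.** Study censoring rules (10-year horizon,
   subsequent CRT-D upgrade, transplantation, query date), Kaplan–Meier
   with Greenwood variance and log-log CIs, reverse-KM follow-up,
   Mantel–Cox log-rank, Cox proportional hazards with Efron tie handling
   (Newton–Raphson, implemented here and cross-checked against lifelines
   in the tests), and a subgroup forest analysis of the device effect.
4. **Classifier ensemble.** 5×5 nested cross-validation (inner folds tune
   hyperparameters by balanced accuracy, outer folds give the honest
   estimate) yields a 5-member ensemble that risk-stratifies new patients
   by averaged class probabilities.
5. **Synthetic cohorts.** Because the motivating cohort is private, a
   seeded generator plants three phenogroups with realistic feature
   profiles, exponential survival with group hazards in ratio
   1 : 1.618 : 2.632, a CRT-D effect (HR 0.454) confined to the high-risk
   group, non-death censoring, and per-feature missingness — so the whole
   pipeline is testable end to end.

## Worked example

```python
import numpy as np
from phenomapper import (SimulationConfig, generate_cohort, preprocess,
                         CoverConfig, build_mapper, phenogroup_pipeline)

cohort = generate_cohort(SimulationConfig(n_patients=1000, seed=1))
features = preprocess(cohort.cohort_table)
events = cohort.cohort_table["event"].to_numpy(float)
graph = build_mapper(features.values, CoverConfig(), events=events)
part = phenogroup_pipeline(graph, events, target_groups=14, seed=1)
print(part.group_sizes)
print({g: round(m, 3) for g, m in part.group_mortality.items()})
```

prints (seed 1):

```
{'intermediate': 281, 'high': 367, 'low': 135}
{'intermediate': 0.584, 'high': 0.597, 'low': 0.563}
```

i.e. three phenogroups over the 778 patients kept in the main network
component, labeled by their crude mortality. On noisy draws the mortality
spread between groups can be small — the merge step is driven by observed
group mortality, whose sampling noise at these group sizes is comparable
to the planted between-group differences (see `docs/methods.md`).
The scripts in `examples/` walk through each capability (simulation,
network construction, survival analysis, classification) and print
annotated output; `python -m phenomapper.cli --help` (or the installed
`phenomapper` command) exposes the same pipeline as `simulate`, `run`,
`report` and `predict` subcommands.

## Layout

- `src/phenomapper/` — `synthetic`, `preprocessing`, `mapper`,
  `phenogroup`, `survival`, `classify`, `pipeline`, `viz`, `cli`
- `tests/` — unit, property and end-to-end acceptance tests (with
  independent brute-force oracles in `tests/oracles.py`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — the model, its assumptions, parameter choices and
  known limitations
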