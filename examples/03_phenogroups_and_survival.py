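"""Delineate risk phenogroups and run the survival analysis.

Louvain autogroups (~14) are merged by mortality similarity down to three
phenogroups; Kaplan-Meier, log-rank, and Cox models quantify their risk
separation and the device effect within each group.
"""

import numpy as np

from phenomapper import (
    CoverConfig,
    SimulationConfig,
    build_mapper,
    cox_fit,
    generate_cohort,
    logrank,
    phenogroup_pipeline,
    preprocess,
    reverse_km_followup,
)

cohort = generate_cohort(SimulationConfig(n_patients=1000, seed=1))
tab = cohort.cohort_table
features = preprocess(tab)
events = tab["event"].to_numpy(float)

graph = build_mapper(features.values, CoverConfig(), events=events)
part = phenogroup_pipeline(graph, events, target_groups=14, seed=1)

print("phenogroup sizes:    ", part.group_sizes)
print("crude mortality:     ", {g: round(m, 3) for g, m in part.group_mortality.items()})
print("dual-membership patients:", len(part.multi_membership))

retained = sorted(part.patient_to_group)
labels = np.array([part.patient_to_group[i] for i in retained])
t = tab["time_years"].to_numpy()[retained]
e = tab["event"].to_numpy()[retained]

fu = reverse_km_followup(t, e)
print(f"median follow-up (reverse KM): {fu['median']:.1f} years")
lr = logrank(t, e, labels)
print(f"log-rank across phenogroups: chi2={lr['statistic']:.2f}, p={lr['p']:.3g}")

dummies = np.column_stack([(labels == "intermediate").astype(float),
                           (labels == "high").astype(float)])
fit = cox_fit(t, e, dummies, names=["intermediate", "high"])
print(fit.to_frame().round(3).to_string(index=False))
# The intermediate/high rows compare those phenogroups to the low-risk
# reference. HRs well above 1 mean the network recovered the mortality
# gradient; values near 1 (as on noisy draws) mean the mortality-guided
# merge mixed the latent risk strata — see docs/methods.md on why the
# merge step is the noise-limited part of the procedure.
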