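# Methods

## The analysis in one paragraph

The package reconstructs a published phenomapping workflow for CRT-upgrade
cohorts: build a Mapper network over 16 pre-procedure clinical features,
partition it into mortality-ordered phenogroups, quantify their survival
separation and the within-group device effect, and train a multi-class
ensemble that places new patients into the phenogroups. The commercial TDA
platform used in the original analysis is proprietary and its within-cell
clustering undocumented; this package implements the classical, published
Mapper construction and states every choice explicitly below.

## Feature pipeline

The 16 features are fixed in a canonical order (age, sex, device type,
NYHA III–IV indicator, AF, hypertension, diabetes, ischemic etiology, MI,
PCI, CABG, creatinine, GFR, LVEF, LVIDd, LVIDs). Missing entries are
replaced by the column mean (unconditional mean imputation), then columns
are Z-scored with the sample (n−1) SD; constant columns map to zero with a
warning. Means and SDs are frozen on the analysis cohort and reused
verbatim for new patients at prediction time. Mean imputation is unbiased
under missing-completely-at-random, which is exactly what the synthetic
generator produces; inside the classifier's cross-validation, imputation
and scaling are instead refit within each training fold so no test-fold
statistic leaks into training.

## Mapper construction

* **Metric.** `d(i,j) = 1 − Pearson(x_i, x_j)` across the standardized
  feature vectors, clipped to [0, 2]; invariant to positive affine
  transforms of a patient row. A zero-variance row is an error.
* **Lens.** Two classical (Torgerson) MDS coordinates: double-center
  `−½·J·D²·J`, take the top-2 positive eigenpairs, scale eigenvectors by
  the root eigenvalue. Classical MDS was chosen over stress-minimizing
  MDS because it is closed-form and deterministic — no iteration, no
  seed. Negative eigenvalues (correlation distances are not Euclidean)
  are dropped with a logged warning. Axes are oriented so the
  largest-magnitude coordinate is positive, fixing the sign convention.
  Above n ≈ 1200 a Lanczos eigensolver replaces the full decomposition.
* **Cover.** Default resolution 25 (intervals per axis) and gain 2.1
  (interval-width expansion factor; overlap fraction 1 − 1/gain ≈ 52.4%),
  both equalized. "Equalized" means each lens axis is passed through its
  empirical CDF via mid-ranks, `(rank − ½)/n` with average ranks on ties,
  so base intervals hold equal patient counts. Membership uses closed
  intervals with a 1e-12 tolerance. Note the source platform's
  documentation describes gain as controlling node count and resolution
  edge count — inverted relative to the conventional semantics
  implemented here (resolution = number of intervals, gain = overlap).
* **Clustering.** Single linkage on the within-cell distance submatrix.
  The dendrogram's merge heights are histogrammed into B = 10 bins over
  [0, max height]; the cut is placed at the first empty bin *after* the
  first occupied one (no such gap → one cluster). The "after the first
  occupied bin" qualifier matters: when all merge heights are similar
  they land in the top bins and the leading empty bins must not trigger a
  cut, otherwise every tight cell would shatter into singletons.
* **Graph.** One node per cluster, edge iff two nodes share a patient,
  node ids in cell-major order. The construction is randomness-free.
* **Outliers.** Keep the connected component with the most patients
  (ties: most nodes, then lowest id). Patients appearing only in removed
  nodes are reported as outliers; a patient also present in a kept node
  is retained.

## Phenogrouping

Louvain modularity maximization runs on the node graph with edge weight =
number of shared patients, with a fixed, recorded seed. When a target
autogroup count is requested (default 14, as in the motivating study),
the Louvain resolution parameter is tuned by bisection until the count is
within ±2. Autogroups are then merged greedily: at each step the adjacent
pair (≥1 network edge between their nodes) with the smallest absolute
difference in crude mortality is combined — ties broken by smaller
combined size, then lower group id — skipping merges that would push a
group above `balance_cap × total/3` patients (default cap 1.4, relaxed
×1.1 whenever no merge is permissible). Crude mortality (deaths / unique
members) is used rather than a fixed-horizon KM estimate because the
source procedure refers only to the "survival rate" of members with no
time point. The loop stops at exactly three groups, labeled
low / intermediate / high by mortality; patients receive the majority
group of their nodes, ties toward the riskier group, with multi-group
membership recorded.

## Survival analysis

Censoring applies the earliest of: 10-year administrative horizon,
subsequent CRT-D upgrade, heart transplantation, or the data-query date;
deaths after a censoring event do not count. The estimators are
implemented in the package (generic numerics only) and cross-checked
against lifelines in the test suite:

* Kaplan–Meier with Greenwood variance and log(−log S) 95% bands (bounds
  respect [0, 1]);
* reverse KM (censoring indicator as the event) for median follow-up;
* k-group Mantel–Cox log-rank with the hypergeometric covariance;
* Cox partial likelihood with the Efron tie correction (appropriate for
  heavily tied follow-up times), maximized by damped Newton iteration,
  convergence at |Δ log L| < 1e-8, max 100 iterations, Wald CIs from the
  observed information; separation is flagged when coefficients diverge.
  The published multivariable covariate set (device, age, sex, AF,
  etiology, creatinine, LVEF, ACE-I/ARB, loop diuretics) ships as a named
  preset.
* Subgroup forest: univariable device HR within strata defined by
  etiology, age 80, sex, NYHA class, GFR 60, AF, DM, and LVEF 30; strata
  with no events report an undefined HR instead of raising.

## Classifier ensemble

Nested cross-validation, 5 outer × 5 inner stratified folds, inner grid
search maximizing balanced accuracy across all (family, hyperparameter)
combinations; the per-fold winner is refit on the outer-training split
and evaluated once on the held-out fold. Shipped families: multinomial
logistic regression, random forest, gradient boosting, RBF SVC, and a
multi-layer perceptron, each behind an imputer+scaler pipeline; the
framework accepts any estimator/grid map. The five outer-fold winners
form the ensemble; prediction averages their class-probability vectors
and breaks ties toward the higher-risk class (clinically conservative).
Metrics: balanced accuracy (= unweighted mean of per-class recalls),
accuracy, micro/macro precision/recall/F1, micro/macro one-vs-rest AUC;
95% CIs use the normal approximation across outer folds — a
methodological assumption, since fold metrics are not independent.

## Synthetic cohort generator

The generator defines the study conditions for all end-to-end tests.
Per patient: a latent group from weights (0.312, 0.369, 0.319); features
drawn independently given the group — binaries Bernoulli, continuous
truncated Gaussians — with per-group parameters transcribed from the
published phenogroup profiles (e.g. male 58/75/93%, ischemic etiology
2/47/100%, LVEF 30/30/28% with IQR/1.35 SDs); exponential survival with
baseline hazards 0.06 / 0.0971 / 0.1579 per year (ratio 1 : 1.618 :
2.632; the 0.06 level was chosen so that ~55% of patients die within the
10-year horizon, matching an elderly CRT-upgrade population); a CRT-D
log-hazard of ln 0.454 in the high-risk group only; independent
exponential non-death censoring at 0.015/year (transplant / subsequent
upgrade analogue); administrative censoring at 10 years applied last;
MCAR missingness at the published per-feature availability rates
(creatinine/GFR 23%, LVIDs 31%, LVIDd 14%, LVEF 10%). All draws are
seeded.

What the generator does *not* emulate: within-group feature correlation
(e.g. the near-deterministic ischemic/MI/PCI block of real cohorts),
non-proportional or time-varying hazards, informative (MNAR)
missingness, NT-proBNP dynamics or medication effects. Passing tests
therefore show the pipeline's behavior under an idealized, independent-
feature proportional-hazards world, not under real clinical data.

## Problem sizes and numerical choices

End-to-end checks run at n = 1000 (phenogroup recovery, classifier) and
n = 5000 (hazard-ratio recovery); calibration uses 200 replicates at
n = 500; the Mapper implementation is verified against a brute-force
enumerator on 50 random instances with n ≤ 30 and resolution ≤ 4. The
acceptance-run classifier uses the logistic and single-hidden-layer MLP
families with compact grids; larger grids and the remaining families are
available through the same configuration object. Distance computations
clip to [0, 2] against rounding; cover membership uses a 1e-12 tolerance;
Cox fitting centers covariates for conditioning and halves the Newton
step until the likelihood is non-decreasing.

## Known limitations

* **Planted-group recovery is bounded well below 1.** With the default
  (published-profile, independent-feature) generator, even the
  Bayes-optimal classifier that knows the true generative model reaches
  an adjusted Rand index of only ≈ 0.65 against the latent groups — the
  three risk strata genuinely overlap. The unsupervised pipeline lands
  well below that bound (ARI ≈ 0.05–0.3 across seeds at n = 1000),
  because the mortality-similarity merge is noise-limited: Louvain
  autogroups of 40–90 patients carry crude-mortality standard errors
  (~0.07) of the same order as the planted between-group mortality gaps,
  so the merge order is partly driven by sampling noise. The network
  itself is not the bottleneck (median node purity ≈ 0.9). Consequences
  propagate downstream: on unlucky draws the recovered phenogroups show
  little survival separation, the device HR estimated in the *recovered*
  high-risk group is attenuated toward 1 relative to the planted 0.454,
  and a classifier trained on the recovered labels plateaus below the
  accuracy it reaches on cleanly separated labels.
* The merge rule's "nearly equal number of patients" is operationalized
  as the balance cap; the original study gives no explicit rule.
* Whether the source platform's MDS was metric or non-metric is unknown;
  classical MDS is used throughout.
* No competing-risks modeling, time-varying covariates or cause-specific
  mortality; non-death censoring is treated as independent.
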