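# Methods

## Model and search

The method assumes the data are generated by a linear-Gaussian structural
equation model whose graph satisfies the Markov condition and faithfulness;
these are documented preconditions, not runtime checks.  The score is the
decomposable Gaussian BIC: for each variable, the maximized log-likelihood of
its linear regression on its parents (intercept included, ML 1/n residual
variance) minus (k/2)·log n with k = |parents| + 2 (coefficients, intercept,
residual variance).  Integer-coded categorical variables are scored as
numeric, matching common clinical-table practice; no discrete or
nonparametric score is provided.

The search operates in DAG space: single-edge insertions (forward phase,
from the empty graph) and single-edge deletions (backward phase), each
accepting the largest strictly positive score change, under the acyclicity
check and the group constraint that outcome variables have no out-edges.
This mirrors the method's literal procedural description — one forward pass
then one backward pass, no iteration between them, and no equivalence-class
(Insert/Delete-operator) moves.  The trade-off is that orientations within a
score-equivalent class are arbitrary; the package therefore exposes
`cpdag_of`, which restores the honest equivalence class (v-structures plus
compelled edges via Meek rules R1–R4, with the group constraint treated as
background knowledge) for reporting and for multiset IDA.  The forward
phase's initial score bookkeeping starts from the empty graph's actual BIC
value; the score of the empty graph is finite, and only score *differences*
drive the search.

Numerical choices: all regressions are solved from the centered
cross-product matrix computed once per dataset (cost per local score is
O(|Pa|³), independent of n); score deltas within 1e−9 of zero are treated as
zero (no extra improvement slack beyond the BIC penalty); ties among equal
candidates are broken lexicographically by (source, target) in input column
order, making every output deterministic.  Collinear parent sets and
residual variances below 1e−12 of the child's marginal variance raise a
degenerate-model error; during search such candidates are skipped with a
warning rather than aborting the fit.  Undirected ties in consistent
extensions (Dor–Tarsi) resolve as earlier-node → later-node in column order.

## Effects

IDA estimates the total causal effect of x on y as the coefficient of x in
the regression of y on {x} ∪ Pa(x); if y is a parent of x the effect is 0 by
definition.  The default reports a single estimate per variable on the
fitted DAG; `ida_multiset` enumerates the locally valid parent sets of x in
the restricted equivalence class (subsets of undirected neighbors forming a
clique, creating no new collider) and aggregates by minimum absolute value —
the method's standard conservative summary.  Signed values are reported;
rankings use |IDA|.  Effects are computed on raw columns by default, with a
standardization flag for SD-unit effects, since published effect magnitudes
for this kind of cohort span orders of magnitude and suggest unstandardized
units.  On a known weighted SEM the exact total effect is the (x, y) entry
of (I − W)⁻¹ − I, equal to the sum of path products; it is the oracle for
IDA recovery tests.  TCE is defined for known-weight models only; effect
strength on estimated graphs is reported via IDA.

## Evaluation

AP/AR compare skeletons; AHP/AHR compare directed endpoints, an estimated
arrowhead counting as correct only when the reference directs the same
ordered pair.  Undirected estimated edges contribute adjacencies but no
arrowheads.  Precision with an empty estimate is reported as "undefined"
(JSON null), never silently 0 or 1.  Because no ground-truth graph exists
for an observational cohort, the cross-validation harness evaluates each
training-fold graph against the full-data graph and reports per-edge
stability (fraction of folds containing each edge); fold splits are a seeded
permutation dealt round-robin.

## Synthetic cohort

The emulator generates a surgical-lung-cancer-like table (default n = 363)
whose marginal targets follow the published cohort summary: age
N(68.3, 9.45²), BMI N(27.8, 5.98²), female fraction 0.4628, race/stage
category proportions, recurrence prevalence 0.67.  Design choices that were
genuinely open:

- **Adiposity and frame-size drivers are observed, not latent.**  BMI plays
  the adiposity factor and height the frame-size factor, each feeding the
  body-composition volumes; masses are linear in volume and density
  (approximating mass ≈ volume × density-derived factor).  Keeping the
  drivers observed makes the ground-truth graph identifiable from the
  emitted table, so structure recovery is directly checkable.
- **Height/weight.**  The published height/weight summary (174.4 ± 43.0 cm,
  66.3 ± 4.02 kg) is internally inconsistent with the BMI row and would
  generate impossible bodies; height is instead sex-dependent Normal around
  170 cm and weight is the linearization of BMI × (height/100)² at the
  means.
- **Recurrence** is Bernoulli with a logistic link over TNM stage, muscle
  density, visceral fat volume and subcutaneous fat mass.  The intercept is
  set analytically from the latent-predictor variance (probit approximation
  to the logistic) so the population mean hits its target without any
  post-hoc fitting.  **Recurrence-free survival** is linear in t-stage,
  smoking code, height and intermuscular fat mass plus Gaussian noise,
  truncated below at 0; its printed mean/SD are treated as free parameters
  of the emulator because the published summary's denominator (all patients
  vs recurrence cases) is ambiguous.
- All structural coefficients live in one packaged config
  (`gges/data/cohort_default.yaml`) and can be overridden via YAML.

What the emulator does *not* reproduce: CT-protocol heterogeneity and
radiomics noise, survival censoring mechanisms, missing data (complete-case
deletion is the only policy), and nonlinear dose-response shapes.  Passing
recovery tests on this generator therefore demonstrates correctness of the
search and effect machinery under the model's own assumptions, not
performance on real imaging-derived cohorts.  Because the two outcome nodes
are generated through a logistic link and truncation, their ground-truth
weights are latent-scale coefficients; effect-recovery validation uses pure
linear SEMs (`sample_linear_sem`) where TCE is exact.

## Problem sizes

Validation uses 4-variable problems (n = 500, 50 seeds) for exhaustive
oracle comparison, 10-variable SEMs with 10 edges and coefficients
|β| ∈ [0.8, 1.5] (n = 5000, 20 seeds) for structure recovery, n = 10000 ×
20 seeds for IDA/TCE consistency, and the published n = 363 for cohort
marginal fidelity — sizes at which the tested properties are statistically
stable while the whole suite runs in well under a minute.

## Known limitations

- A single forward-then-backward pass is not guaranteed to reach a global or
  even CPDAG-local optimum; it is, however, exactly the procedure validated
  against the naive oracle, and empirically insertion/deletion/reversal
  locally optimal on the tested problems.
- Gaussian BIC treats ordinal codes as interval-scaled; strongly non-Gaussian
  or nonlinear mechanisms can distort both structure and IDA estimates.
- IDA confidence intervals (bootstrap) and joint interventions are out of
  scope; `n ≥ p` is recommended though not enforced.
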