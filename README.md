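# gges

Score-based causal discovery for clinical feature tables in which the
variables are split into two groups: *causal* variables (demographics,
CT-derived body composition, tumor stage, ...) that may influence one
another, and *outcome* variables (e.g. cancer recurrence, recurrence-free
survival) that may only be influenced.  The package implements the grouped
greedy equivalence search (GGES), quantifies each variable's causal
contribution to an outcome via IDA adjustment scores, evaluates structural
accuracy, and ships a synthetic clinical-cohort generator with a known
ground-truth graph so the entire method can be exercised and validated
without access to any patient data.

## The method

Given an n×p data table D and a candidate directed acyclic graph G, the
search maximizes a decomposable Gaussian BIC graph score

    f(G, D) = Σ_j [ max log L( x_j | Pa_G(x_j) ) − (k_j / 2) · log n ],

the sum over variables of the maximized log-likelihood of the linear
regression of each variable on its graph parents, penalized per free
parameter (k_j = |Pa_G(x_j)| + 2).  The search is constrained: variables are
partitioned into a causal group V_c and an outcome group V_p, and any edge
whose source lies in V_p is inadmissible, so outcomes are sinks.  Two greedy
phases run under this constraint and an acyclicity check:

1. **Greedy forward search** — from the empty graph, repeatedly insert the
   single admissible edge with the largest strictly positive score gain;
2. **Greedy backward search** — repeatedly delete the edge whose removal
   yields the largest strictly positive gain.

Because BIC is score-equivalent, orientations within a Markov equivalence
class are not identifiable from data alone; `cpdag_of` reports the honest
equivalence class of a fitted graph (v-structures plus Meek rules R1–R4 with
the group constraint as background knowledge).

Each variable's contribution to an outcome y is the **IDA** (intervention
do-calculus adjustment) score: the coefficient of x in the regression of y on
{x} ∪ Pa_G(x), which under a linear structural equation model is the total
causal effect of a unit intervention on x.  On a known weighted SEM the exact
**total causal effect** (TCE) — the sum over directed paths of edge-weight
products — is available in closed form and serves as the recovery oracle.
Structural accuracy is measured by adjacency precision/recall (AP, AR) on
skeletons and arrowhead precision/recall (AHP, AHR) on directed endpoints,
with a k-fold cross-validation harness reporting per-edge stability.

## Worked example

Draw a 2000-subject synthetic cohort (26 variables: demographics, body
composition, stage codes, binary recurrence `Recur` and continuous
recurrence-free survival), fit the grouped search, and compare the fitted
graph with the generating ground truth:

```
$ gges simulate --n 2000 --seed 7 --outdir demo
wrote cohort of 2000 rows × 26 variables

$ gges fit --input demo/cohort.csv --roles demo/roles.yaml --outdir demo/fit
fitted graph: 44 edges, score -71714.388, pruned 2

$ head -6 demo/fit/ida_Recur.csv
variable,ida,abs_ida,n_equivalent,rank
n_stage,0.13724677978532085,0.13724677978532085,1,1
mass_subcutaneous_fat,0.11287712379766798,0.11287712379766798,1,2
TNM_stage,0.09585024180048989,0.09585024180048989,1,3
mass_intermuscular_fat,-0.08639609969722659,0.08639609969722659,1,4
t_stage,0.08118916888540285,0.08118916888540285,1,5

$ gges metrics --estimated demo/fit/graph_edges.csv --reference demo/true_edges.csv
{
  "ap": 0.8409090909090909,
  "ar": 0.9736842105263158,
  "ahp": 0.75,
  "ahr": 0.868421052631579,
  ...
}
```

The IDA table ranks variables by absolute effect on recurrence: here nodal
stage, subcutaneous fat mass and overall TNM stage carry the largest
estimated effects per unit intervention, consistent with the generating
model in which recurrence depends on stage and adiposity.  The metrics
output shows the fitted graph recovered 97% of true adjacencies (AR) with
84% precision (AP) at this sample size; arrowhead agreement is lower because
score-equivalent orientations within the causal block are resolved by a
deterministic tie-break, not by data.

`gges cv --input ... --roles ... --k 10 --seed 0 --outdir ...` refits on each
training fold and writes per-fold AP/AR/AHP/AHR against the full-data graph
plus a per-edge stability table.  Every run directory contains a
`manifest.json` (seed, config hash, version) sufficient to reproduce it.

The same functionality is available as a library — `fit_gges`, `ida_table`,
`cross_validate`, `simulate_cohort`, etc.; see the module docstrings.

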