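# Methods

## Model and assumptions

`diabnet` treats progression to a diabetes complication as a binary
contrast — *fast* (fastest quartile of time from the type-2-diabetes index
date to the first complication diagnosis) versus *slow* (slowest quartile) —
and asks which second-year clinical facts discriminate the two groups.

The statistical object is a heterogeneous comorbidity network over typed
feature tokens (3-character ICD categories, demographic values, age and lab
quartiles, normal/abnormal statuses). Every training patient contributes
their token set as a clique; an element (node or unordered edge) carried by
`k_f` fast and `k_s` slow patients out of `n_f` / `n_s` gets

- weight `w = k_f / (k_f + k_s)` — an estimate of P(fast | element present)
  in a balanced cohort, and
- a pooled two-proportion Z statistic for the prevalence difference.

Only elements reaching two-sided 95% significance survive; no
multiple-testing correction is applied, deliberately mirroring the source
protocol — the scoring stage is therefore fed a set that contains roughly
an α-fraction of false discoveries, whose weights hover near 0.5 and dilute
rather than bias the product.

Scoring assumes matched elements are *equally likely and statistically
independent*: the posterior is the product form
`P(fast) = Π w_i / (Π w_i + Π (1−w_i))` over the top-`n` matched elements
by |z| (n ≤ 12), after removing the single lowest-weight element. That
removal is a signal-boosting heuristic, not a probability operation; with
it active the score is no longer a calibrated posterior, and because
surviving weights are mostly > 0.5 the scores crowd toward 1. Evaluation is
therefore rank-based (AUC); sensitivity/specificity at the fixed threshold
0.5 are reported for completeness but depend strongly on that arbitrary
threshold. The full ROC curve is available via `evaluation.roc_points`.

The independence assumption is plainly false for edges (an edge is a
deterministic function of its endpoints), which is precisely why capping the
element budget and working with significant elements only is load-bearing:
the product over a small, high-|z| subset behaves like a crude profile of
the strongest evidence rather than a likelihood.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| feature window | (365, 730] days | second year after index; earlier facts are peri-diagnostic noise, later ones attrition-biased |
| q_fast / q_slow | 0.25 / 0.75 | nearest-rank quantiles of time-to-complication; middle half excluded |
| min exposure | > 365 days | complications within a year of index exclude the patient |
| node prevalence floor | 1% (ceil) | tokens carried by fewer patients are dropped |
| patient filters | ≥ 5 and ≤ 2 × median diagnoses | guards against empty and hypertrophic histories |
| pruning α | 0.05 two-sided | z-critical 1.959964 |
| element budget n | 12 (grid 7–20) | number of matched elements multiplied, before the single removal |
| classification threshold | 0.5 | for sensitivity/specificity only |
| holdout | 20% test, 5 repeats | stratified by label, seed-deterministic |

Quantile assignment uses nearest-rank cuts with ties going down (a value
equal to the 25th-percentile cut maps to the bottom quartile). Progressor
labeling resolves a patient qualifying for both quartiles at once (possible
only when the two cuts coincide) to *excluded*, keeping the groups disjoint.
Per-patient lab summaries default to the mean of in-window QC-passed values
(configurable to last/min/max); the mean was chosen for robustness to
single aberrant measurements. The normal/abnormal status thresholds in
`features.DEFAULT_STATUS_RULES` are conventional clinical cut-offs supplied
as implementation defaults, not fitted values.

Two leakage guards are intentional deviations from a literal reading of the
protocol's order of operations:

- the 2×-median diagnosis-count cap is computed on the *training split
  only* and applied to both splits, so a deleted or added test patient can
  never perturb anything fitted on train (this is asserted by test);
- codes defining the labeled complication are stripped from the feature
  stream even inside the window, so the outcome definition cannot score
  itself.

Quartile boundaries are likewise fitted on the training split only.

## Synthetic cohorts

The generator emulates the three-table extract: diagnosis events
(STUDYID, DX_INDEX, DX_CODE; day 0 = first T2DM criterion), demographics
(STUDYID, INDEX_YEAR, INDEX_AGE, GENDER, RACE), and a sparse wide lab panel
(STUDYID, AGE, DAYS_VIS_INDEX, INDEX_AGE, variables…). Each patient is fast
with probability `frac_fast`; fast complication days are uniform on
366–730 (fast progressors develop the complication within two years of
index by construction), slow on 1096–1825. Planted binary features fire
with probability `p_fast` / `p_slow` given the label and materialise as
in-window diagnosis codes ("F00"…), demographic values, or a mean-shift in
a lab variable (so the informative quartile arises from the measurements
themselves). Background diagnoses are label-independent 3-character codes
drawn from letters that cannot prefix-match any T2DM or complication list;
3-character codes are used so that identities survive ICD truncation.
Label-independent noise events before the index and in year one exercise
the windowing rules.

Because features are conditionally independent Bernoullis given the label,
the exact posterior is a sum of per-feature log-likelihood ratios and
`planted_bayes_auc` Monte-Carlo-estimates the AUC upper bound any
classifier reading those features can attain. The pipeline's held-out AUC
is judged against this bound.

What the generator does **not** model: realistic ICD co-occurrence
structure, visit-level billing patterns, medication records, informative
missingness, unit-mix-ups across data sources, or code-assignment drift
over calendar time. Passing tests therefore demonstrate that the
implementation recovers the structure the model class assumes — not that
the method attains any particular performance on real claims data, where
correlated features and label noise will lower the ceiling.

## Numerical choices and degenerate inputs

- Two-proportion Z returns 0 when the pooled proportion is 0 or 1 (both
  sample proportions necessarily equal); zero group sizes are an error,
  except that a one-class network (useful for counting) reports z = 0.
- Weights entering the product are clamped to `[ε, 1−ε]` with
  `ε = 1/(n_f + n_s + 2)` (add-one style), preventing 0/0 when weights of
  exactly 0 and 1 co-occur.
- Selection order in scoring is (|z| desc, weight desc, lexicographic token
  identity); all rankings in the package break ties lexicographically on
  token identity so that reruns and permuted inputs are bit-identical.
- The element removal is skipped with fewer than two selected candidates;
  an empty candidate list scores 0.5 and is flagged via `n_used = 0`.
- Lab QC drops values outside configured physiologic bounds, then values
  beyond 2 *sample* SD (ddof = 1) from the per-variable median of the
  range-passed values; a zero SD drops nothing.
- Experiment summaries report the population SD over splits so that a
  single-repeat run reports 0 spread rather than NaN.
- The between-complication correlation is the Pearson/phi coefficient of
  the binary fast indicator over patients labeled (fast or slow) for both
  complications. It is symmetric by construction; direction-dependent
  variants reported elsewhere for this statistic cannot arise here.

## Problem sizes

Bundled experiments run at desk scale, chosen to make the statistical
assertions sharp without bulk: planted-signal evaluation uses 4000 patients
(≈ 1000 labeled per class, 5 splits), null/type-I checks 2000 patients with
200 background features, parameter-recovery 2000 patients, and the Bayes
bound 10⁵ Monte-Carlo draws. At these sizes the full acceptance run
completes in well under a minute.

## Known limitations

- Weights estimate P(fast | element) only under the enforced 1:1 class
  balance; the score is not transportable to the population prevalence.
- The product score ignores *absence* of significant elements, discarding
  the evidence an absent high-weight feature carries; this is the main gap
  to the Bayes bound visible in the evaluation example.
- Code matching is prefix-based on opaque strings; no ICD-9↔ICD-10
  equivalence mapping is attempted, so a condition coded differently across
  revisions appears as two tokens.
- With heavy ties in time-to-complication the nearest-rank quartiles can
  make group sizes deviate from 25% (ties join or leave whole blocks).
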