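# diabnet

Graph-based prediction of **fast vs slow progression to diabetes
complications** from longitudinal EHR-style data.

After a type-2-diabetes (T2DM) diagnosis, patients differ sharply in how
quickly they develop complications — kidney disease, heart failure, stroke,
liver disease, retinopathy, myocardial infarction. `diabnet` implements a
comorbidity-network pipeline for separating *fast progressors* (fastest
quartile of time from T2DM index to first complication) from *slow
progressors* (slowest quartile), aimed at biostatisticians and clinical
informaticians working with de-identified longitudinal claims/EHR extracts.
Because such cohorts live behind health-information-exchange walls, the
package ships a synthetic-EHR generator that emulates the three input tables
(diagnosis events, demographics, lab panels) with *planted*, analytically
tractable fast/slow structure — so every stage of the pipeline can be
validated quantitatively on a laptop.

## The method

1. **Cohort & labels.** Day 0 is the first day any T2DM inclusion criterion
   holds (diagnosis code in {249, 250, 357.2, 362.01–07, 366.41, E10, E11},
   HbA1C ≥ 6.5%, or an anti-diabetes-medication flag). The first diagnosis
   prefix-matching a complication's code list marks the complication day;
   patients reaching it within one year of index are excluded, the fastest
   quartile of the rest is *fast*, the slowest *slow*.
2. **Features.** Only facts from the second year after index (days 366–730)
   count. ICD codes are truncated to 3-character categories; age and lab
   variables are binned into quartiles of the training distribution (some
   labs dichotomised normal/abnormal); gender and race enter verbatim.
   Tokens below 1% prevalence, and patients with < 5 or > 2× the median
   number of diagnoses, are removed; classes are downsampled to equal size.
3. **Network.** Each training patient's token set forms a clique in a
   heterogeneous graph. An element (node or edge) carried by `k_fast` fast
   and `k_slow` slow patients gets weight `w = k_fast / (k_fast + k_slow)`
   and a pooled two-proportion Z statistic

   ```
   z = (k_f/n_f − k_s/n_s) / sqrt( p̂(1−p̂) (1/n_f + 1/n_s) ),   p̂ = (k_f+k_s)/(n_f+n_s)
   ```

   Elements with |z| below the two-sided 95% critical value are pruned.
4. **Scoring.** A test patient's matched significant elements are ranked by
   |z|; the top *n* ≤ 12 are kept and the single lowest-weight one dropped.
   With surviving weights w_0 … w_n,

   ```
   p_t = Π w_i,   p_f = Π (1 − w_i),   P(fast) = p_t / (p_t + p_f)
   ```

   — a naive-Bayes-style posterior treating elements as independent.
5. **Evaluation.** Repeated stratified 80/20 holdout (5 splits), rank-based
   AUC, sensitivity/specificity at 0.5, a sweep over the element budget
   n ∈ {7, 10, 12, 15, 17, 20}, and a between-complication correlation of
   fast-progressor status.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

```python
import diabnet as dn

config = dn.SyntheticCohortConfig(
    n_patients=2000, complication="kidney",
    planted=dn.default_planted(5, p_fast=0.8, p_slow=0.4), seed=2,
)
patients, diagnosis, clinical, truth = dn.generate_cohort(config)
labels = dict(zip(truth.STUDYID, truth.LABEL))

model = dn.fit_pipeline(patients, diagnosis, clinical, labels,
                        sorted(labels, key=str), "kidney",
                        dn.PipelineConfig(), seed=0)
print(dn.top_conditions(model.network, 3))
```

Running `python examples/03_network_and_top_conditions.py` prints:

```
training cohort: 998 fast / 998 slow
network: 64 nodes, 1991 edges
after 95% Z-test pruning: 11 nodes, 415 edges remain

top nodes by fast-progressor fraction (weight) and by Z score:
condition                          weight    condition                               Z
diagnosis:F01=present                0.67    diagnosis:F01=present               19.53
diagnosis:F02=present                0.67    diagnosis:F03=present               18.53
diagnosis:F03=present                0.67    diagnosis:F02=present               18.28
```

The five planted features (prevalence 0.8 among fast vs 0.4 among slow) top
both rankings, and their estimated weights sit at the analytic value
`0.5·0.8 / (0.5·0.8 + 0.5·0.4) = 2/3`. `examples/05_full_evaluation.py`
runs the full repeated-holdout protocol on a stronger cohort (ten planted
features, n = 4000) and prints a mean held-out AUC of 0.954 at n = 12
against the generative model's exact-posterior upper bound of 0.971 —
i.e. the network plus product score recover essentially all recoverable
signal. The other `examples/` scripts each demonstrate one stage
(simulation, labeling/windowing, scoring).

A thin CLI wraps the same pipeline for shell use:

```bash
diabnet all --config examples/demo_config.yaml --out runs/demo --seed 1
```

with subcommands `simulate | label | network | score | evaluate | all`; each
writes CSV artifacts plus a `manifest.json` (config hash, seed, row counts)
that makes the run bit-reproducible.

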