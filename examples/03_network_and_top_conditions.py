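"""Build the heterogeneous network, prune it, and list the top conditions.

Each training patient contributes their token set as a clique; every node
and edge is weighted by the fraction of its carriers who are fast
progressors and tested with a pooled two-proportion Z statistic. Elements
failing 95% significance are pruned. The planted features (F00..F04, true
weight 2/3) should dominate both rankings.
"""

import diabnet as dn

config = dn.SyntheticCohortConfig(
    n_patients=2000, complication="kidney",
    planted=dn.default_planted(5, 0.8, 0.4), seed=2,
)
patients, diagnosis, clinical, truth = dn.generate_cohort(config)
labels = dict(zip(truth.STUDYID, truth.LABEL))

model = dn.fit_pipeline(patients, diagnosis, clinical, labels,
                        sorted(labels, key=str), "kidney",
                        dn.PipelineConfig(), seed=0)
full, pruned = model.full_network, model.network
print(f"training cohort: {full.n_fast} fast / {full.n_slow} slow")
print(f"network: {len(full.node_counts)} nodes, {len(full.edge_counts)} edges")
print(f"after 95% Z-test pruning: {len(pruned.node_counts)} nodes, "
      f"{len(pruned.edge_counts)} edges remain")

by_weight, by_z = dn.top_conditions(pruned, 5)
print("\ntop nodes by fast-progressor fraction (weight) and by Z score:")
print(f"{'condition':34s} {'weight':>6s}    {'condition':34s} {'Z':>6s}")
for w, z in zip(by_weight, by_z):
    print(f"{str(w.element):34s} {w.weight:6.2f}    {str(z.element):34s} {z.z:6.2f}")
print("\n(weight ~0.67 is the analytic value for a 0.8-vs-0.4 planted feature"
      " in a balanced cohort)")
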