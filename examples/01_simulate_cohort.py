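"""Generate a synthetic diabetes cohort and inspect its three tables.

Every patient gets a type-2-diabetes index event at day 0, a complication
event (fast progressors inside the second year, slow progressors in years
4-5), planted diagnosis features that are more common among fast
progressors, background noise diagnoses, and a sparse lab panel.
"""

import diabnet as dn

config = dn.SyntheticCohortConfig(
    n_patients=500,
    complication="kidney",
    planted=dn.default_planted(5, p_fast=0.8, p_slow=0.4),
    seed=1,
)
patients, diagnosis, clinical, truth = dn.generate_cohort(config)

print("patients:", patients.shape, "| diagnosis events:", diagnosis.shape,
      "| lab rows:", clinical.shape)
print(diagnosis.head(6).to_string(index=False))
print()
fast = truth[truth.LABEL == "fast"]
print(f"{len(fast)} fast / {len(truth) - len(fast)} slow progressors; "
      f"fast complications at days {fast.DAYS_TO_COMPLICATION.min()}-"
      f"{fast.DAYS_TO_COMPLICATION.max()} (all inside the second year)")
# The planted feature F00 should appear in ~80% of fast patients vs ~40% of slow.
carriers = set(diagnosis.loc[diagnosis.DX_CODE == "F00", "STUDYID"])
for label in ("fast", "slow"):
    ids = set(truth.loc[truth.LABEL == label, "STUDYID"])
    print(f"planted feature F00 prevalence among {label}: "
          f"{len(ids & carriers) / len(ids):.2f}")
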