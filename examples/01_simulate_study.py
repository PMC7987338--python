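"""Simulate a synthetic maternal-loss study and summarize its design.

Generates 19 gorilla groups, each with one maternal-loss incident, and the
focal-scan stream for the 6-month windows before and after each loss.
"""

import silverback as sb

config = sb.PopulationConfig(seed=1)
study = sb.simulate_incident_dataset(config)

roster, incidents, scans = study.roster, study.incidents, study.scans
orphans = roster[roster.orphan_class != "non_orphan"]
scans_per_ind = scans.groupby(["group", "focal"]).size()

print(f"groups/incidents: {len(incidents)}")
print(f"individuals:      {len(roster)}")
print(f"orphans:          {len(orphans)} "
      f"({orphans.orphan_class.value_counts().to_dict()})")
print(f"focal scans:      {len(scans)} "
      f"(per individual over both windows: mean {scans_per_ind.mean():.1f}, "
      f"sd {scans_per_ind.std():.1f})")

# The orphan counts mirror the study population (incidents with 1-2 orphans
# aged 2-8); the per-individual scan effort matches the reported scale of
# ~145 focal scans per 6-month window (~290 over both windows).
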