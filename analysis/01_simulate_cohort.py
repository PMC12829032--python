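"""Simulate the synthetic biopsy cohort: 70 normal + 35 cancer cores.

Each core gets 3,000 bisulfite amplicon reads drawn from its epiallele
mixture (high-methylation fraction Beta-distributed per lesion group) plus
primer-dimer and off-target contamination, with clinical labels and true
expression linked to the methylation level.  FASTQs land in scratch/cohort
(large, regenerable); truth and metadata tables in results/.
"""

import os

from epihap.simulate import simulate_cohort

OUT = "scratch/cohort"
SEED = 1

sim = simulate_cohort(n_normal=70, n_cancer=35, seed=SEED, n_reads=3000)
manifest = sim.write(OUT)
os.makedirs("results", exist_ok=True)
sim.truth.to_csv("results/cohort_truth.csv", index=False)
sim.metadata.to_csv("results/cohort_metadata.csv", index=False)

n_cancer = (sim.metadata["lesion"] == "cancer").sum()
print(f"wrote {len(manifest)} samples ({n_cancer} cancer) under {OUT}")
print(f"true high-methylation fraction: "
      f"normal mean {sim.truth.loc[sim.truth.group == 'normal', 'true_high_frac'].mean():.3f}, "
      f"cancer mean {sim.truth.loc[sim.truth.group == 'cancer', 'true_high_frac'].mean():.3f}")
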