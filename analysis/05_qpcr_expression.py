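"""qPCR relative expression via per-target standard curves.

Simulates a Cq plate for the cohort (duplicated unknowns, serial-dilution
standards, no-template/no-RT controls), fits Cq vs log10(input) per target,
derives PCR efficiency, quantifies Q = 10^((Cq-intercept)/slope), normalizes
ONECUT2 to HPRT1 and scales to the LNCaP calibrator.  Writes the Cq table
and expression results to results/.
"""

import pandas as pd

from epihap.qpcr import control_check, quantify_plate
from epihap.simulate import simulate_qpcr_plate

truth = pd.read_csv("results/cohort_truth.csv")
plate = simulate_qpcr_plate(truth, noise_sd=0.25, seed=2)
plate.to_csv("results/cq_table.csv", index=False)

print(control_check(plate).to_string(index=False))
expression, curves = quantify_plate(plate)
expression.to_csv("results/expression.csv", index=False)
for t, c in curves.items():
    print(f"{t}: slope {c.slope:.3f}, intercept {c.intercept:.2f}, "
          f"r2 {c.r2:.4f}, efficiency {c.efficiency_pct:.1f}%")
print(f"{expression['excluded'].sum()} of {len(expression)} samples excluded "
      f"by the reference-gene Cq cutoff")
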