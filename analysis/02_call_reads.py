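"""Classify every read of every core against the ONECUT2 amplicon.

Reads are compared directly to the bisulfite-converted reference in both
orientations; dimers, off-target reads, poorly converted reads and
ambiguous CpG calls are filtered before any methylation statistic.  Call
TSVs go to scratch/calls; the per-sample QC report to results/.
"""

import pandas as pd

from epihap.amplicon import onecut2_amplicon
from epihap.reads import cohort_run

manifest = pd.read_csv("scratch/cohort/manifest.csv")
tables, report = cohort_run(manifest, onecut2_amplicon(), out_dir="scratch/calls")
report.to_csv("results/qc_report.csv", index=False)

frac = report["retained"].sum() / report["n_reads"].sum()
print(f"{len(report)} samples, {report['n_reads'].sum()} reads, "
      f"{100 * frac:.1f}% retained; {report['excluded'].sum()} samples excluded")
print(report[["dimer", "off_target", "low_conversion", "ambiguous_cpg"]].sum())
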