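"""Epiallele spectra and the highly-methylated-strand biomarker score.

Retained reads are binned by methylated-CpG count (0..8); the per-core
score is the fraction of strands with 7 or 8 methylated sites.  Writes the
row-normalized spectrum matrix (the cohort heatmap's input) and per-core
scores to results/.
"""

import glob
import os

import pandas as pd

from epihap.amplicon import onecut2_amplicon
from epihap.pipeline import score_samples
from epihap.reads import SampleCallTable, calls_to_spectrum
from epihap.spectrum import spectrum_matrix

K = onecut2_amplicon().n_sites
tables = {}
for path in sorted(glob.glob("scratch/calls/*.calls.tsv")):
    sid = os.path.basename(path)[: -len(".calls.tsv")]
    calls = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""],
                        dtype={"pattern": str})
    tables[sid] = SampleCallTable(sid, calls, calls["status"].value_counts().to_dict())

scores = score_samples(tables, K)
scores.to_csv("results/scores.csv", index=False)
matrix = spectrum_matrix([calls_to_spectrum(t, K) for t in tables.values()])
matrix.to_csv("results/spectrum_matrix.csv")

meta = pd.read_csv("results/cohort_metadata.csv")
m = scores.merge(meta, on="sample_id")
print(m.groupby("lesion")["score"].describe()[["count", "mean", "50%"]])
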