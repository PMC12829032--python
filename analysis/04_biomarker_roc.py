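"""Group comparisons of the 7-8-CpG score: Mann-Whitney and ROC/AUC.

Normal vs cancer over the whole cohort, then the aggressiveness dichotomies
(Gleason grade group 3-5 vs 1-2, T3 vs T2, EPE, SV, LN) among cancer cores,
plus per-bin tests across the whole spectrum.  Writes biomarker and
per-bin tables to results/.
"""

import pandas as pd

from epihap.pipeline import biomarker_panel, feature_labels
from epihap.spectrum import per_bin_tests

scores = pd.read_csv("results/scores.csv")
meta = pd.read_csv("results/cohort_metadata.csv")
matrix = pd.read_csv("results/spectrum_matrix.csv", index_col=0)

panel = biomarker_panel(scores, meta)
panel.to_csv("results/biomarkers.csv", index=False)
bins = per_bin_tests(matrix, feature_labels(meta, "lesion").astype(bool))
bins.to_csv("results/per_bin_tests.csv", index=False)

print(panel.to_string(index=False))
top = bins.sort_values("p").iloc[0]
print(f"most significant bin: {top['bin']} (p = {top['p']:.3g})")
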