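# Methods

## Amplicon model and read classification

The assay is a single bisulfite-PCR amplicon: chr18:55107668–55107793
(126 bp, 1-based inclusive; all internal offsets 0-based half-open) with
eight CpG sites, amplified with primers containing IUPAC degenerate bases
(Y = C/T, R = G/A) where a primer unavoidably spans a CpG. The published
assay does not disclose the genomic sequence between the primers, so the
built-in `onecut2_amplicon()` reference is **synthetic**: primer-binding
regions back-mapped from the degenerate primers and an interior with eight
evenly spaced CpGs plus eight non-CpG cytosines that power the conversion
QC. Probe ids are assigned to two sites (cg10835584 → index 2,
cg24771804 → index 5); the other six are unnamed in the assay, so indices
are arbitrary. Every result in this package depends on the amplicon only
through its CpG count and cytosine layout, not the filler bases.

Bisulfite chemistry is modelled deterministically: unmethylated C → T,
methylated CpG C → C. A read is classified by direct comparison against
the fully converted reference — no aligner, since reads cover a single
known locus:

1. **dimer** if shorter than `min_read_length` (40 nt);
2. orientation: the read and its reverse complement are both compared and
   the lower mismatch fraction wins (equivalent to matching the
   reverse-strand amplicon variant);
3. **off_target** if the mismatch fraction over non-wildcard positions
   (reference A/G/T; every reference C accepts C or T) exceeds
   `max_mismatch_frac` (0.10);
4. **low_conversion** if the fraction of non-CpG, non-primer reference
   cytosines read as T falls below `min_conversion_rate` (0.95) — the
   standard per-read control for bisulfite conversion failure;
5. CpG calling (C → M, T → U, anything else → N); any N →
   **ambiguous_cpg**, else **retained** with its methylation count.

The vendor's actual noise-elimination criteria are not public; these three
thresholds are conventional bisulfite-amplicon QC values, declared
stand-ins, all exposed in configuration. Ambiguous reads are excluded
rather than partially counted so the spectrum is defined over complete
strands only. FASTQ base qualities are parsed but unused by default; a
Phred mask cutoff exists as a config hook. Raising `min_conversion_rate`
can only shrink the retained set (monotone filter, tested). With eight
conversion-check cytosines, a single unconverted one drops a read to 7/8 =
0.875 < 0.95, so at default error rates roughly 8 % of genuine reads are
sacrificed to conversion QC — visible in the ~84 % retained fraction of
the default cohort.

## Epiallele spectrum and biomarker

Retained strands are binned by methylated-CpG count m = 0…8 without regard
to position. The biomarker score is the mass of the top two bins,
(n₇+n₈)/Σnₘ (parameterizable to any minimum bin, enabling the single-site
comparison). Samples with fewer than 20 retained reads return NaN rather
than a silent zero — the observed floor in the real assay was 68 reads
pre-filter, and 20 keeps the score's binomial error below ~0.11 even in
the worst case. Group comparisons: Mann–Whitney U with the pair-counting
convention (exact null for pooled n ≤ 16 without ties, otherwise normal
approximation with tie and continuity corrections, via scipy); AUC =
U/(n₊n₋), verified identical to the trapezoid area under the threshold
sweep. Per-bin comparisons across the spectrum are reported raw
(Benjamini–Hochberg available, off by default, mirroring how the original
analysis reports them). The clinical dichotomies are: lesion
(normal/cancer, whole cohort) and, among cancer cores only, Gleason grade
group 1–2 vs 3–5, T2 vs T3, and EPE/SV/LN negative vs positive.

## Synthetic cohort generator

What it emulates: per-core read depth (3,000, the assay's median depth
regime of 68–9,848 reads/core), epiallele mixtures, bisulfite conversion
failure (P(unmethylated C read as C) = 0.01), inappropriate conversion
(P(methylated C read as T) = 0.01), per-base substitution error (0.005),
primer dimers (2 %) and off-target reads (3 %), clinical labels linked to
methylation, and a qPCR plate with duplicated unknowns, five-point
ten-fold standards and clean controls.

Cohort structure: each core draws a high-methylation fraction h from
Beta(2, 38) (normal, mean 0.05) or Beta(8, 12) (cancer, mean 0.40); h
splits evenly between bins 7 and 8, and 1−h spreads geometrically (ratio
0.5) over bins 0–6. These effect sizes are configuration, not estimates
from the real cohort (which reports only its AUCs); the two default Beta
laws are nearly separated — analytic P(h_cancer > h_normal) ≈ 0.9997 — so
the synthetic lesion AUC sits near 1, stronger than the real-data regime.
Aggressiveness labels are Bernoulli with logistic probability
σ(12·(h − c)), centers c between 0.40 and 0.60 per label, so they
correlate with, but are not determined by, the score. Expression is
max(0.01, 0.1 + 5h) times lognormal noise (σ = 0.3); Cq values follow the
standard curves (slopes −3.30, the assay's reported median) plus N(0,
noise_sd) with a per-sample lognormal input amount that cancels under
reference normalization.

What it does **not** model: partial read coverage (reads span the whole
126 bp amplicon), PCR duplicates, strand bias, batch effects, replicate
outliers, or clinical covariate realism beyond the label–score link.
Passing tests therefore demonstrate correctness of the estimators under a
clean generative model, not robustness to every artefact of real
libraries.

## qPCR quantification

Curves are ordinary least squares of Cq on log₁₀(input), fitted per target
per plate (the assay reports per-run slope medians with IQRs, implying
per-run curves); ≥3 distinct dilution levels required. Efficiency
E = (10^(−1/slope) − 1)·100 % — exactly 100 % at slope −1/log₁₀2 ≈ −3.3219.
Q = 10^((Cq−intercept)/slope). Replicates are normalized first
(Q_target/Q_ref per replicate) and then averaged; the published wording is
ambiguous between that and averaging Cq first, so the alternative is a
switch (`order="cq_first"`) — on noise-free data they agree to rounding.
Reference (HPRT1) replicates with Cq > 35 are dropped; a sample with no
surviving reference replicate is flagged `ref_failed` and excluded from
the association, matching the assay's exclusion rule. No cutoff applies to
the target gene; an undetected target well quantifies as 0 with a flag.
Control wells (no-template, no-RT) fail their target if any shows a
numeric Cq below the 40-cycle sentinel. No replicate-outlier rejection is
performed beyond SD reporting.

## COBRA model

The assay never writes its digestion-rate formula; this module states its
model explicitly: intact fraction = f^(−ΔCq) with ΔCq = Cq_digested −
Cq_undigested and f the per-cycle amplification factor (2.0 by default, or
1 + E/100 from a fitted curve — identical at 100 % efficiency), clamped to
(0, 1]; cut fraction = 1 − intact. Orientation is the explicit assumption
that *cut = methylated*: BstUI (CGCG) and BsiWI (CGTACG) sites survive
conversion only when their CpG cytosines were methylated. ΔCq below −0.5
cycles flags an assay inconsistency rather than raising. Timepoint ratios
(cut_after/cut_before) express treatment trajectories; a zero baseline
yields NaN, not an exception. Per-replicate rates are computed first and
averaged afterwards where replicates exist.

## Association

Both variables are Yeo-Johnson transformed. x defaults to the mean
methylation level (mean over retained reads of m/K), matching the axis of
the original correlation analysis; the 7–8 score is a config alternative.
λ is fitted per variable by maximizing the Gaussian profile log-likelihood
with golden-section search on [−5, 5] to 1e-6 (cross-checked against
scipy's optimizer in tests); strongly skewed bounded inputs can push λ to
the search boundary, which is reported as-is. Constant input falls back to
λ = 1 with a flag. The transformation uses expm1/log1p forms so the λ → 0
and λ → 2 branches are numerically continuous. The regression is Huber
M-estimation (tuning 1.345, MAD scale, IRLS to 1e-8 or 100 iterations, via
statsmodels RLM), chosen as the conventional default for "robust linear
regression" where the estimator is unspecified; Tukey bisquare is a
switch. R² is reported as the squared Pearson correlation between fitted
and observed transformed responses (an OLS-R² on robust residuals is the
other defensible reading; this one is documented and used consistently).
No p-value is attached to the robust slope.

## Problem sizes and determinism

The default cohort is 70 normal + 35 cancer cores at 3,000 reads each
(315,000 reads end to end, ≈40 s); spectrum-recovery checks use 5,000
reads; null calibration of the Mann–Whitney test uses 10,000 cohorts of
20+20; slope-sign stability uses 100 replicate cohorts at the
truth-table level (sampling the qPCR/association stages without re-reads).
Every stochastic step takes a `numpy.random.default_rng` seed; identical
seeds give byte-identical FASTQ, CSV and JSON outputs.

## Known limitations

- Single-amplicon design: no multi-locus panels, no SAM/BAM, no general
  aligner. Reads much shorter than the amplicon are compared over their
  prefix overlap with uncovered CpGs called N.
- The synthetic reference sequence and effect sizes are stand-ins; numbers
  computed here characterize the estimators, not the clinical assay.
- AUC is reported without confidence intervals; survival analysis is out
  of scope (the PSA-recurrence label is carried in metadata only).
- The score's λ search range [−5, 5] is a hard box; boundary hits are
  visible in the output rather than warned about.
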