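"""Epiallele spectrum, high-methylation biomarker score and group statistics.

Retained reads are binned by how many of the K CpG sites are methylated,
without regard to position — the epiallele spectrum.  The biomarker score is
the fraction of highly methylated strands (>= K-1 methylated sites, i.e. the
7-8 bins for the 8-CpG assay).  Group comparisons use the Mann-Whitney U
test and ROC/AUC with the pair-counting convention (ties count one half).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .amplicon import ReadPatternCall

#: minimum retained reads before a per-sample score is considered defined
MIN_RETAINED_READS = 20

STATUSES = ("retained", "dimer", "off_target", "low_conversion", "ambiguous_cpg")


@dataclass
class EpialleleSpectrum:
    """Per-sample counts of reads with 0..K methylated CpGs plus QC totals."""

    sample_id: str
    counts: np.ndarray  # length K+1
    totals: dict = field(default_factory=dict)  # per-status read counts

    @property
    def n_retained(self) -> int:
        return int(self.counts.sum())

    @property
    def proportions(self) -> np.ndarray:
        """Row-normalized spectrum; NaN when no retained reads."""
        n = self.n_retained
        if n == 0:
            return np.full(len(self.counts), np.nan)
        return self.counts / n


def build_spectrum(calls: Iterable[ReadPatternCall], K: int, sample_id: str = "") -> EpialleleSpectrum:
    """Aggregate read calls into the 0..K epiallele spectrum.

    Only retained reads enter the counts; every call is accounted for exactly
    once in the per-status totals.
    """
    counts = np.zeros(K + 1, dtype=np.int64)
    totals = {s: 0 for s in STATUSES}
    for call in calls:
        totals[call.status] = totals.get(call.status, 0) + 1
        if call.status == "retained":
            if call.n_methylated is None or not 0 <= call.n_methylated <= K:
                raise ValueError(f"retained read {call.read_id!r} has invalid n_methylated")
            counts[call.n_methylated] += 1
    return EpialleleSpectrum(sample_id, counts, totals)


def spectrum_from_counts(sample_id: str, counts: Sequence[int]) -> EpialleleSpectrum:
    counts = np.asarray(counts, dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative counts")
    return EpialleleSpectrum(sample_id, counts, {"retained": int(counts.sum())})


def high_meth_score(spectrum: EpialleleSpectrum, min_sites: Optional[int] = None,
                    min_reads: int = MIN_RETAINED_READS) -> float:
    """Fraction of retained strands with at least ``min_sites`` methylated CpGs.

    Defaults to K-1, i.e. the 7-8 methylated-site bins of the 8-CpG assay.
    Returns NaN (an undefined-score flag, never a silent 0) for samples with
    fewer than ``min_reads`` retained reads.
    """
    K = len(spectrum.counts) - 1
    ms = K - 1 if min_sites is None else min_sites
    if not 0 <= ms <= K:
        raise ValueError(f"min_sites must be in [0, {K}]")
    n = spectrum.n_retained
    if n < min_reads:
        return float("nan")
    return float(spectrum.counts[ms:].sum() / n)


def single_site_rate(calls: Iterable[ReadPatternCall], site_index: int,
                     min_reads: int = MIN_RETAINED_READS) -> float:
    """Fraction of retained reads methylated at one CpG site."""
    n = m = 0
    for call in calls:
        if call.status != "retained":
            continue
        if site_index < 0 or site_index >= len(call.cpg_states):
            raise IndexError(f"site_index {site_index} out of range")
        n += 1
        m += call.cpg_states[site_index] == "M"
    if n < min_reads:
        return float("nan")
    return m / n


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (pair-counting, ties half) and two-sided p.

    Exact null distribution for small tie-free samples, otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size + y.size <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def pair_count_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as P(score_pos > score_neg) + 0.5 P(tie), via midranks."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, pd.DataFrame]:
    """Pair-counting AUC and the ROC point table from a threshold sweep.

    The trapezoid area under the returned points equals the pair-counting
    AUC (ties contribute half a pair each).
    """
    auc = pair_count_auc(scores, labels)
    fpr, tpr, thresholds = roc_curve(np.asarray(labels).astype(int), scores, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return auc, points


@dataclass
class BiomarkerResult:
    """Two-group comparison of per-sample scores for one clinical feature."""

    feature: str
    n_neg: int
    n_pos: int
    u_statistic: float
    p_value: float
    auc: float
    scores: pd.DataFrame  # sample_id, score, label

    def to_dict(self) -> dict:
        return {"feature": self.feature, "n_neg": self.n_neg, "n_pos": self.n_pos,
                "U": self.u_statistic, "p_two_sided": self.p_value, "auc": self.auc}


def compare_groups(scores: pd.DataFrame, feature: str, labels: pd.Series) -> BiomarkerResult:
    """Mann-Whitney + ROC of score against a boolean label (1 = positive class).

    ``scores`` needs columns sample_id, score; samples with NaN scores or
    missing labels are dropped.  AUC is oriented so that higher scores
    indicate the positive class.
    """
    df = scores.merge(labels.rename("label"), left_on="sample_id", right_index=True)
    df = df.dropna(subset=["score", "label"])
    lab = df["label"].astype(bool).astype(int).to_numpy()
    pos = df.loc[lab == 1, "score"].to_numpy()
    neg = df.loc[lab == 0, "score"].to_numpy()
    u, p = mann_whitney(pos, neg)
    auc = pair_count_auc(df["score"].to_numpy(), lab)
    return BiomarkerResult(feature, int((lab == 0).sum()), int(lab.sum()), u, p, auc,
                           df[["sample_id", "score"]].assign(label=lab))


def spectrum_matrix(spectra: Sequence[EpialleleSpectrum]) -> pd.DataFrame:
    """Samples x (K+1) table of row-normalized bin proportions.

    Rows for samples without retained reads are all-NaN (flagged, not zero).
    This is the matrix the cohort methylation-pattern heatmap draws from.
    """
    if not spectra:
        raise ValueError("need at least one sample")
    K = len(spectra[0].counts) - 1
    rows = {s.sample_id: s.proportions for s in spectra}
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"m{m}" for m in range(K + 1)])


def per_bin_tests(matrix: pd.DataFrame, labels: pd.Series,
                  adjust: Optional[str] = None) -> pd.DataFrame:
    """Mann-Whitney per epiallele bin between two groups of samples.

    Mirrors the per-bin significance row of the cohort heatmap; raw p-values
    by default, with optional Benjamini-Hochberg adjustment.
    """
    lab = labels.reindex(matrix.index).astype(bool)
    out = []
    for col in matrix.columns:
        v = matrix[col].dropna()
        l = lab.reindex(v.index)
        u, p = mann_whitney(v[l].to_numpy(), v[~l].to_numpy())
        out.append({"bin": col, "U": u, "p": p})
    df = pd.DataFrame(out)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
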