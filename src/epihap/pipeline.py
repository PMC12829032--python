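"""End-to-end orchestration: simulate -> call -> score -> qPCR -> associate.

Reproduces the study's needle-biopsy analysis shape on a synthetic cohort
(or on real inputs via a manifest): per-read pattern calling, the epiallele
spectrum matrix, the high-methylation biomarker score with Mann-Whitney and
ROC statistics for each clinicopathological dichotomy, qPCR-calibrated
relative expression, and the transformed-scale robust regression linking
methylation to expression.
"""

from __future__ import annotations

import hashlib
import json
import os
from typing import Optional

import numpy as np
import pandas as pd

from .amplicon import QCThresholds, classify_read, onecut2_amplicon
from .association import fit_association
from .qpcr import quantify_plate
from .reads import CALL_COLUMNS, SampleCallTable, calls_to_spectrum
from .simulate import CohortSim, EffectConfig, simulate_cohort, simulate_qpcr_plate
from .spectrum import (MIN_RETAINED_READS, compare_groups, high_meth_score,
                       per_bin_tests, spectrum_matrix)

DEFAULT_CONFIG = {
    "n_normal": 70,
    "n_cancer": 35,
    "n_reads": 3000,
    "seed": 1,
    "qc": {"min_read_length": 40, "max_mismatch_frac": 0.10, "min_conversion_rate": 0.95},
    "min_retained_reads": MIN_RETAINED_READS,
    "qpcr_noise_sd": 0.25,
    "effect": {},
    "score_min_sites": None,  # default: K-1 (the 7-8 bins for K=8)
}

#: the clinicopathological dichotomies evaluated against the biomarker score
FEATURES = ("lesion", "gleason", "t_stage", "epe", "sv", "ln")


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def score_samples(tables: dict, K: int, min_sites: Optional[int] = None,
                  min_reads: int = MIN_RETAINED_READS) -> pd.DataFrame:
    """Per-sample biomarker score and mean methylation from call tables."""
    rows = []
    for sid, table in tables.items():
        spec = calls_to_spectrum(table, K)
        score = high_meth_score(spec, min_sites=min_sites, min_reads=min_reads)
        n = spec.n_retained
        mean_meth = float((np.arange(K + 1) * spec.counts).sum() / (n * K)) if n else float("nan")
        rows.append({"sample_id": sid, "score": score, "mean_meth": mean_meth,
                     "n_retained": n})
    return pd.DataFrame(rows)


def feature_labels(metadata: pd.DataFrame, feature: str) -> pd.Series:
    """Positive-class labels for one dichotomy, indexed by sample_id.

    lesion: cancer vs normal over the whole cohort; the aggressiveness
    dichotomies (Gleason grade group 3-5 vs 1-2, T3 vs T2, EPE/SV/LN
    positive vs negative) are defined on cancer samples only.
    """
    meta = metadata.set_index("sample_id")
    if feature == "lesion":
        return (meta["lesion"] == "cancer").astype(int)
    cancer = meta[meta["lesion"] == "cancer"]
    if feature == "gleason":
        return (cancer["gleason_group"].astype("Int64") >= 3).astype("Int64")
    if feature == "t_stage":
        return (cancer["t_stage"] == "T3").astype(int)
    if feature in ("epe", "sv", "ln", "psa_recurrence"):
        return cancer[feature].astype("boolean").astype("Int64")
    raise KeyError(f"unknown feature {feature!r}")


def biomarker_panel(scores: pd.DataFrame, metadata: pd.DataFrame,
                    features=FEATURES) -> pd.DataFrame:
    """Mann-Whitney U, p and AUC of the score for each dichotomy."""
    rows = []
    for feat in features:
        labels = feature_labels(metadata, feat)
        try:
            res = compare_groups(scores, feat, labels)
        except ValueError:
            rows.append({"feature": feat, "n_neg": np.nan, "n_pos": np.nan,
                         "U": np.nan, "p_two_sided": np.nan, "auc": np.nan})
            continue
        rows.append(res.to_dict())
    return pd.DataFrame(rows)


def run_all(config: Optional[dict] = None, out_dir: Optional[str] = None,
            sim: Optional[CohortSim] = None) -> dict:
    """Execute the full analysis on a synthetic cohort; return a report bundle.

    The report carries the spectrum matrix, per-bin tests, the six biomarker
    rows, the qPCR expression table and the association fit, all reproducible
    from the intermediate tables it bundles.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    spec = onecut2_amplicon()
    K = spec.n_sites
    qc = QCThresholds(**cfg["qc"])
    seed = int(cfg["seed"])

    if sim is None:
        sim = simulate_cohort(cfg["n_normal"], cfg["n_cancer"],
                              EffectConfig(**cfg["effect"]), seed=seed,
                              spec=spec, n_reads=cfg["n_reads"])

    # classify in memory, no FASTQ round trip
    tables = {}
    for sid, recs in sim.reads.items():
        counts, rows = {}, []
        for rid, seq, _ in recs:
            call = classify_read(seq, spec, qc, read_id=rid)
            counts[call.status] = counts.get(call.status, 0) + 1
            rows.append((call.read_id, call.status, call.cpg_states or "",
                         call.n_methylated, call.mismatch_frac,
                         call.conversion_rate, call.orientation))
        tables[sid] = SampleCallTable(sid, pd.DataFrame(rows, columns=CALL_COLUMNS), counts)

    scores = score_samples(tables, K, cfg["score_min_sites"], cfg["min_retained_reads"])
    spectra = [calls_to_spectrum(t, K) for t in tables.values()]
    matrix = spectrum_matrix(spectra)
    lesion_labels = feature_labels(sim.metadata, "lesion")
    bins = per_bin_tests(matrix, lesion_labels.astype(bool))
    panel = biomarker_panel(scores, sim.metadata)

    plate = simulate_qpcr_plate(sim.truth, noise_sd=cfg["qpcr_noise_sd"], seed=seed + 1)
    expression, curves = quantify_plate(plate)

    merged = scores.merge(expression[["sample_id", "relative", "excluded"]], on="sample_id")
    usable = merged[~merged["excluded"]].dropna(subset=["mean_meth", "relative"])
    fit = fit_association(usable["mean_meth"], usable["relative"])

    lesion = lesion_labels.reindex(scores["sample_id"]).to_numpy()
    n_total = sum(t.n_reads for t in tables.values())
    n_retained = sum(t.n_retained for t in tables.values())
    report = {
        "config": cfg,
        "config_hash": config_hash(cfg),
        "n_samples": len(tables),
        "retained_read_fraction": n_retained / n_total if n_total else float("nan"),
        "score_mean_cancer": float(np.nanmean(scores.loc[lesion == 1, "score"])),
        "score_mean_normal": float(np.nanmean(scores.loc[lesion == 0, "score"])),
        "biomarkers": panel.to_dict(orient="records"),
        "per_bin_p": bins.to_dict(orient="records"),
        "association": fit.to_dict(),
        "qpcr_curves": {t: {"slope": c.slope, "intercept": c.intercept,
                            "r2": c.r2, "efficiency_pct": c.efficiency_pct}
                        for t, c in curves.items()},
    }

    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        scores.to_csv(os.path.join(out_dir, "scores.csv"), index=False)
        matrix.to_csv(os.path.join(out_dir, "spectrum_matrix.csv"))
        panel.to_csv(os.path.join(out_dir, "biomarkers.csv"), index=False)
        bins.to_csv(os.path.join(out_dir, "per_bin_tests.csv"), index=False)
        expression.to_csv(os.path.join(out_dir, "expression.csv"), index=False)
        sim.metadata.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
        with open(os.path.join(out_dir, "results.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report
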