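"""Synthetic cohorts with the statistical structure the pipeline assumes.

Stands in for the patient biopsy cohort: per-sample epiallele mixtures over
0..K methylated CpGs, noisy bisulfite amplicon reads (conversion failure,
inappropriate conversion, sequencing error, primer dimers, off-target
contamination), clinical labels correlated with the true high-methylation
fraction, and linked qPCR Cq plates.  Everything is deterministic under a
seed; every emitted read appears exactly once in the truth table.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon import AmpliconSpec, bisulfite_convert_reference, onecut2_amplicon

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimSampleConfig:
    """Generative settings for one sample's read set.

    ``epiallele_mix`` is the probability vector over 0..K methylated sites.
    ``conv_failure`` is the chance an unmethylated C escapes conversion (read
    as C, i.e. falsely methylated); ``inappropriate_conv`` the chance a
    methylated C converts anyway (read as T).  Default read depth of 3,000
    sits at the median depth of the targeted assay (68-9,848 reads per core).
    """

    sample_id: str
    group: str = "normal"
    n_reads: int = 3000
    epiallele_mix: Sequence[float] = ()
    conv_failure: float = 0.01
    inappropriate_conv: float = 0.01
    seq_error: float = 0.005
    frac_dimer: float = 0.02
    frac_offtarget: float = 0.03
    seed: int = 0

    def __post_init__(self):
        mix = np.asarray(self.epiallele_mix, dtype=float)
        if mix.size and abs(mix.sum() - 1.0) > 1e-9:
            raise ValueError("epiallele_mix must sum to 1")
        for name in ("conv_failure", "inappropriate_conv", "seq_error",
                     "frac_dimer", "frac_offtarget"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")
        if self.frac_dimer + self.frac_offtarget > 1.0:
            raise ValueError("contaminant fractions exceed 1")


def simulate_sample_reads(
    cfg: SimSampleConfig,
    spec: Optional[AmpliconSpec] = None,
    dimer_max_len: int = 39,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate one sample's FASTQ records and per-read truth rows.

    Returns ``(records, truth)`` where records are ``(read_id, sequence,
    quality)`` triples and truth holds the generating category and pattern of
    every read.  Non-contaminant reads draw a methylation count m from the
    epiallele mix, methylate m sites uniformly at random, bisulfite-convert
    the reference, then apply conversion-failure / inappropriate-conversion
    flips and per-base substitution errors.  Dimers are short random
    sequences; off-target reads are random DNA of amplicon length.
    """
    if cfg.n_reads <= 0:
        raise ValueError("n_reads must be positive")
    spec = spec or onecut2_amplicon()
    K = spec.n_sites
    mix = np.asarray(cfg.epiallele_mix, dtype=float)
    if mix.size != K + 1:
        raise ValueError(f"epiallele_mix must have length {K + 1}")

    rng = np.random.default_rng(cfg.seed)
    L = len(spec.ref_seq)
    converted = np.frombuffer(
        bisulfite_convert_reference(spec, [False] * K).encode(), dtype=np.uint8
    )
    ref = np.frombuffer(spec.ref_seq.encode(), dtype=np.uint8)
    c_positions = np.flatnonzero(ref == ord("C"))  # all reference cytosines
    cpg_idx = np.asarray(spec.cpg_positions, dtype=np.intp)

    cats = rng.choice(
        3, size=cfg.n_reads,
        p=[cfg.frac_dimer, cfg.frac_offtarget, 1.0 - cfg.frac_dimer - cfg.frac_offtarget],
    )
    records, truth = [], []
    for i, cat in enumerate(cats):
        rid = f"{cfg.sample_id}:read{i:06d}"
        if cat == 0:
            n = int(rng.integers(8, dimer_max_len + 1))
            seq_arr = rng.choice(_BASES, size=n)
            m, pattern, category = -1, "", "dimer"
        elif cat == 1:
            seq_arr = rng.choice(_BASES, size=L)
            m, pattern, category = -1, "", "off_target"
        else:
            m = int(rng.choice(K + 1, p=mix))
            sites = rng.choice(K, size=m, replace=False)
            flags = np.zeros(K, dtype=bool)
            flags[sites] = True
            seq_arr = converted.copy()
            meth_pos = cpg_idx[flags]
            seq_arr[meth_pos] = ord("C")
            # conversion failure: unmethylated Cs (now T) read back as C
            unmeth_c = np.setdiff1d(c_positions, meth_pos, assume_unique=False)
            if cfg.conv_failure > 0 and unmeth_c.size:
                flip = rng.random(unmeth_c.size) < cfg.conv_failure
                seq_arr[unmeth_c[flip]] = ord("C")
            # inappropriate conversion: methylated Cs read as T
            if cfg.inappropriate_conv > 0 and meth_pos.size:
                flip = rng.random(meth_pos.size) < cfg.inappropriate_conv
                seq_arr[meth_pos[flip]] = ord("T")
            if cfg.seq_error > 0:
                err = rng.random(L) < cfg.seq_error
                if err.any():
                    idx = np.flatnonzero(err)
                    # substitute with a uniformly chosen different base
                    shift = rng.integers(1, 4, size=idx.size)
                    cur = np.searchsorted(_BASES, seq_arr[idx])
                    seq_arr = seq_arr.copy()
                    seq_arr[idx] = _BASES[(cur + shift) % 4]
            pattern, category = "".join("M" if f else "U" for f in flags), "template"
        seq = seq_arr.tobytes().decode()
        records.append((rid, seq, "I" * len(seq)))
        truth.append((rid, category, m, pattern))
    truth_df = pd.DataFrame(truth, columns=["read_id", "category", "n_methylated_true", "pattern_true"])
    return records, truth_df


def write_fastq(records: Sequence[tuple[str, str, str]], path: str) -> None:
    """Write (id, seq, qual) triples as a plain Phred+33 FASTQ file."""
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


@dataclass
class EffectConfig:
    """Cohort-level effect sizes and label links.

    The high-methylation fraction h (mass on the top two epiallele bins) is
    drawn per sample from a group-specific Beta law; the remaining 1-h is
    spread geometrically over bins 0..K-2 with ratio ``low_bin_decay``.
    Aggressiveness labels attach to cancer samples through a logistic link on
    h.  Relative expression is an affine function of h with lognormal noise,
    which is the generative counterpart of the downstream transformed-scale
    regression.
    """

    normal_alpha: float = 2.0
    normal_beta: float = 38.0
    cancer_alpha: float = 8.0
    cancer_beta: float = 12.0
    low_bin_decay: float = 0.5
    top_split: float = 0.5  # share of h placed on the fully methylated bin K
    label_steepness: float = 12.0
    label_centers: dict = field(default_factory=lambda: {
        "gleason_high": 0.45, "t3": 0.45, "epe": 0.40, "sv": 0.55,
        "ln": 0.60, "psa_recurrence": 0.55,
    })
    expr_intercept: float = 0.1
    expr_slope: float = 5.0
    expr_sd: float = 0.3


def mix_from_high_fraction(h: float, K: int, decay: float = 0.5, top_split: float = 0.5) -> np.ndarray:
    """Epiallele mix with mass h on bins K-1 and K, the rest geometric below."""
    mix = np.zeros(K + 1)
    mix[K] = h * top_split
    mix[K - 1] = h * (1.0 - top_split)
    w = decay ** np.arange(K - 1)
    mix[: K - 1] = (1.0 - h) * w / w.sum()
    return mix


def draw_cohort_truth(
    n_normal: int,
    n_cancer: int,
    effect: Optional[EffectConfig] = None,
    seed: int = 0,
    spec: Optional[AmpliconSpec] = None,
    n_reads: int = 3000,
    **sample_kwargs,
) -> tuple[list[SimSampleConfig], pd.DataFrame, pd.DataFrame]:
    """Draw per-sample generative configs, truth table and clinical metadata.

    Does not simulate reads; :func:`simulate_cohort` adds those.  Returns
    ``(configs, truth, metadata)``.
    """
    if n_normal < 1 or n_cancer < 1:
        raise ValueError("need at least one sample per group")
    effect = effect or EffectConfig()
    spec = spec or onecut2_amplicon()
    K = spec.n_sites
    rng = np.random.default_rng(seed)

    configs, truth_rows, meta_rows = [], [], []
    groups = ["normal"] * n_normal + ["cancer"] * n_cancer
    for i, group in enumerate(groups):
        sid = f"{group}_{i:03d}" if group == "normal" else f"{group}_{i - n_normal:03d}"
        if group == "normal":
            h = float(rng.beta(effect.normal_alpha, effect.normal_beta))
        else:
            h = float(rng.beta(effect.cancer_alpha, effect.cancer_beta))
        mix = mix_from_high_fraction(h, K, effect.low_bin_decay, effect.top_split)
        mean_meth = float((np.arange(K + 1) * mix).sum() / K)
        expr = max(0.01, effect.expr_intercept + effect.expr_slope * h) * float(
            np.exp(rng.normal(0.0, effect.expr_sd))
        )
        cfg = SimSampleConfig(
            sample_id=sid, group=group, n_reads=n_reads,
            epiallele_mix=tuple(mix), seed=int(rng.integers(0, 2**31 - 1)),
            **sample_kwargs,
        )
        configs.append(cfg)
        row = {"sample_id": sid, "group": group, "true_high_frac": h,
               "true_mean_meth": mean_meth, "true_rel_expr": expr}
        row.update({f"mix_{m}": mix[m] for m in range(K + 1)})
        truth_rows.append(row)

        meta = {"sample_id": sid, "core_id": f"core_{i:03d}", "lesion": group}
        if group == "cancer":
            def bern(center):
                p = 1.0 / (1.0 + np.exp(-effect.label_steepness * (h - center)))
                return bool(rng.random() < p)
            gl_high = bern(effect.label_centers["gleason_high"])
            meta["gleason_group"] = int(rng.integers(3, 6)) if gl_high else int(rng.integers(1, 3))
            meta["t_stage"] = "T3" if bern(effect.label_centers["t3"]) else "T2"
            meta["epe"] = bern(effect.label_centers["epe"])
            meta["sv"] = bern(effect.label_centers["sv"])
            meta["ln"] = bern(effect.label_centers["ln"])
            meta["psa_recurrence"] = bern(effect.label_centers["psa_recurrence"])
        else:
            meta.update({"gleason_group": pd.NA, "t_stage": pd.NA, "epe": pd.NA,
                         "sv": pd.NA, "ln": pd.NA, "psa_recurrence": pd.NA})
        meta_rows.append(meta)
    return configs, pd.DataFrame(truth_rows), pd.DataFrame(meta_rows)


@dataclass
class CohortSim:
    """A simulated cohort: generative configs, truth, metadata and reads."""

    configs: list
    truth: pd.DataFrame
    metadata: pd.DataFrame
    reads: dict  # sample_id -> list of (read_id, seq, qual)
    read_truth: pd.DataFrame

    def write(self, out_dir: str) -> pd.DataFrame:
        """Write FASTQs, metadata and a manifest; returns the manifest."""
        os.makedirs(out_dir, exist_ok=True)
        rows = []
        for sid, recs in self.reads.items():
            path = os.path.join(out_dir, f"{sid}.fastq")
            write_fastq(recs, path)
            rows.append({"sample_id": sid, "fastq": path})
        manifest = pd.DataFrame(rows)
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
        self.metadata.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
        self.truth.to_csv(os.path.join(out_dir, "truth.csv"), index=False)
        return manifest


def simulate_cohort(
    n_normal: int,
    n_cancer: int,
    effect: Optional[EffectConfig] = None,
    seed: int = 0,
    spec: Optional[AmpliconSpec] = None,
    n_reads: int = 3000,
    **sample_kwargs,
) -> CohortSim:
    """Simulate a full cohort of bisulfite read sets with linked metadata."""
    spec = spec or onecut2_amplicon()
    configs, truth, metadata = draw_cohort_truth(
        n_normal, n_cancer, effect, seed, spec, n_reads, **sample_kwargs
    )
    reads, per_read = {}, []
    for cfg in configs:
        recs, rt = simulate_sample_reads(cfg, spec)
        reads[cfg.sample_id] = recs
        rt.insert(0, "sample_id", cfg.sample_id)
        per_read.append(rt)
    return CohortSim(configs, truth, metadata, reads, pd.concat(per_read, ignore_index=True))


DEFAULT_CURVES = {
    # slope, intercept: slopes at the assay's reported median of -3.30
    "ONECUT2": (-3.30, 32.0),
    "HPRT1": (-3.30, 28.0),
}


def simulate_qpcr_plate(
    truth: pd.DataFrame,
    curve_params: Optional[dict] = None,
    noise_sd: float = 0.25,
    seed: int = 0,
    calibrator_id: str = "LNCaP",
    dilution_log10: Sequence[float] = (-2, -1, 0, 1, 2),
    input_sd: float = 0.2,
) -> pd.DataFrame:
    """Emit a Cq table for a cohort: unknowns in duplicate, standards, controls.

    The target quantity of each sample is its true relative expression times a
    per-sample lognormal input amount (which cancels under reference-gene
    normalization); Cq = intercept + slope*log10(quantity) + N(0, noise_sd).
    The calibrator sample is included with normalized quantity exactly 1.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    curves = curve_params or DEFAULT_CURVES
    rng = np.random.default_rng(seed)
    rows = []

    def cq(target, quantity):
        slope, intercept = curves[target]
        return intercept + slope * np.log10(quantity) + rng.normal(0.0, noise_sd)

    for target, (slope, intercept) in curves.items():
        for lg in dilution_log10:
            for rep in (1, 2):
                rows.append({"sample": f"std_{target}", "target": target, "replicate": rep,
                             "Cq": cq(target, 10.0 ** lg), "well_type": "standard",
                             "log10_input": lg})
        rows.append({"sample": f"ntc_{target}", "target": target, "replicate": 1,
                     "Cq": np.nan, "well_type": "ntc", "log10_input": np.nan})
        rows.append({"sample": f"nort_{target}", "target": target, "replicate": 1,
                     "Cq": np.nan, "well_type": "no_rt", "log10_input": np.nan})

    samples = list(truth["sample_id"]) + [calibrator_id]
    expr = dict(zip(truth["sample_id"], truth["true_rel_expr"]))
    expr[calibrator_id] = 1.0
    for sid in samples:
        q_ref = float(np.exp(rng.normal(0.0, input_sd))) if sid != calibrator_id else 1.0
        q_target = expr[sid] * q_ref
        for rep in (1, 2):
            rows.append({"sample": sid, "target": "ONECUT2", "replicate": rep,
                         "Cq": cq("ONECUT2", q_target), "well_type": "unknown",
                         "log10_input": np.nan})
            rows.append({"sample": sid, "target": "HPRT1", "replicate": rep,
                         "Cq": cq("HPRT1", q_ref), "well_type": "unknown",
                         "log10_input": np.nan})
    return pd.DataFrame(rows)
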