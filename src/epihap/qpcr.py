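"""Standard-curve qPCR quantification of relative gene expression.

Implements the absolute-quantification workflow: per-target standard curves
fitted by ordinary least squares of Cq on log10(input), PCR efficiency
E = (10^(-1/slope) - 1) x 100%, absolute quantities Q = 10^((Cq-intercept)/slope),
normalization of the target to a reference gene (HPRT1), replicate
summarization as mean +/- SD, and scaling to a calibrator sample (LNCaP,
set to 1).  Reference-gene replicates above the Cq cutoff (35) are excluded;
samples with no usable reference replicate are flagged and excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

REF_CQ_CUTOFF = 35.0
MAX_CYCLES = 40.0


@dataclass
class StandardCurve:
    """Fitted dilution series for one target."""

    target: str
    slope: float
    intercept: float
    r2: float
    n_levels: int

    @property
    def efficiency_pct(self) -> float:
        """PCR efficiency E = (10^(-1/slope) - 1) x 100%."""
        return (10.0 ** (-1.0 / self.slope) - 1.0) * 100.0


def fit_standard_curve(log10_input, cq, target: str = "") -> StandardCurve:
    """OLS fit of Cq versus log10(input) over a serial dilution."""
    x = np.asarray(log10_input, dtype=float)
    y = np.asarray(cq, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    levels = np.unique(x)
    if levels.size < 3:
        raise ValueError(f"standard curve for {target!r} needs >=3 distinct dilution levels")
    res = stats.linregress(x, y)
    return StandardCurve(target, float(res.slope), float(res.intercept),
                         float(res.rvalue ** 2), int(levels.size))


def absolute_quantity(cq: float, curve: StandardCurve) -> float:
    """Q = 10^((Cq - intercept)/slope); strictly decreasing in Cq for slope < 0."""
    return 10.0 ** ((cq - curve.intercept) / curve.slope)


@dataclass
class ExpressionResult:
    """Calibrated relative expression of one sample."""

    sample_id: str
    q_target: float  # mean over replicates
    q_ref: float
    normalized: float  # mean of per-replicate q_target/q_ref
    normalized_sd: float
    relative: float  # normalized scaled to the calibrator
    n_replicates: int
    qc_flags: tuple = ()

    @property
    def excluded(self) -> bool:
        return "ref_failed" in self.qc_flags


def _replicate_normalized(rows: pd.DataFrame, curves: dict, ref_target: str,
                          ref_cutoff: float) -> tuple[list, list, list, list]:
    """Per-replicate normalized quantities for one sample's Cq rows."""
    flags = []
    targets = [t for t in rows["target"].unique() if t != ref_target]
    if len(targets) != 1:
        raise ValueError(f"expected one target gene, found {targets}")
    target = targets[0]
    for t in (target, ref_target):
        if t not in curves:
            raise KeyError(f"no standard curve for target {t!r}")
    norm, qt_all, qr_all = [], [], []
    reps = sorted(rows["replicate"].unique())
    for rep in reps:
        sub = rows[rows["replicate"] == rep]
        cq_t = sub.loc[sub["target"] == target, "Cq"]
        cq_r = sub.loc[sub["target"] == ref_target, "Cq"]
        if cq_t.empty or cq_r.empty:
            flags.append(f"missing_replicate_{rep}")
            continue
        cq_r = float(cq_r.iloc[0])
        cq_t = float(cq_t.iloc[0])
        if not math.isfinite(cq_r) or cq_r > ref_cutoff:
            flags.append(f"ref_above_cutoff_rep{rep}")
            continue
        # no cutoff on the target gene: undetected wells quantify as 0
        q_t = 0.0 if not math.isfinite(cq_t) else absolute_quantity(cq_t, curves[target])
        if q_t == 0.0:
            flags.append(f"target_undetected_rep{rep}")
        q_r = absolute_quantity(cq_r, curves[ref_target])
        norm.append(q_t / q_r)
        qt_all.append(q_t)
        qr_all.append(q_r)
    return norm, qt_all, qr_all, flags


def quantify_sample(rows: pd.DataFrame, curves: dict, calibrator_normalized: float,
                    ref_target: str = "HPRT1", ref_cutoff: float = REF_CQ_CUTOFF) -> ExpressionResult:
    """Relative expression of one sample from its replicate Cq rows.

    Replicates are normalized first (Q_target/Q_ref per replicate) and then
    averaged; the alternative order (average quantities, then normalize) is
    available via :func:`quantify_plate`.
    """
    sid = rows["sample"].iloc[0]
    norm, qt, qr, flags = _replicate_normalized(rows, curves, ref_target, ref_cutoff)
    if not norm:
        return ExpressionResult(sid, float("nan"), float("nan"), float("nan"),
                                float("nan"), float("nan"), 0, tuple(flags) + ("ref_failed",))
    normalized = float(np.mean(norm))
    sd = float(np.std(norm, ddof=1)) if len(norm) > 1 else float("nan")
    return ExpressionResult(sid, float(np.mean(qt)), float(np.mean(qr)), normalized, sd,
                            normalized / calibrator_normalized, len(norm), tuple(flags))


def control_check(cq_table: pd.DataFrame, max_cycles: float = MAX_CYCLES) -> pd.DataFrame:
    """Pass/fail per target for no-template and no-RT control wells.

    A control well with a numeric Cq below the max-cycle sentinel indicates
    contamination or genomic carry-over and fails the whole target.
    """
    ctrl = cq_table[cq_table["well_type"].isin(["ntc", "no_rt"])]
    out = []
    for target, sub in ctrl.groupby("target"):
        amplified = sub["Cq"].astype(float)
        bad = amplified[np.isfinite(amplified) & (amplified < max_cycles)]
        out.append({"target": target, "n_control_wells": len(sub),
                    "n_amplified": int(bad.size), "passed": bad.size == 0})
    return pd.DataFrame(out)


def fit_plate_curves(cq_table: pd.DataFrame) -> dict:
    """Fit one standard curve per target from the plate's standard wells."""
    std = cq_table[cq_table["well_type"] == "standard"]
    curves = {}
    for target, sub in std.groupby("target"):
        curves[target] = fit_standard_curve(sub["log10_input"], sub["Cq"], target)
    return curves


def quantify_plate(
    cq_table: pd.DataFrame,
    calibrator_id: str = "LNCaP",
    ref_target: str = "HPRT1",
    ref_cutoff: float = REF_CQ_CUTOFF,
    curves: Optional[dict] = None,
    order: str = "quantities_first",
) -> tuple[pd.DataFrame, dict]:
    """Full plate workflow: curves, controls, calibrator, per-sample results.

    Returns ``(results, curves)`` where results has one row per unknown
    sample.  ``order`` selects replicate summarization: ``quantities_first``
    normalizes each replicate then averages (default); ``cq_first`` averages
    Cq values per target before quantification.
    """
    curves = curves or fit_plate_curves(cq_table)
    controls = control_check(cq_table)
    plate_flag = () if controls.empty or controls["passed"].all() else ("control_failure",)

    unknowns = cq_table[cq_table["well_type"] == "unknown"].copy()
    if order == "cq_first":
        unknowns = (unknowns.groupby(["sample", "target"], as_index=False)
                    .agg(Cq=("Cq", "mean")))
        unknowns["replicate"] = 1

    cal_rows = unknowns[unknowns["sample"] == calibrator_id]
    if cal_rows.empty:
        raise ValueError(f"calibrator sample {calibrator_id!r} not on plate")
    cal_norm, _, _, _ = _replicate_normalized(cal_rows, curves, ref_target, ref_cutoff)
    if not cal_norm:
        raise ValueError("calibrator reference gene failed the Cq cutoff")
    cal = float(np.mean(cal_norm))

    results = []
    for sid, rows in unknowns.groupby("sample"):
        if sid == calibrator_id:
            continue
        r = quantify_sample(rows, curves, cal, ref_target, ref_cutoff)
        results.append({"sample_id": r.sample_id, "normalized": r.normalized,
                        "normalized_sd": r.normalized_sd, "relative": r.relative,
                        "n_replicates": r.n_replicates, "excluded": r.excluded,
                        "qc_flags": ";".join(r.qc_flags + plate_flag)})
    return pd.DataFrame(results), curves
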