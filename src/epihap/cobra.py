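"""Modified COBRA (combined bisulfite restriction analysis) quantification.

A bisulfite-PCR amplicon is split into a digested and an undigested aliquot
and both are re-amplified by qPCR.  The restriction sites used here (BstUI
at CG/CG for cg10835584, BsiWI at C/GTACG for cg24771804) survive bisulfite
conversion only when their CpG cytosines were methylated, so the digested
fraction reads out the methylation level of the targeted site.

The assay never observes the digested fraction directly; this module's model
is the standard exponential qPCR interpretation: the intact (undigestible)
template fraction is f^-(dCq) with dCq = cq_digested - cq_undigested and f
the per-cycle amplification factor (2 for perfect efficiency, or 1 + E/100
from a fitted standard curve).  The orientation "cut = methylated" is an
explicit, flaggable assumption recorded on each measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd

#: tolerated negative dCq (cycles) before a measurement is flagged inconsistent
DCQ_TOLERANCE = 0.5

SITE_ENZYMES = {"cg10835584": "BstUI", "cg24771804": "BsiWI"}


@dataclass
class CobraMeasurement:
    """One digested/undigested Cq pair for one sample and restriction site."""

    sample_id: str
    site: str
    cq_digested: float
    cq_undigested: float
    amplification_factor: float = 2.0
    timepoint: str = ""

    def __post_init__(self):
        if self.amplification_factor <= 1.0:
            raise ValueError("amplification_factor must exceed 1")
        if not (math.isfinite(self.cq_digested) and math.isfinite(self.cq_undigested)):
            raise ValueError("both Cq values must be present")

    @property
    def delta_cq(self) -> float:
        return self.cq_digested - self.cq_undigested

    @property
    def inconsistent(self) -> bool:
        """Digested amplifying earlier than undigested beyond tolerance."""
        return self.delta_cq < -DCQ_TOLERANCE

    @property
    def intact_fraction(self) -> float:
        """Surviving template fraction f^-(dCq), clamped to (0, 1]."""
        frac = self.amplification_factor ** (-self.delta_cq)
        return min(frac, 1.0)

    @property
    def methylation_level(self) -> float:
        return 1.0 - self.intact_fraction


def digestion_rate(m: CobraMeasurement) -> float:
    """Fraction of template cut by the enzyme, read as the methylated fraction."""
    return 1.0 - m.intact_fraction


def relative_methylation(before: CobraMeasurement, after: CobraMeasurement) -> float:
    """Ratio of digestion rates after/before treatment (same site).

    NaN signals an undefined ratio (no detectable digestion before
    treatment); the absolute cut fractions stay reportable.
    """
    if before.site != after.site:
        raise ValueError(f"site mismatch: {before.site!r} vs {after.site!r}")
    cut_before = digestion_rate(before)
    if cut_before == 0.0:
        return float("nan")
    return digestion_rate(after) / cut_before


def analyze_table(df: pd.DataFrame, baseline_timepoint: Optional[str] = None) -> pd.DataFrame:
    """Cut fractions (and ratios to a baseline timepoint) for a COBRA CSV.

    Expects columns sample, site, timepoint, cq_digested, cq_undigested and
    optionally amplification_factor.  With ``baseline_timepoint`` given, each
    (sample, site) row also carries its digestion rate relative to baseline —
    the treatment-trajectory readout (e.g. demethylation after a DNMT
    inhibitor and subsequent restoration).
    """
    rows = []
    for _, r in df.iterrows():
        m = CobraMeasurement(
            sample_id=str(r["sample"]), site=str(r["site"]),
            cq_digested=float(r["cq_digested"]), cq_undigested=float(r["cq_undigested"]),
            amplification_factor=float(r.get("amplification_factor", 2.0) or 2.0),
            timepoint=str(r.get("timepoint", "")),
        )
        rows.append({"sample": m.sample_id, "site": m.site, "timepoint": m.timepoint,
                     "enzyme": SITE_ENZYMES.get(m.site, ""), "delta_cq": m.delta_cq,
                     "cut_fraction": digestion_rate(m), "inconsistent": m.inconsistent})
    out = pd.DataFrame(rows)
    if baseline_timepoint is not None and not out.empty:
        base = (out[out["timepoint"] == baseline_timepoint]
                .set_index(["sample", "site"])["cut_fraction"])
        key = list(zip(out["sample"], out["site"]))
        base_vals = base.reindex(key).to_numpy()
        out["relative_to_baseline"] = out["cut_fraction"] / base_vals
    return out
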