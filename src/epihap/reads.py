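"""Per-sample FASTQ driver: stream reads, classify, emit call tables and QC.

Each sample's FASTQ is streamed record by record (constant per-read state),
every read is classified against the amplicon in both orientations, and the
result is a plain one-row-per-read call table plus a QC summary.  Downstream
modules consume call tables, never raw FASTQ.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .amplicon import AmpliconSpec, QCThresholds, classify_read
from .spectrum import MIN_RETAINED_READS, STATUSES, build_spectrum

log = logging.getLogger(__name__)

CALL_COLUMNS = ["read_id", "status", "pattern", "n_methylated",
                "mismatch_frac", "conversion_rate", "orientation"]


@dataclass
class SampleCallTable:
    """Per-read calls and QC summary for one sample."""

    sample_id: str
    calls: pd.DataFrame  # CALL_COLUMNS
    status_counts: dict = field(default_factory=dict)
    conversion_quantiles: dict = field(default_factory=dict)
    empty_input: bool = False

    @property
    def n_reads(self) -> int:
        return len(self.calls)

    @property
    def n_retained(self) -> int:
        return int(self.status_counts.get("retained", 0))


def _iter_fastq(path: str) -> Iterator:
    try:
        yield from SeqIO.parse(path, "fastq")
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc


def process_sample(
    fastq_path: str,
    spec: AmpliconSpec,
    qc: QCThresholds = QCThresholds(),
    sample_id: Optional[str] = None,
) -> SampleCallTable:
    """Classify every read of one sample's FASTQ."""
    sid = sample_id or os.path.splitext(os.path.basename(fastq_path))[0]
    rows = []
    conv = []
    counts = {s: 0 for s in STATUSES}
    for i, rec in enumerate(_iter_fastq(fastq_path)):
        qual = rec.letter_annotations.get("phred_quality") if qc.phred_mask_cutoff else None
        try:
            call = classify_read(str(rec.seq), spec, qc, read_id=rec.id, qual=qual)
        except Exception as exc:  # pragma: no cover - defensive
            raise ValueError(f"failed on record {i} ({rec.id}) of {fastq_path}") from exc
        counts[call.status] += 1
        if np.isfinite(call.conversion_rate):
            conv.append(call.conversion_rate)
        rows.append((call.read_id, call.status, call.cpg_states or "",
                     call.n_methylated, call.mismatch_frac, call.conversion_rate,
                     call.orientation))
    calls = pd.DataFrame(rows, columns=CALL_COLUMNS)
    quantiles = {}
    if conv:
        q = np.quantile(conv, [0.05, 0.25, 0.5, 0.75, 0.95])
        quantiles = dict(zip(["q05", "q25", "q50", "q75", "q95"], map(float, q)))
    table = SampleCallTable(sid, calls, counts, quantiles, empty_input=not rows)
    if table.empty_input:
        log.warning("sample %s: empty FASTQ", sid)
    else:
        log.info("sample %s: %d reads, %d retained (%.1f%%)", sid, table.n_reads,
                 table.n_retained, 100.0 * table.n_retained / table.n_reads)
    return table


def calls_to_spectrum(table: SampleCallTable, K: int):
    """Epiallele spectrum from a call table (retained reads only)."""
    from .amplicon import ReadPatternCall
    calls = [
        ReadPatternCall(r.read_id, r.status, r.pattern or None,
                        int(r.n_methylated) if pd.notna(r.n_methylated) else None)
        for r in table.calls.itertuples()
    ]
    return build_spectrum(calls, K, table.sample_id)


def cohort_run(
    manifest: pd.DataFrame,
    spec: AmpliconSpec,
    qc: QCThresholds = QCThresholds(),
    min_retained: int = MIN_RETAINED_READS,
    out_dir: Optional[str] = None,
) -> tuple[dict, pd.DataFrame]:
    """Run every sample of a manifest (columns sample_id, fastq).

    Returns ``(tables, qc_report)``; samples below the minimum retained-read
    threshold are flagged excluded, mirroring the exclusion of poor-quality
    cores.  Per-sample call TSVs are written when ``out_dir`` is given.
    """
    if manifest["sample_id"].duplicated().any():
        dups = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s) in manifest: {dups}")
    tables, report = {}, []
    for row in manifest.itertuples():
        table = process_sample(row.fastq, spec, qc, sample_id=row.sample_id)
        tables[row.sample_id] = table
        rep = {"sample_id": row.sample_id, "n_reads": table.n_reads,
               "excluded": table.n_retained < min_retained}
        rep.update({s: table.status_counts.get(s, 0) for s in STATUSES})
        report.append(rep)
        if out_dir:
            os.makedirs(out_dir, exist_ok=True)
            table.calls.to_csv(os.path.join(out_dir, f"{row.sample_id}.calls.tsv"),
                               sep="\t", index=False)
    return tables, pd.DataFrame(report)
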