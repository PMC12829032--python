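"""Amplicon coordinate system, in-silico bisulfite chemistry and per-read pattern calling.

The assay interrogates a single targeted bisulfite-PCR amplicon (for the
prostate application: a 126 bp window of the ONECUT2 gene body on chr18
carrying eight CpG sites).  Reads are compared directly against the
bisulfite-converted reference — no general-purpose aligner — and classified
as retained / dimer / off-target / low-conversion / ambiguous before any
methylation statistics are computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTRYN", "TGCAYRN")

# IUPAC codes matching more than one base; positions under a primer footprint
# carrying one of these are wildcards during read comparison.
_DEGENERATE = set("RYSWKMBDHVN")


def revcomp(seq: str) -> str:
    """Reverse complement, preserving the degenerate codes R and Y."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconSpec:
    """A single bisulfite amplicon: reference, CpG sites and primers.

    Coordinates follow the convention of the source assay: ``start``/``end``
    are 1-based inclusive genomic positions, while ``cpg_positions`` are
    0-based offsets into ``ref_seq`` pointing at the C of each CG dinucleotide.
    ``primer_fwd``/``primer_rev`` are the PCR primers in bisulfite space and
    may contain the degenerate codes R (A/G) and Y (C/T) where a primer spans
    an unavoidable CpG.
    """

    name: str
    chrom: str
    start: int
    end: int
    ref_seq: str
    cpg_positions: tuple[int, ...]
    primer_fwd: str = ""
    primer_rev: str = ""
    named_sites: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.end - self.start + 1 != len(self.ref_seq):
            raise ValueError(
                f"coordinate span {self.end - self.start + 1} != reference length {len(self.ref_seq)}"
            )
        if set(self.ref_seq) - set("ACGT"):
            raise ValueError("ref_seq must be uppercase A/C/G/T")
        prev = -1
        for p in self.cpg_positions:
            if p <= prev:
                raise ValueError("cpg_positions must be strictly increasing")
            if self.ref_seq[p : p + 2] != "CG":
                raise ValueError(f"offset {p} is not a CG dinucleotide")
            prev = p
        for probe, idx in self.named_sites.items():
            if not 0 <= idx < self.n_sites:
                raise ValueError(f"named site {probe!r} maps to invalid index {idx}")

    def __hash__(self):  # named_sites (a dict) is excluded so specs stay cacheable
        return hash((self.name, self.chrom, self.start, self.end,
                     self.ref_seq, self.cpg_positions, self.primer_fwd, self.primer_rev))

    @property
    def n_sites(self) -> int:
        """Number of CpG sites K."""
        return len(self.cpg_positions)

    def to_json(self) -> str:
        d = asdict(self)
        d["cpg_positions"] = list(self.cpg_positions)
        d["named_sites"] = dict(self.named_sites)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "AmpliconSpec":
        d = json.loads(text)
        d["cpg_positions"] = tuple(d["cpg_positions"])
        return cls(**d)


@dataclass(frozen=True)
class QCThresholds:
    """Read-level QC cutoffs for pattern calling.

    The assay vendor's noise-elimination criteria are not public; these are
    conventional bisulfite amplicon values, declared stand-ins and exposed in
    the pipeline configuration.

    min_read_length : reads shorter than this are primer dimers (nt).
    max_mismatch_frac : tolerated disagreement with the converted reference
        over non-cytosine-context positions before a read is off-target.
    min_conversion_rate : minimum fraction of non-CpG reference cytosines
        read as T (bisulfite conversion efficiency per read).
    phred_mask_cutoff : if set, bases with Phred quality below this are
        masked to no-calls before pattern calling (default off).
    """

    min_read_length: int = 40
    max_mismatch_frac: float = 0.10
    min_conversion_rate: float = 0.95
    phred_mask_cutoff: Optional[int] = None


@dataclass
class ReadPatternCall:
    """Classification of one read against an amplicon.

    ``cpg_states`` is a length-K string over {M, U, N} once classification
    reached the calling stage, otherwise None.  ``n_methylated`` is set only
    for retained reads.
    """

    read_id: str
    status: str  # retained | dimer | off_target | low_conversion | ambiguous_cpg
    cpg_states: Optional[str] = None
    n_methylated: Optional[int] = None
    mismatch_frac: float = float("nan")
    conversion_rate: float = float("nan")
    orientation: str = "+"


def bisulfite_convert_reference(spec: AmpliconSpec, methylated: Sequence[bool]) -> str:
    """In-silico bisulfite conversion of the amplicon reference.

    Every cytosine converts to T except a CpG-site C whose ``methylated``
    flag is true.  CpG sites are the listed ``cpg_positions``; a CG
    dinucleotide inside a primer footprint (covered by a degenerate primer
    base) is treated as unmethylated template.
    """
    if len(methylated) != spec.n_sites:
        raise ValueError(f"expected {spec.n_sites} methylation flags, got {len(methylated)}")
    keep = {p for p, m in zip(spec.cpg_positions, methylated) if m}
    return "".join(
        "T" if (b == "C" and i not in keep) else b for i, b in enumerate(spec.ref_seq)
    )


@lru_cache(maxsize=16)
def _spec_arrays(spec: AmpliconSpec):
    """Precomputed numpy views used by classify_read (cached per spec)."""
    ref = np.frombuffer(spec.ref_seq.encode(), dtype=np.uint8)
    L = len(ref)
    template = np.frombuffer(
        bisulfite_convert_reference(spec, [False] * spec.n_sites).encode(), dtype=np.uint8
    )
    is_c = ref == ord("C")
    # wildcard positions: any reference C (reads may carry C or T there) and
    # degenerate primer-footprint bases
    wildcard = is_c.copy()
    primer_footprint = np.zeros(L, dtype=bool)
    if spec.primer_fwd:
        n = len(spec.primer_fwd)
        primer_footprint[:n] = True
        for i, b in enumerate(spec.primer_fwd):
            if b in _DEGENERATE:
                wildcard[i] = True
    if spec.primer_rev:
        tail = revcomp(spec.primer_rev)
        n = len(tail)
        primer_footprint[L - n :] = True
        for i, b in enumerate(tail):
            if b in _DEGENERATE:
                wildcard[L - n + i] = True
    followed_by_g = np.zeros(L, dtype=bool)
    followed_by_g[:-1] = ref[1:] == ord("G")
    # conversion-rate positions: non-CpG-context Cs outside primer footprints
    conv_pos = np.flatnonzero(is_c & ~followed_by_g & ~primer_footprint)
    cpg_idx = np.asarray(spec.cpg_positions, dtype=np.intp)
    compare_mask = ~wildcard
    return template, compare_mask, conv_pos, cpg_idx


def _score_orientation(read: np.ndarray, spec: AmpliconSpec) -> float:
    template, compare_mask, _, _ = _spec_arrays(spec)
    n = min(len(read), len(template))
    mask = compare_mask[:n]
    total = int(mask.sum())
    if total == 0:
        return 1.0
    return float((read[:n][mask] != template[:n][mask]).sum() / total)


def classify_read(
    seq: str,
    spec: AmpliconSpec,
    qc: QCThresholds = QCThresholds(),
    read_id: str = "",
    qual: Optional[Sequence[int]] = None,
) -> ReadPatternCall:
    """Classify one read and call its per-CpG methylation pattern.

    The read is compared position-by-position against the fully converted
    reference, with every reference cytosine treated as a C/T wildcard.  Both
    orientations are tried (the read as given and its reverse complement
    against the forward spec, which is equivalent to matching the
    reverse-strand amplicon variant) and the one with the lower mismatch
    fraction is kept.  Classification cascades dimer → off_target →
    low_conversion → ambiguous_cpg → retained.
    """
    seq = seq.upper()
    if len(seq) < qc.min_read_length:
        return ReadPatternCall(read_id, "dimer")

    fwd = np.frombuffer(seq.encode(), dtype=np.uint8)
    mm_fwd = _score_orientation(fwd, spec)
    if mm_fwd == 0.0:
        read, mismatch, orient = fwd, 0.0, "+"
        qual_arr = qual
    else:
        rc = np.frombuffer(revcomp(seq).encode(), dtype=np.uint8)
        mm_rev = _score_orientation(rc, spec)
        if mm_rev < mm_fwd:
            read, mismatch, orient = rc, mm_rev, "-"
            qual_arr = qual[::-1] if qual is not None else None
        else:
            read, mismatch, orient = fwd, mm_fwd, "+"
            qual_arr = qual

    if mismatch > qc.max_mismatch_frac:
        return ReadPatternCall(read_id, "off_target", mismatch_frac=mismatch, orientation=orient)

    template, _, conv_pos, cpg_idx = _spec_arrays(spec)
    n = min(len(read), len(template))
    masked = None
    if qc.phred_mask_cutoff is not None and qual_arr is not None:
        masked = np.asarray(qual_arr[: len(read)]) < qc.phred_mask_cutoff

    cp = conv_pos[conv_pos < n]
    bases = read[cp]
    if masked is not None:
        bases = bases[~masked[cp]]
    n_t = int((bases == ord("T")).sum())
    n_c = int((bases == ord("C")).sum())
    conversion = n_t / (n_t + n_c) if (n_t + n_c) else 1.0
    if conversion < qc.min_conversion_rate:
        return ReadPatternCall(
            read_id, "low_conversion", mismatch_frac=mismatch,
            conversion_rate=conversion, orientation=orient,
        )

    states = []
    for p in cpg_idx:
        if p >= n or (masked is not None and masked[p]):
            states.append("N")
            continue
        b = chr(read[p])
        states.append("M" if b == "C" else "U" if b == "T" else "N")
    pattern = "".join(states)
    if "N" in pattern:
        return ReadPatternCall(
            read_id, "ambiguous_cpg", cpg_states=pattern,
            mismatch_frac=mismatch, conversion_rate=conversion, orientation=orient,
        )
    return ReadPatternCall(
        read_id, "retained", cpg_states=pattern, n_methylated=pattern.count("M"),
        mismatch_frac=mismatch, conversion_rate=conversion, orientation=orient,
    )


def reverse_strand_variant(spec: AmpliconSpec) -> AmpliconSpec:
    """The reverse-complement amplicon with CpG offsets remapped.

    Site index i on the forward spec corresponds to index K-1-i on the
    variant; applying the operation twice returns the original spec.
    """
    L = len(spec.ref_seq)
    cpg = tuple(sorted(L - 2 - p for p in spec.cpg_positions))
    K = spec.n_sites
    named = {probe: K - 1 - i for probe, i in spec.named_sites.items()}
    return AmpliconSpec(
        name=spec.name,
        chrom=spec.chrom,
        start=spec.start,
        end=spec.end,
        ref_seq=revcomp(spec.ref_seq),
        cpg_positions=cpg,
        primer_fwd=spec.primer_rev,
        primer_rev=spec.primer_fwd,
        named_sites=named,
    )


def onecut2_amplicon() -> AmpliconSpec:
    """The default ONECUT2 gene-body amplicon (synthetic reference).

    The assay's coordinates (chr18:55107668-55107793, 126 bp), primer
    sequences and CpG count (8 sites, including probes cg10835584 and
    cg24771804) are as published for the targeted bisulfite assay, but the
    genomic sequence between the primers is a synthetic stand-in constructed
    to be consistent with them: primer-binding regions whose bisulfite
    conversion matches the degenerate primers, and an interior carrying eight
    evenly spaced CpG sites plus non-CpG cytosines for conversion QC.  Probe
    index assignments for the six unnamed CpGs are arbitrary.
    """
    primer_fwd = "GGTTTTTTTTGGGTTTTYGGGGT"
    primer_rev = "AAAACCAAATACTTACRCTAAAAACTCTAC"
    fwd_genomic = primer_fwd.replace("Y", "C")  # bisulfite primer back-mapped, Y at a primer CpG
    rev_genomic = revcomp(primer_rev).replace("Y", "C")
    interior = "ACGTTCATG" * 8 + "A"
    ref = fwd_genomic + interior + rev_genomic
    cpg = tuple(len(fwd_genomic) + 9 * i + 1 for i in range(8))
    return AmpliconSpec(
        name="ONECUT2_gene_body",
        chrom="chr18",
        start=55107668,
        end=55107793,
        ref_seq=ref,
        cpg_positions=cpg,
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
        named_sites={"cg10835584": 2, "cg24771804": 5},
    )
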