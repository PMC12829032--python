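"""Amplicon model: in-silico conversion, read classification, strand handling."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from epihap.amplicon import (AmpliconSpec, QCThresholds, bisulfite_convert_reference,
                             classify_read, onecut2_amplicon, revcomp,
                             reverse_strand_variant)


@pytest.mark.parametrize("ref,cpg,flags,expected", [
    ("ACGTCA", (1,), [True], "ACGTTA"),   # only the non-CpG C converts
    ("ACGTCA", (1,), [False], "ATGTTA"),  # everything converts
    ("AGGTTA", (), [], "AGGTTA"),         # nothing to convert
])
def test_convert_reference(ref, cpg, flags, expected):
    spec = AmpliconSpec("t", "chrT", 1, len(ref), ref, cpg)
    assert bisulfite_convert_reference(spec, flags) == expected


def test_convert_reference_flag_length_checked(toy_spec):
    with pytest.raises(ValueError):
        bisulfite_convert_reference(toy_spec, [True, False])


def test_spec_invariants_enforced():
    with pytest.raises(ValueError):  # offset not at a CG
        AmpliconSpec("t", "chrT", 1, 6, "ACGTCA", (2,))
    with pytest.raises(ValueError):  # coordinate span mismatch
        AmpliconSpec("t", "chrT", 1, 5, "ACGTCA", (1,))
    with pytest.raises(ValueError):  # not strictly increasing
        AmpliconSpec("t", "chrT", 1, 8, "ACGTACGT", (4, 1))


def test_spec_json_round_trip(spec):
    assert AmpliconSpec.from_json(spec.to_json()) == spec


def test_fully_methylated_read_retained(spec):
    read = bisulfite_convert_reference(spec, [True] * spec.n_sites)
    call = classify_read(read, spec)
    assert call.status == "retained"
    assert call.n_methylated == spec.n_sites
    assert call.cpg_states == "M" * spec.n_sites


def test_short_read_is_dimer(spec):
    assert classify_read("ACGTACGTACGTACG", spec).status == "dimer"


def test_random_dna_is_off_target(spec):
    rng = np.random.default_rng(42)
    L = len(spec.ref_seq)
    statuses = set()
    for _ in range(1000):
        seq = "".join(rng.choice(list("ACGT"), L))
        statuses.add(classify_read(seq, spec).status)
    assert statuses == {"off_target"}


def test_all_patterns_recovered_exhaustively(spec):
    """Noiseless reads from every 2^K pattern call back exactly."""
    K = spec.n_sites
    for bits in itertools.product([False, True], repeat=K):
        read = bisulfite_convert_reference(spec, bits)
        call = classify_read(read, spec)
        assert call.status == "retained"
        assert call.cpg_states == "".join("M" if b else "U" for b in bits)
        assert call.n_methylated == sum(bits)


def test_low_conversion_detected(spec):
    # leave every non-CpG C unconverted: conversion rate 0
    seq = spec.ref_seq  # raw genomic sequence, no conversion at all
    call = classify_read(seq, spec)
    assert call.status == "low_conversion"
    assert call.conversion_rate < 0.95


def test_ambiguous_cpg_excluded(spec):
    read = list(bisulfite_convert_reference(spec, [True] * spec.n_sites))
    read[spec.cpg_positions[3]] = "G"  # non-C/T base at a CpG site
    call = classify_read("".join(read), spec)
    assert call.status == "ambiguous_cpg"
    assert call.cpg_states.count("N") == 1


def test_conversion_filter_is_monotone(spec):
    """Raising min_conversion_rate never increases retained reads."""
    rng = np.random.default_rng(3)
    reads = []
    conv = np.frombuffer(bisulfite_convert_reference(spec, [False] * 8).encode(), np.uint8)
    ref = np.frombuffer(spec.ref_seq.encode(), np.uint8)
    c_pos = np.flatnonzero(ref == ord("C"))
    for _ in range(300):
        arr = conv.copy()
        flip = c_pos[rng.random(c_pos.size) < 0.05]
        arr[flip] = ord("C")
        reads.append(arr.tobytes().decode())
    retained_at = []
    for thr in (0.0, 0.5, 0.9, 0.95, 0.99, 1.0):
        qc = QCThresholds(min_conversion_rate=thr)
        retained_at.append(sum(classify_read(r, spec, qc).status == "retained" for r in reads))
    assert retained_at == sorted(retained_at, reverse=True)


def test_reverse_strand_variant_properties(spec, toy_spec):
    # palindromic CpG: reverse of ACGT-like toy maps onto itself
    pal = AmpliconSpec("pal", "chrT", 1, 4, "ACGT", (1,))
    rv = reverse_strand_variant(pal)
    assert rv.ref_seq == "ACGT" and rv.cpg_positions == (1,)
    # involution
    assert reverse_strand_variant(reverse_strand_variant(spec)) == spec
    # site remap: index i <-> K-1-i
    rv = reverse_strand_variant(spec)
    L, K = len(spec.ref_seq), spec.n_sites
    for i, p in enumerate(spec.cpg_positions):
        assert rv.cpg_positions[K - 1 - i] == L - 2 - p
    assert rv.named_sites["cg10835584"] == K - 1 - spec.named_sites["cg10835584"]


def test_reverse_complemented_reads_classified_identically(spec):
    """Simulated forward reads give the same call submitted either way."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        bits = rng.random(spec.n_sites) < 0.5
        read = bisulfite_convert_reference(spec, bits)
        fwd = classify_read(read, spec)
        rev = classify_read(revcomp(read), spec)
        assert (fwd.status, fwd.cpg_states, fwd.n_methylated) == \
               (rev.status, rev.cpg_states, rev.n_methylated)


@given(st.text(alphabet="ACGT", min_size=1, max_size=80),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_conversion_output_has_no_unexpected_cytosines(seq, seed):
    """After conversion, C survives only at methylated CpG sites."""
    cpg = tuple(i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
    spec = AmpliconSpec("h", "chrT", 1, len(seq), seq, cpg)
    rng = np.random.default_rng(seed)
    flags = (rng.random(len(cpg)) < 0.5).tolist()
    out = bisulfite_convert_reference(spec, flags)
    assert len(out) == len(seq)
    kept = {p for p, f in zip(cpg, flags) if f}
    for i, (a, b) in enumerate(zip(seq, out)):
        if a != "C":
            assert a == b
        else:
            assert b == ("C" if i in kept else "T")
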