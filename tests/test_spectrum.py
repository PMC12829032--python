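"""Epiallele spectrum, biomarker score, Mann-Whitney and ROC statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from epihap.amplicon import ReadPatternCall
from epihap.spectrum import (build_spectrum, compare_groups, high_meth_score,
                             mann_whitney, pair_count_auc, per_bin_tests,
                             roc_auc, single_site_rate, spectrum_from_counts,
                             spectrum_matrix)


def _retained(n_meth, K=8):
    pattern = "M" * n_meth + "U" * (K - n_meth)
    return ReadPatternCall("r", "retained", pattern, n_meth)


def test_build_spectrum_counts():
    calls = [_retained(m) for m in (8, 8, 7, 3, 0)] + [ReadPatternCall("d", "dimer")]
    s = build_spectrum(calls, 8)
    assert s.counts[8] == 2 and s.counts[7] == 1 and s.counts[3] == 1 and s.counts[0] == 1
    assert s.counts.sum() == 5 and s.totals["dimer"] == 1


def test_build_spectrum_empty_and_invalid():
    assert build_spectrum([], 8).counts.sum() == 0
    with pytest.raises(ValueError):
        build_spectrum([_retained(9, K=9)], 8)


def test_high_meth_score_examples():
    s = spectrum_from_counts("a", [80, 0, 0, 0, 0, 0, 0, 10, 10])
    assert high_meth_score(s) == pytest.approx(0.20)
    s = spectrum_from_counts("b", [0] * 8 + [50])
    assert high_meth_score(s) == 1.0
    # parameterized bin: everything with >= 1 methylated site
    s = spectrum_from_counts("c", [50, 25, 0, 0, 0, 0, 0, 0, 25])
    assert high_meth_score(s, min_sites=1) == pytest.approx(0.5)


def test_high_meth_score_flags_low_coverage():
    s = spectrum_from_counts("a", [1, 0, 0, 0, 0, 0, 0, 0, 1])
    assert math.isnan(high_meth_score(s))  # below the retained-read minimum


def test_score_invariant_to_read_duplication():
    calls = [_retained(m) for m in (8, 7, 7, 2, 0, 5) for _ in range(5)]
    s1 = build_spectrum(calls, 8)
    s2 = build_spectrum(calls * 3, 8)
    assert high_meth_score(s1, min_reads=1) == pytest.approx(
        high_meth_score(s2, min_reads=1))


def test_single_site_rate():
    full = [ReadPatternCall("r", "retained", "M" * 8, 8)] * 25
    for i in range(8):
        assert single_site_rate(full, i) == 1.0
    alt = ([ReadPatternCall("a", "retained", "MUMUMUMU", 4)] * 15
           + [ReadPatternCall("b", "retained", "UMUMUMUM", 4)] * 15)
    for i in range(8):
        assert single_site_rate(alt, i) == pytest.approx(0.5)
    with pytest.raises(IndexError):
        single_site_rate(full, 8)


def test_mann_whitney_examples():
    u, p = mann_whitney([3, 4], [1, 2])
    assert u == 4.0  # complete separation
    u, p = mann_whitney([5, 5, 5], [5, 5, 5])
    assert u == pytest.approx(4.5)  # n1*n2/2 under pure ties
    assert p > 0.9
    with pytest.raises(ValueError):
        mann_whitney([], [1.0])


def _exact_p_by_enumeration(x, y):
    """Two-sided p from the permutation null of the U statistic (no ties)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(xi > yj for xi in x for yj in y)
    center = n1 * len(y) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(xi > yj for xi in xs for yj in ys)
        count += abs(u - center) >= abs(u_obs - center) - 1e-12
        total += 1
    return count / total


def test_mann_whitney_matches_permutation_enumeration():
    rng = np.random.default_rng(8)
    for _ in range(10):
        n1, n2 = rng.integers(2, 9, size=2)
        pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # distinct values
        x, y = pooled[:n1], pooled[n1:]
        _, p = mann_whitney(x, y)
        assert p == pytest.approx(_exact_p_by_enumeration(x, y), abs=1e-12)


def test_roc_auc_examples():
    auc, pts = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert auc == 1.0
    auc, _ = roc_auc([0.5] * 10, [1] * 5 + [0] * 5)
    assert auc == 0.5
    with pytest.raises(ValueError):
        roc_auc([1.0, 2.0], [1, 1])


def test_trapezoid_equals_pair_counting():
    rng = np.random.default_rng(17)
    for _ in range(50):
        n = int(rng.integers(4, 13))
        labels = np.r_[1, 0, (rng.random(n - 2) < 0.5).astype(int)]
        scores = rng.choice(np.arange(6.0), size=n)  # ties likely
        auc, pts = roc_auc(scores, labels)
        trap = np.trapezoid(pts["tpr"], pts["fpr"])
        assert trap == pytest.approx(auc, abs=1e-12)


@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=30),
       st.data())
def test_auc_label_flip_symmetry(scores, data):
    n = len(scores)
    labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
    if not (0 < sum(labels) < n):
        return
    a = pair_count_auc(scores, labels)
    b = pair_count_auc(scores, [1 - l for l in labels])
    assert a + b == pytest.approx(1.0, abs=1e-12)


def test_spectrum_matrix_rows():
    s1 = spectrum_from_counts("a", [2, 0, 0, 0, 0, 0, 0, 0, 2])
    s2 = spectrum_from_counts("b", [2, 0, 0, 0, 0, 0, 0, 0, 2])
    zero = spectrum_from_counts("z", [0] * 9)
    m = spectrum_matrix([s1, s2, zero])
    assert m.loc["a", "m0"] == 0.5 and m.loc["a", "m8"] == 0.5
    assert (m.loc["a"] == m.loc["b"]).all()
    assert m.loc["z"].isna().all()
    assert m.loc["a"].sum() == pytest.approx(1.0)


def test_per_bin_null_pvalues_roughly_uniform():
    """On a null cohort the per-bin Mann-Whitney p-values are calibrated."""
    rng = np.random.default_rng(23)
    pvals = []
    for _ in range(200):
        mat = pd.DataFrame(rng.random((30, 3)), columns=["m0", "m1", "m2"],
                           index=[f"s{i}" for i in range(30)])
        labels = pd.Series([True] * 15 + [False] * 15, index=mat.index)
        pvals.extend(per_bin_tests(mat, labels)["p"])
    from scipy.stats import kstest
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_compare_groups_orientation():
    scores = pd.DataFrame({"sample_id": [f"s{i}" for i in range(8)],
                           "score": [0.9, 0.8, 0.7, 0.6, 0.2, 0.15, 0.1, 0.05]})
    labels = pd.Series([1, 1, 1, 1, 0, 0, 0, 0],
                       index=[f"s{i}" for i in range(8)])
    res = compare_groups(scores, "lesion", labels)
    assert res.auc == 1.0 and res.n_pos == 4 and res.n_neg == 4
    assert res.p_value < 0.05
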