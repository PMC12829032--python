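"""Standard-curve fitting, absolute quantification and relative expression."""

import math

import numpy as np
import pandas as pd
import pytest

from epihap.qpcr import (StandardCurve, absolute_quantity, control_check,
                         fit_standard_curve, quantify_plate, quantify_sample)

PERFECT_SLOPE = -1.0 / math.log10(2.0)  # -3.321928...


def test_fit_exact_line():
    x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    curve = fit_standard_curve(x, PERFECT_SLOPE * x + 30.0, "t")
    assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-12)
    assert curve.intercept == pytest.approx(30.0, abs=1e-12)
    assert curve.r2 == pytest.approx(1.0, abs=1e-12)
    assert curve.efficiency_pct == pytest.approx(100.0, abs=1e-9)


def test_efficiency_closed_form():
    c = StandardCurve("t", -3.0, 30.0, 1.0, 5)
    assert c.efficiency_pct == pytest.approx((10 ** (1 / 3) - 1) * 100, abs=1e-9)


def test_efficiency_decreasing_in_slope_magnitude():
    effs = [StandardCurve("t", s, 30, 1.0, 5).efficiency_pct
            for s in (-2.5, -3.0, -3.32, -3.6, -4.0)]
    assert effs == sorted(effs, reverse=True)


def test_fit_requires_three_levels():
    with pytest.raises(ValueError):
        fit_standard_curve([0.0, 1.0], [30.0, 27.0], "t")
    with pytest.raises(ValueError):
        fit_standard_curve([1.0, 1.0, 1.0], [30.0, 30.1, 29.9], "t")


def test_absolute_quantity():
    c = StandardCurve("t", PERFECT_SLOPE, 30.0, 1.0, 5)
    assert absolute_quantity(30.0, c) == pytest.approx(1.0)
    assert absolute_quantity(26.678072, c) == pytest.approx(10.0, rel=1e-6)
    # one |slope| more cycles = tenfold less template
    q1 = absolute_quantity(25.0, c)
    q2 = absolute_quantity(25.0 + abs(c.slope), c)
    assert q1 / q2 == pytest.approx(10.0, rel=1e-9)


def _curves():
    return {"ONECUT2": StandardCurve("ONECUT2", -3.3, 32.0, 1.0, 5),
            "HPRT1": StandardCurve("HPRT1", -3.3, 28.0, 1.0, 5)}


def _rows(sample, cq_target, cq_ref):
    return pd.DataFrame([
        {"sample": sample, "target": "ONECUT2", "replicate": r, "Cq": ct}
        for r, ct in enumerate(cq_target, 1)
    ] + [
        {"sample": sample, "target": "HPRT1", "replicate": r, "Cq": cr}
        for r, cr in enumerate(cq_ref, 1)
    ])


def test_sample_matching_calibrator_is_one():
    rows = _rows("s1", [30.0, 30.0], [27.0, 27.0])
    cal = quantify_sample(rows, _curves(), calibrator_normalized=1.0)
    res = quantify_sample(rows, _curves(), calibrator_normalized=cal.normalized)
    assert res.relative == pytest.approx(1.0)


def test_reference_cutoff_excludes_sample():
    rows = _rows("s1", [30.0, 30.0], [36.0, 36.0])  # HPRT1 above Cq 35
    res = quantify_sample(rows, _curves(), calibrator_normalized=1.0)
    assert res.excluded and math.isnan(res.relative)
    assert "ref_above_cutoff_rep1" in res.qc_flags


def test_single_failing_replicate_dropped_not_fatal():
    rows = _rows("s1", [30.0, 30.0], [27.0, 36.0])
    res = quantify_sample(rows, _curves(), calibrator_normalized=1.0)
    assert not res.excluded and res.n_replicates == 1


def test_relative_invariant_to_global_input_scaling():
    """Multiplying every input quantity by a constant shifts all Cq equally."""
    curves = _curves()
    rows = _rows("s1", [30.0, 30.2], [27.0, 27.1])
    shift = -3.3  # one log10 more input at slope -3.3
    shifted = rows.assign(Cq=rows["Cq"] + shift)
    a = quantify_sample(rows, curves, 1.0)
    b = quantify_sample(shifted, curves, 1.0)
    assert a.normalized == pytest.approx(b.normalized, rel=1e-9)


def test_replicate_order_irrelevant():
    rows = _rows("s1", [30.0, 31.0], [27.0, 27.5])
    rev = rows.iloc[::-1].reset_index(drop=True)
    a = quantify_sample(rows, _curves(), 1.0)
    b = quantify_sample(rev, _curves(), 1.0)
    assert a.normalized == pytest.approx(b.normalized)


def test_control_check():
    clean = pd.DataFrame([
        {"sample": "ntc", "target": "ONECUT2", "replicate": 1, "Cq": np.nan, "well_type": "ntc"},
        {"sample": "nort", "target": "ONECUT2", "replicate": 1, "Cq": np.nan, "well_type": "no_rt"},
    ])
    assert control_check(clean)["passed"].all()
    contaminated = pd.concat([clean, pd.DataFrame([
        {"sample": "ntc", "target": "HPRT1", "replicate": 1, "Cq": 32.0, "well_type": "ntc"},
    ])], ignore_index=True)
    res = control_check(contaminated).set_index("target")
    assert res.loc["ONECUT2", "passed"] and not res.loc["HPRT1", "passed"]


def test_quantify_plate_requires_calibrator():
    from epihap.simulate import draw_cohort_truth, simulate_qpcr_plate
    _, truth, _ = draw_cohort_truth(2, 2, seed=0)
    plate = simulate_qpcr_plate(truth, noise_sd=0.0, seed=0)
    with pytest.raises(ValueError):
        quantify_plate(plate, calibrator_id="missing")


def test_cq_first_order_close_to_quantities_first():
    from epihap.simulate import draw_cohort_truth, simulate_qpcr_plate
    _, truth, _ = draw_cohort_truth(3, 3, seed=4)
    plate = simulate_qpcr_plate(truth, noise_sd=0.0, seed=4)
    a, _ = quantify_plate(plate, order="quantities_first")
    b, _ = quantify_plate(plate, order="cq_first")
    m = a.merge(b, on="sample_id", suffixes=("_q", "_c"))
    assert np.allclose(m["relative_q"], m["relative_c"], rtol=1e-9)
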