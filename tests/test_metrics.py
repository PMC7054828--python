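"""Test characteristics: 2x2 tabulation, proportions, Wald intervals."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oacphen.errors import LinkageError, UndefinedMetricError
from oacphen.metrics import (
    Counts2x2,
    evaluate,
    proportion_ci,
    round_half_up,
    round_rate,
    tabulate,
)


@pytest.mark.parametrize(
    "counts, sens, spec, ppv, npv, rate",
    [
        # rows of the reported validation table, frozen as regression anchors
        (Counts2x2(335, 1466, 146, 68), 0.831, 0.909, 0.696, 0.956, 23.9),
        (Counts2x2(198, 1576, 36, 205), 0.491, 0.978, 0.846, 0.885, 11.6),
        (Counts2x2(194, 1524, 35, 197), 0.496, 0.978, 0.847, 0.886, 11.7),
        (Counts2x2(1, 1, 0, 0), 1.0, 1.0, 1.0, 1.0, 50.0),
    ],
)
def test_evaluate_point_estimates(counts, sens, spec, ppv, npv, rate):
    row = evaluate(counts).to_row()
    assert row["sens"] == sens
    assert row["spec"] == spec
    assert row["ppv"] == ppv
    assert row["npv"] == npv
    assert row["rate_percent"] == rate


def test_wald_interval_specificity_row():
    est = proportion_ci(1466, 1612)
    assert est.rounded(3) == (0.909, 0.895, 0.923)


def test_wald_interval_high_precision_anchor():
    # frozen from a 50-digit Decimal recomputation of p +/- 1.96*sqrt(p(1-p)/n)
    est = proportion_ci(335, 403)
    assert est.point == pytest.approx(0.83126550868486352, abs=1e-12)
    assert est.ci_low == pytest.approx(0.79469968489969297, abs=1e-12)
    assert est.ci_high == pytest.approx(0.86783133247003408, abs=1e-12)


def test_wald_interval_clipped_at_zero():
    est = proportion_ci(0, 50)
    assert est.point == 0.0
    assert est.ci_low == 0.0  # Wald interval degenerates at p = 0
    assert est.ci_high == 0.0


def test_zero_denominator_raises():
    with pytest.raises(UndefinedMetricError):
        proportion_ci(0, 0)


def test_evaluate_absent_metric_does_not_mask_others():
    res = evaluate(Counts2x2(tp=0, tn=5, fp=2, fn=0))
    assert res.sensitivity is None  # no reference positives
    assert res.specificity is not None
    assert res.npv is not None
    assert res.rate_percent == pytest.approx(100 * 2 / 7)


def test_wald_matches_statsmodels_normal_interval():
    """Independent cross-check of the interval arithmetic."""
    sm = pytest.importorskip("statsmodels.stats.proportion")
    for k, n in [(1466, 1612), (335, 403), (98, 403), (15, 1612), (1, 10)]:
        lo, hi = sm.proportion_confint(k, n, alpha=0.05, method="normal")
        est = proportion_ci(k, n)
        assert est.ci_low == pytest.approx(lo, abs=1e-4)
        assert est.ci_high == pytest.approx(hi, abs=1e-4)


def _labels(d):
    return pd.DataFrame(
        {"patient_id": list(d), "positive": [v[0] for v in d.values()],
         "reference_label": [v[1] for v in d.values()]}
    )


def test_tabulate_enumeration_fixture():
    d = {  # 2 TP, 2 TN, 1 FP, 1 FN by construction
        "a": (True, True), "b": (True, True), "c": (False, False),
        "d": (False, False), "e": (True, False), "f": (False, True),
    }
    df = _labels(d)
    c = tabulate(df[["patient_id", "positive"]], df[["patient_id", "reference_label"]])
    assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 1, 1)
    assert c.n == 6


def test_tabulate_agreement_and_complement():
    ref = pd.DataFrame({"patient_id": list("abcd"),
                        "reference_label": [True, True, False, False]})
    same = ref.rename(columns={"reference_label": "positive"})
    c = tabulate(same, ref)
    assert (c.fp, c.fn) == (0, 0)
    flipped = same.assign(positive=~same["positive"])
    c = tabulate(flipped, ref)
    assert (c.tp, c.tn) == (0, 0)


def test_tabulate_mismatched_ids_raises():
    ref = pd.DataFrame({"patient_id": ["a", "b"], "reference_label": [True, False]})
    pred = pd.DataFrame({"patient_id": ["a", "c"], "positive": [True, False]})
    with pytest.raises(LinkageError):
        tabulate(pred, ref)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.tuples(*[st.integers(0, 500)] * 4))
def test_transposing_roles_swaps_sens_ppv_and_spec_npv(cells):
    """Swapping predicted and reference labels transposes the 2x2."""
    c = Counts2x2(*cells)
    a, b = evaluate(c), evaluate(c.transpose())

    def pt(est):
        return None if est is None else est.point

    assert pt(a.sensitivity) == pt(b.ppv)
    assert pt(a.ppv) == pt(b.sensitivity)
    assert pt(a.specificity) == pt(b.npv)
    assert pt(a.npv) == pt(b.specificity)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.tuples(*[st.integers(0, 500)] * 4))
def test_rate_is_positive_share_of_classified(cells):
    c = Counts2x2(*cells)
    res = evaluate(c)
    if c.n == 0:
        assert res.rate_percent is None
    else:
        assert res.rate_percent == pytest.approx(100 * (c.tp + c.fp) / c.n)


def test_display_rounding_is_half_up():
    assert round_half_up(0.8345, 3) == 0.835
    assert round_half_up(0.8344999, 3) == 0.834
    # the two-stage rate rule: 13.6476 -> 13.65 -> 13.7
    assert round_rate(13.6476) == 13.7
    assert round_rate(13.6449) == 13.6
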