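"""Diagnostic-accuracy statistics against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from pancyst.stats import (
    ConfusionTable,
    binary_auc,
    confusion_from_rates,
    delong_paired_test,
    fisher_exact_2x2,
    mcnemar_exact,
    metrics,
    round_half_up,
    wilson_ci,
)

Z95 = sps.norm.ppf(0.975)  # 1.959964 to printed precision


def wilson_oracle(k, n, z=Z95):
    """Closed-form Wilson score interval, written out independently."""
    p = k / n
    center = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / (1 + z * z / n)
    return max(0.0, center - half), min(1.0, center + half)


def fisher_oracle(a, b, c, d):
    """Brute-force two-sided Fisher: sum hypergeometric probabilities of all
    tables with the observed margins that are no more probable."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    rv = sps.hypergeom(n, c1, r1)
    p_obs = rv.pmf(a)
    total = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        p = rv.pmf(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


# ---------------------------------------------------------------------------
# Wilson intervals

@pytest.mark.parametrize("k,n", [(0, 10), (8, 10), (10, 10), (3, 7), (50, 60), (176, 186)])
def test_wilson_matches_closed_form(k, n):
    lo, hi = wilson_ci(k, n)
    olo, ohi = wilson_oracle(k, n)
    assert lo == pytest.approx(olo, abs=1e-9)
    assert hi == pytest.approx(ohi, abs=1e-9)


def test_wilson_boundaries_and_example():
    assert wilson_ci(0, 10)[0] == 0.0
    assert wilson_ci(10, 10)[1] == 1.0
    lo, hi = wilson_ci(8, 10)
    assert (round(lo, 3), round(hi, 3)) == (0.490, 0.943)


def test_wilson_contains_point_and_width_shrinks_with_n():
    widths = []
    for n in (10, 40, 160, 640):
        k = int(0.8 * n)
        lo, hi = wilson_ci(k, n)
        assert lo <= k / n <= hi
        widths.append(hi - lo)
    assert widths == sorted(widths, reverse=True)


def test_wilson_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        wilson_ci(0, 0)
    with pytest.raises(ValueError):
        wilson_ci(5, 3)


# ---------------------------------------------------------------------------
# metrics and AUC

def test_metrics_published_mucinous_table():
    m = metrics(ConfusionTable(tp=176, fp=2, fn=10, tn=53))
    assert (m.sensitivity.percent, m.specificity.percent) == (94.6, 96.4)
    assert (m.ppv.percent, m.npv.percent, m.accuracy.percent) == (98.9, 84.1, 95.0)
    assert round(m.auc, 3) == 0.955


def test_metrics_published_advanced_neoplasia_table():
    m = metrics(ConfusionTable(tp=84, fp=3, fn=13, tn=141))
    assert (m.sensitivity.percent, m.specificity.percent) == (86.6, 97.9)
    assert (m.npv.percent, m.ppv.percent, m.accuracy.percent) == (91.6, 96.6, 93.4)
    assert round(m.auc, 3) == 0.923


def test_perfect_classifier_metrics_all_one():
    m = metrics(ConfusionTable(1, 0, 0, 1))
    for name in ("sensitivity", "specificity", "npv", "ppv", "accuracy"):
        assert getattr(m, name).point == 1.0
    assert m.auc == 1.0


def test_zero_denominator_metric_absent_not_zero():
    with pytest.warns(UserWarning):
        m = metrics(ConfusionTable(tp=0, fp=0, fn=0, tn=5))
    assert m.sensitivity is None and m.ppv is None
    assert m.specificity.point == 1.0
    assert m.auc is None


def test_auc_identity_on_random_tables():
    rng = np.random.default_rng(11)
    for _ in range(200):
        tp, fp, fn, tn = (int(x) for x in rng.integers(0, 60, size=4))
        t = ConfusionTable(tp + 1, fp, fn, tn + 1)  # keep both classes non-empty
        sens = t.tp / t.n_positive
        spec = t.tn / t.n_negative
        assert binary_auc(t) == pytest.approx((sens + spec) / 2, abs=1e-12)


def test_auc_half_for_chance_level_table():
    assert binary_auc(ConfusionTable(tp=30, fp=30, fn=70, tn=70)) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# paired and exact tests

@pytest.mark.parametrize(
    "b, c, expected",
    [(6, 0, 0.03125), (12, 2, 0.0129), (7, 0, 0.015625), (0, 0, 1.0), (12, 0, 0.00049)],
)
def test_mcnemar_exact_values(b, c, expected):
    assert mcnemar_exact(b, c) == pytest.approx(expected, rel=5e-2)


def test_mcnemar_symmetric_and_bounded_and_matches_statsmodels():
    from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

    for b, c in itertools.product(range(0, 15), repeat=2):
        p = mcnemar_exact(b, c)
        assert p == mcnemar_exact(c, b)
        assert 0.0 < p <= 1.0
        sm_p = sm_mcnemar([[0, b], [c, 0]], exact=True).pvalue
        assert p == pytest.approx(float(sm_p), abs=1e-12)


def test_fisher_published_10q_table():
    p = fisher_exact_2x2(3, 0, 3, 25)
    assert round(p, 3) == 0.004
    assert p == pytest.approx(0.00445, abs=5e-5)


def test_fisher_symmetric_table_is_one():
    assert fisher_exact_2x2(1, 1, 1, 1) == pytest.approx(1.0)


def test_fisher_equals_enumeration_oracle_on_small_tables():
    rng = np.random.default_rng(5)
    tables = [(3, 0, 3, 25), (0, 5, 5, 0), (10, 10, 10, 10), (1, 0, 0, 1)]
    tables += [tuple(int(x) for x in rng.integers(0, 25, size=4)) for _ in range(60)]
    for a, b, c, d in tables:
        if a + b + c + d == 0:
            continue
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-9, abs=1e-12
        )


# ---------------------------------------------------------------------------
# table reconstruction

@pytest.mark.parametrize(
    "n_pos, n_neg, sens, spec, expected",
    [
        (186, 55, 0.946, 0.964, (176, 2, 10, 53)),
        (97, 144, 0.866, 0.979, (84, 3, 13, 141)),
        (10, 10, 1.0, 1.0, (10, 0, 0, 10)),
    ],
)
def test_confusion_from_rates(n_pos, n_neg, sens, spec, expected):
    assert confusion_from_rates(n_pos, n_neg, sens, spec).as_tuple() == expected


def test_round_half_up_breaks_ties_upward():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(94.65, 1) == 94.7
    assert round_half_up(2.5) == 3.0


def test_reconstruction_consistency_with_published_secondary_metrics():
    """Published NPV/PPV/accuracy/AUC follow from the reconstructed tables."""
    cases = [
        ((186, 55, 0.946, 0.964), dict(npv=84.1, ppv=98.9, accuracy=95.0, auc=0.955)),
        ((97, 144, 0.866, 0.979), dict(npv=91.6, ppv=96.6, accuracy=93.4, auc=0.923)),
        ((186, 55, 0.882, 1.0), dict(accuracy=90.9, auc=0.941)),
    ]
    for args, expected in cases:
        m = metrics(confusion_from_rates(*args))
        for name, value in expected.items():
            if name == "auc":
                assert round(m.auc, 3) == value
            else:
                assert getattr(m, name).percent == value


# ---------------------------------------------------------------------------
# DeLong paired comparison (no published anchor; properties only)

def test_delong_binary_auc_matches_table_auc():
    rng = np.random.default_rng(3)
    ref = rng.random(120) < 0.4
    a = np.where(ref, rng.random(120) < 0.9, rng.random(120) < 0.1)
    b = np.where(ref, rng.random(120) < 0.7, rng.random(120) < 0.2)
    out = delong_paired_test(a, b, ref)
    t = ConfusionTable(
        tp=int((a & ref).sum()), fp=int((a & ~ref).sum()),
        fn=int((~a & ref).sum()), tn=int((~a & ~ref).sum()),
    )
    assert out["auc_a"] == pytest.approx(binary_auc(t), abs=1e-12)
    assert 0.0 <= out["p"] <= 1.0


def test_delong_identical_tests_give_p_one():
    rng = np.random.default_rng(4)
    ref = rng.random(80) < 0.5
    a = rng.random(80) < 0.6
    out = delong_paired_test(a, a.copy(), ref)
    assert out["z"] == 0.0 and out["p"] == pytest.approx(1.0)
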