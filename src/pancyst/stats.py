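"""Diagnostic-accuracy statistics.

2x2 confusion-table metrics (sensitivity, specificity, NPV, PPV, accuracy)
with 95% Wilson score intervals; single-threshold ROC AUC by the
trapezoidal rule, which for one binary test reduces to
(sensitivity + specificity) / 2; the exact (binomial) McNemar test for
paired designs; Fisher's exact test; confusion-table reconstruction from
published rates; and cohort evaluation with complete-case handling of
unknown modality results.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .classifier import ClassifierCall, CystType, MetastaticRisk
from .modalities import ModalityCall
from .models import HistologicType, SpecimenProfile

__all__ = [
    "ConfusionTable",
    "MetricWithCI",
    "DiagnosticMetrics",
    "wilson_ci",
    "metrics",
    "binary_auc",
    "mcnemar_exact",
    "fisher_exact_2x2",
    "confusion_from_rates",
    "evaluate",
    "paired_discordance",
    "delong_paired_test",
    "round_half_up",
    "CONDITIONS",
]

CONDITIONS = ("mucinous", "advanced_neoplasia", "serous", "neuroendocrine", "metastasis")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention used for reported percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 counts of a binary test against a reference condition."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn

    def as_tuple(self) -> Tuple[int, int, int, int]:
        return (self.tp, self.fp, self.fn, self.tn)


@dataclass(frozen=True)
class MetricWithCI:
    point: float
    ci_low: float
    ci_high: float
    successes: int
    trials: int

    @property
    def percent(self) -> float:
        """Point estimate as a percentage, rounded half-up to one decimal."""
        return round_half_up(100.0 * self.point, 1)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: Optional[MetricWithCI]
    specificity: Optional[MetricWithCI]
    npv: Optional[MetricWithCI]
    ppv: Optional[MetricWithCI]
    accuracy: Optional[MetricWithCI]
    auc: Optional[float]

    def to_dict(self) -> dict:
        out: dict = {}
        for name in ("sensitivity", "specificity", "npv", "ppv", "accuracy"):
            m = getattr(self, name)
            out[name] = None if m is None else {
                "point": m.point, "percent": m.percent,
                "ci_low": m.ci_low, "ci_high": m.ci_high,
                "successes": m.successes, "trials": m.trials,
            }
        out["auc"] = self.auc
        return out


def wilson_ci(successes: int, trials: int, confidence: float = 0.95) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion, clipped to [0, 1]."""
    if trials < 1:
        raise ValueError("wilson_ci requires trials >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must be in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - confidence, method="wilson")
    # the Wilson bounds are exactly 0/1 at the boundaries; snap float error
    lo = 0.0 if successes == 0 else max(0.0, float(lo))
    hi = 1.0 if successes == trials else min(1.0, float(hi))
    return (lo, hi)


def _metric(successes: int, trials: int, confidence: float) -> Optional[MetricWithCI]:
    if trials == 0:
        warnings.warn("metric denominator is zero; reporting as absent", stacklevel=3)
        return None
    lo, hi = wilson_ci(successes, trials, confidence)
    return MetricWithCI(successes / trials, lo, hi, successes, trials)


def metrics(t: ConfusionTable, confidence: float = 0.95) -> DiagnosticMetrics:
    """All five accuracy statistics with Wilson CIs, plus the binary AUC.

    Metrics with an empty denominator (and the AUC when either class is
    empty) are reported as ``None`` with a warning, never as zero.
    """
    if t.total == 0:
        raise ValueError("empty confusion table")
    auc = None
    if t.n_positive > 0 and t.n_negative > 0:
        auc = binary_auc(t)
    return DiagnosticMetrics(
        sensitivity=_metric(t.tp, t.n_positive, confidence),
        specificity=_metric(t.tn, t.n_negative, confidence),
        npv=_metric(t.tn, t.tn + t.fn, confidence),
        ppv=_metric(t.tp, t.tp + t.fp, confidence),
        accuracy=_metric(t.tp + t.tn, t.total, confidence),
        auc=auc,
    )


def binary_auc(t: ConfusionTable) -> float:
    """Trapezoidal area under the three-point ROC {(0,0), (1-spec, sens), (1,1)}
    of a single-threshold binary test; equals (sensitivity + specificity)/2."""
    if t.n_positive == 0 or t.n_negative == 0:
        raise ValueError("binary_auc requires both classes non-empty")
    sens = t.tp / t.n_positive
    spec = t.tn / t.n_negative
    fpr = np.array([0.0, 1.0 - spec, 1.0])
    tpr = np.array([0.0, sens, 1.0])
    return float(np.trapezoid(tpr, fpr))


def mcnemar_exact(b: int, c: int) -> float:
    """Exact two-sided McNemar p-value from the discordant-pair counts.

    ``b`` and ``c`` count specimens where exactly one of the two paired
    tests is correct. Under H0 the discordances are Binomial(b+c, 1/2);
    p = 2 * P(X <= min(b, c)), capped at 1. Symmetric in (b, c).
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    m = b + c
    if m == 0:
        return 1.0
    return min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), m, 0.5)))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the table [[a, b], [c, d]]
    (sum of hypergeometric probabilities <= the observed table's)."""
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def confusion_from_rates(
    n_positive: int, n_negative: int, sensitivity: float, specificity: float
) -> ConfusionTable:
    """Reconstruct the integer 2x2 table behind published rates
    (tp = round-half-up of sensitivity * n_positive, etc.)."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("rates must be in [0, 1]")
    tp = int(round_half_up(sensitivity * n_positive))
    tn = int(round_half_up(specificity * n_negative))
    return ConfusionTable(tp=tp, fp=n_negative - tn, fn=n_positive - tp, tn=tn)


# ---------------------------------------------------------------------------
# cohort evaluation

def _reference_state(s: SpecimenProfile, condition: str) -> Optional[bool]:
    r = s.reference
    if r is None:
        return None
    if condition == "mucinous":
        return r.is_mucinous
    if condition == "advanced_neoplasia":
        return r.is_advanced_neoplasia
    if condition == "serous":
        return r.histologic_type is HistologicType.SCA
    if condition == "neuroendocrine":
        return r.is_neuroendocrine_type
    if condition == "metastasis":
        if r.histologic_type is not HistologicType.CPANNET:
            return None  # metastasis analysis is restricted to cystic PanNETs
        return r.distant_metastasis  # None when follow-up is unavailable
    raise ValueError(f"unknown condition {condition!r}")


def _call_state(call, condition: str) -> Optional[bool]:
    if isinstance(call, ModalityCall):
        return call.result
    if isinstance(call, ClassifierCall):
        if condition == "mucinous":
            return call.mucinous_positive
        if condition == "advanced_neoplasia":
            return call.advanced_neoplasia_positive
        if condition == "serous":
            return call.cyst_type is CystType.SEROUS
        if condition == "neuroendocrine":
            return call.cyst_type is CystType.NEUROENDOCRINE
        if condition == "metastasis":
            if call.metastatic_risk is MetastaticRisk.NOT_APPLICABLE:
                return None
            return call.metastatic_risk in (MetastaticRisk.ELEVATED, MetastaticRisk.HIGH)
        raise ValueError(f"unknown condition {condition!r}")
    raise TypeError(f"unsupported call type {type(call).__name__}")


def evaluate(
    calls: Sequence[Union[ModalityCall, ClassifierCall]],
    specimens: Sequence[SpecimenProfile],
    condition: str,
    confidence: float = 0.95,
) -> Tuple[ConfusionTable, DiagnosticMetrics]:
    """Build the 2x2 table of ``calls`` against the reference ``condition``
    and compute metrics. Complete-case: specimens with an unknown call or an
    unavailable reference state are excluded from the table."""
    by_id = {c.specimen_id: c for c in calls}
    tp = fp = fn = tn = 0
    for s in specimens:
        ref = _reference_state(s, condition)
        call = by_id.get(s.specimen_id)
        if ref is None or call is None:
            continue
        res = _call_state(call, condition)
        if res is None:
            continue
        if ref and res:
            tp += 1
        elif ref and not res:
            fn += 1
        elif res:
            fp += 1
        else:
            tn += 1
    table = ConfusionTable(tp=tp, fp=fp, fn=fn, tn=tn)
    if table.total == 0:
        raise ValueError(f"no evaluable specimens for condition {condition!r}")
    return table, metrics(table, confidence)


def paired_discordance(
    calls_a: Sequence,
    calls_b: Sequence,
    specimens: Sequence[SpecimenProfile],
    condition: str,
    restrict: str = "all",
) -> Tuple[int, int]:
    """Discordant-pair counts (b, c) for an exact McNemar comparison of two
    tests on the same specimens. ``b`` counts specimens where test A is
    correct and B wrong; ``c`` the reverse. ``restrict`` limits the paired
    universe: ``all`` (accuracy comparisons), ``reference_positive``
    (sensitivity), ``reference_negative`` (specificity), or
    ``called_positive_both``/``called_negative_both`` — predictive-value
    comparisons interpreted as correctness within the called class."""
    a_by_id = {c.specimen_id: c for c in calls_a}
    b_by_id = {c.specimen_id: c for c in calls_b}
    b_count = c_count = 0
    for s in specimens:
        ref = _reference_state(s, condition)
        ca, cb = a_by_id.get(s.specimen_id), b_by_id.get(s.specimen_id)
        if ref is None or ca is None or cb is None:
            continue
        ra, rb = _call_state(ca, condition), _call_state(cb, condition)
        if ra is None or rb is None:
            continue
        if restrict == "reference_positive" and not ref:
            continue
        if restrict == "reference_negative" and ref:
            continue
        if restrict == "called_positive_both" and not (ra and rb):
            continue
        if restrict == "called_negative_both" and (ra or rb):
            continue
        ok_a, ok_b = ra == ref, rb == ref
        if ok_a and not ok_b:
            b_count += 1
        elif ok_b and not ok_a:
            c_count += 1
    return b_count, c_count


def delong_paired_test(
    results_a: Sequence[bool],
    results_b: Sequence[bool],
    reference: Sequence[bool],
) -> Dict[str, float]:
    """DeLong's paired test for the difference of two correlated AUCs,
    specialised to binary tests evaluated on the same specimens.

    Uses placement values: for case i, V10_i = mean over controls of the
    Mann-Whitney kernel; for control j, V01_j likewise over cases. The
    variance of (AUC_a - AUC_b) follows from the empirical covariance of
    the paired placement vectors. Returns auc_a, auc_b, z, p.
    """
    y = np.asarray(reference, dtype=bool)
    scores = [np.asarray(r, dtype=float) for r in (results_a, results_b)]
    if not (0 < y.sum() < len(y)):
        raise ValueError("need both cases and controls")
    cases = [s[y] for s in scores]
    controls = [s[~y] for s in scores]
    m, n = len(cases[0]), len(controls[0])
    aucs, v10, v01 = [], [], []
    for cs, ct in zip(cases, controls):
        kernel = (cs[:, None] > ct[None, :]) + 0.5 * (cs[:, None] == ct[None, :])
        v10.append(kernel.mean(axis=1))
        v01.append(kernel.mean(axis=0))
        aucs.append(kernel.mean())
    s10 = np.cov(np.vstack(v10))
    s01 = np.cov(np.vstack(v01))
    cov = s10 / m + s01 / n
    contrast = np.array([1.0, -1.0])
    var = float(contrast @ cov @ contrast)
    diff = aucs[0] - aucs[1]
    if var <= 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 2.0 * float(sps.norm.sf(abs(z))) if math.isfinite(z) else 0.0
    return {"auc_a": float(aucs[0]), "auc_b": float(aucs[1]), "z": float(z), "p": p}
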