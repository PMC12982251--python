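"""Guideline comparator definitions and modality combination semantics."""

import itertools

import pytest

from pancyst.modalities import (
    ModalityCall,
    combine,
    high_risk_stigmata,
    malignant_cytopathology,
    modality_calls,
    worrisome_features,
)
from pancyst.models import ClinicalFeatures, Cytopathology, SpecimenProfile


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(cyst_size_cm=3.2), True),            # size >= 3.0 cm
        (dict(cyst_size_cm=2.9), False),
        (dict(main_duct_mm=7.0), True),            # duct 5-9 mm
        (dict(main_duct_mm=5.0), True),
        (dict(main_duct_mm=9.0), True),
        (dict(cyst_size_cm=2.0, main_duct_mm=3.0), False),
        (dict(mural_nodule_present=True), True),   # nonenhancing nodule
        (dict(mural_nodule_present=True, mural_nodule_enhancing=True), False),
        (dict(growth_mm_per_year=5.0), False),     # growth is strict > 5
        (dict(growth_mm_per_year=5.1), True),
        (dict(ca19_9_elevated=True), True),
        (dict(pancreatitis_attributable=True), True),
    ],
)
def test_worrisome_features(kwargs, expected):
    assert worrisome_features(ClinicalFeatures(**kwargs)) is expected


@pytest.mark.parametrize(
    "kwargs, expected",
    [
        (dict(main_duct_mm=12.0), True),           # duct >= 10 mm
        (dict(main_duct_mm=9.9), False),
        (dict(mural_nodule_enhancing=True, mural_nodule_size_mm=6.0), True),
        (dict(mural_nodule_enhancing=True, mural_nodule_size_mm=3.0), False),
        (dict(obstructive_jaundice_head_cyst=True), True),
        (dict(cytopathology=Cytopathology.ADENOCARCINOMA), True),
        (dict(cytopathology=Cytopathology.ATYPICAL), False),
    ],
)
def test_high_risk_stigmata(kwargs, expected):
    assert high_risk_stigmata(ClinicalFeatures(**kwargs)) is expected


@pytest.mark.parametrize(
    "cyto, expected",
    [
        (Cytopathology.SUSPICIOUS_FOR_ADENOCARCINOMA, True),
        (Cytopathology.ADENOCARCINOMA, True),
        (Cytopathology.ATYPICAL, False),
        (Cytopathology.NEUROENDOCRINE, False),
        (None, None),
    ],
)
def test_malignant_cytopathology(cyto, expected):
    assert malignant_cytopathology(ClinicalFeatures(cytopathology=cyto)) is expected


def test_missing_clinical_record_is_unknown():
    assert worrisome_features(None) is None
    assert high_risk_stigmata(None) is None


def test_comparators_are_monotone_in_contributing_flags():
    base = ClinicalFeatures(cyst_size_cm=3.5)
    assert worrisome_features(base) is True
    for flag in ("cyst_wall_thickened_or_enhancing", "lymphadenopathy",
                 "ca19_9_elevated", "pancreatitis_attributable"):
        from dataclasses import replace

        assert worrisome_features(replace(base, **{flag: True})) is True


def _mc(result, sid="X", modality="viscosity"):
    return [ModalityCall(sid, modality, result)]


@pytest.mark.parametrize(
    "a, b, expected",
    [
        (True, False, True),
        (False, True, True),
        (False, False, False),
        (None, False, False),  # unknown + measured negative -> negative
        (None, True, True),
        (None, None, None),
    ],
)
def test_combine_either_positive(a, b, expected):
    [out] = combine(_mc(a), _mc(b))
    assert out.result is expected


def test_combine_commutative_associative_idempotent():
    states = [True, False, None]
    for a, b, c in itertools.product(states, repeat=3):
        ab = combine(_mc(a), _mc(b))
        ba = combine(_mc(b), _mc(a))
        assert ab[0].result == ba[0].result
        left = combine(ab, _mc(c))
        right = combine(_mc(a), combine(_mc(b), _mc(c)))
        assert left[0].result == right[0].result
        assert combine(_mc(a), _mc(a))[0].result == a


def test_combine_rejects_mismatched_specimens():
    with pytest.raises(ValueError, match="specimen sets differ"):
        combine(_mc(True, sid="A"), _mc(True, sid="B"))


def test_modality_calls_emit_unknown_only_when_unmeasured(cohort):
    for call in modality_calls(cohort, "viscosity"):
        spec = next(s for s in cohort if s.specimen_id == call.specimen_id)
        measured = spec.clinical is not None and spec.clinical.fluid_viscosity_increased is not None
        assert (call.result is None) == (not measured)


def test_combined_sensitivity_dominates_components(cohort, gc_calls):
    """OR-combination can only add positives, so its sensitivity is at least
    each component's on the same evaluation set."""
    from pancyst.stats import evaluate

    gc_as_modality = [
        ModalityCall(c.specimen_id, "gc", c.mucinous_positive) for c in gc_calls
    ]
    for modality in ("viscosity", "cea"):
        comp = modality_calls(cohort, modality)
        both = combine(gc_as_modality, comp)
        # restrict every arm to the combined evaluable set for a fair comparison
        _, m_comb = evaluate(both, cohort, "mucinous")
        _, m_gc = evaluate(gc_as_modality, cohort, "mucinous")
        _, m_single = evaluate(comp, cohort, "mucinous")
        assert m_comb.sensitivity.point >= m_gc.sensitivity.point - 1e-12
        assert m_comb.sensitivity.point >= m_single.sensitivity.point - 1e-12
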