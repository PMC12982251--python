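"""Synthetic cohort generator and the deterministic reconstruction cohort."""

import numpy as np
import pytest

from pancyst import Ruleset, classify_cohort, evaluate
from pancyst.classifier import Mode
from pancyst.cohort import CohortSpec, default_cohort_spec, fixture_cohort, generate_cohort
from pancyst.models import MUCINOUS_TYPES, HistologicType


def test_default_spec_validates_and_matches_study_sizes():
    spec = default_cohort_spec()
    assert spec.n_total == 241
    assert spec.n_mucinous == 186
    assert sum(spec.advanced_counts.values()) == 97
    assert spec.diagnosis_counts[HistologicType.IPMN] == 164
    assert spec.diagnosis_counts[HistologicType.MCN] == 18


def test_expected_kras_frequency_near_58_percent():
    spec = default_cohort_spec()
    assert round(spec.expected_gene_fraction("KRAS") * 241) == 140
    assert spec.expected_gene_fraction("GNAS") == pytest.approx(0.37, abs=0.005)


def test_invalid_spec_rejected():
    spec = default_cohort_spec()
    from dataclasses import replace

    with pytest.raises(ValueError):
        replace(spec, p_dna_driver=1.5).validate()
    with pytest.raises(ValueError):
        replace(spec, n_pannet_metastatic=99).validate()


def test_generator_is_deterministic_under_seed():
    assert generate_cohort(seed=13) == generate_cohort(seed=13)
    assert generate_cohort(seed=13) != generate_cohort(seed=14)


def test_generated_cohort_composition_and_references():
    cohort = generate_cohort(seed=1)
    assert len(cohort) == 241
    assert all(s.reference is not None for s in cohort)
    mucinous = [s for s in cohort if s.reference.is_mucinous]
    assert len(mucinous) == 186
    assert sum(s.reference.is_advanced_neoplasia for s in cohort) == 97


@pytest.mark.parametrize("seed", range(4))
def test_exclusivity_constraints_hold_in_every_specimen(seed):
    for s in generate_cohort(seed=seed):
        genes = {v.gene for v in s.variants}
        mucinous = s.reference.histologic_type in MUCINOUS_TYPES
        if genes & {"KRAS", "GNAS", "BRAF"}:
            assert mucinous
            assert not genes & {"VHL", "MEN1"}
        if s.chromosomal_alterations:
            assert (s.reference.is_advanced_neoplasia
                    or s.reference.histologic_type is HistologicType.CPANNET)
        if s.expression is not None and s.expression.evaluable:
            if s.expression.chga_overexpressed:
                assert not mucinous
            if s.expression.ceacam5_geu > 200:
                assert s.expression.krt7_expressed or s.expression.krt20_expressed


def test_generated_marker_frequencies_within_binomial_99ci():
    """Pooled marker counts over 20 seeds stay inside the exact binomial
    99% interval around the spec's own expected frequencies."""
    spec = default_cohort_spec()
    genes = ("KRAS", "GNAS", "VHL", "MEN1", "TP53", "RNF43", "CDKN2A")
    counts = dict.fromkeys(genes, 0)
    n = 0
    for seed in range(20):
        cohort = generate_cohort(spec, seed=seed)
        n += len(cohort)
        for s in cohort:
            present = {v.gene for v in s.variants}
            for g in genes:
                counts[g] += g in present
    from scipy.stats import binom

    for g in genes:
        p = spec.expected_gene_fraction(g)
        lo, hi = binom.ppf(0.005, n, p), binom.ppf(0.995, n, p)
        assert lo <= counts[g] <= hi, f"{g}: {counts[g]} outside [{lo}, {hi}]"


def test_fixture_is_deterministic_and_valid():
    a, b = fixture_cohort(), fixture_cohort()
    assert a == b
    assert len(a) == 241
    ids = {s.specimen_id for s in a}
    assert len(ids) == 241


def test_fixture_composition_matches_study():
    cohort = fixture_cohort()
    by_type = {}
    for s in cohort:
        by_type[s.reference.histologic_type] = by_type.get(s.reference.histologic_type, 0) + 1
    assert by_type[HistologicType.IPMN] == 164
    assert by_type[HistologicType.MCN] == 18
    assert by_type[HistologicType.IOPN] == 3
    assert by_type[HistologicType.CPANNET] == 34
    assert by_type[HistologicType.SCA] == 12
    assert sum(s.reference.is_advanced_neoplasia for s in cohort) == 97
    evaluable = [s for s in cohort if s.expression is not None and s.expression.evaluable]
    assert len(evaluable) == 215
    elevated = [s for s in evaluable if s.expression.ceacam5_geu > 200]
    assert len(elevated) == 145
    followup = [s for s in cohort
                if s.reference.histologic_type is HistologicType.CPANNET
                and s.reference.distant_metastasis is not None]
    assert len(followup) == 31
    assert sum(s.reference.distant_metastasis for s in followup) == 3


def test_fixture_reproduces_all_confusion_tables(cohort, gc_calls, legacy_calls,
                                                 extended_calls):
    from pancyst.modalities import modality_calls

    expected = {
        ("mucinous", "gc"): (176, 2, 10, 53),
        ("mucinous", "legacy"): (164, 0, 22, 55),
        ("advanced_neoplasia", "gc"): (84, 3, 13, 141),
        ("advanced_neoplasia", "legacy"): (78, 3, 19, 141),
        ("advanced_neoplasia", "extended"): (91, 7, 6, 137),
        ("serous", "gc"): (10, 0, 2, 229),
        ("neuroendocrine", "gc"): (35, 0, 1, 205),
    }
    call_sets = {"gc": gc_calls, "legacy": legacy_calls, "extended": extended_calls}
    for (condition, mode), table in expected.items():
        t, _ = evaluate(call_sets[mode], cohort, condition)
        assert t.as_tuple() == table, (condition, mode)
    markers = {
        "chromosomal_ge3": (3, 10, 0, 18),
        "loh_10q": (3, 3, 0, 25),
        "size_gt_2cm": (2, 10, 1, 18),
    }
    for marker, table in markers.items():
        t, _ = evaluate(modality_calls(cohort, marker), cohort, "metastasis")
        assert t.as_tuple() == table, marker
    t, _ = evaluate(modality_calls(cohort, "cytopathology_neuroendocrine"),
                    cohort, "neuroendocrine")
    assert t.as_tuple() == (6, 0, 30, 205)


def test_fixture_legacy_mucinous_calls_nest_in_gc_calls(gc_calls, legacy_calls):
    gc_pos = {c.specimen_id for c in gc_calls if c.mucinous_positive}
    legacy_pos = {c.specimen_id for c in legacy_calls if c.mucinous_positive}
    assert legacy_pos <= gc_pos
    assert len(gc_pos - legacy_pos) == 14  # 12 mucinous rescues + 2 expression FPs
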