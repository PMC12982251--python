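"""Rule engine behaviour: precedence, risk rules, legacy masking, invariants."""

import numpy as np
import pytest

from conftest import random_profile
from pancyst.classifier import (
    ClassifierCall,
    CystType,
    MetastaticRisk,
    Mode,
    Ruleset,
    SubtypeHint,
    call_metastatic_risk,
    classify,
    reportable_variants,
)
from pancyst.models import (
    ChromosomalAlteration,
    ExpressionPanel,
    FusionTranscript,
    GenomicVariant,
    SpecimenProfile,
)

GC = Ruleset()
LEGACY = Ruleset(mode=Mode.LEGACY_DNA_ONLY)


def _v(gene, tier="I", vclass="missense"):
    return GenomicVariant(gene=gene, variant_class=vclass, tier=tier)


def _profile(sid="T", variants=(), fusions=(), arms=(), expr=None):
    return SpecimenProfile(specimen_id=sid, variants=variants, fusions=fusions,
                           chromosomal_alterations=arms, expression=expr)


def _arm(arm, atype="loss"):
    return ChromosomalAlteration(arm=arm, alteration_type=atype)


_HI = ExpressionPanel(ceacam5_geu=5000.0, krt7_expressed=True)


def test_reportable_variants_filters_tiers_order_preserving():
    vs = [_v("KRAS", "I"), _v("TP53", "III"), _v("RNF43", "II"), _v("PTEN", "IV")]
    assert [v.gene for v in reportable_variants(vs)] == ["KRAS", "RNF43"]
    assert reportable_variants([]) == []
    assert reportable_variants([_v("KRAS", "III")]) == []


@pytest.mark.parametrize(
    "profile, expected_type, expected_hint",
    [
        (_profile(variants=[_v("KRAS")]), CystType.MUCINOUS, SubtypeHint.IPMN_LIKE),
        (_profile(fusions=[FusionTranscript("DNAJB1", "PRKACA")]),
         CystType.MUCINOUS, SubtypeHint.IOPN),
        (_profile(fusions=[FusionTranscript("ATP1B1", "PRKACB")]),
         CystType.MUCINOUS, SubtypeHint.IOPN),
        (_profile(fusions=[FusionTranscript("ETV6", "NTRK3")]),
         CystType.MUCINOUS, SubtypeHint.IPMN_LIKE),
        (_profile(variants=[_v("MEN1")]), CystType.NEUROENDOCRINE, SubtypeHint.NONE),
        (_profile(expr=ExpressionPanel(ceacam5_geu=900, krt7_expressed=True,
                                       chga_overexpressed=True)),
         CystType.NEUROENDOCRINE, SubtypeHint.NONE),   # CHGA beats expression signal
        (_profile(variants=[_v("VHL")], expr=_HI),
         CystType.SEROUS, SubtypeHint.NONE),           # VHL beats expression signal
        (_profile(expr=_HI), CystType.MUCINOUS, SubtypeHint.IPMN_LIKE),
        (_profile(variants=[_v("TP53")]), CystType.NONMUCINOUS_OTHER, SubtypeHint.NONE),
        (_profile(variants=[_v("RNF43", "II")]), CystType.NONMUCINOUS_OTHER, SubtypeHint.NONE),
        (_profile(variants=[_v("KRAS", "III")]), CystType.NO_ALTERATIONS, SubtypeHint.NONE),
        (_profile(), CystType.NO_ALTERATIONS, SubtypeHint.NONE),
    ],
)
def test_cyst_type_rules_and_precedence(profile, expected_type, expected_hint):
    call = classify(profile, GC)
    assert call.cyst_type is expected_type
    assert call.subtype_hint is expected_hint
    assert call.mucinous_positive is (expected_type is CystType.MUCINOUS)


def test_exactly_one_type_rule_fires_per_profile():
    rng = np.random.default_rng(20240901)
    for i in range(300):
        call = classify(random_profile(rng, f"R{i}"), GC)
        type_rules = [rid for rid, _ in call.evidence if rid.startswith("R")]
        assert len(type_rules) == 1


@pytest.mark.parametrize(
    "profile, expected",
    [
        (_profile(variants=[_v("KRAS"), _v("TP53")]), True),
        (_profile(variants=[_v("KRAS")]), False),
        (_profile(variants=[_v("KRAS")], arms=[_arm("6p")]), True),
        (_profile(fusions=[FusionTranscript("DNAJB1", "PRKACA")]), True),
        # rescue fusions alone are not advanced-neoplasia markers
        (_profile(fusions=[FusionTranscript("ETV6", "NTRK3")]), False),
        (_profile(fusions=[FusionTranscript("SND1", "BRAF")]), False),
        # a fusion driver with a TP53 mutation is
        (_profile(variants=[_v("TP53")], fusions=[FusionTranscript("SND1", "BRAF")]), True),
        # advanced-neoplasia genes without a mucinous call never fire
        (_profile(variants=[_v("TP53"), _v("SMAD4")]), False),
    ],
)
def test_advanced_neoplasia_rules(profile, expected):
    assert classify(profile, GC).advanced_neoplasia_positive is expected


def test_ctnnb1_cdkn2a_are_opt_in():
    p = _profile(variants=[_v("KRAS"), _v("CDKN2A")])
    assert classify(p, GC).advanced_neoplasia_positive is False
    assert classify(p, Ruleset(include_cdkn2a=True)).advanced_neoplasia_positive is True
    q = _profile(variants=[_v("KRAS"), _v("CTNNB1")])
    assert classify(q, Ruleset(include_ctnnb1=True)).advanced_neoplasia_positive is True


@pytest.mark.parametrize(
    "arms, expected",
    [
        ([_arm("10q", "LOH")], MetastaticRisk.HIGH),
        ([_arm("3p"), _arm("6q"), _arm("22q")], MetastaticRisk.ELEVATED),
        ([_arm("3p")], MetastaticRisk.LOW),
        ([], MetastaticRisk.LOW),
        ([_arm("10q", "loss")], MetastaticRisk.LOW),  # 10q loss is not 10q LOH
    ],
)
def test_metastatic_risk_tiers(arms, expected):
    p = _profile(variants=[_v("MEN1")], arms=arms)
    call = classify(p, GC)
    assert call.cyst_type is CystType.NEUROENDOCRINE
    assert call.metastatic_risk is expected


def test_metastatic_risk_not_applicable_outside_neuroendocrine():
    call = classify(_profile(variants=[_v("KRAS")], arms=[_arm("10q", "LOH")]), GC)
    assert call.metastatic_risk is MetastaticRisk.NOT_APPLICABLE


def test_legacy_mode_masks_rna_and_chromosomal_evidence():
    iopn = _profile(fusions=[FusionTranscript("DNAJB1", "PRKACA")], expr=_HI)
    assert classify(iopn, LEGACY).cyst_type is CystType.NO_ALTERATIONS
    expr_only = _profile(expr=_HI)
    assert classify(expr_only, LEGACY).cyst_type is CystType.NO_ALTERATIONS
    chrom = _profile(variants=[_v("KRAS")], arms=[_arm("6p")])
    legacy_call = classify(chrom, LEGACY)
    assert legacy_call.mucinous_positive and not legacy_call.advanced_neoplasia_positive
    mut = _profile(variants=[_v("KRAS"), _v("TP53")])
    assert classify(mut, LEGACY).advanced_neoplasia_positive


def test_classify_is_pure_and_deterministic():
    rng = np.random.default_rng(7)
    p = random_profile(rng, "D1")
    assert classify(p, GC) == classify(p, GC)


def test_evidence_nonempty_on_positive_calls(gc_calls):
    for call in gc_calls:
        if (call.mucinous_positive or call.advanced_neoplasia_positive
                or call.cyst_type in (CystType.SEROUS, CystType.NEUROENDOCRINE)):
            assert call.evidence, call.specimen_id


def test_monotonicity_tp53_and_arms_on_random_profiles():
    """Adding a TP53 mutation to a KRAS-positive profile never retracts an
    advanced-neoplasia call; adding an arm never lowers metastatic risk."""
    rng = np.random.default_rng(20240902)
    order = [MetastaticRisk.NOT_APPLICABLE, MetastaticRisk.LOW,
             MetastaticRisk.ELEVATED, MetastaticRisk.HIGH]
    for i in range(400):
        p = random_profile(rng, f"M{i}")
        base = classify(p, GC)
        if "KRAS" in {v.gene for v in reportable_variants(p.variants)}:
            aug = p.with_(variants=p.variants + (_v("TP53"),))
            assert classify(aug, GC).advanced_neoplasia_positive >= base.advanced_neoplasia_positive
        if all(a.arm != "2q" for a in p.chromosomal_alterations):
            aug = p.with_(chromosomal_alterations=p.chromosomal_alterations + (_arm("2q"),))
            after = classify(aug, GC)
            if after.cyst_type is base.cyst_type is CystType.NEUROENDOCRINE:
                assert order.index(after.metastatic_risk) >= order.index(base.metastatic_risk)


def test_legacy_calls_nest_within_gc_calls():
    """DNA-only evidence is a subset of the full evidence, so every legacy
    mucinous call must also be a full-classifier mucinous call."""
    rng = np.random.default_rng(20240903)
    for i in range(1000):
        p = random_profile(rng, f"N{i}")
        if classify(p, LEGACY).mucinous_positive:
            assert classify(p, GC).mucinous_positive


def test_ruleset_from_file(tmp_path):
    cfg = tmp_path / "rules.yaml"
    cfg.write_text(
        "ruleset:\n  include_cdkn2a: true\n  mode: legacy_dna_only\n"
        "  advanced_neoplasia_genes: [TP53, SMAD4]\n"
    )
    rs = Ruleset.from_file(cfg)
    assert rs.include_cdkn2a and rs.mode is Mode.LEGACY_DNA_ONLY
    assert rs.effective_an_genes == {"TP53", "SMAD4", "CDKN2A"}
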