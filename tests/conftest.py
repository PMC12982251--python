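import numpy as np
import pytest

from pancyst import Ruleset, classify_cohort, fixture_cohort
from pancyst.classifier import Mode
from pancyst.models import (
    AlterationType,
    ChromosomalAlteration,
    ExpressionPanel,
    FusionTranscript,
    GenomicVariant,
    SpecimenProfile,
    Tier,
    VariantClass,
)

_GENE_POOL = [
    "KRAS", "GNAS", "BRAF", "TP53", "SMAD4", "VHL", "MEN1", "CDKN2A",
    "CTNNB1", "RNF43", "PIK3CA", "PTEN", "STK11", "TERT", "ZZZ9",
]
_ARM_POOL = ["1p", "3p", "6p", "6q", "9p", "10q", "17p", "22q"]


def random_profile(rng: np.random.Generator, sid: str) -> SpecimenProfile:
    """A structurally valid but otherwise arbitrary specimen profile."""
    n_var = int(rng.integers(0, 4))
    variants = tuple(
        GenomicVariant(
            gene=str(rng.choice(_GENE_POOL)),
            variant_class=VariantClass(
                str(rng.choice([v.value for v in VariantClass]))
            ),
            tier=Tier(str(rng.choice(["I", "II", "III"], p=[0.5, 0.2, 0.3]))),
        )
        for _ in range(n_var)
    )
    fusions = ()
    if rng.random() < 0.15:
        g3 = str(rng.choice(["PRKACA", "PRKACB", "BRAF", "NTRK3", "ALK"]))
        fusions = (FusionTranscript(gene_5prime="PARTNER", gene_3prime=g3),)
    arms = ()
    if rng.random() < 0.3:
        chosen = rng.choice(_ARM_POOL, size=int(rng.integers(1, 4)), replace=False)
        arms = tuple(
            ChromosomalAlteration(
                arm=str(a),
                alteration_type=AlterationType(str(rng.choice(["loss", "LOH"]))),
            )
            for a in chosen
        )
    expr = None
    if rng.random() < 0.85:
        expr = ExpressionPanel(
            ceacam5_geu=float(rng.lognormal(5.0, 2.0)),
            krt7_expressed=bool(rng.random() < 0.6),
            krt20_expressed=bool(rng.random() < 0.4),
            chga_overexpressed=bool(rng.random() < 0.1),
            evaluable=bool(rng.random() < 0.9),
        )
    return SpecimenProfile(
        specimen_id=sid, variants=variants, fusions=fusions,
        chromosomal_alterations=arms, expression=expr,
    )


@pytest.fixture(scope="session")
def cohort():
    return fixture_cohort()


@pytest.fixture(scope="session")
def gc_calls(cohort):
    return classify_cohort(cohort, Ruleset())


@pytest.fixture(scope="session")
def legacy_calls(cohort):
    return classify_cohort(cohort, Ruleset(mode=Mode.LEGACY_DNA_ONLY))


@pytest.fixture(scope="session")
def extended_calls(cohort):
    return classify_cohort(cohort, Ruleset(include_ctnnb1=True, include_cdkn2a=True))
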