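"""Rule-based genomic classification of pancreatic cyst fluid profiles.

The classifier proceeds in three stages:

1. **Cyst type** from five classes of genomic evidence, applied in a fixed
   precedence order (rules R1-R7): PRKACA/B fusions define IOPN-type
   mucinous cysts; KRAS/GNAS/BRAF mutations and BRAF/NTRK3 fusions define
   generic (IPMN-like) mucinous cysts; CHGA overexpression or MEN1
   mutation defines neuroendocrine lesions; VHL defines serous
   cystadenoma; the CEACAM5/KRT expression signal rescues driver-negative
   mucinous cysts; any other reportable alteration is nonmucinous-other;
   otherwise no alterations detected.

2. **Advanced neoplasia** (high-grade dysplasia / microscopic PDAC) for
   mucinous calls only: an IOPN-defining fusion (A1), a MAPK/PKA driver
   co-occurring with a mutation in an advanced-neoplasia gene set (A2,
   default TP53/SMAD4/PIK3CA/PTEN, optionally extended with CTNNB1 and/or
   CDKN2A), or any arm-level chromosomal alteration (A3).

3. **Metastatic risk** for neuroendocrine calls: 10q LOH is high risk,
   >= 3 distinct altered arms elevated, otherwise low.

Only tier I/II variants enter any rule. A legacy DNA-only mode masks
fusions, expression, and chromosomal evidence, emulating the preceding
22-gene panel; its calls are a subset of full-mode calls by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

from .expression import CEACAM5_THRESHOLD_GEU, mucinous_expression_signal
from .models import AlterationType, GenomicVariant, SpecimenProfile, Tier

__all__ = [
    "CystType",
    "SubtypeHint",
    "MetastaticRisk",
    "Mode",
    "Ruleset",
    "ClassifierCall",
    "reportable_variants",
    "call_cyst_type",
    "call_advanced_neoplasia",
    "call_metastatic_risk",
    "classify",
    "classify_cohort",
    "MAPK_PKA_MUTATION_GENES",
    "IOPN_FUSION_GENES",
    "MUCINOUS_FUSION_GENES",
]

#: MAPK/PKA pathway driver genes (mutations); mucinous-cyst defining.
MAPK_PKA_MUTATION_GENES = frozenset({"KRAS", "GNAS", "BRAF"})
#: Fusion partners defining IOPN.
IOPN_FUSION_GENES = frozenset({"PRKACA", "PRKACB"})
#: Fusion partners acting as alternative MAPK drivers in KRAS wild-type IPMNs.
MUCINOUS_FUSION_GENES = frozenset({"BRAF", "NTRK3"})
#: Observed but carrying no classification weight.
UNINFORMATIVE_GENES = frozenset({"STK11", "TERT"})

DEFAULT_ADVANCED_NEOPLASIA_GENES = frozenset({"TP53", "SMAD4", "PIK3CA", "PTEN"})


class CystType(str, Enum):
    MUCINOUS = "mucinous"
    SEROUS = "serous"
    NEUROENDOCRINE = "neuroendocrine"
    NONMUCINOUS_OTHER = "nonmucinous_other"
    NO_ALTERATIONS = "no_alterations"


class SubtypeHint(str, Enum):
    IPMN_LIKE = "IPMN_like"
    IOPN = "IOPN"
    NONE = "none"


class MetastaticRisk(str, Enum):
    NOT_APPLICABLE = "not_applicable"
    LOW = "low"
    ELEVATED = "elevated"
    HIGH = "high"


class Mode(str, Enum):
    GC = "gc"
    LEGACY_DNA_ONLY = "legacy_dna_only"


@dataclass(frozen=True)
class Ruleset:
    """Tunable rule configuration.

    ``legacy_dna_only`` restricts the evidence to tiered DNA mutations:
    fusions, expression, and chromosomal alterations are masked before any
    rule fires.
    """

    advanced_neoplasia_genes: frozenset = DEFAULT_ADVANCED_NEOPLASIA_GENES
    include_ctnnb1: bool = False
    include_cdkn2a: bool = False
    use_chromosomal_alterations: bool = True
    mode: Mode = Mode.GC
    ceacam5_threshold_geu: float = CEACAM5_THRESHOLD_GEU

    def __post_init__(self):
        object.__setattr__(self, "advanced_neoplasia_genes",
                           frozenset(g.upper() for g in self.advanced_neoplasia_genes))
        object.__setattr__(self, "mode", Mode(self.mode))

    @property
    def effective_an_genes(self) -> frozenset:
        genes = set(self.advanced_neoplasia_genes)
        if self.include_ctnnb1:
            genes.add("CTNNB1")
        if self.include_cdkn2a:
            genes.add("CDKN2A")
        return frozenset(genes)

    @classmethod
    def from_file(cls, path) -> "Ruleset":
        """Load from a YAML or JSON config file (keys as field names)."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            doc = yaml.safe_load(text) or {}
        else:
            doc = json.loads(text)
        doc = doc.get("ruleset", doc)
        kwargs = {}
        for key in ("advanced_neoplasia_genes", "include_ctnnb1", "include_cdkn2a",
                    "use_chromosomal_alterations", "mode", "ceacam5_threshold_geu"):
            if key in doc:
                kwargs[key] = doc[key]
        if "advanced_neoplasia_genes" in kwargs:
            kwargs["advanced_neoplasia_genes"] = frozenset(kwargs["advanced_neoplasia_genes"])
        return cls(**kwargs)


@dataclass(frozen=True)
class ClassifierCall:
    """The classifier's output for one specimen, with an evidence trail of
    (rule_id, justification) pairs for every fired rule."""

    specimen_id: str
    cyst_type: CystType
    subtype_hint: SubtypeHint
    mucinous_positive: bool
    advanced_neoplasia_positive: bool
    metastatic_risk: MetastaticRisk
    evidence: Tuple[Tuple[str, str], ...] = ()

    def to_dict(self) -> dict:
        return {
            "specimen_id": self.specimen_id,
            "cyst_type": self.cyst_type.value,
            "subtype_hint": self.subtype_hint.value,
            "mucinous_positive": self.mucinous_positive,
            "advanced_neoplasia_positive": self.advanced_neoplasia_positive,
            "metastatic_risk": self.metastatic_risk.value,
            "evidence": [list(e) for e in self.evidence],
        }


def reportable_variants(variants: Sequence[GenomicVariant]) -> List[GenomicVariant]:
    """Tier I and tier II variants only, order-preserving; tier III/IV
    variants are observed but never enter a rule."""
    return [v for v in variants if v.tier in (Tier.I, Tier.II)]


# ---------------------------------------------------------------------------
# evidence views

@dataclass(frozen=True)
class _Evidence:
    """Masked, tier-filtered view of a specimen under one ruleset."""

    reportable: tuple
    fusion_partners: frozenset
    arms: tuple
    expression: object  # ExpressionPanel or None
    chga: bool

    @classmethod
    def gather(cls, profile: SpecimenProfile, ruleset: Ruleset) -> "_Evidence":
        rep = tuple(reportable_variants(profile.variants))
        if ruleset.mode is Mode.LEGACY_DNA_ONLY:
            return cls(rep, frozenset(), (), None, False)
        partners = frozenset().union(*(f.partners for f in profile.fusions)) if profile.fusions else frozenset()
        expr = profile.expression if (profile.expression is not None and profile.expression.evaluable) else None
        chga = bool(expr and expr.chga_overexpressed)
        return cls(rep, partners, tuple(profile.chromosomal_alterations), expr, chga)

    def genes(self) -> frozenset:
        return frozenset(v.gene for v in self.reportable)


# ---------------------------------------------------------------------------
# stage 1: cyst type

def call_cyst_type(profile: SpecimenProfile, ruleset: Ruleset = Ruleset()):
    """Determine cyst type by the first matching rule R1-R7.

    Returns ``(cyst_type, subtype_hint, evidence)``.
    """
    ev = _Evidence.gather(profile, ruleset)
    genes = ev.genes()
    evidence: List[Tuple[str, str]] = []

    mapk_mut = sorted(genes & MAPK_PKA_MUTATION_GENES)
    mucinous_fusions = sorted(ev.fusion_partners & MUCINOUS_FUSION_GENES)
    iopn_fusions = sorted(ev.fusion_partners & IOPN_FUSION_GENES)

    # R1: PRKACA/B fusion -> IOPN-type mucinous cyst
    if iopn_fusions:
        evidence.append(("R1", f"IOPN-defining fusion involving {'/'.join(iopn_fusions)}"))
        _note_uninformative(ev, evidence)
        return CystType.MUCINOUS, SubtypeHint.IOPN, evidence

    # R2: MAPK/PKA driver mutation or fusion -> mucinous (IPMN-like)
    if mapk_mut or mucinous_fusions:
        parts = []
        if mapk_mut:
            parts.append("mutation in " + "/".join(mapk_mut))
        if mucinous_fusions:
            parts.append("fusion involving " + "/".join(mucinous_fusions))
        if "RNF43" in genes:
            parts.append("co-occurring RNF43 mutation")
        evidence.append(("R2", "MAPK/PKA driver: " + "; ".join(parts)))
        _note_uninformative(ev, evidence)
        return CystType.MUCINOUS, SubtypeHint.IPMN_LIKE, evidence

    # R3: CHGA overexpression or MEN1 mutation -> neuroendocrine
    if ev.chga or "MEN1" in genes:
        parts = [p for p, ok in (("CHGA overexpression", ev.chga), ("MEN1 mutation", "MEN1" in genes)) if ok]
        evidence.append(("R3", "neuroendocrine marker: " + " and ".join(parts)))
        return CystType.NEUROENDOCRINE, SubtypeHint.NONE, evidence

    # R4: VHL -> serous cystadenoma
    if "VHL" in genes:
        evidence.append(("R4", "VHL mutation (serous cystadenoma marker)"))
        return CystType.SEROUS, SubtypeHint.NONE, evidence

    # R5: CEACAM5/KRT expression signal -> mucinous
    if ev.expression is not None and mucinous_expression_signal(
        ev.expression, ruleset.ceacam5_threshold_geu
    ):
        evidence.append((
            "R5",
            f"CEACAM5 {ev.expression.ceacam5_geu:g} GEU > {ruleset.ceacam5_threshold_geu:g}"
            " with KRT7/KRT20 co-expression",
        ))
        return CystType.MUCINOUS, SubtypeHint.IPMN_LIKE, evidence

    # R6: any other reportable alteration -> nonmucinous, not otherwise classed
    if ev.reportable or ev.fusion_partners or ev.arms:
        what = sorted(genes) or sorted(ev.fusion_partners) or [a.arm for a in ev.arms]
        evidence.append(("R6", "reportable alteration without cyst-type assignment: " + ", ".join(what)))
        _note_uninformative(ev, evidence)
        return CystType.NONMUCINOUS_OTHER, SubtypeHint.NONE, evidence

    # R7: nothing reportable, no expression signal
    evidence.append(("R7", "no reportable alterations detected"))
    return CystType.NO_ALTERATIONS, SubtypeHint.NONE, evidence


def _note_uninformative(ev: _Evidence, evidence: list) -> None:
    noted = sorted(ev.genes() & UNINFORMATIVE_GENES)
    if noted:
        evidence.append(("OBS", "observed, uninformative: " + ", ".join(noted)))


# ---------------------------------------------------------------------------
# stage 2: advanced neoplasia

def call_advanced_neoplasia(
    profile: SpecimenProfile,
    cyst_type: CystType,
    subtype_hint: SubtypeHint,
    ruleset: Ruleset = Ruleset(),
):
    """Advanced-neoplasia risk call; positive only for mucinous calls.

    Returns ``(positive, evidence)``.
    """
    evidence: List[Tuple[str, str]] = []
    if cyst_type is not CystType.MUCINOUS:
        return False, evidence
    ev = _Evidence.gather(profile, ruleset)
    genes = ev.genes()

    # A1: IOPN-defining fusion (IOPNs universally harbor advanced neoplasia)
    if subtype_hint is SubtypeHint.IOPN:
        evidence.append(("A1", "IOPN-defining PRKACA/B fusion"))

    # A2: MAPK/PKA driver plus advanced-neoplasia gene mutation
    has_driver = bool(genes & MAPK_PKA_MUTATION_GENES) or bool(
        ev.fusion_partners & MUCINOUS_FUSION_GENES
    )
    an_hits = sorted(genes & ruleset.effective_an_genes)
    if has_driver and an_hits:
        evidence.append(("A2", "MAPK/PKA driver with mutation in " + "/".join(an_hits)))

    # A3: any arm-level chromosomal alteration
    if ruleset.use_chromosomal_alterations and ev.arms:
        arms = ", ".join(a.arm for a in ev.arms)
        evidence.append(("A3", f"chromosomal alteration(s): {arms}"))

    return bool(evidence), evidence


# ---------------------------------------------------------------------------
# stage 3: metastatic risk (neuroendocrine lesions)

def call_metastatic_risk(profile: SpecimenProfile, cyst_type: CystType,
                         ruleset: Ruleset = Ruleset()):
    """Metastatic-risk tier for neuroendocrine calls.

    Returns ``(risk, evidence)``; ``not_applicable`` for other cyst types.
    """
    evidence: List[Tuple[str, str]] = []
    if cyst_type is not CystType.NEUROENDOCRINE:
        return MetastaticRisk.NOT_APPLICABLE, evidence
    ev = _Evidence.gather(profile, ruleset)
    loh_10q = any(
        a.arm == "10q" and a.alteration_type is AlterationType.LOH for a in ev.arms
    )
    n_arms = len({a.arm for a in ev.arms})
    if loh_10q:
        evidence.append(("M1", "LOH at chromosome 10q"))
        return MetastaticRisk.HIGH, evidence
    if n_arms >= 3:
        evidence.append(("M2", f">= 3 distinct altered chromosome arms (n={n_arms})"))
        return MetastaticRisk.ELEVATED, evidence
    return MetastaticRisk.LOW, evidence


# ---------------------------------------------------------------------------
# composition

def classify(profile: SpecimenProfile, ruleset: Ruleset = Ruleset()) -> ClassifierCall:
    """Full three-stage classification of one specimen (pure, deterministic)."""
    cyst_type, hint, evidence = call_cyst_type(profile, ruleset)
    an_positive, an_evidence = call_advanced_neoplasia(profile, cyst_type, hint, ruleset)
    risk, risk_evidence = call_metastatic_risk(profile, cyst_type, ruleset)
    return ClassifierCall(
        specimen_id=profile.specimen_id,
        cyst_type=cyst_type,
        subtype_hint=hint,
        mucinous_positive=cyst_type is CystType.MUCINOUS,
        advanced_neoplasia_positive=an_positive,
        metastatic_risk=risk,
        evidence=tuple(evidence) + tuple(an_evidence) + tuple(risk_evidence),
    )


def classify_cohort(specimens, ruleset: Ruleset = Ruleset()) -> List[ClassifierCall]:
    return [classify(s, ruleset) for s in specimens]
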