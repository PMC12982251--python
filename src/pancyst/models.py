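"""Domain types for pancreatic cyst fluid molecular profiles.

A specimen couples gene-level interpreted sequencing calls (tiered point
mutations/indels, fusion transcripts, arm-level chromosomal alterations),
an RT-qPCR expression panel (CEACAM5 in gene expression units, KRT7/KRT20
co-expression, CHGA overexpression), optional clinical features used by
guideline comparators, and an optional histopathologic reference diagnosis.

Validation is eager: constructing any type with out-of-range or
inconsistent fields raises ``ValueError`` naming the offending field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

__all__ = [
    "VariantClass",
    "Tier",
    "AlterationType",
    "Cytopathology",
    "HistologicType",
    "Grade",
    "GenomicVariant",
    "FusionTranscript",
    "ChromosomalAlteration",
    "ExpressionPanel",
    "ClinicalFeatures",
    "ReferenceDiagnosis",
    "SpecimenProfile",
    "MUCINOUS_TYPES",
    "NEUROENDOCRINE_TYPES",
]


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    PROMOTER = "promoter"


class Tier(str, Enum):
    """AMP/ASCO/CAP consensus tiers for somatic variant clinical significance."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


class AlterationType(str, Enum):
    LOSS = "loss"
    LOH = "LOH"
    GAIN = "gain"


class Cytopathology(str, Enum):
    NONDIAGNOSTIC = "nondiagnostic"
    BENIGN = "benign"
    ATYPICAL = "atypical"
    NEUROENDOCRINE = "neuroendocrine"
    SEROUS = "serous"
    SUSPICIOUS_FOR_ADENOCARCINOMA = "suspicious_for_adenocarcinoma"
    ADENOCARCINOMA = "adenocarcinoma"


class HistologicType(str, Enum):
    IPMN = "IPMN"
    MCN = "MCN"
    IOPN = "IOPN"
    ITPN = "ITPN"
    SCA = "SCA"
    PSEUDOCYST = "pseudocyst"
    CPANNET = "cPanNET"
    MIXED_SCA_NET = "mixed_SCA_NET"
    CYSTIC_SCHWANNOMA = "cystic_schwannoma"
    CYSTIC_ACC = "cystic_ACC"
    PARAGANGLIOMA = "paraganglioma"
    OTHER_NONMUCINOUS = "other_nonmucinous"


class Grade(str, Enum):
    LOW_GRADE = "low_grade"
    HIGH_GRADE_DYSPLASIA = "high_grade_dysplasia"
    PDAC = "PDAC"
    NOT_APPLICABLE = "not_applicable"


#: Mucinous (PDAC-precursor) cyst types.
MUCINOUS_TYPES = frozenset(
    {HistologicType.IPMN, HistologicType.MCN, HistologicType.IOPN, HistologicType.ITPN}
)

#: Neuroendocrine-type neoplasms for the subtype accuracy analysis: cystic
#: PanNETs, the mixed serous/neuroendocrine lesion, and the CHGA-expressing
#: paraganglioma. (A schwannoma is not a neuroendocrine neoplasm and is
#: evaluated as a generic nonmucinous lesion.)
NEUROENDOCRINE_TYPES = frozenset(
    {HistologicType.CPANNET, HistologicType.MIXED_SCA_NET, HistologicType.PARAGANGLIOMA}
)

_VALID_CHROMOSOMES = {str(i) for i in range(1, 23)} | {"X", "Y"}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class GenomicVariant:
    """A gene-level interpreted DNA variant carried by a specimen."""

    gene: str
    variant_class: VariantClass
    tier: Tier
    description: Optional[str] = None
    allele_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        _require(bool(self.gene) and self.gene.strip() != "", "GenomicVariant.gene must be non-empty")
        object.__setattr__(self, "gene", self.gene.strip().upper())
        object.__setattr__(self, "variant_class", VariantClass(self.variant_class))
        object.__setattr__(self, "tier", Tier(self.tier))
        if self.allele_fraction is not None:
            _require(
                0.0 <= self.allele_fraction <= 1.0,
                f"GenomicVariant.allele_fraction must be in [0,1], got {self.allele_fraction}",
            )


@dataclass(frozen=True)
class FusionTranscript:
    """A fusion gene transcript; partners are ordered 5' -> 3'."""

    gene_5prime: str = ""
    gene_3prime: str = ""
    supporting_reads: Optional[int] = None

    def __post_init__(self) -> None:
        g5 = (self.gene_5prime or "").strip().upper()
        g3 = (self.gene_3prime or "").strip().upper()
        _require(g5 != "" or g3 != "", "FusionTranscript requires at least one partner gene")
        object.__setattr__(self, "gene_5prime", g5)
        object.__setattr__(self, "gene_3prime", g3)
        if self.supporting_reads is not None:
            _require(self.supporting_reads >= 0, "FusionTranscript.supporting_reads must be >= 0")

    @property
    def partners(self) -> frozenset:
        return frozenset(g for g in (self.gene_5prime, self.gene_3prime) if g)


@dataclass(frozen=True)
class ChromosomalAlteration:
    """An arm-level copy-number loss, gain, or LOH (e.g. arm='10q', type=LOH)."""

    arm: str
    alteration_type: AlterationType

    def __post_init__(self) -> None:
        arm = self.arm.strip()
        _require(len(arm) >= 2 and arm[-1] in ("p", "q"), f"arm must end in p or q: {arm!r}")
        chrom = arm[:-1].upper() if arm[:-1] in ("x", "y") else arm[:-1]
        _require(chrom in _VALID_CHROMOSOMES, f"invalid chromosome in arm {arm!r}")
        object.__setattr__(self, "arm", chrom + arm[-1])
        object.__setattr__(self, "alteration_type", AlterationType(self.alteration_type))


@dataclass(frozen=True)
class ExpressionPanel:
    """RT-qPCR expression results.

    When ``evaluable`` is false (insufficient RNA), every other field is
    ignored by all consumers; the panel is kept rather than dropped so
    per-modality denominators remain computable.
    """

    ceacam5_geu: float = 0.0
    krt7_expressed: bool = False
    krt20_expressed: bool = False
    chga_overexpressed: bool = False
    evaluable: bool = True

    def __post_init__(self) -> None:
        _require(
            math.isfinite(self.ceacam5_geu) and self.ceacam5_geu >= 0,
            f"ceacam5_geu must be finite and >= 0, got {self.ceacam5_geu}",
        )


@dataclass(frozen=True)
class ClinicalFeatures:
    """Imaging, laboratory, and cytopathologic features for guideline comparators.

    Tri-state fields (``fluid_viscosity_increased``, ``cea_elevated``) use
    ``None`` for "not measured", distinct from a measured negative.
    """

    cyst_size_cm: Optional[float] = None
    growth_mm_per_year: Optional[float] = None
    cyst_wall_thickened_or_enhancing: bool = False
    mural_nodule_present: bool = False
    mural_nodule_enhancing: bool = False
    mural_nodule_size_mm: Optional[float] = None
    main_duct_mm: Optional[float] = None
    abrupt_duct_caliber_change_with_atrophy: bool = False
    lymphadenopathy: bool = False
    ca19_9_elevated: bool = False
    pancreatitis_attributable: bool = False
    obstructive_jaundice_head_cyst: bool = False
    cytopathology: Optional[Cytopathology] = None
    fluid_viscosity_increased: Optional[bool] = None
    cea_elevated: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.cyst_size_cm is not None:
            _require(self.cyst_size_cm > 0, "cyst_size_cm must be positive")
        if self.mural_nodule_size_mm is not None:
            _require(self.mural_nodule_size_mm >= 0, "mural_nodule_size_mm must be >= 0")
        if self.main_duct_mm is not None:
            _require(self.main_duct_mm >= 0, "main_duct_mm must be >= 0")
        if self.cytopathology is not None:
            object.__setattr__(self, "cytopathology", Cytopathology(self.cytopathology))


@dataclass(frozen=True)
class ReferenceDiagnosis:
    """Histopathologic reference-standard diagnosis from surgical resection."""

    histologic_type: HistologicType
    grade: Grade
    distant_metastasis: Optional[bool] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "histologic_type", HistologicType(self.histologic_type))
        object.__setattr__(self, "grade", Grade(self.grade))
        if self.histologic_type not in MUCINOUS_TYPES:
            _require(
                self.grade is Grade.NOT_APPLICABLE,
                f"nonmucinous type {self.histologic_type.value} must have grade not_applicable",
            )
        else:
            _require(
                self.grade is not Grade.NOT_APPLICABLE,
                f"mucinous type {self.histologic_type.value} requires a dysplasia grade",
            )

    @property
    def is_mucinous(self) -> bool:
        return self.histologic_type in MUCINOUS_TYPES

    @property
    def is_advanced_neoplasia(self) -> bool:
        """High-grade dysplasia or microscopic PDAC within a mucinous cyst."""
        return self.is_mucinous and self.grade in (Grade.HIGH_GRADE_DYSPLASIA, Grade.PDAC)

    @property
    def is_neuroendocrine_type(self) -> bool:
        return self.histologic_type in NEUROENDOCRINE_TYPES


@dataclass(frozen=True)
class SpecimenProfile:
    """One cyst fluid specimen: molecular evidence plus optional clinical
    features and reference diagnosis. Empty evidence lists are valid (a
    "no alterations detected" specimen)."""

    specimen_id: str
    variants: tuple = ()
    fusions: tuple = ()
    chromosomal_alterations: tuple = ()
    expression: Optional[ExpressionPanel] = None
    clinical: Optional[ClinicalFeatures] = None
    reference: Optional[ReferenceDiagnosis] = None

    def __post_init__(self) -> None:
        _require(bool(self.specimen_id.strip()), "specimen_id must be non-empty")
        object.__setattr__(self, "variants", tuple(self.variants))
        object.__setattr__(self, "fusions", tuple(self.fusions))
        object.__setattr__(self, "chromosomal_alterations", tuple(self.chromosomal_alterations))
        arms = [a.arm for a in self.chromosomal_alterations]
        if len(arms) != len(set(arms)):
            dupes = sorted({a for a in arms if arms.count(a) > 1})
            raise ValueError(
                f"specimen {self.specimen_id}: duplicate chromosomal arm(s) {dupes}"
            )

    def with_(self, **changes) -> "SpecimenProfile":
        return replace(self, **changes)


def validate_cohort(specimens) -> list:
    """Check cohort-level invariants (unique specimen ids) and return a list."""
    specimens = list(specimens)
    seen: dict = {}
    for s in specimens:
        if s.specimen_id in seen:
            raise ValueError(f"duplicate specimen_id {s.specimen_id!r} in cohort")
        seen[s.specimen_id] = s
    return specimens
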