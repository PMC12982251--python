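"""Non-molecular comparator calls: guideline imaging criteria, cytopathology,
cyst fluid viscosity, and CEA, plus OR-combination of modalities.

Worrisome features and high-risk stigmata follow the international
(Kyoto) IPMN management guideline definitions. Results are tri-state:
``True`` / ``False`` / ``None`` (unknown, measurement unavailable); a
single-test evaluation drops unknowns (complete case), while OR-combination
treats (unknown, negative) as negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .models import AlterationType, ClinicalFeatures, Cytopathology, SpecimenProfile

__all__ = [
    "ModalityCall",
    "worrisome_features",
    "high_risk_stigmata",
    "malignant_cytopathology",
    "combine",
    "modality_calls",
    "MODALITIES",
]

#: Modality identifiers usable in :func:`modality_calls`.
MODALITIES = (
    "viscosity",
    "cea",
    "cytopathology_malignant",
    "cytopathology_neuroendocrine",
    "cytopathology_serous",
    "worrisome_features",
    "high_risk_stigmata",
    # metastatic-risk markers for cystic PanNETs
    "chromosomal_ge3",
    "loh_10q",
    "size_gt_2cm",
)


@dataclass(frozen=True)
class ModalityCall:
    """One modality's tri-state result for one specimen."""

    specimen_id: str
    modality: str
    result: Optional[bool]  # True=positive, False=negative, None=unknown

    @property
    def result_label(self) -> str:
        return {True: "positive", False: "negative", None: "unknown"}[self.result]


def worrisome_features(c: Optional[ClinicalFeatures]) -> Optional[bool]:
    """Any worrisome feature: cyst >= 3.0 cm, thickened/enhancing wall,
    nonenhancing mural nodule, main duct 5-9 mm, abrupt caliber change with
    atrophy, lymphadenopathy, elevated CA 19-9, growth > 5 mm/year, or
    cyst-attributable pancreatitis."""
    if c is None:
        return None
    positives = [
        c.cyst_size_cm is not None and c.cyst_size_cm >= 3.0,
        c.cyst_wall_thickened_or_enhancing,
        c.mural_nodule_present and not c.mural_nodule_enhancing,
        c.main_duct_mm is not None and 5.0 <= c.main_duct_mm <= 9.0,
        c.abrupt_duct_caliber_change_with_atrophy,
        c.lymphadenopathy,
        c.ca19_9_elevated,
        c.growth_mm_per_year is not None and c.growth_mm_per_year > 5.0,
        c.pancreatitis_attributable,
    ]
    return any(positives)


def high_risk_stigmata(c: Optional[ClinicalFeatures]) -> Optional[bool]:
    """Obstructive jaundice with a head cyst, enhancing mural nodule
    >= 5 mm, main duct >= 10 mm, or malignant cytopathology."""
    if c is None:
        return None
    return any(
        [
            c.obstructive_jaundice_head_cyst,
            c.mural_nodule_enhancing
            and c.mural_nodule_size_mm is not None
            and c.mural_nodule_size_mm >= 5.0,
            c.main_duct_mm is not None and c.main_duct_mm >= 10.0,
            bool(malignant_cytopathology(c)),
        ]
    )


def malignant_cytopathology(c: Optional[ClinicalFeatures]) -> Optional[bool]:
    """At least suspicious for adenocarcinoma; unknown if no cytology."""
    if c is None or c.cytopathology is None:
        return None
    return c.cytopathology in (
        Cytopathology.SUSPICIOUS_FOR_ADENOCARCINOMA,
        Cytopathology.ADENOCARCINOMA,
    )


def _cyto_is(c: Optional[ClinicalFeatures], value: Cytopathology) -> Optional[bool]:
    if c is None or c.cytopathology is None:
        return None
    return c.cytopathology is value


def modality_calls(specimens: Sequence[SpecimenProfile], modality: str) -> List[ModalityCall]:
    """Evaluate one comparator modality across a cohort."""
    out = []
    for s in specimens:
        c = s.clinical
        if modality == "viscosity":
            result = c.fluid_viscosity_increased if c is not None else None
        elif modality == "cea":
            result = c.cea_elevated if c is not None else None
        elif modality == "cytopathology_malignant":
            result = malignant_cytopathology(c)
        elif modality == "cytopathology_neuroendocrine":
            result = _cyto_is(c, Cytopathology.NEUROENDOCRINE)
        elif modality == "cytopathology_serous":
            result = _cyto_is(c, Cytopathology.SEROUS)
        elif modality == "worrisome_features":
            result = worrisome_features(c)
        elif modality == "high_risk_stigmata":
            result = high_risk_stigmata(c)
        elif modality == "chromosomal_ge3":
            result = len({a.arm for a in s.chromosomal_alterations}) >= 3
        elif modality == "loh_10q":
            result = any(
                a.arm == "10q" and a.alteration_type is AlterationType.LOH
                for a in s.chromosomal_alterations
            )
        elif modality == "size_gt_2cm":
            result = (
                None if c is None or c.cyst_size_cm is None else c.cyst_size_cm > 2.0
            )
        else:
            raise ValueError(f"unknown modality {modality!r}")
        out.append(ModalityCall(s.specimen_id, modality, result))
    return out


def combine(
    calls_a: Sequence[ModalityCall],
    calls_b: Sequence[ModalityCall],
    rule: str = "either_positive",
    modality: str = "combined",
) -> List[ModalityCall]:
    """OR-combination of two aligned modality call lists.

    Positive if either is positive; negative if at least one measured
    negative and neither positive; unknown only when both are unknown.
    """
    if rule != "either_positive":
        raise ValueError(f"unknown combination rule {rule!r}")
    by_id_b = {c.specimen_id: c for c in calls_b}
    if {c.specimen_id for c in calls_a} != set(by_id_b):
        raise ValueError("combine: specimen sets differ between modalities")
    out = []
    for a in calls_a:
        b = by_id_b[a.specimen_id]
        if a.result or b.result:
            r: Optional[bool] = True
        elif a.result is None and b.result is None:
            r = None
        else:
            r = False
        out.append(ModalityCall(a.specimen_id, modality, r))
    return out
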