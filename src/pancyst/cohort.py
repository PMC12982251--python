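"""Synthetic cohorts of surgically confirmed pancreatic cysts.

Two entry points:

* :func:`generate_cohort` draws a stochastic cohort from a
  :class:`CohortSpec` whose defaults encode the validation study
  conditions: 241 resected cysts (186 mucinous, 97 with advanced
  neoplasia; 55 nonmucinous), per-diagnosis marker prevalences, the
  heavy-tailed CEACAM5 distribution, and the biological exclusivity
  constraints (KRAS/GNAS/BRAF confined to mucinous cysts; VHL/MEN1
  mutually exclusive of MAPK/PKA drivers; CHGA confined to
  neuroendocrine lesions; chromosomal alterations confined to
  advanced-neoplasia mucinous cysts and cystic PanNETs).

* :func:`fixture_cohort` builds one deterministic 241-specimen cohort
  whose classifier output reproduces, exactly, every published 2x2 table
  of the validation analysis (the tables are integer-determined by the
  published group sizes and rates). It is the reconstruction device used
  by the end-to-end reproduction pipeline and tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .models import (
    AlterationType,
    ChromosomalAlteration,
    ClinicalFeatures,
    Cytopathology,
    ExpressionPanel,
    FusionTranscript,
    GenomicVariant,
    Grade,
    HistologicType,
    ReferenceDiagnosis,
    SpecimenProfile,
    Tier,
    VariantClass,
    validate_cohort,
)

__all__ = ["CohortSpec", "default_cohort_spec", "generate_cohort", "fixture_cohort"]

_HT = HistologicType

#: Arm pool for sampled chromosomal losses (most prevalent arms first).
_ARM_POOL = ["6q", "3p", "22q", "6p", "17p", "9p", "8p", "18q", "1p", "11q"]


@dataclass(frozen=True)
class CohortSpec:
    """Per-diagnosis counts and marker prevalences driving the generator.

    Defaults encode the study conditions of the 241-specimen surgical
    cohort; every probability is the reconstructed per-specimen rate
    implied by the published counts.
    """

    diagnosis_counts: Dict[HistologicType, int] = field(default_factory=lambda: {
        _HT.IPMN: 164, _HT.MCN: 18, _HT.IOPN: 3, _HT.ITPN: 1,
        _HT.SCA: 12, _HT.CPANNET: 34, _HT.MIXED_SCA_NET: 1,
        _HT.CYSTIC_SCHWANNOMA: 1, _HT.CYSTIC_ACC: 1, _HT.PARAGANGLIOMA: 1,
        _HT.PSEUDOCYST: 5,
    })
    #: advanced-neoplasia counts per mucinous type (97 of 186 total).
    advanced_counts: Dict[HistologicType, int] = field(default_factory=lambda: {
        _HT.IPMN: 88, _HT.MCN: 5, _HT.IOPN: 3, _HT.ITPN: 1,
    })

    # --- mucinous evidence ------------------------------------------------
    p_dna_driver: float = 164 / 183          # MAPK/PKA mutation, non-IOPN mucinous
    #: driver composition given a driver is present
    driver_composition: Dict[str, float] = field(default_factory=lambda: {
        "kras": 0.434, "gnas": 0.123, "kras+gnas": 0.420, "braf": 0.023,
    })
    p_multi_kras: float = 16 / 140           # second KRAS mutation (IPMN only)
    p_fusion_given_no_driver: float = 6 / 19  # BRAF/NTRK3 rescue fusions (non-IOPN)
    p_rnf43_given_driver: float = 27 / 164
    p_an_gene_given_driver_an: float = 78 / 84
    an_gene_weights: Dict[str, float] = field(default_factory=lambda: {
        "TP53": 0.70, "SMAD4": 0.20, "PIK3CA": 0.05, "PTEN": 0.05,
    })
    p_an_gene_given_driver_lg: float = 3 / 86
    p_cdkn2a_an: float = 32 / 97
    p_cdkn2a_lg: float = 1 / 89
    p_ctnnb1_an: float = 1 / 97
    p_ctnnb1_lg: float = 2 / 89
    p_chrom_given_an: float = 48 / 97        # chromosomal alteration, AN mucinous

    # --- expression -------------------------------------------------------
    p_expr_evaluable: float = 215 / 241
    p_elevated_given_driver: float = 0.957   # CEACAM5 > 200 GEU
    p_elevated_given_no_driver: float = 0.375
    geu_log_mu: float = math.log(2269.0)     # elevated-case log-normal (median)
    geu_log_sigma: float = 1.70              # implies mean ~= 9600 GEU
    p_krt7: float = 0.85
    p_krt20: float = 0.55

    # --- nonmucinous ------------------------------------------------------
    p_vhl_sca: float = 10 / 12
    p_sca_elevated_expr: float = 1 / 12
    p_chga_pannet: float = 33 / 34
    p_men1_given_chga: float = 7 / 33
    n_pannet_followup: int = 31
    n_pannet_metastatic: int = 3
    p_ge3_arms_nonmet: float = 10 / 28
    p_10q_given_ge3_nonmet: float = 0.3
    p_size_gt2_nonmet: float = 10 / 28
    p_size_gt2_met: float = 2 / 3
    p_nonmuc_other_elevated: float = 1.0     # cystic ACC / schwannoma CEACAM5 signal

    def validate(self) -> None:
        if any(v < 0 for v in self.diagnosis_counts.values()):
            raise ValueError("diagnosis counts must be non-negative")
        for ht, k in self.advanced_counts.items():
            if k > self.diagnosis_counts.get(ht, 0):
                raise ValueError(f"advanced count for {ht} exceeds diagnosis count")
        probs = [
            self.p_dna_driver, self.p_multi_kras, self.p_fusion_given_no_driver,
            self.p_rnf43_given_driver, self.p_an_gene_given_driver_an,
            self.p_an_gene_given_driver_lg, self.p_cdkn2a_an, self.p_cdkn2a_lg,
            self.p_ctnnb1_an, self.p_ctnnb1_lg, self.p_chrom_given_an,
            self.p_expr_evaluable, self.p_elevated_given_driver,
            self.p_elevated_given_no_driver, self.p_vhl_sca, self.p_chga_pannet,
            self.p_men1_given_chga, self.p_ge3_arms_nonmet,
        ] + list(self.driver_composition.values()) + list(self.an_gene_weights.values())
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.driver_composition.values()) - 1.0) > 1e-9:
            raise ValueError("driver_composition must sum to 1")
        if self.n_pannet_metastatic > self.n_pannet_followup:
            raise ValueError("metastatic count exceeds follow-up count")

    @property
    def n_total(self) -> int:
        return sum(self.diagnosis_counts.values())

    @property
    def n_mucinous(self) -> int:
        from .models import MUCINOUS_TYPES

        return sum(v for k, v in self.diagnosis_counts.items() if k in MUCINOUS_TYPES)

    def expected_gene_fraction(self, gene: str) -> float:
        """Closed-form expected cohort-wide mutation frequency for the major
        genes, from the same parameters the sampler draws from (used as the
        analytic anchor for calibration tests)."""
        n = self.n_total
        comp = self.driver_composition
        n_driver_pool = self.n_mucinous - self.diagnosis_counts.get(_HT.IOPN, 0)
        n_an = sum(self.advanced_counts.values())
        n_an_noniopn = n_an - self.advanced_counts.get(_HT.IOPN, 0)
        n_lg = (self.n_mucinous - n_an)
        if gene == "KRAS":
            return n_driver_pool * self.p_dna_driver * (comp["kras"] + comp["kras+gnas"]) / n
        if gene == "GNAS":
            return n_driver_pool * self.p_dna_driver * (comp["gnas"] + comp["kras+gnas"]) / n
        if gene == "VHL":
            return self.diagnosis_counts.get(_HT.SCA, 0) * self.p_vhl_sca / n
        if gene == "MEN1":
            return (self.diagnosis_counts.get(_HT.CPANNET, 0)
                    * self.p_chga_pannet * self.p_men1_given_chga / n)
        if gene == "CDKN2A":
            return (n_an_noniopn * self.p_cdkn2a_an + n_lg * self.p_cdkn2a_lg) / n
        if gene == "RNF43":
            return n_driver_pool * self.p_dna_driver * self.p_rnf43_given_driver / n
        if gene in self.an_gene_weights:
            w = self.an_gene_weights[gene]
            p_an = self.p_dna_driver * self.p_an_gene_given_driver_an
            p_lg = self.p_dna_driver * self.p_an_gene_given_driver_lg
            return (n_an_noniopn * p_an + n_lg * p_lg) * w / n
        raise KeyError(f"no closed-form expectation for {gene}")


def default_cohort_spec() -> CohortSpec:
    """The study-condition cohort specification (validated)."""
    spec = CohortSpec()
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# helpers

def _var(gene: str, vclass=VariantClass.MISSENSE, tier=Tier.I, desc=None) -> GenomicVariant:
    return GenomicVariant(gene=gene, variant_class=vclass, tier=tier, description=desc)


def _expr(geu: float, krt7=False, krt20=False, chga=False, evaluable=True) -> ExpressionPanel:
    return ExpressionPanel(ceacam5_geu=geu, krt7_expressed=krt7, krt20_expressed=krt20,
                           chga_overexpressed=chga, evaluable=evaluable)


def _arms(*specs: Tuple[str, AlterationType]) -> Tuple[ChromosomalAlteration, ...]:
    return tuple(ChromosomalAlteration(arm=a, alteration_type=t) for a, t in specs)


_LOSS = AlterationType.LOSS
_LOH = AlterationType.LOH


# ---------------------------------------------------------------------------
# stochastic generator

def generate_cohort(spec: Optional[CohortSpec] = None, seed: int = 0) -> List[SpecimenProfile]:
    """Draw one cohort from ``spec``; reproducible given ``seed``."""
    spec = spec or default_cohort_spec()
    spec.validate()
    rng = np.random.default_rng(seed)
    specimens: List[SpecimenProfile] = []
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"S-{counter[0]:03d}"

    def bern(p: float) -> bool:
        return bool(rng.random() < p)

    def sample_expression(driver_or_fusion: bool, chga: bool = False,
                          force_elevated: Optional[bool] = None) -> ExpressionPanel:
        if not bern(spec.p_expr_evaluable):
            return _expr(0.0, evaluable=False, chga=False)
        if force_elevated is None:
            p = spec.p_elevated_given_driver if driver_or_fusion else spec.p_elevated_given_no_driver
            elevated = bern(p)
        else:
            elevated = force_elevated
        if elevated:
            geu = float(rng.lognormal(spec.geu_log_mu, spec.geu_log_sigma))
            geu = max(geu, 201.0)
            krt7, krt20 = bern(spec.p_krt7), bern(spec.p_krt20)
            if not (krt7 or krt20):
                krt7 = True  # elevated cases always co-express KRT7 and/or KRT20
        else:
            geu = float(rng.uniform(0.0, 180.0))
            krt7, krt20 = bern(0.2), bern(0.1)
        return _expr(geu, krt7, krt20, chga=chga)

    def sample_arms(n: int, include_10q_loh: bool = False) -> tuple:
        pool = [a for a in _ARM_POOL if a != "10q"]
        chosen = list(rng.choice(pool, size=min(n, len(pool)), replace=False))
        out = [(a, _LOH if bern(0.3) else _LOSS) for a in chosen]
        if include_10q_loh:
            out.append(("10q", _LOH))
        return _arms(*out)

    def sample_clinical(an: Optional[bool], mucinous: bool,
                        cyto_pool: Optional[Cytopathology] = None,
                        size_cm: Optional[float] = None) -> ClinicalFeatures:
        # comparator rates reconstructed from the published comparator tables
        if an:
            wf, hrs, cyto_mal = bern(0.845), bern(0.567), bern(0.443)
        else:
            wf, hrs, cyto_mal = bern(0.576), False, bern(0.035)
        if cyto_pool is not None:
            cyto: Optional[Cytopathology] = cyto_pool
        elif cyto_mal:
            cyto = Cytopathology.ADENOCARCINOMA if bern(0.6) else Cytopathology.SUSPICIOUS_FOR_ADENOCARCINOMA
        else:
            cyto = rng.choice([None, Cytopathology.BENIGN, Cytopathology.ATYPICAL,
                               Cytopathology.NONDIAGNOSTIC])
        visc = (bern(0.714) if mucinous else bern(0.036)) if bern(0.8) else None
        cea = (bern(0.75) if mucinous else bern(0.06)) if bern(0.7) else None
        size = size_cm if size_cm is not None else float(rng.uniform(1.0, 5.0) if wf else rng.uniform(0.8, 2.9))
        if wf and size < 3.0:
            size = 3.0 + float(rng.uniform(0.0, 2.0))
        return ClinicalFeatures(
            cyst_size_cm=round(size, 1),
            main_duct_mm=12.0 if (hrs and not cyto_mal) else 3.0,
            cytopathology=cyto,
            fluid_viscosity_increased=visc,
            cea_elevated=cea,
        )

    # ---- mucinous cysts ---------------------------------------------------
    for ht, total in spec.diagnosis_counts.items():
        if ht not in (_HT.IPMN, _HT.MCN, _HT.IOPN, _HT.ITPN):
            continue
        n_an = spec.advanced_counts.get(ht, 0)
        for i in range(total):
            an = i < n_an
            grade = (Grade.PDAC if (an and bern(71 / 97)) else
                     Grade.HIGH_GRADE_DYSPLASIA) if an else Grade.LOW_GRADE
            variants: List[GenomicVariant] = []
            fusions: List[FusionTranscript] = []
            arms: tuple = ()

            if ht is _HT.IOPN:
                g3 = "PRKACA" if bern(2 / 3) else "PRKACB"
                fusions.append(FusionTranscript(gene_5prime="DNAJB1", gene_3prime=g3))
                driverish = True
            else:
                driver = bern(spec.p_dna_driver)
                if driver:
                    cats, ps = zip(*spec.driver_composition.items())
                    cat = rng.choice(cats, p=np.asarray(ps) / sum(ps))
                    if "kras" in cat:
                        variants.append(_var("KRAS", desc="p.G12D"))
                        if ht is _HT.IPMN and bern(spec.p_multi_kras):
                            variants.append(_var("KRAS", desc="p.G12V"))
                    if "gnas" in cat:
                        variants.append(_var("GNAS", desc="p.R201C"))
                    if cat == "braf":
                        variants.append(_var("BRAF", desc="p.V600E"))
                    if bern(spec.p_rnf43_given_driver):
                        variants.append(_var("RNF43", VariantClass.NONSENSE, Tier.II))
                    p_an_gene = (spec.p_an_gene_given_driver_an if an
                                 else spec.p_an_gene_given_driver_lg)
                    if bern(p_an_gene):
                        genes, ws = zip(*spec.an_gene_weights.items())
                        g = rng.choice(genes, p=np.asarray(ws) / sum(ws))
                        variants.append(_var(str(g)))
                elif bern(spec.p_fusion_given_no_driver):
                    if bern(0.6):
                        fusions.append(FusionTranscript(gene_5prime="SND1", gene_3prime="BRAF"))
                    else:
                        fusions.append(FusionTranscript(gene_5prime="ETV6", gene_3prime="NTRK3"))
                if bern(spec.p_cdkn2a_an if an else spec.p_cdkn2a_lg):
                    variants.append(_var("CDKN2A", VariantClass.FRAMESHIFT))
                if bern(spec.p_ctnnb1_an if an else spec.p_ctnnb1_lg):
                    variants.append(_var("CTNNB1", desc="p.S33C"))
                if an and bern(spec.p_chrom_given_an):
                    arms = sample_arms(1 + int(rng.poisson(0.9)))
                driverish = driver or bool(fusions)

            expr = sample_expression(driverish)
            specimens.append(SpecimenProfile(
                specimen_id=next_id(), variants=tuple(variants), fusions=tuple(fusions),
                chromosomal_alterations=arms, expression=expr,
                clinical=sample_clinical(an, mucinous=True),
                reference=ReferenceDiagnosis(histologic_type=ht, grade=grade),
            ))

    # ---- nonmucinous cysts ------------------------------------------------
    n_sca = spec.diagnosis_counts.get(_HT.SCA, 0)
    for i in range(n_sca):
        vhl = bern(spec.p_vhl_sca)
        variants = [_var("VHL", VariantClass.FRAMESHIFT)] if vhl else []
        expr = sample_expression(False, force_elevated=bern(spec.p_sca_elevated_expr))
        specimens.append(SpecimenProfile(
            specimen_id=next_id(), variants=tuple(variants), expression=expr,
            clinical=sample_clinical(None, mucinous=False,
                                     cyto_pool=Cytopathology.SEROUS if i == 0 else None),
            reference=ReferenceDiagnosis(_HT.SCA, Grade.NOT_APPLICABLE),
        ))

    n_net = spec.diagnosis_counts.get(_HT.CPANNET, 0)
    followup = min(spec.n_pannet_followup, n_net)
    for i in range(n_net):
        chga = bern(spec.p_chga_pannet)
        variants = [_var("MEN1", VariantClass.NONSENSE)] if (chga and bern(spec.p_men1_given_chga)) else []
        if i < spec.n_pannet_metastatic:
            met: Optional[bool] = True
            arms = sample_arms(3, include_10q_loh=True)
            size = 2.5 if bern(spec.p_size_gt2_met) else 1.6
        elif i < followup:
            met = False
            if bern(spec.p_ge3_arms_nonmet):
                arms = sample_arms(2, include_10q_loh=bern(spec.p_10q_given_ge3_nonmet))
                if len(arms) < 3:
                    arms = sample_arms(3)
            else:
                arms = sample_arms(1) if bern(0.2) else ()
            size = 2.6 if bern(spec.p_size_gt2_nonmet) else 1.4
        else:
            met = None
            arms = sample_arms(2) if bern(0.5) else ()
            size = 1.8
        expr = sample_expression(False, chga=chga, force_elevated=bern(0.03))
        specimens.append(SpecimenProfile(
            specimen_id=next_id(), variants=tuple(variants),
            chromosomal_alterations=arms, expression=expr,
            clinical=sample_clinical(None, mucinous=False, size_cm=size,
                                     cyto_pool=Cytopathology.NEUROENDOCRINE if bern(6 / 36) else None),
            reference=ReferenceDiagnosis(_HT.CPANNET, Grade.NOT_APPLICABLE,
                                         distant_metastasis=met),
        ))

    other = [
        (_HT.MIXED_SCA_NET, dict(chga=True)),
        (_HT.CYSTIC_SCHWANNOMA, dict(elevated=True)),
        (_HT.CYSTIC_ACC, dict(elevated=True)),
        (_HT.PARAGANGLIOMA, dict(chga=True)),
        (_HT.PSEUDOCYST, dict()),
    ]
    for ht, kw in other:
        for _ in range(spec.diagnosis_counts.get(ht, 0)):
            elevated = kw.get("elevated", False) and bern(spec.p_nonmuc_other_elevated)
            expr = sample_expression(False, chga=kw.get("chga", False),
                                     force_elevated=elevated)
            specimens.append(SpecimenProfile(
                specimen_id=next_id(), expression=expr,
                clinical=sample_clinical(None, mucinous=False),
                reference=ReferenceDiagnosis(ht, Grade.NOT_APPLICABLE),
            ))

    _check_constraints(specimens)
    return validate_cohort(specimens)


def _check_constraints(specimens: List[SpecimenProfile]) -> None:
    """Exclusivity constraints that must hold in every generated specimen."""
    from .models import MUCINOUS_TYPES

    for s in specimens:
        genes = {v.gene for v in s.variants}
        r = s.reference
        if r is None:
            continue
        mucinous = r.histologic_type in MUCINOUS_TYPES
        if genes & {"KRAS", "GNAS", "BRAF"}:
            assert mucinous, f"{s.specimen_id}: MAPK driver in nonmucinous cyst"
            assert not (genes & {"VHL", "MEN1"}), \
                f"{s.specimen_id}: VHL/MEN1 co-occurring with MAPK driver"
        if s.chromosomal_alterations:
            assert (r.is_advanced_neoplasia
                    or r.histologic_type is _HT.CPANNET), \
                f"{s.specimen_id}: chromosomal alteration outside AN mucinous/cPanNET"
        if s.expression is not None and s.expression.evaluable and s.expression.chga_overexpressed:
            assert not mucinous, f"{s.specimen_id}: CHGA overexpression in mucinous cyst"


# ---------------------------------------------------------------------------
# deterministic reconstruction cohort

def fixture_cohort() -> List[SpecimenProfile]:
    """The deterministic 241-specimen reconstruction of the validation cohort.

    Every published 2x2 table is reproduced exactly when this cohort is run
    through the classifier and evaluators:

    * mucinous, full classifier:      (tp, fp, fn, tn) = (176, 2, 10, 53)
    * mucinous, DNA-only mode:        (164, 0, 22, 55)
    * advanced neoplasia, full:       (84, 3, 13, 141)
    * advanced neoplasia, DNA-only:   (78, 3, 19, 141)
    * serous cystadenoma:             (10, 0, 2, 229)
    * neuroendocrine-type:            (35, 0, 1, 205)
    * cytopathology, NET comparator:  (6, 0, 30, 205)
    * cPanNET metastasis, >=3 arms:   (3, 10, 0, 18)
    * cPanNET metastasis, 10q LOH:    (3, 3, 0, 25)
    * cPanNET metastasis, >2.0 cm:    (2, 10, 1, 18)
    """
    specimens: List[SpecimenProfile] = []
    counter = [0]

    def add(variants=(), fusions=(), arms=(), expr=None, clinical=None, ref=None):
        counter[0] += 1
        specimens.append(SpecimenProfile(
            specimen_id=f"F-{counter[0]:03d}", variants=tuple(variants),
            fusions=tuple(fusions), chromosomal_alterations=tuple(arms),
            expression=expr, clinical=clinical, reference=ref,
        ))

    def geu_hi(i: int) -> float:
        # deterministic right-skewed spread of elevated GEU values
        vals = [181423.0, 2269.0, 9611.0, 460.0, 1200.0, 3800.0, 25000.0, 730.0]
        return vals[i % len(vals)] + 7.0 * i

    def geu_lo(i: int) -> float:
        return float((i * 37) % 180)

    def muc_clin(i_an: Optional[int], i_lg: Optional[int],
                 cyto: Optional[Cytopathology] = None,
                 viscosity: Optional[bool] = None,
                 cea: Optional[bool] = None) -> ClinicalFeatures:
        """Clinical features for mucinous cysts; indices select the
        comparator positives (worrisome features 82/97 AN vs 83/144 non-AN;
        high-risk stigmata 55/97 vs 5/144; malignant cytology 43/97 vs 5/144)."""
        if i_an is not None:
            wf, hrs, mal = i_an < 82, i_an < 55, i_an < 43
        else:
            wf, hrs, mal = (i_lg or 0) < 83, False, False
        if cyto is None:
            if mal:
                cyto = (Cytopathology.ADENOCARCINOMA if (i_an or 0) % 2 == 0
                        else Cytopathology.SUSPICIOUS_FOR_ADENOCARCINOMA)
            else:
                cyto = (Cytopathology.ATYPICAL if ((i_an if i_an is not None else i_lg) or 0) % 2
                        else Cytopathology.BENIGN)
        return ClinicalFeatures(
            cyst_size_cm=3.4 if wf else 2.1,
            main_duct_mm=12.0 if (hrs and not mal) else 3.0,
            cytopathology=cyto,
            fluid_viscosity_increased=viscosity,
            cea_elevated=cea,
        )

    an_idx = [0]   # running index over advanced-neoplasia mucinous cysts
    lg_idx = [0]   # running index over all non-AN specimens
    muc_idx = [0]  # running index over mucinous cysts (viscosity/CEA subsets)

    def next_muc_clin(an: bool, cyto=None):
        i = muc_idx[0]
        muc_idx[0] += 1
        viscosity = (i < 100) if i < 140 else None   # 100/140 measured positive
        cea = (i < 94) if i < 120 else None          # 94/120 measured positive
        if an:
            c = muc_clin(an_idx[0], None, cyto=cyto, viscosity=viscosity, cea=cea)
            an_idx[0] += 1
        else:
            c = muc_clin(None, lg_idx[0], cyto=cyto, viscosity=viscosity, cea=cea)
            lg_idx[0] += 1
        return c

    def ref_muc(ht: HistologicType, grade: Grade) -> ReferenceDiagnosis:
        return ReferenceDiagnosis(histologic_type=ht, grade=grade)

    HGD, PDAC, LG = Grade.HIGH_GRADE_DYSPLASIA, Grade.PDAC, Grade.LOW_GRADE
    ei = [0]  # elevated-GEU counter for value variety

    def hi_expr(krt20=False) -> ExpressionPanel:
        ei[0] += 1
        return _expr(geu_hi(ei[0]), krt7=not krt20, krt20=krt20)

    # -- group 1: IOPN, PRKACA/B fusions, universally advanced (3) ----------
    for i, g3 in enumerate(["PRKACA", "PRKACA", "PRKACB"]):
        add(fusions=[FusionTranscript(gene_5prime="DNAJB1", gene_3prime=g3)],
            expr=hi_expr(), clinical=next_muc_clin(an=True),
            ref=ref_muc(_HT.IOPN, HGD))

    # -- group 2: AN mucinous, driver + advanced-neoplasia gene (78) ---------
    #    55x KRAS+TP53, 10x KRAS+SMAD4, 5x GNAS+TP53+SMAD4, 3x KRAS+PIK3CA,
    #    2x KRAS+PTEN, 3x KRAS+TP53+CDKN2A; first 45 also carry arm losses
    #    (first 39 of those two arms, the next 6 one arm).
    combos = ([("KRAS", "TP53")] * 55 + [("KRAS", "SMAD4")] * 10
              + [("GNAS", "TP53", "SMAD4")] * 5 + [("KRAS", "PIK3CA")] * 3
              + [("KRAS", "PTEN")] * 2 + [("KRAS", "TP53", "CDKN2A")] * 3)
    arm_cycle = [("6q", _LOSS), ("3p", _LOSS), ("22q", _LOH), ("6p", _LOSS),
                 ("17p", _LOH), ("9p", _LOSS)]
    for i, genes in enumerate(combos):
        variants = [_var(g, VariantClass.FRAMESHIFT if g in ("SMAD4", "CDKN2A")
                         else VariantClass.MISSENSE) for g in genes]
        if i % 6 == 0:
            variants.append(_var("RNF43", VariantClass.NONSENSE, Tier.II))
        if i < 39:
            arms = _arms(arm_cycle[i % 6], arm_cycle[(i + 2) % 6])
        elif i < 45:
            arms = _arms(arm_cycle[i % 6])
        else:
            arms = ()
        # histology: first 70 IPMN, then 5 MCN, 1 ITPN, last 2 IPMN
        if i < 70:
            ht = _HT.IPMN
        elif i < 75:
            ht = _HT.MCN
        elif i == 75:
            ht = _HT.ITPN
        else:
            ht = _HT.IPMN
        grade = PDAC if i < 71 else HGD
        add(variants=variants, arms=arms, expr=hi_expr(krt20=i % 3 == 0),
            clinical=next_muc_clin(an=True), ref=ref_muc(ht, grade))

    # -- group 3: AN mucinous, driver + chromosomal alterations only (3) -----
    for i in range(3):
        add(variants=[_var("KRAS", desc="p.G12V")],
            arms=_arms(("6p", _LOSS), ("17p", _LOH)),
            expr=hi_expr(), clinical=next_muc_clin(an=True),
            ref=ref_muc(_HT.IPMN, HGD))

    # -- group 4: AN mucinous, driver + CTNNB1/CDKN2A only (7; base-rule FN) --
    ext = [("CTNNB1", VariantClass.MISSENSE)] * 2 + [("CDKN2A", VariantClass.FRAMESHIFT)] * 5
    for gene, vc in ext:
        add(variants=[_var("KRAS", desc="p.G12D"), _var(gene, vc)],
            expr=hi_expr(), clinical=next_muc_clin(an=True),
            ref=ref_muc(_HT.IPMN, HGD))

    # -- group 5: AN mucinous, driver only (4; risk-rule FN) ------------------
    for i in range(4):
        add(variants=[_var("KRAS", desc="p.G12R")], expr=hi_expr(),
            clinical=next_muc_clin(an=True), ref=ref_muc(_HT.IPMN, HGD))

    # -- group 6: AN mucinous, marker-silent (2; FN for both calls) ----------
    for i in range(2):
        add(expr=_expr(geu_lo(i + 1)), clinical=next_muc_clin(an=True),
            ref=ref_muc(_HT.IPMN, HGD))

    # -- group 7: low-grade mucinous, driver + TP53 (3; AN false positives) --
    for i in range(3):
        add(variants=[_var("KRAS", desc="p.G12D"), _var("TP53")], expr=hi_expr(),
            clinical=next_muc_clin(an=False, cyto=Cytopathology.SUSPICIOUS_FOR_ADENOCARCINOMA),
            ref=ref_muc(_HT.IPMN, LG))

    # -- group 8: low-grade mucinous, driver + CTNNB1/CDKN2A (4; ext-rule FP) -
    ext_lg = [("CTNNB1", VariantClass.MISSENSE)] + [("CDKN2A", VariantClass.FRAMESHIFT)] * 3
    for j, (gene, vc) in enumerate(ext_lg):
        cyto = Cytopathology.SUSPICIOUS_FOR_ADENOCARCINOMA if j < 2 else None
        add(variants=[_var("KRAS", desc="p.G12V"), _var(gene, vc)], expr=hi_expr(),
            clinical=next_muc_clin(an=False, cyto=cyto), ref=ref_muc(_HT.IPMN, LG))

    # -- group 9: low-grade mucinous, driver only (65) ------------------------
    #    expression: first 30 elevated, next 11 low, last 24 non-evaluable
    for i in range(65):
        if i < 40:
            variants = [_var("KRAS", desc="p.G12D")]
            if i % 5 == 0:
                variants.append(_var("RNF43", VariantClass.FRAMESHIFT, Tier.II))
            if i % 16 == 0:
                variants.append(_var("KRAS", desc="p.G12V"))  # multi-KRAS (IPMN)
        elif i < 55:
            variants = [_var("GNAS", desc="p.R201C")]
        elif i < 63:
            variants = [_var("KRAS", desc="p.G12D"), _var("GNAS", desc="p.R201H")]
        else:
            variants = [_var("BRAF", desc="p.V600E")]
        if i < 30:
            expr = hi_expr(krt20=i % 4 == 0)
        elif i < 41:
            expr = _expr(geu_lo(i))
        else:
            expr = _expr(0.0, evaluable=False)
        ht = _HT.MCN if i >= 52 else _HT.IPMN  # 13 MCNs among low-grade
        add(variants=variants, expr=expr, clinical=next_muc_clin(an=False),
            ref=ref_muc(ht, LG))

    # -- group 10: low-grade KRAS-wild-type IPMNs with rescue fusions (3) -----
    for f in [FusionTranscript(gene_5prime="SND1", gene_3prime="BRAF"),
              FusionTranscript(gene_5prime="AGK", gene_3prime="BRAF"),
              FusionTranscript(gene_5prime="ETV6", gene_3prime="NTRK3")]:
        add(fusions=[f], expr=hi_expr(), clinical=next_muc_clin(an=False),
            ref=ref_muc(_HT.IPMN, LG))

    # -- group 11: low-grade mucinous, expression signal only (6) -------------
    for i in range(6):
        add(expr=hi_expr(krt20=i % 2 == 0), clinical=next_muc_clin(an=False),
            ref=ref_muc(_HT.IPMN, LG))

    # -- group 12: low-grade mucinous, marker-silent (8) ----------------------
    for i in range(8):
        add(expr=_expr(geu_lo(i + 3)), clinical=next_muc_clin(an=False),
            ref=ref_muc(_HT.IPMN, LG))

    # ---- nonmucinous --------------------------------------------------------
    def nonmuc_clin(cyto: Optional[Cytopathology] = None,
                    size_cm: float = 1.8) -> ClinicalFeatures:
        i = lg_idx[0]
        lg_idx[0] += 1
        return ClinicalFeatures(
            cyst_size_cm=3.4 if i < 83 else size_cm if size_cm < 3.0 else 2.9,
            main_duct_mm=3.0, cytopathology=cyto or Cytopathology.BENIGN,
            fluid_viscosity_increased=False, cea_elevated=False,
        )

    def nonmuc_clin_sized(size_cm: float, cyto=None) -> ClinicalFeatures:
        lg_idx[0] += 1
        return ClinicalFeatures(cyst_size_cm=size_cm, main_duct_mm=3.0,
                                cytopathology=cyto or Cytopathology.BENIGN,
                                fluid_viscosity_increased=False, cea_elevated=False)

    ref_nm = lambda ht, met=None: ReferenceDiagnosis(ht, Grade.NOT_APPLICABLE,
                                                     distant_metastasis=met)

    # -- SCAs (12): 10 VHL-positive (one also CEACAM5/KRT-elevated),
    #    1 TP53 + hTERT promoter, 1 marker-silent
    for i in range(10):
        expr = hi_expr() if i == 0 else _expr(geu_lo(i))
        cyto = Cytopathology.SEROUS if i == 1 else None
        add(variants=[_var("VHL", VariantClass.FRAMESHIFT)], expr=expr,
            clinical=nonmuc_clin(cyto=cyto), ref=ref_nm(_HT.SCA))
    add(variants=[_var("TP53"), _var("TERT", VariantClass.PROMOTER, Tier.II)],
        expr=_expr(geu_lo(4)), clinical=nonmuc_clin(), ref=ref_nm(_HT.SCA))
    add(expr=_expr(geu_lo(5)), clinical=nonmuc_clin(), ref=ref_nm(_HT.SCA))

    # -- cystic PanNETs (34) --------------------------------------------------
    def net_expr(i: int, chga: bool, elevated: bool = False) -> ExpressionPanel:
        if elevated:
            ei[0] += 1
            return _expr(geu_hi(ei[0]), krt7=True, chga=chga)
        return _expr(geu_lo(i), chga=chga)

    # 3 metastatic: 10q LOH plus >= 3 altered arms; sizes 2.5, 2.4, 1.8 cm
    met_sizes = [2.5, 2.4, 1.8]
    for i in range(3):
        add(variants=[_var("MEN1", VariantClass.NONSENSE)] if i == 0 else [],
            arms=_arms(("10q", _LOH), ("3p", _LOSS), ("6q", _LOSS), ("11q", _LOH)),
            expr=net_expr(i, chga=True),
            clinical=nonmuc_clin_sized(met_sizes[i],
                                       cyto=Cytopathology.NEUROENDOCRINE if i == 0 else None),
            ref=ref_nm(_HT.CPANNET, met=True))
    # 28 without metastasis: 3 with 10q LOH (>=3 arms), 7 with 3 arms no 10q,
    # 18 with no arms; 10 of 28 measure > 2.0 cm (the arm-positive ones)
    for i in range(28):
        if i < 3:
            arms = _arms(("10q", _LOH), ("22q", _LOSS), ("6p", _LOSS))
        elif i < 10:
            arms = _arms(("3p", _LOSS), ("6q", _LOSS), ("1p", _LOSS))
        else:
            arms = ()
        men1 = i in (0, 3, 4, 11, 12)  # 5 more MEN1 carriers
        chga = i != 27                 # the last one is the CHGA-negative NET (call FN)
        cyto = Cytopathology.NEUROENDOCRINE if i in (0, 3, 11, 15, 20) else None
        add(variants=[_var("MEN1", VariantClass.NONSENSE)] if men1 else [],
            arms=arms, expr=net_expr(i, chga=chga, elevated=(i == 5)),
            clinical=nonmuc_clin_sized(2.6 if i < 10 else 1.4, cyto=cyto),
            ref=ref_nm(_HT.CPANNET, met=False))
    # 3 without follow-up (metastasis status unknown)
    for i in range(3):
        add(variants=[_var("MEN1", VariantClass.NONSENSE)] if i == 0 else [],
            arms=_arms(("6q", _LOSS), ("18q", _LOSS)),
            expr=net_expr(i, chga=True),
            clinical=nonmuc_clin_sized(1.5), ref=ref_nm(_HT.CPANNET, met=None))

    # -- remaining nonmucinous ------------------------------------------------
    add(expr=net_expr(0, chga=True), clinical=nonmuc_clin(),
        ref=ref_nm(_HT.MIXED_SCA_NET))                       # mixed SCA-NET
    add(expr=net_expr(1, chga=True), clinical=nonmuc_clin(),
        ref=ref_nm(_HT.PARAGANGLIOMA))                       # paraganglioma
    add(expr=hi_expr(), clinical=nonmuc_clin(),
        ref=ref_nm(_HT.CYSTIC_SCHWANNOMA))                   # mucinous FP 1
    add(expr=hi_expr(krt20=True), clinical=nonmuc_clin(),
        ref=ref_nm(_HT.CYSTIC_ACC))                          # mucinous FP 2
    for i in range(5):
        expr = _expr(0.0, evaluable=False) if i < 2 else _expr(geu_lo(i))
        add(expr=expr, clinical=nonmuc_clin(), ref=ref_nm(_HT.PSEUDOCYST))

    assert counter[0] == 241, f"fixture has {counter[0]} specimens, expected 241"
    return validate_cohort(specimens)
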