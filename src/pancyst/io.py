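"""Cohort exchange formats: JSON ("pancyst-cohort/1") and a flat TSV dialect.

JSON is the canonical nested form. The TSV dialect packs list-valued
evidence into one cell per class using ``;`` between records and ``:``
between fields, e.g. ``KRAS:missense:I;TP53:missense:I`` for variants and
``10q:LOH;3p:loss`` for chromosomal alterations. Separators may not occur
inside tokens. Both formats round-trip losslessly through
:func:`write_cohort` / :func:`read_cohort`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict
from pathlib import Path
from typing import List, Optional

from .models import (
    ChromosomalAlteration,
    ClinicalFeatures,
    Cytopathology,
    ExpressionPanel,
    FusionTranscript,
    GenomicVariant,
    ReferenceDiagnosis,
    SpecimenProfile,
    validate_cohort,
)

SCHEMA_VERSION = "pancyst-cohort/1"

__all__ = ["read_cohort", "write_cohort", "SCHEMA_VERSION"]


class CohortFormatError(ValueError):
    """Raised when a cohort file is malformed; names specimen and field."""


# ---------------------------------------------------------------------------
# value helpers

def _fmt_opt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return "true" if x else "false"
    if isinstance(x, float) and x == int(x):
        return str(int(x))
    return str(x)


def _parse_opt_float(s: str) -> Optional[float]:
    return float(s) if s not in ("", None) else None


def _parse_opt_int(s: str) -> Optional[int]:
    return int(s) if s not in ("", None) else None


def _parse_bool(s, default=False) -> bool:
    if s in ("", None):
        return default
    if isinstance(s, bool):
        return s
    s = str(s).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _parse_tristate(s) -> Optional[bool]:
    if s in ("", None, "unknown"):
        return None
    return _parse_bool(s)


_SEPS = (";", ":")


def _check_token(tok: str, sid: str, field: str) -> str:
    for sep in _SEPS:
        if sep in tok:
            raise CohortFormatError(f"specimen {sid}: separator {sep!r} inside token in {field}")
    return tok


# ---------------------------------------------------------------------------
# dict <-> model (shared by JSON and TSV paths)

def _variant_to_dict(v: GenomicVariant) -> dict:
    d = {"gene": v.gene, "variant_class": v.variant_class.value, "tier": v.tier.value}
    if v.description is not None:
        d["description"] = v.description
    if v.allele_fraction is not None:
        d["allele_fraction"] = v.allele_fraction
    return d


def _specimen_to_dict(s: SpecimenProfile) -> dict:
    d: dict = {"specimen_id": s.specimen_id}
    d["variants"] = [_variant_to_dict(v) for v in s.variants]
    d["fusions"] = [
        {k: v for k, v in asdict(f).items() if v not in (None, "")} for f in s.fusions
    ]
    d["chromosomal_alterations"] = [
        {"arm": a.arm, "alteration_type": a.alteration_type.value}
        for a in s.chromosomal_alterations
    ]
    if s.expression is not None:
        d["expression"] = asdict(s.expression)
    if s.clinical is not None:
        c = asdict(s.clinical)
        if c["cytopathology"] is not None:
            c["cytopathology"] = s.clinical.cytopathology.value
        d["clinical"] = {k: v for k, v in c.items() if v is not None}
    if s.reference is not None:
        r = {
            "histologic_type": s.reference.histologic_type.value,
            "grade": s.reference.grade.value,
        }
        if s.reference.distant_metastasis is not None:
            r["distant_metastasis"] = s.reference.distant_metastasis
        d["reference"] = r
    return d


def _specimen_from_dict(d: dict) -> SpecimenProfile:
    sid = d.get("specimen_id", "<missing id>")
    try:
        variants = tuple(GenomicVariant(**v) for v in d.get("variants", []))
        fusions = tuple(FusionTranscript(**f) for f in d.get("fusions", []))
        arms = tuple(ChromosomalAlteration(**a) for a in d.get("chromosomal_alterations", []))
        expr = ExpressionPanel(**d["expression"]) if "expression" in d else None
        clin = ClinicalFeatures(**d["clinical"]) if "clinical" in d else None
        ref = ReferenceDiagnosis(**d["reference"]) if "reference" in d else None
        return SpecimenProfile(
            specimen_id=d["specimen_id"],
            variants=variants,
            fusions=fusions,
            chromosomal_alterations=arms,
            expression=expr,
            clinical=clin,
            reference=ref,
        )
    except (TypeError, ValueError, KeyError) as exc:
        raise CohortFormatError(f"specimen {sid}: {exc}") from exc


# ---------------------------------------------------------------------------
# TSV microformat

_TSV_COLUMNS = [
    "specimen_id",
    "variants",
    "fusions",
    "chromosomal_alterations",
    "expression_evaluable",
    "ceacam5_geu",
    "krt7_expressed",
    "krt20_expressed",
    "chga_overexpressed",
    "cyst_size_cm",
    "growth_mm_per_year",
    "cyst_wall_thickened_or_enhancing",
    "mural_nodule_present",
    "mural_nodule_enhancing",
    "mural_nodule_size_mm",
    "main_duct_mm",
    "abrupt_duct_caliber_change_with_atrophy",
    "lymphadenopathy",
    "ca19_9_elevated",
    "pancreatitis_attributable",
    "obstructive_jaundice_head_cyst",
    "cytopathology",
    "fluid_viscosity_increased",
    "cea_elevated",
    "histologic_type",
    "grade",
    "distant_metastasis",
]

_CLINICAL_BOOL_COLS = [
    "cyst_wall_thickened_or_enhancing",
    "mural_nodule_present",
    "mural_nodule_enhancing",
    "abrupt_duct_caliber_change_with_atrophy",
    "lymphadenopathy",
    "ca19_9_elevated",
    "pancreatitis_attributable",
    "obstructive_jaundice_head_cyst",
]


def _variants_cell(s: SpecimenProfile) -> str:
    toks = []
    for v in s.variants:
        fields = [v.gene, v.variant_class.value, v.tier.value,
                  _fmt_opt(v.description), _fmt_opt(v.allele_fraction)]
        while fields and fields[-1] == "":
            fields.pop()
        toks.append(":".join(_check_token(f, s.specimen_id, "variants") for f in fields))
    return ";".join(toks)


def _specimen_to_row(s: SpecimenProfile) -> dict:
    row = dict.fromkeys(_TSV_COLUMNS, "")
    row["specimen_id"] = s.specimen_id
    row["variants"] = _variants_cell(s)
    row["fusions"] = ";".join(
        ":".join(
            p for p in (f.gene_5prime, f.gene_3prime, _fmt_opt(f.supporting_reads))
        ).rstrip(":")
        for f in s.fusions
    )
    row["chromosomal_alterations"] = ";".join(
        f"{a.arm}:{a.alteration_type.value}" for a in s.chromosomal_alterations
    )
    if s.expression is not None:
        e = s.expression
        row["expression_evaluable"] = _fmt_opt(e.evaluable)
        row["ceacam5_geu"] = _fmt_opt(e.ceacam5_geu)
        row["krt7_expressed"] = _fmt_opt(e.krt7_expressed)
        row["krt20_expressed"] = _fmt_opt(e.krt20_expressed)
        row["chga_overexpressed"] = _fmt_opt(e.chga_overexpressed)
    if s.clinical is not None:
        c = s.clinical
        row["cyst_size_cm"] = _fmt_opt(c.cyst_size_cm)
        row["growth_mm_per_year"] = _fmt_opt(c.growth_mm_per_year)
        row["mural_nodule_size_mm"] = _fmt_opt(c.mural_nodule_size_mm)
        row["main_duct_mm"] = _fmt_opt(c.main_duct_mm)
        for col in _CLINICAL_BOOL_COLS:
            row[col] = _fmt_opt(getattr(c, col))
        row["cytopathology"] = c.cytopathology.value if c.cytopathology else ""
        row["fluid_viscosity_increased"] = _fmt_opt(c.fluid_viscosity_increased)
        row["cea_elevated"] = _fmt_opt(c.cea_elevated)
    if s.reference is not None:
        row["histologic_type"] = s.reference.histologic_type.value
        row["grade"] = s.reference.grade.value
        row["distant_metastasis"] = _fmt_opt(s.reference.distant_metastasis)
    return row


def _parse_variants_cell(cell: str) -> list:
    out = []
    for tok in filter(None, cell.split(";")):
        parts = tok.split(":")
        if len(parts) < 3:
            raise ValueError(f"variant token needs gene:class:tier, got {tok!r}")
        gene, vclass, tier = parts[:3]
        desc = parts[3] if len(parts) > 3 and parts[3] != "" else None
        af = _parse_opt_float(parts[4]) if len(parts) > 4 else None
        out.append(GenomicVariant(gene=gene, variant_class=vclass, tier=tier,
                                  description=desc, allele_fraction=af))
    return out


def _specimen_from_row(row: dict) -> SpecimenProfile:
    sid = row.get("specimen_id", "<missing id>")
    try:
        variants = _parse_variants_cell(row.get("variants", ""))
        fusions = []
        for tok in filter(None, row.get("fusions", "").split(";")):
            parts = tok.split(":")
            fusions.append(
                FusionTranscript(
                    gene_5prime=parts[0],
                    gene_3prime=parts[1] if len(parts) > 1 else "",
                    supporting_reads=_parse_opt_int(parts[2]) if len(parts) > 2 else None,
                )
            )
        arms = []
        for tok in filter(None, row.get("chromosomal_alterations", "").split(";")):
            arm, _, atype = tok.partition(":")
            arms.append(ChromosomalAlteration(arm=arm, alteration_type=atype))

        expr = None
        if row.get("expression_evaluable", "") != "":
            expr = ExpressionPanel(
                evaluable=_parse_bool(row["expression_evaluable"]),
                ceacam5_geu=_parse_opt_float(row.get("ceacam5_geu", "")) or 0.0,
                krt7_expressed=_parse_bool(row.get("krt7_expressed", "")),
                krt20_expressed=_parse_bool(row.get("krt20_expressed", "")),
                chga_overexpressed=_parse_bool(row.get("chga_overexpressed", "")),
            )
        clin = None
        clinical_cols = _TSV_COLUMNS[9:24]
        if any(row.get(c, "") != "" for c in clinical_cols):
            clin = ClinicalFeatures(
                cyst_size_cm=_parse_opt_float(row.get("cyst_size_cm", "")),
                growth_mm_per_year=_parse_opt_float(row.get("growth_mm_per_year", "")),
                mural_nodule_size_mm=_parse_opt_float(row.get("mural_nodule_size_mm", "")),
                main_duct_mm=_parse_opt_float(row.get("main_duct_mm", "")),
                cytopathology=row.get("cytopathology") or None,
                fluid_viscosity_increased=_parse_tristate(row.get("fluid_viscosity_increased", "")),
                cea_elevated=_parse_tristate(row.get("cea_elevated", "")),
                **{c: _parse_bool(row.get(c, "")) for c in _CLINICAL_BOOL_COLS},
            )
        ref = None
        if row.get("histologic_type", "") != "":
            ref = ReferenceDiagnosis(
                histologic_type=row["histologic_type"],
                grade=row["grade"],
                distant_metastasis=_parse_tristate(row.get("distant_metastasis", "")),
            )
        return SpecimenProfile(
            specimen_id=sid, variants=tuple(variants), fusions=tuple(fusions),
            chromosomal_alterations=tuple(arms), expression=expr, clinical=clin,
            reference=ref,
        )
    except (TypeError, ValueError, KeyError) as exc:
        if isinstance(exc, CohortFormatError):
            raise
        raise CohortFormatError(f"specimen {sid}: {exc}") from exc


# ---------------------------------------------------------------------------
# public API

def read_cohort(path, format: str = None) -> List[SpecimenProfile]:
    """Read and validate a cohort file (format inferred from suffix if omitted)."""
    path = Path(path)
    fmt = format or ("tsv" if path.suffix.lower() in (".tsv", ".txt") else "json")
    if fmt == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        if isinstance(doc, dict):
            records = doc.get("specimens", [])
        else:
            records = doc
        specimens = [_specimen_from_dict(d) for d in records]
    elif fmt == "tsv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            specimens = [_specimen_from_row(row) for row in reader]
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")
    return validate_cohort(specimens)


def write_cohort(specimens, path, format: str = None) -> None:
    """Write a validated cohort; output round-trips through :func:`read_cohort`."""
    specimens = validate_cohort(specimens)
    path = Path(path)
    fmt = format or ("tsv" if path.suffix.lower() in (".tsv", ".txt") else "json")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        doc = {"schema": SCHEMA_VERSION, "specimens": [_specimen_to_dict(s) for s in specimens]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
    elif fmt == "tsv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_TSV_COLUMNS, delimiter="\t")
            writer.writeheader()
            for s in specimens:
                writer.writerow(_specimen_to_row(s))
    else:
        raise ValueError(f"unknown cohort format {fmt!r}")
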