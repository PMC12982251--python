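"""Curated gene/variant-class tier map (AMP/ASCO/CAP tier I-III shortcut).

Full consensus-guideline evidence aggregation is out of scope: variants
arrive already tiered from the reporting pipeline, and this helper exists
for synthetic and ad-hoc inputs. The table maps (gene, variant class) and
a few named hotspots to tier I or II; anything unmatched falls back to
tier III (never IV). The table is configuration, not ground truth.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Mapping, Optional, Tuple

from .models import GenomicVariant, Tier, VariantClass

__all__ = ["DEFAULT_KNOWLEDGE_TABLE", "assign_tier"]

_M = VariantClass.MISSENSE
_N = VariantClass.NONSENSE
_F = VariantClass.FRAMESHIFT
_I = VariantClass.INFRAME_INDEL
_S = VariantClass.SPLICE
_P = VariantClass.PROMOTER

#: (gene, variant_class) -> tier. Genes with well-established hotspot or
#: truncating alterations in pancreatic cyst neoplasia are tier I; rarer or
#: potentially significant ones tier II.
DEFAULT_KNOWLEDGE_TABLE: Mapping[Tuple[str, VariantClass], Tier] = {
    ("KRAS", _M): Tier.I,
    ("GNAS", _M): Tier.I,
    ("BRAF", _M): Tier.I,
    ("BRAF", _I): Tier.I,
    ("TP53", _M): Tier.I,
    ("TP53", _N): Tier.I,
    ("TP53", _F): Tier.I,
    ("TP53", _S): Tier.I,
    ("SMAD4", _M): Tier.I,
    ("SMAD4", _N): Tier.I,
    ("SMAD4", _F): Tier.I,
    ("VHL", _M): Tier.I,
    ("VHL", _N): Tier.I,
    ("VHL", _F): Tier.I,
    ("CDKN2A", _M): Tier.I,
    ("CDKN2A", _N): Tier.I,
    ("CDKN2A", _F): Tier.I,
    ("RNF43", _N): Tier.II,
    ("RNF43", _F): Tier.II,
    ("RNF43", _M): Tier.II,
    ("MEN1", _M): Tier.I,
    ("MEN1", _N): Tier.I,
    ("MEN1", _F): Tier.I,
    ("CTNNB1", _M): Tier.I,
    ("PIK3CA", _M): Tier.I,
    ("PTEN", _M): Tier.II,
    ("PTEN", _N): Tier.II,
    ("PTEN", _F): Tier.II,
    ("STK11", _M): Tier.II,
    ("STK11", _N): Tier.II,
    ("TERT", _P): Tier.II,  # hTERT promoter
}

#: Named hotspots, matched against the free-text description when present.
DEFAULT_HOTSPOTS: Mapping[Tuple[str, str], Tier] = {
    ("KRAS", "p.G12D"): Tier.I,
    ("KRAS", "p.G12V"): Tier.I,
    ("KRAS", "p.G12R"): Tier.I,
    ("KRAS", "p.Q61H"): Tier.I,
    ("GNAS", "p.R201C"): Tier.I,
    ("GNAS", "p.R201H"): Tier.I,
    ("BRAF", "p.V600E"): Tier.I,
    ("CTNNB1", "p.S33C"): Tier.I,
    ("PIK3CA", "p.H1047R"): Tier.I,
}


def assign_tier(
    variant: GenomicVariant,
    knowledge_table: Optional[Mapping] = None,
    hotspots: Optional[Mapping] = None,
) -> GenomicVariant:
    """Return a copy of ``variant`` with its tier (re)assigned from the table.

    Hotspot entries take precedence over (gene, class) entries; anything
    unmatched becomes tier III. Unknown genes never raise.
    """
    table = DEFAULT_KNOWLEDGE_TABLE if knowledge_table is None else knowledge_table
    spots = DEFAULT_HOTSPOTS if hotspots is None else hotspots
    tier = None
    if variant.description:
        tier = spots.get((variant.gene, variant.description.strip()))
    if tier is None:
        tier = table.get((variant.gene, variant.variant_class))
    return replace(variant, tier=tier if tier is not None else Tier.III)
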