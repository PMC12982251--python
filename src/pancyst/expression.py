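"""RT-qPCR relative quantification and expression-derived classifier signals.

CEACAM5 mRNA abundance is expressed in gene expression units (GEU),
the 2^-ddCt relative quantity against an endogenous reference gene and a
calibrator sample:

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator)
    GEU  = 2 ** (-ddCt)

CEACAM5 is the mRNA correlate of cyst fluid CEA; the mucinous expression
signal requires CEACAM5 above threshold (default > 200 GEU, strict) with
co-expression of KRT7 and/or KRT20, the epithelial keratin pattern of
mucinous cyst lining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .models import ExpressionPanel

__all__ = [
    "QpcrMeasurement",
    "geu_from_ddct",
    "ceacam5_elevated",
    "mucinous_expression_signal",
    "CEACAM5_THRESHOLD_GEU",
]

#: Default CEACAM5 positivity threshold in gene expression units.
CEACAM5_THRESHOLD_GEU = 200.0


@dataclass(frozen=True)
class QpcrMeasurement:
    """Four raw Ct values for one target/reference/calibrator design."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_sample",
            "ct_reference_sample",
            "ct_target_calibrator",
            "ct_reference_calibrator",
        ):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative Ct, got {v}")


def geu_from_ddct(m: QpcrMeasurement) -> float:
    """Relative quantity 2^-ddCt in GEU; strictly positive, and monotone
    decreasing in the sample's target Ct."""
    ddct = (m.ct_target_sample - m.ct_reference_sample) - (
        m.ct_target_calibrator - m.ct_reference_calibrator
    )
    return 2.0 ** (-ddct)


def ceacam5_elevated(geu: float, threshold: float = CEACAM5_THRESHOLD_GEU) -> bool:
    """True iff CEACAM5 abundance is strictly above ``threshold`` GEU."""
    if not (geu >= 0):
        raise ValueError(f"geu must be >= 0, got {geu}")
    return geu > threshold


def mucinous_expression_signal(
    panel: ExpressionPanel, threshold: float = CEACAM5_THRESHOLD_GEU
) -> bool:
    """CEACAM5 elevated AND KRT7 and/or KRT20 co-expressed.

    Callers must gate on ``panel.evaluable``; a non-evaluable panel raises.
    """
    if not panel.evaluable:
        raise ValueError("expression panel is not evaluable; gate on panel.evaluable")
    return ceacam5_elevated(panel.ceacam5_geu, threshold) and (
        panel.krt7_expressed or panel.krt20_expressed
    )
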