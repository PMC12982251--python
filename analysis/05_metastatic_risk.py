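#!/usr/bin/env python
"""Metastatic-risk markers in cystic pancreatic neuroendocrine tumors.

Finding: among the 31 cystic PanNETs with follow-up (3 metastatic), 10q
LOH predicts distant metastasis with 100% sensitivity and 89.3%
specificity (Fisher p = 0.004), outperforming both the >=3-altered-arms
rule (specificity 64.3%) and the conventional >2.0 cm size criterion
(sensitivity 66.7%). Tables go to results/metastatic_risk.csv.
"""

from pathlib import Path

import pandas as pd

from pancyst import evaluate, fixture_cohort
from pancyst.modalities import modality_calls
from pancyst.stats import fisher_exact_2x2

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = fixture_cohort()
    rows = []
    for marker in ("chromosomal_ge3", "loh_10q", "size_gt_2cm"):
        t, m = evaluate(modality_calls(cohort, marker), cohort, "metastasis")
        rows.append({
            "marker": marker, "tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn,
            "sensitivity_pct": m.sensitivity.percent,
            "specificity_pct": m.specificity.percent,
            "npv_pct": m.npv.percent, "ppv_pct": m.ppv.percent,
            "accuracy_pct": m.accuracy.percent,
            "fisher_p": fisher_exact_2x2(t.tp, t.fn, t.fp, t.tn),
        })
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "metastatic_risk.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nwrote {RESULTS/'metastatic_risk.csv'}")


if __name__ == "__main__":
    main()
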