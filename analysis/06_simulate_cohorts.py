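#!/usr/bin/env python
"""Stochastic-cohort study: classifier performance across simulated cohorts.

Finding: over 20 independently simulated 241-specimen cohorts drawn under
the study conditions, mucinous-cyst sensitivity stays within a few points
of the reconstruction value (94.6%), and the generator's marker
frequencies track their specified prevalences. Summary goes to
results/simulation_summary.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pancyst import Ruleset, classify_cohort, evaluate
from pancyst.cohort import default_cohort_spec, generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
GENES = ("KRAS", "GNAS", "TP53", "VHL", "MEN1", "RNF43", "CDKN2A")


def main() -> None:
    spec = default_cohort_spec()
    rows = []
    for seed in range(20):
        cohort = generate_cohort(spec, seed=seed)
        calls = classify_cohort(cohort, Ruleset())
        _, m_muc = evaluate(calls, cohort, "mucinous")
        _, m_an = evaluate(calls, cohort, "advanced_neoplasia")
        row = {"seed": seed,
               "mucinous_sensitivity_pct": m_muc.sensitivity.percent,
               "mucinous_specificity_pct": m_muc.specificity.percent,
               "an_sensitivity_pct": m_an.sensitivity.percent,
               "an_specificity_pct": m_an.specificity.percent}
        genes_per_specimen = [{v.gene for v in s.variants} for s in cohort]
        for g in GENES:
            row[f"freq_{g}"] = np.mean([g in gs for gs in genes_per_specimen])
        rows.append(row)
    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "simulation_summary.csv", index=False)

    print("classifier performance over 20 simulated cohorts (mean [min, max]):")
    for col in ("mucinous_sensitivity_pct", "mucinous_specificity_pct",
                "an_sensitivity_pct", "an_specificity_pct"):
        print(f"  {col}: {df[col].mean():.1f} [{df[col].min():.1f}, {df[col].max():.1f}]")
    print("\nmarker frequencies, observed mean vs specified expectation:")
    for g in GENES:
        print(f"  {g}: {df[f'freq_{g}'].mean():.3f} vs {spec.expected_gene_fraction(g):.3f}")
    print(f"\nwrote {RESULTS/'simulation_summary.csv'}")


if __name__ == "__main__":
    main()
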