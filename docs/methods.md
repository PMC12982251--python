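# Methods

## The classification model

The classifier is deliberately a deterministic rule engine, not a fitted
model: each rule encodes an established genotype–phenotype association in
pancreatic cyst biology, and every positive call carries an evidence
trail of fired rule ids so a reviewer can audit the decision the way a
molecular pathology report would be audited.

Evidence enters the rules only after tier filtering: tier III (unknown
significance) and tier IV (benign) variants are never used. The engine
consumes tiers as input; `pancyst.tiers.assign_tier` is a convenience for
synthetic or ad-hoc data, mapping (gene, variant class) pairs and named
hotspots to tiers I/II with a tier-III fallback. Full consensus-guideline
evidence aggregation is out of scope, and the shipped table is
configuration, not ground truth.

Cyst-type precedence (R1→R7) embeds three substantive choices:

* **Neuroendocrine and serous markers override the expression signal**
  (R3/R4 above R5). *CEACAM5* elevation occurs in occasional nonmucinous
  lesions; among those, the *VHL*-mutant serous cystadenoma and the
  *CHGA*-overexpressing neuroendocrine tumor are correctly suppressed,
  leaving only truly marker-ambiguous lesions (in the reconstruction
  cohort, a cystic acinar cell carcinoma and a cystic schwannoma) as
  expression-driven mucinous false positives.
* **RNF43 alone does not call mucinous.** *RNF43* mutations co-occur with
  MAPK/PKA drivers in the large majority of carriers; a solo *RNF43*
  call would rest on an unsupported marker and lands in R6 instead.
* ***STK11* and *TERT*-promoter variants carry no weight** and are
  surfaced as "observed, uninformative" evidence. Multiple *KRAS*/*GNAS*
  mutations are recorded but attach to no decision.

Advanced-neoplasia positivity requires a mucinous call plus one of: an
IOPN-defining *PRKACA*/*PRKACB* fusion (IOPNs essentially always harbor
advanced neoplasia); a MAPK/PKA driver co-occurring with a mutation in
the risk gene set {*TP53*, *SMAD4*, *PIK3CA*, *PTEN*} (co-mutation
patterns that track high-grade dysplasia at ≥ 94%); or any arm-level
chromosomal alteration (low-grade mucinous cysts essentially never carry
them). *BRAF*/*NTRK3* rescue fusions alone do **not** trigger the risk
call — their carriers are typically low grade — but they do satisfy the
driver leg of the co-mutation rule. *CTNNB1* and *CDKN2A* are opt-in
extensions (`include_ctnnb1`, `include_cdkn2a`): they buy sensitivity at
a measurable specificity cost, and keeping them out of the default set
keeps the base classifier's near-perfect specificity.

Metastatic risk for neuroendocrine lesions is tiered: 10q LOH → high;
≥ 3 distinct altered arms → elevated; otherwise low. 10q LOH is checked
before the arm count, so a 10q-LOH lesion is always high regardless of
burden; the tiers are therefore monotone under added alterations.

The `legacy_dna_only` mode masks fusions, expression, and chromosomal
evidence before any rule fires, leaving tier-filtered mutations only.
Because DNA evidence is a strict subset of the full evidence, legacy
calls nest inside full-mode calls — a property the test suite checks on
random profiles — which is what makes the paired McNemar comparisons
one-sided in the discordance counts.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `ceacam5_threshold_geu` | 200 GEU | *CEACAM5* positivity, strict `>` |
| `advanced_neoplasia_genes` | TP53, SMAD4, PIK3CA, PTEN | co-mutation risk set |
| `include_ctnnb1` / `include_cdkn2a` | false | risk-set extensions |
| `use_chromosomal_alterations` | true | A3 rule on/off |
| `mode` | `gc` | `gc` or `legacy_dna_only` |

GEU are relative quantities from the 2^−ΔΔCt method; the reference gene
and calibrator are assay properties, so `geu_from_ddct` is generic over
them. *KRT7*/*KRT20* and *CHGA* are consumed as detected/overexpressed
flags because no numeric thresholds are defined for them.

## Statistics

All five accuracy metrics use Wilson score 95% intervals (bounds snapped
to exact 0/1 at the boundary counts). The AUC of a single-threshold
binary test is the trapezoidal area of its three-point ROC, identically
(sensitivity + specificity)/2. McNemar tests are the exact binomial form,
p = 2·P(X ≤ min(b, c)) with X ~ Binomial(b+c, ½) capped at 1 — the
chi-square approximation would not reproduce small-discordance p-values
like 2·(½)⁶ = 0.031. Fisher's exact test is two-sided by hypergeometric
enumeration (via scipy; an independent brute-force enumerator is the test
oracle). A paired DeLong test for two correlated binary-test AUCs is
included (placement-value covariance); it has no published anchor value
and is covered by property tests only. Predictive-value McNemar
comparisons are nonstandard; where used they are interpreted as
correct/incorrect McNemar restricted to the called class, and documented
as such.

Evaluation is complete-case per modality: a specimen with an unknown
result for a modality (unmeasured viscosity, missing cytology, no
metastasis follow-up) drops out of that modality's table only. Modality
OR-combination treats (unknown, negative) as negative and is only unknown
when both inputs are. Percentages are reported rounded half-up to one
decimal; AUC to three decimals.

Reported-rate reconstruction (`confusion_from_rates`) recovers the
integer 2×2 table behind published sensitivity/specificity via half-up
rounding of rate × group size; with the published group sizes the
rounding is unambiguous, which is what makes the whole analysis exactly
recomputable without the raw data.

One denominator choice matters: advanced-neoplasia specificity counts
**all** specimens without advanced neoplasia (low-grade mucinous plus
nonmucinous, 144 in the reconstruction), not low-grade mucinous only —
141/144 = 97.9% reproduces the published value where 87/89 would not.
Similarly, the "neuroendocrine-type" condition is defined here as
{cystic PanNET, mixed SCA-NET, paraganglioma}: the CHGA-expressing
paraganglioma belongs with the neuroendocrine lesions (and any other
assignment would break the published 100% specificity), while a
schwannoma is not a neuroendocrine neoplasm and is evaluated as a generic
nonmucinous lesion.

## The synthetic cohorts

`fixture_cohort()` is the deterministic reconstruction: 241 specimens
(IPMN 164, MCN 18, IOPN 3, ITPN 1; SCA 12, cPanNET 34, one each of mixed
SCA-NET, schwannoma, acinar cell carcinoma, paraganglioma; 5 pseudocysts
— the composition of the last 5 is an assumption, the rest is fixed by
published per-type counts). Marker assignments are chosen so that the
classifier output reproduces every published 2×2 table bit-exactly; the
docstring lists all ten tables. Identities not recoverable from published
counts (which histologies the 10 marker-silent mucinous cysts have, which
low-grade cysts carry the false-positive co-mutations) are assumptions
and are encoded once, deterministically.

`generate_cohort(spec, seed)` draws stochastic cohorts from a
`CohortSpec` whose defaults are the per-specimen rates implied by the
published counts (e.g. MAPK/PKA driver probability 164/183 among
non-IOPN mucinous cysts; *CEACAM5* elevation 0.957 given a driver and
0.375 given none, reproducing both the 87% mucinous marginal and the
observed rescue rate among driver-negative cysts; *VHL* in 10/12 SCAs;
*CHGA* in 33/34 cPanNETs). Elevated *CEACAM5* is log-normal with median
2269 GEU and σ = 1.70 (chosen so the mean ≈ 9600 GEU matches the heavy
right skew of the reported range). Biological exclusivity constraints are
enforced by construction and re-asserted after sampling: MAPK drivers
only in mucinous cysts, never with *VHL*/*MEN1*; *CHGA* only in
neuroendocrine-type lesions; chromosomal alterations only in
advanced-neoplasia mucinous cysts and cPanNETs; every elevated specimen
co-expresses *KRT7*/*KRT20*. `CohortSpec.expected_gene_fraction` gives
closed-form expected frequencies from the same parameters, which the
calibration tests compare against pooled Monte Carlo counts (exact
binomial 99% intervals over 20 seeds).

What the generator does **not** emulate: sequencing noise and allele
fractions, within-gene variant spectra beyond a few named hotspots,
longitudinal surveillance, correlations between clinical comparators and
specific genotypes beyond grade, and site effects. Passing tests on
generated cohorts therefore demonstrate that the rule engine and the
statistics behave correctly under the study's marker structure — not that
the classifier would achieve these operating characteristics on new
clinical material.

## Numerical choices and degenerate inputs

* *CEACAM5* "elevated" is strict `>` at 200 GEU; cyst growth is strict
  `>` 5 mm/year ("exceeding"); duct 5–9 mm and nodule ≥ 5 mm are
  inclusive at their printed bounds.
* Ratios with empty denominators are reported as absent (with a warning),
  never as 0; `binary_auc` refuses an empty class; `evaluate` refuses an
  empty evaluable set.
* Duplicate chromosome arms within a specimen are rejected at
  construction; arm counts are over distinct arms.
* Rounding of reported percentages is decimal half-up (banker's rounding
  would flip printed one-decimal values that end in 5).
* Problem sizes in the default test and reproduction runs: the
  241-specimen cohorts, 20 generator seeds, 10,000-draw coverage
  simulation, and 1,000 random profiles for the property checks — sizes
  at which every check runs in seconds while the binomial intervals are
  tight enough to detect a miscalibrated sampler.

## Known limitations

* The DNA-only legacy mode is defined operationally (full ruleset minus
  RNA/chromosomal evidence); the historical 22-gene panel's exact risk
  rule is not restated here.
* Low-level (subthreshold allele fraction) variants are not modeled;
  variants arrive already interpreted, and no VCF/coordinate handling is
  provided by design.
* The *CHGA* overexpression criterion is a boolean input; no numeric
  threshold is defined.
* ITPN has no dedicated molecular signature; ITPN specimens classify via
  the generic mucinous rules.
* The paraganglioma/schwannoma membership choice for the
  neuroendocrine-type condition (above) is the package's own definition.
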