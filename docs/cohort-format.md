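# Cohort exchange formats

Version: `pancyst-cohort/1`. Both formats are UTF-8 and round-trip
losslessly through `pancyst.io.read_cohort` / `write_cohort`.

## JSON

```json
{
 "schema": "pancyst-cohort/1",
 "specimens": [
  {
   "specimen_id": "P-001",
   "variants": [
    {"gene": "KRAS", "variant_class": "missense", "tier": "I",
     "description": "p.G12D", "allele_fraction": 0.32}
   ],
   "fusions": [{"gene_5prime": "DNAJB1", "gene_3prime": "PRKACA"}],
   "chromosomal_alterations": [{"arm": "10q", "alteration_type": "LOH"}],
   "expression": {"ceacam5_geu": 2269.0, "krt7_expressed": true,
                  "krt20_expressed": false, "chga_overexpressed": false,
                  "evaluable": true},
   "clinical": {"cyst_size_cm": 3.4, "main_duct_mm": 3.0,
                "cytopathology": "atypical",
                "fluid_viscosity_increased": true, "cea_elevated": false},
   "reference": {"histologic_type": "IPMN", "grade": "PDAC"}
  }
 ]
}
```

Optional sections (`expression`, `clinical`, `reference`) and optional
fields are omitted when absent. Tri-state fields
(`fluid_viscosity_increased`, `cea_elevated`, `distant_metastasis`) are
`true`/`false`/omitted, with omitted meaning "not measured". A
non-evaluable expression panel is kept with `"evaluable": false` rather
than dropped so per-modality denominators stay computable.

## TSV

One row per specimen, one column per scalar field (see the header
written by `write_cohort`). List-valued evidence packs into one cell per
class with `;` between records and `:` between fields:

* variants: `gene:class:tier[:description[:allele_fraction]]`, e.g.
  `KRAS:missense:I;TP53:missense:I` or `KRAS:missense:I:p.G12D:0.32`
* fusions: `gene5:gene3[:supporting_reads]`, e.g. `DNAJB1:PRKACA`
* chromosomal alterations: `arm:type`, e.g. `10q:LOH;3p:loss`

The separators `;` and `:` may not occur inside tokens (rejected on
write). Empty cells mean an empty list or a missing optional section;
tri-states serialise as `true`/`false`/empty.

## Validation

Reading validates every type invariant: gene symbols non-empty
(normalised to uppercase), allele fractions in [0, 1], arms of the form
`<chrom><p|q>` with chrom in 1–22/X/Y and no duplicate arm per specimen,
mucinous histologies with a dysplasia grade and nonmucinous ones with
`not_applicable`, unique specimen ids per cohort. Errors name the
specimen id and offending field. Gene symbols outside the classifier's
rule tables are preserved verbatim and ignored by the rules. There is no
VCF/BAM import: the classifier operates on gene-level interpreted calls,
not raw variants, and HGVS descriptions are free text.
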