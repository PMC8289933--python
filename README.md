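# mgp-triage

Triage of incidental findings from germline hereditary-cancer NGS
multi-gene panel (MGP) testing.

Blood-based panel testing assumes peripheral-blood-leukocyte (PBL) DNA
represents the germline, with a heterozygous variant expected near a 50%
allele fraction (AF). Sensitive NGS panels also surface findings that do
not fit: pathogenic variants at low AF, several pathogenic variants in one
patient, or a pathogenic *TP53* variant in a family without a Li-Fraumeni
phenotype (non-Chompret). Such results may instead reflect **clonal
hematopoiesis (CH)**, **post-zygotic mosaicism**, or a **hematologic
malignancy** — distinctions that change management completely: germline and
mosaic carriers need surveillance and family cascade testing, while
blood-restricted findings need CBC monitoring, hematology input, and
cardiovascular-risk follow-up, but are not transmissible.

This package implements that triage workflow for clinical genetics and
molecular diagnostics teams:

* **screen** — flag records fulfilling any inclusion category:
  (1) multiple pathogenic variants, (2) pathogenic variants at low blood
  AF, (3) pathogenic *TP53* without Chompret criteria (criteria are a
  configurable rule table);
* **tissue evidence** — grade AFs against the assay's heterozygous window
  (30–70%), detect blood contamination of direct skin biopsies
  (skin AF ≤ 0.5 x blood AF), rank tissues by reliability (cultured
  fibroblasts/muscle/buccal > tumour > direct skin), and track serial
  blood draws;
* **classify** — a deterministic first-match rule cascade assigning
  `FULL_GERMLINE`, `LIKELY_GERMLINE`, `MOSAIC`, `CONFIRMED_CH`,
  `LIKELY_CH`, or `HEME_MALIGNANCY_RELATED`, with an auditable evidence
  trail and follow-up recommendations per patient;
* **summarize** — cohort counts and fractions by conclusion, category,
  gene, chemotherapy exposure and tissue testing;
* **simulate** — synthetic cohorts with known etiologies and binomial
  read noise, plus confusion-matrix scoring of label-family recovery.

A 24-patient reference cohort (probands flagged on a 6060-test clinical
series, with per-tissue AFs, white-cell counts, chemotherapy exposure and
chart diagnoses) ships with the package: `load_fixture_cohort()`.

## Worked example

```python
from mgp_triage import load_fixture_cohort, run_pipeline, format_summary

cohort = load_fixture_cohort()          # 24 validated patient records
result = run_pipeline(cohort)           # screen -> evidence -> classify -> summarize

c41 = next(c for c in result.conclusions if c.patient_id == "41")
print(c41.primary_label.value)
for rule, why in c41.primary_variants[0].evidence:
    print(f"  {rule}: {why}")
```

prints

```
LIKELY_CH
  contra-tumour-negative: tumour trace (below 30% germline minimum)
  ch-likely-contradicted: apparently heterozygous blood AF 47.5% with evidence against germline origin and no germline confirmation
```

— patient 41's *TP53* variant sits at an apparently heterozygous 47.5% in
blood, but the breast tumour carries it at only 3.5% (admixed leukocytes),
so the cascade rejects a germline origin and concludes likely CH.

The cohort summary (`format_summary(result.summary, "fraction")`):

```
included patients: 24
-- primary classification --
full germline: 1/24
likely germline: 0/24
mosaic: 3/24
confirmed CH: 8/24
likely CH: 10/24
hematologic malignancy-related: 2/24
CH combined (confirmed + likely): 18/24
-- inclusion categories --
category 1: 4/24
category 2: 18/24
category 3: 17/24
...
chemotherapy among CH: 14/18
-- secondary tissue testing --
direct skin tested: 11/24
paired fibroblast culture: 7/11
blood-contamination pattern: 4/11
tumour tested: 3/24
```

Three quarters of the flagged cohort turns out to be clonal hematopoiesis
(confirmed or likely), most with prior chemotherapy; only one patient in
24 has a confirmed full germline syndrome.

The same stages are available from the shell:

```bash
mgp-triage fixture   --out cohort.json
mgp-triage screen    --patients cohort.json --out screen.tsv
mgp-triage classify  --patients cohort.json --out report.tsv --json conclusions.json
mgp-triage summarize --patients cohort.json --style percent_1dp
mgp-triage simulate  --n 500 --seed 7 --out sim.json --truth truth.json
```

Cohorts are read/written as a single JSON document or as three linked TSV
tables (patients / variants / observations); per-sample AFs can also be
ingested from a minimal VCF with `AD`/`DP` (or `AF`) FORMAT fields via
`ingest_vcf`.

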