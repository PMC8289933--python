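# Methods

## The clinical problem

Germline testing for hereditary cancer syndromes sequences DNA from
peripheral blood leukocytes (PBL) on a multi-gene panel, assuming blood
represents the constitutional genome. A monoallelic germline variant is
expected near a 50% allele fraction (AF). Panel sequencing at 500–1000x
routinely detects calls that do not fit that expectation: variants at low
AF, several pathogenic variants in one person, or a pathogenic *TP53*
variant in a family with no Li-Fraumeni phenotype. The alternative
explanations — clonal hematopoiesis (CH), post-zygotic mosaicism, or an
(occult) hematologic malignancy — have radically different consequences:
germline and mosaic variants demand surveillance and cascade testing of
relatives; blood-restricted variants do not, but carry their own
hematologic and cardiovascular follow-up.

`mgp_triage` encodes the full triage workflow as an auditable rule engine:
screen, grade multi-tissue evidence, classify, summarise.

## Inclusion screen

A patient record screens in when any of three categories fires on
pathogenic / likely pathogenic variants:

1. **Multiple variants** — at least two such variants detected in blood.
2. **Low allele fraction** — any blood draw of such a variant with a
   representative AF in `[category2_lower, category2_upper)` (defaults 1% and
   30%), or reported present-but-unquantified by the source laboratory.
   The lower bound defaults to the assay noise floor rather than a nominal
   10% so that reportable sub-10% calls (which clinical laboratories do
   issue) still screen in; a strict 10–30% band is one configuration change
   away.
3. **TP53 / non-Chompret** — a pathogenic *TP53* variant in a patient whose
   recorded personal and family history does not satisfy the Chompret
   criteria.

The Chompret criteria are configuration data, not code
(`ChompretRules`): a tumour-spectrum keyword list plus three age cut-offs
(proband < 46, relative < 56, breast-only < 31), defaulting to the 2015
revision, evaluated in four arms (familial presentation, multiple
primaries, rare LFS-defining tumour, early-onset breast). Evaluation is
deliberately conservative: an age that was never recorded can never satisfy
an age-bounded clause, so missing data keeps a patient in the screen. The
"relative with multiple tumours" clause requires at least two
spectrum tumours in that relative; without that restriction a relative with
any two unrelated cancers would trigger Li-Fraumeni suspicion.

## Tissue evidence

Each observation is graded on the assay's empirical bands (percent AF):

| level | band | default |
|---|---|---|
| ABSENT | below detection floor | < 1 |
| TRACE | contamination range | 1 – 10 |
| PRESENT_SUBHET | mosaic range | 10 – 30 |
| PRESENT_HET | heterozygous window | 30 – 70 |
| PRESENT_HIGH | clonal expansion / LOH | > 70 |

Secondary tissues carry a reliability grade: cultured fibroblasts, muscle
and buccal DNA are HIGH (leukocyte-poor; buccal swabs are flagged as
admixture-prone in the call basis), tumour is MEDIUM (lymphocyte
infiltration), a direct skin punch is LOW (vascularised). A direct-skin
call in the TRACE/SUBHET range at or below `contamination_ratio` (default
0.5) times the **maximum** blood AF is flagged as suspected blood
carry-over — the maximum over serial draws, because blood clones wax and
wane and the largest observed clone bounds achievable contamination.
Serial blood AFs are kept as an age-ordered series with their max–min
fluctuation; fluctuation is reported descriptively and is never decisive,
since between-draw variance is not modelled.

Variants detected in skin but never in blood (encoded with an explicit
ABSENT blood observation) are skin-limited somatic events: they are
surfaced as report annotations and never influence the blood variant's
classification.

## Decision cascade

First match wins; every fired contradiction and decisive negative is logged
into the evidence trail:

1. **Full germline** — blood AF in the heterozygous window and a
   HIGH-reliability tissue also heterozygous.
2. **Likely germline** — heterozygous blood AF, no contradiction, no
   informative negative, no chart hematologic malignancy, and any secondary
   results are heterozygous calls in tissues that cannot confirm on their
   own (direct skin, tumour).
3. **Mosaic** — blood AF below the heterozygous window plus an independent
   (non-contamination-suspected) detection in any second tissue, at any
   reliability — including an unquantified "present" in tumour-adjacent
   tissue such as a polyp. A LOW-reliability skin detection is overridden
   when a HIGH-reliability tissue is outright negative: the fibroblast
   culture wins a discrepancy with the direct biopsy.
4. **Blood-restricted, confirmed** — an informative negative (HIGH-reliability
   tissue ABSENT, or direct skin ABSENT corroborated by a second negative
   tissue): hematologic-malignancy-related when chart review carries a
   malignancy diagnosis, otherwise confirmed CH.
5. **Blood-restricted, unconfirmed** — remaining blood-pattern variants
   (secondary results, if any, all absent, contamination-suspected, or
   trace-level leukocyte-admixture range): malignancy-related if the chart
   says so, otherwise likely CH.
6. Anything else is **unresolved**.

Contradiction rules capture evidence against germline origin for an
apparently heterozygous call: a tumour result below `tumour_germline_min`
(default 30%); two pathogenic hits in the same gene in blood; a
co-occurring low-AF pathogenic hit in another gene when the variant itself
sits within `borderline_margin` (default 10 points) above the heterozygous
floor; a blood AF above the window (copy-neutral LOH / clonal expansion).

A white-cell count outside `[wbc_normal_low, wbc_normal_high]` (default
4.0–11.0 x10⁹/L; the range is configurable because laboratories differ)
only sets a flag and adds CBC monitoring to the follow-up set — the chart
diagnosis, not the count, decides the malignancy label.

Patient-level roll-up: the label comes from the variants that triggered
inclusion; with several, the most confirmed incidental etiology has
precedence (malignancy > confirmed CH > mosaic > likely CH > germline
labels), and heterozygous-band variants with germline-family labels are
reported as co-findings. Follow-up flags: germline/mosaic →
surveillance + family variant testing; CH → CBC monitoring +
cardiovascular-risk program; malignancy → hematology referral.

## Synthetic cohorts

The generator emulates the statistical structure of the triage problem with
one pathogenic variant per patient and binomial read noise
(`alt ~ Binomial(depth, AF)`, depth default 500, matching panel coverage;
zero supporting reads report as ABSENT). Clone sizes are specified as
**cell fractions** and converted to expected AF = cell fraction / 2, which
keeps the configuration biologically interpretable:

* germline — true AF 50% everywhere; always *TP53* with a non-Chompret
  history, because the het-AF germline route into the screen is the
  TP53/Chompret category;
* mosaic — one shared sub-heterozygous AF (cell fraction 5–30%) in blood
  and all secondary tissues;
* CH — blood-only clone (cell fraction 5–40%) with ±30% multiplicative
  drift between draws, skin contaminated at U(0, 0.5) of the blood AF,
  fibroblasts clean, chemotherapy drawn at elevated probability;
* hematologic malignancy — blood-only AF U(15–85)%, abnormal WBC
  (U(12–90) x10⁹/L), chart diagnosis set;
* controls — either no reportable variant or a *TP53* heterozygote whose
  early-onset-breast history satisfies Chompret; neither screens in.

Secondary-tissue availability defaults to fibroblast 0.8, skin 0.5, tumour
0.15 — deliberately higher than typical clinical uptake for the two biopsy
tissues, because the generator's purpose is to exercise the tissue-evidence
logic; availability is configuration. One variant in ten is emitted as a
copy-number call with an interval AF (midpoint ± 2.5 points) to exercise
the interval code path. Ages, WBC and chemotherapy are simple
uniform/Bernoulli draws; they are configuration, not claims about any real
population.

What the simulation does **not** model — and hence what passing recovery
tests cannot show about real data: clonal dynamics over time, non-binomial
sequencing error, germline mosaicism gradients across tissues, tumour
lymphocyte-infiltration fractions, multi-variant patients, or realistic
pedigrees. Recovery is scored as a confusion matrix over label families
(germline / mosaic / blood-restricted / malignancy / excluded, plus an
unresolved column so marginals are conserved). With defaults at depth 500
the residual error is dominated by mosaic patients simulated without any
secondary tissue — whom the workflow itself can only call "likely CH" —
and by contamination fractions drawn adjacent to the 0.5 decision boundary.

## Numerical and design choices

* AFs are percentages throughout; interval estimates are summarised by
  their midpoint; "~" prefixed laboratory values are stored as points.
* Band edges: detection floor and trace ceiling are half-open from below
  (`x < floor` is ABSENT), the heterozygous window is closed
  (`30 ≤ x ≤ 70`).
* Ties between serial draws sort by age, then input order; unknown ages
  sort last.
* Percentages are stored at full precision and formatted only on output;
  clinical reports mix truncation and rounding, so comparisons against
  published one-decimal figures should allow ±0.1.
* All randomness flows through one `numpy` generator seeded from the
  simulation configuration; identical configuration gives identical
  cohorts, and the classifier itself is fully deterministic.
* Test problem sizes (1000-patient recovery cohorts, 800 per depth for the
  depth sweep, 10⁴ replicates for binomial moments) were chosen to make the
  stochastic assertions stable at the stated tolerances.

## Known limitations

* Pathogenicity is an input; no variant interpretation is performed, and
  HGVS strings are carried verbatim without transcript validation.
* The Chompret keyword matcher works on free-text labels; unusual phrasing
  of a spectrum tumour can be missed (conservatively — towards inclusion).
* No probabilistic etiology posterior: the cascade is deliberately
  rule-shaped so that each conclusion carries a human-readable trail, at
  the cost of sharp thresholds near band edges.
* Leukocyte admixture in biopsies is handled by a ratio heuristic, not a
  formal deconvolution; extreme contamination of skin by a high-AF
  leukemic clone can leave a variant unresolved.
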