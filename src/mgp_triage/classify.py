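"""Per-variant and per-patient etiology conclusions.

The decision engine is a deterministic, first-match rule cascade over the
graded tissue evidence. In outline:

* germline confirmation: a heterozygous-band blood AF reproduced as a
  heterozygous call in a leukocyte-free tissue (cultured fibroblasts,
  muscle, buccal) confirms a full germline variant; a heterozygous blood AF
  with nothing arguing against it, but no confirming tissue, is likely
  germline;
* mosaicism: a sub-heterozygous blood AF that is independently detected in a
  second tissue (not explainable as blood contamination) indicates a
  post-zygotic event shared across lineages;
* blood-restricted findings: a variant that disappears in a reliable second
  tissue is clonal hematopoiesis — or, when chart review shows a hematologic
  malignancy, malignancy-related; without the tissue confirmation the same
  pattern is "likely" clonal hematopoiesis;
* contradiction rules capture evidence against germline origin for an
  apparently heterozygous call: a (near-)negative tumour, two hits in the
  same gene in blood, a co-occurring low-AF hit in another gene, or a blood
  AF above the heterozygous window (clonal expansion / copy-neutral LOH).

An abnormal white-cell count only raises a flag and a follow-up action; the
chart-review diagnosis, not the count, decides the malignancy label.
"""

from __future__ import annotations

import enum
import logging
from typing import Optional

from pydantic import model_validator

from .errors import ConsistencyError, TriageError
from .evidence import (
    PresenceCall,
    PresenceLevel,
    Reliability,
    TissueEvidence,
    summarize_evidence,
)
from .model import (
    ACTIONABLE,
    PatientRecord,
    StrictModel,
    ThresholdConfig,
    Tissue,
    max_pbl_af,
    pbl_detected,
)
from .screen import ChompretRules, InclusionResult, screen_cohort

logger = logging.getLogger(__name__)


class ConclusionLabel(str, enum.Enum):
    FULL_GERMLINE = "FULL_GERMLINE"
    LIKELY_GERMLINE = "LIKELY_GERMLINE"
    MOSAIC = "MOSAIC"
    CONFIRMED_CH = "CONFIRMED_CH"
    LIKELY_CH = "LIKELY_CH"
    HEME_MALIGNANCY_RELATED = "HEME_MALIGNANCY_RELATED"
    UNRESOLVED = "UNRESOLVED"


GERMLINE_FAMILY = {ConclusionLabel.FULL_GERMLINE, ConclusionLabel.LIKELY_GERMLINE}
CH_FAMILY = {ConclusionLabel.CONFIRMED_CH, ConclusionLabel.LIKELY_CH}

#: Precedence when a patient has several category-triggering variants: the
#: most confirmed incidental (non-germline) etiology names the patient.
_PRIMARY_PRIORITY = [
    ConclusionLabel.HEME_MALIGNANCY_RELATED,
    ConclusionLabel.CONFIRMED_CH,
    ConclusionLabel.MOSAIC,
    ConclusionLabel.LIKELY_CH,
    ConclusionLabel.FULL_GERMLINE,
    ConclusionLabel.LIKELY_GERMLINE,
    ConclusionLabel.UNRESOLVED,
]


class FollowUp(str, enum.Enum):
    HEREDITARY_SURVEILLANCE = "HEREDITARY_SURVEILLANCE"
    HEMATOLOGY_REFERRAL = "HEMATOLOGY_REFERRAL"
    CBC_MONITORING = "CBC_MONITORING"
    FAMILY_VARIANT_TESTING = "FAMILY_VARIANT_TESTING"
    CARDIOVASCULAR_RISK_PROGRAM = "CARDIOVASCULAR_RISK_PROGRAM"


_FOLLOW_UP = {
    ConclusionLabel.FULL_GERMLINE: {
        FollowUp.HEREDITARY_SURVEILLANCE,
        FollowUp.FAMILY_VARIANT_TESTING,
    },
    ConclusionLabel.LIKELY_GERMLINE: {
        FollowUp.HEREDITARY_SURVEILLANCE,
        FollowUp.FAMILY_VARIANT_TESTING,
    },
    ConclusionLabel.MOSAIC: {
        FollowUp.HEREDITARY_SURVEILLANCE,
        FollowUp.FAMILY_VARIANT_TESTING,
    },
    ConclusionLabel.CONFIRMED_CH: {
        FollowUp.CBC_MONITORING,
        FollowUp.CARDIOVASCULAR_RISK_PROGRAM,
    },
    ConclusionLabel.LIKELY_CH: {
        FollowUp.CBC_MONITORING,
        FollowUp.CARDIOVASCULAR_RISK_PROGRAM,
    },
    ConclusionLabel.HEME_MALIGNANCY_RELATED: {FollowUp.HEMATOLOGY_REFERRAL},
    ConclusionLabel.UNRESOLVED: set(),
}


class VariantConclusion(StrictModel):
    patient_id: str
    variant_key: str
    label: ConclusionLabel
    #: ordered (rule_id, rationale) pairs: fired contradictions, decisive
    #: negatives, and the concluding rule last
    evidence: list[tuple[str, str]] = []
    cbc_flag: bool = False

    @model_validator(mode="after")
    def _check(self) -> "VariantConclusion":
        if self.label is not ConclusionLabel.UNRESOLVED and not self.evidence:
            raise ValueError("non-UNRESOLVED conclusion requires evidence")
        return self


class PatientConclusion(StrictModel):
    patient_id: str
    primary_label: ConclusionLabel
    primary_variants: list[VariantConclusion] = []
    co_findings: list[VariantConclusion] = []
    follow_up: set[FollowUp] = set()

    @model_validator(mode="after")
    def _check(self) -> "PatientConclusion":
        if not self.primary_variants:
            raise ValueError("primary_variants must be non-empty")
        if all(vc.label is not self.primary_label for vc in self.primary_variants):
            raise ValueError("primary_label must come from primary_variants")
        return self


def _cbc_flag(patient: PatientRecord, config: ThresholdConfig) -> bool:
    wbc = patient.clinical.wbc
    return wbc is not None and not (
        config.wbc_normal_low <= wbc <= config.wbc_normal_high
    )


def _contradictions(
    patient: PatientRecord,
    variant_key: str,
    ev: TissueEvidence,
    config: ThresholdConfig,
) -> list[tuple[str, str]]:
    """Evidence against a germline origin for this variant."""
    out: list[tuple[str, str]] = []
    pbl_max = ev.max_pbl
    gene = patient.variant(variant_key).gene

    tumour = ev.calls.get(Tissue.TUMOUR)
    if tumour is not None:
        tumour_rep = _call_rep(patient, variant_key, Tissue.TUMOUR)
        if tumour.level is PresenceLevel.ABSENT or (
            tumour_rep is not None and tumour_rep < config.tumour_germline_min
        ):
            out.append(
                (
                    "contra-tumour-negative",
                    f"tumour {tumour.level.value.lower()} (below "
                    f"{config.tumour_germline_min:g}% germline minimum)",
                )
            )

    same_gene = [
        v
        for v in patient.variants
        if v.gene == gene
        and v.pathogenicity in ACTIONABLE
        and pbl_detected(patient, v.key)
    ]
    if len(same_gene) >= 2:
        out.append(
            (
                "contra-multi-hit-same-gene",
                f"{len(same_gene)} pathogenic {gene} variants in blood",
            )
        )

    if config.het_low <= pbl_max <= config.het_low + config.borderline_margin:
        for v in patient.variants:
            if v.key == variant_key or v.gene == gene:
                continue
            if v.pathogenicity not in ACTIONABLE or not pbl_detected(patient, v.key):
                continue
            other_max = max_pbl_af(patient, v.key)
            if config.detection_floor <= other_max < config.het_low:
                out.append(
                    (
                        "contra-co-occurring-low-af",
                        f"borderline heterozygous AF with co-occurring {v.gene} "
                        f"at {other_max:g}%",
                    )
                )
                break

    if pbl_max > config.het_high:
        out.append(
            (
                "contra-above-het-band",
                f"blood AF {pbl_max:g}% above heterozygous window "
                "(clonal expansion / copy-neutral LOH signature)",
            )
        )
    return out


def _call_rep(
    patient: PatientRecord, variant_key: str, tissue: Tissue
) -> Optional[float]:
    reps = [
        o.af.representative
        for o in patient.observations_for(variant_key, tissue)
        if o.af.representative is not None
    ]
    return max(reps) if reps else None


def _informative_negative(ev: TissueEvidence) -> Optional[str]:
    """An informative second-tissue negative: a HIGH-reliability tissue with
    no trace of the variant, or a fully negative direct skin corroborated by
    a second negative tissue."""
    high_absent = [
        t.value
        for t, c in ev.calls.items()
        if t is not Tissue.PBL
        and ev.reliability.get(t) is Reliability.HIGH
        and c.level is PresenceLevel.ABSENT
    ]
    if high_absent:
        return f"variant absent in {', '.join(sorted(high_absent))}"
    skin = ev.calls.get(Tissue.DIRECT_SKIN)
    if skin is not None and skin.level is PresenceLevel.ABSENT:
        others = [
            t.value
            for t, c in ev.calls.items()
            if t not in (Tissue.PBL, Tissue.DIRECT_SKIN)
            and c.level is PresenceLevel.ABSENT
        ]
        if others:
            return (
                "variant absent in direct skin, corroborated by absence in "
                + ", ".join(sorted(others))
            )
    return None


def _second_tissue_detection(ev: TissueEvidence) -> Optional[tuple[Tissue, PresenceCall]]:
    """A second-tissue detection that supports mosaicism: any detected,
    non-contamination-suspected call in a non-blood tissue — except that a
    LOW-reliability (direct skin) detection is overridden when a
    HIGH-reliability tissue is outright negative (fibroblast culture wins a
    discrepancy with the direct biopsy)."""
    high_negative = any(
        ev.reliability.get(t) is Reliability.HIGH and c.level is PresenceLevel.ABSENT
        for t, c in ev.calls.items()
        if t is not Tissue.PBL
    )
    for tissue, call in ev.calls.items():
        if tissue is Tissue.PBL:
            continue
        if call.level is PresenceLevel.ABSENT or call.contamination_suspected:
            continue
        if ev.reliability.get(tissue) is Reliability.LOW and high_negative:
            continue
        return tissue, call
    return None


def classify_variant(
    patient: PatientRecord,
    variant_key: str,
    evidence: TissueEvidence | None = None,
    config: ThresholdConfig | None = None,
) -> VariantConclusion:
    """Run the rule cascade for one variant; first matching rule wins."""
    config = config or ThresholdConfig()
    ev = evidence if evidence is not None else summarize_evidence(
        patient, variant_key, config
    )
    if not patient.observations_for(variant_key, Tissue.PBL):
        raise TriageError(
            f"patient {patient.patient_id}, variant {variant_key!r}: "
            "no blood observation; the cascade requires one"
        )

    cbc = _cbc_flag(patient, config)
    trail: list[tuple[str, str]] = []
    if cbc:
        trail.append(
            (
                "cbc-flag",
                f"WBC {patient.clinical.wbc:g} outside "
                f"[{config.wbc_normal_low:g}, {config.wbc_normal_high:g}] x10^9/L "
                "(flag only; chart diagnosis decides)",
            )
        )

    def conclude(label: ConclusionLabel, rule: str, text: str) -> VariantConclusion:
        return VariantConclusion(
            patient_id=patient.patient_id,
            variant_key=variant_key,
            label=label,
            evidence=trail + [(rule, text)],
            cbc_flag=cbc,
        )

    pbl_call = ev.calls.get(Tissue.PBL)
    blood_detected = pbl_call is not None and pbl_call.level is not PresenceLevel.ABSENT
    pbl_max = ev.max_pbl

    # Skin-limited finding: detected in the biopsy, never in blood. These are
    # somatic events isolated to the skin (or sequencing artifacts); they are
    # surfaced as annotations and never drive the blood variant's label.
    if not blood_detected:
        skin = ev.calls.get(Tissue.DIRECT_SKIN)
        if skin is not None and skin.level is not PresenceLevel.ABSENT:
            trail.append(
                (
                    "skin-limited",
                    "detected in direct skin but not in blood: likely somatic "
                    "event isolated to the skin; annotation only",
                )
            )
        return VariantConclusion(
            patient_id=patient.patient_id,
            variant_key=variant_key,
            label=ConclusionLabel.UNRESOLVED,
            evidence=trail,
            cbc_flag=cbc,
        )

    contradictions = _contradictions(patient, variant_key, ev, config)
    negative = _informative_negative(ev)
    het_band = config.het_low <= pbl_max <= config.het_high
    heme_dx = patient.clinical.heme_malignancy_dx

    # germline-confirmed: heterozygous blood AF reproduced in a
    # leukocyte-free tissue
    if het_band:
        het_high_rel = [
            t.value
            for t, c in ev.calls.items()
            if t is not Tissue.PBL
            and ev.reliability.get(t) is Reliability.HIGH
            and c.level is PresenceLevel.PRESENT_HET
        ]
        if het_high_rel:
            trail.extend(contradictions)
            return conclude(
                ConclusionLabel.FULL_GERMLINE,
                "germline-confirmed",
                f"blood AF {pbl_max:g}% heterozygous and confirmed in "
                + ", ".join(sorted(het_high_rel)),
            )

    # germline-likely: heterozygous blood AF, nothing arguing against, no
    # confirming leukocyte-free tissue (secondary results, if any, are
    # het-band calls in tissues that cannot confirm on their own). A chart
    # hematologic malignancy is an alternative explanation and blocks an
    # unconfirmed germline call.
    if het_band and not contradictions and negative is None and not heme_dx:
        secondary = {t: c for t, c in ev.calls.items() if t is not Tissue.PBL}
        consistent = all(
            c.level in (PresenceLevel.PRESENT_HET, PresenceLevel.PRESENT_HIGH)
            and not c.contamination_suspected
            for c in secondary.values()
        )
        if consistent:
            which = (
                "no secondary tissue tested"
                if not secondary
                else "secondary tissue(s) consistent but not confirmatory"
            )
            return conclude(
                ConclusionLabel.LIKELY_GERMLINE,
                "germline-likely",
                f"blood AF {pbl_max:g}% heterozygous; {which}; "
                "no evidence against germline origin",
            )

    # mosaic: sub-heterozygous in blood and independently detected in a
    # second tissue
    if pbl_max < config.het_low and pbl_max > 0:
        hit = _second_tissue_detection(ev)
        if hit is not None:
            tissue, call = hit
            trail.extend(contradictions)
            return conclude(
                ConclusionLabel.MOSAIC,
                "mosaic-second-tissue",
                f"blood AF {pbl_max:g}% below heterozygous window and detected "
                f"in {tissue.value} ({call.basis})",
            )

    # blood-restricted with an informative second-tissue negative
    if negative is not None:
        trail.extend(contradictions)
        trail.append(("tissue-negative", negative))
        if heme_dx:
            return conclude(
                ConclusionLabel.HEME_MALIGNANCY_RELATED,
                "malignancy-chart-dx",
                f"blood-restricted variant with chart diagnosis: {heme_dx}",
            )
        return conclude(
            ConclusionLabel.CONFIRMED_CH,
            "ch-confirmed",
            "blood-restricted variant confirmed by second-tissue negative; "
            "no hematologic malignancy on chart review",
        )

    # blood-restricted pattern without a confirming negative: any secondary
    # detections are contamination-suspected or trace-level (leukocyte
    # admixture range)
    secondary = {t: c for t, c in ev.calls.items() if t is not Tissue.PBL}
    unconfirmed_blood_pattern = all(
        c.level is PresenceLevel.ABSENT
        or c.contamination_suspected
        or c.level is PresenceLevel.TRACE
        for c in secondary.values()
    )
    if unconfirmed_blood_pattern:
        trail.extend(contradictions)
        if heme_dx:
            return conclude(
                ConclusionLabel.HEME_MALIGNANCY_RELATED,
                "malignancy-chart-dx",
                "blood-pattern variant without tissue confirmation; chart "
                f"diagnosis dominates: {heme_dx}",
            )
        if het_band and contradictions:
            return conclude(
                ConclusionLabel.LIKELY_CH,
                "ch-likely-contradicted",
                f"apparently heterozygous blood AF {pbl_max:g}% with evidence "
                "against germline origin and no germline confirmation",
            )
        return conclude(
            ConclusionLabel.LIKELY_CH,
            "ch-likely-unconfirmed",
            f"blood AF {pbl_max:g}% with no (reliable) secondary tissue "
            "analysis; clinical history supports clonal hematopoiesis",
        )

    trail.extend(contradictions)
    return VariantConclusion(
        patient_id=patient.patient_id,
        variant_key=variant_key,
        label=ConclusionLabel.UNRESOLVED,
        evidence=trail,
        cbc_flag=cbc,
    )


def classify_patient(
    patient: PatientRecord,
    inclusion: InclusionResult,
    variant_conclusions: list[VariantConclusion],
) -> PatientConclusion:
    """Roll per-variant conclusions up to one patient-level conclusion.

    The primary label comes from the variants that triggered inclusion; when
    several trigger, the most confirmed incidental etiology wins and
    germline-band co-occurring variants are reported as co-findings.
    """
    if not inclusion.included:
        raise ConsistencyError(
            f"patient {patient.patient_id} was not included by the screen"
        )
    by_key = {vc.variant_key: vc for vc in variant_conclusions}
    triggering = [
        by_key[k] for k in sorted(inclusion.triggering_variants) if k in by_key
    ]
    if not triggering:
        raise ConsistencyError(
            f"patient {patient.patient_id}: no triggering variant classified"
        )
    primary_label = min(triggering, key=lambda vc: _PRIMARY_PRIORITY.index(vc.label)).label
    primary = [vc for vc in triggering if vc.label is primary_label]
    co = [vc for vc in variant_conclusions if vc not in primary]

    follow = set(_FOLLOW_UP[primary_label])
    if any(vc.cbc_flag for vc in variant_conclusions):
        follow.add(FollowUp.CBC_MONITORING)

    return PatientConclusion(
        patient_id=patient.patient_id,
        primary_label=primary_label,
        primary_variants=primary,
        co_findings=co,
        follow_up=follow,
    )


def classify_cohort(
    patients: list[PatientRecord],
    config: ThresholdConfig | None = None,
    rules: ChompretRules | None = None,
) -> list[PatientConclusion]:
    """screen -> evidence -> classify for every included patient.

    Excluded patients are omitted (with a logged notice); a failure on one
    patient is logged and does not abort the cohort.
    """
    config = config or ThresholdConfig()
    inclusions = screen_cohort(patients, config, rules)
    out: list[PatientConclusion] = []
    for patient, inclusion in zip(patients, inclusions):
        if not inclusion.included:
            logger.info(
                "patient %s excluded: no inclusion category fired",
                patient.patient_id,
            )
            continue
        try:
            vcs = [
                classify_variant(
                    patient,
                    v.key,
                    summarize_evidence(patient, v.key, config),
                    config,
                )
                for v in patient.variants
            ]
            out.append(classify_patient(patient, inclusion, vcs))
        except TriageError as exc:
            logger.error("patient %s failed classification: %s", patient.patient_id, exc)
    return out
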