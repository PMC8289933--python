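"""End-to-end orchestration: screen -> tissue evidence -> classify -> summarize."""

from __future__ import annotations

from dataclasses import dataclass, field

from .classify import (
    PatientConclusion,
    classify_patient,
    classify_variant,
)
from .errors import TriageError
from .evidence import TissueEvidence, summarize_evidence
from .model import PatientRecord, ThresholdConfig
from .screen import ChompretRules, InclusionResult, screen_cohort
from .summary import CohortSummary, summarize_cohort

import logging

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    patients: list[PatientRecord]
    inclusions: list[InclusionResult]
    #: (patient_id, variant_key) -> evidence, for every included patient
    evidence: dict[tuple[str, str], TissueEvidence] = field(default_factory=dict)
    conclusions: list[PatientConclusion] = field(default_factory=list)
    summary: CohortSummary | None = None
    errors: list[str] = field(default_factory=list)


def run_pipeline(
    patients: list[PatientRecord],
    config: ThresholdConfig | None = None,
    rules: ChompretRules | None = None,
) -> PipelineResult:
    """Run the full triage workflow on a validated cohort.

    Excluded patients stay in ``patients``/``inclusions`` but get no
    conclusion; a failure on one patient is recorded in ``errors`` and does
    not abort the rest.
    """
    config = config or ThresholdConfig()
    inclusions = screen_cohort(patients, config, rules)
    result = PipelineResult(patients=patients, inclusions=inclusions)

    for patient, inclusion in zip(patients, inclusions):
        if not inclusion.included:
            continue
        try:
            vcs = []
            for v in patient.variants:
                ev = summarize_evidence(patient, v.key, config)
                result.evidence[(patient.patient_id, v.key)] = ev
                vcs.append(classify_variant(patient, v.key, ev, config))
            result.conclusions.append(classify_patient(patient, inclusion, vcs))
        except TriageError as exc:
            msg = f"patient {patient.patient_id}: {exc}"
            logger.error(msg)
            result.errors.append(msg)

    ok_ids = {c.patient_id for c in result.conclusions}
    result.summary = summarize_cohort(
        patients,
        [r for r in inclusions if not r.included or r.patient_id in ok_ids],
        result.conclusions,
        result.evidence,
    )
    return result
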