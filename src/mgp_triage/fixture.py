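"""The packaged 24-patient reference cohort.

Twenty-four probands flagged during germline hereditary-cancer multi-gene
panel testing of blood DNA: multiple pathogenic variants, low allele
fractions, or pathogenic TP53 findings in families whose history does not
suggest Li-Fraumeni syndrome. Each record carries the blood allele fractions
(often at several ages), any secondary-tissue results (direct skin punch,
cultured fibroblasts, tumour, muscle), white-cell counts, chemotherapy
exposure and chart-review diagnoses.
"""

from __future__ import annotations

import json
from importlib import resources

from pydantic import ValidationError

from .errors import CohortValidationError
from .model import PatientRecord

_FIXTURE = "cohort_fixture.json"


def load_fixture_cohort() -> list[PatientRecord]:
    """Return the 24 packaged patient records, validated, in table order."""
    text = resources.files("mgp_triage.data").joinpath(_FIXTURE).read_text()
    doc = json.loads(text)
    out = []
    for entry in doc["patients"]:
        try:
            out.append(PatientRecord.model_validate(entry))
        except ValidationError as exc:  # pragma: no cover - fixture is static
            raise CohortValidationError(
                f"fixture patient {entry.get('patient_id')}: {exc}"
            ) from exc
    return out


def fixture_metadata() -> dict:
    """Provenance notes for the packaged cohort (encoding decisions)."""
    text = resources.files("mgp_triage.data").joinpath(_FIXTURE).read_text()
    return json.loads(text)["metadata"]
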