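"""Inclusion screening: which findings are suspicious enough to work up.

Three triggers mark a panel result as a potential incidental (non-germline)
finding:

1. multiple pathogenic or likely pathogenic variants in the same person,
2. a pathogenic/likely pathogenic variant at a low blood allele fraction,
3. a pathogenic TP53 variant in a patient whose personal/family history does
   not satisfy the Chompret criteria for Li-Fraumeni syndrome.

Chompret evaluation is conservative: a criterion that depends on an age that
was never recorded is treated as unmet, so missing data can only keep a
patient in the screen, never argue them out of it.
"""

from __future__ import annotations

from typing import Optional

from pydantic import model_validator

from .errors import CohortValidationError
from .model import (
    ACTIONABLE,
    AFStatus,
    CancerDiagnosis,
    PatientRecord,
    StrictModel,
    ThresholdConfig,
    Tissue,
    max_pbl_af,
    pbl_detected,
)

#: Default Li-Fraumeni tumour-spectrum keywords (matched case-insensitively
#: as substrings of free-text diagnosis labels).
DEFAULT_LFS_SPECTRUM = (
    "breast",
    "ductal carcinoma",
    "soft-tissue sarcoma",
    "sarcoma",
    "osteosarcoma",
    "brain",
    "cns",
    "glioma",
    "medulloblastoma",
    "choroid plexus",
    "adrenocortical",
    "leukemia",
    "bronchoalveolar",
)

#: Tumours that justify TP53 testing regardless of family history.
DEFAULT_RARE_TUMOURS = (
    "adrenocortical",
    "choroid plexus",
    "anaplastic rhabdomyosarcoma",
)


class ChompretRules(StrictModel):
    """Configurable Chompret criteria (defaults follow the 2015 revision).

    The criteria are data, not code: the tumour spectrum and the three age
    cut-offs can be swapped out wholesale when the clinical criteria are
    revised, without touching the evaluation logic.
    """

    lfs_spectrum: tuple[str, ...] = DEFAULT_LFS_SPECTRUM
    rare_tumours: tuple[str, ...] = DEFAULT_RARE_TUMOURS
    proband_age_max: float = 46.0
    relative_age_max: float = 56.0
    breast_only_age_max: float = 31.0

    @model_validator(mode="after")
    def _check(self) -> "ChompretRules":
        if not self.lfs_spectrum:
            raise ValueError("lfs_spectrum must be non-empty")
        for f in ("proband_age_max", "relative_age_max", "breast_only_age_max"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        return self

    def in_spectrum(self, label: str) -> bool:
        low = label.lower()
        return any(k in low for k in self.lfs_spectrum)

    def is_rare_tumour(self, label: str) -> bool:
        low = label.lower()
        return any(k in low for k in self.rare_tumours)


def _is_breast(label: str) -> bool:
    low = label.lower()
    return "breast" in low or "ductal carcinoma" in low


class ChompretResult(StrictModel):
    met: bool
    fired_rule: Optional[str] = None
    rationale: str = ""

    @model_validator(mode="after")
    def _check(self) -> "ChompretResult":
        if self.met != (self.fired_rule is not None):
            raise ValueError("met must be true iff fired_rule is present")
        return self


class InclusionResult(StrictModel):
    patient_id: str
    categories: set[int] = set()
    chompret: ChompretResult
    included: bool
    #: keys of the variants that fired at least one category
    triggering_variants: set[str] = set()

    @model_validator(mode="after")
    def _check(self) -> "InclusionResult":
        if self.included != bool(self.categories):
            raise ValueError("included must equal (categories non-empty)")
        if 3 in self.categories and self.chompret.met:
            raise ValueError("category 3 requires an unmet Chompret evaluation")
        return self


def evaluate_chompret(
    patient: PatientRecord, rules: ChompretRules | None = None
) -> ChompretResult:
    """Evaluate the (configured) Chompret criteria on recorded data only.

    Four arms are checked: familial presentation, multiple primaries, a rare
    LFS-defining tumour, and early-onset breast cancer. Unknown ages never
    satisfy an age-bounded arm.
    """
    rules = rules or ChompretRules()
    notes: list[str] = []
    proband_has_breast = any(_is_breast(d.label) for d in patient.diagnoses)

    # -- familial presentation: spectrum tumour before proband_age_max plus a
    #    1st/2nd-degree relative with a spectrum tumour before relative_age_max
    #    (breast excluded when the proband has breast cancer) or with multiple
    #    spectrum primaries at any age.
    early = [
        d
        for d in patient.diagnoses
        if rules.in_spectrum(d.label)
        and d.age_at_dx is not None
        and d.age_at_dx < rules.proband_age_max
    ]
    if early:

        def relative_spectrum(dx: CancerDiagnosis) -> bool:
            if proband_has_breast and _is_breast(dx.label):
                return False
            return rules.in_spectrum(dx.label)

        for member in patient.family:
            spectrum_dxs = [d for d in member.diagnoses if relative_spectrum(d)]
            aged = [
                d
                for d in spectrum_dxs
                if d.age_at_dx is not None and d.age_at_dx < rules.relative_age_max
            ]
            if aged:
                return ChompretResult(
                    met=True,
                    fired_rule="familial_presentation",
                    rationale=(
                        f"proband {early[0].label} at {early[0].age_at_dx:g} with a "
                        f"relative {aged[0].label} at {aged[0].age_at_dx:g}"
                    ),
                )
            if len(spectrum_dxs) >= 2:
                return ChompretResult(
                    met=True,
                    fired_rule="familial_presentation",
                    rationale=(
                        f"proband {early[0].label} at {early[0].age_at_dx:g} with a "
                        "relative carrying multiple spectrum primaries"
                    ),
                )
        notes.append(
            "familial presentation unmet: no relative with a documented "
            f"spectrum tumour before {rules.relative_age_max:g}"
        )
    else:
        notes.append(
            "familial presentation unmet: no spectrum tumour before "
            f"{rules.proband_age_max:g} with a recorded age"
        )

    # -- multiple primaries (multiple breast tumours alone do not count)
    spectrum_dxs = [d for d in patient.diagnoses if rules.in_spectrum(d.label)]
    non_breast_spectrum = [d for d in spectrum_dxs if not _is_breast(d.label)]
    known_ages = [d.age_at_dx for d in patient.diagnoses if d.age_at_dx is not None]
    if (
        len(patient.diagnoses) >= 2
        and len(spectrum_dxs) >= 2
        and non_breast_spectrum
        and known_ages
        and min(known_ages) < rules.proband_age_max
    ):
        return ChompretResult(
            met=True,
            fired_rule="multiple_primaries",
            rationale=(
                f"{len(spectrum_dxs)} spectrum primaries, first diagnosis at "
                f"{min(known_ages):g}"
            ),
        )
    notes.append("multiple-primaries unmet")

    # -- rare LFS-defining tumour, any age, regardless of family history
    for d in patient.diagnoses:
        if rules.is_rare_tumour(d.label):
            return ChompretResult(
                met=True,
                fired_rule="rare_tumour",
                rationale=f"rare LFS-defining tumour: {d.label}",
            )
    notes.append("rare-tumour unmet")

    # -- early-onset breast cancer
    for d in patient.diagnoses:
        if (
            _is_breast(d.label)
            and d.age_at_dx is not None
            and d.age_at_dx < rules.breast_only_age_max
        ):
            return ChompretResult(
                met=True,
                fired_rule="early_onset_breast",
                rationale=f"breast cancer at {d.age_at_dx:g}",
            )
    notes.append(
        f"early-onset-breast unmet (no breast dx before {rules.breast_only_age_max:g})"
    )

    return ChompretResult(met=False, rationale="; ".join(notes))


def _low_af_in_pbl(
    patient: PatientRecord, key: str, config: ThresholdConfig
) -> bool:
    """True if any blood draw of the variant falls in the low-AF band, or the
    source laboratory reported it present-but-unquantified (their shorthand
    for a low-level call)."""
    for obs in patient.observations_for(key, Tissue.PBL):
        if obs.af.status is AFStatus.PRESENT_UNQUANTIFIED:
            return True
        rep = obs.af.representative
        if rep is not None and config.category2_lower <= rep < config.category2_upper:
            return True
    return False


def screen_patient(
    patient: PatientRecord,
    config: ThresholdConfig | None = None,
    rules: ChompretRules | None = None,
) -> InclusionResult:
    """Assign inclusion categories 1/2/3 to one patient."""
    config = config or ThresholdConfig()
    chompret = evaluate_chompret(patient, rules)

    actionable_in_blood = [
        v
        for v in patient.variants
        if v.pathogenicity in ACTIONABLE and pbl_detected(patient, v.key)
    ]
    categories: set[int] = set()
    triggering: set[str] = set()

    if len(actionable_in_blood) >= 2:
        categories.add(1)
        triggering.update(v.key for v in actionable_in_blood)
    low = [v for v in actionable_in_blood if _low_af_in_pbl(patient, v.key, config)]
    if low:
        categories.add(2)
        triggering.update(v.key for v in low)
    if not chompret.met:
        tp53 = [v for v in actionable_in_blood if v.gene == "TP53"]
        if tp53:
            categories.add(3)
            triggering.update(v.key for v in tp53)

    return InclusionResult(
        patient_id=patient.patient_id,
        categories=categories,
        chompret=chompret,
        included=bool(categories),
        triggering_variants=triggering,
    )


def screen_cohort(
    patients: list[PatientRecord],
    config: ThresholdConfig | None = None,
    rules: ChompretRules | None = None,
) -> list[InclusionResult]:
    """Element-wise :func:`screen_patient`; order preserved."""
    ids = [p.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise CohortValidationError(f"duplicate patient_id(s): {dupes}")
    return [screen_patient(p, config, rules) for p in patients]
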