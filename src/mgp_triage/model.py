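"""Domain types for incidental-finding triage on hereditary-cancer NGS panels.

The central objects are :class:`PatientRecord` (one proband with their
pathogenic variant calls and per-tissue allele-fraction observations) and
:class:`ThresholdConfig` (the allele-fraction bands the screen, the tissue
evidence grading and the decision cascade operate on).

Allele fractions are stored in percent (0-100). A heterozygous germline
variant is expected near 50%; the 30-70% band is the empirical heterozygous
calling window for the assay this workflow was designed around.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, model_validator


class AFStatus(str, enum.Enum):
    """How an allele fraction was reported by the laboratory."""

    QUANTIFIED = "QUANTIFIED"
    PRESENT_UNQUANTIFIED = "PRESENT_UNQUANTIFIED"
    ABSENT = "ABSENT"


class VariantKind(str, enum.Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    SPLICE_SITE = "SPLICE_SITE"
    EXON_DELETION = "EXON_DELETION"
    WHOLE_GENE_DELETION = "WHOLE_GENE_DELETION"


class Pathogenicity(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    VUS = "VUS"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN = "BENIGN"


#: Pathogenicity classes that make a variant reportable / screen-relevant.
ACTIONABLE = frozenset({Pathogenicity.PATHOGENIC, Pathogenicity.LIKELY_PATHOGENIC})


class Tissue(str, enum.Enum):
    PBL = "PBL"
    DIRECT_SKIN = "DIRECT_SKIN"
    CULTURED_FIBROBLAST = "CULTURED_FIBROBLAST"
    TUMOUR = "TUMOUR"
    MUSCLE = "MUSCLE"
    BUCCAL = "BUCCAL"
    OTHER_NORMAL = "OTHER_NORMAL"


class Degree(str, enum.Enum):
    FIRST = "FIRST"
    SECOND = "SECOND"


class ChemoHistory(str, enum.Enum):
    YES = "YES"
    NO = "NO"
    UNKNOWN = "UNKNOWN"


class StrictModel(BaseModel):
    model_config = ConfigDict(validate_assignment=True, use_enum_values=False)


class AlleleFraction(StrictModel):
    """One laboratory-reported allele fraction, in percent.

    Copy-number calls are often reported as ranges ("10-15%"); those are kept
    as ``interval_low``/``interval_high`` and summarised by the midpoint. A
    point estimate uses ``value``. ``representative`` is the single number the
    downstream rules consume (``None`` when absent or unquantified).
    """

    status: AFStatus
    value: Optional[float] = None
    interval_low: Optional[float] = None
    interval_high: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "AlleleFraction":
        for name in ("value", "interval_low", "interval_high"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside 0-100 percent")
        if (self.interval_low is None) != (self.interval_high is None):
            raise ValueError("interval_low and interval_high must be given together")
        if self.interval_low is not None and self.interval_low > self.interval_high:
            raise ValueError("interval_low > interval_high")
        if self.status is AFStatus.QUANTIFIED:
            if self.value is None and self.interval_low is None:
                raise ValueError("QUANTIFIED requires a value or an interval")
        elif self.status is AFStatus.ABSENT:
            if self.value is not None or self.interval_low is not None:
                raise ValueError("ABSENT must not carry a value or interval")
        else:  # PRESENT_UNQUANTIFIED
            if self.value is not None:
                raise ValueError("PRESENT_UNQUANTIFIED must not carry a value")
        return self

    @property
    def representative(self) -> Optional[float]:
        if self.status is not AFStatus.QUANTIFIED:
            return None
        if self.value is not None:
            return self.value
        return (self.interval_low + self.interval_high) / 2.0

    @classmethod
    def quantified(cls, value: float) -> "AlleleFraction":
        return cls(status=AFStatus.QUANTIFIED, value=value)

    @classmethod
    def interval(cls, low: float, high: float) -> "AlleleFraction":
        return cls(status=AFStatus.QUANTIFIED, interval_low=low, interval_high=high)

    @classmethod
    def absent(cls) -> "AlleleFraction":
        return cls(status=AFStatus.ABSENT)

    @classmethod
    def present_unquantified(cls) -> "AlleleFraction":
        return cls(status=AFStatus.PRESENT_UNQUANTIFIED)


class VariantCall(StrictModel):
    """One reported variant: gene, HGVS description, kind and classification."""

    key: str
    gene: str
    cdna: str
    protein: Optional[str] = None
    kind: VariantKind
    pathogenicity: Pathogenicity

    @model_validator(mode="after")
    def _check(self) -> "VariantCall":
        if not self.key:
            raise ValueError("variant key must be non-empty")
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if not self.cdna:
            raise ValueError("cdna must be non-empty")
        return self


class TissueObservation(StrictModel):
    """One allele-fraction measurement of one variant in one tissue."""

    variant_key: str
    tissue: Tissue
    af: AlleleFraction
    age_at_sample: Optional[float] = None
    note: Optional[str] = None


class CancerDiagnosis(StrictModel):
    label: str
    age_at_dx: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "CancerDiagnosis":
        if not self.label:
            raise ValueError("diagnosis label must be non-empty")
        if self.age_at_dx is not None and not 0 <= self.age_at_dx <= 120:
            raise ValueError(f"age_at_dx={self.age_at_dx} outside 0-120")
        return self


class FamilyMember(StrictModel):
    degree: Degree
    diagnoses: list[CancerDiagnosis]

    @model_validator(mode="after")
    def _check(self) -> "FamilyMember":
        if not self.diagnoses:
            raise ValueError("family member must have at least one diagnosis")
        return self


class ClinicalContext(StrictModel):
    """Chart-review facts the decision cascade consults beyond the variants."""

    chemo_history: ChemoHistory = ChemoHistory.UNKNOWN
    wbc: Optional[float] = None
    heme_malignancy_dx: Optional[str] = None
    deceased: bool = False

    @model_validator(mode="after")
    def _check(self) -> "ClinicalContext":
        if self.wbc is not None and self.wbc <= 0:
            raise ValueError("wbc must be positive when present")
        return self


class PatientRecord(StrictModel):
    """One proband: diagnoses, family history, clinical context, variants and
    per-tissue allele-fraction observations.

    Every variant must carry at least one PBL observation (a variant never
    seen in blood is encoded with an explicit ABSENT blood observation, which
    is how skin-limited findings are represented).
    """

    patient_id: str
    sex: str
    ethnicity: Optional[str] = None
    diagnoses: list[CancerDiagnosis] = []
    family: list[FamilyMember] = []
    clinical: ClinicalContext = ClinicalContext()
    variants: list[VariantCall] = []
    observations: list[TissueObservation] = []

    @model_validator(mode="after")
    def _check(self) -> "PatientRecord":
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            raise ValueError(f"patient {self.patient_id}: duplicate variant keys")
        keyset = set(keys)
        for obs in self.observations:
            if obs.variant_key not in keyset:
                raise ValueError(
                    f"patient {self.patient_id}: observation references "
                    f"undeclared variant {obs.variant_key!r}"
                )
        pbl_keys = {
            o.variant_key for o in self.observations if o.tissue is Tissue.PBL
        }
        for key in keys:
            if key not in pbl_keys:
                raise ValueError(
                    f"patient {self.patient_id}: variant {key!r} has no PBL "
                    "observation (encode an explicit ABSENT one if undetected)"
                )
        return self

    def variant(self, key: str) -> VariantCall:
        for v in self.variants:
            if v.key == key:
                return v
        from .errors import VariantLookupError

        raise VariantLookupError(
            f"patient {self.patient_id}: unknown variant key {key!r}"
        )

    def observations_for(
        self, key: str, tissue: Optional[Tissue] = None
    ) -> list[TissueObservation]:
        return [
            o
            for o in self.observations
            if o.variant_key == key and (tissue is None or o.tissue is tissue)
        ]


class ThresholdConfig(StrictModel):
    """Allele-fraction bands and clinical cut-offs, all configurable.

    ``het_low``/``het_high`` bound the empirical heterozygous calling window
    (percent). ``category2_lower``/``category2_upper`` bound the low-AF
    inclusion band for the screen; the lower bound defaults to the assay
    noise floor rather than the nominal 10% so that sub-10% reportable calls
    still screen in. ``trace_ceiling`` separates trace-level findings
    (contamination-range) from sub-heterozygous ones. A direct-skin call at or
    below ``contamination_ratio`` times the blood AF is flagged as probable
    blood (leukocyte) carry-over. ``tumour_germline_min`` is the minimum
    tumour AF compatible with a germline variant (below it the tumour result
    counts against germline origin). WBC bounds are in 1e9 cells/L.
    """

    het_low: float = 30.0
    het_high: float = 70.0
    category2_upper: float = 30.0
    category2_lower: float = 1.0
    detection_floor: float = 1.0
    trace_ceiling: float = 10.0
    contamination_ratio: float = 0.5
    wbc_normal_low: float = 4.0
    wbc_normal_high: float = 11.0
    tumour_germline_min: float = 30.0
    # Band above het_low within which a het call is "borderline" and a
    # co-occurring low-AF hit in another gene counts against germline origin.
    borderline_margin: float = 10.0

    @model_validator(mode="after")
    def _check(self) -> "ThresholdConfig":
        if not (
            0
            < self.detection_floor
            <= self.trace_ceiling
            < self.het_low
            < self.het_high
            <= 100
        ):
            raise ValueError(
                "require 0 < detection_floor <= trace_ceiling < het_low < "
                "het_high <= 100"
            )
        if not self.category2_lower < self.category2_upper:
            raise ValueError("category2_lower must be < category2_upper")
        if not 0 < self.wbc_normal_low < self.wbc_normal_high:
            raise ValueError("wbc normal range must be ordered and positive")
        if not 0 <= self.contamination_ratio <= 1:
            raise ValueError("contamination_ratio must be a fraction in [0, 1]")
        return self


def max_pbl_af(patient: PatientRecord, variant_key: str) -> float:
    """Maximum quantified PBL allele fraction for a variant (0 if none).

    The maximum over blood draws is used as the reference for contamination
    testing: blood clones wax and wane, and the largest observed clone bounds
    the blood carry-over achievable in another sample.
    """
    reps = [
        o.af.representative
        for o in patient.observations_for(variant_key, Tissue.PBL)
        if o.af.representative is not None
    ]
    return max(reps) if reps else 0.0


def pbl_detected(patient: PatientRecord, variant_key: str) -> bool:
    """True if the variant was seen in blood at all (quantified or not)."""
    return any(
        o.af.status is not AFStatus.ABSENT
        for o in patient.observations_for(variant_key, Tissue.PBL)
    )
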