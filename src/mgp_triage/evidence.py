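"""Grade raw per-tissue allele fractions into presence calls and assemble
per-variant evidence.

Presence levels follow the assay's heterozygous calling window: below the
detection floor a result is ABSENT; below the trace ceiling it is TRACE
(the range blood carry-over produces in a contaminated biopsy); between
trace ceiling and the low heterozygous bound it is PRESENT_SUBHET (the
mosaic range); within the window PRESENT_HET; above it PRESENT_HIGH (a
clonal-expansion / loss-of-heterozygosity signature in blood).

A direct skin punch biopsy is vascularised tissue: leukocytes from a large
blood clone contaminate it at a fraction of the blood allele fraction. A
skin call at or below ``contamination_ratio`` times the largest blood AF is
therefore flagged ``contamination_suspected`` rather than treated as an
independent second-tissue detection. Cultured fibroblasts, muscle and buccal
DNA are graded HIGH reliability (leukocyte-poor), tumour MEDIUM (lymphocyte
admixture), direct skin LOW.
"""

from __future__ import annotations

from typing import Optional

from pydantic import model_validator

import enum

from .model import (
    AFStatus,
    PatientRecord,
    StrictModel,
    ThresholdConfig,
    Tissue,
    TissueObservation,
    VariantCall,
    max_pbl_af,
)


class PresenceLevel(str, enum.Enum):
    ABSENT = "ABSENT"
    TRACE = "TRACE"
    PRESENT_SUBHET = "PRESENT_SUBHET"
    PRESENT_HET = "PRESENT_HET"
    PRESENT_HIGH = "PRESENT_HIGH"


#: Total order on presence levels (raising the AF never lowers the level).
LEVEL_ORDER = {
    PresenceLevel.ABSENT: 0,
    PresenceLevel.TRACE: 1,
    PresenceLevel.PRESENT_SUBHET: 2,
    PresenceLevel.PRESENT_HET: 3,
    PresenceLevel.PRESENT_HIGH: 4,
}


class Reliability(str, enum.Enum):
    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    LOW = "LOW"


TISSUE_RELIABILITY = {
    Tissue.CULTURED_FIBROBLAST: Reliability.HIGH,
    Tissue.MUSCLE: Reliability.HIGH,
    # Buccal swabs are a practical skin-biopsy alternative, but buccal DNA
    # carries some leukocyte admixture; the grade stays HIGH with a caveat in
    # the call basis.
    Tissue.BUCCAL: Reliability.HIGH,
    Tissue.TUMOUR: Reliability.MEDIUM,
    Tissue.OTHER_NORMAL: Reliability.MEDIUM,
    Tissue.DIRECT_SKIN: Reliability.LOW,
}


class PresenceCall(StrictModel):
    level: PresenceLevel
    contamination_suspected: bool = False
    basis: str = ""


class TissueEvidence(StrictModel):
    """Everything the decision cascade needs to know about one variant."""

    variant_key: str
    calls: dict[Tissue, PresenceCall]
    reliability: dict[Tissue, Reliability]
    #: other variants of the same patient detected in skin but never in blood
    skin_only_variants: list[VariantCall] = []
    #: ordered (age, AF%) blood series; unknown ages sort last in input order
    pbl_af_series: list[tuple[Optional[float], float]] = []
    pbl_af_fluctuation: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "TissueEvidence":
        if self.pbl_af_fluctuation < 0:
            raise ValueError("fluctuation must be >= 0")
        return self

    @property
    def max_pbl(self) -> float:
        return max((af for _, af in self.pbl_af_series), default=0.0)


def call_presence(
    obs: TissueObservation,
    pbl_reference_af: float,
    config: ThresholdConfig | None = None,
) -> PresenceCall:
    """Grade one observation against the configured AF bands.

    ``pbl_reference_af`` is the maximum blood AF of the same variant (0 if
    never quantified in blood); it anchors the contamination test for direct
    skin biopsies.
    """
    config = config or ThresholdConfig()
    rep = obs.af.representative

    if obs.af.status is AFStatus.PRESENT_UNQUANTIFIED:
        # Laboratory shorthand for a low-level detection without a number.
        suspected = (
            obs.tissue is Tissue.DIRECT_SKIN
            and pbl_reference_af >= config.detection_floor
        )
        basis = "present, unquantified by source laboratory; graded as trace"
        if suspected:
            basis += (
                f"; at/below contamination range of blood AF {pbl_reference_af:g}%"
            )
        return PresenceCall(
            level=PresenceLevel.TRACE,
            contamination_suspected=suspected,
            basis=basis,
        )

    if obs.af.status is AFStatus.ABSENT or rep is None or rep < config.detection_floor:
        basis = (
            "not detected"
            if obs.af.status is AFStatus.ABSENT
            else f"{rep:g}% below detection floor {config.detection_floor:g}%"
        )
        return PresenceCall(level=PresenceLevel.ABSENT, basis=basis)

    if rep < config.trace_ceiling:
        level = PresenceLevel.TRACE
    elif rep < config.het_low:
        level = PresenceLevel.PRESENT_SUBHET
    elif rep <= config.het_high:
        level = PresenceLevel.PRESENT_HET
    else:
        level = PresenceLevel.PRESENT_HIGH

    suspected = (
        obs.tissue is Tissue.DIRECT_SKIN
        and level in (PresenceLevel.TRACE, PresenceLevel.PRESENT_SUBHET)
        and rep <= config.contamination_ratio * pbl_reference_af
    )
    basis = f"{rep:g}% -> {level.value}"
    if suspected:
        basis += (
            f" at <= {config.contamination_ratio:g} x blood AF "
            f"{pbl_reference_af:g}%: blood contamination suspected"
        )
    if obs.tissue is Tissue.BUCCAL:
        basis += "; buccal DNA is leukocyte-admixture-prone"
    return PresenceCall(level=level, contamination_suspected=suspected, basis=basis)


def summarize_evidence(
    patient: PatientRecord,
    variant_key: str,
    config: ThresholdConfig | None = None,
) -> TissueEvidence:
    """Assemble per-tissue calls and the blood AF series for one variant.

    For a tissue sampled more than once (serial blood draws) the call is made
    on the highest representative AF. Variants of the same patient detected
    in direct skin but never in blood are listed as skin-only co-findings;
    they annotate the report but never reclassify the blood variant.
    """
    config = config or ThresholdConfig()
    patient.variant(variant_key)  # raises VariantLookupError if unknown
    ref = max_pbl_af(patient, variant_key)

    obs_by_tissue: dict[Tissue, list[TissueObservation]] = {}
    for obs in patient.observations_for(variant_key):
        obs_by_tissue.setdefault(obs.tissue, []).append(obs)

    calls: dict[Tissue, PresenceCall] = {}
    for tissue, obs_list in obs_by_tissue.items():
        def sort_key(o: TissueObservation):
            rep = o.af.representative
            detected = o.af.status is not AFStatus.ABSENT
            return (rep if rep is not None else -1.0, detected)

        best = max(obs_list, key=sort_key)
        calls[tissue] = call_presence(best, ref, config)

    reliability = {
        t: TISSUE_RELIABILITY[t] for t in calls if t is not Tissue.PBL
    }

    series: list[tuple[Optional[float], float]] = []
    for obs in patient.observations_for(variant_key, Tissue.PBL):
        rep = obs.af.representative
        if rep is not None:
            series.append((obs.age_at_sample, rep))
    series.sort(key=lambda p: (p[0] is None, p[0] if p[0] is not None else 0.0))
    afs = [af for _, af in series]
    fluctuation = (max(afs) - min(afs)) if len(afs) >= 2 else 0.0

    skin_only = [
        v
        for v in patient.variants
        if v.key != variant_key
        and any(
            o.af.status is not AFStatus.ABSENT
            for o in patient.observations_for(v.key, Tissue.DIRECT_SKIN)
        )
        and not any(
            o.af.status is not AFStatus.ABSENT
            for o in patient.observations_for(v.key, Tissue.PBL)
        )
    ]

    return TissueEvidence(
        variant_key=variant_key,
        calls=calls,
        reliability=reliability,
        skin_only_variants=skin_only,
        pbl_af_series=series,
        pbl_af_fluctuation=fluctuation,
    )
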