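"""Synthetic cohorts with known etiologies and binomially noised allele
fractions.

The generator emulates the statistical structure of the triage problem, one
patient at a time:

* ``GERMLINE`` — a constitutional heterozygous variant: true allele fraction
  50% in every tissue;
* ``MOSAIC`` — a post-zygotic variant shared across lineages: one
  sub-heterozygous cell fraction, the same in blood and secondary tissues
  (expected AF = cell fraction / 2 for a variant heterozygous within the
  clone);
* ``CH`` — clonal hematopoiesis: a blood-restricted clone whose AF drifts
  between draws, contaminating direct skin biopsies at a fraction of the
  blood AF, absent from cultured fibroblasts; chemotherapy exposure is
  drawn with elevated probability;
* ``HEME_MALIGNANCY`` — a blood-restricted variant at potentially high AF
  with an abnormal white-cell count and a chart diagnosis;
* ``CONTROL`` — either no reportable variant, or an ordinary heterozygous
  germline variant in a family whose history explains it (Chompret-positive
  for TP53); the screen should not include these.

Sequencing noise is binomial in the read depth at the site; no other error
model is applied.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd
from pydantic import model_validator

from .classify import (
    CH_FAMILY,
    GERMLINE_FAMILY,
    ConclusionLabel,
    PatientConclusion,
)
from .errors import ConsistencyError
from .model import (
    AlleleFraction,
    CancerDiagnosis,
    ChemoHistory,
    ClinicalContext,
    Degree,
    FamilyMember,
    Pathogenicity,
    PatientRecord,
    StrictModel,
    Tissue,
    TissueObservation,
    VariantCall,
    VariantKind,
)


class Etiology(str, enum.Enum):
    GERMLINE = "GERMLINE"
    MOSAIC = "MOSAIC"
    CH = "CH"
    HEME_MALIGNANCY = "HEME_MALIGNANCY"
    CONTROL = "CONTROL"


#: classifier label -> label family used for truth-recovery scoring
LABEL_FAMILY = {
    **{label: "germline" for label in GERMLINE_FAMILY},
    ConclusionLabel.MOSAIC: "mosaic",
    **{label: "blood_restricted" for label in CH_FAMILY},
    ConclusionLabel.HEME_MALIGNANCY_RELATED: "malignancy",
    ConclusionLabel.UNRESOLVED: "unresolved",
}

#: truth etiology -> the label family a perfect classifier assigns
EXPECTED_FAMILY = {
    Etiology.GERMLINE: "germline",
    Etiology.MOSAIC: "mosaic",
    Etiology.CH: "blood_restricted",
    Etiology.HEME_MALIGNANCY: "malignancy",
    Etiology.CONTROL: "excluded",
}

FAMILIES = ["germline", "mosaic", "blood_restricted", "malignancy", "excluded", "unresolved"]


class SimulationConfig(StrictModel):
    """Cohort-generator settings.

    Fraction ranges are CELL fractions in percent; the expected allele
    fraction of a variant heterozygous within the clone is half the cell
    fraction. ``skin_contamination`` is the fraction of the blood AF carried
    into a direct skin biopsy by leukocytes. Depth is reads per site (panel
    coverage is typically 500-1000x).
    """

    n_patients: int = 100
    etiology_weights: dict[Etiology, float] = {
        Etiology.GERMLINE: 0.15,
        Etiology.MOSAIC: 0.15,
        Etiology.CH: 0.45,
        Etiology.HEME_MALIGNANCY: 0.10,
        Etiology.CONTROL: 0.15,
    }
    depth: int = 500
    n_pbl_draws: tuple[int, int] = (1, 3)
    mosaic_cell_fraction: tuple[float, float] = (5.0, 30.0)
    ch_cell_fraction: tuple[float, float] = (5.0, 40.0)
    heme_af: tuple[float, float] = (15.0, 85.0)
    skin_contamination: tuple[float, float] = (0.0, 0.5)
    #: per-draw multiplicative drift half-range for blood-restricted clones
    ch_drift: float = 0.3
    p_secondary_tissue: dict[Tissue, float] = {
        Tissue.CULTURED_FIBROBLAST: 0.8,
        Tissue.DIRECT_SKIN: 0.5,
        Tissue.TUMOUR: 0.15,
    }
    #: probability a variant is a copy-number call reported as an AF interval
    p_interval_variant: float = 0.1
    interval_half_width: float = 2.5
    p_chemo: dict[Etiology, float] = {
        Etiology.GERMLINE: 0.3,
        Etiology.MOSAIC: 0.3,
        Etiology.CH: 0.75,
        Etiology.HEME_MALIGNANCY: 0.7,
        Etiology.CONTROL: 0.3,
    }
    wbc_normal: tuple[float, float] = (4.5, 10.5)
    wbc_heme: tuple[float, float] = (12.0, 90.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        weights = self.etiology_weights
        if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
            raise ValueError("etiology weights must be non-negative and sum > 0")
        for name in (
            "n_pbl_draws",
            "mosaic_cell_fraction",
            "ch_cell_fraction",
            "heme_af",
            "skin_contamination",
            "wbc_normal",
            "wbc_heme",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range must be ordered")
        return self


class SyntheticTruth(StrictModel):
    patient_id: str
    etiology: Etiology
    true_af_by_tissue: dict[Tissue, float] = {}
    contamination_used: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "SyntheticTruth":
        if self.etiology is Etiology.GERMLINE:
            if any(af != 50.0 for af in self.true_af_by_tissue.values()):
                raise ValueError("germline truth requires 50% in every tissue")
        if self.etiology in (Etiology.CH, Etiology.HEME_MALIGNANCY):
            for t in (Tissue.CULTURED_FIBROBLAST, Tissue.MUSCLE, Tissue.BUCCAL):
                if self.true_af_by_tissue.get(t, 0.0) != 0.0:
                    raise ValueError(
                        "blood-restricted truth requires 0% in leukocyte-free tissue"
                    )
        return self


def sample_observed_af(
    true_af: float, depth: int, rng: np.random.Generator
) -> AlleleFraction:
    """Binomial read sampling: alt ~ Binomial(depth, true_af/100).

    Zero supporting reads yield status ABSENT (the laboratory reports no
    call, not an AF of zero).
    """
    if not 0 <= true_af <= 100:
        raise ValueError(f"true_af={true_af} outside 0-100")
    alt = int(rng.binomial(depth, true_af / 100.0))
    if alt == 0:
        return AlleleFraction.absent()
    return AlleleFraction.quantified(100.0 * alt / depth)


_GENES = ["TP53", "ATM", "CHEK2", "BRCA1", "APC"]
_GENE_W = [0.6, 0.1, 0.1, 0.1, 0.1]


def _uniform(rng: np.random.Generator, rng_pair: tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _make_variant(
    rng: np.random.Generator, gene: str, key: str, config: SimulationConfig
) -> tuple[VariantCall, bool]:
    """Return a variant call and whether its AFs are reported as intervals."""
    as_interval = bool(rng.random() < config.p_interval_variant)
    if as_interval:
        call = VariantCall(
            key=key,
            gene=gene,
            cdna="c.(?_-20)_(*20_?)del",
            kind=VariantKind.WHOLE_GENE_DELETION,
            pathogenicity=Pathogenicity.PATHOGENIC,
        )
    else:
        pos = int(rng.integers(100, 2000))
        call = VariantCall(
            key=key,
            gene=gene,
            cdna=f"c.{pos}G>A",
            protein=f"p.(Arg{pos // 3}His)",
            kind=VariantKind.SNV,
            pathogenicity=Pathogenicity.PATHOGENIC,
        )
    return call, as_interval


def _observe(
    rng: np.random.Generator,
    true_af: float,
    config: SimulationConfig,
    as_interval: bool,
) -> AlleleFraction:
    af = sample_observed_af(true_af, config.depth, rng)
    if as_interval and af.value is not None:
        w = config.interval_half_width
        return AlleleFraction.interval(
            max(0.0, af.value - w), min(100.0, af.value + w)
        )
    return af


def generate_patient(
    etiology: Etiology,
    config: SimulationConfig,
    rng: np.random.Generator,
    patient_id: str = "S1",
) -> tuple[PatientRecord, SyntheticTruth]:
    """Generate one patient record plus its ground truth."""
    if not isinstance(etiology, Etiology):
        raise ValueError(f"unknown etiology {etiology!r}")

    test_age = int(rng.integers(50, 86))
    chemo = (
        ChemoHistory.YES
        if rng.random() < config.p_chemo[etiology]
        else ChemoHistory.NO
    )
    heme = etiology is Etiology.HEME_MALIGNANCY
    wbc = round(_uniform(rng, config.wbc_heme if heme else config.wbc_normal), 1)
    clinical = ClinicalContext(
        chemo_history=chemo,
        wbc=wbc,
        heme_malignancy_dx="Chronic lymphocytic leukemia" if heme else None,
    )
    # Non-spectrum personal/family history so TP53 carriers stay non-Chompret.
    diagnoses = [CancerDiagnosis(label="Serous Ovarian", age_at_dx=test_age - 2)]
    family = [
        FamilyMember(degree=Degree.FIRST, diagnoses=[CancerDiagnosis(label="Colon")])
    ]

    if etiology is Etiology.CONTROL and rng.random() < 0.5:
        # No reportable variant at all.
        record = PatientRecord(
            patient_id=patient_id,
            sex="F" if rng.random() < 0.5 else "M",
            diagnoses=diagnoses,
            family=family,
            clinical=clinical,
        )
        return record, SyntheticTruth(patient_id=patient_id, etiology=etiology)

    if etiology in (Etiology.GERMLINE, Etiology.HEME_MALIGNANCY):
        gene = "TP53"
    else:
        gene = str(rng.choice(_GENES, p=_GENE_W))
    variant, as_interval = _make_variant(rng, gene, "v1", config)

    contamination = _uniform(rng, config.skin_contamination)
    truth_af: dict[Tissue, float] = {}
    if etiology is Etiology.GERMLINE:
        base = 50.0
    elif etiology is Etiology.MOSAIC:
        base = _uniform(rng, config.mosaic_cell_fraction) / 2.0
    elif etiology is Etiology.CH:
        base = _uniform(rng, config.ch_cell_fraction) / 2.0
    elif etiology is Etiology.HEME_MALIGNANCY:
        base = _uniform(rng, config.heme_af)
    else:  # CONTROL with an explained germline variant
        gene = "TP53"
        variant, as_interval = _make_variant(rng, gene, "v1", config)
        base = 50.0
        # Chompret-positive history: early-onset breast cancer.
        diagnoses = [CancerDiagnosis(label="Breast", age_at_dx=28)]
    truth_af[Tissue.PBL] = base

    observations: list[TissueObservation] = []
    lo, hi = config.n_pbl_draws
    n_draws = int(rng.integers(lo, hi + 1))
    blood_restricted = etiology in (Etiology.CH, Etiology.HEME_MALIGNANCY)
    for i in range(n_draws):
        if blood_restricted:
            drift = 1.0 + float(rng.uniform(-config.ch_drift, config.ch_drift))
            draw_true = float(np.clip(base * drift, 1.0, 95.0))
        else:
            draw_true = base
        observations.append(
            TissueObservation(
                variant_key="v1",
                tissue=Tissue.PBL,
                af=_observe(rng, draw_true, config, as_interval),
                age_at_sample=test_age + i,
            )
        )
    if all(o.af.status.value == "ABSENT" for o in observations):
        # The clone fell below the assay: keep the record valid (the screen
        # will simply not include it).
        pass

    secondary_truth = {
        Tissue.CULTURED_FIBROBLAST: 0.0 if blood_restricted else base,
        Tissue.DIRECT_SKIN: contamination * base if blood_restricted else base,
        Tissue.TUMOUR: 0.0 if blood_restricted else base,
    }
    if etiology is Etiology.GERMLINE or (
        etiology is Etiology.CONTROL and base == 50.0
    ):
        secondary_truth = {t: 50.0 for t in secondary_truth}
    for tissue, p in config.p_secondary_tissue.items():
        if rng.random() < p:
            t_af = secondary_truth[tissue]
            truth_af[tissue] = t_af
            observations.append(
                TissueObservation(
                    variant_key="v1",
                    tissue=tissue,
                    af=_observe(rng, t_af, config, as_interval),
                    age_at_sample=test_age + n_draws,
                )
            )

    record = PatientRecord(
        patient_id=patient_id,
        sex="F" if rng.random() < 0.5 else "M",
        diagnoses=diagnoses,
        family=family,
        clinical=clinical,
        variants=[variant],
        observations=observations,
    )
    truth = SyntheticTruth(
        patient_id=patient_id,
        etiology=etiology,
        true_af_by_tissue=truth_af,
        contamination_used=contamination if blood_restricted else 0.0,
    )
    return record, truth


def generate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[list[PatientRecord], list[SyntheticTruth]]:
    """Generate a cohort reproducibly from ``config.seed``."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    etiologies = list(config.etiology_weights)
    weights = np.array([config.etiology_weights[e] for e in etiologies], dtype=float)
    weights = weights / weights.sum()

    patients, truths = [], []
    width = max(3, len(str(config.n_patients)))
    for i in range(config.n_patients):
        etiology = etiologies[int(rng.choice(len(etiologies), p=weights))]
        pid = f"S{i + 1:0{width}d}"
        record, truth = generate_patient(etiology, config, rng, patient_id=pid)
        patients.append(record)
        truths.append(truth)
    return patients, truths


def evaluate_recovery(
    conclusions: list[PatientConclusion], truths: list[SyntheticTruth]
) -> pd.DataFrame:
    """Confusion matrix: rows true etiology, columns assigned label family.

    Patients with a truth entry but no conclusion were not included by the
    screen and count as "excluded". Order of the inputs is irrelevant.
    """
    truth_ids = {t.patient_id for t in truths}
    extra = {c.patient_id for c in conclusions} - truth_ids
    if extra:
        raise ConsistencyError(f"conclusions for unknown patients: {sorted(extra)}")

    by_id = {c.patient_id: c for c in conclusions}
    rows = [e.value for e in Etiology]
    mat = pd.DataFrame(0, index=rows, columns=FAMILIES, dtype=int)
    for t in truths:
        conc = by_id.get(t.patient_id)
        family = "excluded" if conc is None else LABEL_FAMILY[conc.primary_label]
        mat.loc[t.etiology.value, family] += 1
    return mat


def recovery_accuracy(matrix: pd.DataFrame) -> float:
    """Fraction of patients whose assigned family matches their etiology."""
    total = int(matrix.to_numpy().sum())
    if total == 0:
        return float("nan")
    hits = sum(
        int(matrix.loc[e.value, EXPECTED_FAMILY[e]]) for e in Etiology
    )
    return hits / total
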