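import pytest

from mgp_triage import (
    AlleleFraction,
    ChemoHistory,
    ClinicalContext,
    ConclusionLabel,
    PatientRecord,
    Pathogenicity,
    ThresholdConfig,
    Tissue,
    TissueObservation,
    VariantCall,
    VariantKind,
    load_fixture_cohort,
    run_pipeline,
)

#: Published per-patient conclusions for the 24-patient reference cohort.
EXPECTED_LABELS = {
    "2": ConclusionLabel.CONFIRMED_CH,
    "3": ConclusionLabel.CONFIRMED_CH,
    "5": ConclusionLabel.LIKELY_CH,
    "6": ConclusionLabel.LIKELY_CH,
    "7": ConclusionLabel.MOSAIC,
    "8": ConclusionLabel.LIKELY_CH,
    "10": ConclusionLabel.CONFIRMED_CH,
    "11": ConclusionLabel.HEME_MALIGNANCY_RELATED,
    "12": ConclusionLabel.HEME_MALIGNANCY_RELATED,
    "13": ConclusionLabel.CONFIRMED_CH,
    "14": ConclusionLabel.LIKELY_CH,
    "15": ConclusionLabel.CONFIRMED_CH,
    "16": ConclusionLabel.LIKELY_CH,
    "18": ConclusionLabel.CONFIRMED_CH,
    "19": ConclusionLabel.LIKELY_CH,
    "22": ConclusionLabel.LIKELY_CH,
    "24": ConclusionLabel.LIKELY_CH,
    "27": ConclusionLabel.LIKELY_CH,
    "29": ConclusionLabel.FULL_GERMLINE,
    "33": ConclusionLabel.MOSAIC,
    "40": ConclusionLabel.MOSAIC,
    "41": ConclusionLabel.LIKELY_CH,
    "42": ConclusionLabel.CONFIRMED_CH,
    "43": ConclusionLabel.CONFIRMED_CH,
}


@pytest.fixture(scope="session")
def fixture_cohort():
    return load_fixture_cohort()


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_cohort):
    return run_pipeline(fixture_cohort)


@pytest.fixture
def config():
    return ThresholdConfig()


def make_patient(
    patient_id="T1",
    gene="TP53",
    pbl=(50.0,),
    tissues=None,
    pathogenicity=Pathogenicity.PATHOGENIC,
    clinical=None,
    diagnoses=(),
    family=(),
):
    """Build a minimal single-variant patient for rule-level tests.

    ``pbl`` is a sequence of blood AFs (percent; None means an ABSENT draw);
    ``tissues`` maps a Tissue to an AF (None for ABSENT, "present" for
    present-unquantified).
    """
    variant = VariantCall(
        key="v1",
        gene=gene,
        cdna="c.100G>A",
        protein="p.(Arg34His)",
        kind=VariantKind.SNV,
        pathogenicity=pathogenicity,
    )
    obs = []
    for i, af in enumerate(pbl):
        frac = AlleleFraction.absent() if af is None else AlleleFraction.quantified(af)
        obs.append(
            TissueObservation(
                variant_key="v1", tissue=Tissue.PBL, af=frac, age_at_sample=60 + i
            )
        )
    for tissue, af in (tissues or {}).items():
        if af is None:
            frac = AlleleFraction.absent()
        elif af == "present":
            frac = AlleleFraction.present_unquantified()
        else:
            frac = AlleleFraction.quantified(af)
        obs.append(TissueObservation(variant_key="v1", tissue=tissue, af=frac))
    return PatientRecord(
        patient_id=patient_id,
        sex="F",
        diagnoses=list(diagnoses),
        family=list(family),
        clinical=clinical or ClinicalContext(chemo_history=ChemoHistory.NO, wbc=7.0),
        variants=[variant],
        observations=obs,
    )
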