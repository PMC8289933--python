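"""The decision cascade: per-variant labels, per-patient roll-up, cohort runs."""

import pytest

from conftest import EXPECTED_LABELS, make_patient
from mgp_triage import (
    ClinicalContext,
    ConclusionLabel,
    FollowUp,
    PresenceLevel,
    SimulationConfig,
    Tissue,
    classify_cohort,
    classify_variant,
    generate_cohort,
    run_pipeline,
    summarize_evidence,
)


def classify_simple(patient, config=None):
    return classify_variant(patient, "v1", None, config)


class TestVariantRules:
    def test_het_blood_plus_het_fibroblast_is_full_germline(self):
        patient = make_patient(pbl=(50.0,), tissues={Tissue.CULTURED_FIBROBLAST: 50.0})
        assert classify_simple(patient).label is ConclusionLabel.FULL_GERMLINE

    def test_all_tissues_consistent_is_full_germline(self):
        patient = make_patient(
            pbl=(50.0,),
            tissues={Tissue.CULTURED_FIBROBLAST: 50.0, Tissue.TUMOUR: 60.0},
        )
        assert classify_simple(patient).label is ConclusionLabel.FULL_GERMLINE

    def test_het_blood_without_secondary_is_likely_germline(self):
        patient = make_patient(gene="BRCA1", pbl=(50.0,))
        assert classify_simple(patient).label is ConclusionLabel.LIKELY_GERMLINE

    def test_subhet_blood_with_independent_second_tissue_is_mosaic(self):
        patient = make_patient(pbl=(23.4,), tissues={Tissue.CULTURED_FIBROBLAST: 21.0})
        assert classify_simple(patient).label is ConclusionLabel.MOSAIC

    def test_blood_only_low_af_is_likely_ch(self):
        patient = make_patient(gene="ATM", pbl=(15.0,))
        assert classify_simple(patient).label is ConclusionLabel.LIKELY_CH

    def test_blood_restricted_with_fibroblast_negative_is_confirmed_ch(self):
        patient = make_patient(pbl=(15.0,), tissues={Tissue.CULTURED_FIBROBLAST: None})
        conclusion = classify_simple(patient)
        assert conclusion.label is ConclusionLabel.CONFIRMED_CH
        assert any(rule == "tissue-negative" for rule, _ in conclusion.evidence)

    def test_contaminated_skin_alone_never_supports_mosaic(self):
        # skin at 0.3x blood is explainable as leukocyte carry-over
        patient = make_patient(pbl=(15.0,), tissues={Tissue.DIRECT_SKIN: 4.5})
        assert classify_simple(patient).label is ConclusionLabel.LIKELY_CH

    def test_fibroblast_negative_overrides_discrepant_skin_positive(self):
        patient = make_patient(
            pbl=(20.0,),
            tissues={Tissue.DIRECT_SKIN: 15.0, Tissue.CULTURED_FIBROBLAST: None},
        )
        assert classify_simple(patient).label is ConclusionLabel.CONFIRMED_CH

    def test_chart_malignancy_dominates_tissue_negative(self):
        patient = make_patient(
            pbl=(53.3, 82.3),
            tissues={Tissue.CULTURED_FIBROBLAST: None},
            clinical=ClinicalContext(
                chemo_history="YES", wbc=84.9,
                heme_malignancy_dx="Chronic lymphocytic leukemia",
            ),
        )
        conclusion = classify_simple(patient)
        assert conclusion.label is ConclusionLabel.HEME_MALIGNANCY_RELATED
        assert conclusion.cbc_flag

    def test_abnormal_wbc_alone_does_not_change_the_label(self):
        patient = make_patient(
            pbl=(15.0,),
            tissues={Tissue.CULTURED_FIBROBLAST: None},
            clinical=ClinicalContext(chemo_history="YES", wbc=12.2),
        )
        conclusion = classify_simple(patient)
        assert conclusion.label is ConclusionLabel.CONFIRMED_CH
        assert conclusion.cbc_flag


class TestFixtureConclusions:
    def test_all_24_primary_labels_match_published_conclusions(self, fixture_pipeline):
        got = {c.patient_id: c.primary_label for c in fixture_pipeline.conclusions}
        assert got == EXPECTED_LABELS

    def test_patient_41_reasoning_is_recorded(self, fixture_pipeline):
        c41 = next(c for c in fixture_pipeline.conclusions if c.patient_id == "41")
        assert c41.primary_label is ConclusionLabel.LIKELY_CH
        tp53 = next(vc for vc in c41.primary_variants if vc.variant_key == "v1")
        rules = [rule for rule, _ in tp53.evidence]
        assert "contra-tumour-negative" in rules
        assert rules[-1] == "ch-likely-contradicted"

    def test_patient_24_brca1_is_a_likely_germline_co_finding(self, fixture_pipeline):
        c24 = next(c for c in fixture_pipeline.conclusions if c.patient_id == "24")
        assert c24.primary_label is ConclusionLabel.LIKELY_CH
        (co,) = c24.co_findings
        assert co.variant_key == "v2"
        assert co.label is ConclusionLabel.LIKELY_GERMLINE
        assert FollowUp.CBC_MONITORING in c24.follow_up

    def test_patient_12_followup_is_hematology_referral(self, fixture_pipeline):
        c12 = next(c for c in fixture_pipeline.conclusions if c.patient_id == "12")
        assert c12.follow_up == {FollowUp.HEMATOLOGY_REFERRAL}

    def test_patient_40_mosaic_via_unquantified_polyp(self, fixture_pipeline):
        c40 = next(c for c in fixture_pipeline.conclusions if c.patient_id == "40")
        assert c40.primary_label is ConclusionLabel.MOSAIC

    def test_patient_10_skin_only_variants_are_annotations(self, fixture_pipeline):
        c10 = next(c for c in fixture_pipeline.conclusions if c.patient_id == "10")
        assert c10.primary_label is ConclusionLabel.CONFIRMED_CH
        assert {vc.variant_key for vc in c10.co_findings} == {"v2", "v3"}
        assert all(
            vc.label is ConclusionLabel.UNRESOLVED for vc in c10.co_findings
        )

    def test_removing_patient_29_fibroblast_downgrades_to_likely_germline(
        self, fixture_cohort
    ):
        p29 = next(p for p in fixture_cohort if p.patient_id == "29")
        stripped = p29.model_copy(deep=True)
        stripped.observations = [
            o for o in stripped.observations if o.tissue is Tissue.PBL
        ]
        assert classify_simple(stripped).label is ConclusionLabel.LIKELY_GERMLINE

    def test_deterministic_on_repeat(self, fixture_cohort):
        first = classify_cohort(fixture_cohort)
        second = classify_cohort(fixture_cohort)
        assert first == second

    def test_excluded_patients_are_omitted(self):
        patient = make_patient(gene="BRCA2", pbl=(50.0,))
        assert classify_cohort([patient]) == []

    def test_empty_cohort(self):
        assert classify_cohort([]) == []


@pytest.fixture(scope="module")
def random_run():
    patients, _ = generate_cohort(SimulationConfig(n_patients=300, seed=31))
    return patients, run_pipeline(patients)


class TestCohortProperties:

    def test_every_included_patient_gets_a_primary_label(self, random_run):
        patients, result = random_run
        included = {r.patient_id for r in result.inclusions if r.included}
        assert {c.patient_id for c in result.conclusions} == included
        assert not result.errors

    def test_no_full_germline_without_high_reliability_het_call(self, random_run):
        patients, result = random_run
        by_id = {p.patient_id: p for p in patients}
        for c in result.conclusions:
            for vc in c.primary_variants + c.co_findings:
                if vc.label is not ConclusionLabel.FULL_GERMLINE:
                    continue
                ev = result.evidence[(c.patient_id, vc.variant_key)]
                assert any(
                    ev.reliability.get(t) is not None
                    and ev.reliability[t].value == "HIGH"
                    and call.level is PresenceLevel.PRESENT_HET
                    for t, call in ev.calls.items()
                    if t is not Tissue.PBL
                )

    def test_no_mosaic_from_contamination_suspected_calls_alone(self, random_run):
        patients, result = random_run
        for c in result.conclusions:
            for vc in c.primary_variants + c.co_findings:
                if vc.label is not ConclusionLabel.MOSAIC:
                    continue
                ev = result.evidence[(c.patient_id, vc.variant_key)]
                assert any(
                    call.level is not PresenceLevel.ABSENT
                    and not call.contamination_suspected
                    for t, call in ev.calls.items()
                    if t is not Tissue.PBL
                )
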