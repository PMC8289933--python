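"""Chompret evaluation and the three-category inclusion screen."""

import pytest
from pydantic import ValidationError

from conftest import make_patient
from mgp_triage import (
    AlleleFraction,
    CancerDiagnosis,
    ChompretResult,
    ChompretRules,
    Degree,
    FamilyMember,
    PatientRecord,
    SimulationConfig,
    Tissue,
    TissueObservation,
    VariantCall,
    evaluate_chompret,
    generate_cohort,
    screen_cohort,
    screen_patient,
)
from mgp_triage.errors import CohortValidationError


class TestChompret:
    def test_no_cancer_and_no_family_is_unmet(self):
        patient = make_patient(diagnoses=(), family=())
        result = evaluate_chompret(patient)
        assert not result.met and result.fired_rule is None

    def test_early_onset_breast_alone_fires(self):
        patient = make_patient(
            diagnoses=(CancerDiagnosis(label="Breast", age_at_dx=30),)
        )
        result = evaluate_chompret(patient)
        assert result.met and result.fired_rule == "early_onset_breast"

    def test_familial_presentation_needs_documented_relative_age(self):
        dx = (CancerDiagnosis(label="Breast", age_at_dx=40),)
        relative_no_age = FamilyMember(
            degree=Degree.SECOND, diagnoses=[CancerDiagnosis(label="Sarcoma")]
        )
        assert not evaluate_chompret(make_patient(diagnoses=dx, family=(relative_no_age,))).met
        relative_aged = FamilyMember(
            degree=Degree.SECOND,
            diagnoses=[CancerDiagnosis(label="Sarcoma", age_at_dx=40)],
        )
        result = evaluate_chompret(make_patient(diagnoses=dx, family=(relative_aged,)))
        assert result.met and result.fired_rule == "familial_presentation"

    def test_rare_tumour_fires_regardless_of_family(self):
        patient = make_patient(
            diagnoses=(CancerDiagnosis(label="Adrenocortical Carcinoma", age_at_dx=70),)
        )
        assert evaluate_chompret(patient).fired_rule == "rare_tumour"

    def test_fixture_patient_7_unmet_without_relative_ages(self, fixture_cohort):
        # early-onset spectrum tumour in the proband, 13 affected relatives,
        # but no relative diagnosis age is documented -> conservative unmet
        p7 = next(p for p in fixture_cohort if p.patient_id == "7")
        result = evaluate_chompret(p7)
        assert not result.met
        assert "relative" in result.rationale

    def test_removing_ages_never_flips_unmet_to_met(self, fixture_cohort):
        for patient in fixture_cohort:
            if evaluate_chompret(patient).met:
                continue
            stripped = patient.model_copy(deep=True)
            for d in stripped.diagnoses:
                d.age_at_dx = None
            for m in stripped.family:
                for d in m.diagnoses:
                    d.age_at_dx = None
            assert not evaluate_chompret(stripped).met

    def test_result_invariant_met_iff_rule(self):
        with pytest.raises(ValidationError):
            ChompretResult(met=True, fired_rule=None)


class TestScreen:
    def test_single_heterozygous_non_tp53_not_included(self):
        patient = make_patient(gene="BRCA2", pbl=(50.0,))
        result = screen_patient(patient)
        assert result.categories == set() and not result.included

    def test_low_af_fires_category_2(self):
        result = screen_patient(make_patient(pbl=(12.0,)))
        assert 2 in result.categories

    def test_any_blood_draw_in_low_band_suffices(self):
        result = screen_patient(make_patient(gene="ATM", pbl=(45.0, 22.0)))
        assert 2 in result.categories

    def test_tp53_without_chompret_fires_category_3(self):
        result = screen_patient(make_patient(gene="TP53", pbl=(50.0,)))
        assert result.categories == {3}

    def test_tp53_with_chompret_positive_family_not_category_3(self):
        patient = make_patient(
            gene="TP53",
            pbl=(50.0,),
            diagnoses=(CancerDiagnosis(label="Breast", age_at_dx=28),),
        )
        assert 3 not in screen_patient(patient).categories

    def test_fixture_patient_24_is_categories_1_and_2(self, fixture_pipeline):
        inc = next(r for r in fixture_pipeline.inclusions if r.patient_id == "24")
        assert inc.categories == {1, 2}

    def test_fixture_patient_29_is_category_3_only(self, fixture_pipeline):
        inc = next(r for r in fixture_pipeline.inclusions if r.patient_id == "29")
        assert inc.categories == {3}

    def test_fixture_category_counts(self, fixture_pipeline):
        inclusions = fixture_pipeline.inclusions
        assert sum(r.included for r in inclusions) == 24
        assert sum(1 for r in inclusions if 1 in r.categories) == 4
        assert sum(1 for r in inclusions if 2 in r.categories) == 18
        cat3 = [r for r in inclusions if 3 in r.categories]
        assert len(cat3) == 17

    def test_category_3_implies_tp53_and_non_chompret(self, fixture_cohort):
        patients, _ = generate_cohort(SimulationConfig(n_patients=150, seed=9))
        patients = patients + list(fixture_cohort)
        by_id = {p.patient_id: p for p in patients}
        for r in screen_cohort(patients):
            if 3 in r.categories:
                assert not r.chompret.met
                assert any(v.gene == "TP53" for v in by_id[r.patient_id].variants)

    def test_adding_a_pathogenic_variant_never_removes_categories(self, fixture_cohort):
        extra = VariantCall(
            key="extra", gene="PALB2", cdna="c.509_510del", kind="INDEL",
            pathogenicity="PATHOGENIC",
        )
        for patient in fixture_cohort:
            before = screen_patient(patient).categories
            doc = patient.model_dump()
            doc["variants"].append(extra.model_dump())
            doc["observations"].append(
                TissueObservation(
                    variant_key="extra", tissue=Tissue.PBL,
                    af=AlleleFraction.quantified(48.0),
                ).model_dump()
            )
            augmented = PatientRecord.model_validate(doc)
            assert screen_patient(augmented).categories >= before

    def test_duplicate_ids_rejected(self):
        patient = make_patient()
        with pytest.raises(CohortValidationError):
            screen_cohort([patient, patient])
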