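"""Presence grading, contamination detection, and evidence assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_patient
from mgp_triage import (
    AlleleFraction,
    PresenceLevel,
    Reliability,
    ThresholdConfig,
    Tissue,
    TissueObservation,
    call_presence,
    sample_observed_af,
    summarize_evidence,
)
from mgp_triage.errors import VariantLookupError
from mgp_triage.evidence import LEVEL_ORDER


def obs(tissue, af, **kwargs):
    if af is None:
        frac = AlleleFraction.absent()
    elif af == "present":
        frac = AlleleFraction.present_unquantified()
    else:
        frac = AlleleFraction.quantified(af)
    return TissueObservation(variant_key="v1", tissue=tissue, af=frac, **kwargs)


class TestCallPresence:
    @pytest.mark.parametrize(
        "af,expected",
        [
            (None, PresenceLevel.ABSENT),
            (0.5, PresenceLevel.ABSENT),  # below detection floor
            (5.0, PresenceLevel.TRACE),
            (15.0, PresenceLevel.PRESENT_SUBHET),
            (50.0, PresenceLevel.PRESENT_HET),
            (82.3, PresenceLevel.PRESENT_HIGH),
        ],
    )
    def test_level_bands(self, af, expected, config):
        call = call_presence(obs(Tissue.PBL, af), 0.0, config)
        assert call.level is expected

    def test_skin_trace_below_half_blood_flags_contamination(self, config):
        # direct skin at 2.2% against a 15% blood clone
        call = call_presence(obs(Tissue.DIRECT_SKIN, 2.2), 15.0, config)
        assert call.level is PresenceLevel.TRACE
        assert call.contamination_suspected

    def test_fibroblast_never_flagged_as_contamination(self, config):
        # same fractions, but a cultured fibroblast carries no leukocytes
        call = call_presence(obs(Tissue.CULTURED_FIBROBLAST, 2.2), 15.0, config)
        assert not call.contamination_suspected

    def test_subhet_fibroblast_matching_blood_is_independent_signal(self, config):
        call = call_presence(obs(Tissue.CULTURED_FIBROBLAST, 24.0), 23.6, config)
        assert call.level is PresenceLevel.PRESENT_SUBHET
        assert not call.contamination_suspected

    def test_skin_above_contamination_ratio_not_flagged(self, config):
        call = call_presence(obs(Tissue.DIRECT_SKIN, 27.0), 23.6, config)
        assert not call.contamination_suspected

    def test_unquantified_presence_graded_trace(self, config):
        call = call_presence(obs(Tissue.DIRECT_SKIN, "present"), 12.5, config)
        assert call.level is PresenceLevel.TRACE
        assert call.contamination_suspected
        assert "unquantified" in call.basis

    @settings(max_examples=60, deadline=None)
    @given(
        lo=st.floats(min_value=0, max_value=100),
        hi=st.floats(min_value=0, max_value=100),
        ref=st.floats(min_value=0, max_value=100),
    )
    def test_level_monotone_in_allele_fraction(self, lo, hi, ref):
        lo, hi = min(lo, hi), max(lo, hi)
        cfg = ThresholdConfig()
        low_call = call_presence(obs(Tissue.PBL, lo), ref, cfg)
        high_call = call_presence(obs(Tissue.PBL, hi), ref, cfg)
        assert LEVEL_ORDER[low_call.level] <= LEVEL_ORDER[high_call.level]

    @settings(max_examples=60, deadline=None)
    @given(
        tissue=st.sampled_from(list(Tissue)),
        af=st.floats(min_value=0, max_value=100),
        ref=st.floats(min_value=0, max_value=100),
    )
    def test_contamination_flag_only_for_direct_skin(self, tissue, af, ref):
        call = call_presence(obs(tissue, af), ref, ThresholdConfig())
        if call.contamination_suspected:
            assert tissue is Tissue.DIRECT_SKIN


class TestSummarizeEvidence:
    def test_fixture_patient_2_calls_and_fluctuation(self, fixture_cohort, config):
        p2 = next(p for p in fixture_cohort if p.patient_id == "2")
        ev = summarize_evidence(p2, "v1", config)
        assert ev.calls[Tissue.PBL].level is PresenceLevel.TRACE
        assert ev.calls[Tissue.DIRECT_SKIN].level is PresenceLevel.ABSENT
        assert ev.calls[Tissue.CULTURED_FIBROBLAST].level is PresenceLevel.ABSENT
        assert ev.max_pbl == pytest.approx(5.8)
        assert ev.pbl_af_fluctuation == pytest.approx(4.5)
        assert [age for age, _ in ev.pbl_af_series] == [66, 67, 68]

    def test_fixture_patient_10_skin_only_variants(self, fixture_cohort, config):
        p10 = next(p for p in fixture_cohort if p.patient_id == "10")
        ev = summarize_evidence(p10, "v1", config)
        assert sorted(v.cdna for v in ev.skin_only_variants) == [
            "c.380C>T",
            "c.880G>T",
        ]

    def test_single_draw_has_zero_fluctuation(self, config):
        patient = make_patient(pbl=(12.0,))
        assert summarize_evidence(patient, "v1", config).pbl_af_fluctuation == 0

    def test_reliability_grades(self, config):
        patient = make_patient(
            pbl=(12.0,),
            tissues={
                Tissue.CULTURED_FIBROBLAST: None,
                Tissue.TUMOUR: None,
                Tissue.DIRECT_SKIN: 4.0,
            },
        )
        ev = summarize_evidence(patient, "v1", config)
        assert ev.reliability[Tissue.CULTURED_FIBROBLAST] is Reliability.HIGH
        assert ev.reliability[Tissue.TUMOUR] is Reliability.MEDIUM
        assert ev.reliability[Tissue.DIRECT_SKIN] is Reliability.LOW

    def test_unknown_variant_key_raises(self, config):
        with pytest.raises(VariantLookupError):
            summarize_evidence(make_patient(), "ghost", config)


def test_contamination_detected_reliably_under_binomial_noise(config):
    """Skin at 0.3x a 20% blood clone, depth 500: the contamination flag
    fires in essentially every replicate."""
    rng = np.random.default_rng(77)
    depth, blood_true, ratio = 500, 20.0, 0.3
    hits = 0
    n_rep = 1000
    for _ in range(n_rep):
        blood = sample_observed_af(blood_true, depth, rng)
        skin = sample_observed_af(ratio * blood_true, depth, rng)
        skin_obs = TissueObservation(
            variant_key="v1", tissue=Tissue.DIRECT_SKIN, af=skin
        )
        ref = blood.representative or 0.0
        if call_presence(skin_obs, ref, config).contamination_suspected:
            hits += 1
    assert hits / n_rep >= 0.95
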