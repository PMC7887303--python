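"""Predictor derivation, GHD ascertainment and eligibility screening."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as stn

from ghdrule.cohort import (
    EraCutoffs,
    PatientRecord,
    PredictorProfile,
    RawClinicalPanel,
    ValidationError,
    ascertain_ghd,
    check_eligibility,
    derive_predictors,
)


def _record(**overrides):
    base = dict(
        patient_id="p1",
        sex="M",
        age_years=7.0,
        era=2008,
        pubertal_stage=1,
        height_sds=-2.5,
        weight_kg=22.0,
        gh_peaks_ng_ml=(3.2, 5.0),
        ghd_status="unknown",
    )
    base.update(overrides)
    return PatientRecord(**base)


class TestDerivePredictors:
    def test_tsh_deficiency_low_t4_nonelevated_tsh(self):
        panel = RawClinicalPanel(free_t4_ng_dl=0.6, tsh_mIU_l=4.0)
        prof = derive_predictors(panel, age_years=3.0, mri_available=False)
        assert prof.tsh_deficiency is True

    def test_tsh_limit_is_age_dependent(self):
        # TSH 8 is still "non-elevated" in a 1-month-old (limit 10) but
        # counts as elevated (appropriate) beyond 2 months (limit 6.5)
        panel = RawClinicalPanel(free_t4_ng_dl=0.6, tsh_mIU_l=8.0)
        young = derive_predictors(panel, age_years=1 / 12, mri_available=False)
        old = derive_predictors(panel, age_years=1.0, mri_available=False)
        assert young.tsh_deficiency is True
        assert old.tsh_deficiency is False

    def test_cholestasis_from_bilirubin_ratio(self):
        panel = RawClinicalPanel(conjugated_bilirubin=1.2, total_bilirubin=6.0)
        prof = derive_predictors(panel, age_years=0.05, mri_available=False)
        assert prof.neonatal_cholestasis is True  # ratio 0.20 > 0.15

    def test_dysgenesis_missing_without_mri(self):
        prof = derive_predictors(RawClinicalPanel(), 5.0, mri_available=False)
        assert prof.pituitary_dysgenesis is None
        assert prof.mri_available is False

    def test_dysgenesis_needs_two_of_three_findings(self):
        one = RawClinicalPanel(mri_findings=frozenset({"stalk_interrupted_or_hypoplastic"}))
        two = RawClinicalPanel(
            mri_findings=frozenset(
                {"stalk_interrupted_or_hypoplastic", "posterior_ectopic_or_absent"}
            )
        )
        assert derive_predictors(one, 5.0, True).pituitary_dysgenesis is False
        assert derive_predictors(two, 5.0, True).pituitary_dysgenesis is True

    def test_radiotherapy_below_threshold(self):
        panel = RawClinicalPanel(radiotherapy_dose_Gy=12.0)
        prof = derive_predictors(panel, 8.0, False)
        assert prof.cranial_radiotherapy_ge18Gy is False
        assert (
            derive_predictors(
                RawClinicalPanel(radiotherapy_dose_Gy=18.0), 8.0, False
            ).cranial_radiotherapy_ge18Gy
            is True
        )

    def test_microadenoma_does_not_count_as_sellar_tumor(self):
        prof = derive_predictors(
            RawClinicalPanel(tumor_or_surgery_sellar="microadenoma_only"), 9.0, False
        )
        assert prof.sellar_tumor_surgery is False

    def test_hypogenitalism_requires_two_findings(self):
        one = RawClinicalPanel(penile_length_sds=-3.0, cryptorchidism=False,
                               testis_volume_ml=2.0)
        two = RawClinicalPanel(penile_length_sds=-3.0, cryptorchidism=True,
                               testis_volume_ml=2.0)
        assert derive_predictors(one, 0.05, False).neonatal_hypogenitalism is False
        assert derive_predictors(two, 0.05, False).neonatal_hypogenitalism is True

    def test_missing_inputs_leave_flags_missing(self):
        prof = derive_predictors(RawClinicalPanel(), 5.0, mri_available=False)
        assert all(v is None for v in prof.as_dict().values())

    def test_negative_concentration_names_field(self):
        with pytest.raises(ValidationError, match="cortisol_ug_dl"):
            RawClinicalPanel(cortisol_ug_dl=-1.0)

    def test_deterministic(self):
        panel = RawClinicalPanel(free_t4_ng_dl=0.6, tsh_mIU_l=4.0,
                                 cortisol_ug_dl=3.0, acth_status="low_or_normal")
        a = derive_predictors(panel, 3.0, False)
        b = derive_predictors(panel, 3.0, False)
        assert a == b


class TestAscertainGHD:
    @pytest.mark.parametrize(
        "peaks, era, expected",
        [
            ((3.2, 5.0), 2008, "case"),  # max 5.0 < 6.1
            ((6.71, 3.0), 2017, "control"),  # one peak above the 4.7 cutoff
            ((4.7, 2.0), 2013, "control"),  # boundary: 4.7 is not < 4.7
            ((6.1, 1.0), 2008, "control"),  # boundary in the earlier era
            ((4.69, 4.0), 2013, "case"),
        ],
    )
    def test_era_dependent_cutoffs(self, peaks, era, expected):
        assert ascertain_ghd(_record(gh_peaks_ng_ml=peaks, era=era)) == expected

    def test_empty_peaks_error(self):
        with pytest.raises(ValidationError):
            ascertain_ghd(_record(gh_peaks_ng_ml=()))

    def test_era_outside_windows_error(self):
        with pytest.raises(ValidationError):
            ascertain_ghd(_record(era=1999))

    def test_two_arms_required_at_or_above_10kg(self):
        with pytest.raises(ValidationError, match="10 kg"):
            _record(gh_peaks_ng_ml=(3.0,), weight_kg=25.0, ghd_status="case")
        # a single test suffices under 10 kg
        light = _record(gh_peaks_ng_ml=(3.0,), weight_kg=8.0, age_years=0.5,
                        ghd_status="case")
        assert light.ghd_status == "case"

    @settings(max_examples=100, deadline=None)
    @given(
        peaks=stn.lists(stn.floats(0, 25, allow_nan=False), min_size=2, max_size=4),
        bump=stn.floats(0, 20, allow_nan=False),
        idx=stn.integers(0, 3),
    )
    def test_monotone_in_peaks(self, peaks, bump, idx):
        """Raising any GH peak never converts a control into a case."""
        rec = _record(gh_peaks_ng_ml=tuple(peaks))
        before = ascertain_ghd(rec)
        raised = list(peaks)
        raised[idx % len(raised)] += bump
        after = ascertain_ghd(_record(gh_peaks_ng_ml=tuple(raised)))
        assert not (before == "control" and after == "case")


class TestEligibility:
    def test_severe_short_stature(self):
        eligible, crit = check_eligibility(_record(height_sds=-3.2))
        assert eligible and "severe_short_stature" in crit

    def test_unremarkable_child_ineligible(self):
        eligible, crit = check_eligibility(_record(height_sds=-1.0))
        assert not eligible and crit == []

    def test_short_with_decelerating_growth(self):
        eligible, crit = check_eligibility(
            _record(height_sds=-2.2, height_velocity_sds=-1.4)
        )
        assert eligible and "short_and_slowing" in crit

    def test_below_midparental(self):
        eligible, crit = check_eligibility(
            _record(height_sds=-1.8, midparental_height_sds=0.2)
        )
        assert eligible and "below_midparental" in crit

    def test_all_satisfied_criteria_returned(self):
        eligible, crit = check_eligibility(
            _record(height_sds=-3.5, height_velocity_sds=-2.5,
                    intracranial_lesion_signs=True)
        )
        assert set(crit) >= {
            "severe_short_stature",
            "growth_deceleration",
            "intracranial_lesion",
        }


def test_profile_rejects_dysgenesis_without_mri():
    with pytest.raises(ValidationError):
        PredictorProfile(pituitary_dysgenesis=True, mri_available=False)


def test_cutoff_table_configurable():
    custom = EraCutoffs(windows=((2000, 2010, 10.0),))
    assert custom.cutoff_for(2005) == 10.0
    with pytest.raises(ValidationError):
        custom.cutoff_for(2011)
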