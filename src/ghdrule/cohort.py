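"""Domain model of a GH-stimulation-tested child.

A patient enters the cohort because growth failure (or neonatal signs)
triggered a growth hormone stimulation test (GHST).  This module derives
the fifteen dichotomous risk predictors from raw clinical measurements,
screens eligibility against the Growth Hormone Research Society auxologic
criteria, and ascertains GHD case/control status from the era-dependent
peak-GH cut-off.

Predictor flags are tri-state: ``True``, ``False`` or ``None`` (missing).
Missingness is a first-class value at this layer — in particular pituitary
dysgenesis is *missing*, never ``False``, when no MRI was performed.
Downstream layers (rule, tree) decide their own missing-value policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Optional, Sequence

__all__ = [
    "PREDICTORS",
    "ANTERIOR_DEFICIENCIES",
    "RULE_COMORBIDITIES",
    "EraCutoffs",
    "PredictorProfile",
    "RawClinicalPanel",
    "PatientRecord",
    "derive_predictors",
    "ascertain_ghd",
    "check_eligibility",
    "ValidationError",
]

#: The fifteen candidate predictors, in the order they appear in the
#: association table.  Column order doubles as the deterministic tie-break
#: order during tree induction.
PREDICTORS = (
    "pituitary_dysgenesis",
    "midline_abnormality",
    "sellar_tumor_surgery",
    "cns_infection",
    "severe_tbi",
    "cranial_radiotherapy_ge18Gy",
    "chemotherapy_ge6mo",
    "genetic_ghd",
    "tsh_deficiency",
    "acth_deficiency",
    "prolactin_deficiency",
    "central_diabetes_insipidus",
    "neonatal_hypoglycemia",
    "neonatal_cholestasis",
    "neonatal_hypogenitalism",
)

#: Anterior pituitary axes counted by the prediction rule.
ANTERIOR_DEFICIENCIES = (
    "tsh_deficiency",
    "acth_deficiency",
    "prolactin_deficiency",
)

#: Comorbidities that, combined with exactly one anterior deficiency,
#: fire the rule's third clause.
RULE_COMORBIDITIES = (
    "neonatal_hypoglycemia",
    "neonatal_hypogenitalism",
    "central_diabetes_insipidus",
    "midline_abnormality",
    "sellar_tumor_surgery",
    "cranial_radiotherapy_ge18Gy",
)


class ValidationError(ValueError):
    """A clinical field failed validation; the message names the field."""


@dataclass(frozen=True)
class EraCutoffs:
    """Era-dependent peak-GH cut-offs (ng/ml) for GHD ascertainment.

    The assay standard changed between eras, moving the diagnostic
    threshold from 6.1 ng/ml (2004-2011) to 4.7 ng/ml (2012-2019).
    Windows are inclusive calendar-year ranges.
    """

    windows: tuple[tuple[int, int, float], ...] = (
        (2004, 2011, 6.1),
        (2012, 2019, 4.7),
    )

    def cutoff_for(self, year: int) -> float:
        for start, end, cutoff in self.windows:
            if start <= year <= end:
                return cutoff
        raise ValidationError(
            f"era {year} outside configured study windows {self.windows}"
        )


@dataclass
class PredictorProfile:
    """Tri-state risk-predictor flags for one patient.

    Every flag is ``True``, ``False`` or ``None`` (missing).  When
    ``mri_available`` is false, ``pituitary_dysgenesis`` must be missing.
    """

    pituitary_dysgenesis: Optional[bool] = None
    midline_abnormality: Optional[bool] = None
    sellar_tumor_surgery: Optional[bool] = None
    cns_infection: Optional[bool] = None
    severe_tbi: Optional[bool] = None
    cranial_radiotherapy_ge18Gy: Optional[bool] = None
    chemotherapy_ge6mo: Optional[bool] = None
    genetic_ghd: Optional[bool] = None
    tsh_deficiency: Optional[bool] = None
    acth_deficiency: Optional[bool] = None
    prolactin_deficiency: Optional[bool] = None
    central_diabetes_insipidus: Optional[bool] = None
    neonatal_hypoglycemia: Optional[bool] = None
    neonatal_cholestasis: Optional[bool] = None
    neonatal_hypogenitalism: Optional[bool] = None
    mri_available: bool = False

    def __post_init__(self) -> None:
        if not self.mri_available and self.pituitary_dysgenesis is not None:
            raise ValidationError(
                "pituitary_dysgenesis must be missing when mri_available is False"
            )

    def as_dict(self) -> dict[str, Optional[bool]]:
        return {name: getattr(self, name) for name in PREDICTORS}

    def anterior_deficiency_count(self) -> int:
        """Number of anterior pituitary axes (TSH, ACTH, prolactin)
        flagged deficient.  Missing flags do not count."""
        return sum(bool(getattr(self, name)) for name in ANTERIOR_DEFICIENCIES)


@dataclass
class RawClinicalPanel:
    """Raw clinical/biochemical measurements the predictors derive from.

    Units are fixed by field name (free T4 ng/dl, cortisol ug/dl, glucose
    mg/dl, osmolarity mosm/l, radiotherapy Gy).  ``None`` means the
    measurement was not obtained.
    """

    free_t4_ng_dl: Optional[float] = None
    tsh_mIU_l: Optional[float] = None
    cortisol_ug_dl: Optional[float] = None
    acth_status: Optional[str] = None  # low_or_normal | high
    prolactin_centile_flag: Optional[str] = None  # below_p2_5 | normal
    plasma_glucose_mg_dl: Optional[float] = None  # neonatal, day of life 3-28
    conjugated_bilirubin: Optional[float] = None
    total_bilirubin: Optional[float] = None
    penile_length_sds: Optional[float] = None
    cryptorchidism: Optional[bool] = None
    testis_volume_ml: Optional[float] = None
    urine_plasma_osm_ratio: Optional[float] = None
    plasma_osm_mosm_l: Optional[float] = None
    polyuria: Optional[bool] = None
    glasgow_coma_scale: Optional[int] = None
    radiotherapy_dose_Gy: Optional[float] = None
    chemo_duration_months: Optional[float] = None
    mri_findings: Optional[frozenset[str]] = None
    midline_findings: Optional[frozenset[str]] = None
    tumor_or_surgery_sellar: Optional[str] = None  # yes | microadenoma_only | no
    cns_infection_history: Optional[bool] = None
    genetic: Optional[str] = None  # familial_case | pathogenic_mutation | none

    _NONNEGATIVE = (
        "free_t4_ng_dl",
        "tsh_mIU_l",
        "cortisol_ug_dl",
        "plasma_glucose_mg_dl",
        "conjugated_bilirubin",
        "total_bilirubin",
        "testis_volume_ml",
        "urine_plasma_osm_ratio",
        "plasma_osm_mosm_l",
        "radiotherapy_dose_Gy",
        "chemo_duration_months",
    )

    #: MRI findings defining the pituitary-dysgenesis triad.
    MRI_TRIAD = frozenset(
        {
            "anterior_hypoplasia_or_aplasia",
            "stalk_interrupted_or_hypoplastic",
            "posterior_ectopic_or_absent",
        }
    )

    def __post_init__(self) -> None:
        for name in self._NONNEGATIVE:
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be non-negative, got {value}")
        if (self.conjugated_bilirubin is None) != (self.total_bilirubin is None):
            raise ValidationError(
                "conjugated_bilirubin and total_bilirubin must be jointly "
                "present or jointly missing"
            )
        if self.glasgow_coma_scale is not None and not (
            3 <= self.glasgow_coma_scale <= 15
        ):
            raise ValidationError(
                f"glasgow_coma_scale must be in 3..15, got {self.glasgow_coma_scale}"
            )
        if self.mri_findings is not None:
            unknown = set(self.mri_findings) - self.MRI_TRIAD
            if unknown:
                raise ValidationError(f"unknown mri_findings {sorted(unknown)}")


@dataclass
class PatientRecord:
    """One GH-stimulation-tested child."""

    patient_id: str
    sex: str  # M | F
    age_years: float
    era: int  # calendar year of the GHST
    pubertal_stage: int  # Tanner 1-5
    height_sds: float
    weight_kg: float
    gh_peaks_ng_ml: tuple[float, ...] = ()
    weight_sds: Optional[float] = None
    bmi_sds: Optional[float] = None
    midparental_height_sds: Optional[float] = None
    height_velocity_sds: Optional[float] = None
    height_velocity_sds_2yr: Optional[float] = None
    delta_height_sds_1yr: Optional[float] = None
    igf1_sds: Optional[float] = None
    igfbp3_sds: Optional[float] = None
    intracranial_lesion_signs: bool = False
    mphd_signs: bool = False
    neonatal_ghd_signs: bool = False
    predictors: PredictorProfile = field(default_factory=PredictorProfile)
    ghd_status: str = "unknown"  # case | control | unknown

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        if self.age_years < 0:
            raise ValidationError(f"age_years must be >= 0, got {self.age_years}")
        if not 1 <= self.pubertal_stage <= 5:
            raise ValidationError(
                f"pubertal_stage must be in 1..5, got {self.pubertal_stage}"
            )
        if self.weight_kg <= 0:
            raise ValidationError(f"weight_kg must be > 0, got {self.weight_kg}")
        if any(p < 0 for p in self.gh_peaks_ng_ml):
            raise ValidationError("gh_peaks_ng_ml must be non-negative")
        if self.ghd_status not in ("case", "control", "unknown"):
            raise ValidationError(f"invalid ghd_status {self.ghd_status!r}")
        if self.ghd_status != "unknown":
            if not self.gh_peaks_ng_ml:
                raise ValidationError(
                    "gh_peaks_ng_ml required once ghd_status is ascertained"
                )
            # Children >= 10 kg undergo two sequential tests (arginine then
            # clonidine); a single test suffices under 10 kg.
            if self.weight_kg >= 10 and len(self.gh_peaks_ng_ml) < 2:
                raise ValidationError(
                    "patients weighing >= 10 kg require two sequential GHST arms"
                )


def _all_none(*values) -> bool:
    return all(v is None for v in values)


def derive_predictors(
    panel: RawClinicalPanel,
    age_years: float,
    mri_available: bool,
) -> PredictorProfile:
    """Derive the fifteen tri-state predictor flags from raw measurements.

    Thresholds (strict inequalities exactly as operationally defined):

    * pituitary dysgenesis — at least two of {anterior hypoplasia/aplasia,
      interrupted/hypoplastic stalk, ectopic/absent posterior lobe} on MRI;
      missing whenever no MRI was performed;
    * TSH deficiency — free T4 < 0.8 ng/dl with an inappropriately
      non-elevated TSH (<= 10 mIU/l under 2 months of age, <= 6.5 above);
    * ACTH deficiency — cortisol < 6.5 ug/dl with low-or-normal ACTH;
    * prolactin deficiency — below the 2.5th centile for age and sex;
    * central diabetes insipidus — polyuria with urine:plasma osmolarity
      ratio < 1.5 and plasma osmolarity > 300 mosm/l;
    * neonatal hypoglycemia — glucose < 50 mg/dl on days 3-28 of life;
    * neonatal cholestasis — conjugated/total bilirubin > 0.15;
    * neonatal hypogenitalism — at least two of {penile length < -2.5 SDS,
      cryptorchidism, testis volume < 1 ml};
    * severe TBI — Glasgow Coma Scale <= 8;
    * cranial radiotherapy — dose >= 18 Gy;
    * chemotherapy — duration >= 6 months;
    * sellar/suprasellar tumor or surgery — except pituitary microadenoma;
    * genetic GHD — familial case or pathogenic mutation.

    Missing inputs leave the corresponding flag missing (``None``).
    """
    p = panel

    # Pituitary dysgenesis: >= 2 of the MRI triad; missing without MRI.
    if not mri_available:
        dysgenesis: Optional[bool] = None
    elif p.mri_findings is None:
        dysgenesis = None
    else:
        dysgenesis = len(set(p.mri_findings) & RawClinicalPanel.MRI_TRIAD) >= 2

    if p.midline_findings is None:
        midline: Optional[bool] = None
    else:
        midline = len(p.midline_findings) > 0

    if p.tumor_or_surgery_sellar is None:
        tumor: Optional[bool] = None
    elif p.tumor_or_surgery_sellar == "yes":
        tumor = True
    elif p.tumor_or_surgery_sellar in ("microadenoma_only", "no"):
        tumor = False
    else:
        raise ValidationError(
            f"tumor_or_surgery_sellar: unknown value {p.tumor_or_surgery_sellar!r}"
        )

    cns = p.cns_infection_history

    tbi = None if p.glasgow_coma_scale is None else p.glasgow_coma_scale <= 8

    radio = None if p.radiotherapy_dose_Gy is None else p.radiotherapy_dose_Gy >= 18.0

    chemo = (
        None if p.chemo_duration_months is None else p.chemo_duration_months >= 6.0
    )

    if p.genetic is None:
        genetic: Optional[bool] = None
    elif p.genetic in ("familial_case", "pathogenic_mutation"):
        genetic = True
    elif p.genetic == "none":
        genetic = False
    else:
        raise ValidationError(f"genetic: unknown value {p.genetic!r}")

    if _all_none(p.free_t4_ng_dl, p.tsh_mIU_l):
        tsh_def: Optional[bool] = None
    elif p.free_t4_ng_dl is None or p.tsh_mIU_l is None:
        tsh_def = None
    else:
        tsh_limit = 10.0 if age_years < (2.0 / 12.0) else 6.5
        tsh_def = p.free_t4_ng_dl < 0.8 and p.tsh_mIU_l <= tsh_limit

    if p.cortisol_ug_dl is None or p.acth_status is None:
        acth_def: Optional[bool] = None
    else:
        acth_def = p.cortisol_ug_dl < 6.5 and p.acth_status == "low_or_normal"

    if p.prolactin_centile_flag is None:
        prl_def: Optional[bool] = None
    else:
        prl_def = p.prolactin_centile_flag == "below_p2_5"

    if _all_none(p.polyuria, p.urine_plasma_osm_ratio, p.plasma_osm_mosm_l):
        di: Optional[bool] = None
    elif (
        p.polyuria is None
        or p.urine_plasma_osm_ratio is None
        or p.plasma_osm_mosm_l is None
    ):
        di = None
    else:
        di = (
            p.polyuria
            and p.urine_plasma_osm_ratio < 1.5
            and p.plasma_osm_mosm_l > 300.0
        )

    hypoglycemia = (
        None if p.plasma_glucose_mg_dl is None else p.plasma_glucose_mg_dl < 50.0
    )

    if p.conjugated_bilirubin is None:
        cholestasis: Optional[bool] = None
    else:
        if p.total_bilirubin == 0:
            raise ValidationError("total_bilirubin must be > 0 when present")
        cholestasis = (p.conjugated_bilirubin / p.total_bilirubin) > 0.15

    genital_findings = [
        None if p.penile_length_sds is None else p.penile_length_sds < -2.5,
        p.cryptorchidism,
        None if p.testis_volume_ml is None else p.testis_volume_ml < 1.0,
    ]
    if all(g is None for g in genital_findings):
        hypogenitalism: Optional[bool] = None
    else:
        hypogenitalism = sum(bool(g) for g in genital_findings) >= 2

    return PredictorProfile(
        pituitary_dysgenesis=dysgenesis,
        midline_abnormality=midline,
        sellar_tumor_surgery=tumor,
        cns_infection=cns,
        severe_tbi=tbi,
        cranial_radiotherapy_ge18Gy=radio,
        chemotherapy_ge6mo=chemo,
        genetic_ghd=genetic,
        tsh_deficiency=tsh_def,
        acth_deficiency=acth_def,
        prolactin_deficiency=prl_def,
        central_diabetes_insipidus=di,
        neonatal_hypoglycemia=hypoglycemia,
        neonatal_cholestasis=cholestasis,
        neonatal_hypogenitalism=hypogenitalism,
        mri_available=mri_available,
    )


def ascertain_ghd(
    record: PatientRecord, cutoffs: EraCutoffs | None = None
) -> str:
    """Classify a tested child as GHD ``case`` or ``control``.

    A case has *every* stimulated GH peak below the era cut-off
    (max(peaks) < cutoff, strict); a control has at least one peak at or
    above it.
    """
    if cutoffs is None:
        cutoffs = EraCutoffs()
    if not record.gh_peaks_ng_ml:
        raise ValidationError("cannot ascertain GHD from an empty GH peak list")
    cutoff = cutoffs.cutoff_for(record.era)
    return "case" if max(record.gh_peaks_ng_ml) < cutoff else "control"


#: Human-readable labels for the GHRS eligibility criteria.
ELIGIBILITY_CRITERIA = {
    "severe_short_stature": "height more than 3 SD below the mean",
    "below_midparental": "height more than 1.5 SD below mid-parental height",
    "short_and_slowing": (
        "height more than 2 SD below the mean with decelerating growth"
    ),
    "growth_deceleration": "marked height-velocity deceleration without short stature",
    "intracranial_lesion": "signs indicative of an intracranial lesion",
    "mphd_signs": "signs of multiple pituitary hormone deficiency",
    "neonatal_ghd_signs": "neonatal symptoms and signs of GHD",
}


def check_eligibility(record: PatientRecord) -> tuple[bool, list[str]]:
    """Screen a record against the GHRS criteria for performing a GHST.

    Returns ``(eligible, satisfied)`` where *satisfied* lists every
    criterion key the record meets (see :data:`ELIGIBILITY_CRITERIA`).
    Missing optional fields simply cannot satisfy their criterion.
    """
    satisfied: list[str] = []
    r = record

    if r.height_sds < -3:
        satisfied.append("severe_short_stature")
    if (
        r.midparental_height_sds is not None
        and r.height_sds < r.midparental_height_sds - 1.5
    ):
        satisfied.append("below_midparental")
    if r.height_sds < -2 and (
        (r.height_velocity_sds is not None and r.height_velocity_sds < -1)
        or (
            r.delta_height_sds_1yr is not None
            and r.delta_height_sds_1yr < -0.5
            and r.age_years > 2
        )
    ):
        satisfied.append("short_and_slowing")
    if (r.height_velocity_sds is not None and r.height_velocity_sds < -2) or (
        r.height_velocity_sds_2yr is not None and r.height_velocity_sds_2yr < -1.5
    ):
        satisfied.append("growth_deceleration")
    if r.intracranial_lesion_signs:
        satisfied.append("intracranial_lesion")
    if r.mphd_signs:
        satisfied.append("mphd_signs")
    if r.neonatal_ghd_signs:
        satisfied.append("neonatal_ghd_signs")

    return (len(satisfied) > 0, satisfied)
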