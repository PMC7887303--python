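"""The final clinical prediction rule as an executable, traceable
classifier.

A child who meets the GHRS criteria for GH stimulation testing is called
GHD-positive by the rule if any one of three clauses holds:

1. pituitary dysgenesis on MRI; or
2. two or more anterior pituitary hormone (TSH, ACTH or prolactin)
   deficiencies; or
3. exactly one anterior deficiency plus at least one of: neonatal
   hypoglycemia or hypogenitalism, central diabetes insipidus,
   craniofacial midline abnormalities, (supra)sellar tumor/surgery, or
   cranial radiotherapy >= 18 Gy.

Missing predictor flags never satisfy a clause: the rule replaces a
diagnostic test, so its type I error is the costly one and missingness is
resolved conservatively toward a negative call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import pandas as pd

from .cohort import ANTERIOR_DEFICIENCIES, RULE_COMORBIDITIES, PredictorProfile
from .evaluation import ConfusionMatrix

__all__ = [
    "RuleDecision",
    "RuleDomainError",
    "classify",
    "apply_rule_to_cohort",
    "RULE_INPUTS",
]

#: The seven predictor inputs the rule reads; all others are ignored.
RULE_INPUTS = ("pituitary_dysgenesis",) + ANTERIOR_DEFICIENCIES + RULE_COMORBIDITIES


class RuleDomainError(ValueError):
    """The rule was applied outside its validated domain (an ineligible
    patient, i.e. one not meeting the GHRS criteria for a GHST)."""


@dataclass(frozen=True)
class RuleDecision:
    positive: bool
    fired_clause: str  # dysgenesis | two_plus_deficiencies | one_deficiency_plus_comorbidity | none
    qualifying_comorbidities: tuple[str, ...] = ()
    missing_policy_applied: bool = False

    def __post_init__(self) -> None:
        if self.positive != (self.fired_clause != "none"):
            raise ValueError("positive must mirror fired_clause")
        if self.qualifying_comorbidities and self.fired_clause != (
            "one_deficiency_plus_comorbidity"
        ):
            raise ValueError(
                "qualifying_comorbidities only populated for the third clause"
            )


def _flag(profile: Mapping, name: str) -> Optional[bool]:
    value = profile.get(name)
    if value is None or (value is not True and value is not False and pd.isna(value)):
        return None
    return bool(value)


def classify(
    profile: Union[PredictorProfile, Mapping],
    eligible: bool = True,
) -> RuleDecision:
    """Apply the prediction rule to one predictor profile.

    *profile* may be a :class:`~ghdrule.cohort.PredictorProfile` or any
    mapping of predictor name to True/False/missing.  *eligible* must be
    true: the rule is only validated for children meeting the GHRS
    criteria for a GHST.
    """
    if not eligible:
        raise RuleDomainError(
            "the prediction rule applies only to patients meeting the GHRS "
            "criteria for GH stimulation testing"
        )
    if isinstance(profile, PredictorProfile):
        profile = profile.as_dict()

    flags = {name: _flag(profile, name) for name in RULE_INPUTS}
    missing_applied = any(v is None for v in flags.values())

    if flags["pituitary_dysgenesis"] is True:
        return RuleDecision(True, "dysgenesis", (), missing_applied)

    n_deficiencies = sum(
        flags[name] is True for name in ANTERIOR_DEFICIENCIES
    )
    if n_deficiencies >= 2:
        return RuleDecision(True, "two_plus_deficiencies", (), missing_applied)

    if n_deficiencies == 1:
        comorbidities = tuple(
            name for name in RULE_COMORBIDITIES if flags[name] is True
        )
        if comorbidities:
            return RuleDecision(
                True, "one_deficiency_plus_comorbidity", comorbidities, missing_applied
            )

    return RuleDecision(False, "none", (), missing_applied)


def apply_rule_to_cohort(
    cohort: pd.DataFrame,
    eligibility_column: Optional[str] = "eligible",
) -> tuple[pd.DataFrame, ConfusionMatrix, int]:
    """Apply the rule to every eligible patient of an ascertained cohort.

    Returns ``(decisions, confusion, n_ineligible)``: a per-patient
    decisions frame (id, positive, fired clause, comorbidities), the
    confusion matrix against GHST-based ``ghd_status``, and the number of
    ineligible patients excluded.  If the cohort has no eligibility
    column, all patients are assumed eligible (they underwent a GHST).
    """
    if eligibility_column is not None and eligibility_column in cohort.columns:
        eligible_mask = cohort[eligibility_column].fillna(False).astype(bool)
    else:
        eligible_mask = pd.Series(True, index=cohort.index)
    n_ineligible = int((~eligible_mask).sum())
    sub = cohort[eligible_mask]

    rows = []
    for _, patient in sub.iterrows():
        decision = classify(patient.to_dict(), eligible=True)
        rows.append(
            {
                "patient_id": patient.get("patient_id"),
                "positive": decision.positive,
                "fired_clause": decision.fired_clause,
                "qualifying_comorbidities": ";".join(
                    decision.qualifying_comorbidities
                ),
            }
        )
    decisions = pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "positive",
            "fired_clause",
            "qualifying_comorbidities",
        ],
    )
    predicted = decisions["positive"].map({True: "case", False: "control"})
    confusion = ConfusionMatrix.from_labels(sub["ghd_status"], predicted)
    return decisions, confusion, n_ineligible
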