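"""Seeded generation of synthetic GHST cohorts.

Two built-in cohort specifications mirror the statistical structure of
the study populations the pipeline assumes: a derivation cohort (n=770,
150 GHD, tested 2004-2014) and a validation cohort (n=161, 36 GHD,
2017-2019).

``exact_marginal`` mode constructs flag assignments so that every
predictor's case/control 2x2 table equals the spec's integer targets,
MRI availability is differential by status, the isolated-vs-multiple
pituitary deficiency split matches, and the prediction rule applied to
the output reproduces the target confusion counts (no false positives in
the derivation cohort).  The joint distribution of predictors within
those constraints is a package choice — marginal tables alone do not
identify it — and is laid out along clinical archetypes (congenital
multiple-deficiency patients carry dysgenesis plus several axis
deficiencies together; acquired patients carry tumor/radiotherapy flags).

``stochastic`` mode draws each patient independently: case status is
Bernoulli(prevalence), flags are archetype-conditional Bernoullis whose
mixture-averaged rates equal the spec's conditional rates, GH peaks fall
on the correct side of the era cut-off, and auxology comes from
location-scale normals matching the reported medians and IQRs.

Both modes are deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

from .cohort import (
    ANTERIOR_DEFICIENCIES,
    PREDICTORS,
    RULE_COMORBIDITIES,
    EraCutoffs,
)
from .rule import classify

__all__ = [
    "CohortSpec",
    "CohortConstraintError",
    "default_specs",
    "simulate_cohort",
]

_DEF_NAMES = list(ANTERIOR_DEFICIENCIES)
_COMORBIDITY_NAMES = list(RULE_COMORBIDITIES)
_OTHER_FLAGS = [
    "cns_infection",
    "severe_tbi",
    "chemotherapy_ge6mo",
    "genetic_ghd",
    "neonatal_cholestasis",
]


class CohortConstraintError(ValueError):
    """The exact-marginal constraint set is infeasible; the message names
    the conflicting margins."""


@dataclass(frozen=True)
class CohortSpec:
    """Calibration constants for one synthetic cohort.

    ``case_counts``/``control_counts`` give, per predictor, the number of
    flag-positive cases/controls; ``pituitary_dysgenesis`` counts are
    within the MRI-assessed subsets (``mri_cases``/``mri_controls``).
    ``target_tp``/``target_fp`` are the confusion counts the prediction
    rule must reproduce in exact mode; ``mphd_cases`` is the number of
    cases with at least one non-GH pituitary axis involved (TSH, ACTH,
    prolactin or diabetes insipidus).
    """

    name: str
    n_cases: int
    n_controls: int
    case_counts: Mapping[str, int]
    control_counts: Mapping[str, int]
    mri_cases: int
    mri_controls: int
    target_tp: int
    target_fp: int
    mphd_cases: Optional[int] = None
    era_years: tuple[int, ...] = (2010,)
    #: per variable: {"case": (median, q1, q3), "control": (median, q1, q3)}
    auxology: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=dict
    )
    sex_male_rate: Mapping[str, float] = field(
        default_factory=lambda: {"case": 0.6, "control": 0.65}
    )
    pubertal_probs: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "case": (0.82, 0.11, 0.05, 0.02, 0.0),
            "control": (0.78, 0.13, 0.07, 0.01, 0.01),
        }
    )

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        for label, counts, limit in (
            ("case", self.case_counts, self.n_cases),
            ("control", self.control_counts, self.n_controls),
        ):
            for pred, k in counts.items():
                if pred not in PREDICTORS:
                    raise ValueError(f"unknown predictor {pred!r}")
                cap = (
                    (self.mri_cases if label == "case" else self.mri_controls)
                    if pred == "pituitary_dysgenesis"
                    else limit
                )
                if not 0 <= k <= cap:
                    raise CohortConstraintError(
                        f"{label} count for {pred} ({k}) outside 0..{cap}"
                    )
        if self.mri_cases > self.n_cases or self.mri_controls > self.n_controls:
            raise CohortConstraintError("MRI-assessed counts exceed cohort sizes")

    @property
    def n(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def prevalence(self) -> float:
        return self.n_cases / self.n if self.n else float("nan")

    def case_rate(self, predictor: str) -> float:
        denom = self.mri_cases if predictor == "pituitary_dysgenesis" else self.n_cases
        return self.case_counts.get(predictor, 0) / denom if denom else 0.0

    def control_rate(self, predictor: str) -> float:
        denom = (
            self.mri_controls
            if predictor == "pituitary_dysgenesis"
            else self.n_controls
        )
        return self.control_counts.get(predictor, 0) / denom if denom else 0.0


def default_specs() -> dict[str, CohortSpec]:
    """The two built-in cohort specifications.

    Derivation constants come from the published contingency structure of
    the 2004-2014 cohort; the validation cohort's per-predictor counts are
    not published, so the constants are package-chosen plausible values
    consistent with the reported confusion counts (TP=20, FP=1) and the
    isolated/multiple deficiency split (20/16).
    """
    derivation = CohortSpec(
        name="derivation_2004_2014",
        n_cases=150,
        n_controls=620,
        case_counts={
            "pituitary_dysgenesis": 38,
            "midline_abnormality": 19,
            "sellar_tumor_surgery": 13,
            "cns_infection": 0,
            "severe_tbi": 1,
            "cranial_radiotherapy_ge18Gy": 10,
            "chemotherapy_ge6mo": 10,
            "genetic_ghd": 3,
            "tsh_deficiency": 42,
            "acth_deficiency": 32,
            "prolactin_deficiency": 3,
            "central_diabetes_insipidus": 17,
            "neonatal_hypoglycemia": 18,
            "neonatal_cholestasis": 5,
            "neonatal_hypogenitalism": 18,
        },
        control_counts={
            "pituitary_dysgenesis": 0,
            "midline_abnormality": 17,
            "sellar_tumor_surgery": 3,
            "cns_infection": 6,
            "severe_tbi": 2,
            "cranial_radiotherapy_ge18Gy": 10,
            "chemotherapy_ge6mo": 11,
            "genetic_ghd": 1,
            "tsh_deficiency": 1,
            "acth_deficiency": 0,
            "prolactin_deficiency": 0,
            "central_diabetes_insipidus": 4,
            "neonatal_hypoglycemia": 12,
            "neonatal_cholestasis": 4,
            "neonatal_hypogenitalism": 8,
        },
        mri_cases=120,
        mri_controls=98,
        target_tp=61,
        target_fp=0,
        mphd_cases=64,
        era_years=tuple(range(2004, 2015)),
        auxology={
            "age_years": {"case": (7.15, 3.52, 10.89), "control": (7.82, 5.52, 11.11)},
            "height_sds": {
                "case": (-2.58, -3.18, -2.08),
                "control": (-2.50, -2.98, -2.22),
            },
            "weight_sds": {
                "case": (-2.03, -2.78, -0.74),
                "control": (-2.34, -2.77, -1.81),
            },
            "bmi_sds": {"case": (0.00, -0.76, 0.51), "control": (-0.62, -0.96, -0.34)},
            "igf1_sds": {
                "case": (-2.92, -4.68, -1.77),
                "control": (-1.54, -3.11, -0.37),
            },
        },
        sex_male_rate={"case": 88 / 150, "control": 403 / 620},
        pubertal_probs={
            "case": (123 / 150, 16 / 150, 8 / 150, 3 / 150, 0.0),
            "control": (486 / 620, 83 / 620, 43 / 620, 7 / 620, 1 / 620),
        },
    )

    validation = CohortSpec(
        name="validation_2017_2019",
        n_cases=36,
        n_controls=125,
        case_counts={
            "pituitary_dysgenesis": 10,
            "midline_abnormality": 3,
            "sellar_tumor_surgery": 2,
            "cns_infection": 0,
            "severe_tbi": 0,
            "cranial_radiotherapy_ge18Gy": 1,
            "chemotherapy_ge6mo": 1,
            "genetic_ghd": 0,
            "tsh_deficiency": 16,
            "acth_deficiency": 8,
            "prolactin_deficiency": 1,
            "central_diabetes_insipidus": 4,
            "neonatal_hypoglycemia": 3,
            "neonatal_cholestasis": 1,
            "neonatal_hypogenitalism": 2,
        },
        control_counts={
            "pituitary_dysgenesis": 0,
            "midline_abnormality": 4,
            "sellar_tumor_surgery": 1,
            "cns_infection": 1,
            "severe_tbi": 0,
            "cranial_radiotherapy_ge18Gy": 1,
            "chemotherapy_ge6mo": 2,
            "genetic_ghd": 0,
            "tsh_deficiency": 1,
            "acth_deficiency": 0,
            "prolactin_deficiency": 0,
            "central_diabetes_insipidus": 0,
            "neonatal_hypoglycemia": 2,
            "neonatal_cholestasis": 1,
            "neonatal_hypogenitalism": 1,
        },
        mri_cases=27,
        mri_controls=19,
        target_tp=20,
        target_fp=1,
        mphd_cases=16,
        era_years=(2017, 2018, 2019),
        auxology={
            "age_years": {"case": (8.83, 3.73, 11.29), "control": (7.64, 5.24, 11.02)},
            "height_sds": {
                "case": (-2.35, -3.69, -0.92),
                "control": (-2.62, -3.01, -2.18),
            },
            "weight_sds": {
                "case": (-1.25, -2.13, 0.30),
                "control": (-2.40, -2.90, -1.70),
            },
            "bmi_sds": {"case": (0.60, -0.44, 1.10), "control": (-0.56, -0.94, -0.28)},
            "igf1_sds": {
                "case": (-1.78, -2.80, -0.50),
                "control": (-0.09, -1.02, 0.48),
            },
        },
        sex_male_rate={"case": 24 / 36, "control": 87 / 125},
        pubertal_probs={
            "case": (31 / 36, 2 / 36, 2 / 36, 1 / 36, 0.0),
            "control": (109 / 125, 7 / 125, 9 / 125, 0.0, 0.0),
        },
    )
    return {"derivation_2004_2014": derivation, "validation_2017_2019": validation}


# ---------------------------------------------------------------------
# exact-marginal flag construction


def _empty_flags() -> dict[str, Optional[bool]]:
    return {name: False for name in PREDICTORS}


def _assign_case_flags(spec: CohortSpec) -> list[dict]:
    """Deterministic case-flag layout meeting every marginal target.

    Layout: dysgenesis cases first (absorbing surplus deficiency flags),
    then the deficiency-positive rule-positive cases (doubles, then
    singles paired with a qualifying comorbidity), then deficiency-free
    cases.  Exactly ``target_tp`` cases satisfy the rule.
    """
    n = spec.n_cases
    counts = dict(spec.case_counts)
    D = counts.get("pituitary_dysgenesis", 0)
    E = spec.target_tp - D
    if E < 0:
        raise CohortConstraintError(
            f"target_tp ({spec.target_tp}) below dysgenesis case count ({D})"
        )

    defs = {name: counts.get(name, 0) for name in _DEF_NAMES}
    comorb = {name: counts.get(name, 0) for name in _COMORBIDITY_NAMES}
    total_defs = sum(defs.values())

    solution = None
    for k2 in range(0, E + 1):
        k1 = E - k2
        pool = dict(defs)
        # doubles: pair the two largest remaining deficiency types
        doubles: list[tuple[str, str]] = []
        ok = True
        for _ in range(k2):
            ranked = sorted(pool, key=lambda f: (-pool[f], _DEF_NAMES.index(f)))
            first, second = ranked[0], ranked[1]
            if pool[first] == 0 or pool[second] == 0:
                ok = False
                break
            pool[first] -= 1
            pool[second] -= 1
            doubles.append((first, second))
        if not ok:
            continue
        # singles: exhaust the largest pool first, keeping the other axes
        # concentrated on dysgenesis cases (the congenital archetype)
        singles: list[str] = []
        for name in sorted(pool, key=lambda f: (-pool[f], _DEF_NAMES.index(f))):
            take = min(pool[name], k1 - len(singles))
            pool[name] -= take
            singles.extend([name] * take)
            if len(singles) == k1:
                break
        if len(singles) < k1:
            continue
        leftover = dict(pool)
        # surplus deficiency flags stack onto dysgenesis cases from index 0
        if any(v > D for v in leftover.values()):
            continue
        # comorbidity pairing for singles: cycle qualifying types
        comorb_pool = dict(comorb)
        pairing: list[str] = []
        cycle = 0
        for _ in range(k1):
            placed = False
            for off in range(len(_COMORBIDITY_NAMES)):
                name = _COMORBIDITY_NAMES[(cycle + off) % len(_COMORBIDITY_NAMES)]
                if comorb_pool[name] > 0:
                    comorb_pool[name] -= 1
                    pairing.append(name)
                    cycle += off + 1
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if not ok:
            continue
        # multiple-deficiency structure: dysgenesis cases carrying a
        # surplus flag, plus every deficiency-positive non-dys case, plus
        # fresh diabetes-insipidus-only cases as needed
        dys_def_carriers = max(leftover.values()) if leftover else 0
        mphd0 = E + dys_def_carriers
        di_left = comorb_pool["central_diabetes_insipidus"]
        if spec.mphd_cases is not None:
            di_fresh = spec.mphd_cases - mphd0
            if not 0 <= di_fresh <= di_left:
                continue
            if n - D - E < di_fresh:
                continue
        else:
            di_fresh = 0
        solution = (k2, doubles, singles, pairing, leftover, comorb_pool, di_fresh)
        break

    if solution is None:
        raise CohortConstraintError(
            f"no feasible case layout: target_tp={spec.target_tp}, "
            f"dysgenesis={D}, deficiency flags={total_defs}, "
            f"mphd_cases={spec.mphd_cases}"
        )
    k2, doubles, singles, pairing, leftover, comorb_pool, di_fresh = solution

    cases = [_empty_flags() for _ in range(n)]
    for i in range(D):
        cases[i]["pituitary_dysgenesis"] = True
    for name, surplus in leftover.items():
        for i in range(surplus):
            cases[i][name] = True
    pos = D
    for first, second in doubles:
        cases[pos][first] = True
        cases[pos][second] = True
        pos += 1
    for def_name, com_name in zip(singles, pairing):
        cases[pos][def_name] = True
        cases[pos][com_name] = True
        pos += 1
    # fresh DI-only cases complete the multiple-deficiency tally
    for i in range(di_fresh):
        cases[pos + i]["central_diabetes_insipidus"] = True
    comorb_pool = dict(comorb_pool)
    comorb_pool["central_diabetes_insipidus"] -= di_fresh
    # surplus DI lands on dysgenesis cases (already multiple-deficiency)
    extra_di = comorb_pool.pop("central_diabetes_insipidus")
    ptr = 0
    for _ in range(extra_di):
        while cases[ptr]["central_diabetes_insipidus"]:
            ptr += 1
            if ptr >= D:
                raise CohortConstraintError(
                    "cannot place surplus diabetes-insipidus flags without "
                    "breaking the multiple-deficiency target"
                )
        cases[ptr]["central_diabetes_insipidus"] = True
    # remaining qualifying comorbidities: any case may carry them (every
    # single-deficiency case is already rule-positive)
    for name, remaining in comorb_pool.items():
        ptr = 0
        for _ in range(remaining):
            while cases[ptr][name]:
                ptr += 1
            cases[ptr][name] = True
            ptr += 1
    # non-rule flags: distributed from the tail so acquired-condition
    # flags concentrate away from the congenital block
    for name in _OTHER_FLAGS:
        remaining = counts.get(name, 0)
        ptr = n - 1
        for _ in range(remaining):
            while cases[ptr][name]:
                ptr -= 1
            cases[ptr][name] = True
            ptr -= 1

    # MRI availability: all dysgenesis cases, then index order
    mri = [False] * n
    for i in range(D):
        mri[i] = True
    extra_mri = spec.mri_cases - D
    ptr = D
    for _ in range(extra_mri):
        mri[ptr] = True
        ptr += 1
    for i in range(n):
        if not mri[i]:
            cases[i]["pituitary_dysgenesis"] = None
    return [dict(flags, mri_available=mri[i]) for i, flags in enumerate(cases)]


def _assign_control_flags(spec: CohortSpec) -> list[dict]:
    """Deterministic control-flag layout.

    Exactly ``target_fp`` controls satisfy the rule (one anterior
    deficiency plus a qualifying comorbidity each); every remaining
    deficiency-positive control carries no qualifying comorbidity, so no
    further control can fire any clause.
    """
    n = spec.n_controls
    counts = dict(spec.control_counts)
    if counts.get("pituitary_dysgenesis", 0) > 0:
        raise CohortConstraintError(
            "dysgenesis-positive controls are unconditionally rule-positive; "
            "not supported beyond target_fp=0 layouts"
        )
    defs = {name: counts.get(name, 0) for name in _DEF_NAMES}
    comorb = {name: counts.get(name, 0) for name in _COMORBIDITY_NAMES}
    if sum(defs.values()) < spec.target_fp:
        raise CohortConstraintError(
            f"target_fp={spec.target_fp} but controls carry only "
            f"{sum(defs.values())} deficiency flags"
        )

    controls = [_empty_flags() for _ in range(n)]
    pos = 0
    for _ in range(spec.target_fp):
        ranked = sorted(defs, key=lambda f: (-defs[f], _DEF_NAMES.index(f)))
        def_name = ranked[0]
        com_name = next(
            (name for name in _COMORBIDITY_NAMES if comorb[name] > 0), None
        )
        if com_name is None:
            raise CohortConstraintError(
                "target_fp requires a qualifying comorbidity among controls"
            )
        defs[def_name] -= 1
        comorb[com_name] -= 1
        controls[pos][def_name] = True
        controls[pos][com_name] = True
        pos += 1
    # remaining deficiency flags: isolated carriers, no comorbidities
    def_start = pos
    for name, remaining in defs.items():
        for _ in range(remaining):
            controls[pos][name] = True
            pos += 1
    def_end = pos
    if pos > n:
        raise CohortConstraintError("more deficiency-positive controls than controls")

    protected = set(range(def_start, def_end))
    for name, remaining in comorb.items():
        ptr = def_end
        for _ in range(remaining):
            while ptr in protected or controls[ptr][name]:
                ptr += 1
                if ptr >= n:
                    raise CohortConstraintError(
                        f"cannot place control comorbidity {name} without "
                        "creating an unplanned rule-positive control"
                    )
            controls[ptr][name] = True
            ptr += 1
    for name in _OTHER_FLAGS:
        remaining = counts.get(name, 0)
        ptr = n - 1
        for _ in range(remaining):
            while controls[ptr][name]:
                ptr -= 1
            controls[ptr][name] = True
            ptr -= 1

    mri = [False] * n
    # spread MRI over the tail so deficiency carriers are not implicitly imaged
    for i in range(spec.mri_controls):
        mri[n - 1 - i] = True
    for i in range(n):
        controls[i]["pituitary_dysgenesis"] = False if mri[i] else None
    return [dict(flags, mri_available=mri[i]) for i, flags in enumerate(controls)]


# ---------------------------------------------------------------------
# stochastic archetypes

#: Case archetypes: mixture weight and per-predictor rate multipliers.
#: Per-archetype rates are calibrated so the mixture-averaged rate equals
#: the spec's conditional rate for every predictor.
CASE_ARCHETYPES: dict[str, tuple[float, dict[str, float]]] = {
    "congenital_mphd": (
        0.40,
        {
            "pituitary_dysgenesis": 2.2,
            "tsh_deficiency": 2.2,
            "acth_deficiency": 2.2,
            "prolactin_deficiency": 2.2,
            "central_diabetes_insipidus": 2.0,
            "neonatal_hypoglycemia": 1.8,
            "neonatal_hypogenitalism": 1.8,
            "neonatal_cholestasis": 1.8,
            "midline_abnormality": 1.6,
        },
    ),
    "idiopathic_ighd": (0.45, {"genetic_ghd": 1.5}),
    "acquired": (
        0.10,
        {
            "sellar_tumor_surgery": 6.0,
            "cranial_radiotherapy_ge18Gy": 6.0,
            "chemotherapy_ge6mo": 6.0,
            "cns_infection": 4.0,
            "severe_tbi": 4.0,
        },
    ),
    "neonatal_onset": (
        0.05,
        {
            "neonatal_hypoglycemia": 4.0,
            "neonatal_cholestasis": 4.0,
            "neonatal_hypogenitalism": 4.0,
            "tsh_deficiency": 2.0,
        },
    ),
}
_DEFAULT_MULTIPLIER = 0.25


def _calibrate_archetype_rates(p: float, predictor: str) -> dict[str, float]:
    """Per-archetype Bernoulli rates whose mixture average equals ``p``.

    Solves for the scale ``c`` in rate_k = min(1, c * m_k * p) by
    bisection (the mixture mean is continuous and nondecreasing in c).
    """
    if p <= 0:
        return {k: 0.0 for k in CASE_ARCHETYPES}
    weights = {k: w for k, (w, _) in CASE_ARCHETYPES.items()}
    mults = {
        k: m.get(predictor, _DEFAULT_MULTIPLIER)
        for k, (_, m) in CASE_ARCHETYPES.items()
    }

    def mixture_mean(c: float) -> float:
        return sum(w * min(1.0, c * mults[k] * p) for k, w in weights.items())

    lo, hi = 0.0, 1.0
    while mixture_mean(hi) < p and hi < 1e9:
        hi *= 2
    if mixture_mean(hi) < p:
        raise CohortConstraintError(
            f"cannot calibrate archetype rates for {predictor} at rate {p}"
        )
    for _ in range(200):
        mid = (lo + hi) / 2
        if mixture_mean(mid) < p:
            lo = mid
        else:
            hi = mid
    c = (lo + hi) / 2
    return {k: min(1.0, c * mults[k] * p) for k in CASE_ARCHETYPES}


# ---------------------------------------------------------------------
# cohort assembly


def _sample_normal_from_quartiles(
    rng: np.random.Generator, median: float, q1: float, q3: float, size: int
) -> np.ndarray:
    sigma = (q3 - q1) / 1.349 if q3 > q1 else 0.0
    return rng.normal(median, sigma, size)


def _demographics(
    rng: np.random.Generator, spec: CohortSpec, status: str, size: int
) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for var, groups in spec.auxology.items():
        median, q1, q3 = groups[status]
        out[var] = _sample_normal_from_quartiles(rng, median, q1, q3, size)
    out["age_years"] = np.clip(out.get("age_years", np.full(size, 8.0)), 0.1, 17.9)
    out["sex"] = np.where(
        rng.random(size) < spec.sex_male_rate[status], "M", "F"
    )
    probs = np.asarray(spec.pubertal_probs[status], dtype=float)
    probs = probs / probs.sum()
    out["pubertal_stage"] = rng.choice(np.arange(1, 6), size=size, p=probs)
    return out


def _gh_peaks(
    rng: np.random.Generator, status: str, cutoff: float, n_arms: int
) -> tuple[float, ...]:
    if status == "case":
        peaks = rng.uniform(0.3, cutoff * 0.95, n_arms)
    else:
        peaks = rng.uniform(0.3, 20.0, n_arms)
        peaks[0] = rng.uniform(cutoff, 20.0)  # at least one peak at/above cutoff
    return tuple(round(float(p), 2) for p in peaks)


def _rows_to_frame(
    rows: list[dict], spec: CohortSpec, rng: np.random.Generator
) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    if len(df) == 0:
        cols = [
            "patient_id", "sex", "age_years", "era", "pubertal_stage",
            "height_sds", "weight_sds", "bmi_sds", "igf1_sds", "weight_kg",
            "height_velocity_sds", "gh_peaks", "mri_available",
            *PREDICTORS, "ghd_status", "eligible",
        ]
        return pd.DataFrame(columns=cols)
    # shuffle so case/control blocks do not leak through row order
    order = rng.permutation(len(df))
    df = df.iloc[order].reset_index(drop=True)
    df["patient_id"] = [f"{spec.name}-{i:04d}" for i in range(len(df))]
    for pred in PREDICTORS:
        df[pred] = df[pred].astype("boolean")
    df["mri_available"] = df["mri_available"].astype(bool)
    df["eligible"] = True
    cols = [
        "patient_id", "sex", "age_years", "era", "pubertal_stage",
        "height_sds", "weight_sds", "bmi_sds", "igf1_sds", "weight_kg",
        "height_velocity_sds", "gh_peaks", "mri_available",
        *PREDICTORS, "ghd_status", "eligible",
    ]
    return df[cols]


def _build_rows(
    spec: CohortSpec,
    flags_by_status: dict[str, list[dict]],
    rng: np.random.Generator,
    cutoffs: EraCutoffs,
) -> list[dict]:
    rows: list[dict] = []
    for status in ("case", "control"):
        flag_list = flags_by_status[status]
        size = len(flag_list)
        if size == 0:
            continue
        demo = _demographics(rng, spec, status, size)
        eras = rng.choice(np.asarray(spec.era_years), size=size)
        for i, flags in enumerate(flag_list):
            age = float(demo["age_years"][i])
            weight_sds = float(demo.get("weight_sds", np.zeros(size))[i])
            weight_kg = max(2.5, (2.0 * age + 8.0) + 1.2 * weight_sds)
            n_arms = 1 if weight_kg < 10 else 2
            era = int(eras[i])
            cutoff = cutoffs.cutoff_for(era)
            peaks = _gh_peaks(rng, status, cutoff, n_arms)
            # growth-velocity deceleration guarantees GHRS eligibility even
            # for the few patients whose sampled height is unremarkable
            # (checked on the rounded values that are actually stored)
            height_sds = round(float(demo["height_sds"][i]), 2)
            hv = round(float(rng.normal(-1.6, 0.7)), 2)
            if height_sds >= -2 and hv >= -2:
                hv = -2.5
            rows.append(
                {
                    "sex": demo["sex"][i],
                    "age_years": round(age, 2),
                    "era": era,
                    "pubertal_stage": int(demo["pubertal_stage"][i]),
                    "height_sds": height_sds,
                    "weight_sds": round(weight_sds, 2),
                    "bmi_sds": round(float(demo.get("bmi_sds", np.zeros(size))[i]), 2),
                    "igf1_sds": round(float(demo.get("igf1_sds", np.zeros(size))[i]), 2),
                    "weight_kg": round(weight_kg, 1),
                    "height_velocity_sds": hv,
                    "gh_peaks": ";".join(f"{p:.2f}" for p in peaks),
                    "mri_available": flags["mri_available"],
                    **{pred: flags[pred] for pred in PREDICTORS},
                    "ghd_status": status,
                }
            )
    return rows


def _stochastic_flags(
    spec: CohortSpec, rng: np.random.Generator, n: int
) -> dict[str, list[dict]]:
    statuses = np.where(rng.random(n) < spec.prevalence, "case", "control")
    arch_names = list(CASE_ARCHETYPES)
    arch_weights = np.array([CASE_ARCHETYPES[k][0] for k in arch_names])
    arch_weights = arch_weights / arch_weights.sum()
    calibrated = {
        pred: _calibrate_archetype_rates(spec.case_rate(pred), pred)
        for pred in PREDICTORS
    }
    out: dict[str, list[dict]] = {"case": [], "control": []}
    for status in statuses:
        flags = _empty_flags()
        if status == "case":
            arch = arch_names[int(rng.choice(len(arch_names), p=arch_weights))]
            mri = bool(rng.random() < spec.mri_cases / max(spec.n_cases, 1))
            for pred in PREDICTORS:
                if pred == "pituitary_dysgenesis":
                    continue
                flags[pred] = bool(rng.random() < calibrated[pred][arch])
            if mri:
                flags["pituitary_dysgenesis"] = bool(
                    rng.random() < calibrated["pituitary_dysgenesis"][arch]
                )
            else:
                flags["pituitary_dysgenesis"] = None
        else:
            mri = bool(rng.random() < spec.mri_controls / max(spec.n_controls, 1))
            for pred in PREDICTORS:
                if pred == "pituitary_dysgenesis":
                    continue
                flags[pred] = bool(rng.random() < spec.control_rate(pred))
            flags["pituitary_dysgenesis"] = (
                bool(rng.random() < spec.control_rate("pituitary_dysgenesis"))
                if mri
                else None
            )
        out[status].append(dict(flags, mri_available=mri))
    return out


def simulate_cohort(
    spec: CohortSpec,
    seed: int = 0,
    mode: Literal["exact_marginal", "stochastic"] = "exact_marginal",
    n: Optional[int] = None,
    cutoffs: Optional[EraCutoffs] = None,
) -> pd.DataFrame:
    """Generate a synthetic cohort table.

    ``exact_marginal`` reproduces the spec's integer targets exactly
    (cohort size ``spec.n``; *n* is not accepted); ``stochastic`` draws
    *n* patients (default ``spec.n``) independently.  Deterministic for a
    given seed.
    """
    if cutoffs is None:
        cutoffs = EraCutoffs()
    rng = np.random.default_rng(seed)

    if mode == "exact_marginal":
        if n is not None and n != spec.n:
            raise ValueError("exact_marginal mode generates exactly spec.n patients")
        flags = {
            "case": _assign_case_flags(spec) if spec.n_cases else [],
            "control": _assign_control_flags(spec) if spec.n_controls else [],
        }
        # internal consistency: the rule must reproduce the target confusion
        tp = sum(classify(f).positive for f in flags["case"])
        fp = sum(classify(f).positive for f in flags["control"])
        if tp != spec.target_tp or fp != spec.target_fp:
            raise CohortConstraintError(
                f"constructed layout yields TP={tp}, FP={fp}; targets were "
                f"TP={spec.target_tp}, FP={spec.target_fp}"
            )
    elif mode == "stochastic":
        size = spec.n if n is None else int(n)
        flags = _stochastic_flags(spec, rng, size)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rows = _build_rows(spec, flags, rng, cutoffs)
    return _rows_to_frame(rows, spec, rng)
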