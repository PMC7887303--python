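"""Data-exploration statistics: 2x2 tables, odds ratios, chi-squared
association, a-priori frequency tables and continuous summaries.

Every predictor's association with GHD status is summarised through a
:class:`TwoByTwoTable`.  Point odds ratios are ``ad/bc``; interval methods
are the Woolf log-interval (finite cells), the Haldane-Anscombe corrected
log-interval, and exact conditional tail inversion on the noncentral
hypergeometric distribution (the only option giving finite bounds for
zero-cell tables, where the point estimate is 0 or infinity).

p-values come from Pearson's chi-squared test without continuity
correction by default; Fisher's exact test is available for the sparse
tables where the asymptotic test is unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.stats.contingency import odds_ratio as _scipy_odds_ratio

from .cohort import PREDICTORS

__all__ = [
    "TwoByTwoTable",
    "OREstimate",
    "odds_ratio",
    "chisq_association",
    "fisher_exact_p",
    "apriori_table",
    "continuous_summary",
    "association_table",
    "format_p",
]

DenominatorPolicy = Literal["full_cohort", "assessed_only"]
ORMethod = Literal["woolf_log", "haldane_corrected", "exact_conditional"]


@dataclass(frozen=True)
class TwoByTwoTable:
    """Predictor x GHD-status counts.

    ``a`` predictor-positive cases, ``b`` predictor-positive controls,
    ``c`` predictor-negative cases, ``d`` predictor-negative controls.
    """

    a: int
    b: int
    c: int
    d: int
    denominator_policy: DenominatorPolicy = "full_cohort"

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("empty 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_case(self) -> int:
        return self.a + self.c

    @property
    def n_control(self) -> int:
        return self.b + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @classmethod
    def from_cohort(
        cls,
        cohort: pd.DataFrame,
        predictor: str,
        policy: DenominatorPolicy = "full_cohort",
    ) -> "TwoByTwoTable":
        """Cross-tabulate one predictor flag against ``ghd_status``.

        Under ``full_cohort`` a missing flag counts as predictor-negative
        (the whole cohort is the denominator); under ``assessed_only``
        rows with a missing flag are dropped (e.g. pituitary dysgenesis
        is only defined for the MRI-assessed subset).
        """
        flag = cohort[predictor]
        is_case = (cohort["ghd_status"] == "case").to_numpy()
        if policy == "assessed_only":
            keep = flag.notna().to_numpy()
            flag = flag[keep]
            is_case = is_case[keep]
        pos = flag.fillna(False).astype(bool).to_numpy()
        return cls(
            a=int((pos & is_case).sum()),
            b=int((pos & ~is_case).sum()),
            c=int((~pos & is_case).sum()),
            d=int((~pos & ~is_case).sum()),
            denominator_policy=policy,
        )


@dataclass(frozen=True)
class OREstimate:
    or_point: float  # may be 0.0 or math.inf
    ci_low: float
    ci_high: float
    method: ORMethod
    p_value: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not bracket "
                f"point estimate {self.or_point}"
            )


def _woolf_interval(t: TwoByTwoTable, conf_level: float, shift: float = 0.0):
    a, b, c, d = (x + shift for x in (t.a, t.b, t.c, t.d))
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = st.norm.ppf(0.5 + conf_level / 2)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def _exact_conditional_ci(t: TwoByTwoTable, conf_level: float):
    res = _scipy_odds_ratio(t.as_array(), kind="conditional")
    ci = res.confidence_interval(confidence_level=conf_level)
    return float(ci.low), float(ci.high)


def odds_ratio(
    t: TwoByTwoTable,
    method: ORMethod = "woolf_log",
    conf_level: float = 0.95,
    p_method: Literal["pearson", "fisher"] = "pearson",
) -> OREstimate:
    """Odds ratio ``ad/bc`` with a confidence interval.

    Zero-cell tables override the requested interval method: when
    ``b*c == 0`` with ``a, d > 0`` the point estimate is infinity and the
    finite lower bound comes from exact conditional tail inversion;
    symmetrically ``a == 0`` or ``d == 0`` gives a zero point estimate
    with an exact upper bound.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    try:
        p_value = (
            fisher_exact_p(t) if p_method == "fisher" else chisq_association(t)
        )
    except ValueError:
        p_value = math.nan  # zero margin: association undefined, flagged

    if a == 0 or d == 0:
        # OR = 0 (or undefined if also b*c == 0; reported as 0 with a
        # maximally wide exact interval).
        low, high = _exact_conditional_ci(t, conf_level)
        return OREstimate(0.0, 0.0, high, "exact_conditional", p_value)
    if b == 0 or c == 0:
        low, high = _exact_conditional_ci(t, conf_level)
        return OREstimate(math.inf, low, math.inf, "exact_conditional", p_value)

    point = (a * d) / (b * c)
    if method == "woolf_log":
        low, high = _woolf_interval(t, conf_level)
    elif method == "haldane_corrected":
        low, high = _woolf_interval(t, conf_level, shift=0.5)
        low, high = min(low, point), max(high, point)
    elif method == "exact_conditional":
        low, high = _exact_conditional_ci(t, conf_level)
        # the conditional MLE differs from ad/bc; keep the sample OR as the
        # reported point but widen the interval to bracket it if needed
        low, high = min(low, point), max(high, point)
    else:
        raise ValueError(f"unknown OR method {method!r}")
    return OREstimate(point, low, high, method, p_value)


def chisq_association(t: TwoByTwoTable) -> float:
    """Pearson chi-squared p-value (1 df, no continuity correction)."""
    arr = t.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined: zero margin in 2x2 table")
    _, p, _, _ = st.chi2_contingency(arr, correction=False)
    return float(p)


def fisher_exact_p(t: TwoByTwoTable) -> float:
    """Fisher's exact two-sided p-value."""
    return float(st.fisher_exact(t.as_array())[1])


def format_p(p: float, floor: float = 1e-4) -> str:
    """Display formatting: p-values below the floor print as '<0.0001'."""
    if math.isnan(p):
        return "undefined"
    return "<0.0001" if p < floor else f"{p:.4f}".rstrip("0").rstrip(".")


def apriori_table(cohort: pd.DataFrame, predictors: Iterable[str] = PREDICTORS):
    """Per-predictor frequency table with conditional GHD probabilities.

    Returns a DataFrame indexed by (predictor, stratum) with columns
    ``n``, ``n_case`` and ``p_ghd`` = P(GHD | stratum), plus the overall
    prior under predictor '(overall)'.
    """
    is_case = cohort["ghd_status"] == "case"
    rows = []
    n = len(cohort)
    rows.append(
        {
            "predictor": "(overall)",
            "stratum": "all",
            "n": n,
            "n_case": int(is_case.sum()),
            "p_ghd": float(is_case.sum() / n) if n else float("nan"),
        }
    )
    for pred in predictors:
        flag = cohort[pred]
        for stratum, mask in (
            ("yes", flag == True),  # noqa: E712 - nullable boolean comparison
            ("no", flag == False),  # noqa: E712
            ("missing", flag.isna()),
        ):
            count = int(mask.sum())
            ncase = int((mask & is_case).sum())
            rows.append(
                {
                    "predictor": pred,
                    "stratum": stratum,
                    "n": count,
                    "n_case": ncase,
                    "p_ghd": ncase / count if count else float("nan"),
                }
            )
    return pd.DataFrame(rows).set_index(["predictor", "stratum"])


def continuous_summary(cohort: pd.DataFrame, variable: str) -> pd.DataFrame:
    """Median and interquartile range of a continuous variable, for the
    total cohort and the case/control strata."""
    out = []
    groups = {
        "total": cohort,
        "case": cohort[cohort["ghd_status"] == "case"],
        "control": cohort[cohort["ghd_status"] == "control"],
    }
    for name, grp in groups.items():
        x = pd.to_numeric(grp[variable], errors="coerce").dropna()
        if len(x) == 0:
            out.append({"group": name, "n": 0, "median": float("nan"),
                        "q1": float("nan"), "q3": float("nan")})
            continue
        out.append(
            {
                "group": name,
                "n": int(len(x)),
                "median": float(x.median()),
                "q1": float(x.quantile(0.25)),
                "q3": float(x.quantile(0.75)),
            }
        )
    return pd.DataFrame(out).set_index("group")


def association_table(
    cohort: pd.DataFrame,
    predictors: Iterable[str] = PREDICTORS,
    method: ORMethod = "woolf_log",
    p_method: Literal["pearson", "fisher"] = "pearson",
    assessed_only: Iterable[str] = ("pituitary_dysgenesis",),
) -> pd.DataFrame:
    """Association panel: one row per predictor with counts, OR, CI and p.

    Predictors listed in *assessed_only* (by default pituitary dysgenesis,
    which is undefined without an MRI) are tabulated on the assessed
    subset; all others on the full cohort with missing counted as
    predictor-negative.
    """
    assessed = set(assessed_only)
    rows = []
    for pred in predictors:
        policy: DenominatorPolicy = (
            "assessed_only" if pred in assessed else "full_cohort"
        )
        t = TwoByTwoTable.from_cohort(cohort, pred, policy)
        est = odds_ratio(t, method=method, p_method=p_method)
        rows.append(
            {
                "predictor": pred,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "denominator": policy,
                "odds_ratio": est.or_point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "ci_method": est.method,
                "p_value": est.p_value,
                "p_display": format_p(est.p_value),
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
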