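"""Diagnostic-performance evaluation of a binary classifier against
GHST-ascertained GHD status.

All metrics derive from a confusion matrix: sensitivity, specificity,
predictive values, accuracy, F-measure, the positive likelihood ratio
LR+ = sens/(1-spec), and the number needed to test (diagnose)
NNT = 1/(PPV + NPV - 1).  Proportions carry Wilson score intervals, which
stay well-behaved at the proportions near 0 and 1 this high-specificity
setting produces.  Significance on an independent validation cohort is an
exact upper-tail binomial test of the rule's correct-positive count
against the cohort's pre-test GHD probability, judged at a deliberately
conservative alpha (1e-5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import pandas as pd
import scipy.stats as st
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "DiagnosticReport",
    "diagnostic_report",
    "wilson_ci",
    "binomial_significance",
    "validation_axes",
    "format_lr",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, truth, predicted) -> "ConfusionMatrix":
        truth = pd.Series(truth).reset_index(drop=True)
        predicted = pd.Series(predicted).reset_index(drop=True)
        t_case = truth == "case"
        p_case = predicted == "case"
        return cls(
            tp=int((t_case & p_case).sum()),
            fp=int((~t_case & p_case).sum()),
            fn=int((t_case & ~p_case).sum()),
            tn=int((~t_case & ~p_case).sum()),
        )

    def scaled(self, k: int) -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp * k, self.fp * k, self.fn * k, self.tn * k)


def wilson_ci(successes: int, n: int, conf_level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, clamped to [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in 0..n")
    low, high = proportion_confint(successes, n, alpha=1 - conf_level, method="wilson")
    return (max(0.0, float(low)), min(1.0, float(high)))


@dataclass(frozen=True)
class _Proportion:
    value: float
    ci_low: float
    ci_high: float
    k: int
    n: int

    def pct(self, digits: int = 1) -> str:
        return (
            f"{self.value * 100:.{digits}f} "
            f"({self.ci_low * 100:.{digits}f}-{self.ci_high * 100:.{digits}f})"
        )


def _prop(k: int, n: int, conf_level: float) -> Optional[_Proportion]:
    if n == 0:
        return None  # undefined, never silently 0
    low, high = wilson_ci(k, n, conf_level)
    return _Proportion(k / n, low, high, k, n)


def format_lr(lr: float) -> str:
    """Table rendering of the positive likelihood ratio: infinity (perfect
    specificity) prints as '>1,000'."""
    return ">1,000" if math.isinf(lr) else f"{lr:.1f}"


@dataclass(frozen=True)
class DiagnosticReport:
    """Confusion matrix plus derived diagnostic metrics.

    Proportion attributes are ``None`` when their denominator is zero.
    ``lr_positive`` is ``math.inf`` when specificity is exactly 1.
    """

    matrix: ConfusionMatrix
    conf_level: float
    sensitivity: Optional[float]
    sensitivity_ci: Optional[tuple[float, float]]
    specificity: Optional[float]
    specificity_ci: Optional[tuple[float, float]]
    ppv: Optional[float]
    ppv_ci: Optional[tuple[float, float]]
    npv: Optional[float]
    npv_ci: Optional[tuple[float, float]]
    accuracy: Optional[float]
    accuracy_ci: Optional[tuple[float, float]]
    f_measure: Optional[float]
    lr_positive: Optional[float]
    nnt: Optional[float]
    nnt_ci: Optional[tuple[float, float]]

    def summary(self) -> str:
        m = self.matrix

        def fmt(p: Optional[float], ci) -> str:
            if p is None:
                return "undefined"
            return f"{p * 100:.1f} ({ci[0] * 100:.1f}-{ci[1] * 100:.1f})"

        lines = [
            "Diagnostic performance",
            "=" * 46,
            f"confusion (TP/FP/FN/TN): {m.tp}/{m.fp}/{m.fn}/{m.tn}",
            f"Specificity, % (95% CI): {fmt(self.specificity, self.specificity_ci)}",
            f"Sensitivity, % (95% CI): {fmt(self.sensitivity, self.sensitivity_ci)}",
            f"Positive PV, % (95% CI): {fmt(self.ppv, self.ppv_ci)}",
            f"Negative PV, % (95% CI): {fmt(self.npv, self.npv_ci)}",
            "Positive LR            : "
            + ("undefined" if self.lr_positive is None else format_lr(self.lr_positive)),
            "NNT (95% CI)           : "
            + (
                "undefined"
                if self.nnt is None
                else f"{self.nnt:.2f} ({self.nnt_ci[0]:.2f}-{self.nnt_ci[1]:.2f})"
            ),
            f"Accuracy, %            : "
            + ("undefined" if self.accuracy is None else f"{self.accuracy * 100:.1f}"),
            "F-measure              : "
            + ("undefined" if self.f_measure is None else f"{self.f_measure:.3f}"),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "tp": self.matrix.tp,
            "fp": self.matrix.fp,
            "fn": self.matrix.fn,
            "tn": self.matrix.tn,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": self.sensitivity_ci,
            "specificity": self.specificity,
            "specificity_ci": self.specificity_ci,
            "ppv": self.ppv,
            "ppv_ci": self.ppv_ci,
            "npv": self.npv,
            "npv_ci": self.npv_ci,
            "accuracy": self.accuracy,
            "f_measure": self.f_measure,
            "lr_positive": None
            if self.lr_positive is None
            else (self.lr_positive if math.isfinite(self.lr_positive) else "inf"),
            "nnt": self.nnt,
            "conf_level": self.conf_level,
        }


def diagnostic_report(m: ConfusionMatrix, conf_level: float = 0.95) -> DiagnosticReport:
    """Compute the full diagnostic panel from a confusion matrix.

    Metrics whose denominator is zero are reported as ``None``
    (undefined), never coerced to 0.
    """
    if m.total == 0:
        raise ValueError("empty confusion matrix")

    sens = _prop(m.tp, m.tp + m.fn, conf_level)
    spec = _prop(m.tn, m.tn + m.fp, conf_level)
    ppv = _prop(m.tp, m.tp + m.fp, conf_level)
    npv = _prop(m.tn, m.tn + m.fn, conf_level)
    acc = _prop(m.tp + m.tn, m.total, conf_level)

    f_measure = None
    if ppv is not None and sens is not None and (ppv.value + sens.value) > 0:
        f_measure = 2 * ppv.value * sens.value / (ppv.value + sens.value)

    lr_pos = None
    if sens is not None and spec is not None:
        lr_pos = math.inf if spec.value == 1.0 else sens.value / (1 - spec.value)

    nnt = nnt_ci = None
    if ppv is not None and npv is not None:
        youden_pv = ppv.value + npv.value - 1
        if youden_pv > 0:
            nnt = 1 / youden_pv
            # conservative interval: propagate the Wilson bounds of PPV/NPV
            lo = ppv.ci_low + npv.ci_low - 1
            hi = ppv.ci_high + npv.ci_high - 1
            nnt_ci = (1 / hi if hi > 0 else math.inf, 1 / lo if lo > 0 else math.inf)

    def unpack(p: Optional[_Proportion]):
        return (None, None) if p is None else (p.value, (p.ci_low, p.ci_high))

    sens_v, sens_ci = unpack(sens)
    spec_v, spec_ci = unpack(spec)
    ppv_v, ppv_ci = unpack(ppv)
    npv_v, npv_ci = unpack(npv)
    acc_v, acc_ci = unpack(acc)

    return DiagnosticReport(
        matrix=m,
        conf_level=conf_level,
        sensitivity=sens_v,
        sensitivity_ci=sens_ci,
        specificity=spec_v,
        specificity_ci=spec_ci,
        ppv=ppv_v,
        ppv_ci=ppv_ci,
        npv=npv_v,
        npv_ci=npv_ci,
        accuracy=acc_v,
        accuracy_ci=acc_ci,
        f_measure=f_measure,
        lr_positive=lr_pos,
        nnt=nnt,
        nnt_ci=nnt_ci,
    )


def binomial_significance(
    positives_correct: int, positives_total: int, prior_p: float
) -> float:
    """Exact upper-tail binomial p-value.

    Under the null that a rule-positive call is unrelated to true GHD
    status, each of the ``positives_total`` positive calls is correct with
    the cohort's pre-test probability ``prior_p``; the p-value is
    ``P(X >= positives_correct)``.
    """
    if not 0 <= positives_correct <= positives_total:
        raise ValueError("positives_correct must be in 0..positives_total")
    if not 0 < prior_p < 1:
        raise ValueError("prior_p must be strictly between 0 and 1")
    return float(st.binom.sf(positives_correct - 1, positives_total, prior_p))


def validation_axes(
    report: DiagnosticReport,
    binomial_p: float,
    alpha: float = 1e-5,
    min_sensitivity: float = 0.2,
    max_type1_error: float = 0.01,
) -> dict[str, bool]:
    """The three validation axes of the prediction rule.

    * safety — the type I error (1 - specificity) is near zero
      (at most *max_type1_error*);
    * usefulness — sensitivity exceeds *min_sensitivity* (the rule
      resolves a worthwhile fraction of suspected cases without a GHST);
    * significance — the exact binomial p-value beats *alpha*.
    """
    safety = (
        report.specificity is not None
        and (1 - report.specificity) <= max_type1_error
    )
    usefulness = report.sensitivity is not None and report.sensitivity > min_sensitivity
    significance = binomial_p < alpha
    return {"safety": safety, "usefulness": usefulness, "significance": significance}
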