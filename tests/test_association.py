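"""Odds ratios, chi-squared association, a-priori and continuous tables."""

import math

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as stn

from ghdrule.association import (
    TwoByTwoTable,
    apriori_table,
    association_table,
    chisq_association,
    continuous_summary,
    fisher_exact_p,
    format_p,
    odds_ratio,
)

from conftest import TABLE3


class TestOddsRatio:
    @pytest.mark.parametrize("predictor", sorted(TABLE3))
    def test_published_point_estimates_to_one_decimal(self, predictor):
        a, b, c, d, printed = TABLE3[predictor]
        est = odds_ratio(TwoByTwoTable(a, b, c, d))
        if math.isinf(printed):
            assert math.isinf(est.or_point)
        else:
            assert round(est.or_point, 1) == printed

    def test_zero_numerator_cell_gives_zero_with_exact_upper_bound(self):
        est = odds_ratio(TwoByTwoTable(0, 6, 150, 614))
        assert est.or_point == 0.0
        assert est.ci_low == 0.0
        assert 0 < est.ci_high < math.inf
        assert est.method == "exact_conditional"

    def test_zero_denominator_cell_gives_infinity_with_finite_lower_bound(self):
        est = odds_ratio(TwoByTwoTable(38, 0, 82, 98))
        assert math.isinf(est.or_point)
        assert 0 < est.ci_low < math.inf
        assert math.isinf(est.ci_high)

    @pytest.mark.parametrize("k,m", [(3, 5), (10, 10), (1, 7)])
    def test_balanced_table_is_null(self, k, m):
        est = odds_ratio(TwoByTwoTable(k, k, m, m))
        assert est.or_point == pytest.approx(1.0)
        assert chisq_association(TwoByTwoTable(k, k, m, m)) == pytest.approx(1.0)

    def test_interval_brackets_point_for_all_methods(self):
        t = TwoByTwoTable(19, 17, 131, 603)
        for method in ("woolf_log", "haldane_corrected", "exact_conditional"):
            est = odds_ratio(t, method=method)
            assert est.ci_low <= est.or_point <= est.ci_high

    @settings(max_examples=60, deadline=None)
    @given(cells=stn.tuples(*[stn.integers(1, 40)] * 4))
    def test_transpose_consistency(self, cells):
        """Swapping case/control labels inverts the odds ratio exactly."""
        a, b, c, d = cells
        est = odds_ratio(TwoByTwoTable(a, b, c, d))
        swapped = odds_ratio(TwoByTwoTable(b, a, d, c))
        assert swapped.or_point == pytest.approx(1.0 / est.or_point)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwoTable(0, 0, 0, 0)


def _conditional_ci_bruteforce(a, b, c, d, conf=0.95):
    """Independent oracle: invert the noncentral hypergeometric tail
    probabilities by bisection on the odds parameter, evaluating the
    conditional pmf by direct enumeration."""
    r1, r2 = a + b, c + d
    m1 = a + c
    lo_support = max(0, m1 - r2)
    hi_support = min(m1, r1)
    ks = np.arange(lo_support, hi_support + 1)
    logw = np.array(
        [
            math.lgamma(r1 + 1) - math.lgamma(k + 1) - math.lgamma(r1 - k + 1)
            + math.lgamma(r2 + 1) - math.lgamma(m1 - k + 1)
            - math.lgamma(r2 - (m1 - k) + 1)
            for k in ks
        ]
    )

    def tail(psi, upper):
        logp = logw + ks * math.log(psi)
        logp -= logp.max()
        p = np.exp(logp)
        p /= p.sum()
        return p[ks >= a].sum() if upper else p[ks <= a].sum()

    alpha = (1 - conf) / 2

    def bisect(target_upper):
        lo, hi = 1e-12, 1e12
        for _ in range(300):
            mid = math.sqrt(lo * hi)
            if target_upper:
                # upper bound: P(X <= a | psi) = alpha
                if tail(mid, upper=False) > alpha:
                    lo = mid
                else:
                    hi = mid
            else:
                if tail(mid, upper=True) < alpha:
                    lo = mid
                else:
                    hi = mid
        return math.sqrt(lo * hi)

    low = 0.0 if a == lo_support else bisect(target_upper=False)
    high = math.inf if a == hi_support else bisect(target_upper=True)
    return low, high


@pytest.mark.parametrize(
    "cells",
    [(3, 5, 7, 11), (1, 9, 10, 15), (0, 6, 14, 18), (8, 0, 5, 20), (2, 2, 2, 2)],
)
def test_exact_conditional_ci_matches_enumeration_oracle(cells):
    """The exact conditional interval agrees with brute-force tail
    inversion of the conditional distribution on small tables."""
    a, b, c, d = cells
    est = odds_ratio(TwoByTwoTable(a, b, c, d), method="exact_conditional")
    oracle_low, oracle_high = _conditional_ci_bruteforce(a, b, c, d)
    if est.ci_low > 0 and oracle_low > 0:
        assert est.ci_low == pytest.approx(oracle_low, rel=0.02)
    else:
        assert est.ci_low == oracle_low == 0.0
    if math.isfinite(est.ci_high) and math.isfinite(oracle_high):
        assert est.ci_high == pytest.approx(oracle_high, rel=0.02)
    else:
        assert math.isinf(est.ci_high) and math.isinf(oracle_high)


class TestChiSquared:
    def test_strong_association_below_display_floor(self):
        p = chisq_association(TwoByTwoTable(18, 12, 132, 608))
        assert p < 1e-4
        assert format_p(p) == "<0.0001"

    def test_matches_direct_formula(self):
        """Oracle: chi-squared computed cell by cell from sum (O-E)^2/E."""
        a, b, c, d = 1, 2, 149, 618
        n = a + b + c + d
        expected = np.outer([a + b, c + d], [a + c, b + d]) / n
        observed = np.array([[a, b], [c, d]])
        chi2 = ((observed - expected) ** 2 / expected).sum()
        oracle_p = st.chi2.sf(chi2, df=1)
        assert chisq_association(TwoByTwoTable(a, b, c, d)) == pytest.approx(oracle_p)

    def test_zero_margin_flagged(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_association(TwoByTwoTable(0, 0, 10, 20))

    @pytest.mark.parametrize(
        "cells, printed",
        [
            ((0, 6, 150, 614), 0.603),
            ((1, 2, 149, 618), 0.479),
            ((10, 10, 140, 610), 0.002),
            ((10, 11, 140, 609), 0.003),
            ((3, 1, 147, 619), 0.025),
            ((5, 4, 145, 616), 0.017),
        ],
    )
    def test_fisher_reproduces_published_sparse_p_values(self, cells, printed):
        """The published per-predictor p-values match Fisher's exact test
        (not the asymptotic chi-squared) on the sparse tables."""
        assert fisher_exact_p(TwoByTwoTable(*cells)) == pytest.approx(
            printed, abs=2e-3
        )


class TestCohortTables:
    def test_apriori_overall_prior(self, derivation_cohort, validation_cohort):
        d = apriori_table(derivation_cohort)
        assert d.loc[("(overall)", "all"), "p_ghd"] == pytest.approx(150 / 770)
        v = apriori_table(validation_cohort)
        assert v.loc[("(overall)", "all"), "p_ghd"] == pytest.approx(36 / 161)

    def test_apriori_strata_partition_cohort(self, derivation_cohort):
        d = apriori_table(derivation_cohort)
        strata = d.loc["central_diabetes_insipidus"]
        assert strata["n"].sum() == len(derivation_cohort)

    def test_apriori_missing_stratum_counts_mri(self, derivation_cohort):
        d = apriori_table(derivation_cohort)
        assert d.loc[("pituitary_dysgenesis", "missing"), "n"] == 770 - 218

    def test_continuous_summary_matches_calibration(self, derivation_cohort):
        s = continuous_summary(derivation_cohort, "height_sds")
        # generator draws from normals centred on the reported medians
        assert s.loc["total", "median"] == pytest.approx(-2.51, abs=0.15)
        assert s.loc["case", "n"] == 150

    def test_continuous_summary_degenerate_group(self, derivation_cohort):
        single = derivation_cohort.head(1)
        s = continuous_summary(single, "height_sds")
        assert s.loc["total", "median"] == s.loc["total", "q1"]
        assert s.loc["total", "q1"] == s.loc["total", "q3"]

    def test_association_table_shape_and_policies(self, derivation_cohort):
        table = association_table(derivation_cohort)
        assert len(table) == 15
        assert table.loc["pituitary_dysgenesis", "denominator"] == "assessed_only"
        assert table.loc["tsh_deficiency", "denominator"] == "full_cohort"
        row = table.loc["tsh_deficiency"]
        assert (row.a, row.b, row.c, row.d) == (42, 1, 108, 619)
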