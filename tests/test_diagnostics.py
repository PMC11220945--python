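import math

import pandas as pd
import pytest

from mlpscore.diagnostics import (
    ContingencyTable2x2,
    crosstab,
    diagnostic_metrics,
    lr_ci,
    proportion_ci,
    round_half_up,
)
from mlpscore.errors import ValidationError
from mlpscore.synthetic import COHORT_COLUMNS


def binom_cdf(k: int, n: int, p: float) -> float:
    """Pure-python binomial CDF used as the interval oracle."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1)
    )


def clopper_pearson_oracle(s: int, n: int, alpha: float) -> tuple[float, float]:
    """Exact interval by bisection on the binomial tail probabilities."""

    def bisect(f, lo, hi):
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    low = 0.0 if s == 0 else bisect(
        lambda p: alpha / 2 - (1 - binom_cdf(s - 1, n, p)), 0.0, 1.0
    )
    high = 1.0 if s == n else bisect(
        lambda p: binom_cdf(s, n, p) - alpha / 2, 0.0, 1.0
    )
    return low, high


class TestCrosstab:
    def test_validation_cohort_collapses_to_published_table(self, validation_cohort):
        table, by_cell = crosstab(validation_cohort)
        assert (table.tp, table.fp, table.fn, table.tn) == (33, 2, 2, 10)
        assert by_cell.loc["UO"].tolist() == [2, 0, 4, 29]
        assert by_cell.loc["FO"].tolist() == [8, 2, 0, 2]
        assert int(by_cell.sum().sum()) == 47

    def test_empty_cohort_gives_zero_counts(self):
        empty = pd.DataFrame(columns=COHORT_COLUMNS).astype({"mlp": "Int64"})
        table, by_cell = crosstab(empty.assign(favourable=pd.Series(dtype=bool)))
        assert (table.tp, table.fp, table.fn, table.tn) == (0, 0, 0, 0)
        assert int(by_cell.sum().sum()) == 0

    def test_single_record(self):
        one = pd.DataFrame(
            [{"subject_id": "s1", "mlp": 1, "cpc_d30": 1, "cpc_d180": 2}]
        )
        table, _ = crosstab(one)
        assert (table.tp, table.fp, table.fn, table.tn) == (0, 0, 0, 1)

    def test_missing_mlp_names_subject(self, validation_cohort):
        cohort = validation_cohort.copy()
        cohort.loc[3, "mlp"] = pd.NA
        sid = cohort.loc[3, "subject_id"]
        with pytest.raises(ValidationError, match=sid):
            crosstab(cohort)


class TestDiagnosticMetrics:
    def test_raw_mode_uses_exact_fractions(self, published_table):
        r = diagnostic_metrics(published_table, rounding_mode="raw")
        assert r.sensitivity == pytest.approx(33 / 35)
        assert r.specificity == pytest.approx(10 / 12)
        assert r.lr_pos == pytest.approx((33 / 35) / (2 / 12))
        assert r.lr_pos == pytest.approx(5.657, abs=5e-4)
        assert r.lr_neg == pytest.approx((2 / 35) / (10 / 12))

    def test_as_published_mode_matches_printed_ratios(self, published_table):
        r = diagnostic_metrics(published_table, rounding_mode="as_published")
        assert round_half_up(r.lr_pos, 2) == 5.53
        assert round_half_up(r.lr_neg, 2) == 0.07
        # point proportions are unaffected by the LR rounding convention
        assert r.sensitivity == pytest.approx(33 / 35)

    def test_false_rate_conventions(self, published_table):
        r = diagnostic_metrics(published_table)
        assert r.fpr_paper == pytest.approx(2 / 35)
        assert r.fnr_paper == pytest.approx(2 / 12)
        assert r.fpr_standard == pytest.approx(2 / 12)
        assert r.fnr_standard == pytest.approx(2 / 35)

    def test_perfect_classifier(self):
        r = diagnostic_metrics(ContingencyTable2x2(10, 0, 0, 10))
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        assert r.accuracy_pct == 100.0
        assert math.isinf(r.lr_pos)
        assert r.lr_neg == 0.0

    def test_zero_denominators_marked_undefined(self):
        r = diagnostic_metrics(ContingencyTable2x2(0, 0, 0, 5))
        assert math.isnan(r.sensitivity)  # no diseased subjects
        assert math.isnan(r.ppv)  # no positive calls

    @pytest.mark.parametrize(
        "cells", [(33, 2, 2, 10), (5, 1, 2, 7), (1, 1, 1, 1), (6, 0, 3, 2)]
    )
    def test_identities(self, cells):
        t = ContingencyTable2x2(*cells)
        r = diagnostic_metrics(t)
        assert r.accuracy_pct == pytest.approx(100 * (t.tp + t.tn) / t.n)
        if not math.isinf(r.lr_pos):
            assert r.lr_pos * (1 - r.specificity) == pytest.approx(r.sensitivity)
        assert r.fpr_paper == pytest.approx(1 - r.ppv)
        assert r.fnr_paper == pytest.approx(1 - r.npv)
        assert r.fpr_standard == pytest.approx(1 - r.specificity)

    def test_ci_brackets_point_for_proportions(self, published_table):
        r = diagnostic_metrics(published_table)
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            low, high = r.ci[name]
            assert low <= getattr(r, name) <= high

    def test_report_serialises(self, published_table):
        payload = diagnostic_metrics(published_table).to_dict()
        assert payload["metrics"]["sensitivity"]["method"] == "clopper_pearson"
        assert payload["conventions"]["fpr_paper"] == "FP/(TP+FP) = 1 - PPV"


class TestProportionCI:
    @pytest.mark.parametrize("s,n", [(12, 12), (0, 10), (10, 12), (33, 35), (1, 47)])
    def test_matches_bisection_oracle(self, s, n):
        low, high = proportion_ci(s, n, 0.05, "clopper_pearson")
        o_low, o_high = clopper_pearson_oracle(s, n, 0.05)
        assert low == pytest.approx(o_low, abs=1e-9)
        assert high == pytest.approx(o_high, abs=1e-9)

    def test_known_values(self):
        assert proportion_ci(12, 12, 0.05)[0] == pytest.approx(0.7354, abs=5e-5)
        assert proportion_ci(12, 12, 0.05)[1] == 1.0
        assert proportion_ci(0, 10, 0.05)[0] == 0.0
        low, high = proportion_ci(10, 12, 0.05)
        assert low == pytest.approx(0.5159, abs=5e-5)
        assert high == pytest.approx(0.97914, abs=5e-5)

    def test_wilson_method_available(self):
        low, high = proportion_ci(10, 12, 0.05, method="wilson")
        assert 0 < low < 10 / 12 < high < 1
        assert (low, high) != proportion_ci(10, 12, 0.05)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1])
    def test_invalid_alpha_rejected(self, alpha):
        with pytest.raises(ValidationError):
            proportion_ci(5, 10, alpha)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            proportion_ci(11, 10, 0.05)


class TestLrCI:
    def test_negative_lr_interval(self, published_table):
        low, high = lr_ci(published_table, "neg", 0.05)
        assert low == pytest.approx(0.0175, abs=5e-4)
        assert high == pytest.approx(0.2695, abs=5e-4)

    def test_positive_lr_interval(self, published_table):
        low, high = lr_ci(published_table, "pos", 0.05)
        assert low == pytest.approx(1.59, abs=5e-3)
        assert high == pytest.approx(20.1, abs=5e-2)

    def test_formula_direct_evaluation(self, published_table):
        """Interval equals exp(ln LR ± z·SE) with the Simel standard error."""
        tp, fp, fn, tn = 33, 2, 2, 10
        lr_neg = (fn / (tp + fn)) / (tn / (fp + tn))
        se = math.sqrt(1 / fn - 1 / (tp + fn) + 1 / tn - 1 / (fp + tn))
        z = 1.959963984540054
        low, high = lr_ci(published_table, "neg", 0.05)
        assert low == pytest.approx(math.exp(math.log(lr_neg) - z * se))
        assert high == pytest.approx(math.exp(math.log(lr_neg) + z * se))

    def test_symmetric_table_centred_at_unity(self):
        low, high = lr_ci(ContingencyTable2x2(10, 10, 10, 10), "pos", 0.05)
        assert low * high == pytest.approx(1.0)
        assert low < 1.0 < high

    def test_zero_cell_gives_undefined_marker(self):
        low, high = lr_ci(ContingencyTable2x2(10, 0, 0, 10), "pos", 0.05)
        assert math.isnan(low) and math.isnan(high)
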