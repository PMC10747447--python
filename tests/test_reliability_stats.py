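"""Agreement battery: ANOVA mean squares, ICC forms + CIs, CV, SEM, MDC."""
import math

import numpy as np
import pytest

from mvkin import (
    classify_icc,
    cv_method_error,
    icc,
    mdc95,
    reliability_report,
    sem,
    two_way_mean_squares,
)
from mvkin.alignment import AlignedTracePair
from mvkin.errors import ConfigurationError, UndefinedStatisticError
from mvkin.reliability import MDC_FACTOR
from mvkin.series import SignConvention

from conftest import random_ratings_table

HAND_TABLE = np.array([[1.0, 2.0], [3.0, 5.0], [6.0, 6.0], [2.0, 2.0]])


def _hand_mean_squares(table):
    """Independent double-centering oracle, written loop-by-loop."""
    n, k = table.shape
    grand = sum(sum(row) for row in table) / (n * k)
    row_means = [sum(row) / k for row in table]
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((r - grand) ** 2 for r in row_means)
    ss_cols = n * sum((c - grand) ** 2 for c in col_means)
    ss_err = sum(
        (table[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    return ss_rows / (n - 1), ss_cols / (k - 1), ss_err / ((n - 1) * (k - 1))


class TestMeanSquares:
    def test_identical_raters_have_zero_column_and_error_variance(self):
        ms = two_way_mean_squares(np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]]))
        assert ms.msc == 0.0 and ms.mse == 0.0
        assert ms.msr > 0

    def test_components_conserve_total_sum_of_squares(self):
        rng = np.random.default_rng(4)
        t = random_ratings_table(rng, n=6, k=2)
        ms = two_way_mean_squares(t)
        assert ms.ss_rows + ms.ss_cols + ms.ss_error == pytest.approx(ms.ss_total, rel=1e-9)

    def test_matches_hand_double_centering_oracle(self):
        ms = two_way_mean_squares(HAND_TABLE)
        msr, msc, mse = _hand_mean_squares(HAND_TABLE)
        assert ms.msr == pytest.approx(msr, rel=1e-12)
        assert ms.msc == pytest.approx(msc, rel=1e-12)
        assert ms.mse == pytest.approx(mse, rel=1e-12)

    def test_too_small_table_rejected(self):
        with pytest.raises(ConfigurationError):
            two_way_mean_squares(np.array([[1.0, 2.0]]))


class TestIcc:
    def test_identical_columns_give_unity_for_all_forms(self):
        t = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        for form in ("icc21", "icc31", "icc3k"):
            est = icc(t, form)
            assert est.value == 1.0
            assert (est.ci_low, est.ci_high) == (1.0, 1.0)

    def test_rater_offset_lowers_absolute_agreement_only(self):
        rng = np.random.default_rng(8)
        t = random_ratings_table(rng, n=40, k=2)
        shifted = t.copy()
        shifted[:, 1] += 3.0
        assert icc(shifted, "icc31").value == pytest.approx(icc(t, "icc31").value)
        assert icc(shifted, "icc21").value < icc(t, "icc21").value

    def test_hand_table_matches_direct_formula_evaluation(self):
        msr, msc, mse = _hand_mean_squares(HAND_TABLE)
        n, k = HAND_TABLE.shape
        expected = {
            "icc21": (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n),
            "icc31": (msr - mse) / (msr + (k - 1) * mse),
            "icc3k": (msr - mse) / msr,
        }
        for form, value in expected.items():
            assert icc(HAND_TABLE, form).value == pytest.approx(value, rel=1e-12)

    def test_hand_table_matches_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        pg.options["round.column.CI95"] = None
        import pandas as pd

        n = HAND_TABLE.shape[0]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile(["a", "b"], n),
                "score": HAND_TABLE.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
        ref = ref.set_index("Type")
        est = icc(HAND_TABLE, "icc21")
        row = ref.loc["ICC(A,1)"]
        assert est.value == pytest.approx(row["ICC"], abs=1e-9)
        assert est.ci_low == pytest.approx(row["CI95"][0], abs=1e-9)
        assert est.ci_high == pytest.approx(row["CI95"][1], abs=1e-9)

    def test_zero_between_subject_variance_is_undefined(self):
        t = np.array([[2.0, 3.0], [2.0, 3.0], [2.0, 3.0]])
        with pytest.raises(UndefinedStatisticError):
            icc(t, "icc21")

    def test_form_ordering_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            t = random_ratings_table(rng, n=30, k=2)
            ms = two_way_mean_squares(t)
            if not (ms.msr > ms.mse and ms.msc >= ms.mse):
                continue
            e21, e31, e3k = (icc(t, f).value for f in ("icc21", "icc31", "icc3k"))
            assert e21 <= e31 + 1e-12
            assert e31 <= e3k + 1e-12

    def test_joint_affine_transform_leaves_all_forms_unchanged(self):
        rng = np.random.default_rng(13)
        t = random_ratings_table(rng, n=30, k=2)
        for form in ("icc21", "icc31", "icc3k"):
            before = icc(t, form).value
            after = icc(2.5 * t - 7.0, form).value
            assert after == pytest.approx(before, rel=1e-9)

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            t = random_ratings_table(rng, n=50, k=2)
            for form in ("icc21", "icc31", "icc3k"):
                est = icc(t, form)
                assert est.ci_low <= est.value <= est.ci_high


class TestCv:
    def test_identical_series_give_zero(self):
        x = np.array([10.0, 12.0, 14.0])
        assert cv_method_error(x, x) == 0.0

    def test_scale_invariance(self):
        x1 = np.array([10.0, 12.0, 14.0])
        x2 = np.array([11.0, 13.0, 13.0])
        base = cv_method_error(x1, x2)
        assert cv_method_error(3.0 * x1, 3.0 * x2) == pytest.approx(base, rel=1e-12)

    def test_hand_example_both_variants(self):
        x1 = [10.0, 12.0, 14.0]
        x2 = [11.0, 13.0, 13.0]
        diffs = np.array(x1) - np.array(x2)
        sd_d = float(np.std(diffs, ddof=1))
        grand = (np.mean(x1) + np.mean(x2)) / 2.0
        assert cv_method_error(x1, x2) == pytest.approx(100 * sd_d / math.sqrt(2) / grand)
        assert cv_method_error(x1, x2, variant="literal") == pytest.approx(
            100 * sd_d / (2 * grand)
        )

    def test_negative_mean_series_still_give_nonnegative_cv(self):
        x1 = np.array([-10.0, -12.0, -14.0])
        x2 = np.array([-11.0, -13.0, -13.0])
        assert cv_method_error(x1, x2) == pytest.approx(cv_method_error(-x1, -x2))
        assert cv_method_error(x1, x2) > 0

    def test_zero_combined_mean_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cv_method_error([1.0, -1.0], [-1.0, 1.0])


class TestSemMdc:
    def test_perfect_reliability_gives_zero_sem(self):
        assert sem(10.0, 1.0) == 0.0

    def test_rooted_variant_on_reported_magnitudes(self):
        # SD 11.27 deg with ICC 0.895: SEM = 11.27 * sqrt(0.105)
        assert sem(11.27, 0.895) == pytest.approx(11.27 * math.sqrt(1 - 0.895), rel=1e-12)
        assert sem(11.27, 0.895, variant="literal") == pytest.approx(11.27 * 0.105, rel=1e-12)

    def test_zero_sd_gives_zero_for_any_icc(self):
        assert sem(0.0, 0.3) == 0.0

    def test_icc_above_one_rejected(self):
        with pytest.raises(ConfigurationError):
            sem(5.0, 1.1)

    def test_mdc_is_fixed_multiple_of_sem(self):
        assert mdc95(0.0) == 0.0
        assert mdc95(1.0) == pytest.approx(1.96 * math.sqrt(2))
        for s in (0.5, 2.0, 7.3):
            assert mdc95(s) / s == pytest.approx(MDC_FACTOR)

    def test_negative_sem_rejected(self):
        with pytest.raises(ConfigurationError):
            mdc95(-0.1)


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.895, "very good"),
            (0.5, "normal"),
            (0.39, "poor"),
            (0.4, "normal"),
            (0.6, "good"),
            (0.75, "very good"),
        ],
    )
    def test_results_scheme(self, value, band):
        assert classify_icc(value) == band

    @pytest.mark.parametrize(
        "value, band",
        [(0.3, "poor"), (0.6, "moderate"), (0.80, "good"), (0.90, "good"), (0.95, "high")],
    )
    def test_methods_scheme(self, value, band):
        assert classify_icc(value, scheme="methods") == band


def _pair(test, reference, **prov):
    n = len(test)
    return AlignedTracePair(
        test=np.asarray(test, float),
        reference=np.asarray(reference, float),
        t_norm=np.linspace(0, 1, n),
        convention=SignConvention.LEFT_POSITIVE,
        provenance=prov,
    )


class TestReliabilityReport:
    def test_perfect_pair_gives_unit_icc_and_zero_error_terms(self):
        vals = np.linspace(0, 40, 100)
        (row,) = reliability_report([_pair(vals, vals, participant="1")])
        assert row.icc == 1.0
        assert row.sem_deg == 0.0
        assert row.mdc95_deg == 0.0
        assert row.band == "very good"

    def test_one_row_per_pair_in_stable_order(self):
        rng = np.random.default_rng(3)
        pairs = []
        for p in range(10):
            base = np.linspace(0, 30, 100)
            pairs.append(
                _pair(base + rng.normal(0, 1, 100), base + rng.normal(0, 1, 100),
                      participant=str(p))
            )
        rows = reliability_report(pairs)
        assert [r.participant for r in rows] == [str(p) for p in range(10)]
        assert all(r.icc_form == "icc21" for r in rows)

    def test_joint_negation_flips_mean_but_not_icc(self):
        rng = np.random.default_rng(6)
        base = np.linspace(0, 30, 100)
        test = base + rng.normal(0, 1, 100)
        ref = base + rng.normal(0, 1, 100)
        (row,) = reliability_report([_pair(test, ref)])
        (row_neg,) = reliability_report([_pair(-test, -ref)])
        assert row_neg.m == pytest.approx(-row.m)
        assert row_neg.icc == pytest.approx(row.icc, rel=1e-12)
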