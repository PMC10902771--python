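"""Agreement statistics: exact oracles, cross-checks, and calibration."""
import json
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from headcirc.agreement import (
    AgreementStudy,
    ComparisonSpec,
    agreement_report,
    bland_altman,
    bland_altman_plot,
    cohen_kappa,
    icc_category,
    icc_two_way,
    sem_measurement,
    shapiro_wilk,
    summarize_survey,
    two_sample_t,
    variance_ratio_test,
)
from headcirc.errors import (
    ComparisonSpecError,
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidArgumentError,
    MissingCellError,
    PairingError,
    TableSchemaError,
)
from headcirc.phantom import RaterSpec, RaterStudySpec, simulate_rater_study
from headcirc.tables import read_measurement_table, write_measurement_table


def make_table(matrix, raters=("A", "B", "C")):
    """Long table from a subjects x raters matrix of cm values."""
    rows = []
    for i, row in enumerate(matrix):
        for j, v in enumerate(row[: len(raters)]):
            rows.append((f"S{i}", raters[j], "app", 1, float(v)))
    return pd.DataFrame(rows, columns=["subject_id", "rater_id", "method",
                                       "repeat", "hc_cm"])


def icc21_bruteforce(matrix):
    """Independent sum-of-squares ANOVA ICC(2,1), written longhand."""
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    msr = sum(k * (row.mean() - grand) ** 2 for row in x) / (n - 1)
    msc = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_raters_give_icc_one_excellent(self):
        t = make_table([[40 + i, 40 + i] for i in range(10)], raters=("A", "B"))
        r = icc_two_way(t)
        assert r.icc == pytest.approx(1.0)
        assert r.category == "excellent"
        assert r.var_error == pytest.approx(0.0)

    @pytest.mark.parametrize("matrix", [
        [[42.1, 42.9], [44.0, 43.6], [45.2, 45.9], [41.0, 41.4],
         [46.3, 46.1], [43.3, 44.0]],
        [[40, 41, 42], [44, 44, 45], [46, 45, 47], [42, 43, 43], [48, 47, 49]],
        np.random.default_rng(2).normal(45, 2, (10, 2)).tolist(),
        np.random.default_rng(3).normal(45, 2, (7, 4)).tolist(),
    ])
    def test_matches_bruteforce_anova_on_small_tables(self, matrix):
        raters = tuple("ABCD"[: len(matrix[0])])
        r = icc_two_way(make_table(matrix, raters=raters))
        assert r.icc == pytest.approx(icc21_bruteforce(matrix), abs=1e-12)

    def test_matches_pingouin_point_and_ci(self):
        """Independent route: pingouin's ICC2 on the same simulated table."""
        pg = pytest.importorskip("pingouin")
        t = simulate_rater_study(RaterStudySpec(
            n_subjects=40, raters=(RaterSpec("A", 0.0, 0.4),
                                   RaterSpec("B", 0.3, 0.5)), seed=21))
        mine = icc_two_way(t)
        ref = pg.intraclass_corr(data=t, targets="subject_id",
                                 raters="rater_id", ratings="hc_cm")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert mine.icc == pytest.approx(float(row["ICC"]), abs=1e-9)
        lo, hi = row["CI95"]
        assert mine.ci_low == pytest.approx(float(lo), abs=0.01)
        assert mine.ci_high == pytest.approx(float(hi), abs=0.01)

    def test_parameter_recovery_from_simulated_variance_components(self):
        """subject var 4.0, rater error var 0.25 -> ICC near 16/17."""
        spec = RaterStudySpec(
            n_subjects=200, subject_sd_cm=2.0,
            raters=(RaterSpec("A", 0.0, 0.5), RaterSpec("B", 0.0, 0.5)),
            seed=11)
        r = icc_two_way(simulate_rater_study(spec))
        assert spec.true_icc == pytest.approx(4.0 / 4.25)
        assert r.icc == pytest.approx(spec.true_icc, abs=0.03)

    def test_average_measure_form_is_spearman_brown_of_single(self):
        t = make_table(np.random.default_rng(5).normal(45, 2, (12, 2)).tolist(),
                       raters=("A", "B"))
        single = icc_two_way(t, form="2,1")
        avg = icc_two_way(t, form="2,k")
        k = 2
        assert avg.icc == pytest.approx(
            single.icc * k / (1 + single.icc * (k - 1)))

    def test_within_rater_uses_repeat_column(self):
        rows = []
        rng = np.random.default_rng(8)
        for i in range(15):
            base = rng.normal(45, 2)
            for rep in (1, 2):
                rows.append((f"S{i}", "R1", "app", rep, base + rng.normal(0, 0.3)))
        t = pd.DataFrame(rows, columns=["subject_id", "rater_id", "method",
                                        "repeat", "hc_cm"])
        r = icc_two_way(t, cols="repeat")
        assert 0.9 < r.icc <= 1.0

    def test_too_few_subjects_raises(self):
        with pytest.raises(InsufficientDataError):
            icc_two_way(make_table([[40, 41]], raters=("A", "B")))

    def test_missing_cells_named(self):
        t = make_table([[40, 41], [42, 43], [44, 45]], raters=("A", "B"))
        t = t.drop(t[(t.subject_id == "S1") & (t.rater_id == "B")].index)
        with pytest.raises(MissingCellError) as exc:
            icc_two_way(t)
        assert ("S1", "B") in exc.value.cells


class TestICCCategory:
    @pytest.mark.parametrize("value,label", [
        (0.177, "poor"),        # below 0.5
        (0.341, "poor"),
        (0.499, "poor"),
        (0.5, "moderate"),      # boundary joins the band it opens
        (0.74, "moderate"),
        (0.75, "good"),
        (0.9, "good"),
        (0.901, "excellent"),   # above 0.9
        (1.0, "excellent"),
        (-0.2, "poor"),         # negative estimates are reported, not clamped
    ])
    def test_band_assignment(self, value, label):
        assert icc_category(value) == label

    def test_above_one_rejected(self):
        with pytest.raises(InvalidArgumentError):
            icc_category(1.01)


class TestBlandAltman:
    def test_identical_methods_are_zero_bias_zero_loa(self):
        r = bland_altman([44.1, 45.2, 46.0], [44.1, 45.2, 46.0])
        assert r.mean_diff_cm == 0.0
        assert r.loa_lower_cm == 0.0 == r.loa_upper_cm

    def test_hand_computed_example(self):
        """d = (1, 2, 3): mean 2, sd 1, LoA (0.04, 3.96)."""
        r = bland_altman([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert r.mean_diff_cm == pytest.approx(2.0)
        assert r.sd_diff_cm == pytest.approx(1.0)
        assert r.loa_lower_cm == pytest.approx(0.04)
        assert r.loa_upper_cm == pytest.approx(3.96)
        assert r.n == 3

    def test_limits_half_width_is_196_sd_exactly(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(45, 2, 50), rng.normal(45, 2, 50)
        r = bland_altman(x, y)
        assert r.loa_upper_cm - r.mean_diff_cm == pytest.approx(1.96 * r.sd_diff_cm)
        assert r.mean_diff_cm - r.loa_lower_cm == pytest.approx(1.96 * r.sd_diff_cm)

    def test_coverage_is_95pct_under_normal_differences(self):
        """The agreement interval encompasses ~95% of differences."""
        rng = np.random.default_rng(7)
        d = rng.normal(0.0, 1.0, 100_000)
        r = bland_altman(d, np.zeros_like(d))
        inside = np.mean((d >= r.loa_lower_cm) & (d <= r.loa_upper_cm))
        assert inside == pytest.approx(0.95, abs=0.005)

    def test_errors(self):
        with pytest.raises(PairingError):
            bland_altman([1, 2, 3], [1, 2])
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [2.0])

    def test_plot_file_written_and_svg_deterministic(self, tmp_path):
        x = np.array([44.0, 45.0, 46.0])
        y = np.array([44.5, 44.8, 46.3])
        r = bland_altman(x, y)
        p1 = bland_altman_plot(r, x, y, tmp_path / "ba1.svg")
        p2 = bland_altman_plot(r, x, y, tmp_path / "ba2.svg")
        assert p1.exists() and p1.stat().st_size > 0
        assert p1.read_bytes() == p2.read_bytes()
        png = bland_altman_plot(r, x, y, tmp_path / "ba.png")
        assert png.exists()


class TestCohenKappa:
    def test_perfect_agreement(self):
        x = np.array([41.2, 42.3, 43.4, 44.9])
        assert cohen_kappa(x, x).kappa == 1.0

    def test_two_by_two_table_hand_computation(self):
        """Confusion [[20, 5], [10, 15]] -> p_o = 0.7, p_e = 0.5, kappa 0.4."""
        x = np.concatenate([np.full(25, 0.5), np.full(25, 1.5)])
        y = np.concatenate([np.full(20, 0.5), np.full(5, 1.5),
                            np.full(10, 0.5), np.full(15, 1.5)])
        r = cohen_kappa(x, y, bin_width_cm=1.0)
        assert r.p_observed == pytest.approx(0.7)
        assert r.p_expected == pytest.approx(0.5)
        assert r.kappa == pytest.approx(0.4)

    def test_matches_sklearn_on_binned_values(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(3)
        x = rng.normal(45, 2, 200)
        y = x + rng.normal(0, 1.0, 200)
        mine = cohen_kappa(x, y, 1.0)
        ref = sk.cohen_kappa_score(np.floor(x).astype(int),
                                   np.floor(y).astype(int))
        assert mine.kappa == pytest.approx(ref, abs=1e-12)

    def test_independent_ratings_give_near_zero_kappa(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 20, 20_000)
        y = rng.uniform(0, 20, 20_000)
        assert abs(cohen_kappa(x, y, 1.0).kappa) < 0.02

    @given(shift=st.integers(-5, 5),
           seed=st.integers(0, 100))
    def test_relabeling_bins_leaves_kappa_unchanged_and_below_one(self, shift, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(45, 2, 60)
        y = x + rng.normal(0, 1.0, 60)
        k0 = cohen_kappa(x, y, 1.0).kappa
        k1 = cohen_kappa(x + shift, y + shift, 1.0).kappa
        assert k1 == pytest.approx(k0, abs=1e-12)
        assert k0 <= 1.0


class TestSemAndTests:
    @pytest.mark.parametrize("sd,icc,expected", [
        (1.0, 0.0, 1.0), (2.0, 0.75, 1.0), (3.7, 1.0, 0.0),
    ])
    def test_sem_measurement_values(self, sd, icc, expected):
        assert sem_measurement(sd, icc) == pytest.approx(expected)

    def test_sem_decreases_with_icc(self):
        vals = [sem_measurement(2.0, i) for i in (0.0, 0.25, 0.5, 0.75, 1.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_sem_mean_mode_and_errors(self):
        assert sem_measurement(2.0, 0.0, mode="mean", n=4) == pytest.approx(1.0)
        with pytest.raises(InvalidArgumentError):
            sem_measurement(1.0, 1.2)

    def test_f_identical_samples_unity(self):
        x = [43.0, 44.5, 45.1, 46.2]
        r = variance_ratio_test(x, x)
        assert r.statistic == pytest.approx(1.0)
        assert r.df == (3, 3)

    def test_f_definitional_ratio(self):
        x = [0.0, 2.0, 4.0, 6.0]  # var 20/3... scaled version of y
        y = [0.0, 1.0, 2.0, 3.0]
        assert variance_ratio_test(x, y).statistic == pytest.approx(4.0)

    def test_f_zero_denominator_variance(self):
        with pytest.raises(DegenerateVarianceError):
            variance_ratio_test([1.0, 2.0], [3.0, 3.0])

    def test_t_equal_samples(self):
        x = [44.0, 45.0, 46.0]
        r = two_sample_t(x, x)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_t_hand_computed_pooled_statistic(self):
        x, y = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        sp2 = ((x.var(ddof=1) * 2) + (y.var(ddof=1) * 2)) / 4
        expected = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        r = two_sample_t(x, y)
        assert r.statistic == pytest.approx(expected)
        assert r.df == (4,)

    def test_t_and_f_type_one_error_calibrated(self):
        """Under the null, rejection at alpha = 0.05 stays within 3 SE."""
        rng = np.random.default_rng(13)
        reps, n, alpha = 10_000, 50, 0.05
        rej_t = rej_f = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rej_t += two_sample_t(x, y).p_value < alpha
            rej_f += variance_ratio_test(x, y).p_value < alpha
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rej_t / reps - alpha) < 3 * se
        assert abs(rej_f / reps - alpha) < 3 * se

    def test_shapiro_flags_bimodal_and_accepts_normal(self):
        rng = np.random.default_rng(5)
        bimodal = np.concatenate([rng.normal(-4, 0.3, 50), rng.normal(4, 0.3, 50)])
        assert shapiro_wilk(bimodal).p_value < 0.05
        normal = rng.standard_normal(500)
        r = shapiro_wilk(normal)
        assert 0 < r.statistic <= 1.0
        assert r.p_value > 0.05
        with pytest.raises(InsufficientDataError):
            shapiro_wilk([1.0, 2.0])


class TestSurvey:
    @pytest.mark.parametrize("count,n,percent", [
        (31, 37, 84), (33, 37, 89), (0, 37, 0), (37, 37, 100),
        (1, 8, 13),  # 12.5 rounds away from zero
    ])
    def test_percentages(self, count, n, percent):
        assert summarize_survey(count, n).percent == percent

    def test_invalid_counts(self):
        with pytest.raises(InvalidArgumentError):
            summarize_survey(5, 4)
        with pytest.raises(InvalidArgumentError):
            summarize_survey(1, 0)


class TestAgreementReport:
    @pytest.fixture()
    def two_method_table(self):
        spec = RaterStudySpec(
            n_subjects=25,
            raters=(RaterSpec("R1", 0.0, 0.3, method="app"),
                    RaterSpec("R2", 0.3, 0.4, method="tape")),
            seed=9)
        return simulate_rater_study(spec)

    def test_report_has_all_blocks(self, two_method_table, tmp_path):
        rep = agreement_report(two_method_table, ComparisonSpec(),
                               plot_path=tmp_path / "ba.png")
        for key in ("icc", "bland_altman", "kappa", "sem_cm", "f_test",
                    "t_test", "shapiro_wilk"):
            assert key in rep
        assert (tmp_path / "ba.png").exists()

    def test_identical_arms_degenerate(self, two_method_table):
        t = two_method_table.copy()
        dup = t[t.method == "app"].copy()
        dup["method"] = "tape"
        dup["rater_id"] = "R2"
        t = pd.concat([t[t.method == "app"], dup], ignore_index=True)
        rep = agreement_report(t, ComparisonSpec())
        assert rep["icc"]["icc"] == pytest.approx(1.0)
        assert rep["kappa"]["kappa"] == 1.0
        assert rep["bland_altman"]["mean_diff_cm"] == 0.0

    def test_report_is_deterministic_from_csv(self, two_method_table, tmp_path):
        csv = tmp_path / "t.csv"
        write_measurement_table(two_method_table, csv)
        study1 = AgreementStudy.from_csv(csv, ComparisonSpec())
        study2 = AgreementStudy.from_csv(csv, ComparisonSpec())
        assert study1.fit().to_json() == study2.fit().to_json()

    def test_missing_arm_raises(self, two_method_table):
        t = two_method_table[two_method_table.method == "app"]
        with pytest.raises(ComparisonSpecError):
            agreement_report(t, ComparisonSpec())

    def test_summary_mentions_key_quantities(self, two_method_table):
        res = AgreementStudy(two_method_table, ComparisonSpec()).fit()
        text = res.summary()
        for token in ("ICC", "LoA", "kappa", "SEM", "t test", "F test"):
            assert token in text

    def test_comparison_spec_parsing(self):
        c = ComparisonSpec.parse("app-vs-tape")
        assert (c.by, c.left, c.right) == ("method", "app", "tape")
        c = ComparisonSpec.parse("rater:R1:R2")
        assert (c.by, c.left, c.right) == ("rater_id", "R1", "R2")
        with pytest.raises(ComparisonSpecError):
            ComparisonSpec.parse("nonsense")


class TestTableValidation:
    def test_round_trip(self, tmp_path):
        t = simulate_rater_study(RaterStudySpec(n_subjects=5, seed=1))
        path = write_measurement_table(t, tmp_path / "t.csv")
        back = read_measurement_table(path)
        pd.testing.assert_frame_equal(
            t.reset_index(drop=True), back.reset_index(drop=True))

    def test_duplicate_keys_named(self):
        t = simulate_rater_study(RaterStudySpec(n_subjects=3, seed=1))
        dup = pd.concat([t, t.iloc[[0]]], ignore_index=True)
        with pytest.raises(TableSchemaError, match="S001"):
            read_row = None
            from headcirc.tables import validate_measurement_table
            validate_measurement_table(dup)

    def test_nonpositive_hc_rejected_with_row_number(self):
        t = simulate_rater_study(RaterStudySpec(n_subjects=3, seed=1))
        t.loc[2, "hc_cm"] = -1.0
        from headcirc.tables import validate_measurement_table
        with pytest.raises(TableSchemaError, match="3"):
            validate_measurement_table(t)
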