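"""Agreement and reliability statistics for head-circumference studies.

The validation suite a method-comparison study needs, over long-format
measurement tables: intraclass correlation from two-way ANOVA mean squares
with the conventional interpretation bands, Bland-Altman limits of
agreement, Cohen kappa on binned circumferences, the standard error of
measurement, variance-ratio (F) and pooled two-sample t tests, a
Shapiro-Wilk normality check, and survey percentage summaries.

Two entry styles are provided: the individual statistic functions, and an
:class:`AgreementStudy` whose :meth:`~AgreementStudy.fit` bundles one
two-arm comparison into an :class:`AgreementResults` object with a
``summary()`` table — convenient when a whole report is wanted at once.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ComparisonSpecError,
    DegenerateVarianceError,
    InsufficientDataError,
    InvalidArgumentError,
    MissingCellError,
    PairingError,
    UndefinedKappaError,
)
from .tables import validate_measurement_table

__all__ = [
    "ICCResult", "BAResult", "KappaResult", "TestResult", "SurveySummary",
    "icc_two_way", "icc_category", "bland_altman", "bland_altman_plot",
    "cohen_kappa", "sem_measurement", "variance_ratio_test", "two_sample_t",
    "shapiro_wilk", "summarize_survey",
    "ComparisonSpec", "agreement_report", "AgreementStudy", "AgreementResults",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    """Intraclass correlation with variance components and 95% CI.

    The point estimate may fall below zero (more within-subject than
    between-subject variance); it is reported as computed, with category
    "poor", rather than clamped.
    """

    icc: float
    var_subject: float
    var_rater: float
    var_error: float
    ci_low: float
    ci_high: float
    category: str
    form: str
    n_subjects: int
    n_raters: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "icc", "var_subject", "var_rater", "var_error",
            "ci_low", "ci_high", "category", "form", "n_subjects", "n_raters")}


@dataclass(frozen=True)
class BAResult:
    """Bland-Altman bias and 95% limits of agreement (cm)."""

    mean_diff_cm: float
    sd_diff_cm: float
    loa_lower_cm: float
    loa_upper_cm: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "mean_diff_cm", "sd_diff_cm", "loa_lower_cm", "loa_upper_cm", "n")}


@dataclass(frozen=True)
class KappaResult:
    """Cohen kappa after binning continuous cm values."""

    kappa: float
    p_observed: float
    p_expected: float
    bin_width_cm: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "kappa", "p_observed", "p_expected", "bin_width_cm")}


@dataclass(frozen=True)
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, two-sided p."""

    statistic: float
    df: tuple
    p_value: float
    test_name: str

    def to_dict(self) -> dict:
        return {"statistic": self.statistic, "df": list(self.df),
                "p_value": self.p_value, "test_name": self.test_name}


@dataclass(frozen=True)
class SurveySummary:
    """A count out of n with its integer percentage."""

    count: int
    n: int
    percent: int

    def to_dict(self) -> dict:
        return {"count": self.count, "n": self.n, "percent": self.percent}


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def _crossed_matrix(table: pd.DataFrame, cols: str, raters=None) -> pd.DataFrame:
    """Subject x rater matrix, averaging duplicate cells; fails on holes."""
    t = table
    if raters is not None:
        t = t[t[cols].isin(list(raters))]
        if t[cols].nunique() != len(set(raters)):
            missing = sorted(set(raters) - set(t[cols].unique()))
            raise ComparisonSpecError(f"rater set not in table: {missing}")
    wide = t.pivot_table(index="subject_id", columns=cols, values="hc_cm",
                         aggfunc="mean")
    if wide.isna().any().any():
        holes = [(s, c) for s in wide.index for c in wide.columns
                 if pd.isna(wide.at[s, c])]
        raise MissingCellError(holes[:10])
    return wide


def icc_two_way(table: pd.DataFrame, raters=None, *, cols: str = "rater_id",
                form: str = "2,1", alpha: float = 0.05) -> ICCResult:
    """Intraclass correlation from a crossed subject x rater design.

    The default ``form="2,1"`` is the two-way random-effects, absolute
    agreement, single-measurement coefficient,

        ICC = (MS_S - MS_E) / (MS_S + (k-1) MS_E + k (MS_R - MS_E) / n),

    with mean squares from the two-way ANOVA of the n x k cell matrix
    (duplicate cells are averaged first). Consistency ("3,1"), one-way
    ("1,1") and their average-measure counterparts ("2,k", "3,k", "1,k")
    are available behind ``form``. 95% confidence bounds use the standard
    F-based intervals.

    ``cols`` names the column that defines the "rater" axis; pass
    ``cols="repeat"`` (with a single-rater table) for within-rater
    repeatability.
    """
    table = validate_measurement_table(table)
    wide = _crossed_matrix(table, cols, raters)
    x = wide.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2:
        raise InsufficientDataError(f"ICC needs >= 2 subjects, got {n}")
    if k < 2:
        raise InsufficientDataError(f"ICC needs >= 2 raters/repeats, got {k}")

    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ss_r = k * np.sum((row_m - grand) ** 2)       # subjects (rows)
    ss_c = n * np.sum((col_m - grand) ** 2)       # raters (columns)
    ss_e = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    msr = ss_r / (n - 1)
    msc = ss_c / (k - 1)
    mse = ss_e / ((n - 1) * (k - 1))
    msw = (ss_c + ss_e) / (n * (k - 1))           # one-way within MS

    def _icc_point(f):
        if f == "1,1":
            return (msr - msw) / (msr + (k - 1) * msw)
        if f == "2,1":
            return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        if f == "3,1":
            return (msr - mse) / (msr + (k - 1) * mse)
        raise InvalidArgumentError(f"unknown ICC form {f!r}")

    base = form.split(",")[0] + ",1"
    single = form.endswith(",1")
    if not (single or form.endswith(",k")):
        raise InvalidArgumentError(f"unknown ICC form {form!r}")
    icc1 = _icc_point(base)
    lo1, hi1 = _icc_ci(base, icc1, msr, msc, mse, msw, n, k, alpha)
    if single:
        icc_val, lo, hi = icc1, lo1, hi1
    else:
        sb = lambda r: r * k / (1.0 + r * (k - 1.0))  # Spearman-Brown
        icc_val, lo, hi = sb(icc1), sb(lo1), sb(hi1)

    return ICCResult(
        icc=float(icc_val),
        var_subject=float(max(0.0, (msr - mse) / k)),
        var_rater=float(max(0.0, (msc - mse) / n)),
        var_error=float(mse),
        ci_low=float(lo), ci_high=float(min(1.0, hi)),
        category=icc_category(icc_val),
        form=form, n_subjects=n, n_raters=k,
    )


def _icc_ci(base, icc, msr, msc, mse, msw, n, k, alpha):
    """F-based 95% bounds for the single-measure forms (McGraw-Wong)."""
    fdist = stats.f
    if base == "1,1":
        if msw == 0:
            return (1.0, 1.0) if mse == 0 else (icc, icc)
        fstat = msr / msw
        df1, df2 = n - 1, n * (k - 1)
        fl = fstat / fdist.ppf(1 - alpha / 2, df1, df2)
        fu = fstat * fdist.ppf(1 - alpha / 2, df2, df1)
        return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
    if base == "3,1":
        if mse == 0:
            return 1.0, 1.0
        fstat = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = fstat / fdist.ppf(1 - alpha / 2, df1, df2)
        fu = fstat * fdist.ppf(1 - alpha / 2, df2, df1)
        return (fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1)
    # "2,1": Satterthwaite df for the rater term
    if mse == 0:
        return 1.0, 1.0
    fj = msc / mse
    a = k * icc * fj + n * (1 + (k - 1) * icc) - k * icc
    vn = (k - 1) * (n - 1) * a**2
    vd = (n - 1) * (k * icc * fj) ** 2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f2u = fdist.ppf(1 - alpha / 2, n - 1, v)
    f2l = fdist.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f2u * mse) / (f2u * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
    return lo, hi


def icc_category(icc_value: float) -> str:
    """Interpretation band for an ICC point estimate.

    ``< 0.5`` poor, ``[0.5, 0.75)`` moderate, ``[0.75, 0.9]`` good,
    ``> 0.9`` excellent; boundaries belong to the band whose lower bound
    they are (so 0.9 is still "good").
    """
    if icc_value > 1:
        raise InvalidArgumentError(f"ICC cannot exceed 1, got {icc_value}")
    if icc_value < 0.5:
        return "poor"
    if icc_value < 0.75:
        return "moderate"
    if icc_value <= 0.9:
        return "good"
    return "excellent"


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------

def bland_altman(x, y) -> BAResult:
    """Bias and 95% limits of agreement between two paired methods.

    ``d = x - y`` pairwise; the limits ``mean(d) +/- 1.96 sd(d)`` (sample
    SD, n-1) bracket ~95% of the differences when they are normal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PairingError(f"paired vectors required, got shapes {x.shape}, {y.shape}")
    n = len(x)
    if n < 2:
        raise InsufficientDataError(f"Bland-Altman needs >= 2 pairs, got {n}")
    d = x - y
    mean_d = float(d.mean())
    sd_d = float(d.std(ddof=1))
    return BAResult(mean_diff_cm=mean_d, sd_diff_cm=sd_d,
                    loa_lower_cm=mean_d - 1.96 * sd_d,
                    loa_upper_cm=mean_d + 1.96 * sd_d, n=n)


def bland_altman_plot(result: BAResult, x, y, path) -> Path:
    """Scatter of pair means vs differences with bias and LoA lines.

    SVG output is made byte-deterministic (fixed hash salt, no date
    metadata) so regenerated reports can be diffed.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("no pairs to plot")
    if x.shape != y.shape:
        raise PairingError("paired vectors required")
    with plt.rc_context({"svg.hashsalt": "headcirc"}):
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter((x + y) / 2.0, x - y, s=18, color="#33538a", zorder=3)
        ax.axhline(result.mean_diff_cm, color="k", lw=1.2, label="bias")
        for v in (result.loa_lower_cm, result.loa_upper_cm):
            ax.axhline(v, color="crimson", lw=1.0, ls="--")
        ax.set_xlabel("mean of methods (cm)")
        ax.set_ylabel("difference (cm)")
        ax.set_title("Bland-Altman")
        fig.tight_layout()
        path = Path(path)
        fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
        plt.close(fig)
    return path


# ---------------------------------------------------------------------------
# kappa, SEM, tests, survey
# ---------------------------------------------------------------------------

def cohen_kappa(x, y, bin_width_cm: float = 1.0) -> KappaResult:
    """Chance-corrected agreement after binning cm values.

    Measurements fall into fixed bins ``[k*w, (k+1)*w)`` anchored at zero;
    kappa is ``(p_o - p_e) / (1 - p_e)`` with chance agreement from the
    marginal bin frequencies. Perfect agreement with degenerate marginals
    (everything in one bin) is kappa 1 by convention.
    """
    if bin_width_cm <= 0:
        raise InvalidArgumentError(f"bin width must be positive, got {bin_width_cm}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise PairingError("non-empty paired vectors required")
    bx = np.floor(x / bin_width_cm).astype(int)
    by = np.floor(y / bin_width_cm).astype(int)
    n = len(bx)
    p_o = float(np.mean(bx == by))
    cats = np.union1d(bx, by)
    fx = np.array([np.sum(bx == c) for c in cats]) / n
    fy = np.array([np.sum(by == c) for c in cats]) / n
    p_e = float(np.sum(fx * fy))
    if p_e >= 1.0:
        if p_o == 1.0:
            return KappaResult(1.0, p_o, p_e, float(bin_width_cm))
        raise UndefinedKappaError("chance agreement is 1 but observed is not")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(float(kappa), p_o, p_e, float(bin_width_cm))


def sem_measurement(sd_cm: float, icc: float, *, mode: str = "measurement",
                    n: int | None = None) -> float:
    """Standard error of measurement, ``SD * sqrt(1 - ICC)``.

    ``mode="mean"`` gives the literal standard error of the mean
    ``sd / sqrt(n)`` instead (the two readings of the abbreviation SEM).
    """
    if sd_cm < 0:
        raise InvalidArgumentError(f"sd must be non-negative, got {sd_cm}")
    if mode == "mean":
        if n is None or n < 1:
            raise InvalidArgumentError("mode='mean' needs a positive n")
        return sd_cm / math.sqrt(n)
    if mode != "measurement":
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    if icc > 1:
        raise InvalidArgumentError(f"ICC cannot exceed 1, got {icc}")
    return sd_cm * math.sqrt(1.0 - icc)


def variance_ratio_test(x, y) -> TestResult:
    """Two-sided F test of equal variances, ``F = var(x) / var(y)``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("both samples need n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vy == 0:
        raise DegenerateVarianceError("denominator sample has zero variance")
    f_stat = vx / vy
    df = (len(x) - 1, len(y) - 1)
    cdf = stats.f.cdf(f_stat, *df)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return TestResult(float(f_stat), df, p, "f_variance")


def two_sample_t(x, y) -> TestResult:
    """Pooled-variance two-sample t test, two-sided."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError("both samples need n >= 2")
    t_stat, p = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(float(t_stat), (len(x) + len(y) - 2,), float(p), "t_two_sample")


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise InsufficientDataError(f"Shapiro-Wilk needs n >= 3, got {len(x)}")
    if len(x) > 5000:
        raise InvalidArgumentError("Shapiro-Wilk is calibrated for n <= 5000")
    w, p = stats.shapiro(x)
    return TestResult(float(w), (len(x),), float(p), "shapiro_wilk")


def summarize_survey(count: int, n: int) -> SurveySummary:
    """Integer percentage of a survey count, halves rounded away from zero."""
    if n <= 0:
        raise InvalidArgumentError(f"n must be positive, got {n}")
    if count < 0 or count > n:
        raise InvalidArgumentError(f"count must lie in [0, n], got {count}/{n}")
    percent = int(math.floor(100.0 * count / n + 0.5))
    return SurveySummary(count=int(count), n=int(n), percent=percent)


# ---------------------------------------------------------------------------
# bundled comparison report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonSpec:
    """Names the two arms to compare within one measurement table.

    ``by`` is the column splitting the arms ("method" for app-vs-tape,
    "rater_id" for interrater comparisons); values are averaged over the
    remaining design columns per subject before pairing.
    """

    by: str = "method"
    left: str = "app"
    right: str = "tape"
    kappa_bin_cm: float = 1.0
    icc_form: str = "2,1"

    @classmethod
    def parse(cls, text: str, *, kappa_bin_cm: float = 1.0,
              icc_form: str = "2,1") -> "ComparisonSpec":
        """Parse 'app-vs-tape', 'method:app:tape' or 'rater:R1:R2'."""
        if text == "app-vs-tape":
            return cls(kappa_bin_cm=kappa_bin_cm, icc_form=icc_form)
        parts = text.split(":")
        if len(parts) != 3 or parts[0] not in ("method", "rater"):
            raise ComparisonSpecError(
                f"cannot parse comparison {text!r}; expected 'app-vs-tape', "
                "'method:<a>:<b>' or 'rater:<a>:<b>'")
        by = "method" if parts[0] == "method" else "rater_id"
        return cls(by=by, left=parts[1], right=parts[2],
                   kappa_bin_cm=kappa_bin_cm, icc_form=icc_form)


class AgreementStudy:
    """One two-arm agreement comparison over a measurement table.

    Parameters
    ----------
    table : DataFrame in the measurement schema.
    comparison : which two arms to compare and how to bin/model them.
    """

    def __init__(self, table: pd.DataFrame, comparison: ComparisonSpec):
        self.table = validate_measurement_table(table)
        self.comparison = comparison

    @classmethod
    def from_csv(cls, path, comparison: ComparisonSpec) -> "AgreementStudy":
        from .tables import read_measurement_table
        return cls(read_measurement_table(path), comparison)

    def _paired(self) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
        c = self.comparison
        if c.by not in self.table.columns:
            raise ComparisonSpecError(f"no column {c.by!r} in table")
        present = set(self.table[c.by].unique())
        for arm in (c.left, c.right):
            if arm not in present:
                raise ComparisonSpecError(
                    f"arm {arm!r} not present in column {c.by!r} "
                    f"(available: {sorted(present)})")
        sub = self.table[self.table[c.by].isin([c.left, c.right])]
        wide = sub.pivot_table(index="subject_id", columns=c.by,
                               values="hc_cm", aggfunc="mean")
        wide = wide.dropna()
        if len(wide) < 2:
            raise InsufficientDataError(
                "fewer than 2 subjects measured in both arms")
        return (wide[c.left].to_numpy(), wide[c.right].to_numpy(), wide)

    def fit(self, plot_path=None) -> "AgreementResults":
        """Compute every agreement statistic for the comparison."""
        c = self.comparison
        x, y, wide = self._paired()
        long = wide.reset_index().melt(
            id_vars="subject_id", var_name="rater_id", value_name="hc_cm")
        long["method"] = long["rater_id"]
        long["repeat"] = 1
        icc = icc_two_way(long, form=c.icc_form)
        ba = bland_altman(x, y)
        kap = cohen_kappa(x, y, c.kappa_bin_cm)
        pooled_sd = float(np.concatenate([x, y]).std(ddof=1))
        sem = sem_measurement(pooled_sd, icc.icc)
        f_res = variance_ratio_test(x, y)
        t_res = two_sample_t(x, y)
        d = x - y
        # Shapiro-Wilk is undefined on constant differences (zero range)
        sw = shapiro_wilk(d) if len(d) >= 3 and np.ptp(d) > 0 else None
        plot_file = None
        if plot_path is not None:
            plot_file = str(bland_altman_plot(ba, x, y, plot_path))
        return AgreementResults(
            comparison=c, n_pairs=len(x), icc=icc, bland_altman=ba,
            kappa=kap, sem_cm=float(sem), f_test=f_res, t_test=t_res,
            shapiro=sw, plot_path=plot_file)


@dataclass(frozen=True)
class AgreementResults:
    """Bundle of agreement statistics for one two-arm comparison."""

    comparison: ComparisonSpec
    n_pairs: int
    icc: ICCResult
    bland_altman: BAResult
    kappa: KappaResult
    sem_cm: float
    f_test: TestResult
    t_test: TestResult
    shapiro: TestResult | None
    plot_path: str | None = None

    def to_dict(self) -> dict:
        return {
            "comparison": {"by": self.comparison.by, "left": self.comparison.left,
                           "right": self.comparison.right},
            "n_pairs": self.n_pairs,
            "icc": self.icc.to_dict(),
            "bland_altman": self.bland_altman.to_dict(),
            "kappa": self.kappa.to_dict(),
            "sem_cm": self.sem_cm,
            "f_test": self.f_test.to_dict(),
            "t_test": self.t_test.to_dict(),
            "shapiro_wilk": None if self.shapiro is None else self.shapiro.to_dict(),
            "plot_path": self.plot_path,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> str:
        c = self.comparison
        ba = self.bland_altman
        lines = [
            f"Agreement: {c.left} vs {c.right} (by {c.by}), "
            f"n = {self.n_pairs} paired subjects",
            "-" * 66,
            f"ICC({self.icc.form})        {self.icc.icc:8.3f}  "
            f"[{self.icc.ci_low:.3f}, {self.icc.ci_high:.3f}]  "
            f"({self.icc.category})",
            f"Bias (mean diff)  {ba.mean_diff_cm:8.3f} cm",
            f"95% LoA           [{ba.loa_lower_cm:.3f}, {ba.loa_upper_cm:.3f}] cm",
            f"Cohen kappa       {self.kappa.kappa:8.3f}  "
            f"(bins of {self.kappa.bin_width_cm:g} cm)",
            f"SEM               {self.sem_cm:8.3f} cm",
            f"t test            t = {self.t_test.statistic:.3f}, "
            f"df = {self.t_test.df[0]}, p = {self.t_test.p_value:.4f}",
            f"F test            F = {self.f_test.statistic:.3f}, "
            f"df = {self.f_test.df}, p = {self.f_test.p_value:.4f}",
        ]
        if self.shapiro is not None:
            lines.append(
                f"Shapiro-Wilk (d)  W = {self.shapiro.statistic:.3f}, "
                f"p = {self.shapiro.p_value:.4f}")
        return "\n".join(lines)


def agreement_report(table: pd.DataFrame, comparison: ComparisonSpec,
                     plot_path=None) -> dict:
    """One-call JSON-ready report for a two-arm comparison."""
    return AgreementStudy(table, comparison).fit(plot_path=plot_path).to_dict()
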