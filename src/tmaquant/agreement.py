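"""Rater/method agreement statistics for percent-positive ratings.

Implements the comparison protocol applied to percent-positive-area
ratings of the same images by several raters (human observers) and
methods (automated variants):

* absolute-agreement intraclass correlation from a two-way random-effects
  ANOVA (single-rating ICC(A,1) by default), with the F-based 95%
  confidence interval of McGraw & Wong and the conventional
  interpretation scale — poor (< 0.40), acceptable (0.40-0.74),
  excellent (0.75-1);
* Bland-Altman analysis (paired means/differences, limits of agreement at
  mean +/- 1.96 SD), which assumes neither system is a gold standard;
* Kaplan-Meier curves of paired differences: with no censoring — the case
  here, every difference is observed — the Kaplan-Meier estimate reduces
  to the empirical survival function S(d) = #{|diff| > d} / n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingsTable",
    "ICCResult",
    "BlandAltmanResult",
    "DifferenceCurve",
    "DegenerateDataError",
    "icc_absolute_agreement",
    "icc_category",
    "bland_altman",
    "km_difference_curve",
    "compare_all",
]


class DegenerateDataError(ValueError):
    """Raised when ratings carry no variance to partition."""


@dataclass
class RatingsTable:
    """Complete n_subjects x k_raters grid of percent values.

    Every cell must be present (complete design) and lie in [0, 100].
    """

    values: np.ndarray
    subject_ids: list[str]
    rater_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 subjects and 2 raters")
        if len(self.subject_ids) != n or len(self.rater_ids) != k:
            raise ValueError("id lists must match the value grid shape")
        if np.isnan(self.values).any():
            raise ValueError("missing cells: the design must be complete")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("percent values must lie in [0, 100]")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_raters(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RatingsTable":
        return cls(
            values=df.to_numpy(dtype=float),
            subject_ids=[str(i) for i in df.index],
            rater_ids=[str(c) for c in df.columns],
        )

    @classmethod
    def from_csv(cls, path) -> "RatingsTable":
        """Read a CSV with a header of rater ids and image ids in column 0."""
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.rater_ids
        )

    def column(self, rater) -> np.ndarray:
        return self.values[:, self.rater_ids.index(str(rater))]


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    category: str
    anova_table: dict
    kind: str = "ICC(A,1)"


@dataclass
class BlandAltmanResult:
    pair_means: np.ndarray
    pair_diffs: np.ndarray
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


@dataclass
class DifferenceCurve:
    """Step survival curve of paired-difference magnitudes.

    ``survival[i]`` is P(difference > thresholds[i]); the curve is
    non-increasing and reaches 0 at the largest observed difference.
    """

    thresholds: np.ndarray
    survival: np.ndarray
    signed: bool = False

    def probability_exceeding(self, d: float) -> float:
        """S(d) = P(difference > d), right-continuous step evaluation."""
        idx = np.searchsorted(self.thresholds, d, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def icc_category(icc: float) -> str:
    """Interpretation scale: poor < 0.40 <= acceptable < 0.75 <= excellent."""
    if icc < 0.40:
        return "poor"
    if icc < 0.75:
        return "acceptable"
    return "excellent"


def _two_way_anova(values: np.ndarray) -> dict:
    """Mean squares of the two-way (subjects x raters) decomposition."""
    n, k = values.shape
    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((values - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    return {
        "ms_subjects": ss_rows / (n - 1),
        "ms_raters": ss_cols / (k - 1),
        "ms_error": max(ss_err, 0.0) / ((n - 1) * (k - 1)),
        "df_subjects": n - 1,
        "df_raters": k - 1,
        "df_error": (n - 1) * (k - 1),
    }


def icc_absolute_agreement(
    ratings: RatingsTable | np.ndarray | pd.DataFrame,
    confidence: float = 0.95,
    average: bool = False,
) -> ICCResult:
    """Absolute-agreement ICC from a two-way random-effects ANOVA.

    Both subjects and raters are modelled as random samples; rater offsets
    count against agreement. The single-rating form (default) is

        ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR, MSC, MSE the subject, rater and error mean squares. Set
    ``average=True`` for the average-of-k variant ICC(A,k). The confidence
    interval follows the F-based construction of McGraw & Wong (1996),
    the one standard statistical packages use for this estimator.

    Raises
    ------
    DegenerateDataError
        If every cell of the table is identical (no variance to partition).
    """
    if isinstance(ratings, pd.DataFrame):
        ratings = RatingsTable.from_dataframe(ratings)
    elif not isinstance(ratings, RatingsTable):
        arr = np.asarray(ratings, dtype=float)
        ratings = RatingsTable(
            arr,
            [str(i) for i in range(arr.shape[0])],
            [str(j) for j in range(arr.shape[1])],
        )
    values = ratings.values
    n, k = values.shape
    if np.ptp(values) == 0:
        raise DegenerateDataError(
            "all ratings identical: agreement is undefined (zero variance)"
        )

    an = _two_way_anova(values)
    msr, msc, mse = an["ms_subjects"], an["ms_raters"], an["ms_error"]

    denom_single = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc_single = (msr - mse) / denom_single
    alpha = 1.0 - confidence

    if mse == 0 and msc == 0:
        # perfect agreement: interval collapses
        low = high = 1.0
    else:
        # Satterthwaite df for the (a*MSC + b*MSE) denominator combination
        a = (k * icc_single) / (n * (1 - icc_single)) if icc_single < 1 else np.inf
        b = 1 + (k * icc_single * (n - 1)) / (n * (1 - icc_single)) if icc_single < 1 else np.inf
        if np.isinf(a) or np.isinf(b):
            low = high = 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den if den > 0 else 1.0
            f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            low = (
                n * (msr - f_l * mse)
                / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            )
            high = (
                n * (f_u * msr - mse)
                / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
            )

    if average:
        icc = (msr - mse) / (msr + (msc - mse) / n)
        conv = lambda x: (k * x) / (1 + (k - 1) * x) if x < 1 else 1.0
        low, high = conv(low), conv(high)
    else:
        icc = icc_single

    low = min(low, icc)
    high = max(high, icc)
    return ICCResult(
        icc=float(icc),
        ci_low=float(low),
        ci_high=float(high),
        category=icc_category(icc),
        anova_table=an,
        kind="ICC(A,k)" if average else "ICC(A,1)",
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman statistics for two paired measurement series.

    Differences are ``x - y``; the limits of agreement are
    mean_diff -/+ 1.96 * SD (sample SD, n-1 denominator), the conventional
    95% limits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    diffs = x - y
    means = (x + y) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        pair_means=means,
        pair_diffs=diffs,
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - 1.96 * sd_diff,
        loa_high=mean_diff + 1.96 * sd_diff,
    )


def km_difference_curve(x, y, signed: bool = False) -> DifferenceCurve:
    """Kaplan-Meier curve of paired measurement differences.

    The absolute difference |x - y| (or the signed difference with
    ``signed=True``, for diagnostics) is treated as the event time; every
    pair is an observed event (no censoring), so the Kaplan-Meier estimate
    equals the empirical survival function evaluated at each distinct
    observed difference.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size == 0:
        raise ValueError("need at least one pair")
    diffs = x - y if signed else np.abs(x - y)

    from lifelines import KaplanMeierFitter

    # lifelines requires non-negative durations; shift signed inputs
    shift = min(0.0, float(diffs.min()))
    kmf = KaplanMeierFitter()
    kmf.fit(diffs - shift)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float) + shift
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # keep only the observed difference values (drop the t=0 anchor row
    # unless 0 is itself an observed difference)
    observed = np.unique(diffs)
    mask = np.isin(times, observed)
    return DifferenceCurve(
        thresholds=times[mask], survival=surv[mask], signed=signed
    )


@dataclass
class PairComparison:
    rater_x: str
    rater_y: str
    icc: ICCResult
    bland_altman: BlandAltmanResult
    km_curve: DifferenceCurve
    variance_ratio: float
    variance_flag: bool


@dataclass
class AgreementReport:
    pairs: list[PairComparison] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairs:
            rows.append(
                {
                    "rater_x": p.rater_x,
                    "rater_y": p.rater_y,
                    "icc": p.icc.icc,
                    "icc_ci_low": p.icc.ci_low,
                    "icc_ci_high": p.icc.ci_high,
                    "icc_category": p.icc.category,
                    "mean_diff": p.bland_altman.mean_diff,
                    "sd_diff": p.bland_altman.sd_diff,
                    "loa_low": p.bland_altman.loa_low,
                    "loa_high": p.bland_altman.loa_high,
                    "variance_ratio": p.variance_ratio,
                    "unequal_variance_flag": p.variance_flag,
                }
            )
        return pd.DataFrame(rows)


def compare_all(
    ratings: RatingsTable, variance_ratio_alpha: float = 0.05
) -> AgreementReport:
    """Every pairwise comparison between the table's columns.

    For each column pair: Bland-Altman, Kaplan-Meier difference curve, and
    the pairwise ICC. Pairs whose column variances differ significantly
    (two-sided variance-ratio F test at ``variance_ratio_alpha``) are
    flagged, since the absolute-agreement ICC presumes comparable
    variances; the flag is a heuristic screen, not a formal test choice.
    """
    report = AgreementReport()
    n = ratings.n_subjects
    for i, j in combinations(range(ratings.n_raters), 2):
        x = ratings.values[:, i]
        y = ratings.values[:, j]
        sub = RatingsTable(
            ratings.values[:, [i, j]],
            ratings.subject_ids,
            [ratings.rater_ids[i], ratings.rater_ids[j]],
        )
        try:
            icc = icc_absolute_agreement(sub)
        except DegenerateDataError:
            icc = ICCResult(
                icc=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                category="undefined",
                anova_table={},
            )
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        if min(vx, vy) == 0:
            ratio, flag = float("inf"), max(vx, vy) > 0
        else:
            ratio = max(vx, vy) / min(vx, vy)
            p = 2 * stats.f.sf(ratio, n - 1, n - 1)
            flag = p < variance_ratio_alpha
        report.pairs.append(
            PairComparison(
                rater_x=ratings.rater_ids[i],
                rater_y=ratings.rater_ids[j],
                icc=icc,
                bland_altman=bland_altman(x, y),
                km_curve=km_difference_curve(x, y),
                variance_ratio=float(ratio),
                variance_flag=bool(flag),
            )
        )
    return report
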