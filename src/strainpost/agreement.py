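"""Method-agreement statistics for paired measurement series.

The validation battery applied to two methods measuring the same quantity
on the same subjects (here: GLS in % by a reference and a candidate
method) is:

1. **Normality** of each series and of the paired differences
   d = a − b: Q-Q plot against standard-normal quantiles plus the
   Shapiro-Wilk test at α = 0.05.
2. **Correlation**: Pearson if both series are normal, Spearman's rho
   otherwise.
3. **Paired location test** of H0: mean(d) = 0 — Student's paired t if
   the differences are normal, Wilcoxon signed-rank otherwise.
4. **Bland-Altman** agreement: bias = mean(d), limits of agreement
   bias ± 1.96·SD(d).

Equivalence of the two methods is declared when all four clinical
criteria hold (GLS is in %, so the thresholds are absolute percentage
points):

* correlation coefficient ≥ 0.95 (rounded to 2 decimals),
* location-test p-value > 0.05,
* |bias| ≤ 1 %,
* dispersion (the limits-of-agreement half-width, 1.96·SD of the
  differences) ≤ 2 %.

The hypothesis tests themselves are delegated to :mod:`scipy.stats`; this
module contributes the gating, the Bland-Altman quantities and the
verdict logic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, UsageError
from .io import PairedMeasurements

DEFAULT_ALPHA = 0.05
LOA_FACTOR = 1.96  # normal 95% limits of agreement

# clinical equivalence thresholds (absolute, in the unit of the measurement)
CORRELATION_MIN = 0.95
BIAS_MAX = 1.0
DISPERSION_MAX = 2.0

#: sample size above which the Wilcoxon signed-rank test switches from the
#: exact null distribution to the normal approximation with continuity
#: correction
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class QQData:
    """Data behind a normal Q-Q plot.

    ``theoretical`` are standard-normal quantiles at plotting positions
    (i − 0.5)/n; ``ordered`` is the sorted sample; the reference line runs
    through the first- and third-quartile points (the convention of R's
    ``qqline``).
    """

    theoretical: np.ndarray
    ordered: np.ndarray
    slope: float
    intercept: float


@dataclass(frozen=True)
class NormalityResult:
    """Shapiro-Wilk test plus Q-Q data for one sample."""

    statistic: float  # Shapiro-Wilk W
    p_value: float
    alpha: float
    qq: QQData

    @property
    def normal(self) -> bool:
        return self.p_value > self.alpha


@dataclass(frozen=True)
class BlandAltman:
    bias: float  #: mean difference a − b
    sd_diff: float  #: SD of the differences (n − 1 denominator)
    loa_low: float
    loa_high: float

    @property
    def dispersion(self) -> float:
        """Half-width of the limits of agreement, 1.96·SD(d)."""
        return LOA_FACTOR * self.sd_diff


@dataclass(frozen=True)
class Verdict:
    correlation_ok: bool
    test_ok: bool
    bias_ok: bool
    dispersion_ok: bool

    @property
    def equivalent(self) -> bool:
        return (
            self.correlation_ok
            and self.test_ok
            and self.bias_ok
            and self.dispersion_ok
        )


@dataclass(frozen=True)
class AgreementReport:
    """Full outcome of the agreement battery on one pair of series."""

    n: int
    normal_a: NormalityResult
    normal_b: NormalityResult
    normal_diff: NormalityResult | None  #: None when differences are constant
    correlation_method: str  # "pearson" | "spearman"
    r: float
    test_method: str  # "t_paired" | "wilcoxon"
    test_statistic: float
    p_value: float
    bland_altman: BlandAltman
    verdict: Verdict
    warnings: tuple[str, ...] = ()

    def format_report(self) -> str:
        """Stable ``key: value`` summary."""
        ba = self.bland_altman
        lines = [
            f"n: {self.n}",
            f"normal_a: {self.normal_a.normal} (W={self.normal_a.statistic:.4f}, "
            f"p={self.normal_a.p_value:.4g})",
            f"normal_b: {self.normal_b.normal} (W={self.normal_b.statistic:.4f}, "
            f"p={self.normal_b.p_value:.4g})",
        ]
        if self.normal_diff is not None:
            lines.append(
                f"normal_diff: {self.normal_diff.normal} "
                f"(W={self.normal_diff.statistic:.4f}, "
                f"p={self.normal_diff.p_value:.4g})"
            )
        else:
            lines.append("normal_diff: degenerate (constant differences)")
        lines += [
            f"correlation_method: {self.correlation_method}",
            f"r: {self.r:.2f}",
            f"test_method: {self.test_method}",
            f"test_statistic: {self.test_statistic:.4f}",
            f"p_value: {self.p_value:.4f}",
            f"bias: {ba.bias:.4f}",
            f"sd_diff: {ba.sd_diff:.4f}",
            f"loa: ({ba.loa_low:.4f}, {ba.loa_high:.4f})",
            f"dispersion: {ba.dispersion:.4f}",
            f"correlation_ok: {self.verdict.correlation_ok}",
            f"test_ok: {self.verdict.test_ok}",
            f"bias_ok: {self.verdict.bias_ok}",
            f"dispersion_ok: {self.verdict.dispersion_ok}",
            f"equivalent: {self.verdict.equivalent}",
        ]
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def qq_data(sample: np.ndarray) -> QQData:
    """Normal Q-Q plot data with a quartile-anchored reference line."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 3:
        raise UsageError("Q-Q plot needs at least 3 observations")
    theor = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    qx = stats.norm.ppf([0.25, 0.75])
    qy = np.quantile(x, [0.25, 0.75])  # linear interpolation, R type-7
    if qy[1] == qy[0]:
        slope, intercept = 0.0, float(qy[0])
    else:
        slope = float((qy[1] - qy[0]) / (qx[1] - qx[0]))
        intercept = float(qy[0] - slope * qx[0])
    return QQData(theoretical=theor, ordered=x, slope=slope, intercept=intercept)


def shapiro_wilk(sample: np.ndarray, alpha: float = DEFAULT_ALPHA) -> NormalityResult:
    """Shapiro-Wilk normality test plus Q-Q data.

    Valid for 3 ≤ n ≤ 5000; a constant sample has no defined W and raises
    :class:`DegenerateSampleError`.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise UsageError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("Shapiro-Wilk is undefined for a constant sample")
    res = stats.shapiro(x)
    return NormalityResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        alpha=alpha,
        qq=qq_data(x),
    )


def bland_altman_points(pairs: PairedMeasurements) -> np.ndarray:
    """Per-subject (mean, difference) points, in input order.

    Column 0 holds (a_i + b_i)/2, column 1 holds a_i − b_i.  Plotting
    differences against means shows whether disagreement grows at low
    |GLS| (the pattern seen in severely dysfunctional, dyssynchronous
    ventricles).
    """
    return np.column_stack([(pairs.a + pairs.b) / 2.0, pairs.a - pairs.b])


def bland_altman(pairs: PairedMeasurements) -> BlandAltman:
    """Bland-Altman summary of paired series: bias = mean(a − b), limits of
    agreement bias ± 1.96·SD of the differences (n − 1 denominator)."""
    return _bland_altman(pairs.a - pairs.b)


def _bland_altman(d: np.ndarray) -> BlandAltman:
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_FACTOR * sd,
        loa_high=bias + LOA_FACTOR * sd,
    )


def compare_methods(
    pairs: PairedMeasurements, alpha: float = DEFAULT_ALPHA
) -> AgreementReport:
    """Run the full normality-gated agreement battery on paired series.

    Gating:

    * Pearson correlation iff *both* marginal series pass Shapiro-Wilk at
      ``alpha``; Spearman otherwise.
    * Paired t-test iff the differences pass Shapiro-Wilk; Wilcoxon
      signed-rank otherwise (zero differences dropped; exact null for
      n ≤ 25, normal approximation with continuity correction above).

    Degenerate input (b identical to a) yields bias 0, r = 1 and a
    location-test p-value of 1 with a warning instead of an error.
    """
    a, b = pairs.a, pairs.b
    d = a - b
    notes: list[str] = []

    normal_a = shapiro_wilk(a, alpha)
    normal_b = shapiro_wilk(b, alpha)
    if np.ptp(d) == 0:
        normal_diff = None
        diff_normal = True  # all-equal differences: treat as (degenerately) normal
        notes.append("differences are constant; normality of d undefined")
    else:
        normal_diff = shapiro_wilk(d, alpha)
        diff_normal = normal_diff.normal

    # correlation, gated on marginal normality
    if normal_a.normal and normal_b.normal:
        corr_method = "pearson"
        r = float(stats.pearsonr(a, b).statistic)
    else:
        corr_method = "spearman"
        r = float(stats.spearmanr(a, b).statistic)

    # paired location test, gated on normality of the differences
    if np.all(d == 0):
        test_method = "t_paired"
        t_stat, p_value = 0.0, 1.0
        notes.append("all differences are zero; location test degenerate (p = 1)")
    elif diff_normal:
        test_method = "t_paired"
        res = stats.ttest_rel(a, b)
        t_stat, p_value = float(res.statistic), float(res.pvalue)
    else:
        test_method = "wilcoxon"
        nz = int(np.count_nonzero(d))
        method = "exact" if nz <= WILCOXON_EXACT_MAX_N else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(
                a, b, zero_method="wilcox", correction=True, method=method
            )
        t_stat, p_value = float(res.statistic), float(res.pvalue)

    ba = _bland_altman(d)
    verdict = Verdict(
        correlation_ok=round(r, 2) >= CORRELATION_MIN,
        test_ok=p_value > alpha,
        bias_ok=abs(ba.bias) <= BIAS_MAX,
        dispersion_ok=ba.dispersion <= DISPERSION_MAX,
    )
    return AgreementReport(
        n=pairs.n,
        normal_a=normal_a,
        normal_b=normal_b,
        normal_diff=normal_diff,
        correlation_method=corr_method,
        r=r,
        test_method=test_method,
        test_statistic=t_stat,
        p_value=p_value,
        bland_altman=ba,
        verdict=verdict,
        warnings=tuple(notes),
    )
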