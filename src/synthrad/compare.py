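"""Real-vs-synthetic statistical comparison of radiomic feature panels.

For each of the 23 texture features, the two groups (features of real
images, features of synthetic images) are compared with a normality-gated
two-sample test: if both groups pass the D'Agostino-Pearson omnibus
normality test, an unpaired Welch t-test with a 95% CI of the mean
difference; otherwise a Mann-Whitney U test with the Hodges-Lehmann
estimate of the shift and its distribution-free confidence interval.
A feature is flagged significant exactly when the CI of the difference
(real - synthetic) excludes zero.

No multiple-testing correction is applied across the 23 features: the
report mirrors per-feature significance tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .texture import FEATURE_NAMES

__all__ = [
    "NormalityResult", "ComparisonRow", "ComparisonReport",
    "dagostino_normality", "hodges_lehmann_ci", "compare_feature",
    "build_report",
]

MIN_NORMALITY_N = 8  # omnibus K^2 needs at least 8 observations


@dataclass
class NormalityResult:
    normal: bool
    statistic: float
    p_value: float


@dataclass
class ComparisonRow:
    feature_name: str
    mean_real: float
    se_real: float
    mean_synth: float
    se_synth: float
    test_used: str  # "t", "mann-whitney" or "degenerate"
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool


@dataclass
class ComparisonReport:
    rows: list[ComparisonRow]
    alpha: float
    n_real: int
    n_synth: int

    @property
    def n_significant(self) -> int:
        return sum(r.significant for r in self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature": r.feature_name,
                    "mean_real": r.mean_real, "se_real": r.se_real,
                    "mean_synth": r.mean_synth, "se_synth": r.se_synth,
                    "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "test": r.test_used, "p_value": r.p_value,
                    "significant": r.significant,
                }
                for r in self.rows
            ]
        )


def dagostino_normality(x: np.ndarray, alpha: float = 0.05) -> NormalityResult:
    """D'Agostino-Pearson K^2 omnibus test (skewness + kurtosis z-scores).

    Verdict is "normal" iff p >= alpha.  A constant sample is treated as
    not normal (zero-variance convention).
    """
    x = np.asarray(x, dtype=float)
    if x.size < MIN_NORMALITY_N:
        raise ValueError(
            f"normality test needs >= {MIN_NORMALITY_N} values, got {x.size}"
        )
    if np.ptp(x) == 0:
        return NormalityResult(normal=False, statistic=float("inf"), p_value=0.0)
    stat, p = stats.normaltest(x)
    return NormalityResult(normal=bool(p >= alpha), statistic=float(stat),
                           p_value=float(p))


def hodges_lehmann_ci(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Hodges-Lehmann shift estimate of x - y with its distribution-free CI.

    The interval takes the k-th smallest and k-th largest of the m*n
    pairwise differences, with k from the normal approximation to the
    Mann-Whitney U null distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    m, n = x.size, y.size
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    est = float(np.median(diffs))
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    c = m * n / 2.0 - z * np.sqrt(m * n * (m + n + 1) / 12.0)
    k = int(np.floor(c))
    k = max(k, 0)
    lo = float(diffs[k]) if k < diffs.size else float(diffs[0])
    hi = float(diffs[m * n - k - 1])
    return est, lo, hi


def _welch_ci(x, y, alpha):
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(confidence_level=1.0 - alpha)
    return float(res.pvalue), float(ci.low), float(ci.high)


def compare_feature(
    x_real: np.ndarray,
    x_synth: np.ndarray,
    alpha: float = 0.05,
    feature_name: str = "",
    force_test: str | None = None,
) -> ComparisonRow:
    """Compare one feature between groups; difference is real - synthetic.

    ``force_test`` ("t" or "mann-whitney") bypasses the normality gate,
    e.g. for calibration studies of a single test path.
    """
    x = np.asarray(x_real, dtype=float)
    y = np.asarray(x_synth, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")

    mean_real, mean_synth = float(x.mean()), float(y.mean())
    se_real = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
    se_synth = float(y.std(ddof=1) / np.sqrt(y.size)) if y.size > 1 else 0.0

    if np.ptp(x) == 0 and np.ptp(y) == 0:
        if x[0] != y[0]:
            raise ValueError("degenerate samples: zero variance in both groups")
        # identical constants: difference is exactly zero everywhere
        return ComparisonRow(feature_name, mean_real, 0.0, mean_synth, 0.0,
                             "degenerate", 0.0, 0.0, 1.0, False)

    if force_test is not None:
        use_t = force_test == "t"
    else:
        try:
            use_t = (
                dagostino_normality(x, alpha).normal
                and dagostino_normality(y, alpha).normal
            )
        except ValueError:  # too few values for the omnibus test
            use_t = False

    if use_t:
        p, lo, hi = _welch_ci(x, y, alpha)
        test = "t"
    else:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        _, lo, hi = hodges_lehmann_ci(x, y, alpha)
        test = "mann-whitney"
    significant = bool(lo > 0.0 or hi < 0.0)
    return ComparisonRow(feature_name, mean_real, se_real, mean_synth, se_synth,
                         test, lo, hi, p, significant)


def build_report(
    features_real: list[dict[str, float]],
    features_synth: list[dict[str, float]],
    alpha: float = 0.05,
) -> ComparisonReport:
    """One ComparisonRow per texture feature, ordered GLCM / GLRLM / GLSZM."""
    if not features_real or not features_synth:
        raise ValueError("empty feature group")
    rows = []
    for name in FEATURE_NAMES:
        x = np.array([f[name] for f in features_real], dtype=float)
        y = np.array([f[name] for f in features_synth], dtype=float)
        rows.append(compare_feature(x, y, alpha=alpha, feature_name=name))
    return ComparisonReport(rows=rows, alpha=alpha,
                            n_real=len(features_real),
                            n_synth=len(features_synth))
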