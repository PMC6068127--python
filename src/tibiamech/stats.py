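"""Precision and group-comparison statistics.

Short-term precision uses the root-mean-square coefficient of variation
over subjects' repeat measurements,

    CV%RMS = 100 * sqrt( (1/m) * sum_i (SD_i / |mean_i|)^2 ),

with the n-1 SD per subject.  Group comparisons follow a normality gate on
skewness/kurtosis Z-scores (non-normal if either |Z| > 1.96, with the
standard small-sample standard errors): normally distributed samples get a
classic unpaired (pooled-variance) t-test with a t-based 95% CI of the mean
difference; otherwise an exact Mann-Whitney U test with the Hodges-Lehmann
location-shift estimate (median of all pairwise differences) and its exact
(Moses) confidence interval.  Cohen's d = |difference| / SD; the default SD
is the all-scans SD (the SD over every observation), with pooled-group SD
available by configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
from scipy import stats as sps

__all__ = [
    "cv_rms",
    "normality_gate",
    "hodges_lehmann",
    "hodges_lehmann_ci",
    "mann_whitney_exact",
    "compare_groups",
    "effect_size",
    "ComparisonRow",
]


def cv_rms(values_per_subject: list) -> float:
    """Root-mean-square CV%% across subjects' repeat measurements.

    ``values_per_subject`` is a sequence of per-subject repeat lists (each of
    length >= 2).  Signed metrics use |mean|.  Zero iff all repeats are
    identical for every subject.
    """
    terms = []
    for i, reps in enumerate(values_per_subject):
        reps = np.asarray(reps, dtype=float)
        if reps.size < 2:
            raise ValueError(f"subject {i}: at least 2 repeats required")
        mean = reps.mean()
        if mean == 0:
            raise ValueError(f"subject {i}: mean of repeats is exactly zero")
        sd = reps.std(ddof=1)
        terms.append((sd / abs(mean)) ** 2)
    return 100.0 * sqrt(float(np.mean(terms)))


def normality_gate(sample) -> str:
    """'normal' or 'non_normal' by skewness/kurtosis Z-scores vs +/-1.96.

    Uses the adjusted (bias-corrected) sample skewness G1 and excess
    kurtosis G2 with their small-sample standard errors
    SES = sqrt(6n(n-1)/((n-2)(n+1)(n+3))) and
    SEK = 2*SES*sqrt((n^2-1)/((n-3)(n+5))).  The decision is invariant under
    affine transforms of the sample; a constant sample is non_normal by
    convention.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("normality gate requires n >= 4")
    if np.ptp(x) == 0:
        return "non_normal"
    g1 = sps.skew(x, bias=False)
    g2 = sps.kurtosis(x, bias=False, fisher=True)
    ses = sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3)))
    sek = 2.0 * ses * sqrt((n**2 - 1) / ((n - 3) * (n + 5)))
    if abs(g1 / ses) > 1.96 or abs(g2 / sek) > 1.96:
        return "non_normal"
    return "normal"


# ---------------------------------------------------------------------------
# Mann-Whitney / Hodges-Lehmann
# ---------------------------------------------------------------------------

def _u_counts(m: int, n: int) -> np.ndarray:
    """Null distribution counts of the Mann-Whitney U statistic (no ties)."""
    # recurrence on the largest rank: f(m, n, u) = f(m-1, n, u-n) + f(m, n-1, u)
    table = {}

    def f(mm, nn):
        if (mm, nn) in table:
            return table[(mm, nn)]
        if mm == 0 or nn == 0:
            arr = np.zeros(mm * nn + 1)
            arr[0] = 1.0
            table[(mm, nn)] = arr
            return arr
        a = f(mm - 1, nn)
        b = f(mm, nn - 1)
        arr = np.zeros(mm * nn + 1)
        arr[nn : nn + len(a)] += a
        arr[: len(b)] += b
        table[(mm, nn)] = arr
        return arr

    return f(m, n)


def mann_whitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test (U statistic of x, p-value).

    Exact null distribution for min(n) <= 12 without ties; falls back to the
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m, n = x.size, y.size
    ties = len(np.unique(np.concatenate([x, y]))) < m + n
    if not ties and min(m, n) <= 12:
        u = float(sum((xi > y).sum() for xi in x))
        counts = _u_counts(m, n)
        total = comb(m + n, m)
        cdf = np.cumsum(counts) / total
        sf = 1.0 - np.concatenate([[0.0], cdf[:-1]])  # P(U >= u)
        lo = cdf[int(u)]
        hi = sf[int(u)]
        p = min(1.0, 2.0 * min(lo, hi))
        return u, p
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def hodges_lehmann(x, y) -> float:
    """Median of all pairwise differences x_i - y_j."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return float(np.median((x[:, None] - y[None, :]).ravel()))


def hodges_lehmann_ci(x, y, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Moses) distribution-based CI for the location shift x - y.

    With D the sorted pairwise differences and k the largest integer such
    that P(U <= k - 1) <= alpha/2 under the exact U null, the interval is
    (D_(k+1-1 index), D_(mn-k)) in 0-based terms — achieved coverage at
    least 1 - alpha.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    m, n = x.size, y.size
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    N = m * n
    counts = _u_counts(m, n)
    cdf = np.cumsum(counts) / comb(m + n, m)
    # largest k with P(U <= k-1) <= alpha/2
    k = int(np.searchsorted(cdf, alpha / 2.0, side="right"))
    if k <= 0:
        return float(diffs[0]), float(diffs[-1])
    return float(diffs[k - 1]), float(diffs[N - k])


def effect_size(diff: float, sd: float) -> tuple[float, bool]:
    """Cohen's d = |diff| / sd; flagged large when d > 0.8."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    d = abs(diff) / sd
    return d, d > 0.8


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonRow:
    """One region x metric comparison between OA and normal groups."""

    region: str = ""
    metric: str = ""
    central_oa: float = float("nan")  # mean (t-test) or median (Mann-Whitney)
    sd_oa: float = float("nan")
    central_normal: float = float("nan")
    sd_normal: float = float("nan")
    mean_all: float = float("nan")
    sd_all: float = float("nan")
    difference_absolute: float = float("nan")
    difference_percent: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    cohens_d: float = float("nan")
    sign: int = 0
    test_used: str = "t"
    distribution_flag: str = "normal"
    large_effect: bool = False


def compare_groups(
    oa_values,
    normal_values,
    region: str = "",
    metric: str = "",
    sd_choice: str = "all_scans",
    all_scans_sd: float | None = None,
    alpha: float = 0.05,
) -> ComparisonRow:
    """OA-vs-normal comparison with the normality gate.

    Both samples passing the gate -> classic pooled-variance unpaired t-test,
    mean difference and t-based CI.  Otherwise -> exact Mann-Whitney U with
    Hodges-Lehmann estimate and its exact CI; medians reported as the central
    values.  Percent difference is relative to the normal group's central
    value; Cohen's d uses the all-scans SD by default (pooled-group SD via
    ``sd_choice='pooled'``).
    """
    x = np.asarray(oa_values, float)
    y = np.asarray(normal_values, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    allv = np.concatenate([x, y])
    tied = np.ptp(allv) == 0

    # the skewness/kurtosis Z gate needs n >= 4 per sample; smaller groups
    # default to the parametric branch
    flag = "normal"
    if not tied and x.size >= 4 and y.size >= 4:
        if normality_gate(x) == "non_normal" or normality_gate(y) == "non_normal":
            flag = "non_normal"

    mean_all = float(allv.mean())
    sd_all = float(allv.std(ddof=1)) if all_scans_sd is None else float(all_scans_sd)
    sd_x, sd_y = float(x.std(ddof=1)), float(y.std(ddof=1))
    mean_diff = float(x.mean() - y.mean())

    if tied:
        row = ComparisonRow(
            region=region, metric=metric,
            central_oa=float(x.mean()), sd_oa=sd_x,
            central_normal=float(y.mean()), sd_normal=sd_y,
            mean_all=mean_all, sd_all=sd_all,
            difference_absolute=0.0, difference_percent=0.0,
            ci_low=0.0, ci_high=0.0, p_value=1.0,
            cohens_d=0.0, sign=0, test_used="t", distribution_flag="normal",
        )
        return row

    if flag == "normal":
        m, n = x.size, y.size
        df = m + n - 2
        sp2 = ((m - 1) * x.var(ddof=1) + (n - 1) * y.var(ddof=1)) / df
        se = sqrt(sp2 * (1.0 / m + 1.0 / n))
        if se == 0:
            p, tcrit = 1.0, 0.0
        else:
            t = mean_diff / se
            p = float(2 * sps.t.sf(abs(t), df))
            tcrit = float(sps.t.ppf(1 - alpha / 2, df))
        diff = mean_diff
        ci = (diff - tcrit * se, diff + tcrit * se)
        central_x, central_y = float(x.mean()), float(y.mean())
        test = "t"
    else:
        _, p = mann_whitney_exact(x, y)
        diff = hodges_lehmann(x, y)
        ci = hodges_lehmann_ci(x, y, alpha=alpha)
        central_x, central_y = float(np.median(x)), float(np.median(y))
        test = "mann_whitney"

    denom = abs(central_y)
    pct = float("nan") if denom == 0 else 100.0 * diff / denom
    if sd_choice == "all_scans":
        sd_for_d = sd_all
    elif sd_choice == "pooled":
        m, n = x.size, y.size
        sd_for_d = sqrt(((m - 1) * x.var(ddof=1) + (n - 1) * y.var(ddof=1)) / (m + n - 2))
    else:
        raise ValueError("sd_choice must be 'all_scans' or 'pooled'")
    d, large = effect_size(mean_diff, sd_for_d) if sd_for_d > 0 else (0.0, False)

    return ComparisonRow(
        region=region, metric=metric,
        central_oa=central_x, sd_oa=sd_x,
        central_normal=central_y, sd_normal=sd_y,
        mean_all=mean_all, sd_all=sd_all,
        difference_absolute=float(diff), difference_percent=pct,
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_value=float(min(1.0, p)),
        cohens_d=float(d), sign=int(np.sign(diff)),
        test_used=test, distribution_flag=flag, large_effect=large,
    )
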