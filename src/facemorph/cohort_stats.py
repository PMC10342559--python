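"""Two-group cohort statistics, paired validation, and power/sample size.

``summarize`` produces the familiar table layout — per measurement the two
group means, standard deviations (n−1 denominator) and a two-sided p-value.
The default test is Welch's t; the Mann-Whitney U test is selectable (with
the exact null for small tie-free samples, normal approximation with tie
correction otherwise).  No multiple-testing correction is applied: each
measurement is judged at p < 0.05 on its own, and the output names the test
used so the provenance of every p-value is explicit.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.power import TTestIndPower

from .measurements import ALL_FIELDS, records_to_frame

#: largest per-group n for which the exact rank-test null is used
EXACT_N_MAX = 12


def _clean(x) -> np.ndarray:
    x = np.asarray(x, float)
    return x[~np.isnan(x)]


def _two_sample_p(a: np.ndarray, b: np.ndarray, test: str) -> float:
    if test == "welch_t":
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    if test == "mann_whitney":
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        method = "exact" if (max(len(a), len(b)) <= EXACT_N_MAX and no_ties) else "asymptotic"
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)
    raise ValueError(f"unknown test: {test!r}")


def summarize(
    group_a,
    group_b,
    test: str = "welch_t",
    fields=None,
    group_names: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Group means/SDs and two-sided p-values for two cohorts of records.

    ``group_a``/``group_b`` are lists of MeasurementRecords or DataFrames
    with measurement columns.  Measurements with fewer than two non-missing
    values in either group get a missing (NaN) p-value; all-missing
    measurements are reported with NaN throughout.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    fa = group_a if isinstance(group_a, pd.DataFrame) else records_to_frame(group_a)
    fb = group_b if isinstance(group_b, pd.DataFrame) else records_to_frame(group_b)
    if fields is None:
        fields = [f for f in ALL_FIELDS if f in fa.columns]
    na, nb = group_names
    rows = []
    for f in fields:
        a, b = _clean(fa[f]), _clean(fb[f])
        row = {
            "measurement": f,
            f"{na}_mean": a.mean() if a.size else np.nan,
            f"{na}_sd": a.std(ddof=1) if a.size > 1 else np.nan,
            f"{nb}_mean": b.mean() if b.size else np.nan,
            f"{nb}_sd": b.std(ddof=1) if b.size > 1 else np.nan,
            f"n_{na}": a.size,
            f"n_{nb}": b.size,
            "p_value": _two_sample_p(a, b, test) if (a.size >= 2 and b.size >= 2) else np.nan,
            "test_name": test,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def paired_validation(a, b) -> tuple[float, float, float | None]:
    """Agreement between two length series (e.g. photo-derived vs. ruler).

    Returns ``(mean_abs_diff, sd_abs_diff, p)`` in the input units, with the
    two-sided Wilcoxon signed-rank p-value on the signed differences.  With
    all differences zero the p-value is undefined and returned as ``None``.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired series must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    mean_abs = float(np.mean(np.abs(diff)))
    sd_abs = float(np.std(np.abs(diff), ddof=1))
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return mean_abs, sd_abs, None
    no_ties = len(np.unique(np.abs(nonzero))) == len(nonzero)
    method = "exact" if (nonzero.size <= EXACT_N_MAX and no_ties) else "approx"
    p = float(stats.wilcoxon(diff, alternative="two-sided", method=method,
                             correction=(method == "approx")).pvalue)
    return mean_abs, sd_abs, p


def sample_size_two_means(
    mean1: float,
    sd1: float,
    mean2: float,
    sd2: float,
    power: float = 0.95,
    alpha: float = 0.05,
) -> int:
    """Smallest even total n giving the target power for a two-sided t-test.

    Effect size is Cohen's d with the pooled SD ``sqrt((sd1² + sd2²)/2)``
    (equal group sizes); the per-group n solved by the noncentral-t power
    function is rounded up and doubled.
    """
    if not (sd1 > 0 and sd2 > 0):
        raise ValueError("standard deviations must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    d = abs(mean1 - mean2) / math.sqrt(0.5 * (sd1**2 + sd2**2))
    if d == 0:
        raise ValueError("zero effect size: required sample size is unbounded")
    n_per = TTestIndPower().solve_power(
        effect_size=d, alpha=alpha, power=power, ratio=1.0, alternative="two-sided"
    )
    return 2 * math.ceil(n_per)
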