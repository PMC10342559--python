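"""Group statistics against exhaustive-enumeration oracles, plus power helper."""

import numpy as np
import pytest
from scipy import stats

from facemorph.cohort_stats import (
    paired_validation,
    sample_size_two_means,
    summarize,
)
from facemorph.measurements import MeasurementRecord

from util import brute_force_total_n, exact_mann_whitney_p, exact_wilcoxon_p


def _records(values, field="facial_height"):
    return [MeasurementRecord(**{field: v}) for v in values]


def test_identical_samples_mann_whitney_p_is_one():
    table = summarize(_records([1.0, 2.0, 3.0]), _records([1.0, 2.0, 3.0]),
                      test="mann_whitney", fields=["facial_height"])
    assert table.loc[0, "p_value"] == pytest.approx(1.0)
    assert table.loc[0, "a_mean"] == table.loc[0, "b_mean"]


def test_small_sample_exact_permutation_value():
    # {1,2} vs {4,5}: the observed separation is the most extreme of C(4,2)=6
    # assignments in either direction -> two-sided exact p = 2/6
    table = summarize(_records([1.0, 2.0]), _records([4.0, 5.0]),
                      test="mann_whitney", fields=["facial_height"])
    assert table.loc[0, "p_value"] == pytest.approx(1 / 3)
    assert exact_mann_whitney_p([1, 2], [4, 5]) == pytest.approx(1 / 3)


@pytest.mark.parametrize("seed", [1, 2, 3, 4])
def test_mann_whitney_matches_enumeration_for_small_n(seed):
    rng = np.random.default_rng(seed)
    n, m = rng.integers(3, 9), rng.integers(3, 9)
    pool = rng.permutation(100)[: n + m].astype(float)  # tie-free
    x, y = pool[:n], pool[n:]
    p_impl = summarize(_records(x), _records(y), test="mann_whitney",
                       fields=["facial_height"]).loc[0, "p_value"]
    assert p_impl == pytest.approx(exact_mann_whitney_p(x, y), abs=1e-12)


@pytest.mark.parametrize("seed", [5, 6, 7])
def test_wilcoxon_matches_enumeration_for_small_n(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    # mixed signs with distinct absolute values (the exact-null regime)
    diff = rng.permutation(np.arange(1.0, 51.0))[:n] * rng.choice([-1.0, 1.0], n)
    a = np.abs(rng.normal(50, 5, n)) + diff
    b = a - diff
    _, _, p = paired_validation(a, b)
    assert p == pytest.approx(exact_wilcoxon_p(diff), abs=1e-12)


def test_welch_equals_pooled_for_equal_variance_equal_n():
    rng = np.random.default_rng(8)
    x = rng.normal(0, 1, 15)
    y = x + 0.8  # identical sample variance, equal n
    p_welch = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    p_pooled = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
    assert p_welch == pytest.approx(p_pooled, abs=1e-6)


def test_summarize_is_symmetric_in_groups():
    a, b = _records([1.0, 2.0, 5.0]), _records([2.0, 4.0, 9.0, 3.0])
    t1 = summarize(a, b, fields=["facial_height"])
    t2 = summarize(b, a, fields=["facial_height"])
    assert t1.loc[0, "p_value"] == pytest.approx(t2.loc[0, "p_value"])
    assert t1.loc[0, "a_mean"] == t2.loc[0, "b_mean"]
    assert t1.loc[0, "n_a"] == t2.loc[0, "n_b"]


def test_summarize_missing_data_handling():
    a = _records([1.0, 2.0, 3.0])
    b = [MeasurementRecord(facial_height=2.0), MeasurementRecord()]
    table = summarize(a, b, fields=["facial_height", "alar_width"])
    fh = table.set_index("measurement").loc["facial_height"]
    assert fh["n_b"] == 1 and np.isnan(fh["p_value"])
    aw = table.set_index("measurement").loc["alar_width"]
    assert np.isnan(aw["a_mean"]) and np.isnan(aw["p_value"])
    with pytest.raises(ValueError):
        summarize([], a)


def test_paired_validation_identity_and_shift():
    a = np.array([10.0, 11.0, 12.0, 13.0, 14.0, 15.0])
    mean_abs, sd_abs, p = paired_validation(a, a)
    assert mean_abs == 0.0 and p is None
    mean_abs, sd_abs, p = paired_validation(a + 1.0, a)
    assert mean_abs == pytest.approx(1.0)
    assert sd_abs == pytest.approx(0.0)
    assert p is not None and p < 0.1  # consistent positive shift

    with pytest.raises(ValueError):
        paired_validation(a, a[:-1])


def test_sample_size_matches_noncentral_t_enumeration():
    # reported bony mandibular widths: 9.35 +- 0.57 vs 8.70 +- 0.56 cm
    n = sample_size_two_means(9.35, 0.57, 8.70, 0.56, power=0.95, alpha=0.05)
    d = 0.65 / np.sqrt(0.5 * (0.57**2 + 0.56**2))
    assert n == brute_force_total_n(d, 0.95, 0.05)
    n80 = sample_size_two_means(9.35, 0.57, 8.70, 0.56, power=0.80, alpha=0.05)
    assert n80 == brute_force_total_n(d, 0.80, 0.05)
    assert n80 < n


def test_sample_size_monotone_and_degenerate():
    small = sample_size_two_means(10.0, 1.0, 9.0, 1.0)
    large = sample_size_two_means(10.0, 2.0, 9.0, 2.0)
    assert large > small
    with pytest.raises(ValueError):
        sample_size_two_means(10.0, 1.0, 10.0, 1.0)
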