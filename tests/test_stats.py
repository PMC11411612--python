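"""Summary statistics, correlations, Tukey-Kramer HSD and trend binning."""

import numpy as np
import pandas as pd
import pytest

from drugspace import (
    pearson_r2,
    correlation_matrix,
    subset_compare,
    summarise,
    summary_table,
    temporal_trend,
    tukey_kramer_hsd,
)

# Frozen small-sample groups (drawn once from seeded normals) used for the
# permutation cross-check of the studentized-range p-values.
PERM_G1 = [0.001, 0.299, -0.274, -0.891, -0.455, -0.992, 0.06, 1.34]
PERM_G2 = [0.308, 0.18, 1.29, 1.157, 0.905, -0.13, 0.771, 1.495, -0.544, 0.342]
PERM_G3 = [-1.601, -0.99, -1.542, 0.065, -0.967, 0.571]


def test_summarise_constant_vector():
    s = summarise([7.0, 7.0, 7.0])
    assert (s["mean"], s["std"], s["n"]) == (7.0, 0.0, 3)
    assert s["p50"] == s["p75"] == s["p90"] == 7.0


def _quantile_oracle(values, p, method):
    v = sorted(values)
    n = len(v)
    if method == "weibull":
        pos = (n + 1) * p / 100.0
    else:  # linear
        pos = 1 + (n - 1) * p / 100.0
    lo = int(np.floor(pos))
    frac = pos - lo
    if lo < 1:
        return v[0]
    if lo >= n:
        return v[-1]
    return v[lo - 1] + frac * (v[lo] - v[lo - 1])


@pytest.mark.parametrize("method", ["weibull", "linear"])
def test_summarise_percentiles_match_sort_based_oracle(method):
    values = np.arange(1.0, 101.0)
    s = summarise(values, method=method)
    for p in (50, 75, 90):
        assert s[f"p{p}"] == pytest.approx(_quantile_oracle(values, p, method))


def test_summarise_is_permutation_invariant():
    rng = np.random.default_rng(2)
    v = rng.normal(size=51)
    assert summarise(v) == pytest.approx(summarise(rng.permutation(v)), rel=1e-12)
    with pytest.raises(ValueError):
        summarise([])


def test_summary_table_shape(library_profile):
    tbl = summary_table(library_profile, ("mwt", "clogp", "hbd", "hba"))
    assert list(tbl.index) == ["mwt", "clogp", "hbd", "hba"]
    assert (tbl["p50"] <= tbl["p75"]).all() and (tbl["p75"] <= tbl["p90"]).all()
    assert (tbl["n"] == len(library_profile)).all()


def test_pearson_r2():
    x = np.arange(10.0)
    assert pearson_r2(x, 2 * x + 1) == pytest.approx(1.0)
    rng = np.random.default_rng(4)
    a, b = rng.normal(size=10_000), rng.normal(size=10_000)
    assert pearson_r2(a, b) < 0.01
    with pytest.raises(ValueError, match="zero-variance"):
        pearson_r2(x, np.ones(10))


def test_correlation_matrix_symmetric(library_profile):
    m = correlation_matrix(library_profile, ("mwt", "clogp", "hba"))
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 1.0)
    assert ((m.values >= 0) & (m.values <= 1)).all()


def test_hsd_identical_groups_not_significant():
    g = np.arange(20.0)
    res = tukey_kramer_hsd({"a": g, "b": g.copy()})
    assert not res.comparisons["significant"].any()
    assert (res.comparisons["p_adj"] > 0.9).all()


def test_hsd_large_effect_detected():
    rng = np.random.default_rng(9)
    res = tukey_kramer_hsd(
        {"lo": rng.normal(0, 1, 50), "hi": rng.normal(10, 1, 50)}
    )
    assert res.comparisons["significant"].all()
    assert (res.comparisons["p_adj"] < 1e-6).all()


def test_hsd_matches_statsmodels_on_unequal_groups():
    """Kramer-adjusted q/p agree with an independent implementation."""
    sm = pytest.importorskip("statsmodels.stats.multicomp")
    groups = {"a": PERM_G1, "b": PERM_G2, "c": PERM_G3}
    res = tukey_kramer_hsd(groups)
    data = np.concatenate([PERM_G1, PERM_G2, PERM_G3])
    labels = ["a"] * 8 + ["b"] * 10 + ["c"] * 6
    ref = sm.pairwise_tukeyhsd(data, labels)
    assert np.allclose(res.comparisons["p_adj"], ref.pvalues, atol=1e-6)
    assert list(res.comparisons["significant"]) == list(ref.reject)


def test_hsd_matches_permutation_oracle():
    """The smallest adjusted p-value agrees with a permutation null of the
    maximum studentized range statistic."""
    res = tukey_kramer_hsd({"a": PERM_G1, "b": PERM_G2, "c": PERM_G3})
    observed_qmax = res.comparisons["q"].max()
    sizes = [8, 10, 6]
    values = np.concatenate([PERM_G1, PERM_G2, PERM_G3])
    splits = np.cumsum(sizes)[:-1]

    def qmax(v):
        gs = np.split(v, splits)
        df = len(v) - len(gs)
        mse = sum(((g - g.mean()) ** 2).sum() for g in gs) / df
        best = 0.0
        for i in range(len(gs)):
            for j in range(i + 1, len(gs)):
                se = np.sqrt(mse / 2 * (1 / sizes[i] + 1 / sizes[j]))
                best = max(best, abs(gs[i].mean() - gs[j].mean()) / se)
        return best

    rng = np.random.default_rng(123)
    v = values.copy()
    exceed = 0
    n_perm = 20_000
    for _ in range(n_perm):
        rng.shuffle(v)
        if qmax(v) >= observed_qmax:
            exceed += 1
    p_perm = exceed / n_perm
    p_model = res.comparisons["p_adj"].min()
    assert abs(p_perm - p_model) < 0.02
    assert (p_perm < 0.05) == (p_model < 0.05)


def test_hsd_zero_variance_groups_do_not_crash():
    res = tukey_kramer_hsd({"a": [1.0, 1.0], "b": [2.0, 2.0]})
    assert res.pooled_variance == 0.0
    assert res.comparisons["significant"].all()
    res2 = tukey_kramer_hsd({"a": [1.0, 1.0], "b": [1.0, 1.0]})
    assert not res2.comparisons["significant"].any()


def test_hsd_requires_two_groups_of_two():
    with pytest.raises(ValueError):
        tukey_kramer_hsd({"a": [1.0, 2.0]})
    with pytest.raises(ValueError):
        tukey_kramer_hsd({"a": [1.0, 2.0], "b": [3.0]})


def _trend_frame():
    rows = []
    planted = {(2000, 2009): (50, 6), (2010, 2019): (80, 16), (2020, 2022): (30, 5)}
    rng = np.random.default_rng(1)
    for (lo, hi), (n, fails) in planted.items():
        for i in range(n):
            rows.append(
                {
                    "approval_year": int(rng.integers(lo, hi + 1)),
                    "lipinski_fail": i < fails,
                    "mwt": 400.0 + i,
                    "clogp": 3.0,
                    "hbd": 2,
                    "hba": 6,
                }
            )
    return pd.DataFrame(rows), planted


def test_temporal_trend_recovers_planted_counts():
    df, planted = _trend_frame()
    trend = temporal_trend(df)
    assert trend["n"].tolist() == [50, 80, 30]
    assert trend["n_fails"].tolist() == [6, 16, 5]
    assert trend["fail_pct"].tolist() == pytest.approx([12.0, 20.0, 50 / 3])
    assert trend["n"].sum() == len(df)


def test_temporal_trend_counts_conserved_under_rebinning():
    df, _ = _trend_frame()
    fine = temporal_trend(df)
    merged = temporal_trend(df, bins=((2000, 2009), (2010, 2022)))
    assert merged["n"].iloc[1] == fine["n"].iloc[1] + fine["n"].iloc[2]
    assert merged["n_fails"].iloc[1] == fine["n_fails"].iloc[1] + fine["n_fails"].iloc[2]


def test_temporal_trend_rejects_uncovered_years():
    df, _ = _trend_frame()
    df.loc[0, "approval_year"] = 1995
    with pytest.raises(ValueError, match="1995"):
        temporal_trend(df)


def test_subset_compare_pass_fail(library_profile):
    ok = library_profile[~library_profile.descriptor_failure]
    summaries, comparison = subset_compare(
        ok, ok["lipinski_fail"].astype(bool).to_numpy(), "mwt"
    )
    assert set(summaries.index) == {"True", "False"}
    # planted fails are constructed to be much heavier
    assert summaries.loc["True", "mean"] > summaries.loc["False", "mean"] + 100
    assert comparison.comparisons["significant"].all()


def test_subset_compare_warns_on_tiny_subset(library_profile):
    ok = library_profile[~library_profile.descriptor_failure].iloc[:10]
    labels = np.array(["big"] * 9 + ["tiny"])
    with pytest.warns(UserWarning, match="tiny"):
        summaries, comparison = subset_compare(ok, labels, "mwt")
    assert comparison is None
    assert "tiny" in summaries.index


def test_subset_compare_null_labels_control_type_i_error():
    """Random coin-flip partitions reject at about the nominal 5% rate."""
    rng = np.random.default_rng(31)
    data = pd.DataFrame({"mwt": rng.normal(400, 100, 120)})
    rejections = 0
    n_rep = 100
    for _ in range(n_rep):
        labels = rng.integers(0, 2, size=len(data))
        if labels.sum() < 2 or labels.sum() > len(data) - 2:
            continue
        _, comp = subset_compare(data, labels, "mwt")
        rejections += bool(comp.comparisons["significant"].any())
    # 3 Monte-Carlo standard deviations above the nominal level
    assert rejections / n_rep <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)
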