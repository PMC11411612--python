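"""Summary tables, correlations, Tukey–Kramer comparisons and trends.

The summary layer reports mean, sample standard deviation (n-1
denominator) and 50/75/90th percentiles per descriptor.  Percentiles
default to the (n+1)-based empirical quantile rule (numpy's ``weibull``
method), matching the convention of common statistics desktops; the
interpolation variant is available via ``method="linear"``.

All-pairs group comparisons use the Tukey–Kramer honestly-significant-
difference test: for groups i, j with means m_i, sizes n_i and pooled
within-group variance s^2 on df = N - k degrees of freedom,

    q_ij = |m_i - m_j| / sqrt( (s^2 / 2) (1/n_i + 1/n_j) )

is referred to the studentized-range distribution with k groups and df
degrees of freedom.  The Kramer standard error makes the test valid for
unequal group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_PERIOD_BINS = ((2000, 2009), (2010, 2019), (2020, 2022))
DEFAULT_QUANTILE_METHOD = "weibull"


def summarise(
    values,
    percentiles: tuple[float, ...] = (50, 75, 90),
    method: str = DEFAULT_QUANTILE_METHOD,
) -> dict:
    """One summary row: mean, SD (ddof=1), requested percentiles and n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    out = {
        "mean": float(v.mean()),
        "std": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "n": int(v.size),
    }
    for p in percentiles:
        out[f"p{p:g}"] = float(np.percentile(v, p, method=method))
    return out


def summary_table(
    df: pd.DataFrame,
    descriptors: tuple[str, ...] = ("mwt", "clogp", "hbd", "hba"),
    method: str = DEFAULT_QUANTILE_METHOD,
) -> pd.DataFrame:
    """Summary rows for several descriptor columns of a profile table."""
    return pd.DataFrame(
        {d: summarise(df[d].to_numpy(), method=method) for d in descriptors}
    ).T


def pearson_r2(x, y) -> float:
    """Squared Pearson correlation; errors on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)


def correlation_matrix(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Pairwise r^2 matrix over descriptor columns."""
    cols = list(columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for a, b in combinations(cols, 2):
        r2 = pearson_r2(df[a].to_numpy(), df[b].to_numpy())
        out.loc[a, b] = out.loc[b, a] = r2
    return out


@dataclass
class GroupComparison:
    """All-pairs Tukey–Kramer result for labelled numeric samples."""

    groups: list[str]
    means: dict[str, float]
    sizes: dict[str, int]
    pooled_variance: float
    df_error: int
    alpha: float
    comparisons: pd.DataFrame = field(repr=False)  # type: ignore[assignment]

    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.comparisons[self.comparisons["significant"]]
        return list(zip(sig["group1"], sig["group2"]))


@lru_cache(maxsize=256)
def _q_critical(alpha: float, k: int, df: int) -> float:
    """Studentized-range critical value (cached: the ppf is expensive)."""
    return float(sps.studentized_range.ppf(1 - alpha, k, df))


def tukey_kramer_hsd(
    groups: dict[str, np.ndarray],
    alpha: float = 0.05,
    compute_pvalues: bool = True,
) -> GroupComparison:
    """Tukey–Kramer HSD over >= 2 labelled groups (each n >= 2).

    Adjusted p-values come from the studentized-range survival function;
    with ``compute_pvalues=False`` only the q statistics and significance
    flags (against the alpha critical value) are produced, which is much
    faster in simulation loops.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(v.size < 2 for v in data.values()):
        raise ValueError("every group needs n >= 2")

    k = len(labels)
    sizes = {g: int(v.size) for g, v in data.items()}
    means = {g: float(v.mean()) for g, v in data.items()}
    n_total = sum(sizes.values())
    df_error = n_total - k
    sse = sum(float(((v - v.mean()) ** 2).sum()) for v in data.values())
    ms_error = sse / df_error

    q_crit = _q_critical(alpha, k, df_error)
    rows = []
    for g1, g2 in combinations(labels, 2):
        diff = means[g1] - means[g2]
        se = np.sqrt(ms_error / 2 * (1 / sizes[g1] + 1 / sizes[g2]))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_error)) if compute_pvalues else np.nan
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "mean_diff": diff,
                "se": se,
                "q": q,
                "p_adj": min(max(p, 0.0), 1.0) if compute_pvalues else np.nan,
                "significant": bool(q > q_crit),
            }
        )
    return GroupComparison(
        groups=labels,
        means=means,
        sizes=sizes,
        pooled_variance=ms_error,
        df_error=df_error,
        alpha=alpha,
        comparisons=pd.DataFrame(rows),
    )


def temporal_trend(
    df: pd.DataFrame,
    bins: tuple[tuple[int, int], ...] = DEFAULT_PERIOD_BINS,
    descriptors: tuple[str, ...] = ("mwt", "clogp", "hbd", "hba"),
    year_column: str = "approval_year",
    fail_column: str = "lipinski_fail",
) -> pd.DataFrame:
    """Approval counts, Lipinski-fail counts/rates and descriptor means per period."""
    years = df[year_column].to_numpy()
    covered = np.zeros(len(df), dtype=bool)
    rows = []
    for lo, hi in bins:
        mask = (years >= lo) & (years <= hi)
        covered |= mask
        sub = df[mask]
        n = int(mask.sum())
        n_fail = int(sub[fail_column].sum()) if n else 0
        row = {
            "period": f"{lo}-{hi}",
            "n": n,
            "n_fails": n_fail,
            "fail_pct": 100.0 * n_fail / n if n else np.nan,
        }
        for d in descriptors:
            row[f"{d}_mean"] = float(sub[d].mean()) if n else np.nan
        rows.append(row)
    if not covered.all():
        offenders = sorted(set(years[~covered].tolist()))
        raise ValueError(f"approval years outside all bins: {offenders}")
    return pd.DataFrame(rows)


def subset_compare(
    df: pd.DataFrame,
    labels,
    descriptor: str,
    alpha: float = 0.05,
    method: str = DEFAULT_QUANTILE_METHOD,
) -> tuple[pd.DataFrame, GroupComparison | None]:
    """Per-subset summaries plus an HSD comparison on one descriptor.

    ``labels`` is an array-like aligned with ``df`` (e.g. pass/fail,
    macrocycle/non, ionisation class).  Subsets with n < 2 are summarised
    but excluded from the HSD test with a warning.
    """
    labels = np.asarray(labels)
    if len(labels) != len(df):
        raise ValueError("labels must align with the table")
    values = df[descriptor].to_numpy(dtype=float)
    summaries = {}
    groups = {}
    for lab in pd.unique(labels):
        v = values[labels == lab]
        summaries[str(lab)] = summarise(v, method=method)
        if v.size >= 2:
            groups[str(lab)] = v
        else:
            warnings.warn(
                f"subset {lab!r} has n={v.size} < 2; excluded from HSD",
                stacklevel=2,
            )
    comparison = tukey_kramer_hsd(groups, alpha=alpha) if len(groups) >= 2 else None
    return pd.DataFrame(summaries).T, comparison
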