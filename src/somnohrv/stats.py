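"""Two-group comparison with a normality-gated test choice.

Per-animal metrics are compared between two groups with the classical
small-cohort recipe: Shapiro–Wilk normality check per group; if both groups
look normal (p > alpha) an equal-variance (pooled) Student's t-test,
otherwise a two-tailed Mann–Whitney U test (exact for small n).  Summaries
are mean +- sample SD.  A pooled t-test recomputable from printed
mean/SD/n summaries is provided for checking published tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import DataError, ValidationError

NORMALITY_ALPHA = 0.05
EXACT_MW_MAX_N = 8


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float  # sample SD (n-1 denominator)


@dataclass
class ComparisonResult:
    variable: str
    group_a: GroupSummary
    group_b: GroupSummary
    test: str  # "pooled_t" | "mann_whitney"
    statistic: float
    p: float  # two-tailed
    normality_p: Tuple[float, float]


def normality_check(values: Sequence[float]) -> Tuple[float, float]:
    """Shapiro–Wilk statistic and p-value; errors on constant input."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or len(x) > 5000:
        raise ValidationError("Shapiro–Wilk needs 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DataError("normality check undefined for constant input")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def pooled_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> Tuple[float, int, float]:
    """Equal-variance two-sample t from summary statistics.

    sp^2 = ((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2);
    t = (mean2 - mean1) / (sp sqrt(1/n1 + 1/n2)); df = n1+n2-2;
    two-tailed p.  Lets published mean +- SD tables be re-checked directly.
    """
    if n1 < 2 or n2 < 2:
        raise ValidationError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValidationError("SDs must be non-negative")
    if sd1 == 0 and sd2 == 0:
        if mean1 == mean2:
            return 0.0, n1 + n2 - 2, 1.0
        return float(np.inf) * np.sign(mean2 - mean1), n1 + n2 - 2, 0.0
    t, p = sps.ttest_ind_from_stats(
        mean2, sd2, n2, mean1, sd1, n1, equal_var=True
    )
    return float(t), n1 + n2 - 2, float(p)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    variable: str = "",
    labels: Tuple[str, str] = ("a", "b"),
    policy: str = "auto",
    alpha: float = NORMALITY_ALPHA,
) -> ComparisonResult:
    """Two-tailed two-group comparison with the normality-gated test choice.

    ``policy``: 'auto' (gate on Shapiro–Wilk per group), 'pooled_t', or
    'mann_whitney'.  Identical constant groups compare equal with p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise DataError("empty group")
    if policy not in ("auto", "pooled_t", "mann_whitney"):
        raise ValidationError(f"unknown policy {policy!r}")

    norm_p = (np.nan, np.nan)
    test = policy
    if policy == "auto":
        if min(len(a), len(b)) < 3:
            raise ValidationError("auto policy needs n >= 3 per group")
        try:
            pa = normality_check(a)[1]
            pb = normality_check(b)[1]
            norm_p = (pa, pb)
            test = "pooled_t" if (pa > alpha and pb > alpha) else "mann_whitney"
        except DataError:
            # constant group: Shapiro undefined; fall back to rank test
            test = "mann_whitney"

    if test == "pooled_t":
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            stat, p = (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
        else:
            stat, p = sps.ttest_ind(b, a, equal_var=True)
    else:
        if np.array_equal(np.sort(a), np.sort(b)):
            stat, p = float(len(a) * len(b) / 2.0), 1.0
        else:
            pooled = np.concatenate([a, b])
            has_ties = len(np.unique(pooled)) < len(pooled)
            # exact null distribution for small samples; with ties or larger
            # n, the normal approximation with tie correction
            method = (
                "exact"
                if max(len(a), len(b)) <= EXACT_MW_MAX_N and not has_ties
                else "asymptotic"
            )
            res = sps.mannwhitneyu(b, a, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)

    return ComparisonResult(
        variable=variable,
        group_a=GroupSummary(labels[0], len(a), float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0),
        group_b=GroupSummary(labels[1], len(b), float(b.mean()), float(b.std(ddof=1)) if len(b) > 1 else 0.0),
        test=test,
        statistic=float(stat),
        p=min(max(float(p), 0.0), 1.0),
        normality_p=norm_p,
    )


def build_report(
    per_animal_metrics: pd.DataFrame,
    group_col: str = "group",
    groups: Optional[Tuple[str, str]] = None,
    policy: str = "auto",
    alpha: float = NORMALITY_ALPHA,
) -> pd.DataFrame:
    """Row-per-metric comparison table from long-format per-animal metrics.

    Input columns: animal_id, group, metric, value (optionally config_hash;
    mixing rows from different config hashes is rejected).  Each row reports
    mean +- SD and n per group, the chosen test, and the two-tailed p
    (also rounded to 3 decimals, the precision used in print).
    Rows are computed on the animals that have the metric.
    """
    required = {"animal_id", group_col, "metric", "value"}
    missing = required - set(per_animal_metrics.columns)
    if missing:
        raise ValidationError(f"metrics table missing columns: {sorted(missing)}")
    if "config_hash" in per_animal_metrics.columns:
        hashes = per_animal_metrics["config_hash"].dropna().unique()
        if len(hashes) > 1:
            raise DataError(
                f"metrics mix different analysis configurations: {list(hashes)}"
            )
    if groups is None:
        found = tuple(pd.unique(per_animal_metrics[group_col]))
        if len(found) != 2:
            raise ValidationError(f"need exactly 2 groups, found {found}")
        groups = found  # type: ignore[assignment]

    rows = []
    for metric, sub in per_animal_metrics.groupby("metric", sort=False):
        va = sub.loc[sub[group_col] == groups[0], "value"].dropna().to_numpy()
        vb = sub.loc[sub[group_col] == groups[1], "value"].dropna().to_numpy()
        if len(va) < 2 or len(vb) < 2:
            raise DataError(f"metric {metric!r}: fewer than 2 animals per group")
        res = compare_groups(va, vb, variable=str(metric), labels=groups,
                             policy=policy, alpha=alpha)
        rows.append(
            {
                "metric": metric,
                f"{groups[0]}_mean": res.group_a.mean,
                f"{groups[0]}_sd": res.group_a.sd,
                f"{groups[0]}_n": res.group_a.n,
                f"{groups[1]}_mean": res.group_b.mean,
                f"{groups[1]}_sd": res.group_b.sd,
                f"{groups[1]}_n": res.group_b.n,
                "test": res.test,
                "statistic": res.statistic,
                "p": res.p,
                "p_3dec": round(res.p, 3),
            }
        )
    return pd.DataFrame(rows)


def write_report_csv(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False, float_format="%.6g")
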