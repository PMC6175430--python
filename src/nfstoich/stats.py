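"""Cohort statistics: nonparametric tests, one-way GLM and Bonferroni post hocs.

The analysis pipeline reports: Shapiro-Wilk normality screening; Welch t or
Mann-Whitney U for two groups; one-way fixed-effects ANOVA ("GLM", reported
as F with (k-1, N-k) df) together with Kruskal-Wallis H for more than two
groups; and pairwise post hoc contrasts that run only when the omnibus test
is significant, at a Bonferroni-corrected threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .calibration import ParticleProfile
from .constants import ISOFORMS

PROGRESSION_CATEGORIES = ("slow", "intermediate", "fast")


@dataclass
class StatResult:
    test_name: str
    statistic: float
    df: tuple | int | None
    p_value: float
    groups: tuple
    alpha_corrected: float | None = None
    extra: dict | None = None

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected significance threshold alpha/m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


def format_p(p: float, decimals: int = 4) -> float:
    """Round a p-value for reports (round-half-even); thresholds stay exact."""
    return float(np.round(p, decimals))


def is_gaussian(x: Sequence[float], alpha: float = 0.05) -> bool:
    """Shapiro-Wilk screen at the given alpha (constant samples -> False)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return sps.shapiro(x).pvalue > alpha


def two_group_test(
    x: Sequence[float], y: Sequence[float], gaussian: bool | None = None
) -> StatResult:
    """Two-tailed two-group comparison: Welch t (gaussian) or Mann-Whitney U.

    ``gaussian=None`` decides via Shapiro-Wilk on both samples at alpha=0.05.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if gaussian is None:
        gaussian = is_gaussian(x) and is_gaussian(y)
    if gaussian:
        res = sps.ttest_ind(x, y, equal_var=False)
        return StatResult(
            test_name="welch_t",
            statistic=float(res.statistic),
            df=float(res.df),
            p_value=float(res.pvalue),
            groups=("x", "y"),
        )
    if np.ptp(np.concatenate([x, y])) == 0:
        # identical constant samples: no evidence of a difference
        return StatResult("mann_whitney_u", float(x.size * y.size / 2), None, 1.0,
                          ("x", "y"))
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return StatResult(
        test_name="mann_whitney_u",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        groups=("x", "y"),
    )


def multi_group_glm(
    values: Sequence[float],
    labels: Sequence,
    alpha: float = 0.05,
    posthoc_gaussian: bool | None = None,
) -> StatResult:
    """One-way fixed-effects ANOVA across groups, plus Kruskal-Wallis H.

    F is reported with (k-1, N-k) degrees of freedom.  Pairwise post hoc
    contrasts (at the Bonferroni-corrected threshold) are attached in
    ``extra["posthoc"]`` only when the omnibus ANOVA is significant at
    ``alpha`` — a non-significant omnibus test disqualifies all further
    comparisons.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [values[labels == g] for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("every group needs n >= 2")

    k = len(groups)
    n_total = values.size
    if all(np.ptp(s) == 0 for s in samples) and np.ptp(values) == 0:
        f_stat, f_p = 0.0, 1.0
        kw_stat, kw_p = 0.0, 1.0
    else:
        f_res = sps.f_oneway(*samples)
        f_stat, f_p = float(f_res.statistic), float(f_res.pvalue)
        kw_res = sps.kruskal(*samples)
        kw_stat, kw_p = float(kw_res.statistic), float(kw_res.pvalue)

    m = k * (k - 1) // 2
    posthoc = []
    if f_p < alpha:
        thr = bonferroni_threshold(alpha, m)
        for i in range(k):
            for j in range(i + 1, k):
                res = two_group_test(samples[i], samples[j],
                                     gaussian=posthoc_gaussian)
                posthoc.append(
                    {
                        "contrast": f"{groups[i]} vs {groups[j]}",
                        "test": res.test_name,
                        "statistic": res.statistic,
                        "p": res.p_value,
                        "alpha_corrected": thr,
                        "significant": bool(res.p_value < thr),
                    }
                )
    return StatResult(
        test_name="oneway_glm",
        statistic=f_stat,
        df=(k - 1, n_total - k),
        p_value=f_p,
        groups=tuple(groups),
        alpha_corrected=bonferroni_threshold(alpha, m) if m else None,
        extra={
            "kruskal_h": kw_stat,
            "kruskal_p": kw_p,
            "posthoc": posthoc,
        },
    )


def progression_association(
    profiles: Sequence[ParticleProfile],
    categories: Sequence[str],
    alpha: float = 0.05,
) -> dict:
    """Per-isoform GLM of calibrated counts across progression categories.

    ``categories`` gives the slow/intermediate/fast label of each profile.
    Contrasts for categories that are absent from the cohort are skipped with
    a warning; a single-category cohort is an error.
    """
    import warnings

    cats = np.asarray(categories)
    present = [c for c in PROGRESSION_CATEGORIES if np.any(cats == c)]
    if len(present) < 2:
        raise ValueError("need at least two progression categories")
    missing = [c for c in PROGRESSION_CATEGORIES if c not in present]
    if missing:
        warnings.warn(f"progression categories absent, contrasts skipped: {missing}")
    keep = np.isin(cats, present)
    results = {}
    for k, iso in enumerate(ISOFORMS):
        vals = np.array([p.as_array()[k] for p in profiles])[keep]
        results[iso] = multi_group_glm(vals, cats[keep], alpha=alpha)
    return results


def posthoc_table(result: StatResult) -> pd.DataFrame:
    """Post hoc contrasts of a multi_group_glm result as a tidy DataFrame."""
    rows = (result.extra or {}).get("posthoc", [])
    cols = ["contrast", "test", "statistic", "p", "alpha_corrected", "significant"]
    return pd.DataFrame(rows, columns=cols)


def stats_report(results: dict) -> dict:
    """JSON-serialisable report keyed by analysis name."""

    def encode(r: StatResult) -> dict:
        return {
            "test": r.test_name,
            "statistic": r.statistic,
            "df": list(r.df) if isinstance(r.df, tuple) else r.df,
            "p": format_p(r.p_value),
            "groups": list(r.groups),
            "alpha_corrected": r.alpha_corrected,
            "kruskal_h": (r.extra or {}).get("kruskal_h"),
            "kruskal_p": (r.extra or {}).get("kruskal_p"),
            "posthoc": (r.extra or {}).get("posthoc", []),
        }

    return {name: encode(r) for name, r in results.items()}
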