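"""Group-level inference: normality, mixed ANOVA, two-group tests.

Thin, contract-stable wrappers over scipy/statsmodels/pingouin.  Every
test is two-tailed.  The two-group path exposes both the Welch and the
pooled-variance t, and a summary-statistics entry point so printed
group tables (n, mean, sd) can be checked without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatTestResult",
    "shapiro_wilk",
    "mixed_anova",
    "holm_sidak",
    "two_group_t",
    "two_group_t_from_stats",
    "cohens_d",
    "cohens_d_from_stats",
    "mann_whitney_u",
    "auto_two_group_test",
]


@dataclass(frozen=True)
class StatTestResult:
    test: str
    statistic: float
    df: Optional[float]
    p: float
    effect_size: Optional[float] = None
    group_summaries: Optional[tuple[dict, dict]] = None


def _summary(x: np.ndarray) -> dict:
    return {"n": int(x.size), "mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1))}


def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation)."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample has no distribution shape")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: str = "state",
    between: str = "group",
    subject: str = "subject_id",
    correction: bool = False,
) -> pd.DataFrame:
    """Two-way mixed (split-plot) ANOVA: between-subject group, within-subject state.

    Requires every subject to contribute all within-factor levels and
    at least two subjects per group.  Returns the pingouin effect table
    (group, state, interaction rows with F, df, p).  Sphericity
    correction (Greenhouse-Geisser) is off by default and available via
    ``correction=True``.
    """
    import pingouin as pg

    counts = data.groupby([subject])[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced within factor: every subject needs all levels")
    if data.groupby(between)[subject].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")
    if np.ptp(data[dv].to_numpy(float)) == 0:
        # zero total variance: every effect is 0/0
        return pd.DataFrame(
            {"Source": [between, within, "Interaction"], "F": [np.nan] * 3,
             "p_unc": [np.nan] * 3, "note": ["degenerate: constant response"] * 3}
        )
    aov = pg.mixed_anova(
        data=data, dv=dv, within=within, between=between, subject=subject, correction=correction
    )
    return aov


def holm_sidak(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-down Holm-Sidak adjusted p-values and the rejection mask."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="holm-sidak")
    return adj, reject


def two_group_t(
    sample1: Sequence[float], sample2: Sequence[float], variant: str = "welch"
) -> StatTestResult:
    """Independent two-sample t-test, Welch or pooled-variance."""
    x, y = np.asarray(sample1, float), np.asarray(sample2, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 per group")
    equal_var = {"welch": False, "pooled": True}[variant]
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return StatTestResult(
        test=f"t_{variant}",
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        effect_size=cohens_d(x, y),
        group_summaries=(_summary(x), _summary(y)),
    )


def two_group_t_from_stats(
    n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float, variant: str = "pooled"
) -> StatTestResult:
    """Two-sample t from printed summary statistics (n, mean, sd)."""
    equal_var = {"welch": False, "pooled": True}[variant]
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=equal_var)
    if equal_var:
        df = float(n1 + n2 - 2)
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    d = cohens_d_from_stats(n1, mean1, sd1, n2, mean2, sd2)
    return StatTestResult(
        test=f"t_{variant}", statistic=float(t), df=df, p=float(p), effect_size=d,
        group_summaries=({"n": n1, "mean": mean1, "sd": sd1}, {"n": n2, "mean": mean2, "sd": sd2}),
    )


def cohens_d(sample1: Sequence[float], sample2: Sequence[float]) -> float:
    """Pooled-SD standardized mean difference."""
    x, y = np.asarray(sample1, float), np.asarray(sample2, float)
    return cohens_d_from_stats(
        x.size, float(x.mean()), float(x.std(ddof=1)), y.size, float(y.mean()), float(y.std(ddof=1))
    )


def cohens_d_from_stats(n1: int, mean1: float, sd1: float, n2: int, mean2: float, sd2: float) -> float:
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("zero pooled variance: d undefined")
    return float((mean1 - mean2) / pooled)


def mann_whitney_u(sample1: Sequence[float], sample2: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (#{x > y} + half-ties) and two-sided p.

    Exact enumeration when n1*n2 <= 400 and the data are tie-free,
    otherwise the tie-corrected normal approximation.
    """
    x, y = np.asarray(sample1, float), np.asarray(sample2, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("need at least one observation per group")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def auto_two_group_test(sample1: Sequence[float], sample2: Sequence[float], alpha: float = 0.05) -> StatTestResult:
    """Pooled t when Levene accepts variance homogeneity, Welch otherwise."""
    _, p_lev = sps.levene(np.asarray(sample1, float), np.asarray(sample2, float))
    variant = "pooled" if p_lev >= alpha else "welch"
    return two_group_t(sample1, sample2, variant=variant)
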