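"""Single-feature group discrimination by cross-validated ROC AUC.

Each candidate biomarker is evaluated alone: the AUC is the probability
that a randomly chosen positive-group value exceeds a randomly chosen
negative-group value (ties get half credit), estimated under stratified
k-fold cross-validation.  The only quantity "trained" per fold is the
orientation (which direction counts as positive), fixed on the training
portion, so the held-out AUC is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold

from .association import _is_feature
from .stats import mann_whitney_u

__all__ = ["ROCResult", "auc", "stratified_kfold_auc", "screen_all_features"]


@dataclass(frozen=True)
class ROCResult:
    feature: str
    fold_aucs: tuple[float, ...]
    mean_auc: float
    ci_low: float
    ci_high: float
    p: float
    orientation: str  # e.g. "MD>SV"


def auc(scores_positive: Sequence[float], scores_negative: Sequence[float]) -> float:
    """Tie-adjusted probability of a positive score exceeding a negative one.

    Equals the Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    x, y = np.asarray(scores_positive, float), np.asarray(scores_negative, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    u = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").statistic
    return float(u) / (x.size * y.size)


def stratified_kfold_auc(
    values: Sequence[float],
    labels: Sequence[str],
    positive: str,
    k: int = 5,
    seed: int = 0,
    feature: str = "",
    n_bootstrap: int = 0,
) -> ROCResult:
    """Stratified k-fold cross-validated single-feature AUC.

    Per fold the orientation is fixed on the training portion (flip the
    sign if the training AUC is below 0.5) and the AUC is computed on
    the held-out fold with that orientation.  The CI is the 2.5th-97.5th
    percentile of the k fold AUCs (set ``n_bootstrap`` for an optional
    bootstrap CI instead); p comes from a pooled-data Mann-Whitney test.
    """
    v = np.asarray(values, float)
    y = np.asarray([1 if g == positive else 0 for g in labels])
    if min(np.sum(y == 1), np.sum(y == 0)) < k:
        raise ValueError(f"k={k} is too large: need >= k members per class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    flips = []
    for train, test in skf.split(v.reshape(-1, 1), y):
        a_train = auc(v[train][y[train] == 1], v[train][y[train] == 0])
        flip = a_train < 0.5
        a_test = auc(v[test][y[test] == 1], v[test][y[test] == 0])
        fold_aucs.append(1.0 - a_test if flip else a_test)
        flips.append(flip)
    fold_aucs = np.asarray(fold_aucs)
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        boots = []
        pos, neg = v[y == 1], v[y == 0]
        flip_all = auc(pos, neg) < 0.5
        for _ in range(n_bootstrap):
            a = auc(rng.choice(pos, pos.size), rng.choice(neg, neg.size))
            boots.append(1.0 - a if flip_all else a)
        ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    else:
        ci_low, ci_high = np.percentile(fold_aucs, [2.5, 97.5])
    _, p = mann_whitney_u(v[y == 1], v[y == 0])
    groups = sorted(set(labels), key=list(labels).index)
    other = next(g for g in groups if g != positive)
    orientation = f"{other}>{positive}" if np.mean(flips) > 0.5 else f"{positive}>{other}"
    return ROCResult(
        feature=feature,
        fold_aucs=tuple(float(a) for a in fold_aucs),
        mean_auc=float(fold_aucs.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p=float(p),
        orientation=orientation,
    )


def screen_all_features(
    feature_table: pd.DataFrame,
    positive: str = "MD",
    negative: str = "SV",
    k: int = 5,
    seed: int = 0,
    features: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Cross-validated AUC for every feature column, ranked by mean AUC."""
    df = feature_table[feature_table["group"].isin([positive, negative])]
    if features is None:
        features = [c for c in df.columns if _is_feature(c)]
    rows = []
    for feat in features:
        sub = df[[feat, "group"]].dropna()
        res = stratified_kfold_auc(
            sub[feat].to_numpy(), sub["group"].tolist(), positive=positive, k=k, seed=seed, feature=feat
        )
        rows.append(
            {
                "feature": feat,
                "mean_auc": res.mean_auc,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "orientation": res.orientation,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("mean_auc", ascending=False).reset_index(drop=True)
    )
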