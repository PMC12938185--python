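"""Clinical correlation screen with false-discovery-rate control.

Every microstate feature is rank-correlated (Spearman) with each
clinical scale over the patient subgroup, and p-values are adjusted by
the Benjamini-Hochberg step-up procedure separately per scale across
the whole feature family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .features import parse_feature_name

__all__ = ["CorrelationResult", "spearman", "bh_fdr", "clinical_screen"]


@dataclass(frozen=True)
class CorrelationResult:
    feature: str
    scale: str
    rho: float
    p: float
    q: float
    n: int

    @property
    def significant(self) -> bool:
        return self.q < 0.05


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rho (mid-rank ties) with two-tailed t-approximation p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 4:
        raise ValueError("need n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rho undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg q-values in the input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def clinical_screen(
    feature_table: pd.DataFrame,
    scales: Sequence[str] = ("VAS", "ABC"),
    patients_only: bool = True,
    patient_groups: Sequence[str] = ("MD", "SV"),
    q_threshold: float = 0.05,
    per_band: bool = False,
) -> pd.DataFrame:
    """Spearman screen of every feature against each clinical scale.

    Restricted to patient rows when ``patients_only``; missing scores
    are excluded pairwise per scale.  BH-FDR is applied within scale
    across the full feature family (or within band when ``per_band``).
    Returns a tidy frame: feature, scale, rho, p, q, n, significant.
    """
    df = feature_table
    if patients_only:
        df = df[df["group"].isin(patient_groups)]
    features = [c for c in df.columns if _is_feature(c)]
    rows = []
    for scale in scales:
        sub = df[features + [scale]].dropna(subset=[scale])
        if len(sub) < 4:
            raise ValueError(f"fewer than 4 usable patients for scale {scale}")
        y = sub[scale].to_numpy(float)
        complete = [f for f in features if not sub[f].isna().any()]
        if complete:
            rhos, ps = _spearman_block(sub[complete].to_numpy(float), y)
            rows += [
                {"feature": f, "scale": scale, "rho": r, "p": p, "n": len(sub)}
                for f, r, p in zip(complete, rhos, ps)
            ]
        for feat in (f for f in features if f not in complete):
            pair = sub[[feat, scale]].dropna()
            rho, p = spearman(pair[feat], pair[scale])
            rows.append({"feature": feat, "scale": scale, "rho": rho, "p": p, "n": len(pair)})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    group_keys = ["scale"]
    if per_band:
        out["band"] = [parse_feature_name(f)[0] for f in out["feature"]]
        group_keys.append("band")
    for _, idx in out.groupby(group_keys).groups.items():
        out.loc[idx, "q"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    if per_band:
        out = out.drop(columns="band")
    out["significant"] = out["q"] < q_threshold
    return out.sort_values(["scale", "q"]).reset_index(drop=True)


def _spearman_block(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Spearman rho/p of a complete matrix against one vector.

    Mid-rank transform followed by Pearson correlation; identical to
    :func:`spearman` column by column, vectorized for screening.
    """
    n = x.shape[0]
    rx = sps.rankdata(x, axis=0)
    ry = sps.rankdata(y)
    sx = rx.std(axis=0)
    if np.any(sx == 0) or ry.std() == 0:
        raise ValueError("constant vector: rho undefined")
    rx = (rx - rx.mean(axis=0)) / sx
    ry = (ry - ry.mean()) / ry.std()
    rho = rx.T @ ry / n
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = np.where(np.abs(rho) == 1.0, 0.0, 2.0 * sps.t.sf(np.abs(tstat), n - 2))
    return rho, p


def _is_feature(col: str) -> bool:
    try:
        parse_feature_name(col)
        return True
    except ValueError:
        return False
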