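"""Polarity-invariant modified K-means microstate clustering.

Microstate templates are cluster centroids of GFP-peak topographies
under a polarity-ignored spatial-correlation metric: a map and its
sign-flip belong to the same state, as is standard for spontaneous EEG.
The modified K-means alternates (i) assigning each map to the template
with the largest squared spatial correlation and (ii) re-estimating
each template as the dominant eigenvector of its members' outer-product
sum — the direction maximizing polarity-ignored explained variance.

Model selection over K uses the explained-variance profile together
with a predictive-residual criterion

    CV(K) = sigma2_K * ((C - 1) / (C - 1 - K))**2,

where C is the channel count and ``sigma2_K`` is the mean unexplained
map variance at K clusters.  K can also be forced (the four-state
solution is the field's convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .gfp import PeakMaps
from .montage import Montage

__all__ = [
    "TemplateSet",
    "CANONICAL_NAMES",
    "spatial_correlation",
    "canonical_templates",
    "modkmeans",
    "select_k",
    "canonical_label",
]

CANONICAL_NAMES = ("A", "B", "C", "D")


@dataclass
class TemplateSet:
    """K unit-norm, average-referenced microstate topographies."""

    maps: np.ndarray = field(repr=False)  # (K, n_channels)
    labels: tuple[str, ...]
    band: str = ""
    gev_total: float = float("nan")
    cv_criterion: float = float("nan")
    k_profile: Optional[dict] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.maps, dtype=float)
        if m.ndim != 2:
            raise ValueError("maps must be (K, n_channels)")
        if len(self.labels) != m.shape[0]:
            raise ValueError("one label per map required")
        self.maps = m
        self.labels = tuple(self.labels)

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    def reordered(self, order: Sequence[int], labels: Sequence[str]) -> "TemplateSet":
        return replace(self, maps=self.maps[list(order)], labels=tuple(labels))


def _center_norm(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    c = m - m.mean(axis=-1, keepdims=True)
    n = np.linalg.norm(c, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("zero-variance map has no spatial correlation")
    return c / n


def spatial_correlation(map1: np.ndarray, map2: np.ndarray, ignore_polarity: bool = True) -> float:
    """Pearson correlation across channels of two average-referenced maps.

    With ``ignore_polarity`` the absolute value is returned, treating a
    topography and its sign-flip as identical.
    """
    a, b = _center_norm(map1), _center_norm(map2)
    if a.shape != b.shape:
        raise ValueError("maps must have equal channel counts")
    r = float(np.dot(a, b))
    return abs(r) if ignore_polarity else r


def canonical_templates(montage: Montage) -> TemplateSet:
    """Stylized analytic A-D maps on an arbitrary montage.

    A and B are the two diagonal dipolar fields, C an anterior-posterior
    gradient tilted toward the vertex (so it stays distinct from the
    diagonals on a cap montage), D a frontal-midline focal field (a
    smooth average-referenced bump).
    """
    p = montage.positions
    sq2 = np.sqrt(2.0)
    a = p @ np.array([-1.0, 1.0, 0.0]) / sq2
    b = p @ np.array([1.0, 1.0, 0.0]) / sq2
    c = p @ np.array([0.0, 0.2, 0.98]) / np.linalg.norm([0.0, 0.2, 0.98])
    center = np.array([0.0, 0.85, 0.53])
    center /= np.linalg.norm(center)
    d = np.exp((p @ center - 1.0) / 0.18)
    maps = np.stack([a, b, c, d])
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps /= np.linalg.norm(maps, axis=1, keepdims=True)
    return TemplateSet(maps, CANONICAL_NAMES)


def _explained_variance(x: np.ndarray, templates: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
    """Assignments, total EV and per-map best |corr| for centered maps x."""
    norms = np.linalg.norm(x, axis=1)
    corr = (x / norms[:, None]) @ templates.T
    assign = np.argmax(corr**2, axis=1)
    best = np.abs(corr[np.arange(len(x)), assign])
    ev = float(np.sum((norms * best) ** 2) / np.sum(norms**2))
    return assign, ev, best


def _update_template(xk: np.ndarray) -> np.ndarray:
    """Dominant eigenvector of the members' outer-product sum."""
    s = xk.T @ xk
    w, v = np.linalg.eigh(s)
    t = v[:, -1]
    t = t - t.mean()
    n = np.linalg.norm(t)
    return t / n if n > 0 else t


def modkmeans(
    peak_maps: PeakMaps | np.ndarray,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | np.random.Generator = 0,
    band: str = "",
    init_templates: Optional[np.ndarray] = None,
) -> TemplateSet:
    """Fit K polarity-invariant microstate templates to peak maps.

    Best of ``n_restarts`` random initializations by explained variance;
    ``init_templates`` adds one deterministic warm start.  An emptied
    cluster is re-seeded from the currently worst-fit map.
    """
    maps = peak_maps.maps if isinstance(peak_maps, PeakMaps) else np.asarray(peak_maps, float)
    n, n_ch = maps.shape
    if n < k:
        raise ValueError(f"need at least {k} maps, got {n}")
    x = maps - maps.mean(axis=1, keepdims=True)
    keep = np.linalg.norm(x, axis=1) > 0
    x = x[keep]
    n = x.shape[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    inits: list[np.ndarray] = []
    if init_templates is not None:
        t0 = np.asarray(init_templates, float)
        t0 = t0 - t0.mean(axis=1, keepdims=True)
        t0 = t0 / np.linalg.norm(t0, axis=1, keepdims=True)
        inits.append(t0)
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        t0 = x[idx] / np.linalg.norm(x[idx], axis=1, keepdims=True)
        inits.append(t0)

    best_ev, best_templates = -np.inf, None
    for t in inits:
        t = t.copy()
        prev_ev = -np.inf
        for _ in range(max_iter):
            assign, ev, best = _explained_variance(x, t)
            for kk in range(k):
                members = assign == kk
                if not members.any():
                    worst = int(np.argmin(best))
                    t[kk] = x[worst] / np.linalg.norm(x[worst])
                    assign[worst] = kk
                    members = assign == kk
                t[kk] = _update_template(x[members])
            if abs(ev - prev_ev) < tol * max(abs(ev), 1e-12):
                break
            prev_ev = ev
        _, ev, _ = _explained_variance(x, t)
        if ev > best_ev:
            best_ev, best_templates = ev, t.copy()

    labels = tuple(str(i) for i in range(k)) if k != 4 else CANONICAL_NAMES
    return TemplateSet(best_templates, labels, band=band, gev_total=best_ev)


def _cv_criterion(x: np.ndarray, templates: np.ndarray) -> float:
    n_ch = x.shape[1]
    k = templates.shape[0]
    if k >= n_ch - 1:
        return float("inf")
    norms = np.linalg.norm(x, axis=1)
    corr = (x / norms[:, None]) @ templates.T
    best_r2 = np.max(corr**2, axis=1)
    map_var = norms**2 / n_ch  # population variance of each centered map
    sigma2 = float(np.mean((1.0 - best_r2) * map_var))
    return sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2


def select_k(
    peak_maps: PeakMaps | np.ndarray,
    k_range: Sequence[int] = range(2, 11),
    seed: int | np.random.Generator = 0,
    forced_k: Optional[int] = None,
    band: str = "",
    n_restarts: int = 20,
) -> TemplateSet:
    """Fit every K in ``k_range`` and pick by the predictive-residual CV.

    Each K is additionally warm-started from the previous K's solution
    plus one extra template, which guarantees the explained-variance
    profile is non-decreasing in K.  ``forced_k`` overrides the CV
    choice while still reporting the full profile.
    """
    maps = peak_maps.maps if isinstance(peak_maps, PeakMaps) else np.asarray(peak_maps, float)
    x = maps - maps.mean(axis=1, keepdims=True)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    fits: dict[int, TemplateSet] = {}
    profile: dict[int, dict[str, float]] = {}
    prev: Optional[np.ndarray] = None
    for k in sorted(k_range):
        init = None
        if prev is not None:
            norms = np.linalg.norm(x, axis=1)
            corr = (x / norms[:, None]) @ prev.T
            worst = int(np.argmin(np.max(np.abs(corr), axis=1)))
            extra = x[worst] / np.linalg.norm(x[worst])
            init = np.vstack([prev, extra])
        ts = modkmeans(maps, k, n_restarts=n_restarts, seed=rng, band=band, init_templates=init)
        cv = _cv_criterion(x, ts.maps)
        ts.cv_criterion = cv
        fits[k] = ts
        profile[k] = {"gev": ts.gev_total, "cv": cv}
        prev = ts.maps

    chosen = forced_k if forced_k is not None else min(profile, key=lambda k: profile[k]["cv"])
    if chosen not in fits:
        raise ValueError(f"forced_k={chosen} not in k_range")
    out = fits[chosen]
    out.k_profile = profile
    return out


def canonical_label(template_set: TemplateSet, canon: Optional[TemplateSet] = None,
                    montage: Optional[Montage] = None) -> TemplateSet:
    """Relabel a K=4 solution to canonical A-D by optimal matching.

    The one-to-one assignment maximizes the summed polarity-ignored
    spatial correlation over all pairings (solved exactly).
    """
    if template_set.k != 4:
        raise ValueError("canonical labeling requires K=4")
    if canon is None:
        if montage is None:
            raise ValueError("provide canonical templates or a montage")
        canon = canonical_templates(montage)
    cost = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            cost[i, j] = -spatial_correlation(template_set.maps[i], canon.maps[j])
    rows, cols = linear_sum_assignment(cost)
    order = rows[np.argsort(cols)]  # template index that becomes A, B, C, D
    return template_set.reordered(order, CANONICAL_NAMES)
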