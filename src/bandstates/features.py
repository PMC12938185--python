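"""Template back-fitting, temporal smoothing and microstate features.

Back-fitting labels every sample with the template of highest
polarity-ignored spatial correlation.  Temporal smoothing then enforces
a minimum state duration (30 ms by convention) by dissolving too-short
interior runs into their flanking states.  From the smoothed
segmentation the standard per-class metrics (mean duration, coverage,
occurrence, GEV) and the segment-wise transition probabilities are
computed and assembled into a subject x feature table.

Feature naming follows the ``[Band]_TP_[From]-[To]`` /
``[Band]_[Metric]_[State]`` grammar, e.g. ``Delta_TP_C-B`` is the
probability that a delta-band C state is succeeded by B, and
``Delta_MO_D`` the mean occurrence rate of state D in the delta band.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .cluster import TemplateSet
from .gfp import gfp
from .recording import EEGRecording, average_reference

__all__ = [
    "Segmentation",
    "backfit",
    "smooth_min_duration",
    "temporal_metrics",
    "gev_per_class",
    "transition_probabilities",
    "subject_band_features",
    "build_feature_table",
    "parse_feature_name",
    "feature_columns",
]

STATE_NAMES = ("A", "B", "C", "D")
METRIC_CODES = {"mean_duration": "MD", "coverage": "COV", "occurrence": "MO", "gev": "GEV"}

_NAME_RE = re.compile(
    r"^(?P<band>[A-Z][a-z]+)_(?:TP_(?P<frm>[A-D])-(?P<to>[A-D])|(?P<metric>MD|COV|MO|GEV)_(?P<state>[A-D]))$"
)


@dataclass
class Segmentation:
    """Per-sample microstate labels with the full correlation profile."""

    labels: np.ndarray = field(repr=False)  # (n_samples,) int state index
    corr: np.ndarray = field(repr=False)  # (n_samples, K) |spatial correlation|
    sampling_rate: float
    band: str = ""
    label_names: tuple[str, ...] = STATE_NAMES
    flagged: np.ndarray = field(default=None, repr=False)  # zero-variance samples

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.corr = np.asarray(self.corr, dtype=float)
        if self.flagged is None:
            self.flagged = np.zeros(self.labels.size, dtype=bool)

    @property
    def fit(self) -> np.ndarray:
        """Per-sample correlation with the winning template."""
        return self.corr[np.arange(self.labels.size), self.labels]

    @property
    def n_states(self) -> int:
        return self.corr.shape[1]


def _runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Run-length encoding: list of (start, stop, state)."""
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [labels.size]])
    return [(int(a), int(b), int(labels[a])) for a, b in zip(starts, stops)]


def backfit(rec: EEGRecording, template_set: TemplateSet) -> Segmentation:
    """Assign each sample the template of highest |spatial correlation|.

    Ties go to the lowest class index.  Zero-variance samples inherit
    the previous sample's label (class 0 at the start) and are flagged.
    """
    t = template_set.maps
    if t.shape[1] != rec.n_channels:
        raise ValueError("template and recording channel counts differ")
    x = average_reference(rec.data).T  # (n, C)
    norms = np.linalg.norm(x, axis=1)
    bad = norms == 0
    safe = np.where(bad, 1.0, norms)
    corr = np.abs((x / safe[:, None]) @ t.T)
    corr[bad] = 0.0
    labels = np.argmax(corr, axis=1)  # argmax takes the first (lowest) index on ties
    if bad.any():
        for i in np.flatnonzero(bad):
            labels[i] = labels[i - 1] if i > 0 else 0
    return Segmentation(labels, corr, rec.sampling_rate, flagged=bad,
                        label_names=template_set.labels)


class _Run:
    __slots__ = ("start", "stop", "state", "prev", "next", "alive")

    def __init__(self, start: int, stop: int, state: int):
        self.start, self.stop, self.state = start, stop, state
        self.prev: Optional["_Run"] = None
        self.next: Optional["_Run"] = None
        self.alive = True

    @property
    def length(self) -> int:
        return self.stop - self.start


def smooth_min_duration(seg: Segmentation, min_ms: float = 30.0) -> Segmentation:
    """Dissolve interior runs shorter than ``min_ms`` milliseconds.

    Iteratively the shortest violating interior run (leftmost on ties)
    is split contiguously between its two flanking labels at the point
    maximizing the summed winning correlations, then adjacent equal
    runs are re-merged.  First and last runs are exempt (their extent
    is censored by the window).  Every dissolve removes at least one
    run, so termination is guaranteed; a heap over violating runs keeps
    the procedure near-linear.
    """
    import heapq

    min_len = math.ceil(min_ms * seg.sampling_rate / 1000.0)
    nodes = [_Run(a, b, s) for a, b, s in _runs(seg.labels)]
    for u, v in zip(nodes[:-1], nodes[1:]):
        u.next, v.prev = v, u

    heap: list[tuple[int, int, int, _Run]] = []

    def push(node: _Run) -> None:
        if node.alive and node.prev is not None and node.next is not None and node.length < min_len:
            heapq.heappush(heap, (node.length, node.start, id(node), node))

    for node in nodes:
        push(node)

    def merge_right(node: _Run) -> None:
        """Absorb node.next into node (equal states)."""
        nxt = node.next
        node.stop = nxt.stop
        node.next = nxt.next
        if nxt.next is not None:
            nxt.next.prev = node
        nxt.alive = False

    while heap:
        length, start, _nid, node = heapq.heappop(heap)
        if not node.alive or node.length != length or node.start != start:
            continue
        if node.prev is None or node.next is None:
            continue
        left, right = node.prev, node.next
        if left.state == right.state:
            node.state = left.state
            merge_right(left)  # left absorbs node
            merge_right(left)  # then the old right
            push(left)
        else:
            cl = seg.corr[node.start : node.stop, left.state]
            cr = seg.corr[node.start : node.stop, right.state]
            # contiguous split: samples [0, s) go left, [s, L) go right
            gains = np.concatenate([[0.0], np.cumsum(cl - cr)])
            s = int(np.argmax(gains))
            left.stop = node.start + s
            right.start = node.start + s
            left.next, right.prev = right, left
            node.alive = False
            push(left)
            push(right)

    labels = np.empty_like(seg.labels)
    node: Optional[_Run] = next((n for n in nodes if n.alive and n.prev is None), None)
    if node is None:  # single run to begin with
        labels[:] = seg.labels
    while node is not None:
        labels[node.start : node.stop] = node.state
        node = node.next
    return replace(seg, labels=labels)


def temporal_metrics(seg: Segmentation) -> dict[str, dict[str, float]]:
    """Mean duration (ms), coverage and occurrence (1/s) per class.

    An absent class has undefined (NaN) mean duration, coverage 0 and
    occurrence 0.
    """
    runs = _runs(seg.labels)
    n = seg.labels.size
    dur_s = n / seg.sampling_rate
    out: dict[str, dict[str, float]] = {}
    for k, name in enumerate(seg.label_names):
        lens = [stop - start for start, stop, s in runs if s == k]
        out[name] = {
            "mean_duration": float(np.mean(lens) * 1000.0 / seg.sampling_rate) if lens else float("nan"),
            "coverage": float(np.sum(seg.labels == k) / n),
            "occurrence": len(lens) / dur_s,
        }
    return out


def gev_per_class(rec: EEGRecording, seg: Segmentation, template_set: TemplateSet) -> dict[str, float]:
    """GFP-weighted fraction of variance explained by each class.

    ``gev_k = sum_{t: label=k} (GFP(t) * corr(v_t, T_k))^2 / sum_t GFP(t)^2``
    """
    g = gfp(rec).values
    denom = float(np.sum(g**2))
    if denom == 0:
        raise ValueError("zero total GFP")
    fit = seg.fit
    out = {}
    for k, name in enumerate(seg.label_names):
        mask = seg.labels == k
        out[name] = float(np.sum((g[mask] * fit[mask]) ** 2) / denom)
    return out


def transition_probabilities(seg: Segmentation, mode: str = "segment") -> np.ndarray:
    """Conditional transition probabilities between distinct states.

    ``mode="segment"`` (default) counts ordered pairs of consecutive
    distinct runs; ``mode="sample"`` counts consecutive-sample pairs
    with differing labels.  Either way the diagonal is fixed at zero and
    each row is normalized by its outgoing count; rows with no outgoing
    transitions are NaN (undefined).
    """
    k = seg.n_states
    counts = np.zeros((k, k))
    if mode == "segment":
        states = [s for _a, _b, s in _runs(seg.labels)]
        for i, j in zip(states[:-1], states[1:]):
            counts[i, j] += 1
    elif mode == "sample":
        a, b = seg.labels[:-1], seg.labels[1:]
        mask = a != b
        np.add.at(counts, (a[mask], b[mask]), 1)
    else:
        raise ValueError("mode must be 'segment' or 'sample'")
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tp = counts / totals
    tp[totals[:, 0] == 0] = np.nan
    return tp


def subject_band_features(
    rec: EEGRecording,
    template_set: TemplateSet,
    min_ms: float = 30.0,
    tp_mode: str = "segment",
) -> tuple[dict[str, float], Segmentation]:
    """All named features of one subject in one band, plus the segmentation."""
    seg = smooth_min_duration(backfit(rec, template_set), min_ms=min_ms)
    band = template_set.band.capitalize()
    metrics = temporal_metrics(seg)
    gev = gev_per_class(rec, seg, template_set)
    tp = transition_probabilities(seg, mode=tp_mode)
    feats: dict[str, float] = {}
    for name in seg.label_names:
        feats[f"{band}_MD_{name}"] = metrics[name]["mean_duration"]
        feats[f"{band}_COV_{name}"] = metrics[name]["coverage"]
        feats[f"{band}_MO_{name}"] = metrics[name]["occurrence"]
        feats[f"{band}_GEV_{name}"] = gev[name]
    for i, frm in enumerate(seg.label_names):
        for j, to in enumerate(seg.label_names):
            if i != j:
                feats[f"{band}_TP_{frm}-{to}"] = float(tp[i, j])
    return feats, seg


def feature_columns(bands: Iterable[str] = ("delta", "theta", "alpha", "beta")) -> list[str]:
    """The full ordered feature-column grammar (112 names for 4 bands)."""
    cols = []
    for band in bands:
        b = band.capitalize()
        for metric in ("MD", "COV", "MO", "GEV"):
            cols += [f"{b}_{metric}_{s}" for s in STATE_NAMES]
        cols += [
            f"{b}_TP_{x}-{y}" for x in STATE_NAMES for y in STATE_NAMES if x != y
        ]
    return cols


def parse_feature_name(name: str) -> tuple[str, str, tuple[str, ...]]:
    """Parse a feature column name into (band, kind, states).

    ``Delta_TP_C-B -> ("delta", "TP", ("C", "B"))``;
    ``Theta_MO_D -> ("theta", "MO", ("D",))``.
    """
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a feature column name: {name!r}")
    band = m.group("band").lower()
    if m.group("frm"):
        return band, "TP", (m.group("frm"), m.group("to"))
    return band, m.group("metric"), (m.group("state"),)


def build_feature_table(
    subject_features: dict[str, dict[str, float]],
    clinical: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Assemble per-subject feature dicts and clinical scores into a table.

    Subjects missing clinical data keep their feature row with NaN
    scores (the correlation stage excludes them pairwise).
    """
    table = pd.DataFrame.from_dict(subject_features, orient="index")
    table.index.name = "subject_id"
    for col in table.columns:
        parse_feature_name(col)  # enforce the naming grammar
    if clinical is not None:
        clin = clinical.set_index("subject_id") if "subject_id" in clinical.columns else clinical
        keep = [c for c in ("group", "DHI", "VAS", "ABC") if c in clin.columns]
        table = table.join(clin[keep], how="left")
    return table.reset_index()
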