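"""Global field power and GFP-peak topography extraction.

GFP(t) is the spatial standard deviation (population form) of the
average-referenced scalp map at sample t; topographies at GFP peaks are
the high-SNR snapshots submitted to clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import EEGRecording, average_reference

__all__ = ["GFPSeries", "PeakMaps", "gfp", "pick_peaks"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GFPSeries:
    """Per-sample global field power of one recording."""

    values: np.ndarray = field(repr=False)
    sampling_rate: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("GFP values must be 1-D")
        if np.any(v < 0):
            raise ValueError("GFP values must be nonnegative")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PeakMaps:
    """Average-referenced topographies extracted at GFP peaks."""

    maps: np.ndarray = field(repr=False)  # (n_peaks, n_channels)
    peak_indices: np.ndarray = field(repr=False)
    subject_id: str = "s0"
    band: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.peak_indices, dtype=int)
        if idx.size > 1 and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "peak_indices", idx)
        object.__setattr__(self, "maps", np.asarray(self.maps, dtype=float))

    @property
    def n_peaks(self) -> int:
        return self.maps.shape[0]


def gfp(rec: EEGRecording) -> GFPSeries:
    """Spatial standard deviation of the average-referenced map per sample."""
    if rec.n_channels < 2:
        raise ValueError("GFP needs at least 2 channels")
    centered = average_reference(rec.data)
    return GFPSeries(np.sqrt(np.mean(centered**2, axis=0)), rec.sampling_rate)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Strict local maxima; a plateau maximum is reported at its left edge."""
    peaks, props = signal.find_peaks(values, plateau_size=(1, None))
    return props["left_edges"]


def pick_peaks(
    rec: EEGRecording,
    gfp_series: GFPSeries | None = None,
    min_distance: int = 10,
    n_select: int = 1000,
    seed: int | np.random.Generator = 0,
    band: str = "",
) -> PeakMaps:
    """Extract up to ``n_select`` GFP-peak topographies.

    All strict local maxima of the GFP series are found, a minimum
    spacing of ``min_distance`` samples is enforced greedily (the higher
    peak wins), and the survivors are subsampled uniformly without
    replacement.  Edge samples flagged on the recording are never
    eligible.  If fewer than ``n_select`` peaks exist, all are returned
    and a warning is logged.
    """
    if min_distance < 1:
        raise ValueError("min_distance must be >= 1")
    if gfp_series is None:
        gfp_series = gfp(rec)
    values = gfp_series.values
    if values.size == 0:
        raise ValueError("empty GFP series")

    candidates = _local_maxima(values)
    lo, hi = rec.edge_exclude, values.size - rec.edge_exclude
    candidates = candidates[(candidates >= lo) & (candidates < hi)]
    # greedy spacing: tallest first, suppress neighbours within min_distance
    order = candidates[np.argsort(values[candidates])[::-1]]
    kept: list[int] = []
    for idx in order:
        if all(abs(idx - k) >= min_distance for k in kept):
            kept.append(int(idx))
    kept_arr = np.sort(np.asarray(kept, dtype=int))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if kept_arr.size > n_select:
        kept_arr = np.sort(rng.choice(kept_arr, size=n_select, replace=False))
    elif kept_arr.size < n_select:
        logger.warning(
            "subject %s band %s: only %d GFP peaks available (requested %d)",
            rec.subject_id, band or "?", kept_arr.size, n_select,
        )
    maps = average_reference(rec.data)[:, kept_arr].T
    return PeakMaps(maps, kept_arr, subject_id=rec.subject_id, band=band)
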