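"""Broadband conditioning, QC segment selection and narrowband decomposition.

All filters are zero-phase windowed-sinc FIRs (Hamming window) applied
forward-backward, so pass-band components keep their phase.  The
effective transition width at each band edge follows the common
heuristic ``max(0.25 * edge, min(2 Hz, edge))``, which keeps delta-band
filters short enough for 10 s segments while staying sharp at higher
edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional

import numpy as np
from scipy import signal

from .recording import EEGRecording, average_reference

__all__ = [
    "BandSpec",
    "BANDS",
    "fir_bandpass",
    "broadband_condition",
    "select_qc_segment",
    "narrowband_filter",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")


#: The four canonical narrowband analysis bands.
BANDS: dict[str, BandSpec] = {
    "delta": BandSpec("delta", 1.0, 4.0),
    "theta": BandSpec("theta", 4.0, 8.0),
    "alpha": BandSpec("alpha", 8.0, 13.0),
    "beta": BandSpec("beta", 13.0, 30.0),
}


def _transition_width(edge: float) -> float:
    return max(0.25 * edge, min(2.0, edge))


def fir_bandpass(low: float, high: float, fs: float) -> np.ndarray:
    """Design a Hamming-window band-pass FIR with heuristic transitions."""
    if high >= fs / 2:
        raise ValueError(f"upper edge {high} Hz is at or above Nyquist ({fs / 2} Hz)")
    lt, ht = _transition_width(low), _transition_width(high)
    # Hamming main-lobe width: transition ~ 3.3 / N (normalized frequency)
    trans = min(lt, ht)
    numtaps = int(np.ceil(3.3 * fs / trans)) | 1
    f_lo = max(low - lt / 2, 0.05)
    f_hi = min(high + ht / 2, fs / 2 * 0.99)
    return signal.firwin(numtaps, [f_lo, f_hi], pass_zero=False, window="hamming", fs=fs)


def _apply_zero_phase(rec: EEGRecording, taps: np.ndarray) -> np.ndarray:
    n = rec.n_samples
    if n < 3 * len(taps):
        raise ValueError(
            f"recording of {n} samples is shorter than 3x the filter length "
            f"({len(taps)} taps); cannot band-pass filter reliably"
        )
    return signal.filtfilt(taps, [1.0], rec.data, axis=1, padlen=min(3 * len(taps), n - 1))


def broadband_condition(
    rec: EEGRecording,
    low: float = 1.0,
    high: float = 40.0,
    target_rate: float = 256.0,
) -> EEGRecording:
    """Band-pass to [low, high] Hz, resample, and average-reference.

    The anti-aliased resampling uses a polyphase filter at the rational
    ratio ``target_rate / sampling_rate``.
    """
    taps = fir_bandpass(low, high, rec.sampling_rate)
    out = _apply_zero_phase(rec, taps)
    if target_rate != rec.sampling_rate:
        ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(10000)
        out = signal.resample_poly(out, ratio.numerator, ratio.denominator, axis=1)
    out = average_reference(out)
    edge = int(round(len(taps) * target_rate / rec.sampling_rate))
    return rec.with_data(out, sampling_rate=target_rate, edge_exclude=edge)


def select_qc_segment(
    rec: EEGRecording, window: float = 10.0, threshold: float = 100.0
) -> Optional[EEGRecording]:
    """Earliest clean window of ``window`` seconds, or ``None`` if excluded.

    A window is clean when no sample on any channel exceeds
    ``threshold`` microvolts in magnitude.  The scan runs at sample
    resolution from t=0; a trial with no clean window is an exclusion,
    not an error.
    """
    w = int(round(window * rec.sampling_rate))
    if rec.n_samples < w:
        raise ValueError(f"recording shorter than the {window} s QC window")
    bad = np.any(np.abs(rec.data) > threshold, axis=0).astype(int)
    # windowed violation counts via prefix sums
    cs = np.concatenate([[0], np.cumsum(bad)])
    counts = cs[w:] - cs[:-w]
    starts = np.flatnonzero(counts == 0)
    if starts.size == 0:
        logger.info("subject %s: no clean %gs window, trial excluded", rec.subject_id, window)
        return None
    s = int(starts[0])
    return rec.with_data(rec.data[:, s : s + w], edge_exclude=0)


def narrowband_filter(rec: EEGRecording, band: BandSpec) -> EEGRecording:
    """Zero-phase FIR band-pass into ``band``, then average reference.

    The returned recording flags one filter length at each end as edge
    samples; GFP peak picking skips those to avoid filter transients.
    """
    taps = fir_bandpass(band.low, band.high, rec.sampling_rate)
    out = average_reference(_apply_zero_phase(rec, taps))
    return rec.with_data(out, edge_exclude=len(taps))
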