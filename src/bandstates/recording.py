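"""The multichannel EEG recording container shared by every stage."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .montage import Montage

__all__ = ["EEGRecording", "average_reference"]


def average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels from every sample."""
    return data - data.mean(axis=0, keepdims=True)


@dataclass
class EEGRecording:
    """Channel x sample EEG matrix in microvolts.

    Attributes
    ----------
    data
        Array of shape ``(n_channels, n_samples)``.
    sampling_rate
        Samples per second.
    montage
        Sensor layout; its channel count must match ``data``.
    subject_id, group
        Bookkeeping labels (group is ``HC``/``MD``/``SV``/``synthetic``).
    edge_exclude
        Number of samples at each end contaminated by filter transients;
        downstream peak picking skips them.
    """

    data: np.ndarray = field(repr=False)
    sampling_rate: float
    montage: Montage
    subject_id: str = "s0"
    group: str = "synthetic"
    edge_exclude: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def with_data(
        self, data: np.ndarray, *, sampling_rate: Optional[float] = None, edge_exclude: Optional[int] = None
    ) -> "EEGRecording":
        """Copy of this recording with new samples (labels preserved)."""
        return replace(
            self,
            data=data,
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            edge_exclude=self.edge_exclude if edge_exclude is None else edge_exclude,
        )
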