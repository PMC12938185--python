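"""Sensor montages on the unit sphere.

Channel positions are 3D unit vectors in head coordinates (x: right,
y: anterior, z: superior).  The default synthetic montage places 52
sensors on the upper portion of the sphere in a deterministic spiral
layout, mimicking the coverage of a high-density cap after peripheral
channels are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "default_montage"]


@dataclass(frozen=True)
class Montage:
    """A named set of unit-sphere sensor positions.

    Parameters
    ----------
    channel_ids
        Unique channel names, one per sensor.
    positions
        Array of shape ``(n_channels, 3)``; every row must have unit norm.
    """

    channel_ids: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be (n_channels, 3)")
        if len(self.channel_ids) != pos.shape[0]:
            raise ValueError("channel_ids and positions disagree in length")
        if len(set(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel ids must be unique")
        if pos.shape[0] < 8:
            raise ValueError("montage needs at least 8 channels")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("every position must lie on the unit sphere")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "channel_ids", tuple(self.channel_ids))

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]


def default_montage(n_channels: int = 52, max_polar: float = 2.0) -> Montage:
    """Deterministic spiral cap of ``n_channels`` sensors.

    Sensors are laid out along a Fibonacci spiral restricted to polar
    angles below ``max_polar`` radians (default ~115 deg from the vertex,
    i.e. no sensors below the ears).
    """
    if n_channels < 8:
        raise ValueError("montage needs at least 8 channels")
    golden = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n_channels)
    # uniform in cos(theta) over the cap [cos(max_polar), 1]
    z = 1.0 - (1.0 - np.cos(max_polar)) * (k + 0.5) / n_channels
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = golden * k
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    ids = tuple(f"E{i + 1}" for i in range(n_channels))
    return Montage(ids, pos)
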