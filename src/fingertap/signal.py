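"""In-memory containers for tapping signals, EMD output and detected peaks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TapSignal:
    """1-D thumb–index distance series.

    ``values`` is the distance at each frame; when ``normalized`` is True the
    distance has been divided by the per-frame palm size and is dimensionless
    ("palm units"), otherwise it inherits the raw coordinate units.
    Missing samples (pose dropouts) are NaN until interpolated by
    preprocessing.
    """

    values: np.ndarray
    fps: float
    normalized: bool = False
    units: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("TapSignal requires a 1-D series of length >= 2")
        if not self.fps > 0:
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (frame_index / fps)."""
        return np.arange(self.values.size) / self.fps


@dataclass
class EMDResult:
    """Empirical-mode decomposition of a signal.

    ``imfs`` are ordered highest-frequency first; ``residual`` is the slow
    trend.  By construction ``sum(imfs) + residual`` reconstructs the input.
    """

    imfs: list[np.ndarray]
    residual: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out


@dataclass
class PeakSet:
    """Detected full-opening peaks of a tapping signal.

    ``indices`` are strictly increasing frame indices, ``times`` the
    corresponding instants in seconds and ``amplitudes`` the signal values at
    the peaks (palm units for normalized signals).
    """

    indices: np.ndarray
    amplitudes: np.ndarray
    fps: float
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times is None:
            self.times = self.indices / self.fps
        else:
            self.times = np.asarray(self.times, dtype=float)
        if self.indices.size == 0:
            raise ValueError("PeakSet requires at least one peak")
        if self.indices.size != self.amplitudes.size != self.times.size:
            raise ValueError("indices, times and amplitudes must align")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.indices.size)
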