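"""Time-series containers shared across the pipeline.

All positions are in meters, angles in radians, time in seconds. Frames are
0-based and timestamps are ``frame / rate`` from trial start.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class MarkerTrajectories:
    """Labeled 3D point time series.

    data has shape (n_frames, n_markers, 3); missing samples are NaN.
    """

    labels: list[str]
    data: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != 3:
            raise ValueError(f"marker data must be (T, M, 3), got {self.data.shape}")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("label count does not match marker axis")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def frame(self, i: int) -> dict[str, np.ndarray]:
        """One frame as a label -> position mapping (NaN rows included)."""
        return {lab: self.data[i, j] for j, lab in enumerate(self.labels)}

    def copy(self) -> "MarkerTrajectories":
        return MarkerTrajectories(list(self.labels), self.data.copy(), self.rate)


@dataclass
class PoseStream:
    """Per-frame 4x4 homogeneous segment poses in the global frame.

    data has shape (n_frames, n_segments, 4, 4).
    """

    segments: list[str]
    data: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[2:] != (4, 4):
            raise ValueError(f"pose data must be (T, S, 4, 4), got {self.data.shape}")
        if self.data.shape[1] != len(self.segments):
            raise ValueError("segment count does not match pose axis")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def pose(self, i: int, segment: str) -> np.ndarray:
        return self.data[i, self.segments.index(segment)]

    def frame(self, i: int) -> dict[str, np.ndarray]:
        return {seg: self.data[i, j] for j, seg in enumerate(self.segments)}

    def copy(self) -> "PoseStream":
        return PoseStream(list(self.segments), self.data.copy(), self.rate)


@dataclass
class QTrajectory:
    """Generalized-coordinate time series (root pose + free joint angles).

    q has shape (n_frames, n_q). ``valid`` marks frames with a trustworthy
    solution (solver gaps are flagged False, never interpolated).
    """

    q: np.ndarray
    rate: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2:
            raise ValueError(f"q must be (T, n_q), got {self.q.shape}")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.valid is None:
            self.valid = np.ones(self.q.shape[0], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.q.shape[0],):
                raise ValueError("valid mask length mismatch")

    @property
    def n_frames(self) -> int:
        return self.q.shape[0]

    @property
    def n_q(self) -> int:
        return self.q.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def copy(self) -> "QTrajectory":
        return QTrajectory(self.q.copy(), self.rate, self.valid.copy())
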