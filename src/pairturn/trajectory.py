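"""The Trajectory container: one fish's time-indexed planar positions.

Positions are tank-centred Cartesian coordinates in metres with the
origin at the centre of the annulus; frames are 0-based and uniformly
spaced at the arena sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """Positions of one identified fish over a contiguous frame range.

    Attributes
    ----------
    fish_id : str
        Identity label of the fish (stable across the recording).
    frames : ndarray of int, shape (n,)
        Strictly increasing, uniformly spaced frame indices.
    xy : ndarray of float, shape (n, 2)
        Positions in metres, origin at the annulus centre.
    fs : float
        Sampling frequency in Hz (time of frame f is ``f / fs`` seconds).
    """

    fish_id: str
    frames: np.ndarray
    xy: np.ndarray
    fs: float = 50.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise DataError(f"xy must have shape (n, 2), got {self.xy.shape}")
        if len(self.frames) != len(self.xy):
            raise DataError("frames and xy length mismatch")
        if len(self.frames) >= 2:
            steps = np.diff(self.frames)
            if np.any(steps <= 0):
                bad = self.frames[1:][steps <= 0]
                raise DataError(f"frames not strictly increasing at {bad[:5]}")
            if np.any(steps != steps[0]):
                raise DataError("frames not uniformly spaced")
        if not np.all(np.isfinite(self.xy)):
            bad = self.frames[~np.all(np.isfinite(self.xy), axis=1)]
            raise DataError(
                f"non-finite position for fish {self.fish_id!r} at frames {bad[:5]}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def time_s(self) -> np.ndarray:
        """Frame times in seconds."""
        return self.frames / self.fs

    @property
    def radius(self) -> np.ndarray:
        """Radial distance of each position from the tank centre (m)."""
        return np.hypot(self.xy[:, 0], self.xy[:, 1])

    def restrict(self, frames: np.ndarray) -> "Trajectory":
        """Return a copy restricted to the given frame indices (must be present)."""
        mask = np.isin(self.frames, frames)
        return Trajectory(self.fish_id, self.frames[mask], self.xy[mask], self.fs)

    def with_xy(self, xy: np.ndarray) -> "Trajectory":
        """Return a copy with replaced coordinates (same frames and identity)."""
        return Trajectory(self.fish_id, self.frames.copy(), xy, self.fs)
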