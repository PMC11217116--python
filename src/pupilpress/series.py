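"""Pupil-area time series: the central intermediate of the pipeline.

An :class:`AreaTimeSeries` holds timestamped pupil areas sampled at the
camera frame rate, with each sample labelled by protocol phase (dark,
flash, recovery) and the flash on/off instants recorded. Missing samples
(segmentation dropouts) are carried as NaN until interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHASES = ("dark", "flash", "recovery")


@dataclass
class AreaTimeSeries:
    """Timestamped pupil-area recording.

    Attributes
    ----------
    time_s : ndarray
        Sample timestamps in seconds, strictly increasing.
    area_mm2 : ndarray
        Pupil area per sample, mm². NaN marks a missing (dropped) frame.
    phase : ndarray of str
        Protocol phase per sample, one of ``dark``, ``flash``, ``recovery``.
    fps : float
        Nominal sampling rate, frames per second.
    flash_on_s, flash_off_s : float
        Flash onset and offset instants, seconds.
    """

    time_s: np.ndarray
    area_mm2: np.ndarray
    phase: np.ndarray
    fps: float
    flash_on_s: float
    flash_off_s: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.area_mm2 = np.asarray(self.area_mm2, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (self.time_s.shape == self.area_mm2.shape == self.phase.shape):
            raise ValueError("time_s, area_mm2 and phase must have equal length")
        if self.time_s.size == 0:
            raise ValueError("series must be nonempty")
        if np.any(np.diff(self.time_s) <= 0):
            raise ValueError("time_s must be strictly increasing")
        if not self.flash_on_s < self.flash_off_s:
            raise ValueError("flash_on_s must precede flash_off_s")
        bad = set(np.unique(self.phase)) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        valid = self.area_mm2[~np.isnan(self.area_mm2)]
        if np.any(valid <= 0):
            raise ValueError("areas must be > 0 (or NaN for missing)")

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.area_mm2).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time_s, "area_mm2": self.area_mm2, "phase": self.phase}
        )
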