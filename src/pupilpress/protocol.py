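"""Recording protocol for the dark-adaptation / blue-flash pupillometry test.

The measurement session consists of a dark-adaptation period, a short
diffused blue-light flash, and a post-flash recovery window, sampled by a
near-infrared camera at a fixed frame rate. Durations are in seconds; the
flash wavelength is carried as metadata only (no photometric model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing of the dark / flash / recovery stimulus protocol.

    Parameters
    ----------
    dark_s : float
        Dark-adaptation duration before the flash, seconds.
    flash_s : float
        Blue-flash duration, seconds.
    recovery_s : float
        Recorded recovery window after flash offset, seconds. The default
        (8 s) always covers the 6-s post-illumination readout point.
    fps : float
        Camera sampling rate, frames per second.
    flash_wavelength_nm : float
        Flash wavelength, nanometres (metadata only).
    """

    dark_s: float = 10.0
    flash_s: float = 1.5
    recovery_s: float = 8.0
    fps: float = 13.0
    flash_wavelength_nm: float = 480.0

    def __post_init__(self) -> None:
        for name in ("dark_s", "flash_s", "recovery_s", "fps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")

    @property
    def flash_on_s(self) -> float:
        return self.dark_s

    @property
    def flash_off_s(self) -> float:
        return self.dark_s + self.flash_s

    @property
    def total_s(self) -> float:
        return self.dark_s + self.flash_s + self.recovery_s

    @property
    def n_samples(self) -> int:
        return math.ceil(self.total_s * self.fps)

    def phase_of(self, t: float) -> str:
        """Protocol phase ('dark', 'flash' or 'recovery') at time ``t``."""
        if t < self.flash_on_s:
            return "dark"
        if t < self.flash_off_s:
            return "flash"
        return "recovery"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)
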