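"""One-point per-eye calibration and IOP estimation from redilation rate.

Iris mechanics are patient specific, so the rate-to-pressure map must be
anchored per eye with a single simultaneous reference tonometer reading
(Goldmann applanation in the sitting position by convention). Under
linear resistance coupling (tau_d proportional to IOP) one reading fixes
the whole map:

    k = IOP_calib * rate_calib        [mmHg/s]
    IOP_hat = k / rate                [mmHg]

i.e. IOP is proportional to the redilation time constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from .features import PIPRFeatures

__all__ = ["EyeCalibration", "calibrate", "estimate_iop"]

EYES = ("OD", "OS")
INSTRUMENTS = ("GAT", "iCare")


@dataclass(frozen=True)
class EyeCalibration:
    """Per-eye calibration constant with its provenance.

    ``k_mmHg_per_s = calib_iop_mmHg * calib_rate_per_s`` maps a measured
    redilation rate back to pressure via ``IOP = k / rate``.
    """

    subject_id: str
    eye: str
    k_mmHg_per_s: float
    calib_iop_mmHg: float
    calib_rate_per_s: float
    calib_instrument: str

    def __post_init__(self) -> None:
        if self.eye not in EYES:
            raise ValueError(f"eye must be one of {EYES}")
        if self.calib_instrument not in INSTRUMENTS:
            raise ValueError(f"calib_instrument must be one of {INSTRUMENTS}")
        if self.k_mmHg_per_s <= 0:
            raise ValueError("k must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        # external JSON key kept short
        d["k_mmHg_s"] = d.pop("k_mmHg_per_s")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EyeCalibration":
        d = dict(d)
        if "k_mmHg_s" in d:
            d["k_mmHg_per_s"] = d.pop("k_mmHg_s")
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        return cls(**known)


def calibrate(
    calib_iop: float,
    features: PIPRFeatures,
    subject_id: str,
    eye: str,
    instrument: str = "GAT",
) -> EyeCalibration:
    """Anchor the rate-to-IOP map of one eye to a reference reading.

    Parameters
    ----------
    calib_iop : float
        Reference tonometer reading taken alongside the recording, mmHg.
    features : PIPRFeatures
        Features of the calibration recording (same sitting).
    """
    if calib_iop <= 0:
        raise ValueError("calib_iop must be > 0")
    rate = features.redilation_rate_per_s
    if rate <= 0:
        raise ValueError("redilation rate must be > 0")
    return EyeCalibration(
        subject_id=subject_id,
        eye=eye,
        k_mmHg_per_s=calib_iop * rate,
        calib_iop_mmHg=calib_iop,
        calib_rate_per_s=rate,
        calib_instrument=instrument,
    )


def estimate_iop(
    cal: EyeCalibration, features: PIPRFeatures, rounding: str = "0.1"
) -> float:
    """Estimate IOP (mmHg) from a recording's redilation rate.

    ``rounding='0.1'`` reports at rebound-tonometer-like 0.1 mmHg
    resolution; ``rounding='integer'`` mimics Goldmann-dial readings;
    ``rounding='none'`` returns the raw value.
    """
    rate = features.redilation_rate_per_s
    if rate <= 0:
        raise ValueError("redilation rate must be > 0")
    iop = cal.k_mmHg_per_s / rate
    if rounding == "0.1":
        return round(iop, 1)
    if rounding == "integer":
        return float(round(iop))
    if rounding == "none":
        return iop
    raise ValueError("rounding must be '0.1', 'integer' or 'none'")


def save_calibrations(cals: list[EyeCalibration], path: str | Path) -> None:
    Path(path).write_text(json.dumps([c.to_dict() for c in cals], indent=1))


def load_calibrations(path: str | Path) -> list[EyeCalibration]:
    return [EyeCalibration.from_dict(d) for d in json.loads(Path(path).read_text())]
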