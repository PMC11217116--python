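"""Parametric pupil light-response model with IOP-coupled redilation.

The model is the physical hypothesis behind pupillometric tonometry: iris
movement works against the resistance of the anterior-chamber fluid, and
that resistance grows with intraocular pressure (IOP), so the pupil
redilates more slowly after a flash when IOP is higher.

The light response is piecewise exponential — the minimal standard
pupillometry shape with a single interpretable redilation rate:

* dark phase: area stays at the dark-adapted baseline (fraction 1);
* flash: exponential constriction toward ``min_frac`` with time constant
  ``tau_c``;
* recovery: exponential return from the flash-offset value toward
  ``recovery_frac`` with time constant

  .. math:: \\tau_d(\\mathrm{IOP}) = \\tau_\\mathrm{ref}
            \\cdot \\mathrm{IOP} / \\mathrm{IOP}_\\mathrm{ref},

  i.e. the redilation time constant scales linearly with IOP. Linear
  coupling is the simplest form under which a single reference reading
  (one-point calibration) determines the whole rate-to-IOP map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocol import ProtocolConfig
from .series import AreaTimeSeries

__all__ = [
    "PupilResponseParams",
    "NoiseConfig",
    "redilation_tau",
    "area_fraction_at",
    "simulate_area_series",
]


@dataclass(frozen=True)
class PupilResponseParams:
    """Per-eye physiological parameters of the pupil light response.

    Parameters
    ----------
    baseline_area_mm2 : float
        Dark-adapted pupil area, mm² (default 38 mm² ≈ 7 mm diameter).
    min_frac : float
        Fully constricted area as a fraction of baseline, in (0, 1).
    tau_c : float
        Constriction time constant during the flash, seconds.
    tau_ref : float
        Redilation time constant at the reference IOP, seconds.
    iop_ref : float
        Reference IOP at which tau_ref applies, mmHg.
    recovery_frac : float
        Asymptotic recovery level as a fraction of baseline; 1.0 means
        full return to the dark baseline. Values < 1 model a sustained
        post-illumination response.
    """

    baseline_area_mm2: float = 38.0
    min_frac: float = 0.35
    tau_c: float = 0.35
    tau_ref: float = 2.0
    iop_ref: float = 16.0
    recovery_frac: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline_area_mm2 <= 0:
            raise ValueError("baseline_area_mm2 must be > 0")
        if not 0 < self.min_frac < 1:
            raise ValueError("min_frac must be in (0, 1)")
        if not 0 < self.recovery_frac <= 1:
            raise ValueError("recovery_frac must be in (0, 1]")
        if self.min_frac >= self.recovery_frac:
            raise ValueError("min_frac must be < recovery_frac")
        if self.tau_c <= 0 or self.tau_ref <= 0:
            raise ValueError("time constants must be > 0")
        if self.iop_ref <= 0:
            raise ValueError("iop_ref must be > 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement noise on the simulated area series.

    Noise is multiplicative i.i.d. Gaussian per frame (segmentation error
    scales with pupil size): ``area = truth * (1 + eps)`` with
    ``eps ~ N(0, area_noise_frac²)``.
    """

    area_noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.area_noise_frac < 0:
            raise ValueError("area_noise_frac must be >= 0")


def redilation_tau(params: PupilResponseParams, iop: float) -> float:
    """Redilation time constant at a given IOP (linear resistance coupling)."""
    if iop <= 0:
        raise ValueError(f"iop must be > 0, got {iop!r}")
    return params.tau_ref * iop / params.iop_ref


def _fraction(
    t: np.ndarray, params: PupilResponseParams, iop: float, protocol: ProtocolConfig
) -> np.ndarray:
    t_on = protocol.flash_on_s
    t_off = protocol.flash_off_s
    tau_d = redilation_tau(params, iop)

    out = np.ones_like(t, dtype=float)

    flash = (t >= t_on) & (t < t_off)
    out[flash] = params.min_frac + (1.0 - params.min_frac) * np.exp(
        -(t[flash] - t_on) / params.tau_c
    )

    # recovery starts from the value at flash offset -> continuity across
    # the phase boundary by construction
    f_off = params.min_frac + (1.0 - params.min_frac) * math.exp(
        -protocol.flash_s / params.tau_c
    )
    rec = t >= t_off
    out[rec] = params.recovery_frac - (params.recovery_frac - f_off) * np.exp(
        -(t[rec] - t_off) / tau_d
    )
    return out


def area_fraction_at(
    t: float | np.ndarray,
    params: PupilResponseParams,
    iop: float,
    protocol: ProtocolConfig | None = None,
) -> float | np.ndarray:
    """Pupil area at time ``t`` as a fraction of the dark-adapted baseline.

    Parameters
    ----------
    t : float or ndarray
        Time(s) since recording start, seconds; must lie inside the
        recorded window ``[0, protocol.total_s]``.
    params : PupilResponseParams
    iop : float
        Intraocular pressure, mmHg (> 0).
    protocol : ProtocolConfig, optional
        Defaults to the standard 10 s dark / 1.5 s flash / 8 s recovery.

    Returns
    -------
    float or ndarray
        Area fraction in (0, 1]; scalar in, scalar out.
    """
    protocol = protocol or ProtocolConfig()
    arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(arr < 0) or np.any(arr > protocol.total_s):
        raise ValueError(
            f"t must lie within the recorded window [0, {protocol.total_s}] s"
        )
    out = _fraction(arr, params, iop, protocol)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def simulate_area_series(
    params: PupilResponseParams,
    iop: float,
    protocol: ProtocolConfig | None = None,
    noise: NoiseConfig | None = None,
) -> AreaTimeSeries:
    """Simulate a pupil-area recording sampled uniformly at ``protocol.fps``.

    With ``area_noise_frac = 0`` the series equals the closed-form response
    exactly at every timestamp; with noise, areas get i.i.d. multiplicative
    Gaussian perturbations drawn from ``noise.seed``.
    """
    protocol = protocol or ProtocolConfig()
    noise = noise or NoiseConfig()
    n = protocol.n_samples
    t = np.arange(n, dtype=float) / protocol.fps
    frac = _fraction(t, params, iop, protocol)
    area = params.baseline_area_mm2 * frac
    if noise.area_noise_frac > 0:
        rng = np.random.default_rng(noise.seed)
        area = area * (1.0 + noise.area_noise_frac * rng.standard_normal(n))
        area = np.clip(area, 1e-6, None)  # areas must stay positive
    phase = np.array([protocol.phase_of(tk) for tk in t], dtype=object)
    return AreaTimeSeries(
        time_s=t,
        area_mm2=area,
        phase=phase,
        fps=protocol.fps,
        flash_on_s=protocol.flash_on_s,
        flash_off_s=protocol.flash_off_s,
    )
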