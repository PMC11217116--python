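"""Synthetic NIR-like eye frames: the stand-in for the infrared camera.

Frames follow the dark-pupil convention of off-axis NIR pupillometry: the
pupil is the darkest region, surrounded by a brighter iris annulus on a
bright sclera background, plus optional Gaussian sensor noise. Stacks are
written as 8-bit grayscale multi-page TIFF with a JSON sidecar carrying
the protocol, scene and timestamps.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import tifffile

from .protocol import ProtocolConfig
from .series import AreaTimeSeries

__all__ = ["SceneConfig", "FrameStack", "render_frame", "render_sequence", "read_stack"]


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and photometry of the rendered eye scene.

    Gray levels must satisfy ``pupil_gray < iris_gray < sclera_gray``
    (dark-pupil imaging); all pupil radii must fit inside the iris.
    """

    frame_px: tuple[int, int] = (240, 320)  # (height, width)
    pixel_scale_mm: float = 0.05
    pupil_gray: int = 20
    iris_gray: int = 120
    sclera_gray: int = 200
    iris_radius_mm: float = 6.0
    center_jitter_px: float = 0.0
    sensor_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.pupil_gray < self.iris_gray < self.sclera_gray <= 255):
            raise ValueError("require pupil_gray < iris_gray < sclera_gray in [0, 255]")
        if self.pixel_scale_mm <= 0 or self.iris_radius_mm <= 0:
            raise ValueError("pixel_scale_mm and iris_radius_mm must be > 0")
        if self.center_jitter_px < 0 or self.sensor_noise_sd < 0:
            raise ValueError("jitter and noise SD must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["frame_px"] = list(self.frame_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        known = {k: d[k] for k in cls.__dataclass_fields__ if k in d}
        if "frame_px" in known:
            known["frame_px"] = tuple(known["frame_px"])
        return cls(**known)


@dataclass
class FrameStack:
    """A rendered frame sequence plus its acquisition metadata."""

    frames: np.ndarray  # (n, h, w) uint8
    timestamps_s: np.ndarray
    protocol: ProtocolConfig
    scene: SceneConfig

    def __len__(self) -> int:
        return self.frames.shape[0]


def pupil_radius_px(area_mm2: float, scene: SceneConfig) -> float:
    """Pupil radius in pixels implied by an area in mm²."""
    return math.sqrt(area_mm2 / math.pi) / scene.pixel_scale_mm


def render_frame(
    area_mm2: float, scene: SceneConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Render one grayscale frame with a pupil of the given area.

    The pupil is a centered dark disk (optionally jittered), inside an
    iris disk, on a sclera background; i.i.d. Gaussian sensor noise is
    added and the result clipped to [0, 255] uint8.

    Raises
    ------
    ValueError
        If the area is non-positive or the implied pupil radius does not
        fit inside the iris.
    """
    if area_mm2 <= 0:
        raise ValueError("area_mm2 must be > 0")
    r_pupil = pupil_radius_px(area_mm2, scene)
    r_iris = scene.iris_radius_mm / scene.pixel_scale_mm
    if r_pupil >= r_iris:
        raise ValueError(
            f"pupil radius {r_pupil:.1f} px exceeds iris radius {r_iris:.1f} px"
        )
    h, w = scene.frame_px
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if rng is None:
        rng = np.random.default_rng(scene.seed)
    if scene.center_jitter_px > 0:
        cy += rng.normal(0.0, scene.center_jitter_px)
        cx += rng.normal(0.0, scene.center_jitter_px)

    yy, xx = np.ogrid[:h, :w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    img = np.full((h, w), float(scene.sclera_gray))
    img[d2 <= r_iris**2] = scene.iris_gray
    img[d2 <= r_pupil**2] = scene.pupil_gray
    if scene.sensor_noise_sd > 0:
        img = img + rng.normal(0.0, scene.sensor_noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def render_sequence(
    series: AreaTimeSeries,
    scene: SceneConfig,
    protocol: ProtocolConfig | None = None,
    out_path: str | Path | None = None,
) -> FrameStack:
    """Render one frame per series sample; optionally write TIFF + sidecar.

    A single generator seeded with ``scene.seed`` drives jitter and sensor
    noise across the whole sequence, so a fixed seed gives a reproducible
    stack. When ``out_path`` is given, the stack is written as a
    multi-page 8-bit TIFF with a ``<name>.json`` sidecar.
    """
    if len(series) == 0:
        raise ValueError("series must be nonempty")
    protocol = protocol or ProtocolConfig(
        dark_s=series.flash_on_s,
        flash_s=series.flash_off_s - series.flash_on_s,
        recovery_s=max(series.time_s[-1] - series.flash_off_s, 1e-3),
        fps=series.fps,
    )
    rng = np.random.default_rng(scene.seed)
    frames = np.stack(
        [render_frame(a, scene, rng=rng) for a in series.area_mm2], axis=0
    )
    stack = FrameStack(
        frames=frames,
        timestamps_s=np.asarray(series.time_s, dtype=float),
        protocol=protocol,
        scene=scene,
    )
    if out_path is not None:
        write_stack(stack, out_path)
    return stack


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_stack(stack: FrameStack, path: str | Path) -> Path:
    """Write a multi-page 8-bit grayscale TIFF plus JSON sidecar."""
    path = Path(path)
    try:
        tifffile.imwrite(path, stack.frames, photometric="minisblack")
        sidecar = {
            "protocol": stack.protocol.to_dict(),
            "scene": stack.scene.to_dict(),
            "timestamps_s": stack.timestamps_s.tolist(),
        }
        _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    except OSError as exc:
        raise OSError(f"failed writing frame stack to {path}: {exc}") from exc
    return path


def read_stack(path: str | Path) -> FrameStack:
    """Read a TIFF stack written by :func:`write_stack` (with its sidecar)."""
    path = Path(path)
    try:
        frames = tifffile.imread(path)
        meta = json.loads(_sidecar_path(path).read_text())
    except OSError as exc:
        raise OSError(f"failed reading frame stack from {path}: {exc}") from exc
    if frames.ndim == 2:
        frames = frames[None, ...]
    return FrameStack(
        frames=frames,
        timestamps_s=np.asarray(meta["timestamps_s"], dtype=float),
        protocol=ProtocolConfig.from_dict(meta["protocol"]),
        scene=SceneConfig.from_dict(meta["scene"]),
    )
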