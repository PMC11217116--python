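"""Pupil segmentation: grayscale frames -> pupil area time series.

The pipeline per frame is median filter -> threshold -> connected
components -> largest dark component -> optional hole filling -> area by
pixel count times the pixel scale squared. The default threshold is a
three-class multi-Otsu with the darkest class taken as pupil: the scene
histogram is trimodal (pupil / iris / sclera) and a two-class split would
merge pupil and iris into one dark region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import median as median_filter
from skimage.filters import threshold_multiotsu
from skimage.measure import label
from skimage.morphology import footprint_rectangle

from .imaging import FrameStack
from .series import AreaTimeSeries

__all__ = ["SegmentationConfig", "SegmentationResult", "segment_pupil", "extract_series"]

logger = logging.getLogger(__name__)

MAX_MISSING_FRAC = 0.20  # above this a recording is unusable


@dataclass(frozen=True)
class SegmentationConfig:
    """Per-frame segmentation settings.

    ``method='otsu'`` picks the darkest of three multi-Otsu classes
    (illumination-offset invariant); ``method='fixed'`` thresholds at
    ``fixed_threshold`` gray levels.
    """

    method: str = "otsu"
    fixed_threshold: int = 60
    median_filter_px: int = 3
    min_area_px: int = 50
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("otsu", "fixed"):
            raise ValueError("method must be 'otsu' or 'fixed'")
        if not 0 <= self.fixed_threshold <= 255:
            raise ValueError("fixed_threshold must be in [0, 255]")
        if self.median_filter_px < 1 or self.median_filter_px % 2 == 0:
            raise ValueError("median_filter_px must be an odd integer >= 1")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")


@dataclass
class SegmentationResult:
    """Outcome of one frame's segmentation; ``missing`` if no pupil found."""

    area_mm2: float  # NaN when missing
    mask: np.ndarray | None
    centroid: tuple[float, float] | None  # (row, col)

    @property
    def missing(self) -> bool:
        return math.isnan(self.area_mm2)


def _pupil_threshold(img: np.ndarray, config: SegmentationConfig) -> float:
    if config.method == "fixed":
        return float(config.fixed_threshold)
    if img.min() == img.max():  # flat frame: nothing darker than background
        return -1.0
    try:
        thresholds = threshold_multiotsu(img, classes=3)
    except ValueError:  # fewer than 3 gray levels present
        thresholds = threshold_multiotsu(img, classes=2)
    return float(thresholds[0])


def segment_pupil(
    frame: np.ndarray,
    config: SegmentationConfig | None = None,
    pixel_scale_mm: float = 0.05,
) -> SegmentationResult:
    """Segment the pupil in a single grayscale frame.

    Returns a missing-value result (``area_mm2 = NaN``) rather than
    raising when no dark component of at least ``min_area_px`` pixels is
    found; downstream series extraction interpolates isolated dropouts.
    """
    config = config or SegmentationConfig()
    frame = np.asarray(frame)
    if frame.size == 0 or frame.ndim != 2:
        raise ValueError("frame must be a nonempty single-channel image")
    if pixel_scale_mm <= 0:
        raise ValueError("pixel_scale_mm must be > 0")

    if config.median_filter_px > 1:
        fp = footprint_rectangle((config.median_filter_px, config.median_filter_px))
        frame = median_filter(frame, fp)

    thr = _pupil_threshold(frame, config)
    mask = frame <= thr
    if not mask.any():
        return SegmentationResult(float("nan"), None, None)

    labels, n_labels = label(mask, return_num=True)
    if n_labels == 0:
        return SegmentationResult(float("nan"), None, None)
    sizes = np.bincount(labels.ravel())[1:]
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < config.min_area_px:
        return SegmentationResult(float("nan"), None, None)
    pupil = labels == best
    if config.fill_holes:
        pupil = ndimage.binary_fill_holes(pupil)

    n_px = int(pupil.sum())
    rows, cols = np.nonzero(pupil)
    centroid = (float(rows.mean()), float(cols.mean()))
    return SegmentationResult(n_px * pixel_scale_mm**2, pupil, centroid)


def extract_series(
    stack: FrameStack, config: SegmentationConfig | None = None
) -> AreaTimeSeries:
    """Segment every frame of a stack into an :class:`AreaTimeSeries`.

    Missing frames flanked by valid ones are linearly interpolated;
    missing frames at the ends are dropped with a warning. More than 20 %
    missing frames makes the recording unusable.

    Raises
    ------
    ValueError
        If the stack has fewer than 2 frames or too many missing frames.
    """
    config = config or SegmentationConfig()
    if len(stack) < 2:
        raise ValueError("stack must contain at least 2 frames")
    scale = stack.scene.pixel_scale_mm
    areas = np.array(
        [segment_pupil(f, config, scale).area_mm2 for f in stack.frames]
    )
    t = np.asarray(stack.timestamps_s, dtype=float)

    missing = np.isnan(areas)
    if missing.mean() > MAX_MISSING_FRAC:
        raise ValueError(
            f"{missing.mean():.0%} of frames unsegmentable "
            f"(limit {MAX_MISSING_FRAC:.0%}): unusable recording"
        )
    if missing.any():
        valid = ~missing
        interior = missing.copy()
        # leading/trailing dropouts have no flanking pair: drop them
        first, last = np.nonzero(valid)[0][[0, -1]]
        edge = np.zeros_like(missing)
        edge[:first] = missing[:first]
        edge[last + 1 :] = missing[last + 1 :]
        interior &= ~edge
        if interior.any():
            areas[interior] = np.interp(t[interior], t[valid], areas[valid])
        if edge.any():
            logger.warning("dropping %d unsegmentable edge frame(s)", int(edge.sum()))
            keep = ~edge
            t, areas = t[keep], areas[keep]

    protocol = stack.protocol
    phase = np.array([protocol.phase_of(tk) for tk in t], dtype=object)
    return AreaTimeSeries(
        time_s=t,
        area_mm2=areas,
        phase=phase,
        fps=protocol.fps,
        flash_on_s=protocol.flash_on_s,
        flash_off_s=protocol.flash_off_s,
    )
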