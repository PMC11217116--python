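"""Render a synthetic NIR recording and recover the area series by
segmentation.

The full optical chain: pupil model -> grayscale frame stack (dark pupil
on iris/sclera, written as multi-page TIFF) -> per-frame threshold
segmentation -> recovered pupil-area time series, compared against the
ground truth the renderer was fed.
"""

import tempfile
from pathlib import Path

import numpy as np

from pupilpress import (
    PupilResponseParams,
    SceneConfig,
    extract_series,
    render_sequence,
    simulate_area_series,
)

params = PupilResponseParams()
scene = SceneConfig(sensor_noise_sd=3.0, seed=0)

truth = simulate_area_series(params, 16.0)
out = Path(tempfile.mkdtemp()) / "recording.tiff"
stack = render_sequence(truth, scene, out_path=out)
print(f"rendered {len(stack)} frames of {scene.frame_px[0]}x{scene.frame_px[1]} px "
      f"to {out}")

recovered = extract_series(stack)
rel_err = np.abs(recovered.area_mm2 - truth.area_mm2) / truth.area_mm2
print(f"max  per-frame area error: {100 * rel_err.max():.2f} %")
print(f"mean per-frame area error: {100 * rel_err.mean():.2f} %")

# Even with sensor noise, pixel-count segmentation of the dark pupil
# recovers the area to well under the 2 % round-trip budget.
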