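"""Classical hysteresis pre-segmentation.

Used to bootstrap annotation (and as a fast model-free vessel mask):
the volume is first normalized by its local average intensity — the same
box-kernel convolution as the autofluorescence step — to flatten global
intensity gradients, then hysteresis-thresholded: voxels above the high
threshold seed components, voxels above the low threshold survive iff
connected to a seed.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import apply_hysteresis_threshold

from ..preprocess import local_mean
from ..volume import ImageVolume


def hysteresis_preseg(
    volume: ImageVolume,
    low: float,
    high: float,
    k: int = 16,
) -> np.ndarray:
    """Local-mean-normalized hysteresis segmentation.

    ``low``/``high`` are thresholds on the normalized intensity
    (value ÷ local mean); ``k`` is the normalization kernel radius.
    """
    if low > high:
        raise ValueError(f"low ({low}) must not exceed high ({high})")
    m = local_mean(volume, k).data
    normalized = volume.data / np.maximum(m, 1e-12)
    if low == high:
        return normalized > low
    return apply_hysteresis_threshold(normalized, low, high)
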