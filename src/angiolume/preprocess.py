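"""Autofluorescence removal by local-neighborhood peak subtraction.

Cleared-tissue light-sheet stacks carry an autofluorescence (AF)
component that appears in every channel with the same spatial structure
but different intensity, on top of strong global intensity gradients that
rule out any global subtraction. The correction therefore works with
*local* statistics: AF peaks are voxels exceeding the local box-kernel
mean by a configurable number of local standard deviations; inside the
peak mask the AF signal is standardized locally, rescaled to the target
channel's local standard deviation (optionally amplified) and subtracted.
Regions of overwhelming AF (e.g. haemorrhages) are flagged for exclusion
from all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import ImageVolume


@dataclass
class PreprocessParams:
    """Parameters of the AF correction.

    ``k`` is the box-kernel radius in voxels (window edge ``2k+1``);
    ``peak_sd_factor`` is the peak threshold in local standard deviations;
    ``amplify`` scales the subtracted AF estimate for severe cases.
    """

    k: int = 32
    peak_sd_factor: float = 0.2
    amplify: float = 1.0
    severe_af_quantile: float = 0.999
    severe_af_min_size: int = 1000

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be ≥ 1")
        if not 0.05 <= self.peak_sd_factor <= 0.4:
            raise ValueError("peak_sd_factor must lie in [0.05, 0.4]")
        if self.amplify < 1.0:
            raise ValueError("amplify must be ≥ 1")


def _check_kernel(vol: ImageVolume, k: int) -> None:
    if any(2 * k + 1 > 2 * s for s in vol.shape):
        # reflect padding requires the pad width to not exceed the axis extent
        raise ValueError(f"kernel radius {k} too large for volume shape {vol.shape}")


def local_mean(volume: ImageVolume, k: int) -> ImageVolume:
    """Mean over the constant (box) kernel of radius ``k``, reflect-padded."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    _check_kernel(volume, k)
    data = ndimage.uniform_filter(volume.data.astype(np.float64), size=2 * k + 1, mode="reflect")
    return volume.like(data)


def local_sd(volume: ImageVolume, k: int) -> ImageVolume:
    """Standard deviation over the same box kernel, via E[x²] − E[x]²."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    _check_kernel(volume, k)
    x = volume.data.astype(np.float64)
    m = ndimage.uniform_filter(x, size=2 * k + 1, mode="reflect")
    m2 = ndimage.uniform_filter(x * x, size=2 * k + 1, mode="reflect")
    var = np.clip(m2 - m * m, 0.0, None)
    return volume.like(np.sqrt(var))


def detect_af_peaks(af: ImageVolume, params: PreprocessParams) -> np.ndarray:
    """Mask of AF voxels exceeding local mean + ``peak_sd_factor``·local sd.

    A constant volume has zero local sd everywhere and yields an empty
    mask (strict inequality), not an error.
    """
    m = local_mean(af, params.k).data
    s = local_sd(af, params.k).data
    return af.data > m + params.peak_sd_factor * s


def subtract_af(
    target: ImageVolume,
    af: ImageVolume,
    peaks: np.ndarray,
    params: PreprocessParams,
) -> ImageVolume:
    """Subtract the locally standardized AF signal from the target channel.

    Within the peak mask the AF signal is standardized by its local mean
    and sd, rescaled by the *target's* local sd, multiplied by ``amplify``
    and subtracted; the result is clamped at zero. Voxels outside the mask
    are returned untouched.
    """
    if target.data.shape != af.data.shape:
        raise ValueError(f"shape mismatch: target {target.data.shape} vs af {af.data.shape}")
    if not np.any(peaks):
        return target.copy()
    af_m = local_mean(af, params.k).data
    af_s = local_sd(af, params.k).data
    tgt_s = local_sd(target, params.k).data
    with np.errstate(divide="ignore", invalid="ignore"):
        standardized = np.where(af_s > 0, (af.data - af_m) / np.where(af_s > 0, af_s, 1.0), 0.0)
    estimate = params.amplify * standardized * tgt_s
    out = target.data.astype(np.float64).copy()
    out[peaks] = np.clip(out[peaks] - estimate[peaks], 0.0, None)
    return target.like(out)


def mask_severe_af(af: ImageVolume, params: PreprocessParams) -> np.ndarray:
    """Exclusion mask for regions of overwhelming AF.

    Connected components (26-connectivity) of voxels above the
    ``severe_af_quantile`` intensity that contain at least
    ``severe_af_min_size`` voxels.
    """
    thr = np.quantile(af.data, params.severe_af_quantile)
    above = af.data > thr
    if not above.any():
        return above
    labels, n = ndimage.label(above, structure=np.ones((3, 3, 3), bool))
    if n == 0:
        return np.zeros_like(above)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= params.severe_af_min_size) + 1
    return np.isin(labels, keep)


def preprocess_bundle(
    vessel: ImageVolume,
    af: ImageVolume,
    reporter: ImageVolume,
    params: PreprocessParams | None = None,
) -> tuple[ImageVolume, ImageVolume, np.ndarray]:
    """Full AF correction: peak detection once, subtraction from the vessel
    and reporter channels, severe-AF exclusion mask."""
    params = params or PreprocessParams()
    peaks = detect_af_peaks(af, params)
    vessel_c = subtract_af(vessel, af, peaks, params)
    reporter_c = subtract_af(reporter, af, peaks, params)
    exclusion = mask_severe_af(af, params)
    return vessel_c, reporter_c, exclusion
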