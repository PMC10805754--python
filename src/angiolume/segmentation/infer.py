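"""Chunked whole-volume inference with Hann-window stitching.

Whole light-sheet volumes do not fit through the network at once, so
prediction runs on overlapping chunks whose outputs are blended with a
separable periodic Hann window. At 50% overlap the shifted windows sum to
an exact constant along every axis (partition of unity), so blending
introduces no seams; an identity model reproduces its input to float
precision. Border chunks come from reflect padding which is cropped after
stitching.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..volume import ImageVolume


def hann_window_1d(n: int) -> np.ndarray:
    """Periodic Hann samples at half-integer offsets: shifted copies at
    stride n/2 sum to exactly 1."""
    i = np.arange(n)
    return 0.5 - 0.5 * np.cos(2.0 * np.pi * (i + 0.5) / n)


def chunked_inference(
    model,
    volume: ImageVolume | np.ndarray,
    chunk: int = 128,
    overlap: float = 0.5,
) -> np.ndarray:
    """Predict a full volume from half-overlapping chunks.

    ``model`` is any callable mapping a ``(c, c, c)`` array to an array of
    the same shape (e.g. ``UNet3D.predict``).
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    data = data.astype(np.float64)
    if overlap != 0.5:
        raise ValueError("only 50% overlap is supported (partition of unity)")
    stride = chunk // 2
    if any(s < 1 for s in data.shape):
        raise ValueError("empty volume")

    # reflect-pad so that (padded − chunk) is a multiple of the stride and a
    # half-chunk margin puts full blending weight on every original voxel
    pads = []
    for s in data.shape:
        right = int(np.ceil(s / stride)) * stride + chunk - stride - s
        if max(stride, right) > s:  # reflect cannot exceed the axis extent
            raise ValueError(f"chunk {chunk} too large for axis extent {s}")
        pads.append((stride, right))
    padded = np.pad(data, pads, mode="reflect")

    w1 = hann_window_1d(chunk)
    w3 = w1[:, None, None] * w1[None, :, None] * w1[None, None, :]
    num = np.zeros_like(padded)
    den = np.zeros_like(padded)
    fn = model.predict if hasattr(model, "predict") else model
    starts = [range(0, ps - chunk + 1, stride) for ps in padded.shape]
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (slice(z0, z0 + chunk), slice(y0, y0 + chunk), slice(x0, x0 + chunk))
                pred = np.asarray(fn(padded[sl]))
                num[sl] += pred * w3
                den[sl] += w3
    out = num / np.maximum(den, 1e-12)
    crop = tuple(slice(p[0], p[0] + s) for p, s in zip(pads, data.shape))
    return out[crop]


def postprocess(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarize a probability map and fill enclosed 3D cavities."""
    seg = np.asarray(prob) > threshold
    return ndimage.binary_fill_holes(seg)
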