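"""Voxel-grid containers with physical spacing metadata.

Every stage of the pipeline operates on :class:`ImageVolume`: a 3D scalar
grid in (z, y, x) axis order with per-axis spacing in micrometres and a
channel role tag. Light-sheet stacks are typically anisotropic (the z step
exceeds the in-plane pixel size), so spacing travels with the data and all
physical quantities (distances, volumes) are derived from it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

VALID_ROLES = ("vessel", "autofluorescence", "reporter", "mask", "generic")


@dataclass
class ImageVolume:
    """A 3D scalar voxel grid with physical spacing.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``.
    spacing
        Voxel size in micrometres per axis, ``(dz, dy, dx)``.
    role
        Channel role tag, one of :data:`VALID_ROLES`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    role: str = "generic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        if self.role not in VALID_ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {VALID_ROLES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def astype(self, dtype) -> "ImageVolume":
        return ImageVolume(self.data.astype(dtype), self.spacing, self.role)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing, self.role)

    def like(self, data: np.ndarray) -> "ImageVolume":
        """New volume with the same spacing/role but different data."""
        return ImageVolume(data, self.spacing, self.role)


@dataclass
class VolumeBundle:
    """The three channels of one specimen plus optional masks."""

    vessel: ImageVolume
    autofluorescence: ImageVolume
    reporter: ImageVolume
    masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {self.vessel.shape, self.autofluorescence.shape, self.reporter.shape}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")


def write_tiff(path: str | Path, vol: ImageVolume) -> None:
    """Write a volume as TIFF with spacing stored in the ImageJ metadata."""
    path = Path(path)
    dz, dy, dx = vol.spacing
    tifffile.imwrite(
        path,
        np.asarray(vol.data),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )


def read_tiff(path: str | Path, role: str = "generic") -> ImageVolume:
    """Read a TIFF stack; spacing is recovered from ImageJ metadata if present."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        dz = dy = dx = 1.0
        if tf.imagej_metadata and "spacing" in tf.imagej_metadata:
            dz = float(tf.imagej_metadata["spacing"])
        page = tf.pages[0]
        if "XResolution" in page.tags:
            num, den = page.tags["XResolution"].value
            if num:
                dx = den / num
        if "YResolution" in page.tags:
            num, den = page.tags["YResolution"].value
            if num:
                dy = den / num
    return ImageVolume(data, (dz, dy, dx), role)


def write_zarr(path: str | Path, vol: ImageVolume) -> None:
    import zarr

    arr = zarr.open_array(str(path), mode="w", shape=vol.data.shape, dtype=vol.data.dtype)
    arr[:] = vol.data
    arr.attrs["spacing_um"] = list(vol.spacing)
    arr.attrs["role"] = vol.role


def read_zarr(path: str | Path) -> ImageVolume:
    import zarr

    arr = zarr.open_array(str(path), mode="r")
    spacing = tuple(arr.attrs.get("spacing_um", (1.0, 1.0, 1.0)))
    role = arr.attrs.get("role", "generic")
    return ImageVolume(arr[:], spacing, role)


def save_mask_json_legend(path: str | Path, legend: dict[int, str]) -> None:
    Path(path).write_text(json.dumps({str(k): v for k, v in legend.items()}, indent=2))
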