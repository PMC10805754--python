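"""Synthetic multi-channel vascular phantoms with known ground truth.

Emulates the salient properties of cleared-brain light-sheet volumes of
tumor-bearing mice:

* tubular vessel networks with radii from capillaries to large abnormal
  vessels; large vessels carry *wall-only* endothelial signal (no luminal
  fill), which is exactly the failure mode the lumen-aware segmentation
  loss exists for;
* an autofluorescence component that appears in every channel with the
  same spatial distribution but channel-specific intensity ratios;
* a hypoxia-reporter channel whose intensity is low at baseline inside
  the tumor and high in tumor voxels far from the nearest vessel;
* a denser, larger-caliber, more tortuous vascular bed inside an
  ellipsoidal tumor subvolume;
* anisotropic voxel spacing (z step larger than in-plane), a global
  multiplicative intensity gradient, Gaussian blur and additive noise.

All randomness flows from one integer seed through ``numpy``'s
``SeedSequence``, so identical spec + seed yields bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .volume import ImageVolume, VolumeBundle, write_tiff


@dataclass
class PhantomSpec:
    """Generative parameters of one synthetic specimen.

    Spatial quantities are in micrometres; ``shape`` is in voxels,
    (z, y, x) order. Defaults produce a ~96 µm³ cube at light-sheet-like
    anisotropy (1×1 µm in-plane, 3 µm z-step).
    """

    shape: tuple[int, int, int] = (32, 96, 96)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    n_vessels: int = 14
    radius_range_healthy: tuple[float, float] = (2.0, 4.0)
    radius_range_tumor: tuple[float, float] = (4.0, 10.0)
    hollow_radius_threshold: float = 6.0
    tumor_fraction: float = 0.25
    tortuosity_tumor: float = 0.3
    af_density: int = 4
    af_channel_ratios: dict = field(
        default_factory=lambda: {"vessel": 0.5, "af": 1.0, "reporter": 0.5}
    )
    hypoxia_distance_threshold: float = 20.0
    hypoxic_fraction_target: float | None = None
    noise_sd: float = 0.02
    bias_field_amplitude: float = 0.2
    tumor_vessel_boost: float = 3.0
    seed: int = 0

    # fixed rendering constants (documented in the methods note)
    wall_thickness: float = 2.0          # µm, hollow-vessel wall
    tissue_level: float = 0.1            # healthy-tissue AF floor (vessel channel)
    vessel_intensity: float = 1.0
    # reporter channel: parenchyma AF floor at 0.5× the tissue level, a small
    # normoxic-tumor overshoot from promoter background expression, and a
    # hypoxic level ≥3× the floor, so the healthy-mean + 1.5σ rule lands
    # between the normoxic and hypoxic modes
    reporter_healthy: float = 0.05
    reporter_tumor_baseline: float = 0.07
    reporter_hypoxic: float = 0.5
    # myelinated parenchyma shows spatially textured autofluorescence in the
    # reporter band; tumor tissue displaces it. This texture is what makes
    # the healthy-tissue σ (and hence the mean + 1.5σ threshold) meaningful.
    reporter_texture_sd: float = 0.05

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        for name in ("radius_range_healthy", "radius_range_tumor"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive interval, got ({lo}, {hi})")
        if not 0 < self.tumor_fraction < 1:
            raise ValueError("tumor_fraction must lie in (0, 1)")
        if any(r <= 0 for r in self.af_channel_ratios.values()):
            raise ValueError("all af_channel_ratios must be positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")
        extent = [s * d for s, d in zip(self.shape, self.spacing)]
        if self.n_vessels > 0 and min(extent) <= 2 * self.radius_range_healthy[0]:
            raise ValueError(
                f"volume extent {extent} µm too small to host a tube of radius "
                f"{self.radius_range_healthy[0]} µm"
            )


@dataclass
class Centerline:
    """One vessel's centerline: points in µm (z, y, x) with per-point radius."""

    points_um: np.ndarray  # (N, 3)
    radii_um: np.ndarray   # (N,)
    in_tumor: bool = False


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: masks plus the generative centerlines."""

    vessel_mask: np.ndarray
    centerlines: list[Centerline]
    tumor_mask: np.ndarray
    hypoxic_mask: np.ndarray
    af_mask: np.ndarray
    af_field: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)


def _paint_tubes(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    centerlines: list[Centerline],
    inner_margin: float = 0.0,
) -> np.ndarray:
    """Rasterize tubes as a boolean mask.

    With ``inner_margin`` > 0 the painted radius at each point is reduced by
    that many µm (used to carve out the lumen of wall-only vessels).
    """
    mask = np.zeros(shape, dtype=bool)
    sp = np.asarray(spacing)
    for cl in centerlines:
        for p, r in zip(cl.points_um, cl.radii_um):
            r_eff = r - inner_margin
            if r_eff <= 0:
                continue
            center_vox = p / sp
            lo = np.maximum(np.floor(center_vox - r_eff / sp).astype(int), 0)
            hi = np.minimum(np.ceil(center_vox + r_eff / sp).astype(int) + 1, shape)
            if np.any(lo >= hi):
                continue
            zz, yy, xx = np.meshgrid(
                (np.arange(lo[0], hi[0]) - center_vox[0]) * sp[0],
                (np.arange(lo[1], hi[1]) - center_vox[1]) * sp[1],
                (np.arange(lo[2], hi[2]) - center_vox[2]) * sp[2],
                indexing="ij",
            )
            ball = zz * zz + yy * yy + xx * xx <= r_eff * r_eff
            mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball
            if inner_margin == 0.0:
                # the voxel nearest each centerline point is always foreground,
                # even when the radius is small relative to the z step
                nearest = np.clip(np.round(center_vox).astype(int), 0, np.asarray(shape) - 1)
                mask[tuple(nearest)] = True
    return mask


def _tumor_ellipsoid(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Ellipsoidal tumor mask occupying ~tumor_fraction of the volume."""
    shape = np.asarray(spec.shape)
    sp = np.asarray(spec.spacing)
    extent = shape * sp
    total = float(np.prod(extent))
    target = spec.tumor_fraction * total
    # random axis ratios, then scale to hit the target volume of 4/3·π·abc
    ratios = rng.uniform(0.75, 1.3, size=3)
    scale = (target / (4.0 / 3.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    semi = np.minimum(ratios * scale, extent / 2.0 - sp)
    center = extent / 2.0 + rng.uniform(-0.08, 0.08, size=3) * extent
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]) * sp[0],
        np.arange(shape[1]) * sp[1],
        np.arange(shape[2]) * sp[2],
        indexing="ij",
    )
    d = (
        ((zz - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((xx - center[2]) / semi[2]) ** 2
    )
    return d <= 1.0


def _vessel_path(
    spec: PhantomSpec,
    rng: np.random.Generator,
    anchor: np.ndarray,
    in_tumor: bool,
) -> Centerline | None:
    """Smooth polyline through jittered control points, with sinusoidal
    transverse waviness for tumor vessels.

    Healthy vessels traverse the volume; tumor-anchored vessels are
    confined to the tumor neighborhood (~2.5 tumor radii), mirroring the
    locally recruited tumor vascular bed.
    """
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    if in_tumor:
        r_tumor = (3.0 * spec.tumor_fraction * float(np.prod(extent)) / (4.0 * np.pi)) ** (1.0 / 3.0)
        length = min(2.5 * r_tumor, 0.9 * float(np.linalg.norm(extent)))
    else:
        length = 0.9 * float(np.linalg.norm(extent))
    step = 15.0
    n_ctrl = max(int(length / step), 4)
    t = np.linspace(-length / 2.0, length / 2.0, n_ctrl)
    jitter_sd = 2.0 if not in_tumor else 3.0
    ctrl = anchor[None, :] + t[:, None] * direction[None, :]
    ctrl += rng.normal(scale=jitter_sd, size=ctrl.shape)
    spl = CubicSpline(t, ctrl, axis=0)
    dense_t = np.arange(t[0], t[-1], 0.75 * min(spec.spacing))
    pts = spl(dense_t)

    if in_tumor and spec.tortuosity_tumor > 0:
        # two transverse sinusoids give a corkscrew-like abnormal course
        e1 = np.cross(direction, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(direction, [0.0, 1.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(direction, e1)
        amp = spec.tortuosity_tumor * 15.0
        period = 40.0
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        s = dense_t - dense_t[0]
        pts = (
            pts
            + amp * np.sin(2 * np.pi * s / period + phase1)[:, None] * e1[None, :]
            + amp * np.cos(2 * np.pi * s / period + phase2)[:, None] * e2[None, :]
        )

    rlo, rhi = spec.radius_range_tumor if in_tumor else spec.radius_range_healthy
    base_r = rng.uniform(rlo, rhi)
    radii = base_r * (1.0 + 0.05 * np.sin(2 * np.pi * np.arange(len(pts)) / 60.0))

    inside = np.all((pts >= 0) & (pts < extent[None, :] - 1e-9), axis=1)
    if inside.sum() < 2:
        return None
    return Centerline(pts[inside], radii[inside], in_tumor=in_tumor)


def generate_vessel_tree(spec: PhantomSpec) -> PhantomTruth:
    """Generate ground-truth vasculature, tumor, hypoxia and AF structure.

    Tumor vessels are anchored preferentially inside the tumor mask (factor
    ``tumor_vessel_boost``) and drawn from the tumor radius range with
    sinusoidal waviness. The hypoxic mask is exactly the set of tumor voxels
    whose Euclidean distance to the nearest vessel voxel exceeds
    ``hypoxia_distance_threshold`` (or the distance quantile matching
    ``hypoxic_fraction_target`` when that is set).
    """
    ss = np.random.SeedSequence([int(spec.seed), 0])
    rng = np.random.default_rng(ss)
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)

    tumor_mask = _tumor_ellipsoid(spec, rng)

    centerlines: list[Centerline] = []
    sp = np.asarray(spec.spacing)
    n_placed = 0
    attempts = 0
    while n_placed < spec.n_vessels and attempts < 50 * max(spec.n_vessels, 1):
        attempts += 1
        anchor = rng.uniform(0, 1, size=3) * extent
        vox = np.minimum((anchor / sp).astype(int), np.asarray(spec.shape) - 1)
        in_tumor = bool(tumor_mask[tuple(vox)])
        # rejection step makes the tumor bed ~boost× denser than healthy tissue
        if not in_tumor and rng.uniform() < 1.0 - 1.0 / spec.tumor_vessel_boost:
            continue
        cl = _vessel_path(spec, rng, anchor, in_tumor)
        if cl is None:
            continue
        centerlines.append(cl)
        n_placed += 1

    vessel_mask = _paint_tubes(spec.shape, spec.spacing, centerlines)

    # hypoxia: tumor voxels far from any vessel
    if vessel_mask.any():
        dist = ndimage.distance_transform_edt(~vessel_mask, sampling=spec.spacing)
    else:
        dist = np.full(spec.shape, np.inf)
    thr = spec.hypoxia_distance_threshold
    if spec.hypoxic_fraction_target is not None and tumor_mask.any():
        d_in = dist[tumor_mask]
        d_in = d_in[np.isfinite(d_in)]
        if d_in.size:
            thr = float(np.quantile(d_in, 1.0 - spec.hypoxic_fraction_target))
    hypoxic_mask = tumor_mask & (dist > thr)

    # autofluorescent blobs (Gaussian profiles; mask at half maximum)
    af_field = np.zeros(spec.shape, dtype=np.float32)
    zz, yy, xx = np.meshgrid(
        np.arange(spec.shape[0]) * sp[0],
        np.arange(spec.shape[1]) * sp[1],
        np.arange(spec.shape[2]) * sp[2],
        indexing="ij",
    )
    for _ in range(spec.af_density):
        c = rng.uniform(0.1, 0.9, size=3) * extent
        sigma = rng.uniform(4.0, 9.0)
        amp = rng.uniform(0.8, 1.5)
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        af_field += amp * np.exp(-d2 / (2 * sigma**2))
    af_mask = af_field > 0.5 * af_field.max() if spec.af_density > 0 else np.zeros(spec.shape, bool)

    return PhantomTruth(
        vessel_mask=vessel_mask,
        centerlines=centerlines,
        tumor_mask=tumor_mask,
        hypoxic_mask=hypoxic_mask,
        af_mask=af_mask,
        af_field=af_field,
        spacing=spec.spacing,
    )


def render_channels(truth: PhantomTruth, spec: PhantomSpec) -> VolumeBundle:
    """Render vessel / autofluorescence / reporter channels from ground truth.

    Vessels whose radius exceeds ``hollow_radius_threshold`` contribute
    wall-only signal (lumen carved out at ``wall_thickness``); all channels
    share the AF field scaled by ``af_channel_ratios``; a multiplicative
    linear bias field and additive Gaussian noise are applied last.
    """
    if truth.vessel_mask.shape != tuple(spec.shape):
        raise ValueError("truth shape inconsistent with spec shape")
    ss = np.random.SeedSequence([int(spec.seed), 1])
    rng = np.random.default_rng(ss)
    shape = spec.shape
    sp = np.asarray(spec.spacing)

    hollow = [cl for cl in truth.centerlines if cl.radii_um.max() > spec.hollow_radius_threshold]
    solid = [cl for cl in truth.centerlines if cl.radii_um.max() <= spec.hollow_radius_threshold]
    signal = _paint_tubes(shape, spec.spacing, solid)
    if hollow:
        full = _paint_tubes(shape, spec.spacing, hollow)
        inner = _paint_tubes(shape, spec.spacing, hollow, inner_margin=spec.wall_thickness)
        signal |= full & ~inner

    blur_vox = 1.0 / sp  # ≈1 µm PSF
    vessel = spec.tissue_level + spec.vessel_intensity * signal.astype(np.float32)
    vessel = ndimage.gaussian_filter(vessel, sigma=blur_vox)

    af = 0.5 * spec.tissue_level + spec.af_channel_ratios["af"] * truth.af_field

    reporter = np.full(shape, spec.reporter_healthy, dtype=np.float64)
    reporter[truth.tumor_mask] = spec.reporter_tumor_baseline
    reporter[truth.hypoxic_mask] = spec.reporter_hypoxic
    # sharper transition than the vessel channel: the hypoxia front is a
    # tissue property, not an optical one
    reporter = ndimage.gaussian_filter(reporter, sigma=0.5 * blur_vox)
    if spec.reporter_texture_sd > 0:
        tex = ndimage.gaussian_filter(rng.normal(size=shape), sigma=4.0)
        tex *= spec.reporter_texture_sd / max(tex.std(), 1e-12)
        healthy_weight = 1.0 - ndimage.gaussian_filter(truth.tumor_mask.astype(np.float64), 2.0)
        reporter = reporter + tex * healthy_weight

    # shared AF structure in every channel, channel-specific intensity ratio
    vessel = vessel + spec.af_channel_ratios["vessel"] * truth.af_field
    reporter = reporter + spec.af_channel_ratios["reporter"] * truth.af_field

    if spec.bias_field_amplitude > 0:
        g = rng.normal(size=3)
        g /= np.linalg.norm(g)
        zz, yy, xx = np.meshgrid(
            np.linspace(-0.5, 0.5, shape[0]),
            np.linspace(-0.5, 0.5, shape[1]),
            np.linspace(-0.5, 0.5, shape[2]),
            indexing="ij",
        )
        bias = 1.0 + spec.bias_field_amplitude * (g[0] * zz + g[1] * yy + g[2] * xx)
        vessel = vessel * bias
        af = af * bias
        reporter = reporter * bias

    out = []
    for arr, role in ((vessel, "vessel"), (af, "autofluorescence"), (reporter, "reporter")):
        if spec.noise_sd > 0:
            arr = arr + rng.normal(scale=spec.noise_sd, size=shape)
        out.append(ImageVolume(np.clip(arr, 0, None).astype(np.float32), spec.spacing, role))
    return VolumeBundle(vessel=out[0], autofluorescence=out[1], reporter=out[2])


@dataclass
class PhantomDataset:
    """One rendered specimen of a synthetic cohort."""

    animal_id: str
    group: str
    spec: PhantomSpec
    truth: PhantomTruth
    channels: VolumeBundle


_GROUP_EFFECT_KEYS = {"caliber_scale", "hypoxic_fraction_target", "tumor_volume_scale"}


def generate_cohort(
    n_per_group: int,
    group_effects: dict[str, dict],
    base_spec: PhantomSpec,
) -> tuple[list[PhantomDataset], "pandas.DataFrame"]:
    """Generate a labeled multi-group cohort with per-animal seeds.

    ``group_effects`` maps a group label to perturbations of the base spec:
    ``caliber_scale`` multiplies the tumor radius range,
    ``tumor_volume_scale`` multiplies the tumor volume fraction and
    ``hypoxic_fraction_target`` pins the generative hypoxic fraction.
    Returns the datasets plus the generative parameter table used by
    recovery tests.
    """
    import pandas as pd

    if n_per_group < 1:
        raise ValueError("n_per_group must be ≥ 1")
    datasets: list[PhantomDataset] = []
    rows = []
    for gi, (group, effects) in enumerate(group_effects.items()):
        unknown = set(effects) - _GROUP_EFFECT_KEYS
        if unknown:
            raise KeyError(f"unknown group effect keys {sorted(unknown)} for group {group!r}")
        for j in range(n_per_group):
            seed = int(np.random.SeedSequence([int(base_spec.seed), gi, j]).generate_state(1)[0] % (2**31))
            caliber = float(effects.get("caliber_scale", 1.0))
            vol_scale = float(effects.get("tumor_volume_scale", 1.0))
            hypo_target = effects.get("hypoxic_fraction_target", base_spec.hypoxic_fraction_target)
            rlo, rhi = base_spec.radius_range_tumor
            spec = replace(
                base_spec,
                radius_range_tumor=(rlo * caliber, rhi * caliber),
                tumor_fraction=float(np.clip(base_spec.tumor_fraction * vol_scale, 1e-3, 0.9)),
                hypoxic_fraction_target=hypo_target,
                seed=seed,
            )
            truth = generate_vessel_tree(spec)
            channels = render_channels(truth, spec)
            animal_id = f"{group}-{j:02d}"
            datasets.append(PhantomDataset(animal_id, group, spec, truth, channels))
            rows.append(
                {
                    "animal_id": animal_id,
                    "group": group,
                    "seed": seed,
                    "caliber_scale": caliber,
                    "tumor_volume_scale": vol_scale,
                    "hypoxic_fraction_target": hypo_target,
                    "tumor_voxels": int(truth.tumor_mask.sum()),
                    "hypoxic_voxels": int(truth.hypoxic_mask.sum()),
                    "vessel_voxels": int(truth.vessel_mask.sum()),
                }
            )
    return datasets, pd.DataFrame(rows)


def save_phantom(out_dir: str | Path, truth: PhantomTruth, channels: VolumeBundle, spec: PhantomSpec) -> None:
    """Write channels and truth bundle (masks as TIFF, metadata as JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tiff(out / "vessel.tif", channels.vessel)
    write_tiff(out / "autofluorescence.tif", channels.autofluorescence)
    write_tiff(out / "reporter.tif", channels.reporter)
    for name, mask in (
        ("vessel_mask", truth.vessel_mask),
        ("tumor_mask", truth.tumor_mask),
        ("hypoxic_mask", truth.hypoxic_mask),
        ("af_mask", truth.af_mask),
    ):
        write_tiff(out / f"truth_{name}.tif", ImageVolume(mask.astype(np.uint8), spec.spacing, "mask"))
    meta = {
        "spec": {k: v for k, v in vars(spec).items() if not isinstance(v, np.ndarray)},
        "centerlines": [
            {"points_um": cl.points_um.tolist(), "radii_um": cl.radii_um.tolist(), "in_tumor": cl.in_tumor}
            for cl in truth.centerlines
        ],
    }
    (out / "truth.json").write_text(json.dumps(meta, default=lambda o: list(o) if isinstance(o, tuple) else o))
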