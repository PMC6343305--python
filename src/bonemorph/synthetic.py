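"""Synthetic specimens, calibration scans, and CBCT-degraded counterparts.

Every generator is a pure function of its seed so downstream stages can be
tested against a known ground truth without any external data.

The trabecular structure model is a thresholded Gaussian random field:
seeded white noise is smoothed with an isotropic Gaussian whose SD sets
the feature (trabecula) size, then thresholded at the quantile that
realises the requested bone volume fraction exactly (to the nearest
achievable voxel count).  CBCT acquisition is emulated phenomenologically:
a linear axial shading field, a Gaussian point-spread blur, integer
block-average downsampling, and additive noise.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi

from .volume import BinaryVolume, GrayVolume, mm_to_voxels

__all__ = [
    "PhantomSpec",
    "IntensityModel",
    "DegradationSpec",
    "CalibrationPhantomSpec",
    "CohortSpecimen",
    "generate_trabecular_phantom",
    "pad_top",
    "embed_anchor_ball",
    "anchor_ball_center",
    "generate_calibration_scan",
    "degrade_to_cbct",
    "generate_cohort",
]


@dataclass
class PhantomSpec:
    """Geometry and structure of one synthetic cancellous-bone cuboid.

    ``shape_mm`` is (x, y, z) physical extent; the generated grid is
    indexed (z, y, x).
    """

    shape_mm: tuple[float, float, float]
    target_bvtv: float
    feature_sigma_mm: float
    voxel_mm: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape_mm) != 3 or any(s <= 0 for s in self.shape_mm):
            raise ValueError(f"shape_mm must be 3 positive extents, got {self.shape_mm}")
        if not (0.0 < self.target_bvtv < 1.0):
            raise ValueError(f"target_bvtv must be in (0,1), got {self.target_bvtv}")
        if not self.feature_sigma_mm > self.voxel_mm:
            raise ValueError("feature_sigma_mm must exceed voxel_mm")
        if not self.voxel_mm > 0:
            raise ValueError("voxel_mm must be > 0")
        if any(mm_to_voxels(s, self.voxel_mm) < 10 for s in self.shape_mm):
            raise ValueError("degenerate spec: every extent must be >= 10 voxels")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        sx, sy, sz = self.shape_mm
        return (mm_to_voxels(sz, self.voxel_mm),
                mm_to_voxels(sy, self.voxel_mm),
                mm_to_voxels(sx, self.voxel_mm))


@dataclass
class IntensityModel:
    """Mean grayscale response per material plus per-voxel texture noise."""

    bone_gv: float = 180.0
    marrow_gv: float = 60.0
    air_gv: float = 0.0
    texture_sigma: float = 5.0

    def __post_init__(self) -> None:
        if not (self.air_gv < self.marrow_gv < self.bone_gv):
            raise ValueError("require air_gv < marrow_gv < bone_gv")
        if self.texture_sigma < 0:
            raise ValueError("texture_sigma must be >= 0")


@dataclass
class DegradationSpec:
    """Micro-resolution -> CBCT-resolution degradation parameters."""

    psf_sigma_mm: float = 0.2
    downsample_factor: int = 5
    noise_sigma: float = 6.0
    axial_shading_amplitude: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (isinstance(self.downsample_factor, (int, np.integer))
                and self.downsample_factor >= 1):
            raise ValueError("downsample_factor must be an integer >= 1")
        if self.psf_sigma_mm < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.axial_shading_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")


@dataclass
class CalibrationPhantomSpec:
    """Multi-insert density calibration phantom (mg HA/cm^3)."""

    densities: tuple[float, ...] = (0.0, 200.0, 400.0, 800.0)
    insert_radius_mm: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = tuple(float(x) for x in self.densities)
        if len(d) < 2:
            raise ValueError("need >= 2 densities")
        if d[0] != 0.0:
            raise ValueError("first density must be 0")
        if any(b <= a for a, b in zip(d, d[1:])) or any(x < 0 for x in d):
            raise ValueError("densities must be non-negative and strictly increasing")
        if self.insert_radius_mm <= 0:
            raise ValueError("insert_radius_mm must be > 0")
        self.densities = d


@dataclass
class CohortSpecimen:
    specimen_id: str
    target_bvtv: float
    truth: BinaryVolume
    micro: GrayVolume
    cbct: GrayVolume


def generate_trabecular_phantom(
    spec: PhantomSpec,
    intensity: Optional[IntensityModel] = None,
    air_pocket_fraction: float = 0.2,
) -> tuple[GrayVolume, BinaryVolume]:
    """Generate one specimen: micro-resolution grayscale plus ground truth.

    The ground truth mask realises ``target_bvtv`` to the nearest
    achievable voxel count (exact-count quantile thresholding of the
    smoothed field).  The grayscale assigns material means, renders a
    random subset of enclosed background pockets as air, adds texture
    noise, then applies a mild scanner-level blur (SD = 0.5 voxel).
    """
    intensity = intensity or IntensityModel()
    rng = np.random.default_rng(spec.seed)
    shape = spec.grid_shape
    n_total = int(np.prod(shape))

    field_ = ndi.gaussian_filter(
        rng.standard_normal(shape), spec.feature_sigma_mm / spec.voxel_mm
    )
    k = int(round(spec.target_bvtv * n_total))
    k = min(max(k, 1), n_total - 1)
    flat = field_.ravel()
    top = np.argpartition(flat, n_total - k)[n_total - k:]
    mask = np.zeros(n_total, dtype=bool)
    mask[top] = True
    mask = mask.reshape(shape)

    gray = np.where(mask, intensity.bone_gv, intensity.marrow_gv).astype(np.float64)

    # Render some enclosed background pockets as air so that air-removal
    # has a physical substrate; the ambient (largest) background component
    # stays marrow.
    labels, n_comp = ndi.label(~mask)
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        pockets = np.flatnonzero(sizes < sizes.max()) + 1
        n_pick = int(round(air_pocket_fraction * pockets.size))
        if n_pick > 0:
            picked = rng.choice(pockets, size=n_pick, replace=False)
            gray[np.isin(labels, picked)] = intensity.air_gv

    if intensity.texture_sigma > 0:
        gray += rng.normal(0.0, intensity.texture_sigma, size=shape)
    gray = ndi.gaussian_filter(gray, 0.5)

    return (
        GrayVolume(data=gray.astype(np.float32), voxel_mm=spec.voxel_mm,
                   modality="synthetic"),
        BinaryVolume(mask=mask, voxel_mm=spec.voxel_mm, provenance="truth"),
    )


def pad_top(vol: GrayVolume, pad_mm: float, fill: float) -> GrayVolume:
    """Prepend constant-intensity slices (air headroom) before slice 0."""
    n = mm_to_voxels(pad_mm, vol.voxel_mm)
    data = np.pad(vol.data, ((n, 0), (0, 0), (0, 0)), constant_values=fill)
    return vol.with_data(data.astype(vol.data.dtype))


def anchor_ball_center(
    shape: tuple[int, int, int], radius_mm: float, voxel_mm: float, surface_z: int
) -> tuple[float, float, float]:
    """Centre (z, y, x) of a ball of the given radius resting on the top
    surface, on the lateral central axis."""
    r_vox = radius_mm / voxel_mm
    return (surface_z - 1 - r_vox, (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0)


def embed_anchor_ball(
    vol: GrayVolume,
    radius_mm: float,
    intensity_gv: float,
    surface_z: Optional[int] = None,
) -> GrayVolume:
    """Render an opaque sphere resting on the specimen top surface.

    The sphere sits on the lateral central axis with its lowest voxel one
    slice above ``surface_z`` (auto-detected from slice medians when not
    given).  Voxels outside the sphere are untouched.
    """
    from .volume_io import find_top_surface  # local import: io depends on volume only

    if surface_z is None:
        surface_z = find_top_surface(vol)
    r_vox = radius_mm / vol.voxel_mm
    cz, cy, cx = anchor_ball_center(vol.shape, radius_mm, vol.voxel_mm, surface_z)
    if cz - r_vox < 0:
        raise ValueError(
            f"ball radius {radius_mm} mm does not fit above surface_z={surface_z}"
        )
    if r_vox > min(vol.shape[1], vol.shape[2]) / 2.0:
        raise ValueError("ball radius too large for volume cross-section")

    z = np.arange(vol.shape[0])[:, None, None]
    y = np.arange(vol.shape[1])[None, :, None]
    x = np.arange(vol.shape[2])[None, None, :]
    ball = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r_vox * r_vox
    data = vol.data.copy()
    data[ball] = intensity_gv
    return vol.with_data(data)


def generate_calibration_scan(
    spec: CalibrationPhantomSpec,
    intensity_slope: float,
    intensity_intercept: float,
    noise_sigma: float,
    voxel_mm: float = 0.1,
) -> list[tuple[float, float]]:
    """Mean grayscale per insert of a simulated HA calibration phantom.

    Each insert's voxels are drawn around the linear density response and
    averaged; pairs are returned in density order.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(spec.seed)
    r_vox = spec.insert_radius_mm / voxel_mm
    n_vox = max(1, int(round(4.0 / 3.0 * np.pi * r_vox**3)))
    pairs = []
    for density in spec.densities:
        mean_gv = intensity_intercept + intensity_slope * density
        if noise_sigma > 0:
            mean_gv += float(rng.normal(0.0, noise_sigma, size=n_vox).mean())
        pairs.append((float(density), float(mean_gv)))
    return pairs


def degrade_to_cbct(vol: GrayVolume, spec: DegradationSpec) -> GrayVolume:
    """Degrade a micro-resolution volume to CBCT resolution.

    Pipeline, in order: (1) multiply by the axial shading field
    ``1 + a*(2z/Z - 1)``; (2) Gaussian PSF blur; (3) block-average
    downsampling by the integer factor (edge-padding to a multiple first);
    (4) additive Gaussian noise.  Output voxel size is the input voxel
    size times the factor.
    """
    f = int(spec.downsample_factor)
    data = vol.data.astype(np.float64)
    nz = data.shape[0]

    if spec.axial_shading_amplitude > 0:
        z = np.arange(nz, dtype=np.float64)
        shade = 1.0 + spec.axial_shading_amplitude * (2.0 * z / nz - 1.0)
        data = data * shade[:, None, None]

    if spec.psf_sigma_mm > 0:
        data = ndi.gaussian_filter(data, spec.psf_sigma_mm / vol.voxel_mm,
                                   mode="nearest")

    if f > 1:
        pads = [(0, (-s) % f) for s in data.shape]
        if any(p[1] for p in pads):
            data = np.pad(data, pads, mode="edge")
        sz, sy, sx = (s // f for s in data.shape)
        data = data.reshape(sz, f, sy, f, sx, f).mean(axis=(1, 3, 5))

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)

    return GrayVolume(data=data.astype(np.float32),
                      voxel_mm=vol.voxel_mm * f, modality="cbct")


def generate_cohort(
    n: int = 30,
    seed: int = 0,
    bvtv_range: tuple[float, float] = (0.09, 0.40),
    degradation: Optional[DegradationSpec] = None,
    phantom: Optional[PhantomSpec] = None,
    intensity: Optional[IntensityModel] = None,
    anchor_radius_mm: Optional[float] = None,
    anchor_intensity_gv: float = 255.0,
    headroom_mm: Optional[float] = None,
) -> list[CohortSpecimen]:
    """Seeded cohort of (ground truth, micro grayscale, CBCT grayscale).

    Per-specimen target fractions are drawn uniformly from ``bvtv_range``;
    child seeds are derived deterministically from ``seed``.  When
    ``anchor_radius_mm`` is given, air headroom is prepended and a resin
    anchor ball is rendered before degradation so both modalities can be
    aligned the same way as the scanned specimens.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    lo, hi = bvtv_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"invalid bvtv_range {bvtv_range}")
    degradation = degradation or DegradationSpec()
    intensity = intensity or IntensityModel()
    if phantom is None:
        phantom = PhantomSpec(shape_mm=(3.0, 3.0, 5.4), target_bvtv=0.25,
                              feature_sigma_mm=0.10)

    master = np.random.default_rng(seed)
    targets = master.uniform(lo, hi, size=n) if lo < hi else np.full(n, lo)
    spec_seeds = master.integers(0, 2**31 - 1, size=n)
    degr_seeds = master.integers(0, 2**31 - 1, size=n)

    out = []
    for i in range(n):
        pspec = dataclasses.replace(phantom, target_bvtv=float(targets[i]),
                                    seed=int(spec_seeds[i]))
        gray, truth = generate_trabecular_phantom(pspec, intensity)
        if anchor_radius_mm is not None:
            pad_mm = headroom_mm if headroom_mm is not None \
                else 2.0 * anchor_radius_mm + 0.4
            n_pad = mm_to_voxels(pad_mm, gray.voxel_mm)
            gray = pad_top(gray, pad_mm, intensity.air_gv)
            gray = embed_anchor_ball(gray, anchor_radius_mm, anchor_intensity_gv,
                                     surface_z=n_pad)
            truth = BinaryVolume(
                mask=np.pad(truth.mask, ((n_pad, 0), (0, 0), (0, 0))),
                voxel_mm=truth.voxel_mm, provenance="truth")
        dspec = dataclasses.replace(degradation, seed=int(degr_seeds[i]))
        cbct = degrade_to_cbct(gray, dspec)
        micro = GrayVolume(data=gray.data, voxel_mm=gray.voxel_mm,
                           modality="micro_ct")
        out.append(CohortSpecimen(
            specimen_id=f"S{i + 1:02d}", target_bvtv=float(targets[i]),
            truth=truth, micro=micro, cbct=cbct))
    return out
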