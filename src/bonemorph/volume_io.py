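"""Volume readers/writers, anchor-ball location, and ROI extraction.

TIFF slice stacks are the micro-CT dialect (voxel size supplied by the
caller — vendor tags are not trusted); DICOM series are the CBCT dialect
(spacing taken from the files, required isotropic within 1%).
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import scipy.ndimage as ndi
import tifffile

from . import _dicom
from .volume import BinaryVolume, GrayVolume, mm_to_voxels

__all__ = [
    "RoiSpec",
    "AnchorLocation",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_dicom_series",
    "write_dicom_series",
    "find_top_surface",
    "locate_anchor",
    "extract_roi",
]


@dataclass
class RoiSpec:
    """Aligned cuboid ROI; ``extent_mm`` is (x, y, z)."""

    extent_mm: tuple[float, float, float] = (4.0, 4.0, 10.0)
    anchor_mode: str = "ball_centroid"  # ball_centroid | volume_center | explicit
    explicit_origin_voxel: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if len(self.extent_mm) != 3 or any(e <= 0 for e in self.extent_mm):
            raise ValueError(f"extents must be positive, got {self.extent_mm}")
        if self.anchor_mode not in ("ball_centroid", "volume_center", "explicit"):
            raise ValueError(f"unknown anchor_mode {self.anchor_mode!r}")
        if self.anchor_mode == "explicit" and self.explicit_origin_voxel is None:
            raise ValueError("explicit anchor_mode needs explicit_origin_voxel")

    def grid_shape(self, voxel_mm: float) -> tuple[int, int, int]:
        ex, ey, ez = self.extent_mm
        dims = (mm_to_voxels(ez, voxel_mm), mm_to_voxels(ey, voxel_mm),
                mm_to_voxels(ex, voxel_mm))
        if min(dims) < 1:
            raise ValueError(f"ROI collapses to zero voxels at {voxel_mm} mm")
        return dims


@dataclass
class AnchorLocation:
    centroid_voxel: tuple[float, float, float]  # (z, y, x)
    top_surface_z: int


def _natural_key(name: str):
    return [int(p) if p.isdigit() else p for p in re.split(r"(\d+)", name)]


def read_tiff_stack(path, voxel_mm: float, modality: str = "micro_ct") -> GrayVolume:
    """Read a directory of single-slice TIFFs (natural filename order gives
    z) or one multi-page TIFF.  ``voxel_mm`` comes from the caller."""
    p = Path(path)
    if p.is_dir():
        files = sorted(
            (f for f in p.iterdir() if f.suffix.lower() in (".tif", ".tiff")),
            key=lambda f: _natural_key(f.name),
        )
        if not files:
            raise ValueError(f"no TIFF slices in {p}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"mixed slice shapes in {p}: {sorted(shapes)}")
        if slices[0].ndim != 2:
            raise ValueError("slice files must be single-page 2D images")
        data = np.stack(slices, axis=0)
    else:
        data = tifffile.imread(p)
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected 2D/3D TIFF, got ndim={data.ndim}")
    return GrayVolume(data=data, voxel_mm=voxel_mm, modality=modality)


def write_tiff_stack(vol: Union[GrayVolume, BinaryVolume], path,
                     multipage: bool = False) -> list[Path]:
    """Write a volume as TIFF; binary masks are stored 8-bit as 0/255.

    With ``multipage`` a single file is written, otherwise one file per
    slice (``slice_0000.tif`` ...) in the target directory.
    """
    data = vol.mask.astype(np.uint8) * 255 if isinstance(vol, BinaryVolume) \
        else vol.data
    p = Path(path)
    if multipage:
        p.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(p, data)
        return [p]
    p.mkdir(parents=True, exist_ok=True)
    written = []
    for z in range(data.shape[0]):
        f = p / f"slice_{z:04d}.tif"
        tifffile.imwrite(f, data[z])
        written.append(f)
    return written


def write_dicom_series(vol: GrayVolume, path, series_number: int = 1) -> list[Path]:
    """Write one slice file per z as uncompressed 16-bit DICOM.

    Grayscale must be non-negative; values are rounded to the stored
    uint16 (use integer-valued data for lossless round trips).
    """
    if float(vol.data.min()) < 0 or float(vol.data.max()) > 65535:
        raise ValueError("grayscale must fit unsigned 16-bit storage")
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    study_uid = f"2.25.{series_number}"
    series_uid = f"2.25.{series_number}.1"
    written = []
    for z in range(vol.shape[0]):
        f = p / f"slice_{z:04d}.dcm"
        _dicom.write_dicom_file(
            f, vol.data[z],
            pixel_spacing_mm=vol.voxel_mm, slice_thickness_mm=vol.voxel_mm,
            position_mm=(0.0, 0.0, z * vol.voxel_mm), instance_number=z + 1,
            series_uid=series_uid, study_uid=study_uid,
            sop_uid=f"{series_uid}.{z + 1}",
        )
        written.append(f)
    return written


def read_dicom_series(path) -> GrayVolume:
    """Read a single DICOM series; slices ordered by position along the
    slice normal, rescale applied, spacing required isotropic within 1%."""
    p = Path(path)
    files = sorted(f for f in p.iterdir() if f.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no DICOM files in {p}")
    datasets = [_dicom.read_dicom_file(f) for f in files]

    series = {ds.get("SeriesInstanceUID") for ds in datasets}
    if len(series) != 1:
        raise ValueError(f"expected one series, found {len(series)}")

    first = datasets[0]
    spacing = first["PixelSpacing"]
    row_mm, col_mm = (spacing, spacing) if np.isscalar(spacing) else spacing
    if abs(row_mm - col_mm) > 0.01 * max(row_mm, col_mm):
        raise ValueError(f"anisotropic in-plane spacing: {row_mm} vs {col_mm}")

    orient = np.asarray(first.get("ImageOrientationPatient",
                                  [1, 0, 0, 0, 1, 0]), dtype=float)
    normal = np.cross(orient[:3], orient[3:])
    order = sorted(
        range(len(datasets)),
        key=lambda i: float(np.dot(np.asarray(datasets[i]["ImagePositionPatient"],
                                              dtype=float), normal)),
    )
    positions = [
        float(np.dot(np.asarray(datasets[i]["ImagePositionPatient"], dtype=float),
                     normal))
        for i in order
    ]
    if len(positions) > 1:
        steps = np.diff(positions)
        if np.any(np.abs(steps - steps[0]) > 0.01 * abs(steps[0])):
            raise ValueError("non-uniform slice spacing")
        if abs(abs(steps[0]) - row_mm) > 0.01 * row_mm:
            raise ValueError(
                f"anisotropic voxels: slice step {abs(steps[0])} vs "
                f"in-plane {row_mm}")

    slope = float(first.get("RescaleSlope", 1.0))
    intercept = float(first.get("RescaleIntercept", 0.0))
    data = np.stack(
        [datasets[i]["PixelData"].astype(np.float32) * slope + intercept
         for i in order], axis=0)
    return GrayVolume(data=data, voxel_mm=float(row_mm), modality="cbct")


def find_top_surface(vol: GrayVolume, start_z: int = 0) -> int:
    """Slice index (>= start_z) of the specimen top surface.

    The surface is the largest upward jump of the slice-median profile —
    robust against smooth axial shading, which only changes medians
    gradually."""
    med = np.median(vol.data[start_z:], axis=(1, 2))
    if med.size < 2:
        raise ValueError("not enough slices below start_z to find a surface")
    jumps = np.diff(med)
    if float(jumps.max()) <= 0:
        raise ValueError("no surface found: slice medians never increase")
    return start_z + int(np.argmax(jumps)) + 1


def locate_anchor(vol: GrayVolume,
                  ball_threshold_quantile: float = 0.999) -> AnchorLocation:
    """Find the resin anchor ball: the single bright compact component
    above the intensity quantile in the upper third of the volume.

    Returns the component's intensity-weighted centroid and the first
    specimen slice below the ball.
    """
    data = vol.data
    z_cap = int(np.ceil(vol.shape[0] / 3.0))
    zone = data[:z_cap]
    thr = float(np.quantile(zone, ball_threshold_quantile))
    above = np.zeros(data.shape, dtype=bool)
    above[:z_cap] = zone >= thr
    labels, n_comp = ndi.label(above, structure=np.ones((3, 3, 3), dtype=bool))
    # Isolated specks are not compact candidates: drop anything below a
    # tenth of the largest component.
    sizes = np.bincount(labels.ravel())
    min_size = max(2, int(sizes[1:].max()) // 10) if n_comp else 0
    candidates = []
    for lab in range(1, n_comp + 1):
        if sizes[lab] < min_size:
            continue
        comp = labels == lab
        # a resting ball is laterally interior; border-touching blobs are
        # specimen structure, not the anchor
        if (comp[:, 0, :].any() or comp[:, -1, :].any()
                or comp[:, :, 0].any() or comp[:, :, -1].any()):
            continue
        zc = ndi.center_of_mass(comp)[0]
        if zc < vol.shape[0] / 3.0:
            candidates.append((lab, comp))
    if len(candidates) == 0:
        raise ValueError("no anchor-ball candidate in the upper third")
    if len(candidates) > 1:
        raise ValueError(f"{len(candidates)} anchor-ball candidates found")

    lab, comp = candidates[0]
    weights = np.where(comp, data, 0.0)
    cz, cy, cx = ndi.center_of_mass(weights)
    # Slice medians ignore the ball (it covers well under half a slice), so
    # the largest median jump marks the air -> specimen transition.  The
    # blurred ball component may touch the surface, but its centroid must
    # sit above it.
    top_surface_z = find_top_surface(vol)
    if top_surface_z <= cz:
        raise ValueError(
            f"surface (z={top_surface_z}) not below ball centroid (z={cz:.1f})")
    return AnchorLocation(centroid_voxel=(float(cz), float(cy), float(cx)),
                         top_surface_z=top_surface_z)


def _round_half_away(x: float) -> int:
    return mm_to_voxels(x, 1.0)


def extract_roi(vol: Union[GrayVolume, BinaryVolume],
                anchor: Optional[AnchorLocation],
                roi: RoiSpec) -> Union[GrayVolume, BinaryVolume]:
    """Cut the aligned cuboid out of a volume (gray or binary).

    For ``ball_centroid`` the cuboid is centred laterally on the anchor
    centroid and extends from the top surface inward.  Output dims are
    ``round(extent_mm / voxel_mm)`` per axis.
    """
    is_binary = isinstance(vol, BinaryVolume)
    data = vol.mask if is_binary else vol.data
    nz, ny, nx = roi.grid_shape(vol.voxel_mm)

    if roi.anchor_mode == "ball_centroid":
        if anchor is None:
            raise ValueError("ball_centroid mode needs an AnchorLocation")
        _, cy, cx = anchor.centroid_voxel
        origin = (anchor.top_surface_z,
                  _round_half_away(cy) - ny // 2,
                  _round_half_away(cx) - nx // 2)
    elif roi.anchor_mode == "volume_center":
        origin = tuple((s - d) // 2 for s, d in zip(data.shape, (nz, ny, nx)))
    else:
        origin = tuple(int(v) for v in roi.explicit_origin_voxel)

    for o, d, s in zip(origin, (nz, ny, nx), data.shape):
        if o < 0 or o + d > s:
            raise ValueError(
                f"ROI origin {origin} dims {(nz, ny, nx)} exceeds volume {data.shape}")

    oz, oy, ox = origin
    sub = data[oz:oz + nz, oy:oy + ny, ox:ox + nx].copy()
    if is_binary:
        return BinaryVolume(mask=sub, voxel_mm=vol.voxel_mm,
                            provenance=vol.provenance)
    return GrayVolume(data=sub, voxel_mm=vol.voxel_mm, modality=vol.modality)
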