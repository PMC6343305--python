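"""Cumulative image-preprocessing ladder applied before binarization.

Five processing groups are supported.  Group 0 is the micro-CT reference
path (global threshold only); Groups 1-4 apply increasingly aggressive
preprocessing to the CBCT image:

* G1 — global isodata threshold, no filtering.
* G2 — sharpen, despeckle, global threshold.
* G3 — sharpen, despeckle, per-slice threshold.
* G4 — G3 plus removal of voxels at or below the zero-density grayscale
  taken from a calibration-phantom fit.

Filters are 2D and applied slice by slice; the filter order is fixed
(sharpen, then despeckle).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.ndimage as ndi

from .volume import BinaryVolume, GrayVolume

__all__ = [
    "ThresholdResult",
    "CalibrationModel",
    "sharpen",
    "despeckle",
    "isodata_threshold",
    "binarize_global",
    "binarize_per_slice",
    "fit_calibration",
    "remove_air",
    "run_group",
    "GROUPS",
]

GROUPS = ("G0", "G1", "G2", "G3", "G4")

# 3x3 sharpening kernel: center 12, neighbours -1, divided by 4 (weights
# sum to one, so flat regions are untouched).
_SHARPEN_KERNEL = np.array(
    [[-1.0, -1.0, -1.0], [-1.0, 12.0, -1.0], [-1.0, -1.0, -1.0]]
) / 4.0


@dataclass
class ThresholdResult:
    value: float
    scope: str  # "global" | "slice"
    iterations: int
    slice_index: Optional[int] = None

    def __post_init__(self) -> None:
        if self.scope not in ("global", "slice"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class CalibrationModel:
    """Linear grayscale <-> bone mineral density map.

    ``air_cutoff_gv`` is the grayscale at zero density; voxels at or
    below it are treated as air.
    """

    slope: float  # grayscale per (mg HA/cm^3)
    intercept: float
    r_squared: float
    air_cutoff_gv: float

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(f"calibration slope must be > 0, got {self.slope}")

    def density_to_gray(self, density: float) -> float:
        return self.intercept + self.slope * density

    def gray_to_density(self, gray: float) -> float:
        return (gray - self.intercept) / self.slope


def _filter_slices(vol: GrayVolume, fn) -> GrayVolume:
    data = vol.data
    out = np.empty(data.shape, dtype=np.float64)
    for z in range(data.shape[0]):
        out[z] = fn(data[z].astype(np.float64))
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        out = np.clip(np.rint(out), info.min, info.max)
    return vol.with_data(out.astype(data.dtype))


def sharpen(vol: GrayVolume) -> GrayVolume:
    """Per-slice 3x3 unsharp convolution with edge replication; results are
    clipped to the input dtype's representable range."""
    return _filter_slices(
        vol, lambda s: ndi.convolve(s, _SHARPEN_KERNEL, mode="nearest")
    )


def despeckle(vol: GrayVolume) -> GrayVolume:
    """Per-slice 3x3 median filter with edge replication."""
    return _filter_slices(
        vol, lambda s: ndi.median_filter(s, size=3, mode="nearest")
    )


def isodata_threshold(values: np.ndarray, max_iter: int = 500) -> ThresholdResult:
    """Iterative intermeans threshold.

    Starting from the overall mean, T is replaced by the midpoint of the
    means of the two classes it induces (values <= T vs values > T) until
    the change is below 1e-6 of the data range.  Foreground is strictly
    greater than the returned value.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("no values")
    vmin, vmax = float(v.min()), float(v.max())
    if vmin == vmax:
        raise ValueError("constant input: no threshold exists")
    tol = 1e-6 * (vmax - vmin)
    t = float(v.mean())
    for iteration in range(1, max_iter + 1):
        lo = v <= t
        t_new = 0.5 * (float(v[lo].mean()) + float(v[~lo].mean()))
        if abs(t_new - t) < tol:
            return ThresholdResult(value=t_new, scope="global", iterations=iteration)
        t = t_new
    raise RuntimeError(f"isodata did not converge in {max_iter} iterations")


def binarize_global(vol: GrayVolume) -> BinaryVolume:
    """One isodata threshold computed from all voxels; mask = data > T."""
    t = isodata_threshold(vol.data)
    return BinaryVolume(mask=vol.data > t.value, voxel_mm=vol.voxel_mm,
                        provenance="global")


def binarize_per_slice(vol: GrayVolume) -> BinaryVolume:
    """Isodata computed independently for every z-slice.

    Constant slices cannot be thresholded and inherit the threshold of the
    nearest non-constant slice (lower index wins ties).
    """
    data = vol.data
    nz = data.shape[0]
    thresholds: list[Optional[float]] = []
    for z in range(nz):
        s = data[z]
        if float(s.min()) == float(s.max()):
            thresholds.append(None)
        else:
            r = isodata_threshold(s)
            thresholds.append(r.value)
    known = [z for z, t in enumerate(thresholds) if t is not None]
    if not known:
        raise ValueError("all slices constant: no threshold exists")
    mask = np.empty(data.shape, dtype=bool)
    for z in range(nz):
        t = thresholds[z]
        if t is None:
            nearest = min(known, key=lambda k: (abs(k - z), k))
            t = thresholds[nearest]
        mask[z] = data[z] > t
    return BinaryVolume(mask=mask, voxel_mm=vol.voxel_mm, provenance="slice")


def fit_calibration(pairs: Sequence[tuple[float, float]]) -> CalibrationModel:
    """Ordinary least squares of mean grayscale on known density.

    The fitted intercept is the zero-density grayscale and becomes the air
    cutoff.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (density, grayscale) pairs")
    dens, gray = arr[:, 0], arr[:, 1]
    if np.unique(dens).size < 2:
        raise ValueError("singular fit: all densities equal")
    slope, intercept = np.polyfit(dens, gray, 1)
    pred = intercept + slope * dens
    ss_res = float(((gray - pred) ** 2).sum())
    ss_tot = float(((gray - gray.mean()) ** 2).sum())
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationModel(slope=float(slope), intercept=float(intercept),
                            r_squared=r_squared, air_cutoff_gv=float(intercept))


def remove_air(mask: BinaryVolume, gray: GrayVolume,
               calib: CalibrationModel) -> BinaryVolume:
    """Clear mask voxels whose grayscale is at or below the air cutoff."""
    if mask.shape != gray.shape:
        raise ValueError(f"dim mismatch: mask {mask.shape} vs gray {gray.shape}")
    out = mask.mask & (gray.data > calib.air_cutoff_gv)
    return BinaryVolume(mask=out, voxel_mm=mask.voxel_mm, provenance=mask.provenance)


def run_group(gray: GrayVolume, group: str,
              calib: Optional[CalibrationModel] = None) -> BinaryVolume:
    """Dispatch one processing group on a grayscale ROI.

    G0 and G1 binarize directly; G2 adds sharpen+despeckle; G3 switches to
    per-slice thresholding; G4 additionally removes air voxels (requires a
    calibration model; the cutoff is applied against the unfiltered input
    grayscale, matching how the calibration itself is measured).
    """
    if isinstance(group, int):
        group = f"G{group}"
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if group == "G4" and calib is None:
        raise ValueError("G4 requires a calibration model")

    if group in ("G0", "G1"):
        out = binarize_global(gray)
    elif group == "G2":
        out = binarize_global(despeckle(sharpen(gray)))
    else:  # G3 / G4
        out = binarize_per_slice(despeckle(sharpen(gray)))
        if group == "G4":
            out = remove_air(out, gray, calib)
    out.provenance = group
    return out
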