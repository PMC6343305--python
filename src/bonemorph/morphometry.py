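"""Trabecular bone microarchitecture from a binary volume.

The four reported parameters are:

* ``BV/TV`` — bone volume fraction, percent of in-mask voxels.
* ``TbTh``  — mean trabecular thickness (mm), sphere-fitting definition.
* ``TbSp``  — mean trabecular separation (mm), the same thickness measure
  applied to the background phase.
* ``TbN``   — trabecular number per mm, the ratio (BV/TV)/TbTh.

Thickness is model independent: for every in-phase voxel the local value
is the diameter of the largest sphere that lies entirely inside the phase
and covers the voxel.  A sphere centred on voxel ``c`` has maximal radius
``d(c) - 0.5`` voxels, where ``d`` is the Euclidean distance transform
with everything outside the volume counted as out-of-phase (spheres must
fit inside the ROI).  The local diameter is therefore ``2*d(c) - 1``
voxels at the best covering centre; a single isolated voxel measures one
voxel, a 5-voxel slab measures five.

Two implementations are provided: :func:`local_thickness`, an exact
vectorised algorithm (distance transform, redundant-sphere pruning, then
sphere painting), and :func:`brute_force_thickness`, a direct evaluation
of the definition used as its oracle.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.ndimage as ndi

from .volume import BinaryVolume

__all__ = [
    "ThicknessMap",
    "MorphometryResult",
    "bone_volume_fraction",
    "local_thickness",
    "brute_force_thickness",
    "mean_thickness",
    "trabecular_number",
    "compute_morphometry",
]

PARAMETERS = ("bv_tv", "tb_th", "tb_n", "tb_sp")


@dataclass
class ThicknessMap:
    """Per-voxel local thickness.

    ``tau`` holds the local sphere diameter in mm on in-phase voxels and
    exactly 0 elsewhere.
    """

    tau: np.ndarray
    phase: str  # "foreground" | "background"
    voxel_mm: float

    def __post_init__(self) -> None:
        if self.phase not in ("foreground", "background"):
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def in_phase(self) -> np.ndarray:
        return self.tau > 0


@dataclass
class MorphometryResult:
    bv_tv: float  # percent
    tb_th: float  # mm
    tb_n: float  # 1/mm
    tb_sp: float  # mm
    group: str = ""
    specimen_id: str = ""
    degenerate: Optional[str] = None  # "all_foreground" | "all_background"

    def __post_init__(self) -> None:
        if not (0.0 <= self.bv_tv <= 100.0):
            raise ValueError(f"bv_tv out of range: {self.bv_tv}")
        if self.tb_th < 0 or self.tb_sp < 0 or self.tb_n < 0:
            raise ValueError("parameters must be non-negative")


def bone_volume_fraction(mask: BinaryVolume) -> float:
    """Percent of volume voxels that are bone."""
    if mask.mask.size == 0:
        raise ValueError("zero-size volume")
    return 100.0 * float(np.count_nonzero(mask.mask)) / mask.mask.size


# ---------------------------------------------------------------------------
# thickness transform internals
# ---------------------------------------------------------------------------


def _phase_mask(mask: BinaryVolume, phase: str) -> np.ndarray:
    if phase == "foreground":
        return mask.mask
    if phase == "background":
        return ~mask.mask
    raise ValueError(f"unknown phase {phase!r}")


def _edt(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance to nearest out-of-phase voxel centre; outside the volume is
    out-of-phase.  Returns (float distance, exact integer squared distance)."""
    padded = np.pad(phase, 1)
    d = ndi.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    d2 = np.round(d * d).astype(np.int64)
    return d, d2


_OFFSET_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _ball_offsets(r_max: int) -> tuple[np.ndarray, np.ndarray]:
    """All integer offsets in [-r_max, r_max]^3 sorted by squared norm."""
    if r_max not in _OFFSET_CACHE:
        g = np.arange(-r_max, r_max + 1)
        oz, oy, ox = np.meshgrid(g, g, g, indexing="ij")
        off = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)
        n2 = (off * off).sum(axis=1)
        order = np.argsort(n2, kind="stable")
        _OFFSET_CACHE[r_max] = (off[order], n2[order])
    return _OFFSET_CACHE[r_max]


def _covered_r2(d2: int) -> int:
    """Largest integer squared distance covered by the sphere of radius
    sqrt(d2) - 0.5.  Exact for the d2 range reachable in practice."""
    return int(np.floor(d2 + 0.25 - np.sqrt(float(d2))))


def local_thickness(
    mask: BinaryVolume, phase: str = "foreground", _prune_window: int = 2
) -> ThicknessMap:
    """Exact local thickness map of one phase (mm).

    Algorithm: Euclidean distance transform; prune spheres wholly
    contained in a neighbour's sphere (exact integer dominance test);
    paint the surviving spheres grouped by radius in ascending order so
    larger diameters overwrite smaller ones.
    """
    ph = _phase_mask(mask, phase)
    if not ph.any():
        raise ValueError(f"empty phase {phase!r}")
    nz, ny, nx = ph.shape
    d, d2 = _edt(ph)

    # Sphere at c is redundant if a nearby centre c' = c + o satisfies
    # d(c') >= d(c) + |o|  (its sphere contains ours).  Checked exactly in
    # integers: with t = d2' - d2 - n,  t >= 0 and t^2 >= 4 n d2.
    dominated = np.zeros(ph.shape, dtype=bool)
    w2 = _prune_window * _prune_window
    shifted = np.zeros_like(d2)
    for dz in range(-_prune_window, _prune_window + 1):
        for dy in range(-_prune_window, _prune_window + 1):
            for dx in range(-_prune_window, _prune_window + 1):
                n = dz * dz + dy * dy + dx * dx
                if n == 0 or n > w2:
                    continue
                shifted[:] = 0
                src = tuple(
                    slice(max(o, 0), s + min(o, 0))
                    for o, s in zip((dz, dy, dx), ph.shape)
                )
                dst = tuple(
                    slice(max(-o, 0), s + min(-o, 0))
                    for o, s in zip((dz, dy, dx), ph.shape)
                )
                shifted[dst] = d2[src]
                t = shifted - d2 - n
                dominated |= (t >= 0) & (t * t >= 4 * n * d2)

    keep = ph & ~dominated
    zz, yy, xx = np.nonzero(keep)
    d2_keep = d2[zz, yy, xx]
    # int32 flat indices halve scatter traffic; volumes stay far below 2^31
    idx_dtype = np.int32 if ph.size < 2**31 else np.int64
    flat = ((zz * ny + yy) * nx + xx).astype(idx_dtype)

    order = np.argsort(d2_keep, kind="stable")
    d2_keep = d2_keep[order]
    flat = flat[order]

    tau_flat = np.zeros(ph.size, dtype=np.float64)
    r_max = int(np.floor(np.sqrt(float(d2_keep[-1])) - 0.5))
    off, n2 = _ball_offsets(r_max)
    deltas = ((off[:, 0] * ny + off[:, 1]) * nx + off[:, 2]).astype(idx_dtype)

    unique_d2, starts = np.unique(d2_keep, return_index=True)
    bounds = list(starts) + [len(d2_keep)]
    for i, du in enumerate(unique_d2):
        dv = float(np.sqrt(float(du)))
        k = int(np.searchsorted(n2, _covered_r2(int(du)), side="right"))
        centers = flat[bounds[i] : bounds[i + 1]]
        val = 2.0 * dv - 1.0
        # Spheres never cross the volume boundary (radius < distance to the
        # outside), so flat-index scatter cannot wrap.
        chunk = max(1, int(2e7) // max(1, k))
        for j in range(0, len(centers), chunk):
            idx = (centers[j : j + chunk, None] + deltas[None, :k]).ravel()
            tau_flat[idx] = val

    tau = tau_flat.reshape(ph.shape) * mask.voxel_mm
    return ThicknessMap(tau=tau, phase=phase, voxel_mm=mask.voxel_mm)


def brute_force_thickness(mask: BinaryVolume, phase: str = "foreground") -> ThicknessMap:
    """Direct evaluation of the sphere-fitting definition (test oracle).

    Enumerates every in-phase candidate centre, takes its maximal sphere
    radius from the exact distance transform, and records the sphere
    diameter on every voxel it covers.  Definitionally correct; volume is
    capped at 40^3 voxels.
    """
    ph = _phase_mask(mask, phase)
    if ph.size > 40**3:
        raise ValueError(f"volume too large for brute force: {ph.size} > {40 ** 3}")
    if not ph.any():
        raise ValueError(f"empty phase {phase!r}")
    d, _ = _edt(ph)

    tau = np.zeros(ph.shape, dtype=np.float64)
    r_cap = int(np.floor(d.max() - 0.5))
    g = np.arange(-r_cap, r_cap + 1)
    dist2 = (
        g[:, None, None] ** 2 + g[None, :, None] ** 2 + g[None, None, :] ** 2
    ).astype(np.float64)
    for cz, cy, cx in np.argwhere(ph):
        dc = float(d[cz, cy, cx])
        r = dc - 0.5
        R = int(np.floor(r))
        c0 = r_cap - R
        ball = dist2[c0 : c0 + 2 * R + 1, c0 : c0 + 2 * R + 1, c0 : c0 + 2 * R + 1] <= r * r
        sub = tau[cz - R : cz + R + 1, cy - R : cy + R + 1, cx - R : cx + R + 1]
        np.maximum(sub, np.where(ball, 2.0 * dc - 1.0, 0.0), out=sub)

    return ThicknessMap(tau=tau * mask.voxel_mm, phase=phase, voxel_mm=mask.voxel_mm)


def mean_thickness(tmap: ThicknessMap) -> float:
    """Unweighted mean of the local thickness over in-phase voxels, in mm."""
    in_phase = tmap.in_phase
    if not in_phase.any():
        raise ValueError("empty phase")
    return float(tmap.tau[in_phase].mean())


def trabecular_number(bv_tv: float, tb_th: float) -> float:
    """TbN = (BV/TV)/TbTh with BV/TV as a fraction; 0 when there is no bone."""
    if bv_tv == 0:
        return 0.0
    if tb_th <= 0:
        raise ValueError("tb_th must be > 0 when bv_tv > 0")
    return (bv_tv / 100.0) / tb_th


def compute_morphometry(
    mask: BinaryVolume, group: str = "", specimen_id: str = ""
) -> MorphometryResult:
    """All four parameters for one binary volume."""
    if mask.mask.size == 0:
        raise ValueError("zero-size volume")
    bv_tv = bone_volume_fraction(mask)
    group = group or mask.provenance

    if bv_tv == 0.0:
        tb_sp = mean_thickness(local_thickness(mask, "background"))
        return MorphometryResult(0.0, 0.0, 0.0, tb_sp, group, specimen_id,
                                 degenerate="all_background")
    if bv_tv == 100.0:
        tb_th = mean_thickness(local_thickness(mask, "foreground"))
        return MorphometryResult(100.0, tb_th, trabecular_number(100.0, tb_th),
                                 0.0, group, specimen_id, degenerate="all_foreground")

    tb_th = mean_thickness(local_thickness(mask, "foreground"))
    tb_sp = mean_thickness(local_thickness(mask, "background"))
    tb_n = trabecular_number(bv_tv, tb_th)
    return MorphometryResult(bv_tv, tb_th, tb_n, tb_sp, group, specimen_id)
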