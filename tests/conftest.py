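"""Shared fixtures and independent oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest
import scipy.ndimage as ndi

from bonemorph import BinaryVolume, GrayVolume
from bonemorph import synthetic as syn


def isodata_exhaustive(values) -> list[float]:
    """All self-consistent intermeans thresholds, found by enumerating every
    split of the sorted unique values (independent oracle for isodata).

    A split after unique value u_i is consistent when the midpoint of the
    two class means lies in [u_i, u_{i+1}): thresholding at that midpoint
    reproduces the split, so it is a fixed point.
    """
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    uniq = np.unique(v)
    out = []
    for i in range(len(uniq) - 1):
        lo = v[v <= uniq[i]]
        hi = v[v > uniq[i]]
        m = 0.5 * (lo.mean() + hi.mean())
        if uniq[i] <= m < uniq[i + 1]:
            out.append(float(m))
    return out


def random_mask(rng: np.random.Generator, n: int, smooth: bool = False) -> BinaryVolume:
    """Random binary test mask: Bernoulli or thresholded smoothed noise."""
    if smooth:
        f = ndi.gaussian_filter(rng.standard_normal((n, n, n)), 2.0)
        mask = f > np.quantile(f, rng.uniform(0.3, 0.8))
    else:
        mask = rng.random((n, n, n)) < rng.uniform(0.2, 0.8)
    if not mask.any():
        mask[n // 2, n // 2, n // 2] = True
    if mask.all():
        mask[0, 0, 0] = False
    return BinaryVolume(mask=mask, voxel_mm=0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """1 x 1 x 2 mm micro-resolution phantom with ground truth."""
    spec = syn.PhantomSpec(shape_mm=(1.0, 1.0, 2.0), target_bvtv=0.25,
                           feature_sigma_mm=0.06, voxel_mm=0.02, seed=42)
    gray, truth = syn.generate_trabecular_phantom(spec)
    return spec, gray, truth


def tiny_experiment_config(tmp_dir, n=3, seed=5):
    """Config for a fast end-to-end experiment run (~1 mm ROI)."""
    from bonemorph import analysis as an

    cfg = an.default_config(n=n, seed=seed)
    cfg["phantom"]["shape_mm"] = [1.6, 1.6, 2.8]
    cfg["phantom"]["feature_sigma_mm"] = 0.08
    cfg["anchor"] = {"radius_mm": 0.3, "intensity_gv": 255.0, "headroom_mm": 0.8}
    cfg["roi"]["extent_mm"] = [1.0, 1.0, 2.0]
    # gentle degradation: the 0.3 mm ball must survive the PSF
    cfg["degradation"].update(psf_sigma_mm=0.1, noise_sigma=2.0,
                              axial_shading_amplitude=0.15)
    cfg["output"]["dir"] = str(tmp_dir)
    return cfg
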