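"""Image/mask I/O, isotropic resampling, gray-level discretization and
filter channels (Laplacian of Gaussian, single-level 3D wavelet).

All downstream texture statistics assume direction-consistent 3D voxel
offsets, so volumes are resampled to isotropic spacing (default 1 mm) before
feature extraction. Intensities are quantized to a fixed number of gray
levels (default 32) using min–max scaling over *masked* voxels only, which
makes texture features unit-free but ties any absolute feature threshold to
the chosen quantization — thresholds must always be re-derived on the data
at hand rather than transferred between pipelines.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pywt
from scipy import ndimage

from .grids import DiscretizedROI, FilterChannel, ROIMask, VoxelGrid

__all__ = [
    "read_volume_pair",
    "write_volume_pair",
    "resample_isotropic",
    "discretize",
    "log_filter",
    "wavelet_channels",
    "build_channels",
    "SMALL_ROI_VOXELS",
]

#: below this many foreground voxels texture statistics are unstable
SMALL_ROI_VOXELS = 27


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume_pair(grid: VoxelGrid, mask: ROIMask, image_path, mask_path) -> None:
    """Write an image/mask pair as NIfTI-1 with spacing in the affine."""
    nib.save(
        nib.Nifti1Image(grid.values.astype(np.float64), _affine_from(grid.spacing, grid.origin)),
        str(image_path),
    )
    nib.save(
        nib.Nifti1Image(mask.values.astype(np.uint8), _affine_from(mask.spacing, mask.origin)),
        str(mask_path),
    )


def read_volume_pair(image_path, mask_path) -> tuple[VoxelGrid, ROIMask]:
    """Load a NIfTI-1 image and its binary tumor mask.

    The mask is binarized (any nonzero voxel becomes foreground). Shape or
    spacing mismatches beyond 1e-3 mm, or an empty mask, are errors.
    """
    image_path, mask_path = Path(image_path), Path(mask_path)
    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    spacing_i = tuple(float(z) for z in img.header.get_zooms()[:3])
    spacing_m = tuple(float(z) for z in msk.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    grid = VoxelGrid(np.asarray(img.dataobj, dtype=float), spacing_i, origin)
    mask = ROIMask(np.asarray(msk.dataobj), spacing_m, origin)
    mask.check_aligned(grid, tol_mm=1e-3)
    if mask.voxel_count == 0:
        raise ValueError(f"mask {mask_path} is empty")
    return grid, mask


def resample_isotropic(
    grid: VoxelGrid, mask: ROIMask, target_mm: float = 1.0
) -> tuple[VoxelGrid, ROIMask]:
    """Resample to isotropic ``target_mm`` spacing.

    The image is linearly interpolated, the mask nearest-neighbor so it
    stays binary. Already-isotropic input at the target spacing is returned
    unchanged.
    """
    if target_mm <= 0:
        raise ValueError("target_mm must be positive")
    mask.check_aligned(grid)
    if all(abs(s - target_mm) < 1e-9 for s in grid.spacing):
        return grid, mask
    factors = tuple(s / target_mm for s in grid.spacing)
    new_values = ndimage.zoom(grid.values, factors, order=1, mode="nearest")
    new_mask = ndimage.zoom(mask.values.astype(np.uint8), factors, order=0, mode="nearest")
    spacing = (target_mm,) * 3
    return (
        VoxelGrid(new_values, spacing, grid.origin),
        ROIMask(new_mask, spacing, mask.origin),
    )


def discretize(grid: VoxelGrid, mask: ROIMask, ng: int = 32) -> DiscretizedROI:
    """Quantize masked intensities to ``ng`` equal-width gray levels.

    level(x) = min(ng, floor((x - min) / (max - min) * ng) + 1), with min and
    max taken over masked voxels only. A constant ROI maps every voxel to
    level 1. Monotone: x <= y implies level(x) <= level(y).
    """
    if ng < 2:
        raise ValueError(f"ng must be >= 2, got {ng}")
    mask.check_aligned(grid)
    m = mask.values
    n_vox = int(m.sum())
    if n_vox == 0:
        raise ValueError("mask is empty")
    if n_vox < SMALL_ROI_VOXELS:
        warnings.warn(
            f"ROI has only {n_vox} voxels (< {SMALL_ROI_VOXELS}); "
            "texture statistics will be unstable",
            stacklevel=2,
        )
    vals = grid.values[m]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(grid.shape, dtype=np.int32)
    if hi == lo:
        levels[m] = 1
        edges = lo + np.arange(ng + 1, dtype=float)  # degenerate but increasing
    else:
        scaled = np.floor((vals - lo) / (hi - lo) * ng).astype(np.int32) + 1
        levels[m] = np.minimum(scaled, ng)
        edges = np.linspace(lo, hi, ng + 1)
    return DiscretizedROI(levels=levels, ng=ng, bin_edges=edges, mask=m)


def log_filter(grid: VoxelGrid, sigma_mm: float = 3.0) -> FilterChannel:
    """Laplacian-of-Gaussian response at scale ``sigma_mm``.

    Requires isotropic spacing (resample first); sigma is converted from mm
    to voxels via the spacing. Mirror boundary handling.
    """
    if sigma_mm <= 0:
        raise ValueError("sigma_mm must be positive")
    if not grid.is_isotropic:
        raise ValueError(
            f"LoG filter requires isotropic spacing, got {grid.spacing}; "
            "resample_isotropic first"
        )
    sigma_vox = sigma_mm / grid.spacing[0]
    # generous truncation: a short kernel has nonzero DC gain, which would
    # leak the local mean into the response
    response = ndimage.gaussian_laplace(
        grid.values, sigma=sigma_vox, mode="mirror", truncate=8.0
    )
    name = f"log_sigma_{sigma_mm:g}mm"
    return FilterChannel(name, VoxelGrid(response, grid.spacing, grid.origin))


#: subband tag per axis: approximation -> L, detail -> H
_SUBBAND_MAP = {"a": "L", "d": "H"}


def wavelet_channels(grid: VoxelGrid, wavelet: str = "coif1") -> list[FilterChannel]:
    """Single-level separable 3D discrete wavelet transform.

    Returns the 8 subbands tagged ``wavelet_LLL`` ... ``wavelet_HHH``, each
    linearly interpolated back to the input shape so ROI masks apply
    unchanged. Uses periodized boundary handling, which keeps the transform
    orthonormal (Parseval) for orthogonal bases such as Coiflet-1.
    """
    w = pywt.Wavelet(wavelet)
    min_len = w.dec_len
    for ax, n in enumerate(grid.shape):
        if n < min_len:
            raise ValueError(
                f"axis {ax} has length {n} < wavelet filter length {min_len}"
            )
    coeffs = pywt.dwtn(grid.values, w, mode="periodization")
    channels = []
    for key in sorted(coeffs):
        tag = "".join(_SUBBAND_MAP[c] for c in key)
        sub = coeffs[key]
        factors = tuple(n / s for n, s in zip(grid.shape, sub.shape))
        up = ndimage.zoom(sub, factors, order=1, mode="nearest")
        channels.append(
            FilterChannel(f"wavelet_{tag}", VoxelGrid(up, grid.spacing, grid.origin))
        )
    return channels


def build_channels(
    grid: VoxelGrid,
    log_sigmas_mm: tuple[float, ...] = (3.0,),
    wavelet_enabled: bool = True,
    wavelet: str = "coif1",
) -> list[FilterChannel]:
    """Assemble the channel set: original, LoG scales, wavelet subbands."""
    channels = [FilterChannel("original", grid)]
    for sigma in log_sigmas_mm:
        channels.append(log_filter(grid, sigma))
    if wavelet_enabled:
        channels.extend(wavelet_channels(grid, wavelet=wavelet))
    names = [c.name for c in channels]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate channel names: {names}")
    return channels
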