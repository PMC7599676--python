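"""Core in-memory containers for image volumes, masks and discretized ROIs.

A :class:`VoxelGrid` is a 3D scalar lattice with physical voxel spacing (mm)
and an origin; a :class:`ROIMask` is a binary lattice aligned with its grid.
All texture computations operate on a :class:`DiscretizedROI`, whose masked
voxels carry integer gray levels in ``1..ng`` (1-based so that ``1/i**2``
emphasis terms are always defined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "ROIMask", "DiscretizedROI", "FilterChannel"]


@dataclass
class VoxelGrid:
    """3D scalar image with physical spacing.

    Parameters
    ----------
    values : (nx, ny, nz) float array
        Scalar intensities; must be finite.
    spacing : 3-tuple of float
        Voxel size along each axis in mm; strictly positive.
    origin : 3-tuple of float
        Physical coordinate of voxel (0, 0, 0) in mm.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing
        return abs(s[0] - s[1]) < 1e-9 and abs(s[1] - s[2]) < 1e-9

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ROIMask:
    """Binary region-of-interest mask aligned with a :class:`VoxelGrid`."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={arr.ndim}")
        self.values = arr != 0
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    def check_aligned(self, grid: VoxelGrid, tol_mm: float = 1e-3) -> None:
        """Raise if shape or spacing disagree with ``grid`` beyond ``tol_mm``."""
        if self.shape != grid.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match image shape {grid.shape}"
            )
        if any(abs(a - b) > tol_mm for a, b in zip(self.spacing, grid.spacing)):
            raise ValueError(
                f"mask spacing {self.spacing} does not match image spacing "
                f"{grid.spacing} within {tol_mm} mm"
            )


@dataclass
class DiscretizedROI:
    """Masked voxels quantized to ``ng`` gray levels.

    ``levels`` holds an integer in ``1..ng`` for every masked voxel and 0
    elsewhere; ``bin_edges`` are the ``ng + 1`` strictly increasing edges
    used for the quantization.
    """

    levels: np.ndarray
    ng: int
    bin_edges: np.ndarray
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        if self.mask is None:
            self.mask = self.levels > 0
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.ng):
            raise ValueError("masked levels must lie in [1, ng]")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class FilterChannel:
    """A named filter response (``original``, ``log_sigma...``, wavelet tag)."""

    name: str
    grid: VoxelGrid
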