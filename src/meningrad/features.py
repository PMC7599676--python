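"""Texture matrices (GLCM, GLRLM, GLSZM) and the 13-feature radiomic set.

The feature set mirrors the classic meningioma risk-stratification panel:
four first-order statistics (mean, median, minimum, skewness), one shape
descriptor (spherical disproportion), three co-occurrence features (cluster
prominence, difference entropy, inverse difference normalized), two
run-length features (run length non-uniformity, short-run low gray-level
emphasis) and three size-zone features (high-intensity large area emphasis,
low-intensity large/small area emphasis).

Conventions
-----------
* Gray levels are 1-based (``i = 1..Ng``) so inverse-square emphasis terms
  are always defined.
* GLCM: distance 1, the 13 unique 3D directions, symmetric accumulation
  (both orderings), matrices summed over directions then normalized to a
  single matrix. The direction set covers all 26 neighbors under symmetry,
  so direction-aggregated features are invariant to axis-aligned rotations.
* GLRLM: runs counted per direction over the same 13 directions, matrices
  summed (per-direction feature averaging available via ``aggregate``).
* GLSZM: zones are 26-connected components of equal gray level; the matrix
  is direction-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .grids import DiscretizedROI, FilterChannel, ROIMask, VoxelGrid

__all__ = [
    "DIRECTIONS_13",
    "GLCM",
    "GLRLM",
    "GLSZM",
    "compute_glcm",
    "compute_glrlm",
    "compute_glszm",
    "cluster_prominence",
    "difference_entropy",
    "inverse_difference_normalized",
    "run_length_nonuniformity",
    "short_run_low_gray_emphasis",
    "high_intensity_large_area_emphasis",
    "low_intensity_large_area_emphasis",
    "low_intensity_small_area_emphasis",
    "first_order",
    "spherical_disproportion",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "extract_features",
    "FEATURE_NAMES",
    "TEXTURE_FEATURE_NAMES",
]


def _unique_directions() -> tuple[tuple[int, int, int], ...]:
    dirs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                d = (dx, dy, dz)
                if d == (0, 0, 0):
                    continue
                if d > tuple(-c for c in d):  # keep one of each +/- pair
                    dirs.append(d)
    return tuple(dirs)


#: the 13 unique distance-1 offsets of the 26-neighborhood
DIRECTIONS_13 = _unique_directions()

#: wide-table feature names; shape feature reported on the original channel only
FEATURE_NAMES = (
    "mean",
    "median",
    "minimum",
    "skewness",
    "spherical_disproportion",
    "cluster_prominence",
    "difference_entropy",
    "inverse_difference_normalized",
    "run_length_nonuniformity",
    "short_run_low_gray_emphasis",
    "high_intensity_large_area_emphasis",
    "low_intensity_large_area_emphasis",
    "low_intensity_small_area_emphasis",
)

TEXTURE_FEATURE_NAMES = FEATURE_NAMES[5:]


@dataclass
class GLCM:
    """Normalized symmetric gray-level co-occurrence matrix p(i, j)."""

    matrix: np.ndarray  # (ng, ng), sums to 1
    ng: int
    direction_policy: str = "sum_13_symmetric"


@dataclass
class GLRLM:
    """Gray-level run-length counts r(i, j): level i, run length j (1-based)."""

    matrix: np.ndarray  # (ng, max_run_length) integer counts
    ng: int
    direction_policy: str = "sum_13"


@dataclass
class GLSZM:
    """Gray-level size-zone counts s(i, j): level i, zone size j (1-based)."""

    matrix: np.ndarray  # (ng, max_zone_size) integer counts
    ng: int


def _shift_pairs(levels: np.ndarray, d: tuple[int, int, int]):
    """Return (level_a, level_b) arrays for all in-volume voxel pairs at offset d."""
    slices_a, slices_b = [], []
    for n, step in zip(levels.shape, d):
        if step == 0:
            slices_a.append(slice(None))
            slices_b.append(slice(None))
        elif step > 0:
            slices_a.append(slice(0, n - step))
            slices_b.append(slice(step, n))
        else:
            slices_a.append(slice(-step, n))
            slices_b.append(slice(0, n + step))
    return levels[tuple(slices_a)], levels[tuple(slices_b)]


def compute_glcm(disc: DiscretizedROI) -> GLCM:
    """Co-occurrence counts at distance 1 over the 13 directions, symmetrized.

    Pairs with either voxel outside the mask are excluded. Raises if the ROI
    yields no co-occurring pairs (e.g., a single voxel).
    """
    ng = disc.ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    for d in DIRECTIONS_13:
        a, b = _shift_pairs(disc.levels, d)
        valid = (a > 0) & (b > 0)
        if not valid.any():
            continue
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    counts = counts + counts.T  # both orderings
    total = counts.sum()
    if total == 0:
        raise ValueError("no co-occurrences: ROI too small for GLCM")
    return GLCM(matrix=counts / total, ng=ng)


def cluster_prominence(g: GLCM) -> float:
    """Fourth central co-occurrence moment: sum (i + j - mu_i - mu_j)^4 p(i,j).

    Sensitive to asymmetric/peaked clustering of jointly-high or jointly-low
    gray levels; 0 for a constant ROI. Invariant to a common level shift.
    """
    p = g.matrix
    i = np.arange(1, g.ng + 1)
    mu_i = (p.sum(axis=1) * i).sum()
    mu_j = (p.sum(axis=0) * i).sum()
    ii, jj = np.meshgrid(i, i, indexing="ij")
    return float(((ii + jj - mu_i - mu_j) ** 4 * p).sum())


def _diff_distribution(g: GLCM) -> np.ndarray:
    """p_{x-y}(k), k = 0..Ng-1."""
    p = g.matrix
    ng = g.ng
    out = np.zeros(ng)
    i = np.arange(ng)
    k = np.abs(i[:, None] - i[None, :])
    np.add.at(out, k.ravel(), p.ravel())
    return out


def difference_entropy(g: GLCM) -> float:
    """Entropy (bits) of the gray-level difference distribution; in [0, log2 Ng]."""
    pd = _diff_distribution(g)
    nz = pd[pd > 0]
    return float(-(nz * np.log2(nz)).sum())


def inverse_difference_normalized(g: GLCM) -> float:
    """Sum p(i,j) / (1 + |i-j| / Ng); 1 for a purely diagonal matrix."""
    ng = g.ng
    i = np.arange(ng)
    w = 1.0 / (1.0 + np.abs(i[:, None] - i[None, :]) / ng)
    return float((g.matrix * w).sum())


def _runs_along(levels: np.ndarray, d: tuple[int, int, int]) -> np.ndarray:
    """(level, length) pairs for all maximal runs of equal nonzero level along d."""
    # run starts: nonzero voxels whose predecessor along -d is invalid or differs
    a, b = _shift_pairs(levels, d)  # a at p, b at p + d
    shape = levels.shape
    cont = np.zeros(shape, dtype=bool)  # voxel continues the run of its predecessor
    slices_b = []
    for n, step in zip(shape, d):
        if step == 0:
            slices_b.append(slice(None))
        elif step > 0:
            slices_b.append(slice(step, n))
        else:
            slices_b.append(slice(0, n + step))
    cont[tuple(slices_b)] = (a == b) & (b > 0)
    starts = (levels > 0) & ~cont
    idx = np.argwhere(starts)
    if idx.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    lv = levels[tuple(idx.T)]
    lengths = np.ones(len(idx), dtype=np.int64)
    cur = idx.copy()
    active = np.ones(len(idx), dtype=bool)
    dv = np.asarray(d)
    while active.any():
        nxt = cur[active] + dv
        inb = np.all((nxt >= 0) & (nxt < np.asarray(shape)), axis=1)
        same = np.zeros(len(nxt), dtype=bool)
        if inb.any():
            same[inb] = levels[tuple(nxt[inb].T)] == lv[active][inb]
        cur[active] = np.where(same[:, None], nxt, cur[active])
        lengths[np.flatnonzero(active)[same]] += 1
        sub = np.flatnonzero(active)
        active[sub[~same]] = False
    return np.stack([lv, lengths], axis=1)


def compute_glrlm(disc: DiscretizedROI, aggregate: str = "sum") -> GLRLM | list[GLRLM]:
    """Run-length matrices over the 13 directions.

    ``aggregate='sum'`` (default) returns one matrix with counts summed over
    directions; ``'per-direction'`` returns the 13 matrices for feature
    averaging. Conservation holds per direction: sum_j j * r(i, j) equals the
    masked voxel count.
    """
    ng = disc.ng
    per_dir = []
    max_len = 1
    all_runs = []
    for d in DIRECTIONS_13:
        runs = _runs_along(disc.levels, d)
        all_runs.append(runs)
        if len(runs):
            max_len = max(max_len, int(runs[:, 1].max()))
    if all(len(r) == 0 for r in all_runs):
        raise ValueError("empty run-length matrix: mask has no voxels")
    for runs in all_runs:
        m = np.zeros((ng, max_len), dtype=np.int64)
        if len(runs):
            np.add.at(m, (runs[:, 0] - 1, runs[:, 1] - 1), 1)
        per_dir.append(GLRLM(matrix=m, ng=ng, direction_policy="single"))
    if aggregate == "per-direction":
        return per_dir
    total = np.sum([g.matrix for g in per_dir], axis=0)
    return GLRLM(matrix=total, ng=ng)


def run_length_nonuniformity(r: GLRLM) -> float:
    """RLN = sum_j (sum_i r(i,j))^2 / N_r, N_r the total run count."""
    m = r.matrix
    n_runs = m.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    return float((m.sum(axis=0).astype(float) ** 2).sum() / n_runs)


def short_run_low_gray_emphasis(r: GLRLM) -> float:
    """SRLGE = (1/N_r) sum r(i,j) / (i^2 j^2); emphasizes short dark runs."""
    m = r.matrix
    n_runs = m.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    i = np.arange(1, m.shape[0] + 1, dtype=float)
    j = np.arange(1, m.shape[1] + 1, dtype=float)
    w = 1.0 / (i[:, None] ** 2 * j[None, :] ** 2)
    return float((m * w).sum() / n_runs)


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def compute_glszm(disc: DiscretizedROI) -> GLSZM:
    """Size-zone matrix: 26-connected components of equal gray level."""
    ng = disc.ng
    zones = []  # (level, size)
    for level in range(1, ng + 1):
        binary = disc.levels == level
        if not binary.any():
            continue
        labeled, n = ndimage.label(binary, structure=_STRUCT_26)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((level, int(s)) for s in sizes)
    if not zones:
        raise ValueError("empty size-zone matrix: mask has no voxels")
    max_size = max(s for _, s in zones)
    m = np.zeros((ng, max_size), dtype=np.int64)
    for level, size in zones:
        m[level - 1, size - 1] += 1
    return GLSZM(matrix=m, ng=ng)


def _szm_weights(s: GLSZM):
    i = np.arange(1, s.matrix.shape[0] + 1, dtype=float)
    j = np.arange(1, s.matrix.shape[1] + 1, dtype=float)
    return i[:, None], j[None, :], float(s.matrix.sum())


def high_intensity_large_area_emphasis(s: GLSZM) -> float:
    """HILAE = (1/N_z) sum s(i,j) i^2 j^2: large bright zones."""
    i, j, nz = _szm_weights(s)
    return float((s.matrix * i**2 * j**2).sum() / nz)


def low_intensity_large_area_emphasis(s: GLSZM) -> float:
    """LILAE = (1/N_z) sum s(i,j) j^2 / i^2: large dark zones."""
    i, j, nz = _szm_weights(s)
    return float((s.matrix * j**2 / i**2).sum() / nz)


def low_intensity_small_area_emphasis(s: GLSZM) -> float:
    """LISAE = (1/N_z) sum s(i,j) / (i^2 j^2): small dark zones."""
    i, j, nz = _szm_weights(s)
    return float((s.matrix / (i**2 * j**2)).sum() / nz)


def first_order(grid: VoxelGrid, mask: ROIMask) -> dict[str, float]:
    """Mean, median, minimum and Fisher-moment skewness of masked intensities.

    Skewness is m3 / m2^(3/2) (population moments); defined as 0 for a
    constant ROI.
    """
    mask.check_aligned(grid)
    vals = grid.values[mask.values]
    if vals.size == 0:
        raise ValueError("mask is empty")
    m2 = float(np.mean((vals - vals.mean()) ** 2))
    if m2 == 0:
        skew = 0.0
    else:
        m3 = float(np.mean((vals - vals.mean()) ** 3))
        skew = m3 / m2**1.5
    return {
        "mean": float(vals.mean()),
        "median": float(np.median(vals)),
        "minimum": float(vals.min()),
        "skewness": skew,
    }


def spherical_disproportion(mask: ROIMask) -> float:
    """Surface area over that of the equal-volume sphere: A / (4 pi R^2).

    R = (3V / 4pi)^(1/3) with V = voxel count x voxel volume; A from a
    marching-cubes mesh of the (zero-padded) mask. 1 for a perfect sphere,
    larger for any other shape, up to mesh discretization error.
    """
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    s = mask.spacing
    if abs(s[0] - s[1]) > 1e-9 or abs(s[1] - s[2]) > 1e-9:
        raise ValueError(f"spherical disproportion requires isotropic spacing, got {s}")
    padded = np.pad(mask.values.astype(float), 2)
    # mesh a lightly smoothed mask: marching cubes on raw binary data facets
    # along voxel walls and overestimates a sphere's area by ~9%, while heavy
    # smoothing erodes corners; sigma 0.5 voxel balances the two
    smoothed = ndimage.gaussian_filter(padded, sigma=0.5)
    verts, faces, _, _ = measure.marching_cubes(smoothed, level=0.5, spacing=s)
    area = float(measure.mesh_surface_area(verts, faces))
    volume = mask.voxel_count * float(np.prod(s))
    radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
    return area / (4.0 * np.pi * radius**2)


def glcm_features(disc: DiscretizedROI) -> dict[str, float]:
    g = compute_glcm(disc)
    return {
        "cluster_prominence": cluster_prominence(g),
        "difference_entropy": difference_entropy(g),
        "inverse_difference_normalized": inverse_difference_normalized(g),
    }


def glrlm_features(disc: DiscretizedROI) -> dict[str, float]:
    r = compute_glrlm(disc)
    return {
        "run_length_nonuniformity": run_length_nonuniformity(r),
        "short_run_low_gray_emphasis": short_run_low_gray_emphasis(r),
    }


def glszm_features(disc: DiscretizedROI) -> dict[str, float]:
    s = compute_glszm(disc)
    return {
        "high_intensity_large_area_emphasis": high_intensity_large_area_emphasis(s),
        "low_intensity_large_area_emphasis": low_intensity_large_area_emphasis(s),
        "low_intensity_small_area_emphasis": low_intensity_small_area_emphasis(s),
    }


def extract_features(
    grid: VoxelGrid,
    mask: ROIMask,
    channels: list[FilterChannel] | None = None,
    ng: int = 32,
) -> dict[str, dict[str, float]]:
    """Compute the 13-feature set per filter channel.

    ``channels`` defaults to the original channel only. Intensity and texture
    features are recomputed on each channel (each channel is re-discretized
    over the mask); the shape feature is reported for the original channel
    only, since filtering does not change the segmentation. Returns
    ``{channel_name: {feature_name: value}}``, deterministic for fixed input.
    """
    from .preprocessing import discretize  # local import to avoid cycle

    if channels is None:
        channels = [FilterChannel("original", grid)]
    out: dict[str, dict[str, float]] = {}
    for ch in channels:
        try:
            feats = dict(first_order(ch.grid, mask))
            disc = discretize(ch.grid, mask, ng=ng)
            feats.update(glcm_features(disc))
            feats.update(glrlm_features(disc))
            feats.update(glszm_features(disc))
            if ch.name == "original":
                feats["spherical_disproportion"] = spherical_disproportion(mask)
        except ValueError as err:
            raise ValueError(f"channel '{ch.name}': {err}") from err
        out[ch.name] = feats
    return out
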