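"""3D cell segmentation from the round-1 cell-wall channel.

Classical boundary-map + seeded-watershed segmentation: the smoothed,
min-max-normalized wall intensity serves as a boundary probability map;
seeds are the connected regions of low boundary probability (thresholded
basins of the seed-smoothed map); a marker-based 3D watershed floods the
probability map inside an Otsu tissue mask, and regions below a minimum
size are merged into the neighbour sharing the largest boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from plantfish.core import DEFAULT_VOXEL_SIZE, VolumeStack

__all__ = [
    "SegmentationMask",
    "boundary_probability",
    "tissue_mask",
    "watershed_segment",
    "rescale_mask",
]


@dataclass
class SegmentationMask:
    """Labeled cells (0 = background) with a per-cell geometry table."""

    label_volume: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    cell_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.cell_table is None:
            self.cell_table = compute_cell_table(self.label_volume, self.voxel_size)

    @property
    def n_cells(self) -> int:
        return len(self.cell_table)

    def labels(self) -> np.ndarray:
        return self.cell_table["label"].to_numpy()


def compute_cell_table(
    label_volume: np.ndarray, voxel_size: tuple[float, float, float]
) -> pd.DataFrame:
    """Per-label centroid (µm) and volume (µm³); recomputable at any time."""
    labels = np.unique(label_volume)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.DataFrame(columns=["label", "z_um", "y_um", "x_um", "volume_um3", "n_voxels"])
    vs = np.asarray(voxel_size)
    centroids = np.asarray(ndimage.center_of_mass(np.ones_like(label_volume), label_volume, labels))
    sizes = ndimage.sum_labels(np.ones_like(label_volume), label_volume, labels)
    return pd.DataFrame(
        {
            "label": labels.astype(int),
            "z_um": centroids[:, 0] * vs[0],
            "y_um": centroids[:, 1] * vs[1],
            "x_um": centroids[:, 2] * vs[2],
            "volume_um3": sizes * float(np.prod(vs)),
            "n_voxels": sizes.astype(int),
        }
    )


def boundary_probability(
    wall: VolumeStack, smoothing_sigma_um: float = 0.5, percentiles: tuple[float, float] = (1.0, 99.0)
) -> VolumeStack:
    """Gaussian-smoothed, robustly min-max-normalized wall intensity in [0, 1].

    Normalization bounds are intensity percentiles rather than the raw
    extrema, so a handful of bright wall-junction hotspots cannot compress
    the useful wall/interior contrast; values beyond the bounds clip to 0/1.
    """
    data = np.asarray(wall.data, dtype=np.float32)
    if data.size == 0:
        raise ValueError("empty wall volume")
    sigma_vox = smoothing_sigma_um / np.asarray(wall.voxel_size)
    smooth = ndimage.gaussian_filter(data, sigma=sigma_vox)
    lo, hi = np.percentile(smooth, percentiles)
    if hi - lo < 1e-12:
        raise ValueError("constant wall channel: no boundary signal")
    return VolumeStack(np.clip((smooth - lo) / (hi - lo), 0.0, 1.0), wall.voxel_size)


def tissue_mask(wall: VolumeStack, smoothing_sigma_um: float = 4.0) -> np.ndarray:
    """Foreground mask: Otsu threshold of the heavily smoothed wall, filled."""
    sigma_vox = smoothing_sigma_um / np.asarray(wall.voxel_size)
    smooth = ndimage.gaussian_filter(np.asarray(wall.data, dtype=np.float32), sigma=sigma_vox)
    mask = smooth > threshold_otsu(smooth)
    return ndimage.binary_fill_holes(mask)


def watershed_segment(
    prob: VolumeStack,
    boundary_threshold: float = 0.3,
    seed_sigma: float = 1.0,
    min_cell_voxels: int = 64,
    seed_depth: float = 0.1,
    mask: np.ndarray | None = None,
) -> SegmentationMask:
    """Marker-based 3D watershed of the boundary probability map.

    Markers are the local-minimum basins of the ``seed_sigma``-smoothed
    probability — minima at least ``seed_depth`` below their surrounding
    ridges (h-minima, which keeps seeding insensitive to the absolute wall
    intensity) — restricted to voxels below ``boundary_threshold`` inside
    the tissue mask. Labels smaller than ``min_cell_voxels`` are merged
    into the neighbour with which they share the largest boundary.
    """
    data = np.asarray(prob.data, dtype=np.float32)
    if data.min() < -1e-6 or data.max() > 1 + 1e-6:
        raise ValueError("probability volume must lie in [0, 1]")
    if mask is None:
        mask = tissue_mask(prob)
    smooth = ndimage.gaussian_filter(data, sigma=seed_sigma) if seed_sigma > 0 else data
    minima = h_minima(np.where(mask, smooth, 1.0), seed_depth).astype(bool)
    below = (smooth < boundary_threshold) & mask
    seeds, n_seeds = ndimage.label(minima & below)
    if n_seeds == 0 and below.any():
        # flat basins carry no h-minima; fall back to the thresholded basins
        seeds, n_seeds = ndimage.label(below)
    if n_seeds == 0:
        raise ValueError(
            "no watershed seeds below the boundary threshold; raise boundary_threshold"
        )
    labels = watershed(data, markers=seeds, mask=mask)
    labels = _merge_small_regions(labels, min_cell_voxels)
    labels = _relabel_consecutive(labels)
    return SegmentationMask(label_volume=labels.astype(np.int32), voxel_size=prob.voxel_size)


def _merge_small_regions(labels: np.ndarray, min_voxels: int) -> np.ndarray:
    """Merge each under-sized region into the neighbour sharing most boundary."""
    if min_voxels <= 1:
        return labels
    labels = labels.copy()
    while True:
        ids, sizes = np.unique(labels[labels > 0], return_counts=True)
        small = ids[sizes < min_voxels]
        if small.size == 0:
            return labels
        merged_any = False
        order = np.argsort(sizes[np.isin(ids, small)])
        for label in small[order]:
            region = labels == label
            ring = ndimage.binary_dilation(region) & ~region
            neighbours = labels[ring]
            neighbours = neighbours[(neighbours > 0) & (neighbours != label)]
            if neighbours.size == 0:
                labels[region] = 0  # isolated fleck: discard to background
            else:
                counts = np.bincount(neighbours)
                labels[region] = int(np.argmax(counts))
            merged_any = True
        if not merged_any:
            return labels


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    mapping = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    mapping[ids] = np.arange(1, ids.size + 1, dtype=np.int32)
    return mapping[labels]


def rescale_mask(mask: SegmentationMask, factors: tuple[float, float, float]) -> SegmentationMask:
    """Nearest-neighbour label resampling by per-axis zoom factors.

    Voxel size is divided by the factors so physical geometry is preserved;
    labels that vanish at the new resolution are reported via the returned
    mask's cell table (they are simply absent).
    """
    factors = tuple(float(f) for f in factors)
    if any(f <= 0 for f in factors):
        raise ValueError("zoom factors must be positive")
    if factors == (1.0, 1.0, 1.0):
        return SegmentationMask(mask.label_volume.copy(), mask.voxel_size)
    resampled = ndimage.zoom(mask.label_volume, zoom=factors, order=0, mode="nearest")
    new_vs = tuple(v / f for v, f in zip(mask.voxel_size, factors))
    return SegmentationMask(resampled, new_vs)


def segment_wall(
    wall: VolumeStack,
    smoothing_sigma_um: float = 0.5,
    boundary_threshold: float = 0.3,
    seed_sigma: float = 1.0,
    min_cell_voxels: int = 64,
) -> SegmentationMask:
    """Convenience: boundary map + tissue mask + watershed in one call."""
    prob = boundary_probability(wall, smoothing_sigma_um)
    return watershed_segment(
        prob,
        boundary_threshold=boundary_threshold,
        seed_sigma=seed_sigma,
        min_cell_voxels=min_cell_voxels,
        mask=tissue_mask(wall),
    )
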