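"""Affine registration of imaging rounds onto round 1 via the cell-wall channel.

Each round's wall (Calcofluor) volume is aligned to the round-1 reference by
a global 3D affine estimated from feature correspondences: Laplacian-of-
Gaussian maxima on the wall web (wall-junction corners) described by
normalized local intensity patches, matched by mutual nearest neighbour with
a Lowe ratio test, and fitted robustly with RANSAC (4-point minimal affine
fits, least-squares refit on the consensus set). An optional coarse integer
translation from phase correlation widens the capture range before matching.

All geometry is in physical µm; anisotropic voxels enter only through the
voxel-size scaling of coordinates and of the resampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

from plantfish.core import AffineTransform3D, VolumeStack

__all__ = [
    "FeatureSet",
    "detect_features",
    "match_features",
    "ransac_affine",
    "apply_transform",
    "register_wall",
    "register_rounds",
    "write_transforms_csv",
    "read_transforms_csv",
]


@dataclass
class FeatureSet:
    """Keypoints (µm) with fixed-length normalized patch descriptors."""

    points: np.ndarray  # (n, 3) µm
    descriptors: np.ndarray  # (n, d)

    def __len__(self) -> int:
        return self.points.shape[0]


class RegistrationError(RuntimeError):
    pass


def _robust_sigma(values: np.ndarray) -> float:
    med = np.median(values)
    return 1.4826 * float(np.median(np.abs(values - med)))


def detect_features(
    wall: VolumeStack,
    sigma_um: float = 1.0,
    rel_threshold: float = 0.25,
    max_features: int = 1500,
    patch_radius: tuple[int, int, int] = (2, 4, 4),
) -> FeatureSet:
    """LoG blob maxima on the wall channel with local patch descriptors.

    The negated scale-normalized LoG of the wall highlights bright corner/
    junction structure at scale ``sigma_um``; 26-neighbourhood maxima above
    ``rel_threshold`` times the peak response are kept (strongest first, up
    to ``max_features``; the relative threshold keeps the cut comparable
    between raw and interpolation-smoothed volumes). Descriptors are
    z-scored intensity patches of ``2*patch_radius+1`` voxels around each
    keypoint.
    """
    data = np.asarray(wall.data, dtype=np.float32)
    vs = np.asarray(wall.voxel_size)
    sigma_vox = sigma_um / vs
    ptp = float(data.max() - data.min())
    if ptp <= 0:
        return FeatureSet(points=np.empty((0, 3)), descriptors=np.empty((0, 0)))
    response = -(sigma_um**2) * ndimage.gaussian_laplace(data, sigma=sigma_vox)
    local_max = response == ndimage.maximum_filter(response, size=3, mode="nearest")
    peak = float(response.max())
    # the absolute floor guards against numerically-flat responses
    candidates = local_max & (response > max(rel_threshold * peak, 1e-6 * ptp))
    # keep peaks away from the border so full descriptor patches exist
    pr = np.asarray(patch_radius)
    interior = np.zeros_like(candidates)
    interior[pr[0] : -pr[0] or None, pr[1] : -pr[1] or None, pr[2] : -pr[2] or None] = True
    coords = np.argwhere(candidates & interior)
    if coords.shape[0] == 0:
        return FeatureSet(points=np.empty((0, 3)), descriptors=np.empty((0, 0)))
    strengths = response[tuple(coords.T)]
    order = np.argsort(strengths)[::-1][:max_features]
    coords = coords[order]

    patches = np.stack(
        [
            data[
                z - pr[0] : z + pr[0] + 1,
                y - pr[1] : y + pr[1] + 1,
                x - pr[2] : x + pr[2] + 1,
            ].ravel()
            for z, y, x in coords
        ]
    )
    mean = patches.mean(axis=1, keepdims=True)
    std = patches.std(axis=1, keepdims=True)
    std[std < 1e-8] = 1e-8
    descriptors = (patches - mean) / std
    return FeatureSet(points=coords * vs, descriptors=descriptors.astype(np.float32))


def match_features(
    fixed: FeatureSet, moving: FeatureSet, max_ratio: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """Mutual-nearest-neighbour descriptor matches passing a Lowe ratio test.

    Returns ``(fixed_points, moving_points)`` of matched µm coordinates
    (moving point i corresponds to fixed point i).
    """
    if len(fixed) == 0 or len(moving) == 0:
        raise RegistrationError("cannot match empty feature sets")
    d2 = (
        np.sum(fixed.descriptors**2, axis=1)[:, None]
        + np.sum(moving.descriptors**2, axis=1)[None, :]
        - 2.0 * fixed.descriptors @ moving.descriptors.T
    )
    nn_of_fixed = np.argmin(d2, axis=1)
    nn_of_moving = np.argmin(d2, axis=0)
    fixed_idx = np.arange(len(fixed))
    mutual = nn_of_moving[nn_of_fixed] == fixed_idx
    if len(moving) >= 2:
        part = np.partition(d2, 1, axis=1)
        ratio = np.sqrt(np.maximum(part[:, 0], 0) / np.maximum(part[:, 1], 1e-12))
        mutual &= ratio < max_ratio
    keep = np.flatnonzero(mutual)
    if keep.size == 0:
        raise RegistrationError("no feature matches survive the ratio test")
    return fixed.points[keep], moving.points[nn_of_fixed[keep]]


def _fit_affine_lstsq(moving: np.ndarray, fixed: np.ndarray) -> AffineTransform3D:
    """Least-squares affine mapping moving -> fixed (µm)."""
    design = np.hstack([moving, np.ones((moving.shape[0], 1))])
    params, *_ = np.linalg.lstsq(design, fixed, rcond=None)
    return AffineTransform3D(params[:3].T, params[3])


def ransac_affine(
    fixed_pts: np.ndarray,
    moving_pts: np.ndarray,
    inlier_tol_um: float = 2.0,
    n_iter: int = 2000,
    seed: int = 0,
    min_inliers: int = 4,
) -> tuple[AffineTransform3D, np.ndarray]:
    """RANSAC affine (moving -> fixed) with least-squares refit on inliers.

    Repeated 4-point minimal fits (degenerate, near-coplanar samples are
    resampled); the consensus set with the most inliers within
    ``inlier_tol_um`` wins, ties broken by smaller mean residual.
    Deterministic per seed.
    """
    fixed_pts = np.asarray(fixed_pts, dtype=float)
    moving_pts = np.asarray(moving_pts, dtype=float)
    n = fixed_pts.shape[0]
    if n < 4 or moving_pts.shape[0] != n:
        raise RegistrationError(f"need >= 4 correspondences, got {n}")
    rng = np.random.default_rng(seed)
    best: tuple[int, float, np.ndarray] | None = None
    any_valid = False
    for _ in range(n_iter):
        sample = rng.choice(n, size=4, replace=False)
        m = moving_pts[sample]
        # degeneracy: the 4 sample points must span 3D (non-coplanar)
        vol = abs(np.linalg.det(m[1:] - m[0]))
        if vol < 1e-6:
            continue
        try:
            t = _fit_affine_lstsq(m, fixed_pts[sample])
        except ValueError:  # fixed-side degeneracy -> singular fit
            continue
        any_valid = True
        residual = np.linalg.norm(t.apply(moving_pts) - fixed_pts, axis=1)
        inliers = residual < inlier_tol_um
        count = int(inliers.sum())
        mean_res = float(residual[inliers].mean()) if count else np.inf
        if best is None or (count, -mean_res) > (best[0], -best[1]):
            best = (count, mean_res, inliers)
    if not any_valid:
        raise RegistrationError("all RANSAC samples degenerate (coplanar features?)")
    count, _, inliers = best
    if count < min_inliers:
        raise RegistrationError(f"consensus too small ({count} inliers)")
    refit = _fit_affine_lstsq(moving_pts[inliers], fixed_pts[inliers])
    residual = np.linalg.norm(refit.apply(moving_pts) - fixed_pts, axis=1)
    inliers = residual < inlier_tol_um
    refit = _fit_affine_lstsq(moving_pts[inliers], fixed_pts[inliers])
    return refit, inliers


def apply_transform(
    volume: VolumeStack, t: AffineTransform3D, order: int = 1, cval: float = 0.0
) -> VolumeStack:
    """Resample ``volume`` through the µm-space affine ``t`` (moving -> fixed).

    The output lives on the same voxel grid: ``out(v) = volume(T⁻¹(S v))``
    with S the voxel-to-µm scaling; out-of-bounds voxels are ``cval``.
    Identity transforms return the input data unchanged.
    """
    if t.is_identity():
        return VolumeStack(volume.data.copy(), volume.voxel_size)
    scale = np.diag(volume.voxel_size)
    inv = t.inverse()
    matrix = np.linalg.inv(scale) @ inv.matrix @ scale
    offset = np.linalg.inv(scale) @ inv.translation
    resampled = ndimage.affine_transform(
        volume.data, matrix, offset=offset, order=order, mode="constant", cval=cval,
        output=np.float32 if np.issubdtype(volume.data.dtype, np.floating) else None,
    )
    return VolumeStack(resampled, volume.voxel_size)


def register_wall(
    fixed_wall: VolumeStack,
    moving_wall: VolumeStack,
    inlier_tol_um: float = 2.0,
    n_iter: int = 2000,
    seed: int = 0,
    coarse: bool = True,
    sigma_um: float = 1.0,
) -> AffineTransform3D:
    """Estimate the µm affine mapping the moving round onto the fixed round.

    Optional coarse stage: the integer-voxel translation from phase
    correlation pre-shifts the moving volume so feature matching only has to
    absorb the residual rotation/scale; the final transform composes both.
    """
    coarse_t = AffineTransform3D.identity()
    moving_used = moving_wall
    if coarse:
        shift_vox, _, _ = phase_cross_correlation(
            fixed_wall.data, moving_wall.data, upsample_factor=1, normalization=None
        )
        shift_vox = np.round(shift_vox)
        if np.any(shift_vox != 0):
            coarse_t = AffineTransform3D(
                np.eye(3), shift_vox * np.asarray(moving_wall.voxel_size)
            )
            moving_used = apply_transform(moving_wall, coarse_t)
    fixed_feats = detect_features(fixed_wall, sigma_um=sigma_um)
    moving_feats = detect_features(moving_used, sigma_um=sigma_um)
    if len(fixed_feats) < 4 or len(moving_feats) < 4:
        raise RegistrationError(
            f"too few features (fixed {len(fixed_feats)}, moving {len(moving_feats)})"
        )
    fixed_pts, moving_pts = match_features(fixed_feats, moving_feats)
    fine, _ = ransac_affine(
        fixed_pts, moving_pts, inlier_tol_um=inlier_tol_um, n_iter=n_iter, seed=seed
    )
    return fine.compose(coarse_t)


def register_rounds(
    acquisitions: list["RoundAcquisition"],
    seed: int = 0,
    **kwargs,
) -> dict[int, AffineTransform3D]:
    """Register every round's wall channel onto round 1 (the reference)."""
    ref = acquisitions[0]
    if ref.round_index != 1:
        raise ValueError("acquisitions must start with round 1 (the reference)")
    transforms = {1: AffineTransform3D.identity()}
    for acq in acquisitions[1:]:
        transforms[acq.round_index] = register_wall(
            ref.wall, acq.wall, seed=seed + acq.round_index, **kwargs
        )
    return transforms


def write_transforms_csv(transforms: dict[int, AffineTransform3D], path) -> None:
    pd.DataFrame(
        [[r, *t.as_flat()] for r, t in sorted(transforms.items())],
        columns=["round"] + [f"p{i}" for i in range(12)],
    ).to_csv(path, index=False)


def read_transforms_csv(path) -> dict[int, AffineTransform3D]:
    df = pd.read_csv(path)
    return {
        int(row[0]): AffineTransform3D.from_flat(np.asarray(row[1:13], dtype=float))
        for row in df.itertuples(index=False)
    }
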