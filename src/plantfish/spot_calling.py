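"""RCP spot detection and (round, channel) lookup decoding.

Registered signal channels are preprocessed per round — a per-plane
difference-of-Gaussians bandpass (short/long length scales in pixels), a 1D
Gaussian low-pass along z, and a percentile clipping filter — then spots are
detected as scale-space Laplacian-of-Gaussian maxima at scales bracketing
the expected RCP radius (~0.5 µm), with 26-neighbourhood non-maximum
suppression and sub-voxel refinement by a local quadratic fit. Because each
gene owns exactly one (round, channel) slot of the codebook, decoding is a
pure lookup; spots falling in unused slots (including rounds past a
channel's usable limit) are dropped and counted.

The whole stage is deterministic: no randomness anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from plantfish.core import VolumeStack
from plantfish.probe_design import Codebook

__all__ = [
    "DecodedSpot",
    "bandpass_filter",
    "z_lowpass",
    "clip_intensities",
    "preprocess_volume",
    "detect_blobs",
    "decode_spots",
    "detect_round",
    "spots_to_frame",
]


@dataclass(frozen=True)
class DecodedSpot:
    """A sub-voxel 3D detection annotated with its codebook gene."""

    z_um: float
    y_um: float
    x_um: float
    round_index: int
    channel: int
    intensity: float
    sigma_um: float
    gene_id: str


def bandpass_filter(v: VolumeStack, lshort: float = 0.5, llong: float = 11.0) -> VolumeStack:
    """Per-xy-plane difference-of-Gaussians bandpass (scales in pixels).

    Passes structure between ``lshort`` and ``llong`` pixels; the long-scale
    subtraction removes the local background, so large smooth structures come
    out near zero.
    """
    if not (llong > lshort > 0):
        raise ValueError(f"need llong > lshort > 0, got lshort={lshort}, llong={llong}")
    data = np.asarray(v.data, dtype=np.float32)
    smooth = ndimage.gaussian_filter(data, sigma=(0.0, lshort, lshort))
    background = ndimage.gaussian_filter(data, sigma=(0.0, llong, llong))
    return VolumeStack(smooth - background, v.voxel_size)


def z_lowpass(v: VolumeStack, sigma_z: float = 1.0) -> VolumeStack:
    """1D Gaussian smoothing along z (in voxels); ``sigma_z=0`` is identity."""
    if sigma_z < 0:
        raise ValueError("sigma_z must be >= 0")
    if sigma_z == 0:
        return VolumeStack(np.asarray(v.data, dtype=np.float32).copy(), v.voxel_size)
    data = ndimage.gaussian_filter1d(
        np.asarray(v.data, dtype=np.float32), sigma=sigma_z, axis=0, mode="reflect"
    )
    return VolumeStack(data, v.voxel_size)


def clip_intensities(v: VolumeStack, low_pct: float = 0.5, high_pct: float = 99.9) -> VolumeStack:
    """Clip to the [low, high] intensity percentiles of the whole volume."""
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    data = np.asarray(v.data, dtype=np.float32)
    lo, hi = np.percentile(data, [low_pct, high_pct])
    return VolumeStack(np.clip(data, lo, hi), v.voxel_size)


def preprocess_volume(
    v: VolumeStack,
    lshort: float = 0.5,
    llong: float = 11.0,
    sigma_z: float = 1.0,
    low_pct: float = 0.5,
    high_pct: float = 99.9,
) -> VolumeStack:
    """Bandpass -> z low-pass -> percentile clip, in that order."""
    return clip_intensities(z_lowpass(bandpass_filter(v, lshort, llong), sigma_z), low_pct, high_pct)


def _quadratic_offset(values: np.ndarray) -> float:
    """Sub-voxel peak offset from a 3-point quadratic fit (clamped to ±0.5)."""
    denom = values[0] - 2.0 * values[1] + values[2]
    if abs(denom) < 1e-12:
        return 0.0
    offset = 0.5 * (values[0] - values[2]) / denom
    return float(np.clip(offset, -0.5, 0.5))


def detect_blobs(
    v: VolumeStack,
    spot_diameter_um: float = 1.0,
    n_scales: int = 3,
    threshold_factor: float = 6.0,
    scale_range: float = 1.4,
) -> pd.DataFrame:
    """Scale-space LoG spot detection with sub-voxel refinement.

    ``n_scales`` Gaussian scales geometrically bracket the nominal spot
    radius ``spot_diameter_um / 2``, anisotropy-corrected per axis. Maxima
    over the 26-neighbourhood and adjacent scales whose scale-normalized
    response exceeds ``threshold_factor`` robust (MAD-scaled) sigmas of that
    scale's own response are reported with µm positions, the detected scale
    (µm) and the local intensity of the input volume.
    """
    vs = np.asarray(v.voxel_size)
    if spot_diameter_um <= float(np.min(vs)):
        raise ValueError("spot diameter must exceed the voxel size")
    data = np.asarray(v.data, dtype=np.float32)
    if data.size == 0 or not np.any(data != data.flat[0]):
        return _empty_spot_frame()
    sigma0 = spot_diameter_um / 2.0
    if n_scales > 1:
        sigmas = sigma0 * np.geomspace(1.0 / scale_range, scale_range, n_scales)
    else:
        sigmas = np.array([sigma0])
    stack = np.stack(
        [-(s**2) * ndimage.gaussian_laplace(data, sigma=s / vs) for s in sigmas]
    )
    # each scale thresholded against its own noise floor (finer scales are
    # noisier; one shared threshold would flood the stack from below)
    noise = np.array(
        [1.4826 * float(np.median(np.abs(sl - np.median(sl)))) for sl in stack]
    )
    threshold = threshold_factor * np.maximum(noise, 1e-12)

    footprint = np.ones((3, 3, 3, 3), dtype=bool)
    local_max = stack == ndimage.maximum_filter(stack, footprint=footprint, mode="nearest")
    peaks = np.argwhere(local_max & (stack > threshold[:, None, None, None]))
    if peaks.shape[0] == 0:
        return _empty_spot_frame()

    rows = []
    shape = data.shape
    for s_idx, z, y, x in peaks:
        pos = np.array([z, y, x], dtype=float)
        for axis, coord in enumerate((z, y, x)):
            if 0 < coord < shape[axis] - 1:
                idx = [s_idx, z, y, x]
                line = []
                for d in (-1, 0, 1):
                    idx_axis = list(idx)
                    idx_axis[axis + 1] = coord + d
                    line.append(stack[tuple(idx_axis)])
                pos[axis] += _quadratic_offset(np.asarray(line))
        pos_um = pos * vs
        rows.append(
            (
                pos_um[0],
                pos_um[1],
                pos_um[2],
                float(data[z, y, x]),
                float(sigmas[s_idx]),
                float(stack[s_idx, z, y, x]),
            )
        )
    frame = pd.DataFrame(rows, columns=["z_um", "y_um", "x_um", "intensity", "sigma_um", "response"])
    return frame.sort_values(["z_um", "y_um", "x_um"], ignore_index=True)


def _empty_spot_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=["z_um", "y_um", "x_um", "intensity", "sigma_um", "response"])


def decode_spots(
    raw_spots: dict[tuple[int, int], pd.DataFrame], codebook: Codebook
) -> tuple[list[DecodedSpot], dict[tuple[int, int], int]]:
    """Annotate raw detections with the gene owning their (round, channel) slot.

    Spots in slots with no codebook gene — including rounds past a channel's
    usable limit — are dropped; the per-slot dropped counts are returned
    alongside. Decoding is a pure lookup, so spot order never matters.
    """
    inverse = {slot: gene for gene, slot in codebook.entries.items()}
    decoded: list[DecodedSpot] = []
    dropped: dict[tuple[int, int], int] = {}
    for (rnd, ch), frame in sorted(raw_spots.items()):
        n = len(frame)
        if n == 0:
            continue
        gene = inverse.get((rnd, ch))
        if gene is None or not codebook.slot_usable(rnd, ch):
            dropped[(rnd, ch)] = n
            if not codebook.slot_usable(rnd, ch):
                warnings.warn(
                    f"{n} spots in round {rnd} channel {ch}: past the channel's usable "
                    f"round limit; dropped",
                    stacklevel=2,
                )
            continue
        for row in frame.itertuples(index=False):
            decoded.append(
                DecodedSpot(
                    z_um=row.z_um,
                    y_um=row.y_um,
                    x_um=row.x_um,
                    round_index=rnd,
                    channel=ch,
                    intensity=row.intensity,
                    sigma_um=row.sigma_um,
                    gene_id=gene,
                )
            )
    return decoded, dropped


def detect_round(
    acquisition: "RoundAcquisition",
    transform: "AffineTransform3D | None" = None,
    spot_diameter_um: float = 1.0,
    **kwargs,
) -> dict[tuple[int, int], pd.DataFrame]:
    """Preprocess and detect all channels of one round, in the reference frame.

    Detection runs on the round's own voxel grid (no resampling — affine
    interpolation would correlate the noise floor and blur the spots);
    detected µm positions are then mapped into the round-1 reference frame
    through the round's registration transform. Spots mapped outside the
    reference volume are dropped.
    """
    out = {}
    extent = acquisition.wall.extent_um
    for ch, vol in sorted(acquisition.signal.items()):
        pre = preprocess_volume(vol)
        spots = detect_blobs(pre, spot_diameter_um=spot_diameter_um, **kwargs)
        if transform is not None and not transform.is_identity() and len(spots):
            moved = transform.apply(spots[["z_um", "y_um", "x_um"]].to_numpy())
            spots[["z_um", "y_um", "x_um"]] = moved
            inside = np.all((moved >= 0) & (moved <= extent[None, :]), axis=1)
            spots = spots[inside].reset_index(drop=True)
        out[(acquisition.round_index, ch)] = spots
    return out


def spots_to_frame(spots: list[DecodedSpot]) -> pd.DataFrame:
    """Decoded spots as a table (columns match the spots.tsv interface)."""
    return pd.DataFrame(
        [
            (s.z_um, s.y_um, s.x_um, s.round_index, s.channel, s.intensity, s.sigma_um, s.gene_id)
            for s in spots
        ],
        columns=["z_um", "y_um", "x_um", "round", "channel", "intensity", "sigma", "gene"],
    )
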