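"""Shared containers: 3D volumes, per-round acquisitions, affine transforms.

Conventions used throughout the package:

* arrays are ``(z, y, x)``, 0-based voxel indexing;
* physical coordinates are micrometres, ``(z, y, x)`` order, with voxel
  centre ``i`` at ``i * voxel_size`` along each axis;
* the default voxel size is ``(0.42, 0.57, 0.57)`` µm, the acquisition
  geometry of a 40x water objective confocal stack;
* affine transforms act in physical µm space (anisotropy is handled by the
  voxel-to-µm scaling, not inside the transform).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_VOXEL_SIZE = (0.42, 0.57, 0.57)


@dataclass
class VolumeStack:
    """One 3D image with its voxel size.

    Parameters
    ----------
    data
        ``(z, y, x)`` array; converted to ``float32`` unless integer labels
        are intended (callers keep label volumes as plain ndarrays instead).
    voxel_size
        ``(dz, dy, dx)`` in µm.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got shape {self.data.shape}")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be three positive floats, got {self.voxel_size}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_um(self) -> np.ndarray:
        """Physical extent (µm) along (z, y, x)."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def voxel_to_um(self, coords: np.ndarray) -> np.ndarray:
        """Convert (possibly fractional) voxel coordinates to µm."""
        return np.asarray(coords, dtype=float) * np.asarray(self.voxel_size)

    def um_to_voxel(self, coords: np.ndarray) -> np.ndarray:
        """Convert µm coordinates to fractional voxel coordinates."""
        return np.asarray(coords, dtype=float) / np.asarray(self.voxel_size)


@dataclass
class RoundAcquisition:
    """All volumes imaged in one hybridization round.

    ``wall`` is the cell-wall (Calcofluor) channel used for registration and
    segmentation; ``signal`` maps 1-based fluorescence channel -> volume.
    """

    round_index: int  # 1-based
    wall: VolumeStack
    signal: dict[int, VolumeStack] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.round_index < 1:
            raise ValueError("round_index is 1-based and must be >= 1")
        for ch, vol in self.signal.items():
            if vol.shape != self.wall.shape:
                raise ValueError(f"channel {ch} shape {vol.shape} != wall shape {self.wall.shape}")


@dataclass
class AffineTransform3D:
    """Affine map ``y = A @ x + b`` on (z, y, x) points in µm."""

    matrix: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineTransform3D":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 3)`` array (or a single point) of µm coords."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = pts @ self.matrix.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "AffineTransform3D":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform3D(inv, -inv @ self.translation)

    def compose(self, other: "AffineTransform3D") -> "AffineTransform3D":
        """Return the transform applying ``other`` first, then ``self``."""
        return AffineTransform3D(
            self.matrix @ other.matrix, self.matrix @ other.translation + self.translation
        )

    def as_flat(self) -> np.ndarray:
        """Serialize as 12 numbers (row-major 3x3, then translation)."""
        return np.concatenate([self.matrix.ravel(), self.translation])

    @classmethod
    def from_flat(cls, values: np.ndarray) -> "AffineTransform3D":
        values = np.asarray(values, dtype=float).ravel()
        if values.size != 12:
            raise ValueError("expected 12 numbers (9 matrix + 3 translation)")
        return cls(values[:9].reshape(3, 3), values[9:])

    def is_identity(self, atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.matrix, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )
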