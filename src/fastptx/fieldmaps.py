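"""Spatial data model: per-channel transmit sensitivities, off-resonance, mask.

A :class:`FieldMapSet` holds everything the designers need to know about one
subject (or phantom): complex B1+ sensitivity maps in nT/V for each transmit
channel, a B0 off-resonance map in Hz, a boolean region-of-interest mask and
the isotropic voxel size.  Maps travel in MATLAB v5 containers so they can be
exchanged with reconstruction pipelines; variable names inside the container
are configurable because no convention exists across sites.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import scipy.io

__all__ = [
    "FieldMapSet",
    "FieldMapError",
    "build_coords",
    "read_fieldmap_file",
    "write_fieldmap_file",
    "DEFAULT_KEYS",
]

#: default variable names inside the MAT container
DEFAULT_KEYS = ("B1", "B0", "mask")


class FieldMapError(ValueError):
    """Raised for malformed field-map containers or inconsistent arrays."""


def build_coords(grid_shape: Sequence[int], resolution: float) -> np.ndarray:
    """Per-voxel position vectors [m] on a centered grid.

    Voxel ``i`` along an axis of length ``N`` sits at ``(i - (N-1)/2) * res``,
    so the grid center is the coordinate origin; for even ``N`` the origin
    falls between the two middle voxels, keeping the k-space phase symmetric.

    Returns an array of shape ``(*grid_shape, 3)``.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if len(grid_shape) != 3 or any(n < 1 for n in grid_shape):
        raise FieldMapError(f"grid_shape must be 3 positive ints, got {grid_shape}")
    if not (resolution > 0):
        raise FieldMapError(f"resolution must be positive, got {resolution}")
    axes = [(np.arange(n) - (n - 1) / 2.0) * resolution for n in grid_shape]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    return np.stack([xs, ys, zs], axis=-1)


@dataclasses.dataclass
class FieldMapSet:
    """B1+ sensitivities [nT/V], B0 map [Hz], ROI mask and voxel geometry.

    ``b1`` is complex with shape ``(n_channels, *grid_shape)``; ``b0`` and
    ``mask`` have shape ``grid_shape``.  ``resolution`` is the isotropic voxel
    edge length in meters (anisotropic grids are not supported).
    """

    b1: np.ndarray
    b0: np.ndarray
    mask: np.ndarray
    resolution: float

    def __post_init__(self):
        res = self.resolution
        if isinstance(res, (tuple, list, np.ndarray)):
            vals = np.asarray(res, dtype=float).ravel()
            if vals.size != 1 and not np.all(vals == vals[0]):
                raise FieldMapError(
                    f"only isotropic resolution is supported, got {tuple(vals)}"
                )
            res = float(vals[0])
        self.resolution = float(res)
        if not self.resolution > 0:
            raise FieldMapError(f"resolution must be positive, got {self.resolution}")

        self.b1 = np.asarray(self.b1, dtype=np.complex128)
        self.b0 = np.asarray(self.b0, dtype=np.float64)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.b1.ndim != 4:
            raise FieldMapError(
                f"b1 must have shape (n_channels, nx, ny, nz), got {self.b1.shape}"
            )
        if self.b0.shape != self.b1.shape[1:]:
            raise FieldMapError(
                f"b0 shape {self.b0.shape} does not match b1 spatial dims "
                f"{self.b1.shape[1:]}"
            )
        if self.mask.shape != self.b0.shape:
            raise FieldMapError(
                f"mask shape {self.mask.shape} does not match b0 shape {self.b0.shape}"
            )
        if not (np.all(np.isfinite(self.b1)) and np.all(np.isfinite(self.b0))):
            raise FieldMapError("b1/b0 contain non-finite values")
        if not self.mask.any():
            raise FieldMapError("mask has no true voxel")

    # ------------------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.b1.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.b0.shape

    @property
    def coords(self) -> np.ndarray:
        """Per-voxel positions [m], shape ``(*grid_shape, 3)``, origin at center."""
        return build_coords(self.grid_shape, self.resolution)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())

    # masked (flattened) views used by the simulators -------------------
    def b1_masked(self) -> np.ndarray:
        """Complex sensitivities of masked voxels, shape (n_masked, n_channels)."""
        return self.b1[:, self.mask].T

    def b0_masked(self) -> np.ndarray:
        return self.b0[self.mask]

    def coords_masked(self) -> np.ndarray:
        return self.coords[self.mask]


def _detect_channel_axis(b1: np.ndarray, spatial_shape: tuple) -> np.ndarray:
    """Return b1 as (n_channels, *spatial_shape), detecting the on-disk layout.

    The channel axis is whichever axis removal leaves the spatial shape of the
    B0 map; ties are broken in favor of the first axis (documented convention).
    """
    if b1.ndim != 4:
        raise FieldMapError(f"B1 array must be 4-D, got shape {b1.shape}")
    for ax in range(4):
        rest = tuple(n for i, n in enumerate(b1.shape) if i != ax)
        if rest == tuple(spatial_shape):
            return np.moveaxis(b1, ax, 0)
    raise FieldMapError(
        f"no axis of B1 shape {b1.shape} matches the B0/mask shape {spatial_shape}"
    )


def read_fieldmap_file(
    path,
    keys: Sequence[str] = DEFAULT_KEYS,
    resolution: float | None = None,
) -> FieldMapSet:
    """Read a MATLAB field-map container.

    Parameters
    ----------
    path : str or Path
        MAT-file with the B1+ maps [nT/V], B0 map [Hz] and binary mask.
    keys : (str, str, str)
        Variable names of (b1, b0, mask) inside the container.
    resolution : float, optional
        Voxel size [m]; only used when the file itself carries no
        ``resolution`` variable.

    Units are passed through unchanged.
    """
    contents = scipy.io.loadmat(path)
    k_b1, k_b0, k_mask = keys
    for key in (k_b1, k_b0, k_mask):
        if key not in contents:
            raise FieldMapError(f"field-map file {path} is missing array '{key}'")
    b0 = np.squeeze(contents[k_b0]).astype(np.float64)
    mask = np.squeeze(contents[k_mask]).astype(bool)
    b1 = _detect_channel_axis(np.asarray(contents[k_b1]), b0.shape)
    if "resolution" in contents:
        resolution = float(np.squeeze(contents["resolution"]))
    if resolution is None:
        raise FieldMapError(
            f"{path} carries no 'resolution' variable; pass resolution= explicitly"
        )
    return FieldMapSet(b1=b1, b0=b0, mask=mask, resolution=resolution)


def write_fieldmap_file(maps: FieldMapSet, path, keys: Sequence[str] = DEFAULT_KEYS) -> None:
    """Write `maps` to a MATLAB v5 container readable by :func:`read_fieldmap_file`."""
    k_b1, k_b0, k_mask = keys
    scipy.io.savemat(
        path,
        {
            k_b1: maps.b1,
            k_b0: maps.b0,
            k_mask: maps.mask.astype(np.uint8),
            "resolution": maps.resolution,
        },
    )
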