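"""Shared data model and image/table I/O.

All microscopy inputs are held as :class:`VolumeImage` (axes normalized to
``(c, z, y, x)``) with explicit physical voxel spacing in micrometres.
Spacing is always user-supplied: TIFF metadata conventions are too
inconsistent to infer it reliably, and every downstream quantity (object
volumes, areas, centroids) is reported in µm-based units.

Coordinates are 0-based throughout; bins and masks use half-open
conventions unless a function documents otherwise.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    ChannelLookupError,
    FormatError,
    ValidationError,
)

__all__ = [
    "VolumeImage",
    "PlaneImage",
    "LabelMap",
    "load_volume",
    "central_frame",
    "write_records",
    "read_records",
]


def _validate_spacing(spacing: Sequence[float], ndim: int) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != ndim:
        raise ValidationError(f"spacing must have {ndim} components, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValidationError(f"spacing components must be positive, got {spacing}")
    return spacing


@dataclass(frozen=True)
class VolumeImage:
    """A multichannel 3D voxel grid with physical spacing.

    Parameters
    ----------
    voxels
        Intensity grid with axes ``(c, z, y, x)``.  Lower-dimensional arrays
        are promoted on construction: 2D becomes a single-channel,
        single-plane stack; 3D a single-channel stack.
    spacing
        ``(dz, dy, dx)`` voxel spacing in µm; all components positive.
    channel_names
        Ordered channel labels; defaults to ``ch0, ch1, ...``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_names: tuple[str, ...] = ()

    def __post_init__(self):
        arr = np.asarray(self.voxels)
        if arr.ndim == 2:
            arr = arr[np.newaxis, np.newaxis]
        elif arr.ndim == 3:
            arr = arr[np.newaxis]
        elif arr.ndim != 4:
            raise FormatError(f"expected 2-4 axes, got {arr.ndim}")
        if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
            raise ValidationError("voxel intensities must be finite")
        object.__setattr__(self, "voxels", arr)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing, 3))
        names = tuple(self.channel_names) or tuple(f"ch{i}" for i in range(arr.shape[0]))
        if len(names) != arr.shape[0]:
            raise ValidationError(
                f"{len(names)} channel names for {arr.shape[0]} channels"
            )
        object.__setattr__(self, "channel_names", names)
        if arr.shape[1] < 1:
            raise ValidationError("z-extent must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def nz(self) -> int:
        return self.voxels.shape[1]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < self.n_channels:
                raise ChannelLookupError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise ChannelLookupError(
                f"unknown channel {channel!r}; available: {self.channel_names}"
            ) from None

    def channel(self, channel: str | int) -> np.ndarray:
        """Return one channel as a ``(z, y, x)`` array."""
        return self.voxels[self.channel_index(channel)]


@dataclass(frozen=True)
class PlaneImage:
    """A single 2D plane with in-plane pixel spacing ``(dy, dx)`` in µm."""

    pixels: np.ndarray
    spacing: tuple[float, float]

    def __post_init__(self):
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValidationError(f"pixels must be 2D and at least 2x2, got {arr.shape}")
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "spacing", _validate_spacing(self.spacing, 2))

    @property
    def isotropic(self) -> bool:
        dy, dx = self.spacing
        return np.isclose(dy, dx, rtol=1e-6)


@dataclass(frozen=True)
class LabelMap:
    """Integer object labels over an image grid; 0 is background.

    Positive labels are guaranteed contiguous ``1..K`` after construction.
    """

    labels: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("labels must be an integer array")
        if arr.size and arr.min() < 0:
            raise ValidationError("labels must be non-negative")
        present = np.unique(arr)
        present = present[present > 0]
        if len(present) and (present[-1] != len(present)):
            # relabel to a gapless 1..K
            lut = np.zeros(int(present[-1]) + 1, dtype=arr.dtype)
            lut[present] = np.arange(1, len(present) + 1, dtype=arr.dtype)
            arr = lut[arr]
        object.__setattr__(self, "labels", arr)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))

    def __len__(self) -> int:
        return self.n_objects


def load_volume(
    path: str | os.PathLike,
    spacing: Sequence[float],
    channel_names: Sequence[str] = (),
) -> VolumeImage:
    """Read a TIFF stack into a :class:`VolumeImage`.

    2D files are promoted to a single-plane stack, 3D files to a
    single-channel stack, and 4D files are interpreted as ``(c, z, y, x)``.
    Intensities are preserved bit-exact.
    """
    spacing = _validate_spacing(spacing, 3)
    try:
        arr = tifffile.imread(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim not in (2, 3, 4):
        raise FormatError(f"TIFF has {arr.ndim} axes; expected 2, 3 or 4")
    return VolumeImage(arr, spacing, tuple(channel_names))


def save_volume(image: VolumeImage, path: str | os.PathLike) -> None:
    """Write a :class:`VolumeImage` to TIFF with axes ``(c, z, y, x)``.

    Singleton channel/plane axes are squeezed so that single-channel 2D/3D
    images round-trip through :func:`load_volume` unchanged.
    """
    arr = image.voxels
    if arr.shape[0] == 1:
        arr = arr[0]
        if arr.shape[0] == 1:
            arr = arr[0]
    tifffile.imwrite(os.fspath(path), arr, photometric="minisblack")


def central_frame(stack: VolumeImage, channel: str | int = 0) -> PlaneImage:
    """Extract the central z-plane of one channel.

    The plane at z-index ``floor(nz / 2)`` is returned (for even depths the
    upper of the two central planes, a documented convention).
    """
    vol = stack.channel(channel)
    return PlaneImage(vol[vol.shape[0] // 2], stack.spacing[1:])


def write_records(
    records: pd.DataFrame,
    path: str | os.PathLike,
    allow_empty: bool = False,
) -> None:
    """Write a per-object / per-gene table as headered CSV.

    Floats are written at full ``repr`` precision so that a write/read
    round-trip reproduces values bit-exact.
    """
    records = pd.DataFrame(records)
    if records.empty and not allow_empty:
        raise ValidationError("refusing to write an empty table (pass allow_empty=True)")
    records.to_csv(os.fspath(path), index=False)


def read_records(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(os.fspath(path), float_precision="round_trip")
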