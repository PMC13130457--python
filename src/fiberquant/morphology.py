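"""3D mitochondrial volume quantification and 2D shape metrics.

The 3D segmentation is a deliberately classical stand-in for learned
surface segmentation: Gaussian smoothing, a global Otsu threshold and
26-connected components.  Its contracts are segmentation-agnostic, so a
learned backend producing a label map can be swapped in without touching
the measurement code.

Shape metrics follow electron-microscopy practice on 2D masks: area in
µm², perimeter by sub-pixel marching-squares contour length on a lightly
smoothed mask field (naive pixel-edge counts bias disk circularity to
~0.6, weighted boundary steps to ~0.92), and circularity 4πA/P².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage import filters, measure

from .core_io import LabelMap, VolumeImage
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "VolumeDistributionSummary",
    "segment_mito_3d",
    "object_volumes",
    "shape_metrics_2d",
    "volume_distribution_summary",
    "compare_distributions",
    "mask_perimeter",
]


@dataclass(frozen=True)
class VolumeDistributionSummary:
    """Median and empirical CDF of a set of object volumes."""

    n_objects: int
    median_um3: float
    sorted_volumes: np.ndarray
    cumulative_fraction: np.ndarray

    def cdf(self, volume: float) -> float:
        """Fraction of objects with volume <= ``volume``."""
        return float(np.searchsorted(self.sorted_volumes, volume, side="right") / self.n_objects)


def segment_mito_3d(
    volume: VolumeImage,
    channel: str | int = 0,
    smooth_sigma: float = 0.7,
    min_voxels: int = 8,
) -> LabelMap:
    """Segment bright 3D objects: smooth, Otsu, 26-connected components.

    ``smooth_sigma`` is expressed in units of the finest voxel dimension
    and applied physically isotropically (the sigma along each axis is
    scaled by that axis's spacing), so coarse z-sampling is not
    over-blurred.  Components smaller than ``min_voxels`` are discarded
    and the rest relabeled 1..K.
    """
    if min_voxels < 1:
        raise ValidationError("min_voxels must be >= 1")
    vol = volume.channel(channel).astype(float)
    if vol.std() == 0:
        raise DegenerateInputError("volume has zero intensity variance")
    if smooth_sigma > 0:
        finest = min(volume.spacing)
        sigmas = [smooth_sigma * finest / s for s in volume.spacing]
        vol = ndimage.gaussian_filter(vol, sigmas)
    if vol.std() == 0:
        raise DegenerateInputError("volume is constant after smoothing")
    thr = filters.threshold_otsu(vol)
    binary = vol > thr
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_voxels)
    labels[np.isin(labels, small)] = 0
    return LabelMap(labels.astype(np.int32))


def object_volumes(labels: LabelMap, spacing) -> pd.DataFrame:
    """Per-object voxel count and physical volume (voxel count x dz·dy·dx)."""
    dz, dy, dx = (float(s) for s in spacing)
    if min(dz, dy, dx) <= 0:
        raise ValidationError("spacing must be positive")
    voxel_vol = dz * dy * dx
    counts = np.bincount(labels.labels.ravel())[1:]
    return pd.DataFrame(
        {
            "label": np.arange(1, len(counts) + 1, dtype=int),
            "voxel_count": counts.astype(int),
            "volume_um3": counts * voxel_vol,
        }
    )


def mask_perimeter(mask: np.ndarray, contour_sigma: float = 1.0) -> float:
    """Boundary length of a binary mask, in pixels.

    The mask is smoothed with a Gaussian (sigma ``contour_sigma``) and the
    0.5 iso-contour extracted by marching squares; the polygon length is
    the perimeter estimate.  The smoothing removes the staircase bias of
    rasterized boundaries (a digitized disk's raw contour is ~5% long).
    Lengths of all contours (e.g. around holes) are summed.
    """
    field = ndimage.gaussian_filter(np.pad(mask, 4).astype(float), contour_sigma)
    contours = measure.find_contours(field, 0.5)
    return float(
        sum(np.sqrt((np.diff(c, axis=0) ** 2).sum(axis=1)).sum() for c in contours)
    )


def shape_metrics_2d(labels: LabelMap, spacing, contour_sigma: float = 1.0) -> pd.DataFrame:
    """Area, perimeter and circularity (4πA/P²) per 2D object.

    Requires isotropic in-plane spacing; circularity is dimensionless and
    ~1 for a rasterized disk (within a 0.1 discretization tolerance for
    objects more than a few pixels across).
    """
    dy, dx = (float(s) for s in spacing)
    if min(dy, dx) <= 0:
        raise ValidationError("spacing must be positive")
    if not np.isclose(dy, dx, rtol=1e-6):
        raise ValidationError(f"in-plane spacing must be isotropic, got {(dy, dx)}")
    if labels.labels.ndim != 2:
        raise ValidationError("shape metrics are defined on 2D label maps")
    rows = []
    for rp in measure.regionprops(labels.labels):
        r0, c0, r1, c1 = rp.bbox
        mask = labels.labels[r0:r1, c0:c1] == rp.label
        perim_px = mask_perimeter(mask, contour_sigma)
        area_um2 = rp.area * dy * dx
        perim_um = perim_px * dx
        rows.append(
            {
                "label": int(rp.label),
                "area_um2": area_um2,
                "perimeter_um": perim_um,
                "circularity": 4.0 * np.pi * area_um2 / perim_um**2,
            }
        )
    return pd.DataFrame(rows, columns=["label", "area_um2", "perimeter_um", "circularity"])


def volume_distribution_summary(volumes) -> VolumeDistributionSummary:
    """Median (midpoint convention for even n) and empirical CDF."""
    v = np.sort(np.asarray(list(volumes), dtype=float))
    if v.size == 0:
        raise ValidationError("volume list must be non-empty")
    return VolumeDistributionSummary(
        n_objects=int(v.size),
        median_um3=float(np.median(v)),
        sorted_volumes=v,
        cumulative_fraction=np.arange(1, v.size + 1) / v.size,
    )


def compare_distributions(a, b) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test (asymptotic p-value)."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample must have at least 2 values")
    if np.array_equal(np.sort(a), np.sort(b)):
        return 0.0, 1.0  # identical samples: D = 0 exactly
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)
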