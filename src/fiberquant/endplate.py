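"""Endplate morphometry and dual-label AChR pixel-dominance turnover.

The endplate is segmented from the summed old+new bungarotoxin channels;
its volume is voxel count times voxel volume and its fragmentation the
number of 26-connected components.  Turnover is quantified per voxel:
each channel is normalized to its own 99th-percentile intensity within
the endplate mask (robust to per-channel acquisition gain and hot
pixels), and a voxel is assigned to the channel whose normalized
intensity exceeds the other's by more than a tie band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters

from .config import AnalysisConfig, EndplateConfig
from .core_io import VolumeImage
from .errors import ComputationError, DegenerateInputError, ValidationError

__all__ = [
    "EndplateRecord",
    "endplate_mask",
    "endplate_volume",
    "fragment_count",
    "pixel_dominance",
    "run_endplate_pipeline",
]


@dataclass(frozen=True)
class EndplateRecord:
    """Summary of one endplate: morphometry plus dominance fractions."""

    endplate_id: str
    volume_um3: float
    fragment_count: int
    n_mask_voxels: int
    new_fraction: float
    old_fraction: float
    tie_fraction: float

    def __post_init__(self):
        total = self.new_fraction + self.old_fraction + self.tie_fraction
        if self.n_mask_voxels and abs(total - 1.0) > 1e-9:
            raise ValidationError("dominance fractions must sum to 1")


def endplate_mask(
    btx: np.ndarray | list[np.ndarray],
    min_voxels: int = 30,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Binary endplate mask from one or more bungarotoxin channels.

    Channels are summed, smoothed and Otsu-thresholded; connected
    components smaller than ``min_voxels`` are dropped.
    """
    if isinstance(btx, (list, tuple)):
        total = np.sum([np.asarray(c, dtype=float) for c in btx], axis=0)
    else:
        total = np.asarray(btx, dtype=float)
    if total.std() == 0:
        raise DegenerateInputError("bungarotoxin signal has zero intensity variance")
    if smooth_sigma > 0:
        total = ndimage.gaussian_filter(total, smooth_sigma)
    binary = total > filters.threshold_otsu(total)
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_voxels)
    labels[np.isin(labels, small)] = 0
    return labels > 0


def endplate_volume(mask: np.ndarray, spacing) -> float:
    """Mask voxel count times voxel volume, in µm³ (0 for an empty mask)."""
    dz, dy, dx = (float(s) for s in spacing)
    if min(dz, dy, dx) <= 0:
        raise ValidationError("spacing must be positive")
    n = int(np.count_nonzero(mask))
    if n == 0:
        import warnings

        warnings.warn("endplate mask is empty; volume is 0", stacklevel=2)
    return n * dz * dy * dx


def fragment_count(mask: np.ndarray, min_fragment_voxels: int = 1) -> int:
    """Number of 26-connected components with >= ``min_fragment_voxels``."""
    if not mask.any():
        return 0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if min_fragment_voxels <= 1:
        return int(n)
    sizes = np.bincount(labels.ravel())[1:]
    return int(np.count_nonzero(sizes >= min_fragment_voxels))


def pixel_dominance(
    old: np.ndarray,
    new: np.ndarray,
    mask: np.ndarray,
    tie_delta: float = 0.05,
    norm_percentile: float = 99.0,
) -> tuple[float, float, float]:
    """Fractions of endplate voxels dominated by the new / old label.

    Each channel is divided by its own ``norm_percentile`` intensity over
    the mask; a voxel is new-dominant when normalized new exceeds
    normalized old by more than ``tie_delta``, old-dominant in the mirror
    case, and a tie otherwise.  Returns ``(new, old, tie)`` fractions,
    which sum to 1 exactly.  Invariant to independent positive rescaling
    of either channel, and symmetric under swapping the channels.
    """
    if not mask.any():
        raise ValidationError("endplate mask is empty")
    if tie_delta < 0:
        raise ValidationError("tie_delta must be >= 0")
    o = np.asarray(old, dtype=float)[mask]
    n_ = np.asarray(new, dtype=float)[mask]
    p_old = float(np.percentile(o, norm_percentile))
    p_new = float(np.percentile(n_, norm_percentile))
    if p_old <= 0 or p_new <= 0:
        raise ComputationError(
            f"channel normalization percentile must be positive (old={p_old}, new={p_new})"
        )
    diff = n_ / p_new - o / p_old
    total = diff.size
    n_new = int(np.count_nonzero(diff > tie_delta))
    n_old = int(np.count_nonzero(diff < -tie_delta))
    n_tie = total - n_new - n_old
    return n_new / total, n_old / total, n_tie / total


def run_endplate_pipeline(
    stack: VolumeImage,
    endplate_id: str = "ep1",
    config: AnalysisConfig | EndplateConfig | None = None,
) -> tuple[EndplateRecord, pd.DataFrame]:
    """Stack -> one endplate record (and a one-row table for export)."""
    if config is None:
        config = EndplateConfig()
    cfg = config.endplate if isinstance(config, AnalysisConfig) else config

    old = stack.channel(cfg.old_channel)
    new = stack.channel(cfg.new_channel)
    mask = endplate_mask([old, new], cfg.min_voxels, cfg.smooth_sigma)
    vol = endplate_volume(mask, stack.spacing)
    frags = fragment_count(mask, cfg.min_fragment_voxels)
    new_f, old_f, tie_f = pixel_dominance(
        old, new, mask, cfg.tie_delta, cfg.norm_percentile
    )
    record = EndplateRecord(
        endplate_id=endplate_id,
        volume_um3=vol,
        fragment_count=frags,
        n_mask_voxels=int(mask.sum()),
        new_fraction=new_f,
        old_fraction=old_f,
        tie_fraction=tie_f,
    )
    table = pd.DataFrame([record.__dict__])
    return record, table
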