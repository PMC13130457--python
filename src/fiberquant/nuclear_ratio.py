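"""Per-nucleus nuclear/cytoplasmic intensity ratios with per-muscle nesting.

Each nucleus's mean signal intensity is divided by one global cytoplasmic
mean per image (the cytoplasm is the fiber minus dilated nuclei).  The
muscle, not the nucleus, is the unit of analysis: ratios are averaged per
muscle before any group comparison, and muscle means are normalized to the
control-group grand mean so the control group averages exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters

from .config import AnalysisConfig, NuclearRatioConfig
from .core_io import LabelMap, VolumeImage
from .errors import (
    ComputationError,
    DegenerateInputError,
    DegenerateOutputError,
    ValidationError,
)

__all__ = [
    "segment_nuclei",
    "cytoplasm_mask",
    "nucleus_ratios",
    "aggregate_by_muscle",
    "normalize_to_control",
    "run_nc_pipeline",
]

NUCLEUS_COLUMNS = [
    "nucleus", "muscle_id", "group",
    "mean_nuclear_intensity", "mean_cytoplasmic_intensity", "ratio",
]


def segment_nuclei(
    dapi: np.ndarray,
    min_voxels: int = 30,
    smooth_sigma: float = 1.0,
    exclude_border: bool = True,
    spacing=None,
) -> LabelMap:
    """Segment nuclei from a DAPI channel (Otsu on the smoothed volume).

    26-connected components with at least ``min_voxels`` voxels are kept.
    Nuclei touching the lateral (y/x) image border are excluded by default:
    their partial volumes bias mean intensities.  When ``spacing`` is given
    the smoothing is physically isotropic (``smooth_sigma`` in units of the
    finest voxel dimension), avoiding over-blur along a coarse z-axis.
    """
    vol = np.asarray(dapi, dtype=float)
    if vol.std() == 0:
        raise DegenerateInputError("DAPI channel has zero intensity variance")
    if smooth_sigma > 0:
        if spacing is not None:
            finest = min(spacing)
            sigma = [smooth_sigma * finest / s for s in spacing]
        else:
            sigma = smooth_sigma
        vol = ndimage.gaussian_filter(vol, sigma)
    thr = filters.threshold_otsu(vol)
    binary = vol > thr
    labels, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())
    drop = set(np.flatnonzero(sizes < min_voxels).tolist())
    if exclude_border and n:
        for border in (
            labels[:, 0, :], labels[:, -1, :], labels[:, :, 0], labels[:, :, -1]
        ):
            drop.update(np.unique(border).tolist())
    drop.discard(0)
    if drop:
        labels[np.isin(labels, list(drop))] = 0
    return LabelMap(labels.astype(np.int32))


def cytoplasm_mask(
    fiber_mask: np.ndarray, nuclei: LabelMap, margin_px: int = 2
) -> np.ndarray:
    """Fiber voxels at least ``margin_px`` away from every nucleus."""
    if fiber_mask.shape != nuclei.labels.shape:
        raise ValidationError("fiber mask and nuclei label map shapes differ")
    nuc = nuclei.labels > 0
    if margin_px > 0:
        nuc = ndimage.binary_dilation(nuc, iterations=margin_px)
    mask = fiber_mask & ~nuc
    if not mask.any():
        raise DegenerateOutputError("cytoplasm mask is empty")
    return mask


def nucleus_ratios(
    signal: np.ndarray,
    nuclei: LabelMap,
    cytoplasm: np.ndarray,
    muscle_id: str,
    group: str,
) -> pd.DataFrame:
    """Per-nucleus mean signal over the image's global cytoplasmic mean."""
    sig = np.asarray(signal, dtype=float)
    if not cytoplasm.any():
        raise ValidationError("cytoplasm mask is empty")
    cyto_mean = float(sig[cytoplasm].mean())
    if cyto_mean <= 0:
        raise ComputationError(f"cytoplasmic mean must be positive, got {cyto_mean}")
    rows = []
    for label in range(1, nuclei.n_objects + 1):
        nuc_mean = float(sig[nuclei.labels == label].mean())
        rows.append(
            {
                "nucleus": label,
                "muscle_id": muscle_id,
                "group": group,
                "mean_nuclear_intensity": nuc_mean,
                "mean_cytoplasmic_intensity": cyto_mean,
                "ratio": nuc_mean / cyto_mean,
            }
        )
    return pd.DataFrame(rows, columns=NUCLEUS_COLUMNS)


def aggregate_by_muscle(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ratio per muscle (the biological replicate used for statistics)."""
    if records.empty:
        raise ValidationError("no nucleus records to aggregate")
    groups_per_muscle = records.groupby("muscle_id")["group"].nunique()
    mixed = groups_per_muscle[groups_per_muscle > 1]
    if not mixed.empty:
        raise ValidationError(
            f"muscle(s) {list(mixed.index)} carry more than one group label"
        )
    out = (
        records.groupby("muscle_id", sort=True)
        .agg(group=("group", "first"), mean_ratio=("ratio", "mean"), n_nuclei=("ratio", "size"))
        .reset_index()
    )
    return out


def normalize_to_control(summaries: pd.DataFrame, control_group: str) -> pd.DataFrame:
    """Divide each muscle's mean ratio by the control-group grand mean.

    The grand mean is taken over control muscles (not pooled nuclei), so
    the normalized control-group mean is exactly 1.
    """
    control = summaries[summaries["group"] == control_group]
    if control.empty:
        raise ValidationError(f"control group {control_group!r} has no muscles")
    grand = float(control["mean_ratio"].mean())
    if grand == 0:
        raise ComputationError("control-group mean ratio is zero")
    out = summaries.copy()
    out["normalized_ratio"] = out["mean_ratio"] / grand
    return out


def run_nc_pipeline(
    stack: VolumeImage,
    muscle_id: str,
    group: str,
    config: AnalysisConfig | NuclearRatioConfig | None = None,
    exclude_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stack -> per-nucleus ratio table.

    The fiber region is the union of the Otsu-thresholded smoothed signal
    channel and the segmented nuclei (nuclei dimmer than cytoplasm would
    otherwise fall outside).  ``exclude_mask`` removes regions (e.g. the
    sub-synaptic area) from both nuclei and cytoplasm.
    """
    if config is None:
        config = NuclearRatioConfig()
    cfg = config.nuclear_ratio if isinstance(config, AnalysisConfig) else config

    dapi = stack.channel(cfg.dapi_channel)
    signal = stack.channel(cfg.signal_channel).astype(float)
    nuclei = segment_nuclei(
        dapi, cfg.min_voxels, cfg.smooth_sigma, cfg.exclude_border, stack.spacing
    )
    smoothed = ndimage.gaussian_filter(signal, cfg.smooth_sigma) if cfg.smooth_sigma else signal
    if smoothed.std() == 0:
        raise DegenerateInputError("signal channel has zero intensity variance")
    fiber = (smoothed > filters.threshold_otsu(smoothed)) | (nuclei.labels > 0)
    if exclude_mask is not None:
        fiber &= ~exclude_mask
        labels = nuclei.labels.copy()
        labels[exclude_mask] = 0
        nuclei = LabelMap(labels)
    cyto = cytoplasm_mask(fiber, nuclei, cfg.margin_px)
    # measure on in-plane-eroded nuclei: segmentation can overshoot the
    # true boundary by ~1 voxel, and edge voxels carry partial-volume signal
    core = ndimage.binary_erosion(
        nuclei.labels > 0, structure=np.ones((1, 3, 3), dtype=bool)
    )
    eroded = np.where(core, nuclei.labels, 0)
    kept = LabelMap(eroded.astype(np.int32))
    if kept.n_objects:
        nuclei = kept
    return nucleus_ratios(signal, nuclei, cyto, muscle_id, group)
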