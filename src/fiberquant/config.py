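"""Analysis configuration: one validated parameter group per pipeline.

Every tunable surfaced by the pipelines lives here with its documented
default, so a run can be reproduced from a single YAML file.  Values are
range-checked at construction time, not at first use.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ValidationError

__all__ = [
    "OrientationConfig",
    "Morphology3DConfig",
    "NuclearRatioConfig",
    "EndplateConfig",
    "DEGConfig",
    "AnalysisConfig",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass
class OrientationConfig:
    """Parameters of the 2D mitochondria-orientation pipeline."""

    channel: str = "tomm20"
    sigma_spatial: float = 2.0          # bilateral filter, px
    sigma_range: float = 0.15           # bilateral filter, fraction of intensity range
    closing_radius: int = 5             # fiber segmentation, px
    frangi_scales: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    min_area_px: int = 10               # smallest mitochondrial object kept
    eccentricity_min: float = 0.3       # rounder objects have ill-defined angles
    mask_erosion_px: int = 8            # keep fiber-edge ridge responses out
    min_objects: int = 20               # below this the summary is flagged unreliable

    def __post_init__(self):
        _require(self.sigma_spatial > 0, "sigma_spatial must be positive")
        _require(self.sigma_range > 0, "sigma_range must be positive")
        _require(self.closing_radius >= 1, "closing_radius must be >= 1")
        _require(
            len(self.frangi_scales) > 0 and all(s > 0 for s in self.frangi_scales),
            "frangi_scales must be non-empty and positive",
        )
        _require(self.min_area_px >= 1, "min_area_px must be >= 1")
        _require(0 <= self.eccentricity_min < 1, "eccentricity_min must be in [0, 1)")
        _require(self.mask_erosion_px >= 0, "mask_erosion_px must be >= 0")


@dataclass
class Morphology3DConfig:
    """Parameters of 3D mitochondrial segmentation and shape metrics."""

    channel: str = "tomm20"
    smooth_sigma: float = 0.7           # Gaussian pre-smoothing, voxels
    min_voxels: int = 8                 # suppress single-voxel noise
    contour_sigma: float = 1.0          # mask smoothing for perimeter estimation, px

    def __post_init__(self):
        _require(self.smooth_sigma >= 0, "smooth_sigma must be >= 0")
        _require(self.min_voxels >= 1, "min_voxels must be >= 1")
        _require(self.contour_sigma > 0, "contour_sigma must be positive")


@dataclass
class NuclearRatioConfig:
    """Parameters of the nuclear/cytoplasmic intensity-ratio pipeline."""

    dapi_channel: str = "dapi"
    signal_channel: str = "ctbp1"
    smooth_sigma: float = 1.0
    min_voxels: int = 30
    margin_px: int = 2                  # dilation of nuclei excluded from cytoplasm
    exclude_border: bool = True         # drop nuclei touching the lateral image border

    def __post_init__(self):
        _require(self.smooth_sigma >= 0, "smooth_sigma must be >= 0")
        _require(self.min_voxels >= 1, "min_voxels must be >= 1")
        _require(self.margin_px >= 0, "margin_px must be >= 0")


@dataclass
class EndplateConfig:
    """Parameters of endplate morphometry and pixel-dominance turnover."""

    old_channel: str = "old"
    new_channel: str = "new"
    smooth_sigma: float = 1.0
    min_voxels: int = 30
    min_fragment_voxels: int = 10
    tie_delta: float = 0.05             # normalized-intensity tie band
    norm_percentile: float = 99.0       # per-channel normalization reference

    def __post_init__(self):
        _require(self.smooth_sigma >= 0, "smooth_sigma must be >= 0")
        _require(self.min_voxels >= 1, "min_voxels must be >= 1")
        _require(self.min_fragment_voxels >= 1, "min_fragment_voxels must be >= 1")
        _require(self.tie_delta >= 0, "tie_delta must be >= 0")
        _require(0 < self.norm_percentile <= 100, "norm_percentile must be in (0, 100]")


@dataclass
class DEGConfig:
    """Differential-expression thresholds for the gene classifier."""

    fc_thresh: float = 1.5              # linear fold change, boundary inclusive
    p_thresh: float = 0.05              # raw p-value, strict

    def __post_init__(self):
        _require(self.fc_thresh > 1.0, "fc_thresh must exceed 1")
        _require(0 < self.p_thresh <= 1, "p_thresh must be in (0, 1]")


@dataclass
class AnalysisConfig:
    """Top-level configuration bundling every pipeline's parameter group."""

    orientation: OrientationConfig = field(default_factory=OrientationConfig)
    morphology: Morphology3DConfig = field(default_factory=Morphology3DConfig)
    nuclear_ratio: NuclearRatioConfig = field(default_factory=NuclearRatioConfig)
    endplate: EndplateConfig = field(default_factory=EndplateConfig)
    deg: DEGConfig = field(default_factory=DEGConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        kwargs = {}
        groups = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, value in data.items():
            if key not in groups:
                raise ValidationError(f"unknown config group {key!r}")
            if key == "seed":
                kwargs[key] = int(value)
            else:
                factory = {
                    "orientation": OrientationConfig,
                    "morphology": Morphology3DConfig,
                    "nuclear_ratio": NuclearRatioConfig,
                    "endplate": EndplateConfig,
                    "deg": DEGConfig,
                }[key]
                if not isinstance(value, dict):
                    raise ValidationError(f"config group {key!r} must be a mapping")
                value = dict(value)
                for name in ("frangi_scales",):
                    if name in value:
                        value[name] = tuple(value[name])
                try:
                    kwargs[key] = factory(**value)
                except TypeError as exc:
                    raise ValidationError(f"bad parameters in group {key!r}: {exc}") from exc
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["orientation"]["frangi_scales"] = list(out["orientation"]["frangi_scales"])
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
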