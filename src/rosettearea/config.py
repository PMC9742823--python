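"""Per-image-set pipeline configuration.

Channel, threshold and scale choices are properties of an image set (its
background, lighting and camera), not of single images, so they live in a
YAML/JSON config file that is applied to every image in a batch.  Keys
mirror the pipeline stages::

    plate:    {method, threshold_value, threshold_direction, canny_low,
               canny_high, min_area_fraction, aspect_limits, closing_radius}
    channel:  {space, channel, equalize}
    threshold:{value, direction}          # value: 0-255 or "otsu"
    roi:      {top_fraction, side_margin_fraction}
    cluster:  {n_slots}
    filter:   {min_object_px}
    scale:    {mode, marker_area_mm2, plate_width_mm, plate_height_mm,
               search_region, marker_threshold}
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .plate import DetectionConfig
from .segmentation import ChannelSpec, RoiSpec

__all__ = ["ScaleConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ScaleConfig:
    mode: str = "auto"  # marker | plate | auto (marker with plate fallback)
    marker_area_mm2: float = 100.0
    plate_width_mm: float = 100.0
    plate_height_mm: float = 100.0
    search_region: tuple[int, int, int, int] | None = None  # crop coords; None = below ROI
    marker_threshold: float = 158.0

    def __post_init__(self) -> None:
        if self.mode not in ("marker", "plate", "auto"):
            raise ValueError(f"unknown scale mode {self.mode!r}")


@dataclass(frozen=True)
class PipelineConfig:
    plate: DetectionConfig = field(default_factory=DetectionConfig)
    channel: ChannelSpec = field(default_factory=ChannelSpec)
    threshold_value: float | str = "otsu"
    threshold_direction: str = "above"
    roi: RoiSpec = field(default_factory=RoiSpec)
    n_slots: int = 6
    min_object_px: int = 25
    scale: ScaleConfig = field(default_factory=ScaleConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kw: dict = {}
        if "plate" in d:
            p = dict(d["plate"])
            if "aspect_limits" in p:
                p["aspect_limits"] = tuple(p["aspect_limits"])
            kw["plate"] = DetectionConfig(**p)
        if "channel" in d:
            kw["channel"] = ChannelSpec(**d["channel"])
        if "threshold" in d:
            t = d["threshold"]
            kw["threshold_value"] = t.get("value", "otsu")
            kw["threshold_direction"] = t.get("direction", "above")
        if "roi" in d:
            kw["roi"] = RoiSpec(**d["roi"])
        if "cluster" in d:
            kw["n_slots"] = d["cluster"].get("n_slots", 6)
        if "filter" in d:
            kw["min_object_px"] = d["filter"].get("min_object_px", 25)
        if "scale" in d:
            s = dict(d["scale"])
            if s.get("search_region") is not None:
                s["search_region"] = tuple(s["search_region"])
            kw["scale"] = ScaleConfig(**s)
        return cls(**kw)

    def to_dict(self) -> dict:
        return {
            "plate": asdict(self.plate),
            "channel": asdict(self.channel),
            "threshold": {"value": self.threshold_value, "direction": self.threshold_direction},
            "roi": asdict(self.roi),
            "cluster": {"n_slots": self.n_slots},
            "filter": {"min_object_px": self.min_object_px},
            "scale": asdict(self.scale),
        }

    def digest(self) -> str:
        """Stable hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.from_dict(data)
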