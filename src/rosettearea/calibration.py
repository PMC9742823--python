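"""Pixel-to-physical-area calibration.

Two scale sources are supported: a red square reference marker of known
physical area placed inside the image, or the detected plate itself with its
known physical dimensions.  The marker is found by the same
threshold-and-count process used for the leaves, on the a* channel of
L*a*b* where red sits far positive regardless of lighting.  When both modes
are configured the marker wins and the plate is the fallback.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

from .segmentation import ChannelSpec, extract_channel

__all__ = [
    "ScaleCalibration",
    "ScaleNotFoundError",
    "detect_reference_marker",
    "calibrate",
    "pixels_to_area",
]

# a* of strong red is around +60 while neutral plate/background sit near 0;
# the default cut is at the midpoint of those modes on the shifted 0-255
# scale, so edge pixels split evenly and the count stays unbiased.
DEFAULT_MARKER_CHANNEL = ChannelSpec(space="Lab", channel="a")
DEFAULT_MARKER_THRESHOLD = 158.0


class ScaleNotFoundError(RuntimeError):
    """No reference marker found in the search region."""


@dataclass(frozen=True)
class ScaleCalibration:
    """mm^2-per-pixel factor plus its provenance."""

    mm2_per_px: float
    source: Literal["reference_marker", "plate"]
    pixel_count: int  # marker pixel count or plate pixel area
    known_physical_area: float  # mm^2

    def __post_init__(self) -> None:
        if self.mm2_per_px <= 0:
            raise ValueError("mm2_per_px must be positive")


def detect_reference_marker(
    image: np.ndarray,
    marker_channel: ChannelSpec = DEFAULT_MARKER_CHANNEL,
    threshold: float = DEFAULT_MARKER_THRESHOLD,
    search_region: tuple[int, int, int, int] | None = None,
    min_marker_px: int = 50,
) -> int:
    """Pixel count of the largest red component in the search region.

    ``search_region`` is an (x, y, w, h) rectangle, typically the lower
    portion of the plate crop, disjoint from the shoot ROI; ``None`` searches
    the whole image.  Raises :class:`ScaleNotFoundError` when no component
    reaches ``min_marker_px``.
    """
    if search_region is not None:
        x, y, w, h = search_region
        sub = image[y : y + h, x : x + w]
    else:
        sub = image
    gray = extract_channel(sub, marker_channel)
    mask = gray > threshold
    lab = cc_label(mask, connectivity=2)
    best = 0
    for rp in regionprops(lab):
        best = max(best, int(rp.area))
    if best < min_marker_px:
        raise ScaleNotFoundError("scale marker not found in search region")
    return best


def calibrate(
    pixels: int,
    known_physical_area: float,
    source: Literal["reference_marker", "plate"],
) -> ScaleCalibration:
    """mm2_per_px = known physical area / measured pixel count."""
    if pixels <= 0:
        raise ValueError("pixel count must be positive")
    if known_physical_area <= 0:
        raise ValueError("known_physical_area must be positive")
    return ScaleCalibration(
        mm2_per_px=known_physical_area / pixels,
        source=source,
        pixel_count=int(pixels),
        known_physical_area=float(known_physical_area),
    )


def pixels_to_area(pixel_count: int, cal: ScaleCalibration) -> float:
    """Physical area in mm^2 of a pixel count under a calibration."""
    return pixel_count * cal.mm2_per_px
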