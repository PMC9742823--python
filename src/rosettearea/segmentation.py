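"""Leaf identification, ROI restriction, shoot clustering and pixel counting.

The cropped plate image is reduced to a single grayscale channel in which
leaf tissue contrasts strongly with plate and background — the C channel of
CMYK or the b* channel of L*a*b* — then binarized at a per-image-set
threshold.  Objects are restricted to the top-of-plate region of interest
where rosettes sit, grouped into up to six shoots by one-dimensional
clustering of their x centroids, and each shoot's pixel count is read off
the zeroth image moment of its merged mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skimage import exposure
from skimage.color import rgb2lab
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import moments, regionprops

__all__ = [
    "ChannelSpec",
    "BinaryMask",
    "RoiSpec",
    "ShootObject",
    "ShootMeasurement",
    "extract_channel",
    "channel_histogram",
    "threshold_leaves",
    "find_shoot_objects",
    "cluster_shoots",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Which color channel to segment on.

    space: "CMYK", "Lab" or "gray"; channel: one of C/M/Y/K or L/a/b
    (ignored for gray).  ``equalize`` applies histogram equalization after
    extraction, useful for low-contrast image sets.
    """

    space: str = "CMYK"
    channel: str = "C"
    equalize: bool = False

    _VALID = {"CMYK": "CMYK", "Lab": "Lab", "gray": ""}

    def __post_init__(self) -> None:
        if self.space not in self._VALID:
            raise ValueError(f"unknown color space {self.space!r}")
        if self.space != "gray" and self.channel not in self._VALID[self.space]:
            raise ValueError(f"channel {self.channel!r} not in space {self.space!r}")


@dataclass(frozen=True)
class BinaryMask:
    raster: np.ndarray  # 2-D bool
    channel: ChannelSpec | None = None
    threshold: float | None = None
    direction: str | None = None


@dataclass(frozen=True)
class RoiSpec:
    """Top-of-plate region of interest.

    ``top_fraction`` of the crop height is retained from the top;
    ``side_margin_fraction`` is excluded from each side.  The default top
    half mirrors the observation that unmeasurable seedlings are those that
    have fallen below the middle of the plate.
    """

    top_fraction: float = 0.5
    side_margin_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must be in (0, 1]")
        if not 0 <= self.side_margin_fraction < 0.5:
            raise ValueError("side_margin_fraction must be in [0, 0.5)")

    def bounds(self, shape: tuple[int, int]) -> tuple[int, int, int]:
        """(row_stop, col_start, col_stop) of the ROI for a crop shape."""
        h, w = shape
        return (
            int(round(self.top_fraction * h)),
            int(round(self.side_margin_fraction * w)),
            w - int(round(self.side_margin_fraction * w)),
        )


@dataclass
class ShootObject:
    """One connected component inside the ROI (pre-clustering)."""

    pixels: np.ndarray  # (n, 2) array of (row, col)
    centroid: tuple[float, float]  # (x, y)

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)


@dataclass
class ShootMeasurement:
    """Per-seedling record: slot 1-6 left to right."""

    slot: int
    pixel_count: int
    centroid: tuple[float, float] | None
    present: bool

    def __post_init__(self) -> None:
        if not self.present and self.pixel_count != 0:
            raise ValueError("absent shoot must have pixel_count 0")


def _srgb_to_cmyk_c(rgb: np.ndarray) -> np.ndarray:
    """Naive device CMYK: K = 1 - max(R', G', B'); C = (1 - R' - K)/(1 - K)."""
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    k = 1.0 - np.maximum(np.maximum(r, g), b)
    denom = 1.0 - k
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (1.0 - r - k) / denom
        m = (1.0 - g - k) / denom
        y = (1.0 - b - k) / denom
    # pure black: K = 1, chromatic channels defined as 0
    for ch in (c, m, y):
        ch[denom == 0] = 0.0
    return np.stack([c, m, y, k], axis=-1)


def extract_channel(image: np.ndarray, spec: ChannelSpec) -> np.ndarray:
    """Reduce an RGB image to one 0-255 uint8 channel per ``spec``.

    CMYK uses the naive device formula (no ICC profile), scaled to 0-255.
    L*a*b* uses the standard sRGB -> XYZ (D65) -> L*a*b* transform with L*
    scaled from [0, 100] and a*/b* mapped affinely so that 128 is neutral
    (value = channel + 128, clipped).
    """
    rgbf = image.astype(float) / 255.0
    if spec.space == "gray":
        out = rgbf.mean(axis=-1) * 255.0
    elif spec.space == "CMYK":
        idx = "CMYK".index(spec.channel)
        out = _srgb_to_cmyk_c(rgbf)[..., idx] * 255.0
    else:  # Lab
        lab = rgb2lab(rgbf)
        idx = "Lab".index(spec.channel)
        ch = lab[..., idx]
        out = ch * 2.55 if idx == 0 else ch + 128.0
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    if spec.equalize:
        out = np.round(exposure.equalize_hist(out) * 255.0).astype(np.uint8)
    return out


def channel_histogram(gray: np.ndarray) -> np.ndarray:
    """256-bin intensity histogram used to pick per-image-set thresholds."""
    return np.bincount(np.asarray(gray, dtype=np.uint8).ravel(), minlength=256)


def plot_channel_histogram(gray: np.ndarray, out_path: str | None = None):
    """Render the channel histogram (threshold-picking aid); returns bins."""
    hist = channel_histogram(gray)
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(np.arange(256), hist, width=1.0, color="0.3")
        ax.set_xlabel("intensity")
        ax.set_ylabel("pixels")
        fig.tight_layout()
        fig.savefig(out_path, dpi=100)
        plt.close(fig)
    return hist


def threshold_leaves(
    gray: np.ndarray,
    threshold: float | Literal["otsu"] = "otsu",
    direction: Literal["above", "below"] = "above",
    channel: ChannelSpec | None = None,
) -> BinaryMask:
    """Binarize a channel raster at a fixed or Otsu-selected threshold.

    ``direction="above"`` keeps pixels strictly exceeding the threshold;
    ``"below"`` keeps pixels strictly under it.  "otsu" maximizes
    between-class variance over the 256-bin histogram.
    """
    gray = np.asarray(gray)
    t = float(threshold_otsu(gray)) if threshold == "otsu" else float(threshold)
    raster = gray > t if direction == "above" else gray < t
    return BinaryMask(raster=raster, channel=channel, threshold=t, direction=direction)


def find_shoot_objects(
    mask: BinaryMask | np.ndarray,
    roi: RoiSpec | None = None,
    min_object_px: int = 25,
    *,
    coord_transform=None,
    transformed_shape: tuple[int, int] | None = None,
) -> list[ShootObject]:
    """8-connected components intersecting the ROI, clipped to it.

    Components are clipped to the ROI first; clipped components smaller than
    ``min_object_px`` are discarded as speckle.  Objects entirely outside the
    ROI (e.g. rosettes fallen below mid-plate) are dropped by design.

    ``coord_transform`` optionally maps native (x, y) pixel coordinates into
    a de-rotated plate frame of shape ``transformed_shape``; the ROI test and
    reported centroids then live in that frame while pixel counts stay exact
    native-raster counts (no resampling loss for tilted plates).
    """
    raster = mask.raster if isinstance(mask, BinaryMask) else np.asarray(mask, dtype=bool)
    roi = roi or RoiSpec()
    shape_for_roi = transformed_shape if transformed_shape is not None else raster.shape
    row_stop, col_start, col_stop = roi.bounds(shape_for_roi)
    lab = cc_label(raster, connectivity=2)
    objects: list[ShootObject] = []
    for rp in regionprops(lab):
        rows, cols = rp.coords[:, 0].astype(float), rp.coords[:, 1].astype(float)
        if coord_transform is None:
            tx, ty = cols, rows
        else:
            tx, ty = coord_transform(cols, rows)
        inside = (ty >= 0) & (ty < row_stop) & (tx >= col_start) & (tx < col_stop)
        if not inside.any():
            continue
        pix = rp.coords[inside]
        if len(pix) < min_object_px:
            continue
        objects.append(
            ShootObject(
                pixels=pix,
                centroid=(float(tx[inside].mean()), float(ty[inside].mean())),
            )
        )
    return objects


def _kmeans_1d(xs: np.ndarray, k: int, weights: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Deterministic 1-D weighted k-means, centers initialized at evenly
    spaced quantiles.  Returns the cluster index of each point."""
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(xs, qs)
    assign = np.zeros(len(xs), dtype=int)
    for _ in range(200):
        assign = np.argmin(np.abs(xs[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for j in range(k):
            sel = assign == j
            if sel.any():
                new[j] = np.average(xs[sel], weights=weights[sel])
        if np.max(np.abs(new - centers)) < tol:
            centers = new
            break
        centers = new
    return assign


def cluster_shoots(
    objects: Sequence[ShootObject],
    n_slots: int = 6,
    plate_width: int | None = None,
    *,
    crop_shape: tuple[int, int] | None = None,
) -> tuple[list[ShootMeasurement], list[int]]:
    """Group ROI objects into per-slot shoots.

    Objects are clustered on their centroid x coordinate with deterministic
    1-D k-means (k = min(n_slots, #objects), quantile initialization,
    pixel-count weighting); each cluster is assigned to the nearest of
    ``n_slots`` equal-width columns across ``plate_width``.  All objects in a
    cluster merge into one shoot whose pixel count is the zeroth image moment
    of the merged mask.  Empty slots get ``present=False``.

    Returns ``(measurements, collisions)`` where ``collisions`` lists slots
    claimed by more than one cluster (overlapping seedlings; both merged and
    the slot flagged unreliable by the caller).
    """
    if n_slots < 1:
        raise ValueError("n_slots must be >= 1")
    if plate_width is None:
        if crop_shape is None:
            raise ValueError("plate_width or crop_shape required")
        plate_width = crop_shape[1]
    meas = {
        s: ShootMeasurement(slot=s, pixel_count=0, centroid=None, present=False)
        for s in range(1, n_slots + 1)
    }
    collisions: list[int] = []
    if objects:
        xs = np.array([o.centroid[0] for o in objects], dtype=float)
        wts = np.array([o.pixel_count for o in objects], dtype=float)
        k = min(n_slots, len(objects))
        assign = _kmeans_1d(xs, k, wts)
        col_w = plate_width / n_slots
        slot_members: dict[int, list[ShootObject]] = {}
        for j in sorted(set(assign)):
            members = [o for o, a in zip(objects, assign) if a == j]
            cx = np.average([o.centroid[0] for o in members], weights=[o.pixel_count for o in members])
            slot = int(np.clip(np.floor(cx / col_w), 0, n_slots - 1)) + 1
            if slot in slot_members:
                collisions.append(slot)
                slot_members[slot].extend(members)
            else:
                slot_members[slot] = members
        for slot, members in slot_members.items():
            pix = np.vstack([o.pixels for o in members])
            # zeroth image moment of the merged mask == its pixel count
            r0, c0 = pix[:, 0].min(), pix[:, 1].min()
            sub = np.zeros((pix[:, 0].max() - r0 + 1, pix[:, 1].max() - c0 + 1))
            sub[pix[:, 0] - r0, pix[:, 1] - c0] = 1.0
            m = moments(sub, order=1)
            count = int(round(m[0, 0]))
            cx = m[0, 1] / m[0, 0] + c0
            cy = m[1, 0] / m[0, 0] + r0
            meas[slot] = ShootMeasurement(
                slot=slot, pixel_count=count, centroid=(float(cx), float(cy)), present=True
            )
    return [meas[s] for s in range(1, n_slots + 1)], sorted(set(collisions))
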