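"""End-to-end orchestration: image file in, per-shoot areas out.

Per image: detect plate -> crop/rotate -> extract channel -> threshold ->
ROI object detection -> cluster into slots -> calibrate scale -> physical
areas.  Batch mode walks a directory in sorted filename order, degrades
failures to QC flags rather than crashes, and writes one CSV row per
(plate, slot) so downstream statistics see germination failures as data.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .calibration import (
    ScaleCalibration,
    ScaleNotFoundError,
    calibrate,
    detect_reference_marker,
    pixels_to_area,
)
from .config import PipelineConfig
from .plate import AmbiguousPlateError, PlateNotFoundError, crop_to_plate, detect_plate
from .segmentation import (
    ChannelSpec,
    ShootMeasurement,
    cluster_shoots,
    extract_channel,
    find_shoot_objects,
    threshold_leaves,
)

__all__ = ["PlateResult", "process_plate", "run_batch", "RESULT_COLUMNS"]

log = logging.getLogger("rosettearea")

RESULT_COLUMNS = ["plate_id", "slot", "present", "pixel_count", "area_mm2",
                  "scale_source", "flags"]


@dataclass
class PlateResult:
    """All shoot measurements for one image plus QC flags."""

    plate_id: str
    shoots: list[ShootMeasurement]
    areas_mm2: list[float]  # NaN where absent or uncalibrated
    calibration: ScaleCalibration | None
    flags: set[str] = field(default_factory=set)
    config_hash: str = ""

    def rows(self) -> list[dict]:
        src = self.calibration.source if self.calibration else ""
        flags = ";".join(sorted(self.flags))
        return [
            {
                "plate_id": self.plate_id,
                "slot": s.slot,
                "present": s.present,
                "pixel_count": s.pixel_count,
                "area_mm2": f"{a:.6f}" if np.isfinite(a) else "",
                "scale_source": src,
                "flags": flags,
            }
            for s, a in zip(self.shoots, self.areas_mm2)
        ]


def _empty_result(plate_id: str, cfg: PipelineConfig, flag: str) -> PlateResult:
    shoots = [
        ShootMeasurement(slot=s, pixel_count=0, centroid=None, present=False)
        for s in range(1, cfg.n_slots + 1)
    ]
    return PlateResult(
        plate_id=plate_id,
        shoots=shoots,
        areas_mm2=[float("nan")] * cfg.n_slots,
        calibration=None,
        flags={flag},
        config_hash=cfg.digest(),
    )


def _resolve_scale(
    native_crop: np.ndarray,
    region,
    cfg: PipelineConfig,
    flags: set[str],
) -> ScaleCalibration:
    sc = cfg.scale
    plate_area_mm2 = sc.plate_width_mm * sc.plate_height_mm

    def from_plate() -> ScaleCalibration:
        return calibrate(region.pixel_area, plate_area_mm2, "plate")

    if sc.mode == "plate":
        return from_plate()
    # marker search region: configured rectangle, else everything below the
    # shoot ROI so the marker can never collide with a rosette; a tilted
    # plate is searched whole (red selectivity suffices) so the marker count
    # stays an exact native-raster count
    search = sc.search_region
    if search is None and region.rotation_deg == 0.0:
        h, w = native_crop.shape[:2]
        row0 = int(round(cfg.roi.top_fraction * h))
        search = (0, row0, w, h - row0)
    try:
        npx = detect_reference_marker(
            native_crop,
            marker_channel=ChannelSpec(space="Lab", channel="a"),
            threshold=sc.marker_threshold,
            search_region=search,
        )
        return calibrate(npx, sc.marker_area_mm2, "reference_marker")
    except ScaleNotFoundError:
        if sc.mode == "marker":
            raise
        flags.add("scale_fallback")
        return from_plate()


def process_plate(
    image: str | Path | np.ndarray,
    config: PipelineConfig | None = None,
    plate_id: str | None = None,
) -> PlateResult:
    """Measure one plate image; deterministic for fixed image + config.

    Detection failures degrade to a flagged, area-less result so batch runs
    complete.  ``image`` may be a path or an in-memory RGB array (then
    ``plate_id`` should be given).
    """
    cfg = config or PipelineConfig()
    if isinstance(image, (str, Path)):
        plate_id = plate_id or Path(image).stem
        arr = iio.imread(image)
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[:, :, :3]
    else:
        arr = image
        plate_id = plate_id or "plate"

    flags: set[str] = set()
    try:
        region = detect_plate(arr, cfg.plate)
    except (PlateNotFoundError, AmbiguousPlateError):
        return _empty_result(plate_id, cfg, "plate_not_found")

    # Segmentation runs on the un-resampled native crop (the axis-aligned
    # bounds of the plate contour); a tilted plate is handled by de-rotating
    # object *coordinates* for the ROI test and slot clustering.  Pixel
    # counts are therefore exact raster counts with no interpolation loss.
    h, w = arr.shape[:2]
    cx, cy = region.center
    xs_c, ys_c = region.contour[:, 0], region.contour[:, 1]
    nx0 = int(np.clip(np.floor(xs_c.min()), 0, w - 1))
    ny0 = int(np.clip(np.floor(ys_c.min()), 0, h - 1))
    nx1 = int(np.clip(np.floor(xs_c.max()) + 1, 1, w))
    ny1 = int(np.clip(np.floor(ys_c.max()) + 1, 1, h))
    native = arr[ny0:ny1, nx0:nx1]
    bx, by, bw, bh = region.bbox

    if region.rotation_deg != 0.0:
        th = np.deg2rad(-region.rotation_deg)
        cth, sth = np.cos(th), np.sin(th)

        def derotate(xc: np.ndarray, yc: np.ndarray):
            X, Y = xc + nx0 - cx, yc + ny0 - cy
            return (cth * X - sth * Y + cx - bx, sth * X + cth * Y + cy - by)

    else:

        def derotate(xc: np.ndarray, yc: np.ndarray):
            return xc + nx0 - bx, yc + ny0 - by

    gray = extract_channel(native, cfg.channel)
    mask = threshold_leaves(gray, cfg.threshold_value, cfg.threshold_direction,
                            channel=cfg.channel)
    objects = find_shoot_objects(mask, cfg.roi, cfg.min_object_px,
                                 coord_transform=derotate,
                                 transformed_shape=(bh, bw))
    if not objects:
        flags.add("empty_roi")
    shoots, collisions = cluster_shoots(objects, cfg.n_slots, plate_width=bw)
    if collisions:
        flags.add("slot_collision")

    cal = _resolve_scale(native, region, cfg, flags)
    areas = [
        pixels_to_area(s.pixel_count, cal) if s.present else float("nan")
        for s in shoots
    ]
    return PlateResult(
        plate_id=plate_id,
        shoots=shoots,
        areas_mm2=areas,
        calibration=cal,
        flags=flags,
        config_hash=cfg.digest(),
    )


IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def run_batch(
    input_dir: str | Path,
    config: PipelineConfig | None = None,
    output_csv: str | Path | None = None,
    log_file: str | Path | None = None,
) -> dict:
    """Process every image in a directory; one CSV row per (plate, slot).

    Files are processed in sorted filename order for reproducibility.
    Returns a summary dict with image, shoot and flag counts.  A plain-text
    log of per-image timings and flags is written next to the CSV (or to
    ``log_file``).
    """
    cfg = config or PipelineConfig()
    in_dir = Path(input_dir)
    paths = sorted(p for p in in_dir.iterdir() if p.suffix.lower() in IMAGE_EXTS)
    if not paths:
        raise FileNotFoundError(f"no images in {in_dir}")

    rows: list[dict] = []
    log_lines: list[str] = []
    n_flagged = 0
    for p in paths:
        t0 = time.perf_counter()
        try:
            result = process_plate(p, cfg)
        except Exception as exc:  # unreadable file etc.: per-file error record
            log_lines.append(f"{p.name}\tERROR\t{exc}")
            n_flagged += 1
            continue
        rows.extend(result.rows())
        dt = time.perf_counter() - t0
        flag_txt = ";".join(sorted(result.flags)) or "-"
        log_lines.append(f"{p.name}\t{dt:.3f}s\t{flag_txt}")
        if result.flags:
            n_flagged += 1

    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if output_csv is not None:
        out = Path(output_csv)
        out.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out, index=False, lineterminator="\r\n")
        lf = Path(log_file) if log_file else out.with_suffix(".log")
        lf.write_text("\n".join(log_lines) + "\n")

    n_measured = int((table["present"] == True).sum()) if len(table) else 0  # noqa: E712
    summary = {
        "n_images": len(paths),
        "n_rows": len(table),
        "n_shoots_measured": n_measured,
        "n_plates_flagged": n_flagged,
        "table": table,
    }
    return summary
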