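"""Seeded generator of synthetic agar-plate photographs with exact ground truth.

Renders simplified scenes that emulate the imaging conditions of closed
agar-culture-dish photography: a light rectangular plate on a darker
background, up to six green seedling rosettes arranged in a row near the top
of the plate, an optional red square reference scale, small plate tilt,
additive sensor noise and a lateral lighting gradient.

Ground truth (per-slot pixel areas, plate pixel area, marker pixel area,
rotation, mm^2-per-pixel scale) is measured from the rendered raster after
rasterization, never from analytic geometry, so drawing discretization can
never desynchronize truth from image.  Anti-aliasing is disabled throughout.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon
from scipy.ndimage import convolve
from skimage.measure import label as cc_label

__all__ = [
    "ShootBlob",
    "SceneSpec",
    "GroundTruth",
    "generate_plate",
    "generate_batch",
    "simulate_factorial_areas",
    "TRUTH_COLUMNS",
]

# Default palette: plate lighter than background, leaves green, marker red.
PLATE_COLOR = (205, 205, 200)
BACKGROUND_COLOR = (60, 60, 62)
LEAF_COLOR = (45, 140, 55)
MARKER_COLOR = (200, 35, 35)

N_SLOTS = 6

TRUTH_COLUMNS = [
    "plate_id",
    "slot",
    "pixel_area",
    "rotation_deg",
    "plate_pixel_area",
    "marker_pixel_area",
    "mm2_per_px",
    "in_roi",
]


@dataclass(frozen=True)
class ShootBlob:
    """One seedling rosette to paint.

    ``centroid`` is given in the un-tilted scene frame (the whole scene is
    rotated rigidly by ``SceneSpec.rotation_deg`` about the plate center).
    ``shape`` is one of ``"lobed"`` (union of elliptical lobes, the realistic
    default), ``"disk"`` or ``"square"`` (exact-area test shapes).
    """

    slot: int
    centroid: tuple[float, float]
    area_px: float
    shape: str = "lobed"

    def __post_init__(self) -> None:
        if not 1 <= self.slot <= N_SLOTS:
            raise ValueError(f"slot must be in 1..{N_SLOTS}, got {self.slot}")
        if self.shape not in ("lobed", "disk", "square"):
            raise ValueError(f"unknown blob shape {self.shape!r}")
        if self.area_px <= 0:
            raise ValueError("blob area_px must be positive")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic plate photograph."""

    image_size: tuple[int, int] = (1600, 1200)  # (width, height)
    plate_center: tuple[float, float] | None = None  # defaults to image center
    plate_size: tuple[float, float] | None = None  # px; defaults to 0.7*min dim
    rotation_deg: float = 0.0
    plate_color: tuple[int, int, int] = PLATE_COLOR
    background_color: tuple[int, int, int] = BACKGROUND_COLOR
    leaf_color: tuple[int, int, int] = LEAF_COLOR
    marker_color: tuple[int, int, int] = MARKER_COLOR
    shoot_blobs: tuple[ShootBlob, ...] = ()
    marker_rect: tuple[float, float, float, float] | None = None  # x, y, w, h
    marker_area_mm2: float = 100.0  # declared physical area of the marker
    noise_sd: float = 0.0
    lighting_gradient: float = 0.0
    plate_width_mm: float = 100.0
    plate_height_mm: float = 100.0
    seed: int = 0

    @property
    def n_shoots(self) -> int:
        return len(self.shoot_blobs)

    def resolved_plate(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Plate (center, size) in pixels with defaults filled in."""
        w, h = self.image_size
        center = self.plate_center or (w / 2.0, h / 2.0)
        size = self.plate_size or (0.7 * min(w, h), 0.7 * min(w, h))
        return center, size


@dataclass
class GroundTruth:
    """Exact per-scene ground truth, measured from the rendered raster."""

    plate_pixel_area: int
    plate_bbox: tuple[int, int, int, int]  # x, y, w, h (axis-aligned bounds)
    rotation_deg: float
    per_slot_pixel_area: list[int]
    per_slot_centroid: list[tuple[float, float] | None]
    per_slot_in_roi: list[bool]
    marker_pixel_area: int
    mm2_per_px: float


def _rotate_points(pts: np.ndarray, center: tuple[float, float], deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (pts - center) @ rot.T + center


def _rect_corners(cx: float, cy: float, w: float, h: float) -> np.ndarray:
    return np.array(
        [
            [cx - w / 2, cy - h / 2],
            [cx + w / 2, cy - h / 2],
            [cx + w / 2, cy + h / 2],
            [cx - w / 2, cy + h / 2],
        ]
    )


def _paint_polygon(mask: np.ndarray, corners: np.ndarray) -> None:
    rr, cc = draw_polygon(corners[:, 1], corners[:, 0], shape=mask.shape)
    mask[rr, cc] = True


_NB_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def _adjust_to_exact_area(mask: np.ndarray, target: int) -> np.ndarray:
    """Deterministically add/remove boundary pixels until the blob has
    exactly ``target`` pixels, preserving 8-connectivity.

    Blobs then carry the same pixel area at every rotation and rendering
    resolution, which is what makes rotation- and scale-invariance of the
    measurement testable to tight tolerances.
    """
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return mask
    pad = 3 + max(0, target - len(ys))  # room to grow
    r0, r1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, mask.shape[0])
    c0, c1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, mask.shape[1])
    local = mask[r0:r1, c0:c1].copy()

    while local.sum() < target:
        nb = convolve(local.astype(np.int8), _NB_KERNEL, mode="constant")
        cand = np.argwhere(~local & (nb > 0))
        if len(cand) == 0:
            break
        scores = nb[cand[:, 0], cand[:, 1]]
        # fill concavities first; raster order breaks ties
        best = cand[np.lexsort((cand[:, 1], cand[:, 0], -scores))][0]
        local[best[0], best[1]] = True

    protected: set[tuple[int, int]] = set()
    while local.sum() > target:
        nb = convolve(local.astype(np.int8), _NB_KERNEL, mode="constant")
        cand = np.argwhere(local)
        cand = np.array([p for p in cand if (p[0], p[1]) not in protected])
        if len(cand) == 0:
            break
        scores = nb[cand[:, 0], cand[:, 1]]
        order = np.lexsort((cand[:, 1], cand[:, 0], scores))
        removed = False
        for idx in order:
            p = tuple(cand[idx])
            local[p] = False
            if cc_label(local, connectivity=2).max() <= 1:
                removed = True
                break
            local[p] = True  # would disconnect; protect and try next
            protected.add(p)
        if not removed:
            break

    out = mask.copy()
    out[r0:r1, c0:c1] = local
    return out


def _blob_mask(
    blob: ShootBlob,
    center_rot: tuple[float, float],
    scene_rotation: float,
    shape_hw: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize one rosette blob at its rotated centroid."""
    mask = np.zeros(shape_hw, dtype=bool)
    cx, cy = center_rot
    target = int(round(blob.area_px))
    if blob.shape == "square":
        side = max(1, round(np.sqrt(blob.area_px)))
        corners = _rect_corners(cx, cy, side, side)
        if scene_rotation == 0.0:
            # Axis-aligned squares rasterize exactly: paint by half-open slicing.
            x0 = int(round(cx - side / 2))
            y0 = int(round(cy - side / 2))
            mask[max(y0, 0) : y0 + side, max(x0, 0) : x0 + side] = True
            return mask
        corners = _rotate_points(corners, (cx, cy), scene_rotation)
        _paint_polygon(mask, corners)
        return _adjust_to_exact_area(mask, side * side)
    if blob.shape == "disk":
        r = np.sqrt(blob.area_px / np.pi)
        rr, cc = draw_disk((cy, cx), r, shape=shape_hw)
        mask[rr, cc] = True
        return _adjust_to_exact_area(mask, target)
    # Lobed rosette: union of elliptical lobes around the centroid, mimicking
    # an askew rosette seen through the plate lid.  Two-pass area scaling
    # brings the union close to the requested target.
    n_lobes = int(rng.integers(3, 8))
    angles = rng.uniform(0, 2 * np.pi, n_lobes)
    elong = rng.uniform(1.4, 2.4, n_lobes)
    offs = rng.uniform(0.35, 0.75, n_lobes)
    base = np.sqrt(blob.area_px / np.pi) * 0.55

    def paint(scale: float) -> np.ndarray:
        m = np.zeros(shape_hw, dtype=bool)
        for ang, el, off in zip(angles, elong, offs):
            a = base * scale * el  # lobe major semi-axis
            b = base * scale  # minor
            lx = cx + np.cos(ang) * a * off
            ly = cy + np.sin(ang) * a * off
            rr, cc = draw_ellipse(
                ly, lx, b, a, shape=shape_hw,
                rotation=-(ang + np.deg2rad(scene_rotation)),
            )
            m[rr, cc] = True
        return m

    m = paint(1.0)
    got = int(m.sum())
    if got > 0:
        m = paint(float(np.sqrt(blob.area_px / got)))
    # boundary adjustment makes the union carry exactly the target area at
    # any rotation and rendering resolution
    return _adjust_to_exact_area(m, target)


def generate_plate(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic plate photograph.

    Returns the RGB uint8 image and its :class:`GroundTruth`.  Rendering is
    bit-deterministic for a fixed spec (the seed drives noise and lobe
    geometry).  Raises ``ValueError`` if blobs from different slots touch
    after rasterization (the merged object would have no well-defined
    per-slot truth) or if a blob overlaps the reference marker.
    """
    w, h = spec.image_size
    (pcx, pcy), (pw, ph) = spec.resolved_plate()
    rng = np.random.default_rng(spec.seed)

    img = np.empty((h, w, 3), dtype=float)
    img[:] = spec.background_color

    plate_mask = np.zeros((h, w), dtype=bool)
    corners = _rotate_points(_rect_corners(pcx, pcy, pw, ph), (pcx, pcy), spec.rotation_deg)
    if spec.rotation_deg == 0.0:
        x0, y0 = int(round(pcx - pw / 2)), int(round(pcy - ph / 2))
        plate_mask[max(y0, 0) : y0 + int(round(ph)), max(x0, 0) : x0 + int(round(pw))] = True
    else:
        _paint_polygon(plate_mask, corners)
    img[plate_mask] = spec.plate_color

    # Shoot centroids must lie on the plate (un-tilted frame).  Default
    # scenes put them in the top half; below-midline placement is allowed so
    # ROI-exclusion behavior ("fallen" rosettes) can be exercised, and is
    # reflected in per_slot_in_roi.
    for blob in spec.shoot_blobs:
        bx, by = blob.centroid
        if not (pcy - ph / 2 <= by <= pcy + ph / 2) or not (
            pcx - pw / 2 <= bx <= pcx + pw / 2
        ):
            raise ValueError(
                f"slot {blob.slot} centroid {blob.centroid} outside the plate"
            )
    slots_seen = [b.slot for b in spec.shoot_blobs]
    if len(set(slots_seen)) != len(slots_seen):
        raise ValueError("duplicate slot indices in shoot_blobs")

    marker_mask = np.zeros((h, w), dtype=bool)
    if spec.marker_rect is not None:
        mx, my, mw, mh = spec.marker_rect
        mc = _rect_corners(mx + mw / 2, my + mh / 2, mw, mh)
        mc = _rotate_points(mc, (pcx, pcy), spec.rotation_deg)
        if spec.rotation_deg == 0.0:
            marker_mask[int(round(my)) : int(round(my + mh)), int(round(mx)) : int(round(mx + mw))] = True
        else:
            _paint_polygon(marker_mask, mc)
            # same exact-area guarantee as blobs, so marker-based calibration
            # is rotation-invariant
            marker_mask = _adjust_to_exact_area(
                marker_mask, int(round(mw)) * int(round(mh))
            )
        img[marker_mask] = spec.marker_color

    slot_masks: dict[int, np.ndarray] = {}
    leaf_mask = np.zeros((h, w), dtype=bool)
    for blob in spec.shoot_blobs:
        c_rot = _rotate_points(np.array([blob.centroid]), (pcx, pcy), spec.rotation_deg)[0]
        blob_rng = np.random.default_rng([spec.seed, blob.slot])
        m = _blob_mask(blob, (c_rot[0], c_rot[1]), spec.rotation_deg, (h, w), blob_rng)
        if (m & marker_mask).any():
            raise ValueError(f"slot {blob.slot} blob overlaps the reference marker")
        slot_masks[blob.slot] = m
        leaf_mask |= m

    # Reject specs whose rasterized blobs merge across slots: per-slot ground
    # truth would be untestable.
    if slot_masks:
        lab = cc_label(leaf_mask, connectivity=2)
        for comp in range(1, lab.max() + 1):
            owners = [s for s, m in slot_masks.items() if (m & (lab == comp)).any()]
            if len(owners) > 1:
                raise ValueError(f"blobs of slots {owners} merge after rasterization")
    img[leaf_mask] = spec.leaf_color

    if spec.lighting_gradient != 0.0:
        ramp = 1.0 + spec.lighting_gradient * (np.arange(w) / max(w - 1, 1) - 0.5)
        img *= ramp[None, :, None]
    if spec.noise_sd > 0.0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    plate_area = int(plate_mask.sum())
    ys, xs = np.nonzero(plate_mask)
    bbox = (int(xs.min()), int(ys.min()), int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1))
    per_slot = [0] * N_SLOTS
    per_centroid: list[tuple[float, float] | None] = [None] * N_SLOTS
    in_roi = [False] * N_SLOTS
    for s, m in slot_masks.items():
        per_slot[s - 1] = int(m.sum())
        cy_, cx_ = np.nonzero(m)
        per_centroid[s - 1] = (float(cx_.mean()), float(cy_.mean()))
        # In-ROI status in the un-tilted frame: the pipeline's default ROI is
        # the top half of the plate crop.
        blob = next(b for b in spec.shoot_blobs if b.slot == s)
        in_roi[s - 1] = blob.centroid[1] <= pcy

    phys_area = spec.plate_width_mm * spec.plate_height_mm
    truth = GroundTruth(
        plate_pixel_area=plate_area,
        plate_bbox=bbox,
        rotation_deg=spec.rotation_deg,
        per_slot_pixel_area=per_slot,
        per_slot_centroid=per_centroid,
        per_slot_in_roi=in_roi,
        marker_pixel_area=int(marker_mask.sum()),
        mm2_per_px=phys_area / plate_area,
    )
    return img, truth


def default_scene(
    seed: int = 0,
    *,
    image_size: tuple[int, int] = (1600, 1200),
    n_shoots: int = 6,
    rotation_deg: float = 0.0,
    noise_sd: float = 0.0,
    lighting_gradient: float = 0.0,
    area_px_range: tuple[float, float] | None = None,
    with_marker: bool = True,
    marker_area_mm2: float = 100.0,
    germinated: Sequence[int] | None = None,
    below_roi_slots: Sequence[int] = (),
    shape: str = "lobed",
) -> SceneSpec:
    """Build a realistic :class:`SceneSpec` for a given seed.

    ``germinated`` lists the occupied slots (default: the first ``n_shoots``).
    Slots named in ``below_roi_slots`` are planted below the plate midline,
    emulating rosettes that have fallen out of the measurable region.
    """
    w, h = image_size
    side = float(round(0.7 * min(w, h)))
    pcx, pcy = w / 2.0, h / 2.0
    rng = np.random.default_rng(seed)
    if area_px_range is None:
        # ~5-40 mm^2 rosettes at the nominal plate scale.
        mm2_per_px = (100.0 * 100.0) / side**2
        area_px_range = (5.0 / mm2_per_px, 40.0 / mm2_per_px)
    slots = list(germinated) if germinated is not None else list(range(1, n_shoots + 1))
    col_w = side / N_SLOTS
    blobs = []
    for s in slots:
        cx = pcx - side / 2 + (s - 0.5) * col_w + rng.uniform(-0.12, 0.12) * col_w
        if s in below_roi_slots:
            cy = pcy + rng.uniform(0.15, 0.3) * side
        else:
            cy = pcy - side / 2 + rng.uniform(0.2, 0.42) * side
        area = rng.uniform(*area_px_range)
        blobs.append(ShootBlob(slot=s, centroid=(cx, cy), area_px=area, shape=shape))
    marker = None
    declared_marker_mm2 = marker_area_mm2
    if with_marker:
        # integer marker side so the rasterized square is exact; the declared
        # physical area is back-computed from it, keeping both scale
        # geometries exact in the generator
        mside = float(round(np.sqrt(marker_area_mm2) / 100.0 * side))
        declared_marker_mm2 = (mside * 100.0 / side) ** 2
        mx = float(round(pcx - mside / 2))
        my = float(round(pcy + side / 2 - 1.6 * mside))
        marker = (mx, my, mside, mside)
    return SceneSpec(
        image_size=image_size,
        plate_center=(pcx, pcy),
        plate_size=(side, side),
        rotation_deg=rotation_deg,
        shoot_blobs=tuple(blobs),
        marker_rect=marker,
        marker_area_mm2=declared_marker_mm2,
        noise_sd=noise_sd,
        lighting_gradient=lighting_gradient,
        seed=seed,
    )


def _ss_share_sigmas(
    f_g: float, f_t: float, n_genotypes: int, n_treatments: int, n_total: int
) -> tuple[float, float, float]:
    """Solve for effect SDs so that expected ANOVA SS shares hit the targets.

    The "variance fraction" of a factor is defined as its expected share of
    the total sum of squares in a balanced design.  Between-group SS picks up
    a residual-noise contribution of (levels-1)*sigma_e^2, so the effect
    variances must be solved jointly (unit total variance).
    """
    G, T, N = n_genotypes, n_treatments, n_total
    n_g, n_t = N // G, N // T
    # unknowns x = (sigma_g^2, sigma_t^2, sigma_e^2)
    A = np.array(
        [
            [(G - 1) * n_g, 0.0, (G - 1)],
            [0.0, (T - 1) * n_t, (T - 1)],
            [1.0, 1.0, 1.0],
        ]
    )
    b = np.array([f_g * (N - 1), f_t * (N - 1), 1.0])
    x = np.linalg.solve(A, b)
    if (x <= 0).any():
        raise ValueError(
            f"variance fractions f_g={f_g}, f_t={f_t} infeasible for this design"
        )
    return tuple(np.sqrt(x))  # type: ignore[return-value]


def _standardize(v: np.ndarray, sd: float) -> np.ndarray:
    v = v - v.mean()
    s = v.std(ddof=1)
    return v * (sd / s) if s > 0 else v


def simulate_factorial_areas(
    n_genotypes: int = 100,
    sources: Sequence[str] = ("nitrate", "ammonium"),
    concentrations: Sequence[float] = (0.1, 1.0),
    n_reps: int = 2,
    genotype_var_fraction: float = 0.3,
    treatment_var_fraction: float = 0.2,
    baseline_mm2: float = 30.0,
    total_sd_mm2: float = 6.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tidy table of simulated rosette areas for a genotype x nitrogen design.

    Additive model: area = baseline + genotype effect + treatment effect +
    noise.  Genotype and treatment effects are standardized to their exact
    target SDs so the realized sum-of-squares shares match the requested
    fractions closely even at moderate design sizes.

    Returns columns ``genotype, n_source, n_conc, area``.
    """
    rng = np.random.default_rng(seed)
    treatments = [(s, c) for s in sources for c in concentrations]
    G, T = n_genotypes, len(treatments)
    N = G * T * n_reps
    sg, st, se = _ss_share_sigmas(genotype_var_fraction, treatment_var_fraction, G, T, N)
    sg, st, se = sg * total_sd_mm2, st * total_sd_mm2, se * total_sd_mm2
    g_eff = _standardize(rng.normal(size=G), sg)
    t_eff = _standardize(rng.normal(size=T), st)
    rows = []
    for gi in range(G):
        for ti, (src, conc) in enumerate(treatments):
            for _ in range(n_reps):
                area = baseline_mm2 + g_eff[gi] + t_eff[ti] + rng.normal(0.0, se)
                rows.append((f"g{gi + 1:04d}", src, conc, max(area, 0.1)))
    return pd.DataFrame(rows, columns=["genotype", "n_source", "n_conc", "area"])


def generate_batch(
    out_dir: str | Path,
    n_plates: int = 50,
    seed: int = 0,
    *,
    image_size: tuple[int, int] = (1024, 768),
    rotation_range: tuple[float, float] = (-10.0, 10.0),
    noise_sd: float = 4.0,
    germination_prob: float = 0.92,
    below_roi_fraction: float = 0.0,
    with_marker: bool = True,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Write a directory of synthetic plate PNGs plus a ground-truth table.

    One PNG and six truth rows (one per slot) per plate.  When ``design`` is
    given (columns ``genotype, n_source, n_conc``, one row per plate) the
    truth table carries those labels so the statistics stage can consume it
    directly.  Returns the truth table; also writes ``truth.csv``.
    """
    if n_plates < 1:
        raise ValueError("n_plates must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if design is not None and len(design) != n_plates:
        raise ValueError("design must have one row per plate")

    master = np.random.default_rng(seed)
    records = []
    for i in range(n_plates):
        plate_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(plate_seed)
        rot = float(rng.uniform(*rotation_range))
        germ = [s for s in range(1, N_SLOTS + 1) if rng.random() < germination_prob]
        below = [s for s in germ if rng.random() < below_roi_fraction]
        spec = default_scene(
            seed=plate_seed,
            image_size=image_size,
            rotation_deg=rot,
            noise_sd=noise_sd,
            germinated=germ,
            below_roi_slots=below,
            with_marker=with_marker,
        )
        img, truth = generate_plate(spec)
        plate_id = f"plate_{i + 1:04d}"
        iio.imwrite(out / f"{plate_id}.png", img)
        for s in range(1, N_SLOTS + 1):
            rec = {
                "plate_id": plate_id,
                "slot": s,
                "pixel_area": truth.per_slot_pixel_area[s - 1],
                "rotation_deg": rot,
                "plate_pixel_area": truth.plate_pixel_area,
                "marker_pixel_area": truth.marker_pixel_area,
                "mm2_per_px": truth.mm2_per_px,
                "in_roi": truth.per_slot_in_roi[s - 1],
            }
            if design is not None:
                rec["genotype"] = design.iloc[i]["genotype"]
                rec["n_source"] = design.iloc[i]["n_source"]
                rec["n_conc"] = design.iloc[i]["n_conc"]
            records.append(rec)
    table = pd.DataFrame(records)
    table.to_csv(out / "truth.csv", index=False, quoting=csv.QUOTE_MINIMAL)
    return table


def factorial_design(
    n_genotypes: int,
    sources: Sequence[str] = ("nitrate", "ammonium"),
    concentrations: Sequence[float] = (0.1, 1.0),
    n_reps: int = 1,
) -> pd.DataFrame:
    """Plate-level full factorial design table (one row per plate)."""
    rows = [
        (f"g{g + 1:04d}", s, c)
        for g in range(n_genotypes)
        for s in sources
        for c in concentrations
        for _ in range(n_reps)
    ]
    return pd.DataFrame(rows, columns=["genotype", "n_source", "n_conc"])
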