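"""Time-lapse video tag tracking, plus a synthetic frame renderer.

The imaging chain tracks three geometric tags (a circle, a filled
triangle and an outlined triangle) glued to the animals' cephalothorax,
on grey-scale frames (1280 x 1024 by default) shot from above the tank
at 5-s cadence under infrared light:

1. absolute difference against a background reference frame of the
   empty tank;
2. binary segmentation at grey-level threshold > 10 (night) or > 20
   (day);
3. connected components, keeping areas in the 100-400 px range;
4. shape matching of each surviving blob against the tag templates by
   a rotation scan in 2-degree steps, scoring overlap as
   intersection-over-union;
5. centroid coordinates converted to cm via the tank calibration, and
   displacement between consecutive frames as Euclidean distances.

The renderer draws tags onto a background at calibrated positions with
optional Gaussian pixel noise, enabling closed-loop testing: rendered
ground truth in, detections out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk, polygon
from skimage.measure import label, regionprops
from skimage.transform import rotate as _rotate

from .rfid import DisplacementSeries

__all__ = [
    "Frame",
    "Calibration",
    "TagTemplate",
    "TagDetection",
    "default_templates",
    "render_frame",
    "detect_tags",
    "match_shape",
    "track",
    "NIGHT_THRESHOLD",
    "DAY_THRESHOLD",
]

FRAME_WIDTH = 1280
FRAME_HEIGHT = 1024
NIGHT_THRESHOLD = 10  # foreground = |frame - background| strictly above
DAY_THRESHOLD = 20
AREA_MIN = 100  # px, size filter
AREA_MAX = 400
SHAPE_ORDER = ("circle", "triangle", "triangle_outline")  # tie-break order


@dataclass(frozen=True)
class Frame:
    """A grey-scale frame (uint8) with its timestamp and light phase."""

    pixels: np.ndarray
    time: pd.Timestamp
    phase: str  # "day" | "night"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError("frame must be a 2-D grey-scale array")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("grey levels must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if self.phase not in ("day", "night"):
            raise ValueError("phase must be 'day' or 'night'")


@dataclass(frozen=True)
class Calibration:
    """Pixel <-> cm mapping between the frame and the tank reference system.

    Default maps the 150 x 70 cm tank footprint onto the frame with a
    uniform scale fitting the 150 cm side to the frame width.
    """

    px_per_cm_x: float = FRAME_WIDTH / 150.0
    px_per_cm_y: float = FRAME_WIDTH / 150.0
    origin_px: tuple[float, float] = (0.0, 0.0)  # (col, row) of tank origin

    def __post_init__(self) -> None:
        if self.px_per_cm_x <= 0 or self.px_per_cm_y <= 0:
            raise ValueError("calibration scales must be > 0")

    def cm_to_px(self, xy_cm: tuple[float, float]) -> tuple[float, float]:
        return (
            self.origin_px[0] + xy_cm[0] * self.px_per_cm_x,
            self.origin_px[1] + xy_cm[1] * self.px_per_cm_y,
        )

    def px_to_cm(self, colrow_px: tuple[float, float]) -> tuple[float, float]:
        return (
            (colrow_px[0] - self.origin_px[0]) / self.px_per_cm_x,
            (colrow_px[1] - self.origin_px[1]) / self.px_per_cm_y,
        )


class TagTemplate:
    """Binary mask of one geometric tag, with its rotation symmetry.

    ``symmetry_deg`` is the smallest rotation mapping the shape onto
    itself (360 for asymmetric shapes, 120 for an equilateral triangle,
    0 for the rotation-invariant circle).
    """

    def __init__(self, shape: str, mask: np.ndarray, symmetry_deg: float):
        area = int(mask.sum())
        if not AREA_MIN <= area <= AREA_MAX:
            raise ValueError(
                f"template {shape!r} area {area} px outside [{AREA_MIN}, {AREA_MAX}]"
            )
        self.shape = shape
        self.mask = mask.astype(bool)
        self.symmetry_deg = symmetry_deg
        self.nominal_area = area
        self._rotated: dict[float, tuple[np.ndarray, ...]] = {}

    def rotated_masks(self, step: float = 2.0) -> tuple[np.ndarray, ...]:
        """Template rotated through {0, step, ..., 360-step} degrees (cached).

        Rotations are bilinear, giving fractional edge pixels: scores then
        vary smoothly with angle, so the scan can discriminate rotations
        finer than the pixel quantum of a hard-rotated small mask.
        """
        if step not in self._rotated:
            masks = []
            padded = np.pad(self.mask.astype(float), self.mask.shape[0])
            for ang in np.arange(0.0, 360.0, step):
                if ang == 0.0:
                    masks.append(self.mask.astype(float))
                else:
                    r = np.clip(_rotate(padded, -ang, order=1, resize=False), 0.0, 1.0)
                    masks.append(_crop_to_content(r))
            self._rotated[step] = tuple(masks)
        return self._rotated[step]


def _crop_to_content(mask: np.ndarray) -> np.ndarray:
    keep = mask > 1e-6
    rows = np.flatnonzero(keep.any(axis=1))
    cols = np.flatnonzero(keep.any(axis=0))
    return mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]


def _circle_mask(radius: int = 8) -> np.ndarray:
    size = 2 * radius + 1
    m = np.zeros((size, size), dtype=bool)
    rr, cc = disk((radius, radius), radius + 0.5, shape=m.shape)
    m[rr, cc] = True
    return m


def _triangle_mask(side: int = 24, outline: bool = False, thickness: int = 4) -> np.ndarray:
    h = side * math.sqrt(3) / 2
    size = int(math.ceil(h)) + 2
    width = side + 2
    m = np.zeros((size, width), dtype=bool)
    pts_r = np.array([1.0, 1.0 + h, 1.0 + h])
    pts_c = np.array([width / 2.0, width / 2.0 - side / 2.0, width / 2.0 + side / 2.0])
    rr, cc = polygon(pts_r, pts_c, shape=m.shape)
    m[rr, cc] = True
    if outline:
        inner = ndimage.binary_erosion(m, iterations=thickness)
        m &= ~inner
    return m


@lru_cache(maxsize=1)
def _default_templates() -> tuple[TagTemplate, ...]:
    return (
        TagTemplate("circle", _circle_mask(radius=8), symmetry_deg=0.0),
        TagTemplate("triangle", _triangle_mask(side=24), symmetry_deg=120.0),
        TagTemplate(
            "triangle_outline",
            _triangle_mask(side=30, outline=True, thickness=3),
            symmetry_deg=120.0,
        ),
    )


def default_templates() -> list[TagTemplate]:
    """The three standard tags, with areas inside the 100-400 px filter.

    Instances are shared so the rotation-scan cache is built once.
    """
    return list(_default_templates())


@dataclass(frozen=True)
class TagDetection:
    shape: str
    centroid_px: tuple[float, float]  # (col, row)
    centroid_cm: tuple[float, float]
    rotation: float  # degrees in [0, 360)
    score: float  # best IoU over the rotation scan, in [0, 1]
    area: int = 0


def make_background(
    *,
    width: int = FRAME_WIDTH,
    height: int = FRAME_HEIGHT,
    phase: str = "day",
    grey_day: int = 90,
    grey_night: int = 35,
    time: str | pd.Timestamp = "2024-01-01 00:00:00",
) -> Frame:
    """Uniform empty-tank reference frame at the phase's base grey level."""
    level = grey_day if phase == "day" else grey_night
    return Frame(
        pixels=np.full((height, width), level, dtype=np.uint8),
        time=pd.Timestamp(time),
        phase=phase,
    )


def render_frame(
    positions: dict[str, tuple[float, float]],
    shapes: dict[str, str],
    phase: str,
    background: Frame,
    *,
    calibration: Calibration | None = None,
    templates: list[TagTemplate] | None = None,
    rotations: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    tag_grey: int = 230,
    seed: int = 0,
    time: pd.Timestamp | None = None,
) -> Frame:
    """Draw each animal's tag onto the background at its calibrated position.

    The (rotated) template mask is pasted so that its centroid lands on
    the requested pixel position; Gaussian noise of ``noise_sd`` grey
    levels is then added and clipped to [0, 255].  Deterministic per
    seed.  Overlapping tags are rendered as drawn (occlusion is a test
    case, not an error).
    """
    calibration = calibration or Calibration()
    templates = templates or default_templates()
    by_shape = {t.shape: t for t in templates}
    img = background.pixels.astype(float).copy()
    H, W = img.shape
    for uid, xy in positions.items():
        tpl = by_shape[shapes[uid]]
        ang = (rotations or {}).get(uid, 0.0)
        if ang:
            padded = np.pad(tpl.mask, tpl.mask.shape[0])
            mask = _crop_to_content(
                _rotate(padded.astype(float), -ang, order=0, resize=False) > 0.5
            )
        else:
            mask = tpl.mask
        col, row = calibration.cm_to_px(xy)
        # paste so the mask centroid lands on (row, col)
        cr, cc = ndimage.center_of_mass(mask)
        r0 = int(round(row - cr))
        c0 = int(round(col - cc))
        r1, c1 = r0 + mask.shape[0], c0 + mask.shape[1]
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r1, H), min(c1, W)
        if re <= rs or ce <= cs:
            continue  # tag entirely out of frame
        sub = mask[rs - r0 : re - r0, cs - c0 : ce - c0]
        img[rs:re, cs:ce][sub] = tag_grey
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img += rng.normal(0.0, noise_sd, img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return Frame(pixels=img, time=time or background.time, phase=phase)


def threshold_for_phase(phase: str) -> int:
    return NIGHT_THRESHOLD if phase == "night" else DAY_THRESHOLD


def detect_tags(
    frame: Frame,
    background: Frame,
    *,
    calibration: Calibration | None = None,
    templates: list[TagTemplate] | None = None,
    rotation_step: float = 2.0,
    min_score: float = 0.5,
) -> list[TagDetection]:
    """Run the full detection pipeline on one frame.

    Foreground pixels are those whose absolute difference from the
    background is strictly above the phase threshold (10 night, 20 day).
    Connected components outside the 100-400 px area band are dropped;
    survivors are labelled by the best-matching template over the
    rotation scan, and kept if the match score reaches ``min_score``.
    """
    if frame.pixels.shape != background.pixels.shape:
        raise ValueError("frame and background dimensions differ")
    calibration = calibration or Calibration()
    templates = templates if templates is not None else default_templates()
    diff = np.abs(frame.pixels.astype(int) - background.pixels.astype(int))
    fg = diff > threshold_for_phase(frame.phase)
    labels = label(fg, connectivity=2)
    detections = []
    for prop in regionprops(labels):
        if not AREA_MIN <= prop.area <= AREA_MAX:
            continue
        comp = prop.image  # cropped binary mask
        shape, rotation, score = match_shape(comp, templates, step=rotation_step)
        if score < min_score:
            continue
        row, col = prop.centroid
        centroid_px = (float(col), float(row))
        detections.append(
            TagDetection(
                shape=shape,
                centroid_px=centroid_px,
                centroid_cm=calibration.px_to_cm(centroid_px),
                rotation=rotation,
                score=score,
                area=int(prop.area),
            )
        )
    return detections


def _iou_at_centroid(comp: np.ndarray, tpl: np.ndarray) -> float:
    """Overlap of two masks aligned at their centroids (nearest pixel).

    Generalized intersection-over-union: sum(min)/sum(max), which reduces
    to ordinary IoU for binary masks and accepts the fractional pixels of
    bilinear-rotated templates.
    """
    comp = comp.astype(float)
    tpl = tpl.astype(float)
    cr1, cc1 = ndimage.center_of_mass(comp)
    cr2, cc2 = ndimage.center_of_mass(tpl)
    dr = int(round(cr1 - cr2))  # template offset relative to component
    dc = int(round(cc1 - cc2))
    ra, ca = max(0, -dr), max(0, -dc)  # component offset in the canvas
    rb, cb = max(0, dr), max(0, dc)  # template offset in the canvas
    H = max(comp.shape[0] + ra, tpl.shape[0] + rb)
    W = max(comp.shape[1] + ca, tpl.shape[1] + cb)
    a = np.zeros((H, W))
    b = np.zeros((H, W))
    a[ra : ra + comp.shape[0], ca : ca + comp.shape[1]] = comp
    b[rb : rb + tpl.shape[0], cb : cb + tpl.shape[1]] = tpl
    inter = np.minimum(a, b).sum()
    union = np.maximum(a, b).sum()
    return float(inter / union) if union else 0.0


def match_shape(
    component_mask: np.ndarray,
    templates: list[TagTemplate] | None = None,
    step: float = 2.0,
) -> tuple[str, float, float]:
    """Best (shape, rotation, score) for a component over the rotation scan.

    Each template is rotated through 0..358 degrees in ``step`` steps,
    aligned with the component at centroids, and scored by
    intersection-over-union.  Ties go to the lower rotation, then to
    template order (circle, triangle, triangle_outline).  The circle's
    rotation is reported as 0 (rotation-invariant shape).
    """
    comp = np.asarray(component_mask, dtype=bool)
    if not comp.any():
        raise ValueError("component mask is empty")
    templates = templates if templates is not None else default_templates()
    order = {s: i for i, s in enumerate(SHAPE_ORDER)}
    best = ("", 0.0, -1.0)
    for tpl in sorted(templates, key=lambda t: order.get(t.shape, 99)):
        angles = (
            np.array([0.0])
            if tpl.symmetry_deg == 0.0
            else np.arange(0.0, 360.0, step)
        )
        masks = tpl.rotated_masks(step) if tpl.symmetry_deg != 0.0 else (tpl.mask,)
        for ang, m in zip(angles, masks):
            s = _iou_at_centroid(comp, m)
            if s > best[2] + 1e-12:
                best = (tpl.shape, float(ang), float(s))
    return best


def track(
    frames: list[Frame],
    background: Frame | dict[str, Frame],
    *,
    calibration: Calibration | None = None,
    templates: list[TagTemplate] | None = None,
    min_score: float = 0.5,
) -> list[DisplacementSeries]:
    """Track tags through a frame sequence into per-animal displacement.

    One series per shape label (= per animal).  When a tag is missing in
    a frame the track holds its last centroid and emits 0 for that
    interval, flagging the gap; two accepted detections with the same
    label keep the higher score.  ``background`` may be a single
    reference frame or a dict keyed by phase ("day"/"night") when the
    sequence spans light transitions.
    """
    calibration = calibration or Calibration()
    templates = templates if templates is not None else default_templates()
    shape_names = [t.shape for t in templates]
    last_cm: dict[str, tuple[float, float] | None] = {s: None for s in shape_names}
    times: list[pd.Timestamp] = []
    disp: dict[str, list[float]] = {s: [] for s in shape_names}
    gaps: dict[str, list[bool]] = {s: [] for s in shape_names}
    for i, frame in enumerate(frames):
        bg = background[frame.phase] if isinstance(background, dict) else background
        dets = detect_tags(
            frame,
            bg,
            calibration=calibration,
            templates=templates,
            min_score=min_score,
        )
        seen: dict[str, TagDetection] = {}
        for d in dets:
            if d.shape not in seen or d.score > seen[d.shape].score:
                seen[d.shape] = d
        if i > 0:
            times.append(frame.time)
        for s in shape_names:
            if s in seen:
                cm = seen[s].centroid_cm
                if i > 0:
                    prev = last_cm[s]
                    if prev is None:
                        disp[s].append(0.0)
                        gaps[s].append(True)
                    else:
                        disp[s].append(math.dist(prev, cm))
                        gaps[s].append(False)
                last_cm[s] = cm
            else:
                if i > 0:
                    disp[s].append(0.0)
                    gaps[s].append(True)
    return [
        DisplacementSeries(
            animal_uid=s,
            times=pd.DatetimeIndex(times),
            values=np.asarray(disp[s]),
            gap_flags=np.asarray(gaps[s], dtype=bool),
        )
        for s in shape_names
    ]
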