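"""Segmentation of adenoma-like features from photographs of spread gut.

The pipeline mirrors a particle-analysis macro workflow: the blue card
background is subtracted to leave a grey-scale image, the image is
automatically thresholded, despeckled with a median filter, and
connected components larger than a physical area cut-off (0.2 mm² by
default) are kept as candidate adenoma "image features" and measured.

Background subtraction scores each pixel by blueness, b = B - max(R, G).
Blue-card pixels score high (the card is chosen for contrast with
tissue); tissue and lesions score near or below zero. An Otsu cut on the
blueness histogram separates the two populations without per-image
tuning; pixels above the cut are zeroed and the rest become 8-bit luma
(0.299 R + 0.587 G + 0.114 B). When tissue is sparse or absent the
Otsu cut lands inside the card's own noise (its lower class still has
card-like mean blueness above ``blue_floor``); the cut then falls back
to the fixed floor, so a lesion-free photograph yields an all-zero
grey image rather than thresholded noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .morphometry import PerimeterMethod, RegionFeature, measure_region

logger = logging.getLogger(__name__)

ThresholdMethod = Literal["isodata", "otsu"]

#: Minimum mean blueness (B - max(R, G)) for a pixel class to count as card.
BLUE_FLOOR = 25.0


@dataclass(frozen=True)
class CalibratedImage:
    """RGB photograph with a physical scale.

    ``pixels`` is H x W x 3 uint8; ``scale_mm_per_px`` is the physical
    side length of one pixel in mm.
    """

    pixels: np.ndarray
    scale_mm_per_px: float
    image_id: str = ""
    mouse_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3 or p.shape[0] < 1 or p.shape[1] < 1:
            raise ValueError("pixels must be H x W x 3")
        if p.min() < 0 or p.max() > 255:
            raise ValueError("channel values must be in [0, 255]")
        if not self.scale_mm_per_px > 0:
            raise ValueError("scale_mm_per_px must be positive")


@dataclass(frozen=True)
class GrayImage:
    """Background-suppressed grey-scale image (card pixels are 0)."""

    pixels: np.ndarray
    scale_mm_per_px: float
    image_id: str = ""
    mouse_id: str = ""


@dataclass(frozen=True)
class LabelMap:
    """Connected-component labels, 0 = background, 1..n_regions contiguous."""

    labels: np.ndarray
    n_regions: int


def scale_from_two_points(p1: tuple[float, float], p2: tuple[float, float],
                          length_mm: float) -> float:
    """mm-per-pixel scale from a two-point ruler annotation."""
    d = float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))
    if d <= 0 or length_mm <= 0:
        raise ValueError("annotation points must be distinct and length positive")
    return length_mm / d


def subtract_background(img: CalibratedImage, *, blue_floor: float = BLUE_FLOOR) -> GrayImage:
    """Zero blue-card pixels and convert the remainder to 8-bit luma."""
    rgb = np.asarray(img.pixels, dtype=np.int16)
    blueness = rgb[..., 2] - np.maximum(rgb[..., 0], rgb[..., 1])
    flat = blueness.ravel()
    if flat.max() == flat.min():
        cut = float(blue_floor)
    else:
        cut = float(threshold_otsu(flat.astype(float)))
        low = flat[flat <= cut]
        if low.size and low.mean() > blue_floor:
            # the Otsu cut split the card's own noise (sparse or absent
            # tissue); fall back to the fixed blueness floor
            cut = float(blue_floor)
    background = blueness > cut
    luma = (0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2])
    gray = np.where(background, 0, np.round(luma)).astype(np.uint8)
    return GrayImage(gray, img.scale_mm_per_px, img.image_id, img.mouse_id)


def isodata_threshold(hist: np.ndarray) -> int:
    """Iterative intermeans threshold on a 256-bin histogram.

    Starting from the overall mean, iterate
    t <- (mean below-or-at t + mean above t) / 2 to a fixed point, and
    return the integer threshold; foreground is intensity > t.
    """
    hist = np.asarray(hist, dtype=float)
    levels = np.arange(hist.size)
    total = hist.sum()
    if total == 0:
        raise ValueError("empty histogram")
    t = float((hist * levels).sum() / total)
    for _ in range(256):
        below = hist[: int(t) + 1]
        above = hist[int(t) + 1 :]
        wb, wa = below.sum(), above.sum()
        if wb == 0 or wa == 0:
            break
        mb = (below * levels[: int(t) + 1]).sum() / wb
        ma = (above * levels[int(t) + 1 :]).sum() / wa
        t_new = (mb + ma) / 2.0
        if int(t_new) == int(t):
            break
        t = t_new
    return int(t)


def auto_threshold(gray: GrayImage, method: ThresholdMethod = "isodata") -> np.ndarray:
    """Binary foreground mask of the grey image.

    ``isodata`` (iterative intermeans on the 8-bit histogram) is the
    default; ``otsu`` is available as an alternative. A constant image
    yields an empty mask with a logged warning.
    """
    px = np.asarray(gray.pixels)
    if px.min() == px.max():
        logger.warning("constant image %s: empty foreground mask", gray.image_id)
        return np.zeros(px.shape, dtype=bool)
    if method == "isodata":
        t = isodata_threshold(np.bincount(px.ravel(), minlength=256))
    elif method == "otsu":
        t = threshold_otsu(px)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return px > t


def despeckle(mask: np.ndarray, radius: int = 1) -> np.ndarray:
    """Median filter of the binary mask ((2*radius+1)² window, default 3x3)."""
    if mask.dtype != bool:
        raise ValueError("despeckle expects a binary mask")
    size = 2 * radius + 1
    return ndimage.median_filter(mask, size=size, mode="constant", cval=False)


def extract_regions(
    mask: np.ndarray,
    gray: GrayImage,
    *,
    min_area_mm2: float = 0.2,
    connectivity: int = 2,
    fill_holes: bool = True,
    perimeter_method: PerimeterMethod = "crofton",
) -> tuple[LabelMap, list[RegionFeature]]:
    """Label connected components and measure those above the area cut-off.

    ``connectivity`` follows scikit-image semantics (2 = 8-connected).
    Holes inside regions are filled before measurement by default, since
    lesion interiors can threshold unevenly. Returns the relabelled map
    (contiguous 1..n over the retained regions) and measured features.
    """
    if mask.shape != gray.pixels.shape:
        raise ValueError("mask and gray image dimensions differ")
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    structure = ndimage.generate_binary_structure(2, connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    s = gray.scale_mm_per_px
    min_px = min_area_mm2 / (s * s)
    out_labels = np.zeros_like(labels)
    features: list[RegionFeature] = []
    kept = 0
    objects = ndimage.find_objects(labels)
    for i, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rows, cols = np.nonzero(labels[sl] == i)
        if rows.size < min_px:
            continue
        kept += 1
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        out_labels[rows, cols] = kept
        features.append(
            measure_region(
                rows, cols, gray.pixels, s,
                feature_id=f"{gray.image_id}:{kept}" if gray.image_id else str(kept),
                mouse_id=gray.mouse_id,
                image_id=gray.image_id,
                perimeter_method=perimeter_method,
            )
        )
    logger.info("image %s: %d/%d regions >= %.2f mm²", gray.image_id, kept, n, min_area_mm2)
    return LabelMap(out_labels, kept), features


def run_featurecounter(
    img: CalibratedImage,
    *,
    threshold_method: ThresholdMethod = "isodata",
    min_area_mm2: float = 0.2,
    despeckle_radius: int = 1,
    connectivity: int = 2,
    fill_holes: bool = True,
    perimeter_method: PerimeterMethod = "crofton",
) -> tuple[list[RegionFeature], LabelMap]:
    """Full automatic pipeline: photograph in, measured candidate features out.

    Composition of background subtraction, automatic thresholding,
    despeckling, size-filtered connected-component extraction and
    per-region measurement. Deterministic: the same image always yields
    the same feature table. The label map doubles as an audit mask.
    """
    gray = subtract_background(img)
    mask = auto_threshold(gray, threshold_method)
    mask = despeckle(mask, despeckle_radius)
    label_map, features = extract_regions(
        mask, gray,
        min_area_mm2=min_area_mm2,
        connectivity=connectivity,
        fill_holes=fill_holes,
        perimeter_method=perimeter_method,
    )
    return features, label_map


def ingest_manual_mask(
    mask_image: np.ndarray,
    gray: GrayImage,
    *,
    connectivity: int = 2,
    perimeter_method: PerimeterMethod = "crofton",
) -> tuple[list[RegionFeature], LabelMap]:
    """Measure hand-drawn (DRAW) delineations exactly like automatic regions.

    The mask must be binary (bool, or {0, 255} / {0, 1} integers). No
    minimum-area filter is applied: manual delineations are
    authoritative.
    """
    m = np.asarray(mask_image)
    if m.dtype != bool:
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1, 255))):
            raise ValueError("manual mask must be binary (0/255 or 0/1)")
        m = m > 0
    if m.shape != gray.pixels.shape:
        raise ValueError("mask and gray image dimensions differ")
    label_map, features = extract_regions(
        m, gray, min_area_mm2=0.0, connectivity=connectivity,
        fill_holes=False, perimeter_method=perimeter_method,
    )
    return features, label_map
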