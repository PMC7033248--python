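"""Per-region morphometry with particle-analysis semantics.

Computes the 22 measures reported for every segmented image feature:
size (Area, Perim), intensity statistics (Mean, StdDev, Mode, Min, Max,
Median, Skew, Kurt, IntDen, RawIntDen), fitted-ellipse parameters
(Major, Minor, Angle), shape descriptors (Circ, AR, Round, Solidity)
and caliper diameters (Feret, FeretAngle, MinFeret).

Conventions
-----------
* Pixels are unit squares; convex-hull geometry uses the four corner
  points of every member pixel, so a single pixel has ``Feret = sqrt(2)``
  and ``MinFeret = 1`` (in pixels).
* The fitted ellipse shares the region's second central moments and is
  rescaled to match its area exactly; ``Angle`` is the major-axis angle
  in degrees, counter-clockwise from the image x-axis with y pointing up
  (image rows increase downwards), in ``[0, 180)``.
* ``Skew`` and ``Kurt`` use population moments; ``Kurt`` is excess
  kurtosis (0 for a normal distribution). ``Mode`` ties break toward the
  smallest intensity.
* Lengths are reported in mm (``scale_mm_per_px`` per pixel side),
  areas in mm²; intensity statistics are in 8-bit intensity units.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure as _skmeasure

logger = logging.getLogger(__name__)

#: Column order of the 22 measures as they appear in feature tables.
MEASURE_COLUMNS: tuple[str, ...] = (
    "Area", "Perim", "Mean", "StdDev", "Mode", "Min", "Max", "Median",
    "Skew", "Kurt", "Major", "Minor", "Angle", "Circ", "AR", "Round",
    "Solidity", "Feret", "FeretAngle", "MinFeret", "IntDen", "RawIntDen",
)

CALL_VALUES = ("Ad", "nAd", "NA", "uncalled")
PREDICTED_CALL_VALUES = ("Ad", "nAd", "uncalled")

PerimeterMethod = Literal["crofton", "chain-code"]


@dataclass
class RegionFeature:
    """One segmented image feature: identifiers, 22 measures and calls."""

    feature_id: str
    mouse_id: str
    image_id: str = ""
    Area: float = 0.0
    Perim: float = 0.0
    Mean: float = 0.0
    StdDev: float = 0.0
    Mode: float = 0.0
    Min: float = 0.0
    Max: float = 0.0
    Median: float = 0.0
    Skew: float = 0.0
    Kurt: float = 0.0
    Major: float = 0.0
    Minor: float = 0.0
    Angle: float = 0.0
    Circ: float = 0.0
    AR: float = 1.0
    Round: float = 1.0
    Solidity: float = 1.0
    Feret: float = 0.0
    FeretAngle: float = 0.0
    MinFeret: float = 0.0
    IntDen: float = 0.0
    RawIntDen: float = 0.0
    centroid_x_px: float = 0.0
    centroid_y_px: float = 0.0
    call: str = "uncalled"
    predicted_call: str = "uncalled"

    def measures(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_COLUMNS}

    def __post_init__(self) -> None:
        if self.call not in CALL_VALUES:
            raise ValueError(f"invalid call {self.call!r}")
        if self.predicted_call not in PREDICTED_CALL_VALUES:
            raise ValueError(f"invalid predicted_call {self.predicted_call!r}")


def _corner_points(rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Corner points (x, y) of the unit squares of the given pixels.

    x = column, y = -row so that angles come out counter-clockwise from
    the x-axis in the conventional (y-up) orientation.
    """
    x = cols[:, None] + np.array([-0.5, -0.5, 0.5, 0.5])
    y = -rows[:, None] + np.array([-0.5, 0.5, -0.5, 0.5])
    return np.column_stack([x.ravel(), y.ravel()])


def feret_diameters(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Max/min caliper diameters of a pixel region, in pixel units.

    Returns ``(feret, feret_angle_deg, min_feret)``. The maximum Feret is
    the largest distance between convex-hull vertices; the minimum Feret
    is the smallest width over hull edges (rotating calipers). Angles in
    ``[0, 180)`` degrees, counter-clockwise from the image x-axis.
    """
    pts = _corner_points(np.asarray(rows), np.asarray(cols))
    hull = ConvexHull(pts)
    verts = pts[hull.vertices]
    # max caliper: brute force over hull vertex pairs (hulls are small)
    diff = verts[:, None, :] - verts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    feret = math.sqrt(d2[i, j])
    dx, dy = verts[j] - verts[i]
    feret_angle = math.degrees(math.atan2(dy, dx)) % 180.0
    # min caliper: smallest max-distance of vertices from each hull edge
    edges = np.roll(verts, -1, axis=0) - verts
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    normals = np.column_stack([-edges[keep, 1], edges[keep, 0]]) / lengths[keep, None]
    # width normal to each hull edge; the minimum over edges is MinFeret
    projections = verts @ normals.T
    widths = projections.max(axis=0) - projections.min(axis=0)
    min_feret = float(widths.min())
    return float(feret), float(feret_angle), min_feret


def fit_ellipse(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float, float]:
    """Moment-matching ellipse of a pixel region: (major, minor, angle).

    Axis lengths are full diameters in pixel units, scaled so the ellipse
    area equals the pixel count. Angle is in ``[0, 180)`` degrees,
    counter-clockwise from the x-axis (y up). Each pixel contributes the
    second moment of a unit square (the 1/12 diagonal term), so even a
    single-pixel region has a well-defined, non-degenerate ellipse.
    """
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    n = rows.size
    x = cols - cols.mean()
    y = -(rows - rows.mean())
    uxx = (x @ x) / n + 1.0 / 12.0
    uyy = (y @ y) / n + 1.0 / 12.0
    uxy = (x @ y) / n
    common = math.sqrt((uxx - uyy) ** 2 + 4.0 * uxy**2)
    l1 = (uxx + uyy + common) / 2.0  # major eigenvalue
    l2 = (uxx + uyy - common) / 2.0
    if l2 <= 0:  # numerically collinear region
        logger.warning("degenerate region moments; clamping minor axis")
        l2 = 1.0 / 12.0
    major = 4.0 * math.sqrt(l1)
    minor = 4.0 * math.sqrt(l2)
    # rescale so pi * (major/2) * (minor/2) == pixel area
    s = math.sqrt(4.0 * n / (math.pi * major * minor))
    major *= s
    minor *= s
    if uxy == 0 and uxx >= uyy:
        angle = 0.0
    elif uxy == 0:
        angle = 90.0
    else:
        angle = math.degrees(math.atan2(l1 - uxx, uxy)) % 180.0
    return major, minor, angle


def intensity_stats(values: np.ndarray) -> dict[str, float]:
    """Intensity moments over member-pixel values (population normalization)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty region")
    mean = float(v.mean())
    m2 = float(((v - mean) ** 2).mean())
    std = math.sqrt(m2)
    if m2 == 0:
        logger.warning("constant-intensity region; Skew/Kurt set to 0")
        skew = kurt = 0.0
    else:
        m3 = float(((v - mean) ** 3).mean())
        m4 = float(((v - mean) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
    ints = np.asarray(values).astype(np.int64)
    counts = np.bincount(ints, minlength=256)
    mode = float(np.argmax(counts))  # argmax returns the smallest tie
    return {
        "Mean": mean,
        "StdDev": std,
        "Mode": mode,
        "Min": float(v.min()),
        "Max": float(v.max()),
        "Median": float(np.median(v)),
        "Skew": skew,
        "Kurt": kurt,
        "RawIntDen": float(ints.sum()),
    }


def region_perimeter(region_mask: np.ndarray, method: PerimeterMethod = "crofton") -> float:
    """Boundary length of a binary region in pixel units.

    ``crofton`` (default) is the 4-direction Crofton estimate, unbiased
    for smooth outlines; ``chain-code`` is the 8-connected contour length
    with sqrt(2)-weighted diagonal steps, which overestimates smooth
    perimeters by a few percent. Regions of a single pixel report the
    crack length 4.
    """
    if region_mask.sum() == 1:
        return 4.0
    if method == "crofton":
        return float(_skmeasure.perimeter_crofton(region_mask, directions=4))
    if method == "chain-code":
        return float(_skmeasure.perimeter(region_mask, neighborhood=4))
    raise ValueError(f"unknown perimeter method {method!r}")


def measure_region(
    rows: np.ndarray,
    cols: np.ndarray,
    gray: np.ndarray,
    scale_mm_per_px: float,
    *,
    feature_id: str = "",
    mouse_id: str = "",
    image_id: str = "",
    perimeter_method: PerimeterMethod = "crofton",
) -> RegionFeature:
    """Measure all 22 variables for the region given by pixel coordinates.

    ``rows``/``cols`` index member pixels of ``gray`` (H x W, 8-bit).
    Lengths are scaled by ``scale_mm_per_px``, areas by its square.
    """
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    if rows.size == 0:
        raise ValueError("empty region")
    if rows.size < 3:
        logger.warning("region %s has %d pixels; unit-square conventions apply",
                       feature_id, rows.size)
    s = float(scale_mm_per_px)
    n_px = rows.size
    area = n_px * s * s

    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    local = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    local[rows - r0, cols - c0] = True
    perim = region_perimeter(local, perimeter_method) * s

    stats = intensity_stats(gray[rows, cols])
    major_px, minor_px, angle = fit_ellipse(rows, cols)
    feret_px, feret_angle, min_feret_px = feret_diameters(rows, cols)

    pts = _corner_points(rows, cols)
    hull_area_px = ConvexHull(pts).volume
    solidity = min(n_px / hull_area_px, 1.0)

    circ = min(4.0 * math.pi * area / perim**2, 1.0) if perim > 0 else 1.0
    major = major_px * s
    minor = minor_px * s
    return RegionFeature(
        feature_id=feature_id,
        mouse_id=mouse_id,
        image_id=image_id,
        Area=area,
        Perim=perim,
        **stats,
        Major=major,
        Minor=minor,
        Angle=angle,
        Circ=circ,
        AR=major / minor,
        Round=4.0 * area / (math.pi * major**2),
        Solidity=solidity,
        Feret=feret_px * s,
        FeretAngle=feret_angle,
        MinFeret=min_feret_px * s,
        IntDen=area * stats["Mean"],
        centroid_x_px=float(cols.mean()),
        centroid_y_px=float(rows.mean()),
    )
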