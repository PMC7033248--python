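"""Ground-truthed synthetic photographs and feature tables.

Two generators make every stage testable without real data:

* :func:`generate_image` renders a calibrated photograph of a blue-card
  preparation: noisy blue background, bright sessile elliptical lesions
  with soft (half-intensity at the true boundary) edges, and optional
  distractor artifacts of the kinds seen in real preparations — thin
  rolled-edge streaks, pale fat patches and small specular reflections.
  The ground truth records each lesion's exact pixel set and analytic
  area; distractors are recorded separately and never count as lesions.

* :func:`generate_table` draws a mouse-nested feature table with the
  same 22 columns a measured photograph produces. Class signal (Ad
  larger, rounder, brighter, more solid; nAd more elongated and
  irregular) lives in a set of informative measures whose class-mean
  gap scales with ``class_separation``; derived measures (Perim from
  Circ and Area, axes from Area and AR, IntDen from Area and Mean, ...)
  are filled in coherently so the table satisfies the same invariants
  as a measured one. Optional per-mouse random effects, injected batch
  bias for chosen mice, and a radial (quadratic) class geometry are
  available for QC and classifier tests.

Every artifact is a pure function of its spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw as _skdraw

from .segmentation import CalibratedImage

DEFAULT_BACKGROUND = (70, 110, 170)
LESION_RGB = (235, 228, 215)
STREAK_RGB = (205, 198, 185)
FAT_RGB = (228, 216, 170)
REFLECTION_RGB = (252, 252, 250)


@dataclass(frozen=True)
class SynthImageSpec:
    """Parameters of one synthetic photograph."""

    height: int = 600
    width: int = 800
    scale_mm_per_px: float = 0.05
    background_rgb: tuple[int, int, int] = DEFAULT_BACKGROUND
    background_noise_sd: float = 5.0
    n_lesions: int = 10
    lesion_area_range_mm2: tuple[float, float] = (0.3, 2.0)
    lesion_peak: int = 235
    edge_sharpness: float = 6.0  # exponent of the radial intensity fall-off
    min_separation_mm: float = 3.0
    n_edge_streaks: int = 0
    n_fat_patches: int = 0
    n_reflections: int = 0
    seed: int = 0
    image_id: str = "synth"
    mouse_id: str = "m0"


@dataclass
class ImageGroundTruth:
    """Planted lesions (label map + areas) and distractor mask."""

    lesion_labels: np.ndarray        # 0 background, 1..n_lesions
    lesion_areas_mm2: list[float]    # analytic ellipse areas
    lesion_centres_px: list[tuple[float, float]]  # (row, col)
    distractor_mask: np.ndarray


def _place_centres(rng, n, h, w, margin, min_sep_px) -> list[tuple[float, float]]:
    centres: list[tuple[float, float]] = []
    for _ in range(20_000):
        if len(centres) == n:
            break
        r = rng.uniform(margin, h - margin)
        c = rng.uniform(margin, w - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep_px**2 for r0, c0 in centres):
            centres.append((r, c))
    if len(centres) < n:
        raise ValueError("could not place lesions with the requested separation")
    return centres


def generate_image(spec: SynthImageSpec) -> tuple[CalibratedImage, ImageGroundTruth]:
    """Render a calibrated synthetic photograph with its ground truth."""
    rng = np.random.default_rng(spec.seed)
    h, w, s = spec.height, spec.width, spec.scale_mm_per_px
    img = np.empty((h, w, 3), dtype=float)
    for ch in range(3):
        img[..., ch] = spec.background_rgb[ch] + rng.normal(0, spec.background_noise_sd, (h, w))

    max_a_px = math.sqrt(spec.lesion_area_range_mm2[1] / (s * s) / math.pi) * 1.6
    margin = max_a_px + 3
    min_sep_px = spec.min_separation_mm / s
    centres = _place_centres(rng, spec.n_lesions, h, w, margin, min_sep_px)

    rows_idx, cols_idx = np.mgrid[0:h, 0:w]
    lesion_labels = np.zeros((h, w), dtype=np.int32)
    lesion_areas: list[float] = []
    lesion_rgb = np.array(LESION_RGB, dtype=float) * (spec.lesion_peak / 235.0)
    for i, (r0, c0) in enumerate(centres, start=1):
        area_mm2 = rng.uniform(*spec.lesion_area_range_mm2)
        area_px = area_mm2 / (s * s)
        ar = rng.uniform(1.0, 1.6)
        a = math.sqrt(area_px * ar / math.pi)
        b = a / ar
        theta = rng.uniform(0, math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        # bounding window for speed
        ext = int(math.ceil(2.2 * a)) + 2
        rr = slice(max(int(r0) - ext, 0), min(int(r0) + ext + 1, h))
        cc = slice(max(int(c0) - ext, 0), min(int(c0) + ext + 1, w))
        dr = rows_idx[rr, cc] - r0
        dc = cols_idx[rr, cc] - c0
        u2 = ((dc * ct + dr * st) / a) ** 2 + ((-dc * st + dr * ct) / b) ** 2
        u = np.sqrt(u2)
        inside = u <= 1.0
        lesion_labels[rr, cc][inside] = i
        weight = np.exp(-math.log(2.0) * u**spec.edge_sharpness)
        weight[u > 2.0] = 0.0
        for ch in range(3):
            patch = img[rr, cc, ch]
            img[rr, cc, ch] = patch + weight * (lesion_rgb[ch] - patch)
        lesion_areas.append(math.pi * a * b * s * s)

    distractor = np.zeros((h, w), dtype=bool)

    def _paint(mask: np.ndarray, rgb, jitter=4.0) -> None:
        distractor[mask] = True
        for ch in range(3):
            img[..., ch][mask] = rgb[ch] + rng.normal(0, jitter, int(mask.sum()))

    for _ in range(spec.n_edge_streaks):
        # thin, high-aspect-ratio rolled-edge streak
        r0 = rng.integers(10, h - 10)
        c0 = rng.integers(10, w - 10)
        length = rng.uniform(4.0, 10.0) / s
        theta = rng.uniform(0, math.pi)
        r1 = int(np.clip(r0 + length * math.sin(theta), 1, h - 2))
        c1 = int(np.clip(c0 + length * math.cos(theta), 1, w - 2))
        rr_l, cc_l = _skdraw.line(int(r0), int(c0), r1, c1)
        m = np.zeros((h, w), dtype=bool)
        m[rr_l, cc_l] = True
        from scipy import ndimage
        m = ndimage.binary_dilation(m, iterations=1)
        _paint(m, STREAK_RGB)

    for _ in range(spec.n_fat_patches):
        r0 = rng.integers(20, h - 20)
        c0 = rng.integers(20, w - 20)
        rad = math.sqrt(rng.uniform(0.3, 1.0) / (s * s) / math.pi)
        rr_f, cc_f = _skdraw.ellipse(r0, c0, rad * rng.uniform(0.7, 1.0),
                                     rad * rng.uniform(1.0, 1.5), shape=(h, w),
                                     rotation=rng.uniform(0, math.pi))
        m = np.zeros((h, w), dtype=bool)
        m[rr_f, cc_f] = True
        _paint(m, FAT_RGB)

    for _ in range(spec.n_reflections):
        r0 = rng.integers(10, h - 10)
        c0 = rng.integers(10, w - 10)
        rad = math.sqrt(rng.uniform(0.05, 0.15) / (s * s) / math.pi)
        rr_s, cc_s = _skdraw.disk((r0, c0), rad, shape=(h, w))
        m = np.zeros((h, w), dtype=bool)
        m[rr_s, cc_s] = True
        _paint(m, REFLECTION_RGB, jitter=1.5)

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    image = CalibratedImage(pixels, s, image_id=spec.image_id, mouse_id=spec.mouse_id)
    truth = ImageGroundTruth(
        lesion_labels=lesion_labels,
        lesion_areas_mm2=lesion_areas,
        lesion_centres_px=centres,
        distractor_mask=distractor,
    )
    return image, truth


# --- feature tables -------------------------------------------------------

#: (mid, half-gap, sd) of the informative latent measures; the class means
#: are mid +/- separation * half-gap (Ad on the + side of the stated sign).
INFORMATIVE = {
    "log10Area": (-0.275, 0.175, 0.35),   # Ad lesions are larger
    "Circ": (0.72, 0.10, 0.10),           # and rounder
    "log10AR": (0.215, -0.135, 0.16),     # streaks/folds are elongated
    "Mean": (180.0, 10.0, 18.0),          # adenomas are denser white
    "Solidity": (0.90, 0.05, 0.05),
    "StdDev": (21.0, -3.0, 5.0),
    "Skew": (0.35, -0.15, 0.45),
    "Kurt": (0.5, -0.3, 0.9),
}


@dataclass(frozen=True)
class SynthTableSpec:
    """Parameters of one synthetic mouse-nested feature table.

    Defaults emulate the scale of a large adenoma-quantification study:
    117 mice, about 27 features per mouse (Poisson), 40.1% Ad, and a
    class separation giving realistic (high-80s %) discriminability.
    """

    n_mice: int = 117
    mean_features_per_mouse: float = 27.25
    ad_fraction: float = 0.401
    class_separation: float = 0.58
    mouse_effect_sd: float = 0.1
    bias_mice: tuple[str, ...] = ()
    bias_sd: float = 3.0
    bias_n_measures: int = 6
    radial_geometry: bool = False
    radial_r_nad: float = 4.0
    scale_mm_per_px: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.ad_fraction < 1:
            raise ValueError("ad_fraction must be in (0, 1)")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")


def generate_table(spec: SynthTableSpec) -> pd.DataFrame:
    """Draw a feature table with ground-truth calls (one row per feature)."""
    rng = np.random.default_rng(spec.seed)
    mice = [f"m{i:03d}" for i in range(spec.n_mice)]
    counts = np.maximum(rng.poisson(spec.mean_features_per_mouse, spec.n_mice), 1)
    n = int(counts.sum())
    mouse_col = np.repeat(mice, counts)

    is_ad = rng.random(n) < spec.ad_fraction
    sign = np.where(is_ad, 1.0, -1.0)

    names = list(INFORMATIVE)
    latent = {}
    # per-mouse random effects (and injected bias) in latent units
    offsets = {m: rng.normal(0, spec.mouse_effect_sd, len(names)) for m in mice}
    for m in spec.bias_mice:
        if m not in offsets:
            raise ValueError(f"bias mouse {m!r} not in table")
        bias = np.zeros(len(names))
        bias[: spec.bias_n_measures] = spec.bias_sd
        offsets[m] = offsets[m] + bias
    off = np.array([offsets[m] for m in mouse_col])

    for j, name in enumerate(names):
        mid, half, sd = INFORMATIVE[name]
        mu = mid + sign * half * spec.class_separation
        latent[name] = mu + (off[:, j] + rng.standard_normal(n)) * sd

    if spec.radial_geometry:
        # concentric classes in the (Mean, StdDev) plane; all other
        # measures carry no class signal
        for j, name in enumerate(names):
            if name in ("Mean", "StdDev"):
                continue
            mid, _, sd = INFORMATIVE[name]
            latent[name] = mid + (off[:, j] + rng.standard_normal(n)) * sd
        radius = np.where(is_ad, 0.0, spec.radial_r_nad) + rng.standard_normal(n)
        theta = rng.uniform(0, 2 * math.pi, n)
        latent["Mean"] = 150.0 + 12.0 * radius * np.cos(theta)
        latent["StdDev"] = 25.0 + 3.5 * radius * np.sin(theta)

    area = 10.0 ** latent["log10Area"]
    ar = np.maximum(10.0 ** np.abs(latent["log10AR"]), 1.0)
    circ = np.clip(latent["Circ"], 0.05, 1.0)
    mean = np.clip(latent["Mean"], 30.0, 250.0)
    solidity = np.clip(latent["Solidity"], 0.3, 1.0)
    stddev = np.clip(latent["StdDev"], 0.5, 60.0)
    skew = latent["Skew"]
    kurt = latent["Kurt"]

    # coherent derived measures (exact ellipse geometry)
    a = np.sqrt(area * ar / math.pi)   # semi-major, mm
    b = a / ar
    major, minor = 2 * a, 2 * b
    perim = np.sqrt(4 * math.pi * area / circ)
    feret = major * rng.uniform(1.0, 1.06, n)
    min_feret = minor * rng.uniform(0.94, 1.0, n)
    spread = rng.uniform(1.5, 2.5, n)
    vmin = np.clip(mean - stddev * spread, 0, 255)
    vmax = np.clip(mean + stddev * spread, 0, 255)
    vmax = np.maximum(vmax, vmin)
    median = np.clip(mean + rng.normal(0, 2.0, n), vmin, vmax)
    mode = np.clip(np.round(median + rng.normal(0, 4.0, n)), vmin, vmax)
    area_px = area / spec.scale_mm_per_px**2

    table = pd.DataFrame({
        "image_id": mouse_col,
        "mouse_id": mouse_col,
        "feature_id": [f"{m}:{i}" for i, m in enumerate(mouse_col)],
        "Area": area,
        "Perim": perim,
        "Mean": mean,
        "StdDev": stddev,
        "Mode": mode,
        "Min": vmin,
        "Max": vmax,
        "Median": median,
        "Skew": skew,
        "Kurt": kurt,
        "Major": major,
        "Minor": minor,
        "Angle": rng.uniform(0, 180, n),
        "Circ": circ,
        "AR": ar,
        "Round": 4 * area / (math.pi * major**2),
        "Solidity": solidity,
        "Feret": feret,
        "FeretAngle": rng.uniform(0, 180, n),
        "MinFeret": min_feret,
        "IntDen": area * mean,
        "RawIntDen": np.round(area_px * mean),
        "centroid_x_px": np.zeros(n),
        "centroid_y_px": np.zeros(n),
        "call": np.where(is_ad, "Ad", "nAd"),
        "predicted_call": "uncalled",
    })
    return table
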