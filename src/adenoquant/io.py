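"""Readers/writers for feature tables, masks and serialized models.

Tabular interchange is CSV (RFC 4180, UTF-8, "." decimal); masks are
8-bit PNG (background 0, features 255). Every file written here starts
with comment lines recording the tool version, the configuration hash
and the seed(s), so any output can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import __version__
from .lda_pipeline import LdaModel
from .morphometry import (CALL_VALUES, MEASURE_COLUMNS, PREDICTED_CALL_VALUES,
                          RegionFeature)
from .segmentation import CalibratedImage, GrayImage

FEATURE_COLUMNS = (
    "image_id", "mouse_id", "feature_id", *MEASURE_COLUMNS,
    "centroid_x_px", "centroid_y_px", "call", "predicted_call",
)


def features_to_frame(features: list[RegionFeature]) -> pd.DataFrame:
    """One row per RegionFeature, in the canonical column order."""
    rows = [{c: getattr(f, c) for c in FEATURE_COLUMNS} for f in features]
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


def _header_lines(metadata: dict | None) -> str:
    meta = {"tool_version": __version__}
    meta.update(metadata or {})
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_feature_csv(table: pd.DataFrame, path: str | Path,
                      metadata: dict | None = None) -> None:
    """Write a feature table with a reproducibility comment header."""
    path = Path(path)
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")
    ordered = [*FEATURE_COLUMNS, *[c for c in table.columns if c not in FEATURE_COLUMNS]]
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(_header_lines(metadata))
        table[ordered].to_csv(fh, index=False)


def read_feature_csv(path: str | Path) -> pd.DataFrame:
    """Read a feature table; validates columns and call values.

    Unknown extra columns are preserved. Decimal parsing is
    locale-independent ("." decimal, exponent notation accepted).
    """
    table = pd.read_csv(path, comment="#", encoding="utf-8")
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature CSV missing columns: {sorted(missing)}")
    for col, allowed in (("call", CALL_VALUES), ("predicted_call", PREDICTED_CALL_VALUES)):
        bad = ~table[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"invalid {col} value {table[col].iloc[row]!r} in data row {row}"
            )
    return table


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    """Binary or label mask to 8-bit PNG (background 0, features 255)."""
    out = np.where(np.asarray(mask) > 0, 255, 0).astype(np.uint8)
    Image.fromarray(out, mode="L").save(Path(path), format="PNG")


def read_image(path: str | Path, scale_mm_per_px: float, *,
               image_id: str = "", mouse_id: str = "") -> CalibratedImage:
    """Load an 8-bit RGB photograph (PNG/TIFF/JPEG) with its scale."""
    img = Image.open(Path(path)).convert("RGB")
    return CalibratedImage(
        pixels=np.asarray(img, dtype=np.uint8),
        scale_mm_per_px=scale_mm_per_px,
        image_id=image_id or Path(path).stem,
        mouse_id=mouse_id,
    )


def read_mask(path: str | Path) -> np.ndarray:
    """Load a mask image as a boolean array (any nonzero pixel is set)."""
    return np.asarray(Image.open(Path(path)).convert("L")) > 0


def save_model(model: LdaModel, path: str | Path, metadata: dict | None = None) -> None:
    """Serialize a fitted discriminant to a single versioned text file."""
    payload = {
        "format": "adenoquant-lda/1",
        "tool_version": __version__,
        "metadata": metadata or {},
        "columns": model.columns,
        "classes": list(model.classes),
        "means": model.means.tolist(),
        "pooled_cov": model.pooled_cov.tolist(),
        "priors": model.priors.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> LdaModel:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    if d.get("format") != "adenoquant-lda/1":
        raise ValueError(f"unrecognized model file format: {d.get('format')!r}")
    return LdaModel(
        columns=list(d["columns"]),
        classes=tuple(d["classes"]),
        means=np.asarray(d["means"], dtype=float),
        pooled_cov=np.asarray(d["pooled_cov"], dtype=float),
        priors=np.asarray(d["priors"], dtype=float),
    )
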