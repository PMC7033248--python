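"""Per-measure transformations and filtering ahead of PCA/LDA.

Discriminant analysis is sensitive to strongly non-normal inputs and
extreme outliers, so each of the 22 measures is mapped through a
per-measure rule — identity, log10, shifted log10 (log10(x + c)) or
drop — optionally combined with a validity interval outside which the
value is marked missing. Rows with any missing retained value are then
removed, the squares of the retained columns are appended (allowing
quadratic class boundaries in the original variable space), and the
result is the design matrix for PCA/LDA.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphometry import MEASURE_COLUMNS

logger = logging.getLogger(__name__)

RULES = ("identity", "log10", "shifted_log10", "drop")


@dataclass
class TransformSpec:
    """Per-measure transform rules and validity filters.

    ``rules`` maps each of the 22 measures to one of ``identity``,
    ``log10``, ``shifted_log10`` or ``drop``; ``offsets`` holds the
    shift c for shifted_log10 measures; ``filters`` maps a measure to a
    closed interval (lo, hi) outside which values become missing.
    """

    rules: dict[str, str]
    offsets: dict[str, float] = field(default_factory=dict)
    filters: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(MEASURE_COLUMNS) - set(self.rules)
        if missing:
            raise ValueError(f"spec missing rules for: {sorted(missing)}")
        unknown = {m: r for m, r in self.rules.items() if r not in RULES}
        if unknown:
            raise ValueError(f"unknown rules: {unknown}")
        for m, r in self.rules.items():
            if r == "shifted_log10" and m not in self.offsets:
                raise ValueError(f"shifted_log10 measure {m!r} has no offset")

    @property
    def retained(self) -> list[str]:
        return [m for m in MEASURE_COLUMNS if self.rules[m] != "drop"]

    def spec_hash(self) -> str:
        payload = json.dumps(
            {"rules": self.rules, "offsets": self.offsets,
             "filters": {k: list(v) for k, v in self.filters.items()}},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_json(self) -> str:
        return json.dumps(
            {"rules": self.rules, "offsets": self.offsets,
             "filters": {k: list(v) for k, v in self.filters.items()}},
            indent=2, sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TransformSpec":
        d = json.loads(text)
        return cls(
            rules=d["rules"],
            offsets={k: float(v) for k, v in d.get("offsets", {}).items()},
            filters={k: (float(v[0]), float(v[1])) for k, v in d.get("filters", {}).items()},
        )


#: Measures that are strictly positive sizes/intensities and log-transform well.
LOG_MEASURES = ("Area", "Perim", "Major", "Minor", "Feret", "MinFeret",
                "IntDen", "RawIntDen")
#: Signed moment measures needing a shift before log transform.
SHIFTED_MEASURES = ("Skew", "Kurt")
#: Orientation depends on how the tissue was laid out, not on what it is.
DROPPED_MEASURES = ("Angle", "FeretAngle")


def default_spec(table: pd.DataFrame) -> TransformSpec:
    """The package's documented default transform spec, fitted on a table.

    log10 for the strictly positive size measures, shifted log10 with
    c = 1 - min(x) for the signed moment measures (so the smallest
    training value maps to 0), drop for the orientation angles,
    identity otherwise. The offsets are fitted on the given (training)
    table and must be reused verbatim for any table scored later.
    """
    rules = {}
    offsets = {}
    for m in MEASURE_COLUMNS:
        if m in LOG_MEASURES:
            rules[m] = "log10"
        elif m in SHIFTED_MEASURES:
            rules[m] = "shifted_log10"
            offsets[m] = float(1.0 - table[m].min())
        elif m in DROPPED_MEASURES:
            rules[m] = "drop"
        else:
            rules[m] = "identity"
    return TransformSpec(rules=rules, offsets=offsets)


def apply_transforms(table: pd.DataFrame, spec: TransformSpec) -> pd.DataFrame:
    """Apply the per-measure rules; non-finite results become missing.

    Returns a copy with dropped measures removed and every retained
    measure transformed. Values outside a measure's validity interval
    are set missing. Non-measure columns pass through untouched.
    """
    out = table.copy()
    for m in MEASURE_COLUMNS:
        rule = spec.rules[m]
        if rule == "drop":
            if m in out.columns:
                out = out.drop(columns=m)
            continue
        x = out[m].astype(float)
        if m in spec.filters:
            lo, hi = spec.filters[m]
            x = x.where((x >= lo) & (x <= hi))
        if rule == "log10":
            with np.errstate(divide="ignore", invalid="ignore"):
                x = np.log10(x)
        elif rule == "shifted_log10":
            c = spec.offsets[m]
            shifted = x + c
            if (shifted <= 0).any():
                bad = float(x.min())
                raise ValueError(
                    f"shifted_log10 offset for {m!r} too small: min(x)+c = {bad + c}"
                )
            x = np.log10(shifted)
        x = pd.Series(x, index=out.index).where(np.isfinite(x))
        out[m] = x
    return out


def drop_incomplete(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Remove rows with any missing value in the retained measure columns."""
    cols = columns if columns is not None else [c for c in MEASURE_COLUMNS if c in table.columns]
    keep = table[cols].notna().all(axis=1)
    removed = (~keep).groupby(table["mouse_id"]).sum() if "mouse_id" in table.columns else None
    if removed is not None and removed.sum():
        for mouse, k in removed[removed > 0].items():
            logger.info("dropped %d incomplete feature(s) for mouse %s", k, mouse)
    return table.loc[keep].copy()


def augment_squares(matrix: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Append the square of every input column (originals first, then squares)."""
    cols = columns if columns is not None else list(matrix.columns)
    if matrix[cols].isna().any().any():
        raise ValueError("design matrix has missing values; drop_incomplete first")
    squares = matrix[cols].pow(2)
    squares.columns = [f"{c}_sq" for c in cols]
    return pd.concat([matrix[cols], squares], axis=1)


def build_design_matrix(
    table: pd.DataFrame, spec: TransformSpec, *, require_call: bool = True
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Transform, filter and square-augment a feature table.

    Returns ``(X, y, mouse_ids)`` where X has one row per complete
    feature (originals then squares), y is the Ad/nAd call (empty
    strings when ``require_call`` is False) and mouse_ids aligns with X.
    NA-called and uncalled features are excluded when calls are required.
    """
    t = apply_transforms(table, spec)
    if require_call:
        t = t[t["call"].isin(["Ad", "nAd"])]
    t = drop_incomplete(t, spec.retained)
    X = augment_squares(t, spec.retained)
    y = t["call"] if require_call else pd.Series("", index=t.index)
    return X, y, t["mouse_id"]
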