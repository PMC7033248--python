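"""Mouse-level tumour-burden summaries and method comparison.

Each quantification method (DRAW: manual delineation, CALL: manually
verified automatic features, LDA: fully automatic classification)
yields per-mouse adenoma counts and total areas. Methods are compared
with Deming regression — an errors-in-both-variables line fit
appropriate when neither method is a gold standard — at variance ratio
1 (orthogonal regression), with bias-corrected and accelerated (BCa)
bootstrap confidence intervals over mouse resamples. Nonparametric
group comparisons (Mann-Whitney U, Kruskal-Wallis) are exposed as thin
reporting utilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

METHOD_CALL_COLUMN = {"DRAW": None, "CALL": "call", "LDA": "predicted_call"}


@dataclass(frozen=True)
class MouseSummary:
    """Adenoma burden of one mouse under one method."""

    mouse_id: str
    method: str
    ad_count: int
    total_area: float
    mean_area: float  # NaN when count is 0


def summarize_mouse(table: pd.DataFrame, method: str) -> list[MouseSummary]:
    """Per-mouse adenoma count and total area for one method.

    DRAW tables contain only delineated adenomas, so every feature
    counts; CALL uses the manual call column; LDA the predicted call.
    Every mouse present in the table appears, with zeros when it has no
    adenoma under the method.
    """
    if method not in METHOD_CALL_COLUMN:
        raise ValueError(f"unknown method {method!r}")
    col = METHOD_CALL_COLUMN[method]
    sel = table if col is None else table[table[col] == "Ad"]
    out = []
    for mouse in sorted(table["mouse_id"].unique()):
        sub = sel[sel["mouse_id"] == mouse]
        n = len(sub)
        total = float(sub["Area"].sum())
        out.append(MouseSummary(
            mouse_id=mouse, method=method, ad_count=n, total_area=total,
            mean_area=total / n if n else float("nan"),
        ))
    return out


def summaries_frame(summaries: list[MouseSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries]).set_index("mouse_id")


@dataclass(frozen=True)
class DemingFit:
    """Deming regression result at variance ratio 1 with BCa intervals."""

    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    n: int
    variance_ratio: float = 1.0
    n_boot: int = 999


def _deming_slope_intercept(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form orthogonal (variance ratio 1) Deming estimates."""
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    if sxy == 0:
        raise ValueError("no linear association (Sxy = 0)")
    slope = ((syy - sxx) + np.sqrt((syy - sxx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    return float(slope), float(ym - slope * xm)


def _bca_interval(estimate: float, boot: np.ndarray, jack: np.ndarray,
                  alpha: float = 0.05) -> tuple[float, float]:
    """BCa percentile interval from bootstrap replicates and jackknife values."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0 or np.allclose(boot, estimate):
        return (estimate, estimate)  # degenerate (e.g. exactly collinear data)
    prop = np.mean(boot < estimate)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), len(boot) / (len(boot) + 1.0))
    z0 = stats.norm.ppf(prop)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi)


def deming_fit(
    x, y, *, seed: int, n_boot: int = 999, alpha: float = 0.05
) -> DemingFit:
    """Orthogonal Deming regression of y on x with BCa bootstrap CIs.

    ``x`` and ``y`` are mouse-level values paired by mouse (n >= 3).
    Bootstrap resamples mice; resamples with no linear association
    (Sxy = 0) are redrawn, capped at 10 * n_boot attempts. The jackknife
    over mice supplies the BCa acceleration. Seed required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 mice")
    slope, intercept = _deming_slope_intercept(x, y)

    rng = np.random.default_rng(seed)
    boot_s = np.empty(n_boot)
    boot_i = np.empty(n_boot)
    attempts = 0
    k = 0
    while k < n_boot:
        if attempts > 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap resamples")
        attempts += 1
        idx = rng.integers(n, size=n)
        try:
            boot_s[k], boot_i[k] = _deming_slope_intercept(x[idx], y[idx])
        except ValueError:
            continue
        k += 1

    jack_s = np.empty(n)
    jack_i = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            jack_s[i], jack_i[i] = _deming_slope_intercept(x[mask], y[mask])
        except ValueError:
            jack_s[i], jack_i[i] = slope, intercept
    return DemingFit(
        slope=slope,
        intercept=intercept,
        slope_ci=_bca_interval(slope, boot_s, jack_s, alpha),
        intercept_ci=_bca_interval(intercept, boot_i, jack_i, alpha),
        n=n,
        n_boot=n_boot,
    )


def group_compare(values_a, values_b=None, *, alternative: str = "two-sided",
                  groups: list | None = None) -> dict:
    """Rank-based group comparison (reporting utility).

    Two samples: Mann-Whitney U with normal approximation and tie
    correction. More than two (pass ``groups`` as a list of arrays):
    Kruskal-Wallis. Returns a dict with the statistic, p-value and test
    name.
    """
    if groups is not None:
        stat, p = stats.kruskal(*groups)
        return {"test": "kruskal-wallis", "statistic": float(stat), "p_value": float(p)}
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return {"test": "mann-whitney", "statistic": float(res.statistic),
            "p_value": float(res.pvalue), "alternative": alternative}
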