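"""Performance indicators and the mouse-nested bootstrap validation.

Feature-level indicators compare predicted to manually verified calls:
accuracy (ACC), per-class true positive rate (TPR, sensitivity) and
positive predictive value (PPV, precision). Dataset-level indicators
are the predicted-over-true count ratios per class (Ad.ratio,
nAd.ratio); a ratio of 1 is necessary but not sufficient for perfect
classification, since equal numbers of false positives and false
negatives also yield 1. Algebraically, Ad_ratio = TPR_Ad / PPV_Ad
whenever PPV_Ad > 0.

The validation experiment resamples mice — not features — with
replacement, carrying every feature of a drawn mouse (again for each
repeat draw), until at least ``min_mice`` draws and ``min_features``
features have accumulated; datasets with less than ``min_class_frac``
of either class are rejected and redrawn. Each accepted dataset trains
its own discriminant and is scored in-sample; quantiles of each
indicator over the datasets summarize stability against a full-dataset
reference fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lda_pipeline import LdaModel, predict, train_lda

logger = logging.getLogger(__name__)

INDICATOR_NAMES = ("ACC", "TPR_Ad", "PPV_Ad", "TPR_nAd", "PPV_nAd",
                   "Ad_ratio", "nAd_ratio")
QUANTILE_PROBS = (0.0, 0.05, 0.25, 0.50, 0.75, 0.95, 1.0)


@dataclass(frozen=True)
class IndicatorSet:
    """The seven feature- and dataset-level performance indicators."""

    ACC: float
    TPR_Ad: float
    PPV_Ad: float
    TPR_nAd: float
    PPV_nAd: float
    Ad_ratio: float
    nAd_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDICATOR_NAMES}


@dataclass(frozen=True)
class BootstrapConfig:
    """Parameters of the mouse-resampling validation scheme."""

    min_mice: int = 12
    min_features: int = 750
    min_class_frac: float = 0.30
    n_datasets: int = 4000
    max_rejections: int = 10_000

    def __post_init__(self) -> None:
        if self.min_mice < 1 or self.n_datasets < 1:
            raise ValueError("min_mice and n_datasets must be >= 1")
        if not 0 <= self.min_class_frac < 0.5:
            raise ValueError("min_class_frac must be in [0, 0.5)")


def compute_indicators(true_calls, predicted_calls) -> IndicatorSet:
    """All seven indicators from paired Ad/nAd call vectors.

    Undefined quantities (e.g. TPR_Ad with zero true Ad) are reported
    as NaN with a warning.
    """
    t = np.asarray(true_calls)
    p = np.asarray(predicted_calls)
    if t.shape != p.shape:
        raise ValueError("call vectors differ in length")
    bad = set(np.unique(np.concatenate([t, p]))) - {"Ad", "nAd"}
    if bad:
        raise ValueError(f"calls must be Ad/nAd, got {sorted(bad)}")
    tp = int(((t == "Ad") & (p == "Ad")).sum())
    fn = int(((t == "Ad") & (p == "nAd")).sum())
    fp = int(((t == "nAd") & (p == "Ad")).sum())
    tn = int(((t == "nAd") & (p == "nAd")).sum())
    n_ad, n_nad = tp + fn, fp + tn

    def ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            logger.warning("%s undefined (zero denominator); reported as NaN", what)
            return float("nan")
        return num / den

    return IndicatorSet(
        ACC=ratio(tp + tn, len(t), "ACC"),
        TPR_Ad=ratio(tp, n_ad, "TPR_Ad"),
        PPV_Ad=ratio(tp, tp + fp, "PPV_Ad"),
        TPR_nAd=ratio(tn, n_nad, "TPR_nAd"),
        PPV_nAd=ratio(tn, tn + fn, "PPV_nAd"),
        Ad_ratio=ratio(tp + fp, n_ad, "Ad_ratio"),
        nAd_ratio=ratio(tn + fn, n_nad, "nAd_ratio"),
    )


def sample_dataset(
    table: pd.DataFrame,
    cfg: BootstrapConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw one accepted mouse-resampled dataset.

    Mice are drawn uniformly with replacement; each draw contributes all
    of the mouse's features (a mouse drawn twice contributes them
    twice). Drawing stops at the first point where both the draw count
    and the cumulative feature count meet their minima. The candidate is
    accepted only if both class fractions are at least
    ``min_class_frac``; otherwise it is discarded and redrawn, up to
    ``max_rejections`` times.
    """
    if table.empty:
        raise ValueError("empty feature table")
    groups = {m: g for m, g in table.groupby("mouse_id")}
    mice = np.array(sorted(groups))
    for rejection in range(cfg.max_rejections + 1):
        parts: list[pd.DataFrame] = []
        n_feat = 0
        n_draws = 0
        while n_draws < cfg.min_mice or n_feat < cfg.min_features:
            m = mice[rng.integers(len(mice))]
            g = groups[m]
            parts.append(g)
            n_feat += len(g)
            n_draws += 1
        cand = pd.concat(parts, ignore_index=True)
        ad_frac = (cand["call"] == "Ad").mean()
        if min(ad_frac, 1 - ad_frac) >= cfg.min_class_frac:
            cand.attrs["n_draws"] = n_draws
            return cand
    raise RuntimeError(
        f"no acceptable dataset after {cfg.max_rejections} rejections; "
        "check class balance of the input table"
    )


def summarize_quantiles(indicator_sets: list[IndicatorSet]) -> pd.DataFrame:
    """Order statistics of each indicator at 0/5/25/50/75/95/100 %.

    Linear ("type 7") interpolation. Rows are indicators, columns the
    seven probabilities (as percentages).
    """
    if not indicator_sets:
        raise ValueError("no indicator sets to summarize")
    df = pd.DataFrame([s.as_dict() for s in indicator_sets])
    q = df.quantile(list(QUANTILE_PROBS), interpolation="linear").T
    q.columns = [f"{int(100 * p)}%" for p in QUANTILE_PROBS]
    return q


@dataclass
class BootstrapResult:
    """Everything the validation experiment produces."""

    indicators: list[IndicatorSet]
    quantiles: pd.DataFrame
    reference: IndicatorSet
    reference_model: LdaModel
    n_failed: int = 0


def run_bootstrap(
    X: pd.DataFrame,
    y: pd.Series,
    mouse_ids: pd.Series,
    cfg: BootstrapConfig,
    *,
    seed: int,
    out_of_bag: bool = False,
) -> BootstrapResult:
    """The full validation experiment on a preprocessed design matrix.

    For each of ``cfg.n_datasets`` accepted mouse-resampled datasets, a
    discriminant is trained and scored on that same dataset (in-sample;
    set ``out_of_bag`` to score on the never-drawn mice instead). The
    quantile table summarizes the indicator distributions, and a
    reference fit on the complete matrix gives the full-dataset values.
    Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    table = X.copy()
    table["call"] = np.asarray(y)
    table["mouse_id"] = np.asarray(mouse_ids)
    feat_cols = list(X.columns)

    ref_model = train_lda(X, y)
    ref_calls, _ = predict(ref_model, X)
    reference = compute_indicators(np.asarray(y), ref_calls.to_numpy())

    indicators: list[IndicatorSet] = []
    n_failed = 0
    while len(indicators) < cfg.n_datasets:
        sample = sample_dataset(table, cfg, rng)
        Xs = sample[feat_cols]
        ys = sample["call"]
        try:
            model = train_lda(Xs, ys)
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.warning("dataset skipped: %s", exc)
            continue
        if out_of_bag:
            oob = table[~table["mouse_id"].isin(sample["mouse_id"].unique())]
            if oob.empty or oob["call"].nunique() < 2:
                n_failed += 1
                continue
            calls, _ = predict(model, oob[feat_cols])
            indicators.append(compute_indicators(oob["call"].to_numpy(), calls.to_numpy()))
        else:
            calls, _ = predict(model, Xs)
            indicators.append(compute_indicators(ys.to_numpy(), calls.to_numpy()))
    if n_failed:
        logger.info("%d resampled dataset(s) failed and were skipped", n_failed)
    return BootstrapResult(
        indicators=indicators,
        quantiles=summarize_quantiles(indicators),
        reference=reference,
        reference_model=ref_model,
        n_failed=n_failed,
    )
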