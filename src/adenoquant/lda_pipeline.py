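"""Two-class discriminant training/prediction and mouse-level PCA QC.

The classifier is classical linear discriminant analysis with pooled
within-class covariance: class k scores
``log pi_k - (x - mu_k)' S^-1 (x - mu_k) / 2`` and posteriors follow by
softmax. With the squared columns appended by preprocessing the linear
boundary in the augmented space is a quadratic (conic) boundary in the
original measure space. Priors default to the empirical class
frequencies. A near-singular pooled covariance is ridge-regularized
(lambda = 1e-6 * trace(S)/p) with a warning.

Because image features are nested within mice, a poor gut preparation
can bias every feature of one mouse and leak into training. The QC step
runs a correlation (unit-variance) PCA of the design matrix, computes
each mouse's barycentre on the first two components, and flags mice
whose barycentre lies far outside the central cluster, judged by a
robust (minimum covariance determinant) Mahalanobis distance against a
simulation-calibrated family-wise cutoff.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.covariance import MinCovDet

logger = logging.getLogger(__name__)

CLASSES = ("Ad", "nAd")


@dataclass
class LdaModel:
    """Fitted two-class linear discriminant.

    Holds the class means, the (regularized) pooled within-class
    covariance and its inverse, the class priors, and the column
    registry that predictions are validated against.
    """

    columns: list[str]
    classes: tuple[str, str]
    means: np.ndarray          # (2, p)
    pooled_cov: np.ndarray     # (p, p)
    priors: np.ndarray         # (2,)
    _cov_inv: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.pooled_cov)


def train_lda(
    X: pd.DataFrame,
    y: pd.Series,
    *,
    priors: np.ndarray | None = None,
) -> LdaModel:
    """Fit the discriminant on a complete design matrix.

    Requires at least two features per class and no missing values.
    Priors default to empirical class frequencies. Deterministic and
    permutation-invariant in the rows.
    """
    if X.isna().any().any():
        raise ValueError("design matrix has missing values")
    y = np.asarray(y)
    present = set(np.unique(y))
    if present != set(CLASSES):
        raise ValueError(f"need both classes {CLASSES}, got {sorted(present)}")
    Xv = X.to_numpy(dtype=float)
    p = Xv.shape[1]
    means = np.empty((2, p))
    scatter = np.zeros((p, p))
    counts = np.empty(2)
    for k, cls in enumerate(CLASSES):
        xk = Xv[y == cls]
        if len(xk) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 features")
        counts[k] = len(xk)
        means[k] = xk.mean(axis=0)
        d = xk - means[k]
        scatter += d.T @ d
    pooled = scatter / (counts.sum() - 2)
    if priors is None:
        priors = counts / counts.sum()
    # Regularize when singular or near-singular. The ridge is scaled per
    # column (1e-6 of each variance) so that low-variance columns are not
    # drowned by high-variance ones; measured tables are always in this
    # branch because IntDen and RawIntDen are exactly proportional.
    needs_ridge = False
    try:
        np.linalg.cholesky(pooled)
        if np.linalg.cond(pooled) > 1e12:
            needs_ridge = True
    except np.linalg.LinAlgError:
        needs_ridge = True
    if needs_ridge:
        lam = 1e-6 * np.maximum(np.diag(pooled), 1e-30)
        logger.warning("near-singular pooled covariance; adding scaled ridge")
        pooled = pooled + np.diag(lam)
    return LdaModel(
        columns=list(X.columns),
        classes=CLASSES,
        means=means,
        pooled_cov=pooled,
        priors=np.asarray(priors, dtype=float),
    )


def predict(model: LdaModel, X: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Predicted calls and posterior probabilities for a design matrix.

    Columns must match the model registry exactly (names and order).
    A feature is called Ad when its Ad posterior exceeds 0.5; an exact
    tie breaks toward nAd. Posteriors sum to 1 per row.
    """
    if list(X.columns) != model.columns:
        missing = sorted(set(model.columns) - set(X.columns))
        extra = sorted(set(X.columns) - set(model.columns))
        raise ValueError(f"column registry mismatch: missing={missing} extra={extra}")
    Xv = X.to_numpy(dtype=float)
    log_scores = np.empty((len(Xv), 2))
    for k in range(2):
        d = Xv - model.means[k]
        maha = np.einsum("ij,jk,ik->i", d, model._cov_inv, d)
        log_scores[:, k] = np.log(model.priors[k]) - 0.5 * maha
    log_scores -= log_scores.max(axis=1, keepdims=True)
    post = np.exp(log_scores)
    post /= post.sum(axis=1, keepdims=True)
    posteriors = pd.DataFrame(post, columns=list(model.classes), index=X.index)
    calls = pd.Series(
        np.where(posteriors["Ad"] > 0.5, "Ad", "nAd"), index=X.index, name="predicted_call"
    )
    return calls, posteriors


@dataclass
class QcReport:
    """Per-mouse PCA barycentres, robust distances and pass/fail flags."""

    barycentres: pd.DataFrame      # index mouse_id, columns PC1, PC2, distance2, flagged
    cutoff: float
    family_alpha: float
    explained_variance_ratio: tuple[float, float]

    @property
    def flagged(self) -> list[str]:
        return sorted(self.barycentres.index[self.barycentres["flagged"]])


def _rescaled_mcd_distances(points: np.ndarray) -> np.ndarray:
    """Robust squared Mahalanobis distances, median-matched to chi²(2).

    Raw minimum-covariance-determinant distances are inflated; rescaling
    so their median equals the chi²(2) median is the usual consistency
    correction.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mcd = MinCovDet(random_state=0).fit(points)
    d2 = mcd.mahalanobis(points)
    return d2 * chi2.ppf(0.5, df=2) / np.median(d2)


@lru_cache(maxsize=32)
def _null_max_cutoff(n_mice: int, family_alpha: float, n_sim: int = 200) -> float:
    """Family-wise cutoff for the largest robust distance among n mice.

    Simulates standard-normal barycentre clouds of the same size, runs
    the identical robust-distance pipeline and returns the
    (1 - family_alpha) quantile of the per-cloud maximum distance. MCD
    distances are affine-invariant, so a standard-normal null
    calibrates any Gaussian barycentre cloud.
    """
    rng = np.random.default_rng(987654321)
    maxima = np.empty(n_sim)
    for i in range(n_sim):
        d2 = _rescaled_mcd_distances(rng.standard_normal((n_mice, 2)))
        maxima[i] = d2.max()
    return float(np.quantile(maxima, 1.0 - family_alpha))


def pca_qc(
    X: pd.DataFrame,
    mouse_ids: pd.Series,
    *,
    family_alpha: float = 0.05,
) -> QcReport:
    """Mouse-level batch-bias QC on the first two principal components.

    Columns are centred and scaled to unit variance (correlation PCA);
    each mouse's barycentre is the mean of its features' PC1-PC2 scores.
    Because a barycentre of n features has sampling variance
    proportional to 1/n, barycentres are scaled by sqrt(n) before
    outlier scoring (otherwise low-count mice dominate the false
    flags). A mouse is flagged when its scaled barycentre's robust
    (minimum covariance determinant) squared Mahalanobis distance
    exceeds a simulation-calibrated family-wise cutoff: the
    (1 - family_alpha) quantile of the largest distance a same-sized,
    bias-free cohort would produce. Whether any mouse is flagged is a
    question asked across the whole cohort at once, so the cutoff
    controls the probability of flagging anything in an unbiased
    cohort, not a per-mouse rate. Needs at least 3 mice.
    """
    mouse_ids = pd.Series(np.asarray(mouse_ids), index=X.index)
    if mouse_ids.nunique() < 3:
        raise ValueError("pca_qc needs at least 3 mice")
    if X.isna().any().any():
        raise ValueError("design matrix has missing values")
    Xv = X.to_numpy(dtype=float)
    Xv = Xv - Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0  # constant columns carry no information
    Xv = Xv / sd
    # PCA via SVD of the standardized matrix
    _, svals, vt = np.linalg.svd(Xv, full_matrices=False)
    scores = Xv @ vt[:2].T
    var = svals**2 / (len(Xv) - 1)
    evr = (float(var[0] / var.sum()), float(var[1] / var.sum()))
    grouped = pd.DataFrame(scores, columns=["PC1", "PC2"], index=X.index).groupby(
        mouse_ids.rename("mouse_id")
    )
    bary = grouped.mean()
    n_feat = grouped.size()
    scaled = bary.mul(np.sqrt(n_feat), axis=0)
    d2 = _rescaled_mcd_distances(scaled.to_numpy())
    cutoff = _null_max_cutoff(len(bary), family_alpha)
    bary["distance2"] = d2
    bary["flagged"] = d2 > cutoff
    return QcReport(
        barycentres=bary,
        cutoff=cutoff,
        family_alpha=family_alpha,
        explained_variance_ratio=evr,
    )
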