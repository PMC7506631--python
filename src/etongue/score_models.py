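"""PCA and canonical variate analysis of feature blocks, with score-plot
confidence ellipses.

Both projections operate on the compressed feature matrix.  Columns are
mean-centered but not autoscaled: DWT approximation coefficients share a
unit (µA-scaled), and autoscaling would inflate near-zero coefficients.
PCA component signs are fixed deterministically (the largest-magnitude
loading element of each component is made positive) so scores are
reproducible across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy import stats

from .compression import FeatureBlockMatrix
from .core_data import ValidationError

__all__ = ["ScoreModel", "ClusterEllipse", "fit_pca", "fit_cva", "cluster_ellipse"]


@dataclass
class ScoreModel:
    """Fitted linear score projection (PCA or CVA).

    ``loadings`` is features × components; ``scores`` is samples ×
    components; ``explained_variance_fraction`` is per retained component
    (for CVA, the fraction of the discriminant eigenvalue sum).
    """

    method: str
    center: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    scores: np.ndarray
    class_labels: list[str] | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) @ self.loadings


@dataclass(frozen=True)
class ClusterEllipse:
    """Confidence ellipse of one class's 2-D score cloud."""

    class_label: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle_rad: float
    confidence: float

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside (or on) the ellipse boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - np.asarray(self.center)
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, s], [-s, c]])
        local = pts @ rot.T
        a, b = self.semi_axes
        return (local[:, 0] / a) ** 2 + (local[:, 1] / b) ** 2 <= 1.0 + 1e-12


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-|loading| element is positive."""
    loadings = loadings.copy()
    scores = scores.copy()
    for i in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, i])))
        if loadings[j, i] < 0:
            loadings[:, i] *= -1.0
            scores[:, i] *= -1.0
    return loadings, scores


def fit_pca(fb: FeatureBlockMatrix, n_components: int = 2) -> ScoreModel:
    """Column-mean-centered PCA of the feature matrix via SVD."""
    X = fb.values
    n, p = X.shape
    if n < 2:
        raise ValidationError("PCA needs at least 2 samples")
    if not 1 <= n_components <= min(n - 1, p):
        raise ValidationError(
            f"n_components must be in [1, {min(n - 1, p)}], got {n_components}"
        )
    center = X.mean(axis=0)
    Xc = X - center
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(S**2))
    if total == 0.0:
        raise ValidationError("zero total variance: all samples identical")
    loadings = Vt[:n_components].T
    scores = Xc @ loadings
    loadings, scores = _fix_signs(loadings, scores)
    evr = (S[:n_components] ** 2) / total
    return ScoreModel(
        method="pca",
        center=center,
        loadings=loadings,
        explained_variance_fraction=evr,
        scores=scores,
        class_labels=list(fb.class_labels),
    )


def fit_cva(
    fb: FeatureBlockMatrix,
    class_labels=None,
    n_components: int | None = None,
    pre_variance: float = 0.99,
) -> ScoreModel:
    """Canonical variate analysis (between/within scatter maximization).

    To handle the rank deficiency of wide chemometric matrices, the data
    are first projected onto the leading PCA components (up to
    ``pre_variance`` cumulative variance, capped at ``n_samples -
    n_classes``), then the generalized symmetric eigenproblem
    ``S_b w = λ S_w w`` is solved in that subspace.  At most ``k - 1``
    canonical variates exist for ``k`` classes.
    """
    labels = list(class_labels) if class_labels is not None else list(fb.class_labels)
    X = fb.values
    n = X.shape[0]
    if len(labels) != n:
        raise ValidationError("one class label per sample required")
    classes = list(dict.fromkeys(labels))
    k = len(classes)
    if k < 2:
        raise ValidationError(f"CVA needs >= 2 classes, got {k}")
    counts = {c: labels.count(c) for c in classes}
    for c, cnt in counts.items():
        if cnt < 2:
            raise ValidationError(f"class {c!r} has {cnt} sample(s); needs >= 2")

    center = X.mean(axis=0)
    Xc = X - center
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = S**2
    if float(var.sum()) == 0.0:
        raise ValidationError("zero total variance: all samples identical")
    cum = np.cumsum(var) / var.sum()
    m99 = int(np.searchsorted(cum, pre_variance) + 1)
    nonzero = int(np.sum(S > S[0] * 1e-12))
    m = max(1, min(m99, n - k, nonzero))
    P = Vt[:m].T  # features x m pre-projection
    T = Xc @ P

    y = np.array(labels)
    Sw = np.zeros((m, m))
    Sb = np.zeros((m, m))
    gm = T.mean(axis=0)
    for c in classes:
        Tc = T[y == c]
        mc = Tc.mean(axis=0)
        d = Tc - mc
        Sw += d.T @ d
        Sb += len(Tc) * np.outer(mc - gm, mc - gm)
    # regularize only against exact numerical singularity
    Sw += np.eye(m) * (np.trace(Sw) / m * 1e-10 if np.trace(Sw) > 0 else 1e-12)

    evals, evecs = scipy.linalg.eigh(Sb, Sw)
    order = np.argsort(evals)[::-1]
    max_comp = min(k - 1, m)
    if n_components is None:
        n_components = min(2, max_comp)
    if not 1 <= n_components <= max_comp:
        raise ValidationError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    W = evecs[:, order[:n_components]]
    lam = np.clip(evals[order[:n_components]], 0.0, None)
    loadings = P @ W
    scores = Xc @ loadings
    loadings, scores = _fix_signs(loadings, scores)
    total = float(np.clip(evals, 0.0, None).sum())
    evr = lam / total if total > 0 else np.zeros_like(lam)
    return ScoreModel(
        method="cva",
        center=center,
        loadings=loadings,
        explained_variance_fraction=evr,
        scores=scores,
        class_labels=labels,
    )


def cluster_ellipse(
    scores2d: np.ndarray,
    labels,
    class_label: str,
    confidence: float = 0.95,
) -> ClusterEllipse:
    """Confidence ellipse of one class in a 2-D score plot.

    The boundary is the Mahalanobis contour of the class's 2×2 score
    covariance at the chi-square(2 df) quantile of ``confidence`` — the
    population form customarily drawn on electronic-tongue score plots.
    """
    if not 0 < confidence < 1:
        raise ValidationError(f"confidence must be in (0, 1), got {confidence}")
    scores2d = np.asarray(scores2d, dtype=float)
    if scores2d.ndim != 2 or scores2d.shape[1] != 2:
        raise ValidationError("scores2d must be n x 2")
    mask = np.array([l == class_label for l in labels])
    pts = scores2d[mask]
    if pts.shape[0] < 3:
        raise ValidationError(
            f"class {class_label!r} has {pts.shape[0]} samples; needs >= 3"
        )
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if not np.all(np.isfinite(evals)) or evals.min() <= 0:
        raise ValidationError(f"singular score covariance for class {class_label!r}")
    q = stats.chi2.ppf(confidence, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    semi = np.sqrt(evals * q)
    angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return ClusterEllipse(
        class_label=class_label,
        center=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
        semi_axes=(float(semi[0]), float(semi[1])),
        angle_rad=angle,
        confidence=confidence,
    )
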