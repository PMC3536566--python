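"""Study-level diagnostics: Fisher's linear discriminant on vectorized
trees, empirical ROC curves with conservative lower-staircase
interpolation, and false-positive-rate curves.

The ROC treats a battery of GeneOut runs as a binary classifier with the
alpha-level as its boundary: a run on data from two different generating
processes should reject (true positive), a run on data from one process
should not (false positive).  Connecting empirical (FPR, TPR) points by the
lower staircase — horizontal then vertical — gives the most conservative
curve through the points, so the reported AUC never exceeds the trapezoidal
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

from .separation import as_point_cloud

__all__ = [
    "RocCurve",
    "fld",
    "empirical_roc",
    "auc_lower_staircase",
    "trapezoid_auc",
    "false_positive_curve",
]


@dataclass(frozen=True)
class RocCurve:
    """Empirical (FPR, TPR) points, anchored at (0,0) and (1,1), ordered by
    the alpha grid that generated them."""

    fpr: np.ndarray
    tpr: np.ndarray
    alphas: np.ndarray

    def __post_init__(self) -> None:
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        if fpr.shape != tpr.shape:
            raise ValueError("fpr and tpr must have equal length")
        if np.any(np.diff(fpr) < 0) or np.any(np.diff(tpr) < 0):
            raise ValueError("ROC points must be non-decreasing in both coordinates")

    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def to_tsv(self, path) -> None:
        """Write the curve as alpha/FPR/TPR columns (figures are a thin
        layer over this export)."""
        with open(path, "w") as fh:
            fh.write("alpha\tfpr\ttpr\n")
            for al, f, t in zip(self.alphas, self.fpr, self.tpr):
                fh.write(f"{al:.10g}\t{f:.10g}\t{t:.10g}\n")


def fld(x1, x2, pca_components: int = 2, ridge: float = 1e-8) -> float:
    """Fisher's linear discriminant separation of two point clouds.

    The pooled cloud is first reduced to ``pca_components`` principal
    components; the returned value is the maximum over directions w of
    ``(w . (mu1 - mu2))^2 / (w' (S1 + S2) w)`` with S the within-class
    covariance, i.e. ``(mu1-mu2)' (S1+S2)^{-1} (mu1-mu2)``.  A value of 1
    marks between-class separation equal to the within-class spread.
    """
    a = as_point_cloud(x1)
    b = as_point_cloud(x2)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each cloud needs at least 2 points")
    if a.shape[1] != b.shape[1]:
        raise ValueError("clouds must share one dimension")
    ncomp = min(pca_components, a.shape[1])
    if a.shape[1] > ncomp:
        pca = PCA(n_components=ncomp)
        pooled = np.vstack([a, b])
        pca.fit(pooled)
        a = pca.transform(a)
        b = pca.transform(b)
    mu = np.mean(a, axis=0) - np.mean(b, axis=0)
    s = np.cov(a, rowvar=False, ddof=1) + np.cov(b, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    try:
        sol = np.linalg.solve(s, mu)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("singular within-class scatter; applying ridge regularization")
        s = s + np.eye(s.shape[0]) * (ridge * np.trace(s) / s.shape[0] + ridge)
        sol = np.linalg.solve(s, mu)
    return float(mu @ sol)


def _check_pvalues(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError(f"{name} is empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{name} contains values outside [0, 1]")
    return p


def empirical_roc(p_alt: Sequence[float], p_null: Sequence[float]) -> RocCurve:
    """ROC curve of the test viewed as a classifier with boundary alpha.

    For each alpha in the union of the observed p-values and {0, 1}:
    TPR(alpha) = fraction of ``p_alt`` <= alpha (runs on genuinely different
    distributions that reject), FPR(alpha) = fraction of ``p_null`` <= alpha.
    The curve is anchored at (0, 0) and (1, 1).
    """
    pa = _check_pvalues(p_alt, "p_alt")
    pn = _check_pvalues(p_null, "p_null")
    alphas = np.unique(np.concatenate([pa, pn, [0.0, 1.0]]))
    tpr = np.array([(pa <= al).mean() for al in alphas])
    fpr = np.array([(pn <= al).mean() for al in alphas])
    # prepend the (0, 0) anchor (alpha just below any attained p-value)
    fpr = np.concatenate([[0.0], fpr])
    tpr = np.concatenate([[0.0], tpr])
    alphas = np.concatenate([[np.nan], alphas])
    return RocCurve(fpr, tpr, alphas)


def auc_lower_staircase(curve: RocCurve) -> float:
    """Area under the lower-staircase interpolation of the ROC points.

    Between consecutive points (a, b) and (c, d) the staircase runs
    horizontally to (c, b) and then vertically to (c, d), which never
    overestimates the area; the diagonal two-point curve {(0,0), (1,1)}
    therefore scores 0.
    """
    fpr, tpr = curve.fpr, curve.tpr
    return float(np.sum(np.diff(fpr) * tpr[:-1]))


def trapezoid_auc(curve: RocCurve) -> float:
    return float(np.trapezoid(curve.tpr, curve.fpr))


def false_positive_curve(
    p_null: Sequence[float], alphas: Sequence[float] | None = None
) -> np.ndarray:
    """Empirical rejection rate under the null at each alpha-level.

    Returns an ``(len(alphas), 2)`` array of (alpha, rejection rate); a test
    that controls false positives stays at or below the diagonal.  By
    default the alpha grid is the set of distinct observed p-values plus
    {0, 1}.
    """
    pn = _check_pvalues(p_null, "p_null")
    if alphas is None:
        grid = np.unique(np.concatenate([pn, [0.0, 1.0]]))
    else:
        grid = np.asarray(alphas, dtype=float)
    rates = np.array([(pn <= al).mean() for al in grid])
    return np.column_stack([grid, rates])
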