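"""SVM separation percentage between two clouds of vectorized trees.

A soft-margin linear SVM is trained on labeled tree vectors; the separation
percentage ``delta`` of a held-out sample is, under the class-average
convention, half the fraction of the positive cloud in the positive
half-space plus half the fraction of the negative cloud in the negative
half-space.  The pooled convention instead divides total correct points by
the total count; both coincide for equally sized test clouds.  ``delta``
alone says nothing about incongruence — it becomes a test statistic only
against the permutation null (see :mod:`geneout.core`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.svm import SVC

from .treespace import TaxonOrder, TreeVector, vectorize_trees

__all__ = [
    "LinearSeparator",
    "SeparationResult",
    "train_separator",
    "separation_percentage",
    "sampled_separation",
    "as_point_cloud",
]

CONVENTIONS = ("class-average", "pooled")


def as_point_cloud(points) -> np.ndarray:
    """Coerce a list of TreeVectors or an array-like into a 2-D float array."""
    if isinstance(points, np.ndarray) and points.ndim == 2:
        return points.astype(float, copy=False)
    if len(points) and isinstance(points[0], TreeVector):
        return np.stack([p.values for p in points]).astype(float)
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    return arr


@dataclass(frozen=True)
class LinearSeparator:
    """Hyperplane ``w . x + b = 0``; the positive half-space is
    ``H+ = {x : w . x + b >= 0}`` (boundary points count as ``H+``)."""

    weights: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        object.__setattr__(self, "weights", w)

    def decision(self, points) -> np.ndarray:
        x = as_point_cloud(points)
        if x.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"points have dimension {x.shape[1]}, separator expects "
                f"{self.weights.shape[0]}"
            )
        return x @ self.weights + self.offset

    def in_positive_halfspace(self, points) -> np.ndarray:
        return self.decision(points) >= 0.0

    def to_array(self) -> np.ndarray:
        return np.append(self.weights, self.offset)

    @classmethod
    def from_array(cls, arr) -> "LinearSeparator":
        arr = np.asarray(arr, dtype=float)
        return cls(arr[:-1], float(arr[-1]))

    def save(self, path) -> None:
        """Weights then offset, one value per line."""
        np.savetxt(path, self.to_array(), header="weights...; last row is the offset")

    @classmethod
    def load(cls, path) -> "LinearSeparator":
        return cls.from_array(np.loadtxt(path))


@dataclass(frozen=True)
class SeparationResult:
    """A separation percentage plus the per-class counts that produced it."""

    delta: float
    convention: str
    correct_pos: int
    total_pos: int
    correct_neg: int
    total_neg: int


def train_separator(train_pos, train_neg, c: float = 1.0) -> LinearSeparator:
    """Fit a linear-kernel soft-margin SVM; ``train_pos`` is the + class.

    ``c`` is the usual SVM cost parameter balancing margin width against
    training errors.
    """
    xp = as_point_cloud(train_pos)
    xn = as_point_cloud(train_neg)
    if xp.shape[0] == 0 or xn.shape[0] == 0:
        raise ValueError("both training clouds must be non-empty")
    if xp.shape[1] != xn.shape[1]:
        raise ValueError(
            f"dimension mismatch: {xp.shape[1]} (positive) vs {xn.shape[1]} (negative)"
        )
    X = np.vstack([xp, xn])
    y = np.concatenate([np.ones(xp.shape[0]), np.zeros(xn.shape[0])])
    # one pooled scalar rescale (no per-feature standardization) so the cost
    # parameter refers to unit data scale regardless of branch-length units;
    # the fitted hyperplane is mapped back to original coordinates
    scale = float(np.mean(np.abs(X)))
    if not np.isfinite(scale) or scale <= 0.0:
        scale = 1.0
    svc = SVC(kernel="linear", C=c)
    svc.fit(X / scale, y)
    # classes_ == [0, 1]; decision_function > 0 predicts class 1 (= train_pos)
    return LinearSeparator(svc.coef_[0] / scale, float(svc.intercept_[0]))


def separation_percentage(
    sep: LinearSeparator,
    test_pos,
    test_neg,
    convention: str = "class-average",
) -> SeparationResult:
    """Score the separation of held-out clouds against a fixed hyperplane.

    class-average: ``delta = (correct+/total+ + correct-/total-) / 2``;
    pooled: ``delta = (correct+ + correct-) / (total+ + total-)``.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"convention must be one of {CONVENTIONS}")
    xp = as_point_cloud(test_pos)
    xn = as_point_cloud(test_neg)
    if xp.shape[0] == 0 or xn.shape[0] == 0:
        raise ValueError("both test clouds must be non-empty")
    cp = int(np.count_nonzero(sep.in_positive_halfspace(xp)))
    cn = int(np.count_nonzero(~sep.in_positive_halfspace(xn)))
    tp, tn = xp.shape[0], xn.shape[0]
    if convention == "class-average":
        delta = 0.5 * (cp / tp) + 0.5 * (cn / tn)
    else:
        delta = (cp + cn) / (tp + tn)
    return SeparationResult(float(delta), convention, cp, tp, cn, tn)


def _draw_train_test(
    n_pool: int, M: int, N: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint without-replacement train/test index draws when the pool
    allows, else independent with-replacement draws (with a warning)."""
    if n_pool >= M + N:
        perm = rng.permutation(n_pool)
        return perm[:M], perm[M : M + N]
    warnings.warn(
        f"pool of {n_pool} trees is smaller than M+N={M + N}; "
        "sampling with replacement",
        stacklevel=3,
    )
    return rng.integers(0, n_pool, M), rng.integers(0, n_pool, N)


def separation_from_pools(
    pool_pos: np.ndarray,
    pool_neg: np.ndarray,
    M: int,
    N: int,
    rng: np.random.Generator,
    c: float = 1.0,
    convention: str = "class-average",
) -> float:
    """One train/test resample from two vector pools: draw M training and N
    testing vectors per class, train, and score."""
    tr_p, te_p = _draw_train_test(pool_pos.shape[0], M, N, rng)
    tr_n, te_n = _draw_train_test(pool_neg.shape[0], M, N, rng)
    sep = train_separator(pool_pos[tr_p], pool_neg[tr_n], c=c)
    return separation_percentage(sep, pool_pos[te_p], pool_neg[te_n], convention).delta


def sampled_separation(
    pool_pos,
    pool_neg,
    M: int,
    N: int,
    repeats: int,
    map_kind: str = "topological",
    rng: np.random.Generator | None = None,
    order: TaxonOrder | None = None,
    c: float = 1.0,
    convention: str = "class-average",
) -> float:
    """Mean separation percentage over repeated train/test resampling.

    ``pool_pos`` / ``pool_neg`` may be lists of trees (vectorized once with
    ``map_kind``) or ready-made vector arrays.  Each repeat draws fresh
    disjoint train (M per set) and test (N per set) samples, trains an SVM,
    scores the held-out sample, and the mean delta over ``repeats`` is
    returned.
    """
    if rng is None:
        rng = np.random.default_rng()
    if repeats < 1:
        raise ValueError("repeats must be >= 1")

    def prepare(pool) -> np.ndarray:
        if isinstance(pool, np.ndarray):
            return pool
        if len(pool) == 0:
            raise ValueError("empty tree pool")
        if isinstance(pool[0], TreeVector):
            return as_point_cloud(pool)
        ordr = order if order is not None else TaxonOrder.from_tree(pool[0])
        return vectorize_trees(pool, ordr, map_kind)

    xp = prepare(pool_pos)
    xn = prepare(pool_neg)
    deltas = [
        separation_from_pools(xp, xn, M, N, rng, c=c, convention=convention)
        for _ in range(repeats)
    ]
    return float(np.mean(deltas))
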