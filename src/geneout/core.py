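"""The GeneOut two-sample test.

Null hypothesis: the two input collections (gene trees, or gene trees
underlying two sets of alignments) are drawn from the same distribution.
The test statistic is the SVM separation percentage between the two
vectorized samples; its null distribution is approximated either by
resampling trees from a designated null pool (direct-tree mode) or by
permuting alignment set-membership labels and column-bootstrapping each
alignment (alignment mode), re-running the train/test sub-process each
time.

P-value direction: the standard permutation convention
``p = #{delta* >= delta0} / k`` is the default — strong observed separation
relative to the null yields a small p-value, matching the reported usage of
the test.  The literal pseudo-code rule ``#{delta* <= delta0} / k`` is kept
behind ``pvalue_mode="literal"``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import dendropy
import numpy as np

from .reconstruct import Alignment, NJVectorFactory, bootstrap_columns, reconstruct_trees
from .separation import (
    separation_from_pools,
    separation_percentage,
    train_separator,
)
from .treespace import TaxonOrder, leaf_labels, vectorize_trees

__all__ = [
    "GeneOutConfig",
    "GeneOutResult",
    "AlignmentSet",
    "geneout_trees",
    "geneout_alignments",
    "permute_and_bootstrap",
    "pvalue_from_null",
]

_MAP_KINDS = ("branch-length", "topological")


@dataclass(frozen=True)
class GeneOutConfig:
    """Parameters of one GeneOut run.

    M and N are the per-set training and testing sample sizes of the SVM
    sub-process; k the number of null replicates; obs_repeats the number of
    train/test resamples averaged into the observed statistic (1 reproduces
    the plain algorithm; the direct-tree replication protocol uses 100).
    """

    M: int = 168
    N: int = 336
    k: int = 100
    obs_repeats: int = 1
    map_kind: str = "topological"
    method: str = "nj-f84"
    c: float = 1.0
    convention: str = "class-average"
    pvalue_mode: str = "standard"
    null_source: str = "second-set"
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("M", "N", "k", "obs_repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.map_kind not in _MAP_KINDS:
            raise ValueError(f"map_kind must be one of {_MAP_KINDS}")
        if self.pvalue_mode not in ("standard", "literal"):
            raise ValueError("pvalue_mode must be 'standard' or 'literal'")
        if self.null_source not in ("second-set", "pooled"):
            raise ValueError("null_source must be 'second-set' or 'pooled'")


@dataclass(frozen=True)
class GeneOutResult:
    """Observed statistic, null draws, and the permutation p-value."""

    delta0: float
    null_deltas: np.ndarray
    count: int
    pvalue: float
    config: GeneOutConfig
    seed_log: dict

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "null_deltas", np.asarray(self.null_deltas, dtype=float)
        )

    def to_dict(self) -> dict:
        return {
            "delta0": self.delta0,
            "null_deltas": list(map(float, self.null_deltas)),
            "count": self.count,
            "pvalue": self.pvalue,
            "config": asdict(self.config),
            "seed_log": self.seed_log,
        }


@dataclass(frozen=True)
class AlignmentSet:
    """An ordered, named collection of alignments (set A or B of a test)."""

    alignments: tuple[Alignment, ...]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "alignments", tuple(self.alignments))
        if not self.alignments:
            raise ValueError("alignment set is empty")

    def __len__(self) -> int:
        return len(self.alignments)

    def __iter__(self):
        return iter(self.alignments)

    @property
    def taxa(self) -> set[str]:
        return set(self.alignments[0].taxa)


def pvalue_from_null(
    delta0: float, null_deltas: Sequence[float], mode: str = "standard"
) -> float:
    """Permutation p-value from the observed statistic and k null draws.

    standard: ``#{delta* >= delta0} / k`` (ties count toward the null);
    literal: ``#{delta* <= delta0} / k``.
    """
    null = np.asarray(null_deltas, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if mode == "standard":
        return float(np.count_nonzero(null >= delta0)) / null.size
    if mode == "literal":
        return float(np.count_nonzero(null <= delta0)) / null.size
    raise ValueError("mode must be 'standard' or 'literal'")


def _resolve_seed(cfg: GeneOutConfig, rng: np.random.Generator | None) -> int:
    if cfg.seed is not None:
        return int(cfg.seed)
    if rng is not None:
        return int(rng.integers(2**31))
    return int(np.random.default_rng().integers(2**31))


def _child_rngs(master_seed: int, k: int) -> list[np.random.Generator]:
    """One stream for the observed statistic plus one per null replicate, so
    changing k never perturbs earlier replicates."""
    children = np.random.SeedSequence(master_seed).spawn(k + 1)
    return [np.random.default_rng(s) for s in children]


def _shared_order(taxa_sets: list[set[str]], context: str) -> TaxonOrder:
    first = taxa_sets[0]
    for i, s in enumerate(taxa_sets[1:], start=1):
        if s != first:
            raise ValueError(
                f"{context} must share one taxon set; item {i} has "
                f"{sorted(s ^ first)} differing"
            )
    return TaxonOrder.from_labels(first)


# ---------------------------------------------------------------------------
# direct-tree mode

def geneout_trees(
    t1: Sequence[dendropy.Tree],
    t2: Sequence[dendropy.Tree],
    cfg: GeneOutConfig | None = None,
    rng: np.random.Generator | None = None,
) -> GeneOutResult:
    """GeneOut applied directly to two sets of (true or pre-inferred) trees.

    The observed statistic averages ``cfg.obs_repeats`` train/test resamples
    drawn from (t1, t2); each of the k null replicates trains and tests on
    samples drawn entirely from the null pool (by default the second set).
    """
    if cfg is None:
        cfg = GeneOutConfig()
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both tree sets must be non-empty")
    order = _shared_order(
        [set(leaf_labels(t1[0])), set(leaf_labels(t2[0]))], "tree sets"
    )
    x1 = vectorize_trees(t1, order, cfg.map_kind)
    x2 = vectorize_trees(t2, order, cfg.map_kind)

    seed = _resolve_seed(cfg, rng)
    rngs = _child_rngs(seed, cfg.k)

    obs = [
        separation_from_pools(
            x1, x2, cfg.M, cfg.N, rngs[0], c=cfg.c, convention=cfg.convention
        )
        for _ in range(cfg.obs_repeats)
    ]
    delta0 = float(np.mean(obs))

    null_pool = x2 if cfg.null_source == "second-set" else np.vstack([x1, x2])
    null_deltas = np.empty(cfg.k)
    need = 2 * (cfg.M + cfg.N)
    for i in range(cfg.k):
        r = rngs[i + 1]
        npool = null_pool.shape[0]
        if npool >= need:
            idx = r.permutation(npool)[:need]
        else:
            warnings.warn(
                f"null pool of {npool} trees < {need}; sampling with replacement",
                stacklevel=2,
            )
            idx = r.integers(0, npool, need)
        a, b = np.split(idx, 2)
        sep = train_separator(null_pool[a[: cfg.M]], null_pool[b[: cfg.M]], c=cfg.c)
        null_deltas[i] = separation_percentage(
            sep,
            null_pool[a[cfg.M : cfg.M + cfg.N]],
            null_pool[b[cfg.M : cfg.M + cfg.N]],
            cfg.convention,
        ).delta

    pvalue = pvalue_from_null(delta0, null_deltas, cfg.pvalue_mode)
    count = round(pvalue * cfg.k)
    return GeneOutResult(
        delta0, null_deltas, count, pvalue, cfg, {"master": seed, "streams": cfg.k + 1}
    )


# ---------------------------------------------------------------------------
# alignment mode

def permute_and_bootstrap(
    a: AlignmentSet | Sequence[Alignment],
    b: AlignmentSet | Sequence[Alignment],
    rng: np.random.Generator,
) -> tuple[list[Alignment], list[Alignment]]:
    """One permutation-null replicate of the input alignment sets.

    The pooled alignments are reassigned uniformly at random to pseudo-sets
    of the original sizes, then every pseudo-set member is replaced by a
    column-bootstrap replicate of itself (same length).  The originals are
    untouched.
    """
    la, lb = list(a), list(b)
    if len(la) + len(lb) < 2:
        raise ValueError("need at least two alignments to permute")
    pooled = la + lb
    perm = rng.permutation(len(pooled))
    pseudo_a = [bootstrap_columns(pooled[i], rng) for i in perm[: len(la)]]
    pseudo_b = [bootstrap_columns(pooled[i], rng) for i in perm[len(la) :]]
    return pseudo_a, pseudo_b


def _nj_pools(
    alignments: Sequence[Alignment],
    m_per: int,
    n_per: int,
    model: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Training and testing vector pools for one alignment set: per
    alignment, ``m_per`` bootstrap-NJ trees for training and ``n_per`` for
    testing.  Returns (train_plen, train_ecnt, test_plen, test_ecnt)."""
    tr_p, tr_e, te_p, te_e = [], [], [], []
    for aln in alignments:
        fac = NJVectorFactory(aln, model=model)
        plen, ecnt = fac.replicate_vectors(m_per + n_per, rng)
        tr_p.append(plen[:m_per])
        tr_e.append(ecnt[:m_per])
        te_p.append(plen[m_per:])
        te_e.append(ecnt[m_per:])
    return (np.vstack(tr_p), np.vstack(tr_e), np.vstack(te_p), np.vstack(te_e))


def _external_pools(
    alignments: Sequence[Alignment],
    m_per: int,
    n_per: int,
    cfg: GeneOutConfig,
    order: TaxonOrder,
    rng: np.random.Generator,
    external_cmd: str,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    tr_p, tr_e, te_p, te_e = [], [], [], []
    for aln in alignments:
        trees = reconstruct_trees(
            aln, m_per + n_per, cfg.method, rng, external_cmd=external_cmd
        )
        plen = vectorize_trees(trees, order, "branch-length")
        ecnt = vectorize_trees(trees, order, "topological")
        tr_p.append(plen[:m_per])
        tr_e.append(ecnt[:m_per])
        te_p.append(plen[m_per:])
        te_e.append(ecnt[m_per:])
    return (np.vstack(tr_p), np.vstack(tr_e), np.vstack(te_p), np.vstack(te_e))


def _pick(map_kind: str, pools) -> tuple[np.ndarray, np.ndarray]:
    tr_p, tr_e, te_p, te_e = pools
    return (tr_p, te_p) if map_kind == "branch-length" else (tr_e, te_e)


def _delta_from_pools(
    pools_a, pools_b, cfg: GeneOutConfig, map_kind: str, rng: np.random.Generator
) -> float:
    """Train on the full training pools and score the full testing pools;
    with obs_repeats > 1, average over resampled M/N-sized draws instead."""
    tr_a, te_a = _pick(map_kind, pools_a)
    tr_b, te_b = _pick(map_kind, pools_b)
    if cfg.obs_repeats == 1:
        sep = train_separator(tr_a, tr_b, c=cfg.c)
        return separation_percentage(sep, te_a, te_b, cfg.convention).delta
    deltas = []
    for _ in range(cfg.obs_repeats):
        ia = rng.permutation(tr_a.shape[0])[: cfg.M]
        ib = rng.permutation(tr_b.shape[0])[: cfg.M]
        ja = rng.permutation(te_a.shape[0])[: cfg.N]
        jb = rng.permutation(te_b.shape[0])[: cfg.N]
        sep = train_separator(tr_a[ia], tr_b[ib], c=cfg.c)
        deltas.append(
            separation_percentage(sep, te_a[ja], te_b[jb], cfg.convention).delta
        )
    return float(np.mean(deltas))


def geneout_alignments(
    a: AlignmentSet | Sequence[Alignment],
    b: AlignmentSet | Sequence[Alignment],
    cfg: GeneOutConfig | None = None,
    rng: np.random.Generator | None = None,
    external_cmd: str | None = None,
    map_kinds: Sequence[str] | None = None,
) -> GeneOutResult | dict[str, GeneOutResult]:
    """GeneOut on two sets of DNA alignments.

    Per set, ``ceil(M/|set|)`` trees per alignment form the training pool
    and ``ceil(N/|set|)`` the testing pool; the observed statistic trains on
    the pooled training trees and scores the testing trees.  Each of the k
    null replicates permutes set-membership labels, column-bootstraps every
    alignment, and re-runs reconstruction, training and testing from
    scratch.

    ``map_kinds`` may list both dissimilarity maps to score them from the
    same reconstructions (a dict of results is then returned); the null
    reconstruction randomness is shared, the SVM step is per-map.
    """
    if cfg is None:
        cfg = GeneOutConfig()
    la = list(a)
    lb = list(b)
    if not la or not lb:
        raise ValueError("both alignment sets must be non-empty")
    single = map_kinds is None
    kinds = [cfg.map_kind] if single else list(map_kinds)
    for kd in kinds:
        if kd not in _MAP_KINDS:
            raise ValueError(f"map_kind must be one of {_MAP_KINDS}")

    order = _shared_order([set(x.taxa) for x in la + lb], "alignments")
    la = [x.reordered(order.labels) for x in la]
    lb = [x.reordered(order.labels) for x in lb]

    m_a = math.ceil(cfg.M / len(la))
    m_b = math.ceil(cfg.M / len(lb))
    n_a = math.ceil(cfg.N / len(la))
    n_b = math.ceil(cfg.N / len(lb))

    if cfg.method in ("nj-f84", "nj-jc"):
        model = "f84" if cfg.method == "nj-f84" else "jc"

        def build_pools(alns, m_per, n_per, r):
            return _nj_pools(alns, m_per, n_per, model, r)

    elif cfg.method in ("external-ml", "external-bayes"):
        if external_cmd is None:
            raise ValueError(f"method {cfg.method!r} requires external_cmd")

        def build_pools(alns, m_per, n_per, r):
            return _external_pools(alns, m_per, n_per, cfg, order, r, external_cmd)

    else:
        raise ValueError(f"unknown reconstruction method {cfg.method!r}")

    seed = _resolve_seed(cfg, rng)
    rngs = _child_rngs(seed, cfg.k)

    pools_a = build_pools(la, m_a, n_a, rngs[0])
    pools_b = build_pools(lb, m_b, n_b, rngs[0])
    delta0 = {
        kd: _delta_from_pools(pools_a, pools_b, cfg, kd, rngs[0]) for kd in kinds
    }

    null_deltas = {kd: np.empty(cfg.k) for kd in kinds}
    for i in range(cfg.k):
        r = rngs[i + 1]
        try:
            pa, pb = permute_and_bootstrap(la, lb, r)
            pools_pa = build_pools(pa, m_a, n_a, r)
            pools_pb = build_pools(pb, m_b, n_b, r)
        except Exception as exc:
            raise RuntimeError(f"null replicate {i + 1} failed: {exc}") from exc
        for kd in kinds:
            tr_a, te_a = _pick(kd, pools_pa)
            tr_b, te_b = _pick(kd, pools_pb)
            sep = train_separator(tr_a, tr_b, c=cfg.c)
            null_deltas[kd][i] = separation_percentage(
                sep, te_a, te_b, cfg.convention
            ).delta

    results = {}
    for kd in kinds:
        pv = pvalue_from_null(delta0[kd], null_deltas[kd], cfg.pvalue_mode)
        count = round(pv * cfg.k)
        results[kd] = GeneOutResult(
            delta0[kd],
            null_deltas[kd],
            count,
            pv,
            cfg,
            {"master": seed, "streams": cfg.k + 1},
        )
    return results[kinds[0]] if single else results
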