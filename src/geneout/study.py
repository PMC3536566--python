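"""Replication harness for the coalescent ROC study.

Drives batteries of GeneOut runs over simulated data: for each species-tree
depth, *positive* tests compare alignment sets generated under two
different species trees and *negative* tests compare sets generated under
one species tree; the resulting p-value pools feed the lower-staircase ROC
machinery in :mod:`geneout.evaluate`.  Two of the original alignment
sampling designs are supported: ``10v10`` (ten alignments per side) and
``1v10`` (a single alignment against ten).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import GeneOutConfig, geneout_alignments
from .evaluate import auc_lower_staircase, empirical_roc
from .simulate import (
    DEFAULT_NE,
    SpeciesTree,
    SubstitutionModel,
    simulate_alignment,
    simulate_coalescent_gene_tree,
    simulate_yule_species_tree,
)

__all__ = ["RocStudy", "alignment_roc_study"]

_DESIGNS = {"10v10": (10, 10), "1v10": (1, 10)}


@dataclass
class RocStudy:
    """P-value pools of an alignment-mode ROC study.

    ``pvalues[design][map_kind][condition]`` is a list of (depth, p) pairs,
    with condition ``"pos"`` (different species trees) or ``"neg"`` (same
    species tree).
    """

    pvalues: dict
    config: dict = field(default_factory=dict)

    def pool(
        self,
        designs: Sequence[str] | None = None,
        map_kinds: Sequence[str] | None = None,
        condition: str = "pos",
    ) -> list[float]:
        designs = designs or list(self.pvalues)
        out: list[float] = []
        for d in designs:
            kinds = map_kinds or list(self.pvalues[d])
            for kd in kinds:
                out.extend(p for _, p in self.pvalues[d][kd][condition])
        return out

    def auc(
        self,
        designs: Sequence[str] | None = None,
        map_kinds: Sequence[str] | None = None,
    ) -> float:
        """Lower-staircase AUC from the pooled positive and negative runs."""
        pos = self.pool(designs, map_kinds, "pos")
        neg = self.pool(designs, map_kinds, "neg")
        return auc_lower_staircase(empirical_roc(pos, neg))

    def rejection_rate(
        self, design: str, map_kind: str, condition: str, depth: float, alpha: float
    ) -> float:
        ps = [p for d, p in self.pvalues[design][map_kind][condition] if d == depth]
        if not ps:
            raise ValueError(f"no runs at depth {depth}")
        return float(np.mean(np.asarray(ps) <= alpha))


def _make_alignments(
    stree: SpeciesTree,
    count: int,
    model: SubstitutionModel,
    length: int,
    rng: np.random.Generator,
) -> list:
    return [
        simulate_alignment(simulate_coalescent_gene_tree(stree, rng), model, length, rng)
        for _ in range(count)
    ]


def alignment_roc_study(
    depths: Sequence[float],
    tests_per_condition: int = 5,
    k: int = 20,
    designs: Sequence[str] = ("10v10", "1v10"),
    map_kinds: Sequence[str] = ("topological", "branch-length"),
    method: str = "nj-f84",
    M: int = 168,
    N: int = 336,
    n_taxa: int = 8,
    ne: float = DEFAULT_NE,
    length: int = 1000,
    model: SubstitutionModel | None = None,
    seed: int = 0,
) -> RocStudy:
    """Run the scaled-down alignment-based ROC study.

    For every depth (in multiples of Ne) and design, ``tests_per_condition``
    GeneOut tests are run on alignments simulated under two different Yule
    species trees (positive condition) and under a single species tree
    (negative condition).  Each test reconstructs trees with NJ and is
    scored with every requested dissimilarity map from the same
    reconstructions.  Runtime scales linearly in depths, tests and k.
    """
    model = model or SubstitutionModel()
    for d in designs:
        if d not in _DESIGNS:
            raise ValueError(f"unknown design {d!r}; choose from {sorted(_DESIGNS)}")
    pvals: dict = {
        d: {kd: {"pos": [], "neg": []} for kd in map_kinds} for d in designs
    }
    master = np.random.SeedSequence(seed)
    depth_seqs = master.spawn(len(depths))
    for depth, dseq in zip(depths, depth_seqs):
        rng = np.random.default_rng(dseq)
        s1 = simulate_yule_species_tree(n_taxa, depth * ne, rng, ne)
        s2 = simulate_yule_species_tree(n_taxa, depth * ne, rng, ne)
        for design in designs:
            na, nb = _DESIGNS[design]
            for condition in ("pos", "neg"):
                src_a = s1 if condition == "pos" else s2
                for _ in range(tests_per_condition):
                    a = _make_alignments(src_a, na, model, length, rng)
                    b = _make_alignments(s2, nb, model, length, rng)
                    cfg = GeneOutConfig(
                        M=M,
                        N=N,
                        k=k,
                        method=method,
                        map_kind=map_kinds[0],
                        seed=int(rng.integers(2**31)),
                    )
                    res = geneout_alignments(a, b, cfg, map_kinds=list(map_kinds))
                    for kd in map_kinds:
                        pvals[design][kd][condition].append((depth, res[kd].pvalue))
    return RocStudy(
        pvals,
        {
            "depths": list(depths),
            "tests_per_condition": tests_per_condition,
            "k": k,
            "designs": list(designs),
            "map_kinds": list(map_kinds),
            "M": M,
            "N": N,
            "seed": seed,
        },
    )
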