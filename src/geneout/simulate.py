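"""Coalescent validation-data simulators.

The study conditions emulated here: pairs of 8-taxon species trees drawn
from a pure-birth (Yule) process and rescaled to a controlled root-to-tip
depth (0.1 to 10 multiples of the haploid effective population size
Ne = 100,000 generations); neutral coalescent gene trees simulated within
each species tree (one gene copy per species, censored coalescent with
pairwise rate j(j-1)/2 / Ne inside every branch); and 1,000-nt DNA
alignments evolved on the gene trees under HKY+Gamma with ts/tv ratio 3.0,
shape 0.8, four discrete rate categories, stationary frequencies
(0.3, 0.2, 0.2, 0.3), and a branch scaling of 3e-8 substitutions per site
per generation.  Shallow species trees give heavily overlapping gene-tree
distributions (much incomplete lineage sorting); deep trees give nearly
disjoint ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .reconstruct import Alignment, pair_mismatch_types, _count_types

__all__ = [
    "SpeciesTree",
    "SubstitutionModel",
    "DEFAULT_NE",
    "simulate_yule_species_tree",
    "simulate_coalescent_gene_tree",
    "simulate_alignment",
    "simulation_study",
    "mean_pairwise_divergence",
    "discrete_gamma_rates",
    "kappa_from_ts_tv",
]

DEFAULT_NE = 100_000  # haploid effective population size, individuals


@dataclass(frozen=True)
class SpeciesTree:
    """A rooted ultrametric species tree with branch lengths in generations."""

    tree: dendropy.Tree
    depth: float  # root-to-tip height, generations
    ne: float  # haploid effective population size

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.ne <= 0:
            raise ValueError("depth and Ne must be positive")
        ages = [self._tip_age(leaf) for leaf in self.tree.leaf_node_iter()]
        if max(abs(a - self.depth) for a in ages) > 1e-9 * max(self.depth, 1.0):
            raise ValueError("species tree is not ultrametric at the stated depth")

    def _tip_age(self, leaf: dendropy.Node) -> float:
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d


@dataclass(frozen=True)
class SubstitutionModel:
    """HKY+Gamma sequence model.

    ``ts_tv`` is the instantaneous transition/transversion flux ratio R; the
    rate-matrix parameter kappa is derived as
    ``kappa = R * (pi_R * pi_Y) / (pi_A pi_G + pi_C pi_T)``.
    ``scaling`` converts gene-tree branch lengths (generations) to expected
    substitutions per site.
    """

    freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)  # A C G T
    ts_tv: float = 3.0
    gamma_shape: float = 0.8
    n_categories: int = 4
    scaling: float = 3e-8

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("freqs must be four positive values summing to 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValueError("need at least one rate category")

    @property
    def kappa(self) -> float:
        return kappa_from_ts_tv(self.ts_tv, np.asarray(self.freqs))

    def rate_matrix(self) -> np.ndarray:
        """HKY rate matrix normalized to one expected substitution per site
        per unit branch length."""
        f = np.asarray(self.freqs)
        kappa = self.kappa
        Q = np.tile(f, (4, 1))
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):  # A<->G, C<->T
            Q[i, j] *= kappa
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -float(np.dot(f, np.diag(Q)))
        return Q / mu

    def category_rates(self) -> np.ndarray:
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)


def kappa_from_ts_tv(ts_tv: float, freqs: np.ndarray) -> float:
    pa, pc, pg, pt = freqs
    return ts_tv * (pa + pg) * (pc + pt) / (pa * pg + pc * pt)


def discrete_gamma_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability discrete-gamma categories (overall
    mean exactly 1)."""
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, shape, scale=1.0 / shape)
    cuts = np.concatenate([[0.0], bounds * shape, [np.inf]])
    # E[X 1(X <= x)] for X ~ Gamma(a, rate a) is P(a+1, a x)
    mass = gammainc(shape + 1, cuts)
    rates = k * np.diff(mass)
    return rates / rates.mean()


# ---------------------------------------------------------------------------
# species trees

def simulate_yule_species_tree(
    n: int,
    depth: float,
    rng: np.random.Generator,
    ne: float = DEFAULT_NE,
    label_template: str = "T{:02d}",
) -> SpeciesTree:
    """A pure-birth tree on ``n`` tips, rescaled multiplicatively so every
    root-to-tip path equals ``depth`` generations exactly."""
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if depth <= 0:
        raise ValueError("depth must be positive")
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    # active lineages: (parent node, birth time); the root splits at t = 0
    active: list[tuple[dendropy.Node, float]] = [(root, 0.0), (root, 0.0)]
    t = 0.0
    while len(active) < n:
        j = len(active)
        t += rng.exponential(1.0 / j)
        pick = int(rng.integers(j))
        parent, born = active.pop(pick)
        node = dendropy.Node()
        parent.add_child(node)
        node.edge.length = t - born
        active.append((node, t))
        active.append((node, t))
    t_end = t + rng.exponential(1.0 / n)
    # tips of a Yule tree are exchangeable: attach labels by a uniform random
    # permutation so the labeled topology carries no trace of the split order
    label_perm = rng.permutation(n)
    for i, (parent, born) in enumerate(active):
        leaf = dendropy.Node(taxon=ns.new_taxon(label_template.format(label_perm[i] + 1)))
        parent.add_child(leaf)
        leaf.edge.length = t_end - born
    scale = depth / t_end
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= scale
    tree.is_rooted = True
    return SpeciesTree(tree, depth, ne)


# ---------------------------------------------------------------------------
# coalescent gene trees

class _GN:
    """Lightweight gene-tree node (age in generations before present)."""

    __slots__ = ("age", "children", "label")

    def __init__(self, age: float, children=None, label: str | None = None):
        self.age = age
        self.children = children or []
        self.label = label


def _coalesce_in_branch(
    lineages: list[_GN],
    t_start: float,
    t_end: float,
    ne: float,
    rng: np.random.Generator,
) -> list[_GN]:
    """Censored coalescent: pairwise rate j(j-1)/2 / Ne while j lineages are
    present; stops at ``t_end`` (pass ``inf`` for the root population)."""
    t = t_start
    lineages = list(lineages)
    while len(lineages) > 1:
        j = len(lineages)
        rate = j * (j - 1) / 2.0 / ne
        t_next = t + rng.exponential(1.0 / rate)
        if t_next > t_end:
            break
        t = t_next
        i1 = int(rng.integers(j))
        i2 = int(rng.integers(j - 1))
        if i2 >= i1:
            i2 += 1
        a = lineages[i1]
        b = lineages[i2]
        merged = _GN(t, [a, b])
        lineages = [x for k, x in enumerate(lineages) if k not in (i1, i2)]
        lineages.append(merged)
    return lineages


def simulate_coalescent_gene_tree(
    species: SpeciesTree, rng: np.random.Generator
) -> dendropy.Tree:
    """One neutral coalescent gene tree inside a species tree, one gene copy
    sampled per species tip; branch lengths in generations.

    Within every species-tree branch the lineages present coalesce at
    exponential rate C(j,2)/Ne; survivors enter the parent branch, and all
    remaining lineages coalesce in the ancestral population above the root.
    """
    stree = species.tree
    depth = species.depth
    # node age = generations before present (tips at 0, root at depth)
    age: dict[int, float] = {}
    for node in stree.postorder_node_iter():
        if node.is_leaf():
            age[id(node)] = 0.0
        else:
            child = node.child_nodes()[0]
            age[id(node)] = age[id(child)] + (child.edge.length or 0.0)

    surviving: dict[int, list[_GN]] = {}
    for node in stree.postorder_node_iter():
        if node.is_leaf():
            incoming = [_GN(0.0, label=node.taxon.label)]
        else:
            incoming = []
            for child in node.child_nodes():
                incoming.extend(surviving.pop(id(child)))
        if node.parent_node is None:
            final = _coalesce_in_branch(incoming, age[id(node)], np.inf, species.ne, rng)
            root_gn = final[0]
        else:
            t0 = age[id(node)]
            t1 = age[id(node.parent_node)]
            surviving[id(node)] = _coalesce_in_branch(incoming, t0, t1, species.ne, rng)

    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)

    def attach(gn: _GN, parent: dendropy.Node | None) -> None:
        if parent is None:
            node = tree.seed_node
        else:
            node = dendropy.Node()
            parent.add_child(node)
            node.edge.length = 0.0  # set by caller
        if gn.label is not None:
            node.taxon = ns.new_taxon(gn.label)
        for child in gn.children:
            attach(child, node)
            node.child_nodes()[-1].edge.length = gn.age - child.age
        node.age = gn.age  # type: ignore[attr-defined]

    attach(root_gn, None)
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# sequence simulation

def simulate_alignment(
    gene_tree: dendropy.Tree,
    model: SubstitutionModel,
    length: int,
    rng: np.random.Generator,
) -> Alignment:
    """Evolve a root sequence drawn from the stationary distribution down a
    gene tree under HKY+Gamma.

    Each site carries a rate multiplier drawn from the discrete-gamma
    distribution; the substitution process on a branch of ``g`` generations
    runs for ``g * scaling * rate`` expected substitutions.
    """
    if length < 1:
        raise ValueError("alignment length must be positive")
    Q = model.rate_matrix()
    rates = model.category_rates()
    freqs = np.asarray(model.freqs)

    cats = rng.integers(0, model.n_categories, size=length)
    root_seq = rng.choice(4, size=length, p=freqs).astype(np.uint8)

    states: dict[int, np.ndarray] = {id(gene_tree.seed_node): root_seq}
    taxa: list[str] = []
    rows: list[np.ndarray] = []
    for node in gene_tree.preorder_node_iter():
        if node is gene_tree.seed_node:
            seq = root_seq
        else:
            g = node.edge.length or 0.0
            parent_seq = states[id(node.parent_node)]
            if g == 0.0:
                seq = parent_seq.copy()
            else:
                d = g * model.scaling
                pmats = np.stack([expm(Q * (d * r)) for r in rates])  # (ncat, 4, 4)
                probs = pmats[cats, parent_seq]  # (L, 4)
                u = rng.random(length)
                seq = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(np.uint8)
        if node.is_leaf():
            taxa.append(node.taxon.label)
            rows.append(seq)
        else:
            states[id(node)] = seq
    order = np.argsort(taxa)
    return Alignment(tuple(taxa[i] for i in order), np.stack([rows[i] for i in order]))


def mean_pairwise_divergence(alignments: Sequence[Alignment]) -> float:
    """Mean uncorrected pairwise sequence divergence in percent: mismatch
    proportion over comparable columns, averaged over all pairs and all
    alignments, times 100."""
    vals = []
    for a in alignments:
        ts, tv, comp = _count_types(pair_mismatch_types(a.codes))
        with np.errstate(invalid="ignore"):
            p = (ts + tv) / comp
        vals.append(np.nanmean(p))
    return float(np.mean(vals) * 100.0)


# ---------------------------------------------------------------------------
# study harness

def simulation_study(
    depths: Sequence[float],
    genes_per_tree: int,
    out_dir: str | Path,
    rng_seed: int,
    n_taxa: int = 8,
    ne: float = DEFAULT_NE,
    model: SubstitutionModel | None = None,
    length: int = 1000,
    write_alignments: bool = True,
    alignment_format: str = "nexus",
) -> dict:
    """Generate and write the full per-depth validation bundle.

    For each depth d (in multiples of Ne): two Yule species trees S1, S2 at
    depth ``d * Ne`` generations, three sets of ``genes_per_tree`` coalescent
    gene trees (T1 within S1; T2 and T3 within S2, T3 for false-positive
    assessment), and one alignment per gene tree.  Everything is written
    under ``out_dir`` with a JSON manifest of all seeds and parameters, so
    the bundle can be regenerated byte-for-byte.
    """
    from . import io as gio

    if alignment_format not in ("nexus", "fasta"):
        raise ValueError("alignment_format must be 'nexus' or 'fasta'")
    model = model or SubstitutionModel()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.SeedSequence(rng_seed)
    depth_seeds = [int(s.generate_state(1)[0] >> 1) for s in master.spawn(len(depths))]
    manifest = {
        "seed": rng_seed,
        "n_taxa": n_taxa,
        "ne": ne,
        "genes_per_tree": genes_per_tree,
        "length": length,
        "alignment_format": alignment_format,
        "model": {
            "freqs": list(model.freqs),
            "ts_tv": model.ts_tv,
            "gamma_shape": model.gamma_shape,
            "n_categories": model.n_categories,
            "scaling": model.scaling,
        },
        "depths": {},
    }
    for depth, dseed in zip(depths, depth_seeds):
        ddir = out / f"depth_{depth:g}"
        ddir.mkdir(exist_ok=True)
        rng = np.random.default_rng(dseed)
        s1 = simulate_yule_species_tree(n_taxa, depth * ne, rng, ne)
        s2 = simulate_yule_species_tree(n_taxa, depth * ne, rng, ne)
        gio.write_newick_trees([s1.tree], ddir / "s1.nwk")
        gio.write_newick_trees([s2.tree], ddir / "s2.nwk")
        for name, stree in (("t1", s1), ("t2", s2), ("t3", s2)):
            genes = [
                simulate_coalescent_gene_tree(stree, rng)
                for _ in range(genes_per_tree)
            ]
            gio.write_newick_trees(genes, ddir / f"{name}.nwk")
            if write_alignments:
                adir = ddir / f"alignments_{name}"
                adir.mkdir(exist_ok=True)
                for i, g in enumerate(genes):
                    aln = simulate_alignment(g, model, length, rng)
                    if alignment_format == "nexus":
                        gio.write_nexus_alignment(aln, adir / f"gene_{i:04d}.nex")
                    else:
                        gio.write_fasta_alignment(aln, adir / f"gene_{i:04d}.fasta")
        manifest["depths"][f"{depth:g}"] = {"seed": dseed}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
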