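"""Gene-tree estimation from alignments.

Pairwise distances (JC69 and F84 with empirical base frequencies), classic
neighbor joining with the Studier–Keppler criterion, and column-bootstrap
replicate trees.  Distances use pairwise deletion: a column with a gap or
ambiguity in either sequence of a pair is skipped for that pair.  Saturated
or undefined distances are capped at ``D_MAX`` substitutions/site so that
downstream tree vectors stay finite.
"""

from __future__ import annotations

import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .treespace import TaxonOrder

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "jc69_distances",
    "f84_distances",
    "neighbor_joining",
    "bootstrap_columns",
    "reconstruct_trees",
    "D_MAX",
]

D_MAX = 5.0  # cap for saturated pairwise distances, substitutions/site

# nucleotide byte codes; 4 = gap, 5 = ambiguous/other
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "-": 4, ".": 4}
_DECODE = np.array(list("ACGT-N"))
_CODE_LUT = np.full(256, 5, dtype=np.uint8)
for _ch, _c in _CODE.items():
    _CODE_LUT[ord(_ch)] = _c
    _CODE_LUT[ord(_ch.lower())] = _c


def encode_sequence(seq: str) -> np.ndarray:
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Alignment:
    """A taxa x sites DNA matrix, stored as a byte-coded array.

    ``codes[i, j]`` is 0..3 for A/C/G/T, 4 for a gap, 5 for any ambiguity.
    """

    taxa: tuple[str, ...]
    codes: np.ndarray

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.uint8)
        object.__setattr__(self, "codes", codes)
        if codes.ndim != 2 or codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be a (n_taxa, n_sites) matrix")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be distinct")

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str] | Sequence[tuple[str, str]]) -> "Alignment":
        items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
        if not items:
            raise ValueError("empty alignment")
        lengths = {len(s) for _, s in items}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        taxa = tuple(t for t, _ in items)
        codes = np.stack([encode_sequence(s) for _, s in items])
        return cls(taxa, codes)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @property
    def sequences(self) -> dict[str, str]:
        return {t: "".join(_DECODE[row]) for t, row in zip(self.taxa, self.codes)}

    def reordered(self, taxa: Sequence[str]) -> "Alignment":
        """Rows permuted into the given taxon order."""
        pos = {t: i for i, t in enumerate(self.taxa)}
        try:
            rows = [pos[t] for t in taxa]
        except KeyError as exc:
            raise ValueError(f"taxon {exc.args[0]!r} not present in alignment") from None
        if len(taxa) != self.n_taxa:
            raise ValueError("taxon list does not cover the alignment")
        return Alignment(tuple(taxa), self.codes[rows])


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a fixed taxon order."""

    taxa: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.taxa)
        if vals.shape != (n, n):
            raise ValueError("distance matrix shape does not match taxa")
        if not np.allclose(vals, vals.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(vals) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(vals < 0):
            raise ValueError("distances must be non-negative")
        if not np.all(np.isfinite(vals)):
            raise ValueError("distances must be finite")


# ---------------------------------------------------------------------------
# pairwise mismatch bookkeeping

def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def pair_mismatch_types(codes: np.ndarray) -> np.ndarray:
    """Per-pair per-column comparison codes.

    Returns a ``(n_pairs, L)`` uint8 array: 0 = match, 1 = transition,
    2 = transversion, 3 = not comparable (gap/ambiguity in either row).
    Pairs follow lexicographic (i, j) order.
    """
    n = codes.shape[0]
    iu, ju = _pair_indices(n)
    a = codes[iu]  # (n_pairs, L)
    b = codes[ju]
    valid = (a < 4) & (b < 4)
    mismatch = valid & (a != b)
    # purines are A(0)/G(2): code & 1 == 0
    same_class = (a & 1) == (b & 1)
    out = np.zeros(a.shape, dtype=np.uint8)
    out[mismatch & same_class] = 1
    out[mismatch & ~same_class] = 2
    out[~valid] = 3
    return out


def _count_types(types: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(#transitions, #transversions, #comparable) per pair."""
    npair, L = types.shape
    counts = np.bincount(
        (types + (np.arange(npair, dtype=np.intp) * 4)[:, None]).ravel(),
        minlength=npair * 4,
    ).reshape(npair, 4)
    ts = counts[:, 1]
    tv = counts[:, 2]
    comp = L - counts[:, 3]
    return ts, tv, comp


def _pair_name(taxa: Sequence[str], k: int) -> str:
    iu, ju = _pair_indices(len(taxa))
    return f"({taxa[iu[k]]}, {taxa[ju[k]]})"


def _jc69_condensed(p: np.ndarray, d_max: float) -> np.ndarray:
    arg = 1.0 - (4.0 / 3.0) * p
    d = np.full_like(p, d_max)
    ok = arg > 0
    d[ok] = -0.75 * np.log(arg[ok])
    return np.minimum(d, d_max)


def _f84_condensed(
    P: np.ndarray, Q: np.ndarray, freqs: np.ndarray, d_max: float
) -> np.ndarray:
    """Maximum-likelihood pairwise F84 distances from transition/transversion
    proportions and base frequencies (A, C, G, T order)."""
    pa, pc, pg, pt = freqs
    pr = pa + pg
    py = pc + pt
    bb = pc * pt + pa * pg
    if pr <= 0 or py <= 0 or bb <= 0:
        # degenerate composition: fall back to JC69 on the total mismatch
        return _jc69_condensed(P + Q, d_max)
    aa = pc * pt / py + pa * pg / pr
    cc = pr * py
    arg1 = 1.0 - P / (2.0 * aa) - (aa - bb) * Q / (2.0 * aa * cc)
    arg2 = 1.0 - Q / (2.0 * cc)
    d = np.full_like(P, d_max)
    ok = (arg1 > 0) & (arg2 > 0)
    d[ok] = -2.0 * aa * np.log(arg1[ok]) + 2.0 * (aa - bb - cc) * np.log(arg2[ok])
    d = np.where(np.isfinite(d), d, d_max)
    return np.clip(d, 0.0, d_max)


def _condensed_to_square(cond: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    iu, ju = _pair_indices(n)
    out[iu, ju] = cond
    out[ju, iu] = cond
    return out


def _check_comparable(comp: np.ndarray, taxa: Sequence[str]) -> None:
    if np.any(comp == 0):
        k = int(np.argmax(comp == 0))
        raise ValueError(
            f"no comparable (ungapped, unambiguous) columns for pair {_pair_name(taxa, k)}"
        )


def jc69_distances(a: Alignment, d_max: float = D_MAX) -> DistanceMatrix:
    """Jukes–Cantor distances: ``d = -(3/4) ln(1 - (4/3) p̂)`` with ``p̂`` the
    mismatch proportion over comparable columns; capped at ``d_max`` when the
    log argument is non-positive (``p̂ >= 3/4``)."""
    types = pair_mismatch_types(a.codes)
    ts, tv, comp = _count_types(types)
    _check_comparable(comp, a.taxa)
    p = (ts + tv) / comp
    cond = _jc69_condensed(p, d_max)
    return DistanceMatrix(a.taxa, _condensed_to_square(cond, a.n_taxa))


def empirical_base_frequencies(a: Alignment) -> np.ndarray:
    """A/C/G/T frequencies pooled over every sequence of the alignment."""
    counts = np.bincount(a.codes.ravel(), minlength=6)[:4].astype(float)
    tot = counts.sum()
    if tot == 0:
        raise ValueError("alignment contains no unambiguous nucleotides")
    return counts / tot


def f84_distances(a: Alignment, d_max: float = D_MAX) -> DistanceMatrix:
    """Pairwise F84 distances with base frequencies pooled over the alignment.

    Reduces to JC69 when frequencies are equal and transitions make up one
    third of the observed differences (the proportion JC69 expects).
    """
    types = pair_mismatch_types(a.codes)
    ts, tv, comp = _count_types(types)
    _check_comparable(comp, a.taxa)
    freqs = empirical_base_frequencies(a)
    cond = _f84_condensed(ts / comp, tv / comp, freqs, d_max)
    return DistanceMatrix(a.taxa, _condensed_to_square(cond, a.n_taxa))


# ---------------------------------------------------------------------------
# neighbor joining

def _nj_events(D: np.ndarray) -> list[tuple[int, int, float, float]]:
    """Agglomeration schedule of Saitou–Nei NJ with the Studier–Keppler
    Q-criterion.

    Node ids 0..n-1 are the input leaves; each join creates node
    ``n + step``.  Returns tuples ``(i, j, length_i, length_j)``; the final
    event (when three nodes remain) has ``j = -1`` and joins the three
    remaining nodes onto one center with the lengths stored separately in
    the last three events.  Ties in Q are broken by the smallest (i, j)
    position in the current node list, which follows creation order, so the
    result is deterministic.  Negative estimated branch lengths are clamped
    to zero.
    """
    n = D.shape[0]
    # grow into a preallocated matrix; node id == row index
    big = np.zeros((2 * n - 2, 2 * n - 2))
    big[:n, :n] = D
    act = list(range(n))
    nxt = n
    events: list[tuple[int, int, float, float]] = []
    while len(act) > 3:
        m = len(act)
        sub = big[np.ix_(act, act)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        k = int(np.argmin(Q))  # first minimum in row-major order: smallest (i, j)
        i, j = divmod(k, m)
        if i > j:
            i, j = j, i
        dij = sub[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        events.append((act[i], act[j], max(li, 0.0), max(lj, 0.0)))
        newrow = 0.5 * (sub[i] + sub[j] - dij)
        big[nxt, act] = newrow
        big[act, nxt] = newrow
        del act[j], act[i]
        act.append(nxt)
        nxt += 1
    # terminal star on the last three nodes
    a, b, c = act
    dab, dac, dbc = big[a, b], big[a, c], big[b, c]
    events.append((a, -1, max(0.5 * (dab + dac - dbc), 0.0), 0.0))
    events.append((b, -1, max(0.5 * (dab + dbc - dac), 0.0), 0.0))
    events.append((c, -1, max(0.5 * (dac + dbc - dab), 0.0), 0.0))
    return events


def _events_to_paths(
    events: list[tuple[int, int, float, float]], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Condensed leaf-to-leaf (path length, edge count) vectors from a join
    schedule, in lexicographic pair order."""
    m = n * (n - 1) // 2
    plen = np.zeros(m)
    ecnt = np.zeros(m)
    # per active node: {leaf: (dist to node, edges to node)}
    maps: dict[int, dict[int, tuple[float, int]]] = {i: {i: (0.0, 0)} for i in range(n)}

    def emit(da: dict[int, tuple[float, int]], db: dict[int, tuple[float, int]]) -> None:
        for i, (di, ei) in da.items():
            for j, (dj, ej) in db.items():
                a, b = (i, j) if i < j else (j, i)
                k = a * n - a * (a + 1) // 2 + (b - a - 1)
                plen[k] = di + dj
                ecnt[k] = ei + ej

    next_id = n
    star: dict[int, tuple[float, int]] = {}
    for i, j, li, lj in events:
        if j == -1:  # terminal center
            lifted = {leaf: (d + li, e + 1) for leaf, (d, e) in maps.pop(i).items()}
            emit(lifted, star)
            star.update(lifted)
            continue
        da = {leaf: (d + li, e + 1) for leaf, (d, e) in maps.pop(i).items()}
        db = {leaf: (d + lj, e + 1) for leaf, (d, e) in maps.pop(j).items()}
        emit(da, db)
        da.update(db)
        maps[next_id] = da
        next_id += 1
    return plen, ecnt


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining on a distance matrix.

    Returns an unrooted tree (dendropy tree whose seed node is the terminal
    NJ junction, of degree 3 for n > 3 or a star for n = 3).  On an additive
    matrix the output reproduces the generating weighted tree exactly.
    """
    n = len(d.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    events = _nj_events(d.values)
    ns = dendropy.TaxonNamespace(list(d.taxa))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(d.taxa):
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes[i] = node
    next_id = n
    for i, j, li, lj in events:
        if j == -1:
            child = nodes.pop(i)
            tree.seed_node.add_child(child)
            child.edge.length = li
            continue
        parent = dendropy.Node()
        ci, cj = nodes.pop(i), nodes.pop(j)
        parent.add_child(ci)
        ci.edge.length = li
        parent.add_child(cj)
        cj.edge.length = lj
        nodes[next_id] = parent
        next_id += 1
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bootstrap and tree factories

def bootstrap_columns(a: Alignment, rng: np.random.Generator) -> Alignment:
    """Resample the alignment's columns uniformly with replacement, keeping
    the number of columns fixed."""
    if a.n_sites < 1:
        raise ValueError("alignment has no columns")
    idx = rng.integers(0, a.n_sites, size=a.n_sites)
    return Alignment(a.taxa, a.codes[:, idx])


class NJVectorFactory:
    """Produces bootstrap-replicate NJ trees of one alignment as tree-space
    vectors, skipping tree-object construction in the hot path.

    Mismatch types and per-column base counts are precomputed once, so each
    replicate costs one index-gather plus the NJ agglomeration.  Rows are
    used in the alignment's own order; reorder the alignment first if a
    global taxon order is required.
    """

    def __init__(self, a: Alignment, model: str = "f84", d_max: float = D_MAX):
        if model not in ("f84", "jc"):
            raise ValueError(f"unknown distance model {model!r}")
        self.alignment = a
        self.model = model
        self.d_max = d_max
        self.n = a.n_taxa
        self.L = a.n_sites
        types = pair_mismatch_types(a.codes)
        # indicator matrices: column-weight vector -> per-pair type counts
        # via one BLAS matvec each, so a bootstrap replicate costs a single
        # length-L bincount plus three (n_pairs x L) products
        self._is_ts = (types == 1).astype(float)
        self._is_tv = (types == 2).astype(float)
        self._is_bad = (types == 3).astype(float)
        cc = np.zeros((4, self.L))
        for b in range(4):
            cc[b] = (a.codes == b).sum(axis=0)
        self.colbase = cc
        self._iu, self._ju = _pair_indices(self.n)
        self._sq = np.zeros((self.n, self.n))

    def _condensed(self, colw: np.ndarray) -> np.ndarray:
        """Condensed distances for a replicate given column multiplicities."""
        ts = self._is_ts @ colw
        tv = self._is_tv @ colw
        bad = self._is_bad @ colw
        comp = colw.sum() - bad
        _check_comparable(comp, self.alignment.taxa)
        P = ts / comp
        Q = tv / comp
        if self.model == "jc":
            return _jc69_condensed(P + Q, self.d_max)
        fr = self.colbase @ colw
        tot = fr.sum()
        freqs = fr / tot if tot > 0 else np.full(4, 0.25)
        return _f84_condensed(P, Q, freqs, self.d_max)

    def _vectors_from_colw(self, colw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        cond = self._condensed(colw)
        sq = self._sq
        sq[self._iu, self._ju] = cond
        sq[self._ju, self._iu] = cond
        return _events_to_paths(_nj_events(sq), self.n)

    def replicate_vectors(self, count: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """(path-length, edge-count) vector arrays, shape (count, n(n-1)/2),
        one bootstrap-replicate NJ tree per row."""
        m = self.n * (self.n - 1) // 2
        plen = np.empty((count, m))
        ecnt = np.empty((count, m))
        for k in range(count):
            idx = rng.integers(0, self.L, size=self.L)
            colw = np.bincount(idx, minlength=self.L).astype(float)
            plen[k], ecnt[k] = self._vectors_from_colw(colw)
        return plen, ecnt

    def point_estimate_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectors of the NJ tree on the full (un-bootstrapped) alignment."""
        return self._vectors_from_colw(np.ones(self.L))


def _run_external(
    a: Alignment, command_template: str, workdir: Path
) -> list[dendropy.Tree]:
    """Hook for external reconstruction: writes the alignment as relaxed
    FASTA, substitutes ``{input}`` in the template, and parses Newick trees
    from the command's stdout."""
    fasta = workdir / "alignment.fasta"
    with open(fasta, "w") as fh:
        for t, s in a.sequences.items():
            fh.write(f">{t}\n{s}\n")
    cmd = command_template.format(input=str(fasta))
    proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(
            f"external reconstruction failed (exit {proc.returncode})\n"
            f"command: {cmd}\nstdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
        )
    trees = dendropy.TreeList.get(data=proc.stdout, schema="newick")
    if not trees:
        raise RuntimeError(f"external command produced no trees\ncommand: {cmd}")
    return list(trees)


def reconstruct_trees(
    a: Alignment,
    count: int,
    method: str = "nj-f84",
    rng: np.random.Generator | None = None,
    external_cmd: str | None = None,
    posterior_stride: int = 1,
) -> list[dendropy.Tree]:
    """Estimate ``count`` gene trees from one alignment.

    For the ``nj-*`` methods each tree is NJ applied to the distances of an
    independent column-bootstrap replicate.  ``external-ml`` and
    ``external-bayes`` shell out to ``external_cmd`` (a template with an
    ``{input}`` placeholder) and read Newick from stdout; for the Bayesian
    hook every ``posterior_stride``-th returned tree is taken.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if method in ("nj-f84", "nj-jc"):
        if rng is None:
            rng = np.random.default_rng()
        dist = f84_distances if method == "nj-f84" else jc69_distances
        out = []
        for _ in range(count):
            rep = bootstrap_columns(a, rng)
            out.append(neighbor_joining(dist(rep)))
        return out
    if method in ("external-ml", "external-bayes"):
        if external_cmd is None:
            raise ValueError(f"method {method!r} requires external_cmd")
        with tempfile.TemporaryDirectory() as tmp:
            trees = _run_external(a, external_cmd, Path(tmp))
        if method == "external-bayes":
            trees = trees[::posterior_stride]
        if len(trees) < count:
            raise RuntimeError(
                f"external command returned {len(trees)} trees, need {count}"
            )
        return trees[:count]
    raise ValueError(f"unknown reconstruction method {method!r}")
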