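"""File formats and run manifests.

Alignments are read from Nexus (DATA/CHARACTERS blocks, sequential or
interleaved), FASTA, or relaxed Phylip via dendropy; trees from Newick.
Every CLI run records a :class:`RunManifest` — config, master seed and
input digests — sufficient to regenerate the run bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import dendropy

from .reconstruct import Alignment

__all__ = [
    "read_nexus_alignments",
    "read_fasta_alignment",
    "read_phylip_alignment",
    "read_alignment_set",
    "write_nexus_alignment",
    "write_fasta_alignment",
    "read_newick_trees",
    "write_newick_trees",
    "RunManifest",
]

_NEXUS_SUFFIXES = (".nex", ".nexus", ".nxs")


def _matrix_to_alignment(matrix: dendropy.DnaCharacterMatrix) -> Alignment:
    pairs = []
    for taxon in matrix:
        pairs.append((taxon.label, str(matrix[taxon]).upper()))
    return Alignment.from_sequences(pairs)


def read_nexus_alignments(path: str | Path) -> list[Alignment]:
    """All alignments in a Nexus file (one per DATA/CHARACTERS block), or in
    a directory of Nexus files taken in sorted filename order."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _NEXUS_SUFFIXES
        )
        if not files:
            raise ValueError(f"no Nexus files (*.nex) found in directory {path}")
        out: list[Alignment] = []
        for f in files:
            out.extend(read_nexus_alignments(f))
        return out
    try:
        ds = dendropy.DataSet.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy errors carry line/column information
        raise ValueError(f"failed to parse Nexus file {path}: {exc}") from exc
    matrices = [m for m in ds.char_matrices if isinstance(m, dendropy.DnaCharacterMatrix)]
    if not matrices:
        raise ValueError(f"{path} contains no DNA DATA/CHARACTERS block")
    return [_matrix_to_alignment(m) for m in matrices]


def read_fasta_alignment(path: str | Path) -> Alignment:
    matrix = dendropy.DnaCharacterMatrix.get(path=str(path), schema="fasta")
    return _matrix_to_alignment(matrix)


def read_phylip_alignment(path: str | Path) -> Alignment:
    matrix = dendropy.DnaCharacterMatrix.get(path=str(path), schema="phylip")
    return _matrix_to_alignment(matrix)


def read_alignment_set(path: str | Path) -> list[Alignment]:
    """Dispatch on suffix: Nexus file/directory, FASTA, or Phylip."""
    path = Path(path)
    if path.is_dir() or path.suffix.lower() in _NEXUS_SUFFIXES:
        return read_nexus_alignments(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        return [read_fasta_alignment(path)]
    if path.suffix.lower() in (".phy", ".phylip"):
        return [read_phylip_alignment(path)]
    return read_nexus_alignments(path)


def _quote(label: str) -> str:
    # quote anything non-alphanumeric; unquoted underscores would be read
    # back as spaces under Nexus token rules
    if not label.isalnum():
        return "'" + label.replace("'", "''") + "'"
    return label


def write_nexus_alignment(a: Alignment, path: str | Path) -> None:
    """Write a single sequential DATA block."""
    width = max(len(_quote(t)) for t in a.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"    DIMENSIONS NTAX={a.n_taxa} NCHAR={a.n_sites};\n")
        fh.write("    FORMAT DATATYPE=DNA MISSING=N GAP=-;\n    MATRIX\n")
        for taxon, seq in a.sequences.items():
            fh.write(f"        {_quote(taxon):<{width}}{seq}\n")
        fh.write("    ;\nEND;\n")


def write_fasta_alignment(a: Alignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in a.sequences.items():
            fh.write(f">{taxon}\n{seq}\n")


def read_newick_trees(path: str | Path, default_length: float = 1.0) -> list[dendropy.Tree]:
    """Newick trees (one per line or semicolon-separated).

    Edges without a branch length get ``default_length`` (1.0), with a
    warning — this makes the branch-length and topological maps coincide on
    such trees.
    """
    try:
        trees = dendropy.TreeList.get(path=str(path), schema="newick")
    except Exception as exc:
        raise ValueError(f"failed to parse Newick file {path}: {exc}") from exc
    missing = 0
    for tree in trees:
        # a bifurcating seed node on a tree not explicitly rooted ([&R]) is a
        # subdivision point of one unrooted edge; collapse it so defaulted
        # unit lengths keep the branch-length and topological maps coincident
        if not tree.is_rooted and len(tree.seed_node.child_nodes()) == 2:
            tree.deroot()
        for node in tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = default_length
                missing += 1
    if missing:
        warnings.warn(
            f"{missing} edges in {path} had no branch length; "
            f"defaulted to {default_length}"
        )
    return list(trees)


def write_newick_trees(trees: Sequence[dendropy.Tree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(
                tree.as_string(
                    schema="newick",
                    suppress_rooting=True,
                    real_value_format_specifier=".10g",
                ).strip()
                + "\n"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to regenerate a CLI run bit-for-bit: the config
    snapshot, the master seed (child streams are derived from it
    deterministically), the tool version, and digests of the input files."""

    mode: str  # "alignments" | "trees"
    config: dict
    master_seed: int
    inputs: dict  # logical name -> path
    input_digests: dict  # logical name -> sha256
    version: str

    @classmethod
    def create(
        cls, mode: str, config: dict, master_seed: int, inputs: dict[str, str]
    ) -> "RunManifest":
        from . import __version__

        digests = {}
        for name, p in inputs.items():
            p = Path(p)
            if p.is_dir():
                digests[name] = "|".join(
                    f"{f.name}:{_sha256(f)}" for f in sorted(p.iterdir()) if f.is_file()
                )
            else:
                digests[name] = _sha256(p)
        return cls(mode, dict(config), int(master_seed), dict(inputs), digests, __version__)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def verify_inputs(self) -> None:
        fresh = RunManifest.create(self.mode, self.config, self.master_seed, self.inputs)
        for name, digest in self.input_digests.items():
            if fresh.input_digests.get(name) != digest:
                raise ValueError(
                    f"input {name!r} ({self.inputs[name]}) does not match the "
                    "digest recorded in the manifest"
                )
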