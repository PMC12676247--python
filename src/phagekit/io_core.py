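"""Shared primitive types and readers/writers for FASTA, newick and TSV.

Coordinates are 1-based inclusive everywhere. Ambiguity characters other
than N are mapped to N with a warning; N never matches any base in
downstream comparisons.
"""

from __future__ import annotations

import io
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import dendropy

VALID_BASES = frozenset("ACGTN")
_AMBIG_RE = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_seq(seq: str, record_id: str = "?") -> str:
    """Uppercase a DNA string and collapse non-ACGTN characters to N."""
    s = seq.upper()
    if _AMBIG_RE.search(s):
        n_bad = len(_AMBIG_RE.findall(s))
        warnings.warn(
            f"record {record_id}: {n_bad} ambiguous character(s) mapped to N",
            stacklevel=2,
        )
        s = _AMBIG_RE.sub("N", s)
    return s


@dataclass
class GenomeRecord:
    """A nucleotide sequence plus the per-genome metadata the pipeline uses.

    Optional fields default to absent (None); ``provirus`` and
    ``in_reference`` default to False.
    """

    id: str
    seq: str
    habitat: Optional[str] = None
    completeness: Optional[float] = None
    lifestyle_score: Optional[float] = None
    provirus: bool = False
    in_reference: bool = False
    host_taxon: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"genome {self.id}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(
                f"genome {self.id}: invalid characters {sorted(bad)}; "
                "run clean_seq() first"
            )
        if self.completeness is not None and not (0 <= self.completeness <= 100):
            raise ValueError(
                f"genome {self.id}: completeness {self.completeness} outside [0, 100]"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneCall:
    """One predicted gene: 1-based inclusive interval, strand, annotation."""

    genome_id: str
    start: int
    end: int
    strand: str
    source_db: str = "none"
    description: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene on {self.genome_id}: bad interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene on {self.genome_id}: strand must be + or -")


@dataclass
class Tree:
    """A phylogenetic tree with unique leaf labels and non-negative branch lengths.

    Thin wrapper around a dendropy tree; ``newick`` round-trips losslessly
    for leaf set and path lengths.
    """

    _tree: dendropy.Tree = field(repr=False)

    @property
    def leaf_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def parse_newick(text: str) -> Tree:
    """Parse a newick string into a :class:`Tree`.

    Raises ValueError on malformed input, duplicate leaf labels, or
    negative branch lengths.
    """
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in dt.leaf_node_iter() if lf.taxon is not None]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate leaf labels in newick tree")
    for edge in dt.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return Tree(dt)


def tree_from_dendropy(dt: dendropy.Tree) -> Tree:
    """Wrap a dendropy tree, clamping float-noise negative lengths to 0."""
    for edge in dt.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            if edge.length < -1e-9:
                raise ValueError(f"negative branch length {edge.length}")
            edge.length = 0.0
    return Tree(dt)


def read_fasta(path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords.

    Ids are taken from the header up to the first whitespace; sequences
    are uppercased and non-ACGTN characters become N. Duplicate ids and
    empty sequences are errors.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rid, seq in _iter_fasta(handle):
            if rid in seen:
                raise ValueError(f"duplicate FASTA id: {rid}")
            seen.add(rid)
            if not seq:
                raise ValueError(f"empty sequence for FASTA id: {rid}")
            records.append(GenomeRecord(id=rid, seq=clean_seq(seq, rid)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _iter_fasta(handle: io.TextIOBase):
    rid = None
    chunks: list[str] = []
    for line in handle:
        line = line.rstrip("\n")
        if line.startswith(">"):
            if rid is not None:
                yield rid, "".join(chunks)
            rid = line[1:].split()[0] if len(line) > 1 else ""
            chunks = []
        elif line:
            chunks.append(line.strip())
    if rid is not None:
        yield rid, "".join(chunks)


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 80) -> None:
    """Write records as FASTA with fixed line wrapping."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                out.write(rec.seq[i : i + width] + "\n")
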