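"""CRISPR array detection, bounded-mismatch spacer matching, host
assignment, phage-phage interaction networks and Cas acquisition status.

Spacer matching is an exhaustive full-length, gapless Hamming scan over
every offset on both strands — the published acceptance rule (<=1
mismatch, 100% alignment) is exactly computable, so no heuristic aligner
is needed. N never matches any base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from phagekit.io_core import GenomeRecord, revcomp


@dataclass
class Spacer:
    spacer_id: str
    source_genome: str
    seq: str
    source_kind: str = "host"  # host | phage

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"spacer {self.spacer_id}: empty sequence")


@dataclass
class CrisprArray:
    genome_id: str
    repeat_seq: str
    positions: list[int]  # 1-based repeat start positions
    spacers: list[Spacer]
    start: int = 0  # 1-based inclusive span of the whole array
    end: int = 0

    @property
    def repeat_len(self) -> int:
        return len(self.repeat_seq)


@dataclass
class SpacerMatch:
    start: int  # 1-based, forward strand
    strand: str  # + / -
    mismatches: int


@dataclass
class InteractionEdge:
    source: str  # spacer owner
    target: str  # matched genome
    spacer_id: str
    mismatches: int
    target_start: int
    target_strand: str
    kind: str  # host_phage | phage_phage


@dataclass
class CasSystem:
    genome_id: str
    subtype: str
    genes: list[str] = field(default_factory=list)
    acquisition_complete: bool = False


def detect_crispr_arrays(
    genome: GenomeRecord,
    min_repeats: int = 3,
    repeat_len: tuple[int, int] = (23, 47),
    spacer_len: tuple[int, int] = (26, 50),
) -> list[CrisprArray]:
    """Find runs of >= min_repeats exact repeat copies separated by unique
    spacers within the configured length bounds.

    Simplified detector: repeat copies must be exact (no degeneracy).
    Candidate arrays are anchored on repeated seed words of the minimum
    repeat length, the repeat is extended to the longest length shared by
    all copies, and overlapping candidates are resolved by most repeats,
    then leftmost position.
    """
    seq = genome.seq
    n = len(seq)
    k = repeat_len[0]
    if n <= 2 * k + spacer_len[0]:
        return []
    occ: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        word = seq[i : i + k]
        if "N" not in word:
            occ.setdefault(word, []).append(i)

    min_step = k + spacer_len[0]
    max_step = repeat_len[1] + spacer_len[1]
    candidates: list[CrisprArray] = []
    used_anchor: set[int] = set()
    for word in sorted(occ, key=lambda w: occ[w][0]):
        positions = occ[word]
        if len(positions) < min_repeats or positions[0] in used_anchor:
            continue
        # greedy chain of occurrences at CRISPR-like spacings
        chain = [positions[0]]
        for p in positions[1:]:
            step = p - chain[-1]
            if min_step <= step <= max_step:
                chain.append(p)
        if len(chain) < min_repeats:
            continue
        # extend the repeat to the longest length identical across all copies
        # while keeping every spacer within bounds
        best_len = None
        for length in range(repeat_len[1], k - 1, -1):
            if chain[-1] + length > n:
                continue
            first = seq[chain[0] : chain[0] + length]
            if any(seq[p : p + length] != first for p in chain[1:]):
                continue
            gaps = [
                chain[i + 1] - (chain[i] + length) for i in range(len(chain) - 1)
            ]
            if all(spacer_len[0] <= g <= spacer_len[1] for g in gaps):
                best_len = length
                break
        if best_len is None:
            continue
        spacer_seqs = [
            seq[chain[i] + best_len : chain[i + 1]] for i in range(len(chain) - 1)
        ]
        if len(set(spacer_seqs)) != len(spacer_seqs):
            continue  # spacers must be unique
        spacers = [
            Spacer(
                spacer_id=f"{genome.id}|arr{len(candidates)}|sp{i}",
                source_genome=genome.id,
                seq=s,
            )
            for i, s in enumerate(spacer_seqs)
        ]
        candidates.append(
            CrisprArray(
                genome_id=genome.id,
                repeat_seq=seq[chain[0] : chain[0] + best_len],
                positions=[p + 1 for p in chain],
                spacers=spacers,
                start=chain[0] + 1,
                end=chain[-1] + best_len,
            )
        )
        for p in chain:
            used_anchor.add(p)

    # overlap resolution: most repeats, then leftmost
    candidates.sort(key=lambda a: (-len(a.positions), a.start))
    chosen: list[CrisprArray] = []
    for cand in candidates:
        if all(cand.end < c.start or cand.start > c.end for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda a: a.start)
    for i, arr in enumerate(chosen):
        for j, sp in enumerate(arr.spacers):
            sp.spacer_id = f"{genome.id}|arr{i}|sp{j}"
    return chosen


def _encode_genome(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 0  # genome N: code 0
    return arr


def _encode_spacer(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[arr == ord("N")] = 1  # spacer N: code 1, never equals genome codes
    return arr


def _scan(genome_arr: np.ndarray, spacer_arr: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """(0-based offset, mismatches) for all full-length placements."""
    L = spacer_arr.size
    n = genome_arr.size
    if L > n:
        return []
    n_off = n - L + 1
    mism = np.zeros(n_off, dtype=np.int32)
    for j in range(L):
        mism += genome_arr[j : j + n_off] != spacer_arr[j]
    hits = np.nonzero(mism <= max_mm)[0]
    return [(int(o), int(mism[o])) for o in hits]


def match_spacer(
    spacer: Spacer, genome: GenomeRecord, max_mm: int = 1
) -> list[SpacerMatch]:
    """Every full-length, gapless placement of the spacer on either strand
    with <= max_mm mismatches; 1-based forward-strand coordinates."""
    if len(spacer.seq) > len(genome.seq):
        raise ValueError("spacer longer than genome")
    garr = _encode_genome(genome.seq)
    out: list[SpacerMatch] = []
    for off, mm in _scan(garr, _encode_spacer(spacer.seq), max_mm):
        out.append(SpacerMatch(start=off + 1, strand="+", mismatches=mm))
    rc = revcomp(spacer.seq)
    for off, mm in _scan(garr, _encode_spacer(rc), max_mm):
        out.append(SpacerMatch(start=off + 1, strand="-", mismatches=mm))
    out.sort(key=lambda m: (m.start, m.strand))
    return out


def _interval_overlaps_arrays(
    start: int, end: int, arrays: Sequence[CrisprArray]
) -> bool:
    return any(not (end < a.start or start > a.end) for a in arrays)


def build_host_edges(
    host_arrays: Iterable[CrisprArray],
    phage_genomes: Sequence[GenomeRecord],
    max_mm: int = 1,
    exclude_array_hits: bool = True,
    phage_arrays: Optional[Mapping[str, Sequence[CrisprArray]]] = None,
) -> list[InteractionEdge]:
    """Host spacers scanned against every phage genome.

    With ``exclude_array_hits`` a hit landing inside a detected CRISPR
    array of the target phage is discarded (shared array content is not
    evidence of infection).
    """
    phage_arrays = phage_arrays or {}
    edges: list[InteractionEdge] = []
    for arr in host_arrays:
        for sp in arr.spacers:
            for pg in phage_genomes:
                if len(sp.seq) > len(pg.seq):
                    continue
                for m in match_spacer(sp, pg, max_mm=max_mm):
                    if exclude_array_hits and _interval_overlaps_arrays(
                        m.start, m.start + len(sp.seq) - 1, phage_arrays.get(pg.id, ())
                    ):
                        continue
                    edges.append(
                        InteractionEdge(
                            source=arr.genome_id,
                            target=pg.id,
                            spacer_id=sp.spacer_id,
                            mismatches=m.mismatches,
                            target_start=m.start,
                            target_strand=m.strand,
                            kind="host_phage",
                        )
                    )
    return edges


def assign_hosts(
    edges: Iterable[InteractionEdge], host_taxa: Mapping[str, str]
) -> dict[str, set[str]]:
    """Phage -> set of host genera whose spacers match it."""
    out: dict[str, set[str]] = {}
    for e in edges:
        if e.source not in host_taxa:
            raise ValueError(f"no genus label for matched host {e.source}")
        out.setdefault(e.target, set()).add(host_taxa[e.source])
    return out


def classify_host_range(host_map: Mapping[str, set[str]]) -> dict[str, str]:
    """specialist (exactly one genus) vs generalist (two or more)."""
    out = {}
    for phage, genera in host_map.items():
        if not genera:
            raise ValueError(f"empty genus set for {phage}")
        out[phage] = "specialist" if len(genera) == 1 else "generalist"
    return out


def build_phage_network(
    phage_arrays: Sequence[CrisprArray],
    phage_genomes: Sequence[GenomeRecord],
    max_mm: int = 1,
    exclude_array_hits: bool = True,
) -> tuple[list[InteractionEdge], nx.DiGraph]:
    """Directed spacer-targeting network among phages.

    Edge A->B for each spacer of A matching genome B (A == B excluded).
    Hits inside a detected array of B are excluded by default — identical
    spacer content indicates shared immunity, not predation. Multi-edges
    are collapsed in the returned graph with a match count attribute.
    """
    arrays_by_genome: dict[str, list[CrisprArray]] = {}
    for arr in phage_arrays:
        arrays_by_genome.setdefault(arr.genome_id, []).append(arr)
    edges: list[InteractionEdge] = []
    for arr in phage_arrays:
        for sp in arr.spacers:
            for pg in phage_genomes:
                if pg.id == arr.genome_id or len(sp.seq) > len(pg.seq):
                    continue
                for m in match_spacer(sp, pg, max_mm=max_mm):
                    if exclude_array_hits and _interval_overlaps_arrays(
                        m.start, m.start + len(sp.seq) - 1,
                        arrays_by_genome.get(pg.id, ()),
                    ):
                        continue
                    edges.append(
                        InteractionEdge(
                            source=arr.genome_id,
                            target=pg.id,
                            spacer_id=sp.spacer_id,
                            mismatches=m.mismatches,
                            target_start=m.start,
                            target_strand=m.strand,
                            kind="phage_phage",
                        )
                    )
    graph = nx.DiGraph()
    for e in edges:
        if graph.has_edge(e.source, e.target):
            graph[e.source][e.target]["n_matches"] += 1
        else:
            graph.add_edge(e.source, e.target, n_matches=1)
    return edges, graph


def classify_pairs(
    graph: nx.DiGraph, host_map: Mapping[str, set[str]]
) -> list[dict]:
    """Unordered targeted pairs labelled single/double-directed, with a
    same-host flag (genus-set intersection of the two phages)."""
    seen: set[frozenset[str]] = set()
    rows = []
    for a, b in graph.edges():
        key = frozenset((a, b))
        if key in seen:
            continue
        seen.add(key)
        reciprocal = graph.has_edge(b, a)
        ga = host_map.get(a, set())
        gb = host_map.get(b, set())
        rows.append(
            dict(
                phage_a=min(a, b),
                phage_b=max(a, b),
                directionality="double_directed" if reciprocal else "single_directed",
                same_host=bool(ga and gb and ga & gb),
            )
        )
    rows.sort(key=lambda r: (r["phage_a"], r["phage_b"]))
    return rows


def cas_acquisition_status(system: CasSystem) -> CasSystem:
    """acquisition_complete iff the gene list contains both cas1 and cas2
    (case-insensitive); cas4 is recorded but not required."""
    names = {g.strip().lower() for g in system.genes}
    system.acquisition_complete = "cas1" in names and "cas2" in names
    return system
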