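"""Alternative genetic-code detection via coding-density contrast.

A genome is scanned for ORFs under four stop-codon sets (standard code 11
and the three single-stop reassignments 15/90/91). Reassigning a stop can
only lengthen or preserve maximal ORFs, so coding density is monotone
under stop removal; a genome whose density jumps past a size-dependent
threshold under one reassignment is called as using that code.
"""

from __future__ import annotations

from dataclasses import dataclass

from phagekit.io_core import GenomeRecord, revcomp
from phagekit.synthetic import STOP_SETS  # {11,15,90,91} -> stop codon tuples

START_CODONS = frozenset({"ATG", "GTG", "TTG"})
ALL_STOPS = frozenset({"TAA", "TAG", "TGA"})

ALT_CODES = (15, 90, 91)  # tie-break order


@dataclass
class CodeProfile:
    genome_id: str
    density_by_code: dict[int, float]
    called_code: int
    gain: float  # relative density increase of called code over code 11


def _frame_orfs(seq: str, frame: int, stop_set: frozenset[str], min_len: int):
    """Maximal start-to-stop ORFs in one forward frame, 0-based half-open.

    Run-off ORFs (no in-frame stop before the sequence end) are reported.
    """
    n = len(seq)
    orfs = []
    i = frame
    start = None
    while i + 3 <= n:
        codon = seq[i : i + 3]
        if codon in stop_set:
            if start is not None and (i + 3) - start >= min_len:
                orfs.append((start, i + 3))
            start = None
        elif start is None and codon in START_CODONS:
            start = i
        i += 3
    if start is not None and i - start >= min_len:
        orfs.append((start, i))
    return orfs


def find_orfs(seq: str, stop_set, min_len: int = 90) -> list[tuple[int, int, str]]:
    """All maximal ORFs over the six frames.

    Returns (start, end, strand) with 1-based inclusive genome coordinates;
    no overlap resolution is applied.
    """
    stop_set = frozenset(stop_set)
    if not stop_set:
        raise ValueError("stop_set must be non-empty")
    if not stop_set <= ALL_STOPS:
        raise ValueError(f"stop_set must be a subset of {sorted(ALL_STOPS)}")
    n = len(seq)
    out = []
    for frame in range(3):
        for s, e in _frame_orfs(seq, frame, stop_set, min_len):
            out.append((s + 1, e, "+"))
    rc = revcomp(seq)
    for frame in range(3):
        for s, e in _frame_orfs(rc, frame, stop_set, min_len):
            out.append((n - e + 1, n - s, "-"))
    return sorted(out)


def coding_density(seq: str, orfs) -> float:
    """Fraction of the genome covered by the union of ORF intervals
    (both strands projected onto genome coordinates)."""
    n = len(seq)
    if n == 0:
        raise ValueError("empty sequence")
    if not orfs:
        return 0.0
    iv = sorted((s, e) for s, e, *_ in orfs)
    for s, e in iv:
        if s < 1 or e > n:
            raise ValueError(f"ORF interval [{s}, {e}] outside genome of length {n}")
    covered = 0
    cur_s, cur_e = iv[0]
    for s, e in iv[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return covered / n


def call_genetic_code(
    genome: GenomeRecord,
    min_orf: int = 90,
    size_cut: int = 100_000,
    gain_small: float = 0.10,
    gain_large: float = 0.05,
    relative: bool = True,
) -> CodeProfile:
    """Call the genetic code from density gains over the standard code.

    Genomes shorter than ``size_cut`` need a relative gain > ``gain_small``;
    larger genomes > ``gain_large``. With ``relative=False`` gains are read
    as absolute (percentage-point) density differences instead.
    """
    if len(genome.seq) < 300:
        raise ValueError(f"{genome.id}: genome shorter than 300 nt")
    densities: dict[int, float] = {}
    for code, stops in STOP_SETS.items():
        densities[code] = coding_density(
            genome.seq, find_orfs(genome.seq, stops, min_len=min_orf)
        )
    d11 = densities[11]
    threshold = gain_small if len(genome.seq) < size_cut else gain_large

    def _gain(code: int) -> float:
        if relative:
            if d11 == 0.0:
                return float("inf") if densities[code] > 0 else 0.0
            return (densities[code] - d11) / d11
        return densities[code] - d11

    best_code = 11
    best_gain = 0.0
    for code in ALT_CODES:  # fixed order breaks ties as 15, 90, 91
        g = _gain(code)
        if g > threshold and g > best_gain:
            best_code = code
            best_gain = g
    return CodeProfile(
        genome_id=genome.id,
        density_by_code=densities,
        called_code=best_code,
        gain=best_gain,
    )
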