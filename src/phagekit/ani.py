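"""Pairwise ANI, exact dereplication and greedy species-level clustering.

ANI is computed by exact k-mer seeding on both strands followed by
gapless evaluation of seeded diagonals; segments below 70% identity are
discarded and coverage is measured on merged intervals so overlapping
segments are never double-counted. This is a desk-scale stand-in for a
local aligner: adequate wherever genuine homology is near-colinear, and
directly checkable against planted substitution counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from phagekit.io_core import GenomeRecord, revcomp

MIN_SEGMENT_IDENTITY = 0.70


@dataclass
class AniResult:
    query_id: str
    target_id: str
    ani: float  # percent, alignment-length weighted
    qcov: float  # percent of query covered by merged segments
    tcov: float  # percent of target covered


@dataclass
class ViralCluster:
    centroid_id: str
    member_ids: list[str]
    level: str = "species"
    is_novel: bool = False


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge half-open [s, e) intervals."""
    if not iv:
        return []
    iv = sorted(iv)
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _covered(iv: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in _merge_intervals(iv))


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _c in enumerate(b"ACGT"):
    _BASE_CODE[_c] = _i


def _kmer_codes(enc: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer integers; windows containing N get code -1."""
    vals = _BASE_CODE[enc]
    n_off = enc.size - k + 1
    if n_off <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n_off, dtype=np.int64)
    valid = np.ones(n_off, dtype=bool)
    for j in range(k):
        win = vals[j : j + n_off]
        valid &= win >= 0
        codes = codes * 4 + np.where(win >= 0, win, 0)
    codes[~valid] = -1
    return codes


def _seeded_diagonals(ea: np.ndarray, eb: np.ndarray, k: int) -> np.ndarray:
    """Distinct diagonals (qpos - tpos) supported by shared exact k-mers.

    Diagonals need at least two seed k-mers (one when the sequences are
    barely longer than k) — genuine homologous diagonals carry hundreds,
    while chance collisions in low-complexity text rarely repeat on the
    same diagonal.
    """
    ca = _kmer_codes(ea, k)
    cb = _kmer_codes(eb, k)
    order = np.argsort(cb, kind="stable")
    sorted_cb = cb[order]
    left = np.searchsorted(sorted_cb, ca, side="left")
    right = np.searchsorted(sorted_cb, ca, side="right")
    hits = (right > left) & (ca >= 0)
    idx = np.flatnonzero(hits)
    if idx.size == 0:
        return np.empty(0, dtype=np.int64)
    cnt = right[idx] - left[idx]
    qpos = np.repeat(idx, cnt)
    base = np.repeat(left[idx], cnt)
    within = np.arange(cnt.sum()) - np.repeat(np.cumsum(cnt) - cnt, cnt)
    tpos = order[base + within]
    diags, counts = np.unique(qpos - tpos, return_counts=True)
    min_seeds = 2 if min(ea.size, eb.size) > 4 * k else 1
    return diags[counts >= min_seeds]


def _diagonal_segments(
    ea: np.ndarray, eb: np.ndarray, diag: int, k: int
) -> list[tuple[int, int, int]]:
    """Evaluate one gapless diagonal; return (qstart, qend, matches) segments.

    The full overlap of the two sequences on the diagonal is taken as one
    candidate segment and kept if its identity is >= MIN_SEGMENT_IDENTITY;
    otherwise it is split at mismatch runs longer than the seed length and
    each piece is re-tested. N never matches.
    """
    qs = max(0, diag)
    qe = min(len(ea), len(eb) + diag)
    if qe - qs < k:
        return []
    sub_a = ea[qs:qe]
    sub_b = eb[qs - diag : qe - diag]
    match = (sub_a == sub_b) & (sub_a != ord("N")) & (sub_b != ord("N"))
    total = qe - qs
    m = int(match.sum())
    if m / total >= MIN_SEGMENT_IDENTITY:
        return [(qs, qe, m)]
    # split on mismatch runs >= k and keep pieces that hold a seed and pass
    # the identity floor (all vectorised: runs via edge detection)
    padded = np.concatenate(([False], match, [False]))
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    match_runs = edges.reshape(-1, 2)  # [start, end) runs of matches
    if match_runs.size == 0 or int(np.max(match_runs[:, 1] - match_runs[:, 0])) < k:
        return []
    seed_starts = match_runs[(match_runs[:, 1] - match_runs[:, 0]) >= k, 0]
    # mismatch runs of length >= k are the break points
    inv = np.concatenate(([False], ~match, [False]))
    iedges = np.flatnonzero(np.diff(inv.view(np.int8)))
    mm_runs = iedges.reshape(-1, 2)
    long_mm = mm_runs[(mm_runs[:, 1] - mm_runs[:, 0]) >= k]
    bounds = np.concatenate(([0], long_mm.ravel(), [total]))
    cm = np.concatenate(([0], np.cumsum(match)))
    segs: list[tuple[int, int, int]] = []
    pieces = bounds.reshape(-1, 2)
    for s, e in pieces:
        if e - s < k:
            continue
        pm = int(cm[e] - cm[s])
        if pm / (e - s) < MIN_SEGMENT_IDENTITY:
            continue
        if not np.any((seed_starts >= s) & (seed_starts < e)):
            continue
        segs.append((qs + int(s), qs + int(e), pm))
    return segs


def pairwise_ani(
    a: GenomeRecord, b: GenomeRecord, k: int = 15
) -> AniResult:
    """Seed-and-extend gapless ANI with merged-interval coverage."""
    if len(a.seq) < k or len(b.seq) < k:
        raise ValueError(f"sequences must be at least {k} nt for ANI")
    ea = _encode(a.seq)
    total_matches = 0
    total_len = 0
    q_iv: list[tuple[int, int]] = []
    t_iv: list[tuple[int, int]] = []
    for strand, bseq in (("+", b.seq), ("-", revcomp(b.seq))):
        eb = _encode(bseq)
        for diag in _seeded_diagonals(ea, eb, k):
            for qs, qe, m in _diagonal_segments(ea, eb, diag, k):
                total_matches += m
                total_len += qe - qs
                q_iv.append((qs, qe))
                ts, te = qs - diag, qe - diag
                if strand == "-":
                    ts, te = len(bseq) - te, len(bseq) - ts
                t_iv.append((ts, te))
    if total_len == 0:
        return AniResult(a.id, b.id, 0.0, 0.0, 0.0)
    return AniResult(
        a.id,
        b.id,
        ani=100.0 * total_matches / total_len,
        qcov=100.0 * _covered(q_iv) / len(a.seq),
        tcov=100.0 * _covered(t_iv) / len(b.seq),
    )


def dereplicate_exact(genomes: Iterable[GenomeRecord]) -> list[GenomeRecord]:
    """One representative per identical-sequence group, strand-insensitive.

    Representative is the longest genome; ties broken by lexicographically
    first id. Output preserves that (length desc, id asc) order.
    """
    groups: dict[str, list[GenomeRecord]] = {}
    for g in genomes:
        canon = min(g.seq, revcomp(g.seq))
        groups.setdefault(canon, []).append(g)
    reps = [
        sorted(members, key=lambda r: (-len(r.seq), r.id))[0]
        for members in groups.values()
    ]
    return sorted(reps, key=lambda r: (-len(r.seq), r.id))


def greedy_species_clusters(
    genomes: Sequence[GenomeRecord],
    ani_min: float = 95.0,
    cov_min: float = 85.0,
    k: int = 15,
) -> list[ViralCluster]:
    """Greedy centroid clustering at >=ani_min ANI and >=cov_min coverage
    of the member genome. Canonical order (length desc, id asc) makes the
    result independent of input order."""
    if not genomes:
        raise ValueError("greedy_species_clusters requires at least one genome")
    ordered = sorted(genomes, key=lambda g: (-len(g.seq), g.id))
    unassigned = list(ordered)
    clusters: list[ViralCluster] = []
    while unassigned:
        centroid = unassigned.pop(0)
        members = [centroid.id]
        rest = []
        for g in unassigned:
            r = pairwise_ani(centroid, g, k=k)
            if r.ani >= ani_min and r.tcov >= cov_min:
                members.append(g.id)
            else:
                rest.append(g)
        unassigned = rest
        clusters.append(ViralCluster(centroid_id=centroid.id, member_ids=members))
    return clusters


def flag_novel_clusters(
    clusters: Iterable[ViralCluster], genomes: Iterable[GenomeRecord]
) -> list[ViralCluster]:
    """is_novel iff no member carries the reference-set flag."""
    ref = {g.id: g.in_reference for g in genomes}
    out = []
    for c in clusters:
        missing = [m for m in c.member_ids if m not in ref]
        if missing:
            raise ValueError(f"unknown cluster member(s): {missing}")
        c.is_novel = not any(ref[m] for m in c.member_ids)
        out.append(c)
    return out
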