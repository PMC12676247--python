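"""Core-marker selection, alignment trimming, NJ trees and patristic distances.

Tree inference is neighbour joining on concatenated-marker p-distances —
a deterministic, oracle-testable stand-in that preserves the distance
semantics of the marker pipeline. On additive distance matrices NJ
recovers the generating topology and branch lengths exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from phagekit.io_core import Tree, parse_newick

GAP_CHARS = frozenset("-.")

MAX_P_DISTANCE = 0.75  # assigned when two rows share no scored columns


@dataclass
class MarkerProfile:
    profile_id: str
    hits: dict[str, int]  # genome -> copy count (genomes with >=1 copy)
    mean_copy: float
    mean_len: float
    prevalence: float


@dataclass
class MarkerAlignment:
    profile_id: str
    rows: dict[str, str]  # genome -> gapped residue string
    n_columns: int = field(default=-1)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.profile_id}: alignment rows differ in length")
        self.n_columns = lengths.pop() if lengths else 0


def compute_profiles(
    families: pd.DataFrame, genomes: Sequence[str]
) -> list[MarkerProfile]:
    """Summarise a family-assignment table over a fixed genome set.

    ``families`` columns: genome_id, profile_id, copy_count, mean_protein_len.
    Prevalence is computed against ``genomes``; mean copy number averages
    only over carrier genomes (the stricter reading).
    """
    if len(genomes) == 0:
        raise ValueError("empty genome set")
    genome_set = set(genomes)
    sub = families[families["genome_id"].isin(genome_set)]
    profiles = []
    for pid, grp in sub.groupby("profile_id", sort=True):
        hits = dict(zip(grp["genome_id"], grp["copy_count"].astype(int)))
        profiles.append(
            MarkerProfile(
                profile_id=str(pid),
                hits=hits,
                mean_copy=float(np.mean(list(hits.values()))),
                mean_len=float(grp["mean_protein_len"].mean()),
                prevalence=len(hits) / len(genome_set),
            )
        )
    return profiles


def select_core_profiles(
    profiles: Iterable[MarkerProfile],
    prev_min: float = 0.10,
    copy_max: float = 1.2,
    len_min: float = 100.0,
) -> list[MarkerProfile]:
    """Core markers: prevalence >= prev_min, mean copy <= copy_max,
    mean protein length strictly > len_min."""
    return [
        p
        for p in profiles
        if p.prevalence >= prev_min and p.mean_copy <= copy_max and p.mean_len > len_min
    ]


def trim_alignment(aln: MarkerAlignment, max_gap_frac: float = 0.5) -> MarkerAlignment:
    """Keep columns whose gap fraction is < max_gap_frac; row order preserved."""
    if not aln.rows:
        raise ValueError("empty alignment")
    genomes = list(aln.rows)
    n_rows = len(genomes)
    keep = []
    for col in range(aln.n_columns):
        gaps = sum(1 for g in genomes if aln.rows[g][col] in GAP_CHARS)
        if gaps / n_rows < max_gap_frac:
            keep.append(col)
    if not keep and aln.n_columns > 0:
        warnings.warn(f"{aln.profile_id}: all columns removed by trimming")
    rows = {g: "".join(aln.rows[g][c] for c in keep) for g in genomes}
    return MarkerAlignment(profile_id=aln.profile_id, rows=rows)


def genome_inclusion(
    genome: str,
    alignments: Iterable[MarkerAlignment],
    min_markers: int = 3,
    min_col_frac: float = 0.05,
) -> bool:
    """Included iff the genome has >= min_markers markers whose row covers
    strictly more than min_col_frac of that marker's columns."""
    n_qualifying = 0
    for aln in alignments:
        row = aln.rows.get(genome)
        if row is None or aln.n_columns == 0:
            continue
        non_gap = sum(1 for ch in row if ch not in GAP_CHARS)
        if non_gap / aln.n_columns > min_col_frac:
            n_qualifying += 1
    return n_qualifying >= min_markers


def nj_tree(distances: np.ndarray, taxa: Sequence[str]) -> Tree:
    """Saitou-Nei neighbour joining.

    Deterministic: ties in the Q criterion are broken by the sorted label
    pair, so the result is invariant to taxon input order. Negative branch
    lengths are clamped to zero.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbour joining requires at least 3 taxa")
    if d.shape != (n, n) or len(taxa) != n:
        raise ValueError("distance matrix / taxa size mismatch")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("distances must be symmetric, non-negative, zero diagonal")

    # each active node holds a newick fragment
    nodes: list[str] = [_quote(t) for t in taxa]
    labels: list[str] = list(taxa)  # for tie-breaking
    dm = d.copy()

    while len(nodes) > 2:
        m = len(nodes)
        r = dm.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                key = (q, tuple(sorted((labels[i], labels[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dm[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new_frag = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        new_label = min(labels[i], labels[j])
        new_row = np.array(
            [0.5 * (dm[i, kk] + dm[j, kk] - dm[i, j]) for kk in range(m)]
        )
        keep = [kk for kk in range(m) if kk not in (i, j)]
        dm = np.vstack([dm[keep][:, keep], np.maximum(new_row[keep], 0.0)])
        last = np.append(np.maximum(new_row[keep], 0.0), 0.0)
        dm = np.hstack([dm, last[:, None]])
        nodes = [nodes[kk] for kk in keep] + [new_frag]
        labels = [labels[kk] for kk in keep] + [new_label]

    newick = f"({nodes[0]}:{max(dm[0, 1], 0.0) / 2:.10g},{nodes[1]}:{max(dm[0, 1], 0.0) / 2:.10g});"
    return parse_newick(newick)


def _quote(label: str) -> str:
    return label.replace(" ", "_")


def patristic_distances(tree: Tree) -> tuple[np.ndarray, list[str]]:
    """Pairwise path-length (sum of branch lengths) matrix over leaves,
    labels sorted. Missing branch lengths are an error."""
    dt = tree.dendropy_tree()
    for edge in dt.preorder_edge_iter():
        if edge.head_node is dt.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a missing branch length")
    pdm = dt.phylogenetic_distance_matrix()
    taxa = sorted(dt.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return out, labels


def p_distance_matrix(
    alignments: Sequence[MarkerAlignment], genomes: Sequence[str]
) -> np.ndarray:
    """Concatenated-marker p-distance: mismatches over shared non-gap columns.

    Pairs sharing no scored column get MAX_P_DISTANCE.
    """
    rows = []
    for g in genomes:
        parts = []
        for aln in alignments:
            parts.append(aln.rows.get(g, "-" * aln.n_columns))
        rows.append("".join(parts))
    n = len(genomes)
    d = np.zeros((n, n))
    arr = [np.frombuffer(r.encode(), dtype=np.uint8) for r in rows]
    gap_codes = {ord(c) for c in GAP_CHARS}
    masks = [~np.isin(a, list(gap_codes)) for a in arr]
    for i in range(n):
        for j in range(i + 1, n):
            shared = masks[i] & masks[j]
            ns = int(shared.sum())
            if ns == 0:
                d[i, j] = d[j, i] = MAX_P_DISTANCE
            else:
                mism = int((arr[i][shared] != arr[j][shared]).sum())
                d[i, j] = d[j, i] = mism / ns
    return d


@dataclass
class IterationResult:
    iteration: int
    core_profiles: list[MarkerProfile]
    included_genomes: list[str]
    tree: Optional[Tree]


def iterate_markers(
    genomes: Sequence[str],
    families: pd.DataFrame,
    alignments: Mapping[str, MarkerAlignment],
    n_iter: int = 5,
    prev_min: float = 0.10,
    copy_max: float = 1.2,
    len_min: float = 100.0,
    min_markers: int = 3,
    min_col_frac: float = 0.05,
    max_gap_frac: float = 0.5,
) -> list[IterationResult]:
    """Five-iteration driver: each round reruns core-marker selection on the
    genomes every earlier round failed to place, so the union of included
    genomes grows monotonically."""
    placed: set[str] = set()
    results: list[IterationResult] = []
    for it in range(1, n_iter + 1):
        remaining = [g for g in genomes if g not in placed]
        if not remaining:
            break
        profiles = compute_profiles(families, remaining)
        core = select_core_profiles(profiles, prev_min, copy_max, len_min)
        if not core:
            break
        trimmed = []
        for p in core:
            aln = alignments.get(p.profile_id)
            if aln is None:
                continue
            sub = MarkerAlignment(
                profile_id=aln.profile_id,
                rows={g: r for g, r in aln.rows.items() if g in set(remaining)},
            )
            if sub.rows:
                trimmed.append(trim_alignment(sub, max_gap_frac))
        included = [
            g for g in remaining if genome_inclusion(g, trimmed, min_markers, min_col_frac)
        ]
        if not included:
            break
        tree = None
        if len(included) >= 3:
            dm = p_distance_matrix(trimmed, included)
            tree = nj_tree(dm, included)
        placed.update(included)
        results.append(
            IterationResult(
                iteration=it,
                core_profiles=core,
                included_genomes=included,
                tree=tree,
            )
        )
    return results
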