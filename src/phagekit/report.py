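"""Summary proportions over pipeline outputs.

Percentages are rounded half-up to two decimals, which reproduces every
count-consistent percentage printed alongside its numerator/denominator
in the source results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Optional, Sequence

import pandas as pd


@dataclass
class ProportionRow:
    label: str
    numerator: int
    denominator: int
    pct: float

    def __post_init__(self) -> None:
        if self.numerator > self.denominator:
            raise ValueError(f"{self.label}: numerator exceeds denominator")


def proportion_pct(numerator: int, denominator: int) -> float:
    """100 * numerator / denominator, rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must be in [0, denominator]")
    frac = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _row(label: str, num: int, den: int) -> ProportionRow:
    return ProportionRow(label, num, den, proportion_pct(num, den))


def build_summary(
    *,
    n_phages: Optional[int] = None,
    triage_decisions: Optional[Sequence] = None,
    clusters: Optional[Sequence] = None,
    code_profiles: Optional[Sequence] = None,
    host_map: Optional[Mapping[str, set]] = None,
    pair_rows: Optional[Sequence[Mapping]] = None,
    cas_systems: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Assemble headline proportion rows from whichever stage outputs are
    available; missing stages are skipped with a warning."""
    rows: list[ProportionRow] = []

    if triage_decisions is not None:
        total = len(triage_decisions)
        if total:
            kept = [d for d in triage_decisions if d.passes_quality]
            rows.append(_row("phage_fraction", len(kept), total))
            for ls in ("virulent", "uncertain", "temperate"):
                rows.append(
                    _row(
                        f"lifestyle_{ls}",
                        sum(1 for d in kept if d.lifestyle == ls),
                        max(len(kept), 1) if kept else 1,
                    )
                )
    else:
        warnings.warn("triage output missing; lifestyle rows omitted")

    if clusters is not None:
        n_clusters = len(clusters)
        if n_clusters:
            rows.append(
                _row(
                    "novel_cluster_fraction",
                    sum(1 for c in clusters if c.is_novel),
                    n_clusters,
                )
            )
            n_genomes = sum(len(c.member_ids) for c in clusters)
            rows.append(
                _row(
                    "genomes_in_novel_clusters",
                    sum(len(c.member_ids) for c in clusters if c.is_novel),
                    n_genomes,
                )
            )
    else:
        warnings.warn("cluster output missing; novelty rows omitted")

    if code_profiles is not None and code_profiles:
        rows.append(
            _row(
                "alt_code_fraction",
                sum(1 for p in code_profiles if p.called_code != 11),
                len(code_profiles),
            )
        )

    if host_map is not None and n_phages:
        assigned = len(host_map)
        rows.append(_row("host_assigned_fraction", assigned, n_phages))
        rows.append(_row("host_unassigned_fraction", n_phages - assigned, n_phages))
        generalists = sum(1 for gs in host_map.values() if len(gs) >= 2)
        specialists = sum(1 for gs in host_map.values() if len(gs) == 1)
        if assigned:
            rows.append(_row("generalist_fraction", generalists, assigned))
            rows.append(_row("specialist_fraction", specialists, assigned))

    if pair_rows is not None and pair_rows:
        total_pairs = len(pair_rows)
        single = sum(1 for r in pair_rows if r["directionality"] == "single_directed")
        rows.append(_row("single_directed_pairs", single, total_pairs))
        rows.append(_row("double_directed_pairs", total_pairs - single, total_pairs))
        rows.append(
            _row(
                "same_host_pairs",
                sum(1 for r in pair_rows if r["same_host"]),
                total_pairs,
            )
        )

    if cas_systems is not None and cas_systems:
        rows.append(
            _row(
                "acquisition_complete_fraction",
                sum(1 for s in cas_systems if s.acquisition_complete),
                len(cas_systems),
            )
        )

    return pd.DataFrame(
        [
            dict(label=r.label, numerator=r.numerator, denominator=r.denominator, pct=r.pct)
            for r in rows
        ]
    )
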