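"""Decision rules that turn annotated contigs into the curated phage set.

Four viral signatures are combined by a configurable >=k-of-4 vote
(the combination rule is exposed in :class:`TriageThresholds` so the
evidence logic stays auditable). Keyword-based phage calling, the
BUSCO/VPF false-positive filter, size/completeness gates and lifestyle
assignment follow fixed published thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from phagekit.io_core import GeneCall, GenomeRecord

#: virus-specific keyword list (case-insensitive substring match)
VIRUS_KEYWORDS = (
    "capsid", "phage", "terminase", "base plate", "baseplate", "prohead",
    "virion", "virus", "viral", "tape measure", "tapemeasure", "neck",
    "tail", "head", "bacteriophage", "prophage", "portal", "dna packaging",
    "t4", "p22", "holin",
)

#: prokaryote-specific exclusion terms
PROKARYOTE_KEYWORDS = (
    "ribosomal protein",
    "preprotein translocase",
    "dna gyrase subunit a",
)


@dataclass
class ContigSignals:
    """Per-contig evidence used by the four-signature viral call."""

    genome_id: str
    n_genes: int
    viral_family_hits: int
    microbial_family_hits: int
    nucleotide_score: float = 0.0
    strand_switch_rate_value: float = 0.0

    def __post_init__(self) -> None:
        if self.viral_family_hits > self.n_genes or self.microbial_family_hits > self.n_genes:
            raise ValueError(f"{self.genome_id}: family hits exceed gene count")
        if not (0.0 <= self.strand_switch_rate_value <= 1.0):
            raise ValueError(f"{self.genome_id}: strand switch rate outside [0,1]")


@dataclass
class TriageThresholds:
    """Thresholds of the four signature predicates and the vote count k."""

    k: int = 2
    min_viral_hits: int = 1
    nucleotide_score_min: float = 0.9
    strand_switch_max: float = 0.25
    strand_min_genes: int = 4


@dataclass
class TriageDecision:
    genome_id: str
    is_viral: bool = False
    is_phage: bool = False
    passes_fp_filter: bool = False
    passes_quality: bool = False
    lifestyle: Optional[str] = None
    reasons: list[str] = field(default_factory=list)


def strand_switch_rate(calls: Sequence[GeneCall]) -> float:
    """Number of strand switches between adjacent genes divided by gene count."""
    if not calls:
        raise ValueError("strand_switch_rate requires at least one gene")
    starts = [c.start for c in calls]
    if starts != sorted(starts):
        raise ValueError("gene calls must be sorted by start coordinate")
    switches = sum(
        1 for a, b in zip(calls, calls[1:]) if a.strand != b.strand
    )
    return switches / len(calls)


def signature_predicates(
    signals: ContigSignals, thresholds: TriageThresholds | None = None
) -> dict[str, bool]:
    """Evaluate the four viral-signature predicates individually."""
    t = thresholds or TriageThresholds()
    return {
        "viral_families_present": (
            signals.viral_family_hits >= t.min_viral_hits
            and signals.microbial_family_hits == 0
        ),
        "viral_nucleotide_signature": signals.nucleotide_score >= t.nucleotide_score_min,
        "same_strand_blocks": (
            signals.strand_switch_rate_value <= t.strand_switch_max
            and signals.n_genes >= t.strand_min_genes
        ),
        "viral_exceed_microbial": signals.viral_family_hits > signals.microbial_family_hits,
    }


def viral_signature_call(
    signals: ContigSignals,
    thresholds: TriageThresholds | None = None,
    reasons: Optional[list[str]] = None,
) -> bool:
    """True iff at least k of the four signature predicates hold."""
    t = thresholds or TriageThresholds()
    preds = signature_predicates(signals, t)
    fired = [name for name, ok in preds.items() if ok]
    if reasons is not None:
        reasons.extend(fired)
    return len(fired) >= t.k


def keyword_phage_call(calls: Iterable[GeneCall], has_spacer_match: bool) -> bool:
    """Keyword rule: >=2 virus-keyword genes, no prokaryote-keyword gene,
    and at least one spacer match from a prokaryotic genome."""
    if not has_spacer_match:
        return False
    n_viral = 0
    for c in calls:
        desc = c.description.lower()
        if any(kw in desc for kw in PROKARYOTE_KEYWORDS):
            return False
        if any(kw in desc for kw in VIRUS_KEYWORDS):
            n_viral += 1
    return n_viral >= 2


def false_positive_filter(n_genes: int, busco_hits: int, vpf_hits: int) -> bool:
    """Keep iff BUSCO ratio < 0.067, else require >=3 VPF hits.

    The boundary ratio == 0.067 is routed to the VPF clause so every
    genome gets a decision.
    """
    if n_genes <= 0:
        raise ValueError("false_positive_filter requires n_genes > 0")
    if busco_hits > n_genes:
        raise ValueError("busco_hits exceeds gene count")
    ratio = busco_hits / n_genes
    if ratio < 0.067:
        return True
    return vpf_hits >= 3


def apply_quality_filters(
    genome: GenomeRecord, min_len: int = 3000, min_completeness: float = 50.0
) -> bool:
    """Keep iff genome length >= min_len and completeness >= min_completeness.

    Missing completeness counts as failure.
    """
    if len(genome.seq) < min_len:
        return False
    if genome.completeness is None:
        return False
    return genome.completeness >= min_completeness


def lifestyle_assign(score: float, provirus: bool) -> str:
    """virulent (<0.5) / uncertain (0.5-0.9) / temperate (>0.9); a detected
    provirus is temperate regardless of score."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"lifestyle score {score} outside [0, 1]")
    if provirus:
        return "temperate"
    if score < 0.5:
        return "virulent"
    if score <= 0.9:
        return "uncertain"
    return "temperate"


def triage_genome(
    genome: GenomeRecord,
    calls: Sequence[GeneCall],
    *,
    nucleotide_score: float = 0.0,
    has_spacer_match: bool = False,
    busco_hits: int = 0,
    vpf_hits: int = 0,
    thresholds: TriageThresholds | None = None,
) -> TriageDecision:
    """Run the full decision cascade for one genome."""
    calls = sorted(calls, key=lambda c: c.start)
    d = TriageDecision(genome_id=genome.id)
    n_genes = len(calls)
    ssr = strand_switch_rate(calls) if calls else 0.0
    signals = ContigSignals(
        genome_id=genome.id,
        n_genes=n_genes,
        viral_family_hits=sum(1 for c in calls if c.source_db == "viral_family"),
        microbial_family_hits=sum(1 for c in calls if c.source_db == "microbial_family"),
        nucleotide_score=nucleotide_score,
        strand_switch_rate_value=ssr,
    )
    d.is_viral = viral_signature_call(signals, thresholds, d.reasons)
    keyword_ok = keyword_phage_call(calls, has_spacer_match)
    if keyword_ok:
        d.reasons.append("keyword_rule")
    d.is_phage = d.is_viral and keyword_ok
    if n_genes > 0:
        d.passes_fp_filter = false_positive_filter(n_genes, busco_hits, vpf_hits)
    d.passes_quality = d.is_phage and d.passes_fp_filter and apply_quality_filters(genome)
    if d.passes_quality:
        score = genome.lifestyle_score if genome.lifestyle_score is not None else 0.0
        d.lifestyle = lifestyle_assign(score, genome.provirus)
    return d
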