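"""Seeded generator of a phage-host community with planted ground truth.

Every downstream stage (triage, clustering, code calling, divergence,
CRISPR networks) can be validated against the planted truth without any
external data. A single integer seed drives one numpy Generator and the
generation order is fixed, so identical config+seed gives byte-identical
output.

Construction order matters for exactness guarantees: genome substitutions
are applied BEFORE spacers are sampled, so planted spacer/protospacer
relations are exact up to the explicit ``spacer_mismatch_rate`` control.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from phagekit.io_core import GenomeRecord, GeneCall, revcomp, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# descriptions seen on planted phage genes (each carries >=1 term from the
# virus-specific keyword list used by triage)
VIRAL_DESCRIPTIONS = [
    "major capsid protein",
    "terminase large subunit",
    "portal protein",
    "tail fiber protein",
    "baseplate wedge subunit",
    "tape measure protein",
    "prohead maturation protease",
    "virion structural protein",
    "DNA packaging protein",
    "holin class I",
]

PROKARYOTE_DESCRIPTIONS = [
    "30S ribosomal protein S1",
    "50S ribosomal protein L2",
    "preprotein translocase subunit SecY",
    "DNA gyrase subunit A",
]

NEUTRAL_DESCRIPTIONS = [
    "hypothetical protein",
    "ATP-binding protein",
    "membrane protein",
    "glycosyltransferase",
]

HOST_GENERA = [
    "Bacteroides",
    "Prevotella",
    "Escherichia",
    "Klebsiella",
    "Lactobacillus",
    "Clostridium",
]

# stop-codon sets per genetic code id; alternative codes each reassign one stop
STOP_SETS = {
    11: ("TAA", "TAG", "TGA"),
    15: ("TAA", "TGA"),  # TAG recoded
    90: ("TAG", "TGA"),  # TAA recoded
    91: ("TAA", "TAG"),  # TGA recoded
}
RECODED_STOP = {15: "TAG", 90: "TAA", 91: "TGA"}


@dataclass
class CommunityConfig:
    """Parameters of the planted community. All fractions in [0,1]."""

    n_phages: int = 40
    n_hosts: int = 10
    phage_len: tuple[int, int] = (8000, 12000)
    host_len: tuple[int, int] = (20000, 30000)
    n_species_groups: int = 10
    within_species_sub_rate: float = 0.02
    n_genus_groups: int = 4
    habitats: tuple[str, ...] = ("gut", "soil")
    habitat_extra_sub_rate: float = 0.05
    divergent_genus_frac: float = 0.5
    frac_recode: float = 0.0
    spacer_len: int = 32
    spacers_per_host_array: int = 3
    spacer_mismatch_rate: float = 0.0
    frac_phage_with_array: float = 0.0
    spacers_per_phage_array: int = 2
    repeat_len: int = 30
    gene_len: int = 300
    gene_gap: int = 50
    gene_strand_switch_rate: float = 0.1
    frac_reference: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "within_species_sub_rate",
            "habitat_extra_sub_rate",
            "divergent_genus_frac",
            "frac_recode",
            "spacer_mismatch_rate",
            "frac_phage_with_array",
            "frac_reference",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_phages", "n_hosts", "n_species_groups", "n_genus_groups"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spacer_len >= self.phage_len[0]:
            raise ValueError("spacer_len must be shorter than the smallest phage genome")
        if not self.habitats:
            raise ValueError("at least one habitat label required")


@dataclass
class GroundTruth:
    """Planted assignments and interaction links."""

    species_assignment: dict[str, str] = field(default_factory=dict)
    genus_assignment: dict[str, str] = field(default_factory=dict)
    genus_divergent: dict[str, bool] = field(default_factory=dict)
    code_assignment: dict[str, int] = field(default_factory=dict)
    # (host_id, phage_id, spacer_id, planted_mismatches)
    host_links: list[tuple[str, str, str, int]] = field(default_factory=list)
    # (source_phage, target_phage, spacer_id, planted_mismatches)
    phage_links: list[tuple[str, str, str, int]] = field(default_factory=list)


@dataclass
class Community:
    """Generated genomes, annotations, metadata table and planted truth."""

    config: CommunityConfig
    phages: list[GenomeRecord]
    hosts: list[GenomeRecord]
    gene_calls: list[GeneCall]
    metadata: pd.DataFrame  # one row per genome (phages then hosts)
    truth: GroundTruth
    # phage_id -> (array_start_1based, array_end_1based) for planted arrays
    phage_array_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    host_array_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _mutate_positions(rng: np.random.Generator, seq: str, positions) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for i in positions:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


# Gene-cassette grammar for phage genomes. Codons are drawn from the eight
# pyrimidine-only triplets: no start codon (ATG/GTG/TTG) and no forward
# triple whose reverse complement is a start (CAT/CAC/CAA) can arise in any
# frame, inside cassettes or across junctions. ORFs therefore exist only
# where planted: from a cassette's ATG head to its terminator. This makes
# coding density a clean, controllable function of the stop-codon set.
_CT_CODONS = ["CCC", "CCT", "CTC", "CTT", "TCC", "TCT", "TTC", "TTT"]
_CT_CODONS_ENDC = ["CCC", "CTC", "TCC", "TTC"]


def _terminator(rng: np.random.Generator) -> str:
    """In-frame stop under every code within 9 nt: TGA stops codes 11/15/90
    immediately and TAA stops code 91 two codons later. The pyrimidine
    codons in between are random so terminators do not repeat genome-wide.
    """
    r1 = _CT_CODONS[rng.integers(0, 8)]
    r2 = _CT_CODONS[rng.integers(0, 8)]
    return "TGA" + r1 + "TAA" + r2 + "TAG"


def _ct_filler(rng: np.random.Generator, lo: int = 30, hi: int = 60) -> str:
    n = int(rng.integers(lo, hi + 1))
    body = "".join("CT"[b] for b in rng.integers(0, 2, n - 1))
    return body + "T"  # last char T keeps the following ATG head junction safe


def _coded_genome(rng: np.random.Generator, length: int, recoded_stop=None) -> str:
    """Genome of gene cassettes separated by stop-free pyrimidine filler.

    Without ``recoded_stop`` each cassette is one long ORF under every
    stop-codon set (the terminator stops all codes), so the standard code
    is never beaten. With ``recoded_stop`` every 8th codon is that stop,
    shredding the cassette into sub-threshold fragments under any code
    that still treats it as a stop — only the reassigned code sees the
    full-length ORFs.
    """
    parts: list[str] = []
    total = 0
    while total < length:
        filler = _ct_filler(rng)
        n_codons = int(rng.integers(250, 350))
        codons = []
        for j in range(n_codons):
            if recoded_stop is not None and j % 8 == 7:
                codons[-1] = _CT_CODONS_ENDC[rng.integers(0, 4)]  # pre-stop ends in C
                codons.append(recoded_stop)
            else:
                codons.append(_CT_CODONS[rng.integers(0, 8)])
        codons[-1] = _CT_CODONS_ENDC[rng.integers(0, 4)]
        cassette = "ATG" + "".join(codons) + _terminator(rng)
        parts.append(filler)
        parts.append(cassette)
        total += len(filler) + len(cassette)
    return "".join(parts)[:length]


def _make_gene_calls(
    rng: np.random.Generator, genome_id: str, glen: int, cfg: CommunityConfig, kind: str
) -> list[GeneCall]:
    """Tile genes along a genome with a configurable strand-switch rate.

    Planted phages always carry >=2 virus-keyword genes and no prokaryote
    keywords; hosts carry ribosomal/gyrase genes plus BUSCO-class hits.
    """
    calls: list[GeneCall] = []
    pos = 1
    strand = "+" if rng.random() < 0.5 else "-"
    idx = 0
    while pos + cfg.gene_len - 1 <= glen:
        if idx > 0 and rng.random() < cfg.gene_strand_switch_rate:
            strand = "-" if strand == "+" else "+"
        if kind == "phage":
            if idx < 2 or idx % 3 != 2:
                desc = VIRAL_DESCRIPTIONS[idx % len(VIRAL_DESCRIPTIONS)]
                src = "viral_family"
            else:
                desc = NEUTRAL_DESCRIPTIONS[idx % len(NEUTRAL_DESCRIPTIONS)]
                src = "none"
        else:
            if idx % 3 == 0:
                desc = PROKARYOTE_DESCRIPTIONS[idx % len(PROKARYOTE_DESCRIPTIONS)]
                src = "busco" if idx % 6 == 0 else "microbial_family"
            else:
                desc = NEUTRAL_DESCRIPTIONS[idx % len(NEUTRAL_DESCRIPTIONS)]
                src = "none"
        calls.append(
            GeneCall(
                genome_id=genome_id,
                start=pos,
                end=pos + cfg.gene_len - 1,
                strand=strand,
                source_db=src,
                description=desc,
            )
        )
        pos += cfg.gene_len + cfg.gene_gap
        idx += 1
    return calls


def _sample_protospacer(
    rng: np.random.Generator,
    target_seq: str,
    base_len: int,
    spacer_len: int,
    orient_rc: bool,
    first_char_avoid: Optional[str],
) -> tuple[str, int]:
    """Pick a protospacer from the target's pre-array region.

    ``first_char_avoid`` forces the extracted spacer to start with a
    different base, which keeps repeat boundaries unambiguous for the
    array detector (no shared flanking base across spacers).
    """
    for _ in range(200):
        start = int(rng.integers(0, base_len - spacer_len + 1))
        proto = target_seq[start : start + spacer_len]
        spacer = revcomp(proto) if orient_rc else proto
        if first_char_avoid is None or (
            spacer[0] != first_char_avoid and spacer[-1] != first_char_avoid
        ):
            return spacer, start
    raise RuntimeError("could not sample a boundary-distinct protospacer")


def generate_community(config: CommunityConfig) -> Community:
    """Build the community deterministically from ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    n_recode = int(round(cfg.frac_recode * cfg.n_phages))
    n_normal = cfg.n_phages - n_recode
    n_groups = min(cfg.n_species_groups, n_normal) if n_normal else 0

    # --- species-group membership (round robin) -------------------------
    group_members: list[list[int]] = [[] for _ in range(n_groups)]
    for i in range(n_normal):
        group_members[i % n_groups].append(i)

    n_div = int(round(cfg.divergent_genus_frac * cfg.n_genus_groups))
    genus_of_group = {g: f"genus_{g % max(cfg.n_genus_groups, 1)}" for g in range(n_groups)}
    for gg in range(cfg.n_genus_groups):
        truth.genus_divergent[f"genus_{gg}"] = gg < n_div

    phages: list[GenomeRecord] = []
    base_seqs: dict[str, str] = {}
    habitats_of: dict[str, str] = {}

    for g, members in enumerate(group_members):
        root_len = int(rng.integers(cfg.phage_len[0], cfg.phage_len[1] + 1))
        root = _coded_genome(rng, root_len)
        genus = genus_of_group[g]
        divergent = truth.genus_divergent[genus]
        # habitat-specific substitution masks shared by same-habitat members
        habitat_variants: dict[str, str] = {}
        if divergent and cfg.habitat_extra_sub_rate > 0:
            for hab in cfg.habitats:
                habitat_variants[hab] = _mutate(rng, root, cfg.habitat_extra_sub_rate)
        for j, m in enumerate(members):
            pid = f"phage_{m:04d}"
            hab = cfg.habitats[j % len(cfg.habitats)]
            backbone = habitat_variants.get(hab, root)
            # first member is the (habitat-adjusted) root itself, so member-to-root
            # identity is 100*(1 - within_species_sub_rate) in expectation
            if j == 0:
                seq = backbone
            else:
                seq = _mutate(rng, backbone, cfg.within_species_sub_rate)
            phages.append(GenomeRecord(id=pid, seq=seq, habitat=hab))
            base_seqs[pid] = seq
            habitats_of[pid] = hab
            truth.species_assignment[pid] = f"species_{g}"
            truth.genus_assignment[pid] = genus
            truth.code_assignment[pid] = 11

    alt_cycle = [15, 90, 91]
    for r in range(n_recode):
        pid = f"phage_{n_normal + r:04d}"
        code = alt_cycle[r % 3]
        seq = _coded_genome(rng, cfg.phage_len[0], RECODED_STOP[code])
        hab = cfg.habitats[r % len(cfg.habitats)]
        phages.append(GenomeRecord(id=pid, seq=seq, habitat=hab))
        base_seqs[pid] = seq
        habitats_of[pid] = hab
        truth.species_assignment[pid] = f"species_recode_{r}"
        truth.genus_assignment[pid] = f"genus_{r % max(cfg.n_genus_groups, 1)}"
        truth.code_assignment[pid] = code

    phage_ids = [p.id for p in phages]

    # --- phage-carried CRISPR arrays (phage->phage targeting) -----------
    n_pa = int(round(cfg.frac_phage_with_array * cfg.n_phages))
    array_carriers = phage_ids[:n_pa]
    phage_array_seqs: dict[str, str] = {}
    spacer_counter = 0
    pp_planted: list[tuple[str, str, str, int]] = []
    for ci, src in enumerate(array_carriers):
        repeat = _random_dna(rng, cfg.repeat_len)
        spacers: list[str] = []
        first_char: Optional[str] = None
        targets: list[str] = []
        # round-robin over phages outside the carrier's species group
        candidates = [
            t
            for t in phage_ids
            if t != src
            and truth.species_assignment[t] != truth.species_assignment[src]
        ]
        if not candidates:
            continue
        for s in range(cfg.spacers_per_phage_array):
            tgt = candidates[(ci + s) % len(candidates)]
            trec = next(p for p in phages if p.id == tgt)
            spacer, _start = _sample_protospacer(
                rng,
                trec.seq,
                len(trec.seq),
                cfg.spacer_len,
                orient_rc=(s % 2 == 1),
                first_char_avoid=first_char,
            )
            if first_char is None:
                first_char = spacer[0]
            mm = 1 if rng.random() < cfg.spacer_mismatch_rate else 0
            if mm:
                pos = int(rng.integers(0, cfg.spacer_len))
                spacer = _mutate_positions(rng, spacer, [pos])
            sp_id = f"psp_{spacer_counter:05d}"
            spacer_counter += 1
            spacers.append(spacer)
            targets.append(tgt)
            pp_planted.append((src, tgt, sp_id, mm))
        phage_array_seqs[src] = repeat + "".join(sp + repeat for sp in spacers)

    community_arrays: dict[str, tuple[int, int]] = {}
    for i, p in enumerate(phages):
        if p.id in phage_array_seqs:
            arr = phage_array_seqs[p.id]
            start = len(p.seq) + 1
            phages[i] = GenomeRecord(id=p.id, seq=p.seq + arr, habitat=p.habitat)
            community_arrays[p.id] = (start, start + len(arr) - 1)

    # --- host genomes with arrays sampling phage protospacers -----------
    hosts: list[GenomeRecord] = []
    host_array_intervals: dict[str, tuple[int, int]] = {}
    host_planted: list[tuple[str, str, str, int]] = []
    tgt_cursor = 0
    for h in range(cfg.n_hosts):
        hid = f"host_{h:03d}"
        genus = HOST_GENERA[h % len(HOST_GENERA)]
        base = _random_dna(rng, int(rng.integers(cfg.host_len[0], cfg.host_len[1] + 1)))
        repeat = _random_dna(rng, cfg.repeat_len)
        spacers = []
        first_char = None
        for s in range(cfg.spacers_per_host_array):
            if not phage_ids:
                break
            tgt = phage_ids[tgt_cursor % len(phage_ids)]
            tgt_cursor += 1
            trec = next(p for p in phages if p.id == tgt)
            base_len = len(base_seqs[tgt])  # avoid the phage's own array region
            spacer, _start = _sample_protospacer(
                rng, trec.seq, base_len, cfg.spacer_len,
                orient_rc=(s % 2 == 1), first_char_avoid=first_char,
            )
            if first_char is None:
                first_char = spacer[0]
            mm = 1 if rng.random() < cfg.spacer_mismatch_rate else 0
            if mm:
                pos = int(rng.integers(0, cfg.spacer_len))
                spacer = _mutate_positions(rng, spacer, [pos])
            sp_id = f"hsp_{spacer_counter:05d}"
            spacer_counter += 1
            spacers.append(spacer)
            host_planted.append((hid, tgt, sp_id, mm))
        array = repeat + "".join(sp + repeat for sp in spacers) if spacers else ""
        seq = base + array
        if array:
            host_array_intervals[hid] = (len(base) + 1, len(seq))
        hosts.append(
            GenomeRecord(id=hid, seq=seq, habitat=cfg.habitats[h % len(cfg.habitats)],
                         host_taxon=genus)
        )

    # --- expand links to identical-sequence clones (exact at rate 0) ----
    clones: dict[str, list[str]] = {}
    for pid, bs in base_seqs.items():
        clones.setdefault(bs, []).append(pid)

    def _expand(links, forbid_self: bool):
        out = []
        seen = set()
        for src, tgt, sp, mm in links:
            for alt in clones[base_seqs[tgt]]:
                if forbid_self and alt == src:
                    continue
                key = (src, alt, sp)
                if key not in seen:
                    seen.add(key)
                    out.append((src, alt, sp, mm))
        return out

    truth.host_links = _expand(host_planted, forbid_self=False)
    truth.phage_links = _expand(pp_planted, forbid_self=True)

    # --- gene calls and metadata ----------------------------------------
    gene_calls: list[GeneCall] = []
    for p in phages:
        gene_calls.extend(_make_gene_calls(rng, p.id, len(p.seq), cfg, "phage"))
    for hrec in hosts:
        gene_calls.extend(_make_gene_calls(rng, hrec.id, len(hrec.seq), cfg, "host"))

    spacer_matched = {tgt for (_h, tgt, _s, _m) in truth.host_links}
    ref_groups: set[str] = set()
    for g in range(n_groups):
        if rng.random() < cfg.frac_reference:
            ref_groups.add(f"species_{g}")

    rows = []
    for p in phages:
        sp_group = truth.species_assignment[p.id]
        in_ref = sp_group in ref_groups
        rows.append(
            dict(
                genome_id=p.id,
                kind="phage",
                length=len(p.seq),
                habitat=p.habitat,
                completeness=100.0,
                lifestyle_score=round(float(rng.random()), 4),
                provirus=False,
                in_reference=in_ref,
                nucleotide_score=round(float(0.9 + 0.1 * rng.random()), 4),
                spacer_match=p.id in spacer_matched,
                host_taxon="",
            )
        )
        p.completeness = 100.0
        p.in_reference = in_ref
    for hrec in hosts:
        rows.append(
            dict(
                genome_id=hrec.id,
                kind="host",
                length=len(hrec.seq),
                habitat=hrec.habitat,
                completeness=100.0,
                lifestyle_score=0.0,
                provirus=False,
                in_reference=False,
                nucleotide_score=round(float(0.1 * rng.random()), 4),
                spacer_match=False,
                host_taxon=hrec.host_taxon,
            )
        )
    metadata = pd.DataFrame(rows)

    return Community(
        config=cfg,
        phages=phages,
        hosts=hosts,
        gene_calls=gene_calls,
        metadata=metadata,
        truth=truth,
        phage_array_intervals=community_arrays,
        host_array_intervals=host_array_intervals,
    )


def write_community(community: Community, outdir: str) -> None:
    """Write genomes.fasta, hosts.fasta, gene_calls.tsv, metadata.tsv and
    ground_truth/*.tsv under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    gt_dir = os.path.join(outdir, "ground_truth")
    os.makedirs(gt_dir, exist_ok=True)

    write_fasta(community.phages, os.path.join(outdir, "genomes.fasta"))
    if community.hosts:
        write_fasta(community.hosts, os.path.join(outdir, "hosts.fasta"))

    pd.DataFrame(
        [
            dict(
                genome_id=c.genome_id,
                start=c.start,
                end=c.end,
                strand=c.strand,
                source_db=c.source_db,
                description=c.description,
            )
            for c in community.gene_calls
        ]
    ).to_csv(os.path.join(outdir, "gene_calls.tsv"), sep="\t", index=False)
    community.metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)

    t = community.truth
    pd.DataFrame(
        sorted(t.species_assignment.items()), columns=["genome_id", "species_group"]
    ).to_csv(os.path.join(gt_dir, "species.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            (g, t.genus_assignment[g], t.genus_divergent[t.genus_assignment[g]])
            for g in sorted(t.genus_assignment)
        ],
        columns=["genome_id", "genus_group", "divergent"],
    ).to_csv(os.path.join(gt_dir, "genus.tsv"), sep="\t", index=False)
    pd.DataFrame(
        sorted(t.code_assignment.items()), columns=["genome_id", "genetic_code"]
    ).to_csv(os.path.join(gt_dir, "codes.tsv"), sep="\t", index=False)
    pd.DataFrame(
        t.host_links, columns=["host_id", "phage_id", "spacer_id", "planted_mismatches"]
    ).to_csv(os.path.join(gt_dir, "host_links.tsv"), sep="\t", index=False)
    pd.DataFrame(
        t.phage_links,
        columns=["source_phage", "target_phage", "spacer_id", "planted_mismatches"],
    ).to_csv(os.path.join(gt_dir, "phage_links.tsv"), sep="\t", index=False)
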