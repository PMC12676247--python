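import numpy as np
import pytest

from phagekit.crispr import (
    CasSystem,
    CrisprArray,
    Spacer,
    assign_hosts,
    build_host_edges,
    build_phage_network,
    cas_acquisition_status,
    classify_host_range,
    classify_pairs,
    detect_crispr_arrays,
    match_spacer,
)
from phagekit.io_core import GenomeRecord, revcomp

from conftest import random_dna


def brute_force_matches(spacer_seq, genome_seq, max_mm=1):
    """Oracle: Hamming scan over every offset and both strands."""
    out = []
    L = len(spacer_seq)
    for strand, s in (("+", spacer_seq), ("-", revcomp(spacer_seq))):
        for off in range(len(genome_seq) - L + 1):
            mm = 0
            for a, b in zip(s, genome_seq[off : off + L]):
                if a != b or a == "N" or b == "N":
                    mm += 1
                    if mm > max_mm:
                        break
            else:
                out.append((off + 1, strand, mm))
    return sorted(out)


def _planted_array_genome(rng, n_repeats=4, repeat_len=30, spacer_len=32):
    repeat = random_dna(rng, repeat_len)
    spacers = []
    for i in range(n_repeats - 1):
        sp = list(random_dna(rng, spacer_len))
        sp[0] = "ACGT"[i % 4]  # distinct boundary bases keep repeat maximal
        sp[-1] = "ACGT"[(i + 1) % 4]
        spacers.append("".join(sp))
    array = repeat + "".join(s + repeat for s in spacers)
    left = random_dna(rng, 2000)
    right = random_dna(rng, 2000)
    return left + array + right, repeat, spacers, len(left) + 1


class TestDetectArrays:
    def test_planted_array_recovered_verbatim(self, rng):
        seq, repeat, spacers, start = _planted_array_genome(rng)
        arrays = detect_crispr_arrays(GenomeRecord("g", seq))
        assert len(arrays) == 1
        arr = arrays[0]
        assert arr.repeat_seq == repeat
        assert [s.seq for s in arr.spacers] == spacers
        assert arr.start == start

    def test_random_sequence_rarely_fires(self):
        fired = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            g = GenomeRecord("g", random_dna(r, 10000))
            fired += bool(detect_crispr_arrays(g))
        assert fired <= 1  # >= 99% of replicates clean

    def test_two_repeat_copies_no_array(self, rng):
        repeat = random_dna(rng, 30)
        spacer = random_dna(rng, 32)
        seq = random_dna(rng, 1000) + repeat + spacer + repeat + random_dna(rng, 1000)
        assert detect_crispr_arrays(GenomeRecord("g", seq)) == []

    def test_spacer_count_invariant(self, rng):
        seq, _, spacers, _ = _planted_array_genome(rng, n_repeats=5)
        (arr,) = detect_crispr_arrays(GenomeRecord("g", seq))
        assert len(arr.spacers) == len(arr.positions) - 1 == 4


class TestMatchSpacer:
    def test_exact_substring(self, rng):
        g = random_dna(rng, 500)
        sp = Spacer("s", "h", g[100:132])
        matches = match_spacer(sp, GenomeRecord("g", g))
        assert any(m.start == 101 and m.mismatches == 0 for m in matches)

    def test_two_mismatches_rejected(self, rng):
        g = random_dna(rng, 300)
        sub = list(g[50:82])
        for i in (3, 20):
            sub[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[i]]
        matches = match_spacer(Spacer("s", "h", "".join(sub)), GenomeRecord("g", g))
        assert all(not (m.start == 51) for m in matches)

    def test_revcomp_with_one_mismatch(self, rng):
        g = random_dna(rng, 400)
        sub = list(g[200:232])
        sub[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sub[10]]
        sp = Spacer("s", "h", revcomp("".join(sub)))
        matches = match_spacer(sp, GenomeRecord("g", g))
        assert any(m.start == 201 and m.strand == "-" and m.mismatches == 1
                   for m in matches)

    def test_n_never_matches(self):
        g = GenomeRecord("g", "AAAANAAAA" + "CGCGCGCGCG")
        sp = Spacer("s", "h", "AAAANAAAA")
        # N-vs-N and N-vs-base both count as mismatches: best placement has
        # exactly 1 mismatch (the N column), none with 0
        matches = match_spacer(sp, g, max_mm=1)
        assert all(m.mismatches >= 1 for m in matches)

    def test_agrees_with_brute_force(self, rng):
        for _ in range(200):
            g = random_dna(rng, 150)
            L = int(rng.integers(20, 40))
            if rng.random() < 0.5:
                start = int(rng.integers(0, 150 - L))
                sp = list(g[start : start + L])
                for i in rng.choice(L, int(rng.integers(0, 3)), replace=False):
                    sp[i] = "ACGT"[int(rng.integers(0, 4))]
                sp = "".join(sp)
            else:
                sp = random_dna(rng, L)
            got = sorted(
                (m.start, m.strand, m.mismatches)
                for m in match_spacer(Spacer("s", "h", sp), GenomeRecord("g", g))
            )
            assert got == brute_force_matches(sp, g)

    def test_spacer_longer_than_genome_error(self):
        with pytest.raises(ValueError):
            match_spacer(Spacer("s", "h", "ACGTACGTAC"), GenomeRecord("g", "ACGT"))


def _edge_list(pairs):
    from phagekit.crispr import InteractionEdge

    return [
        InteractionEdge(src, tgt, f"sp{i}", 0, 1, "+", "host_phage")
        for i, (src, tgt) in enumerate(pairs)
    ]


class TestAssignHosts:
    def test_genus_dedup(self):
        edges = _edge_list([("h1", "p1"), ("h2", "p1")])
        taxa = {"h1": "Bacteroides", "h2": "Bacteroides"}
        assert assign_hosts(edges, taxa) == {"p1": {"Bacteroides"}}

    def test_two_genera(self):
        edges = _edge_list([("h1", "p1"), ("h2", "p1")])
        taxa = {"h1": "Bacteroides", "h2": "Prevotella"}
        assert assign_hosts(edges, taxa)["p1"] == {"Bacteroides", "Prevotella"}

    def test_missing_genus_error(self):
        with pytest.raises(ValueError, match="h1"):
            assign_hosts(_edge_list([("h1", "p1")]), {})


class TestHostRange:
    def test_specialist(self):
        assert classify_host_range({"p": {"Bacteroides"}}) == {"p": "specialist"}

    def test_generalist(self):
        out = classify_host_range({"p": {"Bacteroides", "Prevotella"}})
        assert out == {"p": "generalist"}

    def test_boundary_flip(self):
        assert classify_host_range({"p": {"A"}})["p"] == "specialist"
        assert classify_host_range({"p": {"A", "B"}})["p"] == "generalist"

    def test_empty_set_error(self):
        with pytest.raises(ValueError):
            classify_host_range({"p": set()})


def _array_with(genome_id, repeat, spacers, start):
    pos = []
    p = start
    for _ in range(len(spacers) + 1):
        pos.append(p)
        p += len(repeat) + (len(spacers[0]) if spacers else 0)
    end = start + len(repeat) * (len(spacers) + 1) + sum(len(s) for s in spacers) - 1
    return CrisprArray(
        genome_id=genome_id,
        repeat_seq=repeat,
        positions=pos,
        spacers=[Spacer(f"{genome_id}|sp{i}", genome_id, s, "phage")
                 for i, s in enumerate(spacers)],
        start=start,
        end=end,
    )


class TestPhageNetwork:
    def _genomes(self, rng):
        a = random_dna(rng, 2000)
        b = random_dna(rng, 2000)
        return a, b

    def test_single_directed_edge(self, rng):
        a, b = self._genomes(rng)
        spacer = b[500:532]
        arr = _array_with("A", random_dna(rng, 30), [spacer], 100)
        ga, gb = GenomeRecord("A", a), GenomeRecord("B", b)
        edges, graph = build_phage_network([arr], [ga, gb])
        assert {(e.source, e.target) for e in edges} == {("A", "B")}
        assert not graph.has_edge("B", "A")

    def test_reciprocal_edges(self, rng):
        a, b = self._genomes(rng)
        arr_a = _array_with("A", random_dna(rng, 30), [b[500:532]], 100)
        arr_b = _array_with("B", random_dna(rng, 30), [a[700:732]], 100)
        edges, graph = build_phage_network(
            [arr_a, arr_b], [GenomeRecord("A", a), GenomeRecord("B", b)]
        )
        assert graph.has_edge("A", "B") and graph.has_edge("B", "A")

    def test_shared_array_content_excluded(self, rng):
        # A and B carry the same spacer; the only place A's spacer matches B
        # is inside B's own array -> shared immunity, no edge
        shared = random_dna(rng, 32)
        rep_a, rep_b = random_dna(rng, 30), random_dna(rng, 30)
        a_seq = random_dna(rng, 1000) + rep_a + shared + rep_a + shared[::-1] + rep_a
        b_start = 1000
        b_seq = random_dna(rng, b_start) + rep_b + shared + rep_b + random_dna(rng, 32) + rep_b
        arr_a = _array_with("A", rep_a, [shared], 1001)
        arr_b = _array_with("B", rep_b, [shared], b_start + 1)
        arr_b.end = len(b_seq)
        edges, _ = build_phage_network(
            [arr_a, arr_b], [GenomeRecord("A", a_seq), GenomeRecord("B", b_seq)]
        )
        assert not any(e.source == "A" and e.target == "B" for e in edges)

    def test_self_matches_excluded(self, rng):
        a = random_dna(rng, 2000)
        arr = _array_with("A", random_dna(rng, 30), [a[50:82]], 500)
        edges, _ = build_phage_network([arr], [GenomeRecord("A", a)])
        assert edges == []


class TestClassifyPairs:
    def _graph(self, edges):
        import networkx as nx

        g = nx.DiGraph()
        g.add_edges_from(edges)
        return g

    def test_single_directed(self):
        rows = classify_pairs(self._graph([("A", "B")]), {})
        assert rows[0]["directionality"] == "single_directed"

    def test_double_directed(self):
        rows = classify_pairs(self._graph([("A", "B"), ("B", "A")]), {})
        assert len(rows) == 1
        assert rows[0]["directionality"] == "double_directed"

    def test_same_host_intersection(self):
        host_map = {"A": {"Bacteroides"}, "B": {"Bacteroides", "Prevotella"}}
        rows = classify_pairs(self._graph([("A", "B")]), host_map)
        assert rows[0]["same_host"] is True

    def test_no_host_overlap(self):
        host_map = {"A": {"Escherichia"}, "B": {"Prevotella"}}
        rows = classify_pairs(self._graph([("A", "B")]), host_map)
        assert rows[0]["same_host"] is False


class TestCasStatus:
    def test_complete(self):
        s = cas_acquisition_status(CasSystem("g", "I-C", ["cas1", "cas2", "cas7", "cas8"]))
        assert s.acquisition_complete is True

    def test_incomplete_no_acquisition(self):
        assert cas_acquisition_status(CasSystem("g", "I-F", ["cas3", "cas7"])).acquisition_complete is False

    def test_cas1_only_incomplete(self):
        assert cas_acquisition_status(CasSystem("g", "II-C", ["cas1"])).acquisition_complete is False

    def test_case_insensitive(self):
        assert cas_acquisition_status(CasSystem("g", "I-C", ["Cas1", "CAS2"])).acquisition_complete is True


class TestCommunityRecovery:
    def test_networks_match_planted_truth(self, exact_community):
        c = exact_community
        host_arrays = [a for h in c.hosts for a in detect_crispr_arrays(h)]
        phage_arrays = [a for p in c.phages for a in detect_crispr_arrays(p)]
        by_genome = {}
        for a in phage_arrays:
            by_genome.setdefault(a.genome_id, []).append(a)
        hedges = build_host_edges(host_arrays, c.phages, phage_arrays=by_genome)
        assert {(e.source, e.target) for e in hedges} == {
            (h, p) for h, p, _s, _m in c.truth.host_links
        }
        pedges, _ = build_phage_network(phage_arrays, c.phages)
        assert {(e.source, e.target) for e in pedges} == {
            (s, t) for s, t, _sp, _m in c.truth.phage_links
        }

    def test_edges_satisfy_contract_on_reverification(self, exact_community):
        c = exact_community
        seqs = {p.id: p for p in c.phages}
        host_arrays = [a for h in c.hosts for a in detect_crispr_arrays(h)]
        spacer_by_id = {s.spacer_id: s for a in host_arrays for s in a.spacers}
        hedges = build_host_edges(host_arrays, c.phages, exclude_array_hits=False)
        for e in hedges:
            sp = spacer_by_id[e.spacer_id]
            brute = brute_force_matches(sp.seq, seqs[e.target].seq)
            assert (e.target_start, e.target_strand, e.mismatches) in brute

    def test_planted_mismatch_one_still_recovered(self):
        from phagekit.synthetic import CommunityConfig, generate_community

        cfg = CommunityConfig(
            n_phages=8, n_hosts=3, phage_len=(4000, 5000), host_len=(8000, 9000),
            n_species_groups=8, within_species_sub_rate=0.0,
            divergent_genus_frac=0.0, spacer_mismatch_rate=1.0,
            spacers_per_host_array=3, seed=21,
        )
        c = generate_community(cfg)
        host_arrays = [a for h in c.hosts for a in detect_crispr_arrays(h)]
        hedges = build_host_edges(host_arrays, c.phages)
        got = {(e.source, e.target) for e in hedges}
        want = {(h, p) for h, p, _s, _m in c.truth.host_links}
        assert got == want
        assert all(e.mismatches == 1 for e in hedges)
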