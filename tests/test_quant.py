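"""Read assignment, relocation, adjacency filtering, genomic annotation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from temelano.models import GenomicReadPos, Transcript
from temelano.quant import (adjacency_filter, annotate_genomic_positions,
                            build_count_matrix, locate_reads_on_genome,
                            map_reads, parse_fastq)
from temelano.synthetic import generate_te_library, plant_insertions, render_reads


@pytest.fixture(scope="module")
def library_sources(small_library):
    return {c.id: c.sequence for c in small_library}


class TestMapReads:
    def test_unique_read_assigned_correctly(self, small_library, library_sources):
        reads = render_reads(library_sources, {c.id: 20 for c in small_library},
                             seed=1)
        assignments = map_reads([(r[0], r[2]) for r in reads], library_sources,
                                seed=1)
        truth = {r[0]: r[1].split()[0].removeprefix("src=") for r in reads}
        classes = {c.id: c.te_class for c in small_library}
        assert len(assignments) == len(reads)
        for a in assignments:
            assert a.family_id == truth[a.read_id]
            # reads from an LTR terminal repeat hit both LTRs of the same
            # consensus; everything else has a unique best location
            if classes[a.family_id] != "LTR":
                assert a.n_equal_best == 1

    def test_equal_score_ties_split_evenly(self, small_library):
        src = small_library[0].sequence
        duplicated = {"A#DNA": src, "B#DNA": src}
        reads = render_reads({"A#DNA": src}, {"A#DNA": 10_000}, seed=2)
        assignments = map_reads([(r[0], r[2]) for r in reads], duplicated, seed=3)
        frac_a = np.mean([a.family_id == "A#DNA" for a in assignments])
        sigma = 0.5 / np.sqrt(len(assignments))
        assert abs(frac_a - 0.5) <= 3 * sigma
        assert all(a.n_equal_best == 2 for a in assignments)

    def test_random_reads_stay_unassigned(self, library_sources):
        rng = np.random.default_rng(5)
        reads = [(f"null{i}", "".join(rng.choice(list("ACGT"), 100)))
                 for i in range(1000)]
        assignments = map_reads(reads, library_sources, seed=5)
        assert len(assignments) / len(reads) < 0.01

    def test_seed_changes_only_tie_outcomes(self, small_library):
        src = small_library[0].sequence
        two = {"A#DNA": src, "B#DNA": src}
        sources = {**two, "C#LINE": small_library[1].sequence}
        reads = render_reads({"A#DNA": src, "C#LINE": small_library[1].sequence},
                             {"A#DNA": 50, "C#LINE": 50}, seed=6)
        a1 = map_reads([(r[0], r[2]) for r in reads], sources, seed=1)
        a2 = map_reads([(r[0], r[2]) for r in reads], sources, seed=2)
        unique1 = {a.read_id: a.family_id for a in a1 if a.n_equal_best == 1}
        unique2 = {a.read_id: a.family_id for a in a2 if a.n_equal_best == 1}
        assert unique1 == unique2

    def test_malformed_fastq_skipped(self, tmp_path):
        fq = tmp_path / "reads.fq"
        fq.write_text("@r1\nACGT\n+\nIIII\n"
                      "bad_header\nACGT\n+\nIIII\n"
                      "@r3\nACGTA\n+\nIIIII\n")
        reads, skipped = parse_fastq(fq)
        assert [r[0] for r in reads] == ["r1", "r3"]
        assert skipped == 1


class TestBuildCountMatrix:
    def test_counts_by_family(self, small_library, library_sources):
        reads = render_reads(library_sources,
                             {small_library[0].id: 3, small_library[1].id: 2},
                             seed=7)
        assignments = map_reads([(r[0], r[2]) for r in reads], library_sources,
                                seed=7)
        cm = build_count_matrix({"s1": assignments},
                                [c.id for c in small_library], {"s1": "wildtype"})
        assert cm.counts.loc[small_library[0].id, "s1"] == 3
        assert cm.counts.loc[small_library[1].id, "s1"] == 2
        assert cm.counts["s1"].sum() == len(assignments)

    def test_zero_families_retained(self, small_library):
        cm = build_count_matrix({"s1": []}, [c.id for c in small_library],
                                {"s1": "tg"})
        assert (cm.counts.to_numpy() == 0).all()
        assert list(cm.counts.index) == [c.id for c in small_library]

    def test_truth_tagged_reads_reproduce_true_counts(self, small_library,
                                                      library_sources):
        true_counts = {c.id: 10 + 5 * i for i, c in enumerate(small_library)}
        reads = render_reads(library_sources, true_counts, seed=8)
        assignments = map_reads([(r[0], r[2]) for r in reads], library_sources,
                                seed=8)
        cm = build_count_matrix({"s1": assignments},
                                [c.id for c in small_library], {"s1": "wildtype"})
        for fam, n in true_counts.items():
            assert cm.counts.loc[fam, "s1"] == n


class TestLocateReads:
    def test_unique_copy_located_within_truth(self, small_library,
                                              planted_genome, library_sources):
        genome, truth = planted_genome
        reads = render_reads(library_sources, {c.id: 10 for c in small_library},
                             seed=9)
        assignments = map_reads([(r[0], r[2]) for r in reads], library_sources,
                                seed=9)
        positions = locate_reads_on_genome(assignments,
                                           {r[0]: r[2] for r in reads},
                                           genome, seed=9)
        intervals = {}
        for fam, chrom, s, e, strand, _ in truth.planted_insertions:
            intervals.setdefault(fam, []).append((chrom, s, e))
        assert positions
        for p in positions:
            assert any(c == p.chrom and s <= p.start and p.end <= e
                       for c, s, e in intervals[p.family_id])

    def test_excessive_multimappers_dropped(self, small_library, library_sources):
        src = small_library[0]
        tandem = {"chr1": ("TTTT" + src.sequence + "TTTT") * 20}
        reads = render_reads({src.id: src.sequence}, {src.id: 20}, seed=10)
        assignments = map_reads([(r[0], r[2]) for r in reads], library_sources,
                                seed=10)
        kept = locate_reads_on_genome(assignments, {r[0]: r[2] for r in reads},
                                      tandem, max_locations=10, seed=10)
        assert kept == []

    def test_no_assignments_empty(self, planted_genome):
        genome, _ = planted_genome
        assert locate_reads_on_genome([], {}, genome) == []


def _pos(read_id, start, chrom="chr1"):
    return GenomicReadPos(read_id=read_id, chrom=chrom, start=start,
                          end=start + 50, strand="+", family_id="f#DNA")


class TestAdjacencyFilter:
    def test_pair_within_window_kept(self):
        kept = adjacency_filter([_pos("a", 1000), _pos("b", 1500)])
        assert {p.read_id for p in kept} == {"a", "b"}

    def test_isolated_read_removed(self):
        kept = adjacency_filter([_pos("a", 10_000), _pos("b", 100, "chr2"),
                                 _pos("c", 600, "chr2")])
        assert {p.read_id for p in kept} == {"b", "c"}

    def test_chain_adjacency_keeps_all(self):
        kept = adjacency_filter([_pos("a", 0), _pos("b", 900), _pos("c", 1800)])
        assert {p.read_id for p in kept} == {"a", "b", "c"}

    @given(st.lists(st.integers(0, 20_000), min_size=1, max_size=60))
    def test_sweep_equals_bruteforce(self, starts):
        positions = [_pos(f"r{i}", s) for i, s in enumerate(starts)]
        kept = {p.read_id for p in adjacency_filter(positions, window=1000)}
        brute = {p.read_id for p in positions
                 if any(q.read_id != p.read_id and abs(q.start - p.start) <= 1000
                        for q in positions)}
        assert kept == brute


class TestAnnotate:
    @pytest.fixture()
    def gene(self):
        return Transcript(gene_id="g1", tx_id="t1", chrom="chr1", strand="+",
                          exons=[(100, 200), (300, 400), (500, 600)])

    def test_last_exon_plus_strand(self, gene):
        res = annotate_genomic_positions([_pos("r", 550)], [gene])
        assert res.categories["r"] == "exon_last"
        assert res.gene_read_tally.loc["g1", "exon_last"] == 1

    def test_last_exon_minus_strand(self):
        gene = Transcript(gene_id="g2", tx_id="t2", chrom="chr1", strand="-",
                          exons=[(100, 200), (300, 400)])
        res = annotate_genomic_positions([_pos("r", 120)], [gene])
        assert res.categories["r"] == "exon_last"

    def test_intron_and_intergenic(self, gene):
        res = annotate_genomic_positions([_pos("ri", 230), _pos("rg", 5000)],
                                         [gene])
        assert res.categories["ri"] == "intron"
        assert res.categories["rg"] == "intergenic"

    def test_exon_precedence_over_intron(self, gene):
        other = Transcript(gene_id="g3", tx_id="t3", chrom="chr1", strand="+",
                           exons=[(0, 50), (900, 1000)])
        # read overlaps exon of g1 and intron of g3 -> exon wins
        res = annotate_genomic_positions([_pos("r", 150)], [gene, other])
        assert res.categories["r"].startswith("exon")

    def test_unstranded_marked_indeterminate(self):
        gene = Transcript(gene_id="g4", tx_id="t4", chrom="chr1", strand=".",
                          exons=[(100, 200)])
        res = annotate_genomic_positions([_pos("r", 150)], [gene])
        assert "r" in res.indeterminate
        assert res.categories["r"] == "exon_other"

    def test_exhaustive_per_transcript_oracle(self):
        rng = np.random.default_rng(11)
        transcripts = []
        for g in range(5):
            n_ex = int(rng.integers(1, 4))
            starts = np.sort(rng.choice(np.arange(0, 5000, 10), n_ex,
                                        replace=False))
            exons = [(int(s), int(s) + int(rng.integers(20, 80)))
                     for s in starts]
            transcripts.append(Transcript(gene_id=f"g{g}", tx_id=f"t{g}",
                                          chrom="chr1",
                                          strand="+" if g % 2 else "-",
                                          exons=exons))
        positions = [_pos(f"r{i}", int(s))
                     for i, s in enumerate(rng.integers(0, 6000, 200))]
        res = annotate_genomic_positions(positions, transcripts)
        for p in positions:
            cats = set()
            for tx in transcripts:
                if tx.chrom != p.chrom:
                    continue
                exonic = last = False
                for exon in tx.exons:
                    if p.start < exon[1] and exon[0] < p.end:
                        exonic = True
                        last = last or exon == tx.last_exon
                if exonic:
                    cats.add("exon_last" if last else "exon_other")
                elif tx.span[0] < p.end and p.start < tx.span[1]:
                    cats.add("intron")
            expected = ("exon_last" if "exon_last" in cats else
                        "exon_other" if "exon_other" in cats else
                        "intron" if "intron" in cats else "intergenic")
            assert res.categories[p.read_id] == expected
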