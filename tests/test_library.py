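"""Curation rules: length filter, self-alignment, redundancy, renaming."""

import itertools

import numpy as np
import pytest

from temelano.library import (curate_library, detect_terminal_repeats,
                              filter_short, import_candidates,
                              is_redundant_pair, pairwise_match,
                              remove_redundant, rename_unknowns)
from temelano.models import TEConsensus
from temelano.synthetic import generate_te_library, mutate


def _random_consensus(rng, length, name, te_class="DNA", superfamily="hAT"):
    seq = "".join(rng.choice(list("ACGT"), length))
    return TEConsensus(id=f"{name}#{te_class}/{superfamily}", sequence=seq,
                       te_class=te_class, superfamily=superfamily)


class TestFilterShort:
    def test_80nt_boundary(self):
        rng = np.random.default_rng(0)
        consensi = [_random_consensus(rng, n, f"c{n}") for n in (79, 80, 500)]
        kept = filter_short(consensi)
        assert [c.length for c in kept] == [80, 500]

    def test_identity_when_all_long(self):
        rng = np.random.default_rng(1)
        consensi = [_random_consensus(rng, 100 + i, f"c{i}") for i in range(3)]
        assert filter_short(consensi) == consensi

    def test_empty_input(self):
        assert filter_short([]) == []


class TestDetectTerminalRepeats:
    def test_planted_exact_ltr(self):
        lib = generate_te_library(1, {"LTR": 1.0}, seed=5, ltr_length=300)
        tr = detect_terminal_repeats(lib[0], min_repeat_len=100, min_identity=0.9)
        assert tr is not None
        assert tr.identity == pytest.approx(1.0)
        assert tr.length >= 300
        assert tr.left[0] == 0 and tr.right[1] == lib[0].length

    def test_random_sequence_null(self):
        # false-positive rate under the null: no 100 nt / 90% identity pair
        # should arise from random 1000 nt sequences
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            c = _random_consensus(rng, 1000, "r")
            if detect_terminal_repeats(c, min_repeat_len=100, min_identity=0.9):
                hits += 1
        assert hits == 0

    def test_mutated_repeat_identity_recovered(self):
        rng = np.random.default_rng(7)
        ltr = "".join(rng.choice(list("ACGT"), 300))
        internal = "".join(rng.choice(list("ACGT"), 800))
        right = mutate(ltr, 0.15, np.random.default_rng(8))
        c = TEConsensus(id="x#LTR/Gypsy", sequence=ltr + internal + right,
                        te_class="LTR")
        tr = detect_terminal_repeats(c, min_repeat_len=100, min_identity=0.8)
        assert tr is not None
        assert abs(tr.identity - 0.85) <= 0.03

    def test_min_repeat_len_validated(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            detect_terminal_repeats(_random_consensus(rng, 200, "c"),
                                    min_repeat_len=10)


class TestRemoveRedundant:
    def test_identical_pair_collapses(self):
        rng = np.random.default_rng(2)
        a = _random_consensus(rng, 1000, "a")
        b = TEConsensus(id="b#DNA/hAT", sequence=a.sequence, te_class="DNA")
        kept, removal = remove_redundant([a, b])
        assert len(kept) == 1
        assert removal == {"b#DNA/hAT": a.id}

    def test_exact_fragment_kept_mutual_coverage(self):
        # a 500 nt exact fragment covers only 50% of the 1000 nt original:
        # the mutual-coverage condition fails, both stay
        rng = np.random.default_rng(3)
        full = _random_consensus(rng, 1000, "full")
        frag = TEConsensus(id="frag#DNA/hAT", sequence=full.sequence[:500],
                           te_class="DNA")
        kept, removal = remove_redundant([full, frag])
        assert len(kept) == 2 and removal == {}
        m = pairwise_match(frag, full)
        assert m.evalue < 1e-20  # similarity alone would have removed it

    def test_chain_equals_bruteforce_oracle(self):
        # greedy keep-longest must match exhaustive simulation of the same
        # rule on a tangle of <= 6 sequences
        rng = np.random.default_rng(4)
        base = "".join(rng.choice(list("ACGT"), 900))
        consensi = [
            TEConsensus(id=f"v{i}#DNA/hAT",
                        sequence=mutate(base, 0.02 * i, np.random.default_rng(i))
                        + "".join(rng.choice(list("ACGT"), 10 * i)),
                        te_class="DNA")
            for i in range(5)
        ]
        rng2 = np.random.default_rng(99)
        consensi.append(_random_consensus(rng2, 800, "solo"))
        kept, _ = remove_redundant(consensi)

        # independent oracle: explicit loop over the sorted order
        order = sorted(consensi, key=lambda c: (-c.length, c.id))
        oracle_kept = []
        for cand in order:
            if not any(is_redundant_pair(cand, k) for k in oracle_kept):
                oracle_kept.append(cand)
        assert {c.id for c in kept} == {c.id for c in oracle_kept}
        # and no kept pair is mutually redundant
        for x, y in itertools.combinations(kept, 2):
            assert not is_redundant_pair(x, y)

    def test_duplicate_ids_rejected(self):
        rng = np.random.default_rng(5)
        a = _random_consensus(rng, 200, "a")
        with pytest.raises(ValueError):
            remove_redundant([a, a])


def _encode_peptide(peptide):
    """Reverse-translate with one fixed codon per residue."""
    from Bio.Data.CodonTable import standard_dna_table
    codon = {}
    for cod, aa in sorted(standard_dna_table.forward_table.items()):
        codon.setdefault(aa, cod)
    return "".join(codon[aa] for aa in peptide)


class TestRenameUnknowns:
    @pytest.fixture()
    def rt_peptide(self):
        rng = np.random.default_rng(10)
        return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 150))

    def test_planted_rt_reclassified(self, rt_peptide):
        rng = np.random.default_rng(11)
        flank = "".join(rng.choice(list("ACGT"), 100))
        unk = TEConsensus(id="u1#Unknown", sequence=flank + _encode_peptide(rt_peptide)
                          + flank, te_class="Unknown")
        out = rename_unknowns([unk], {"LINE/I": rt_peptide}, min_bits=100)
        assert out[0].te_class == "LINE" and out[0].superfamily == "I"
        assert out[0].id == "u1#LINE/I"

    def test_classified_untouched(self, rt_peptide):
        line = TEConsensus(id="l1#LINE/L1", sequence=_encode_peptide(rt_peptide),
                           te_class="LINE", superfamily="L1")
        out = rename_unknowns([line], {"LTR/Gypsy": rt_peptide}, min_bits=10)
        assert out[0].id == "l1#LINE/L1"

    def test_no_hit_stays_unknown(self, rt_peptide):
        rng = np.random.default_rng(12)
        unk = TEConsensus(id="u2#Unknown",
                          sequence="".join(rng.choice(list("ACGT"), 400)),
                          te_class="Unknown")
        out = rename_unknowns([unk], {"LINE/I": rt_peptide}, min_bits=100)
        assert out[0].te_class == "Unknown"

    def test_decoy_drops_host_gene(self, rt_peptide):
        rng = np.random.default_rng(13)
        host = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), 150))
        fake = TEConsensus(id="u3#Unknown", sequence=_encode_peptide(host),
                           te_class="Unknown")
        out = rename_unknowns([fake], {"LINE/I": rt_peptide}, min_bits=100,
                              decoys={"host_actin": host})
        assert out == []


class TestImportCandidates:
    def test_novel_helitrons_grow_library(self, small_library):
        rng = np.random.default_rng(20)
        extras = [TEConsensus(id=f"hel{i}#RC/Helitron",
                              sequence="".join(rng.choice(list("ACGT"), 600)),
                              te_class="RC", superfamily="Helitron",
                              source="helitron_candidate")
                  for i in range(2)]
        merged = import_candidates(small_library, extras)
        assert len(merged) == len(small_library) + 2

    def test_identical_candidate_no_growth(self, small_library):
        dup = TEConsensus(id="dup#DNA/hAT", sequence=small_library[0].sequence,
                          te_class="DNA", source="ltr_candidate")
        merged = import_candidates(small_library, [dup])
        assert len(merged) == len(small_library)

    def test_sine_candidate_reannotates_existing(self, small_library):
        target = small_library[0]
        cand = TEConsensus(id="s1#SINE/tRNA", sequence=target.sequence,
                           te_class="SINE", source="sine_candidate")
        merged = import_candidates(small_library, [cand])
        assert len(merged) == len(small_library)
        hit = [c for c in merged if c.name == target.name]
        assert hit and hit[0].te_class == "SINE"

    def test_id_collision_with_different_sequence(self, small_library):
        rng = np.random.default_rng(21)
        clash = TEConsensus(id=small_library[0].id,
                            sequence="".join(rng.choice(list("ACGT"), 300)),
                            source="ltr_candidate")
        with pytest.raises(ValueError):
            import_candidates(small_library, [clash])


class TestCurationProperties:
    def test_idempotence(self, small_library):
        rng = np.random.default_rng(30)
        raw = list(small_library) + [
            _random_consensus(rng, 60, "short"),
            TEConsensus(id="dup#DNA/hAT", sequence=small_library[0].sequence,
                        te_class="DNA"),
        ]
        once = curate_library(raw)
        twice = curate_library(once)
        assert [(c.id, c.sequence) for c in once] == [(c.id, c.sequence) for c in twice]

    def test_no_redundant_pair_survives(self, small_library):
        rng = np.random.default_rng(31)
        raw = list(small_library) + [
            TEConsensus(id=f"m{i}#DNA/hAT",
                        sequence=mutate(small_library[0].sequence, 0.01,
                                        np.random.default_rng(40 + i)),
                        te_class="DNA")
            for i in range(3)
        ]
        curated = curate_library(raw)
        for a, b in itertools.combinations(curated, 2):
            assert not is_redundant_pair(a, b)

    def test_order_invariance(self, small_library):
        rng = np.random.default_rng(32)
        raw = list(small_library) + [
            TEConsensus(id="dup#LINE/I", sequence=small_library[1].sequence,
                        te_class="LINE")
        ]
        fwd = curate_library(list(raw))
        rev = curate_library(list(reversed(raw)))
        assert {c.id for c in fwd} == {c.id for c in rev}
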