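"""Curation of a raw candidate consensus set into a species-specific TE library.

The curation steps mirror how a fish TE library is refined from de novo
repeat predictions: drop short consensi, flag internal/terminal repeats by
self-alignment, collapse redundant consensi under a mutual-coverage e-value
rule, reclassify "unknown" elements by translated similarity to TE proteins
(with an optional host-protein decoy set to weed out multigene families
mistaken for TEs), and fold in candidates from dedicated LTR/Helitron/SINE
detectors.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

from Bio.Seq import Seq

from .align import (alignment_identity, dna_local_aligner, karlin_evalue,
                    protein_local_aligner)
from .models import PairwiseMatch, TEConsensus, TerminalRepeat

logger = logging.getLogger(__name__)

_DNA_ALIGNER = dna_local_aligner(match=1.0, mismatch=-2.0, gap=-3.0)
_TR_ALIGNER = dna_local_aligner(match=1.0, mismatch=-1.0, gap=-2.0)
_PEP_ALIGNER = protein_local_aligner()


def filter_short(consensi: Sequence[TEConsensus], min_len: int = 80) -> list[TEConsensus]:
    """Remove consensi shorter than `min_len` (strictly; 80 nt is kept).

    Order is preserved; removals are logged.
    """
    kept = []
    for c in consensi:
        if c.length >= min_len:
            kept.append(c)
        else:
            logger.info("filter_short: removed %s (%d nt < %d)", c.id, c.length, min_len)
    return kept


def detect_terminal_repeats(consensus: TEConsensus,
                            min_repeat_len: int = 50,
                            min_identity: float = 0.8,
                            end_fraction: float = 0.5) -> Optional[TerminalRepeat]:
    """Self-alignment check for a repeated pair near the two ends.

    The first and last `end_fraction` of the sequence are locally aligned
    against each other (equivalent to self-alignment with the trivial
    diagonal masked). A pair of at least `min_repeat_len` aligned columns at
    identity >= `min_identity` flags an LTR/satellite candidate.
    """
    if min_repeat_len < 20:
        raise ValueError("min_repeat_len must be >= 20")
    seq = consensus.sequence
    half = max(min_repeat_len, int(len(seq) * end_fraction))
    left_part = seq[:half]
    right_offset = len(seq) - half
    right_part = seq[right_offset:]
    if right_offset <= 0:
        return None  # halves would overlap the same residues entirely
    alignments = _TR_ALIGNER.align(left_part, right_part)
    if len(alignments) == 0 or alignments.score <= 0:
        return None
    aln = alignments[0]
    matches, columns, identity = alignment_identity(aln)
    if columns < min_repeat_len or identity < min_identity:
        return None
    (t_blocks, q_blocks) = aln.aligned
    left = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    right = (right_offset + int(q_blocks[0][0]), right_offset + int(q_blocks[-1][1]))
    return TerminalRepeat(left=left, right=right, identity=identity, length=columns)


def pairwise_match(query: TEConsensus, subject: TEConsensus) -> PairwiseMatch:
    """Best local alignment between two consensi with an ungapped
    Karlin-Altschul e-value on the raw score (search space |q|*|s|)."""
    alignments = _DNA_ALIGNER.align(query.sequence, subject.sequence)
    if len(alignments) == 0:
        return PairwiseMatch(query.id, subject.id, 0, 0, 0.0, 0.0, float("inf"))
    aln = alignments[0]
    t_blocks, q_blocks = aln.aligned
    span_q = int(t_blocks[-1][1] - t_blocks[0][0]) if len(t_blocks) else 0
    span_s = int(q_blocks[-1][1] - q_blocks[0][0]) if len(q_blocks) else 0
    _, _, identity = alignment_identity(aln)
    score = float(aln.score)
    ev = karlin_evalue(score, query.length, subject.length)
    return PairwiseMatch(query.id, subject.id, span_q, span_s, identity, score, ev)


def is_redundant_pair(a: TEConsensus, b: TEConsensus,
                      evalue_max: float = 1e-20,
                      min_mutual_cov: float = 0.8) -> bool:
    m = pairwise_match(a, b)
    return (m.evalue < evalue_max
            and m.align_len_query >= min_mutual_cov * a.length
            and m.align_len_subject >= min_mutual_cov * b.length)


def remove_redundant(consensi: Sequence[TEConsensus],
                     evalue_max: float = 1e-20,
                     min_mutual_cov: float = 0.8,
                     ) -> tuple[list[TEConsensus], dict[str, str]]:
    """Collapse redundant consensi (e-value and mutual-coverage rule).

    A pair is redundant when its best local alignment has e-value below
    `evalue_max` AND spans at least `min_mutual_cov` of BOTH sequences.
    Consensi are visited by length descending (ties: id ascending) and kept
    greedily unless redundant with an already-kept one, so the longest
    representative of each redundancy class survives.

    Returns (kept consensi in input order, map removed id -> kept id).
    """
    ids = [c.id for c in consensi]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate consensus ids")
    order = sorted(consensi, key=lambda c: (-c.length, c.id))
    kept: list[TEConsensus] = []
    removal: dict[str, str] = {}
    for cand in order:
        winner = None
        for k in kept:
            if is_redundant_pair(cand, k, evalue_max, min_mutual_cov):
                winner = k
                break
        if winner is None:
            kept.append(cand)
        else:
            removal[cand.id] = winner.id
            logger.info("remove_redundant: %s -> %s", cand.id, winner.id)
    kept_ids = {c.id for c in kept}
    return [c for c in consensi if c.id in kept_ids], removal


def _six_frame_segments(sequence: str, min_aa: int = 20) -> list[str]:
    """Stop-free peptide segments of all six frames, for translated search."""
    segments = []
    seq = Seq(sequence)
    for strand_seq in (seq, seq.reverse_complement()):
        for offset in range(3):
            frame = strand_seq[offset:]
            frame = frame[:len(frame) - len(frame) % 3]
            if len(frame) < 3:
                continue
            for part in str(frame.translate()).split("*"):
                if len(part) >= min_aa:
                    segments.append(part)
    return segments


def best_translated_hit(consensus: TEConsensus,
                        protein_lib: Mapping[str, str]) -> tuple[Optional[str], float]:
    """Best six-frame translated local-alignment score against a peptide set.

    Returns (best protein label, score); (None, 0.0) when nothing aligns.
    """
    best_label, best_score = None, 0.0
    segments = _six_frame_segments(consensus.sequence)
    for label, peptide in protein_lib.items():
        for segment in segments:
            score = _PEP_ALIGNER.score(segment, peptide)
            if score > best_score:
                best_label, best_score = label, float(score)
    return best_label, best_score


def rename_unknowns(consensi: Sequence[TEConsensus],
                    protein_lib: Mapping[str, str],
                    min_bits: float = 50.0,
                    decoys: Optional[Mapping[str, str]] = None,
                    ) -> list[TEConsensus]:
    """Reclassify Unknown consensi by translated TE-protein similarity.

    `protein_lib` maps "Class/Superfamily"-style labels to peptides. An
    Unknown consensus whose best six-frame match scores >= `min_bits` takes
    the hit's classification (id suffix updated). When a `decoys` set of
    host-protein peptides is supplied and a decoy outscores every TE protein
    at >= `min_bits`, the consensus is dropped as an erroneously identified
    multigene family. Already-classified consensi are untouched.
    """
    if not protein_lib:
        raise ValueError("empty protein library")
    out: list[TEConsensus] = []
    for c in consensi:
        if c.te_class != "Unknown":
            out.append(c)
            continue
        label, score = best_translated_hit(c, protein_lib)
        decoy_score = 0.0
        if decoys:
            _, decoy_score = best_translated_hit(c, decoys)
        if decoy_score >= min_bits and decoy_score >= score:
            logger.info("rename_unknowns: dropped %s (host-protein decoy hit %.1f)",
                        c.id, decoy_score)
            continue
        if label is not None and score >= min_bits:
            te_class, _, superfamily = label.partition("/")
            out.append(c.reclassified(te_class, superfamily or None))
            logger.info("rename_unknowns: %s -> %s (score %.1f)", c.id, label, score)
        else:
            out.append(c)
    return out


def import_candidates(consensi: Sequence[TEConsensus],
                      extra: Sequence[TEConsensus],
                      evalue_max: float = 1e-20,
                      min_mutual_cov: float = 0.8) -> list[TEConsensus]:
    """Fold in candidates from dedicated detectors.

    SINE candidates that are redundant with an existing consensus reannotate
    that consensus to class SINE instead of being added; all other
    non-redundant extras are appended. The merged set is deduplicated with
    the standard redundancy rule.
    """
    by_id = {c.id: c for c in consensi}
    for e in extra:
        clash = by_id.get(e.id)
        if clash is not None and clash.sequence != e.sequence:
            raise ValueError(f"id collision with different sequences: {e.id}")

    current = list(consensi)
    to_add: list[TEConsensus] = []
    for e in extra:
        if e.source == "sine_candidate":
            matched = False
            for i, c in enumerate(current):
                if is_redundant_pair(e, c, evalue_max, min_mutual_cov):
                    if c.te_class != "SINE":
                        current[i] = c.reclassified("SINE", c.superfamily)
                        logger.info("import_candidates: %s reannotated to SINE", c.id)
                    matched = True
                    break
            if not matched:
                to_add.append(e if e.te_class == "SINE" else e.reclassified("SINE"))
        else:
            to_add.append(e)
    merged = current + [e for e in to_add if e.id not in {c.id for c in current}]
    kept, _ = remove_redundant(merged, evalue_max, min_mutual_cov)
    return kept


def curate_library(raw: Sequence[TEConsensus],
                   protein_lib: Optional[Mapping[str, str]] = None,
                   decoys: Optional[Mapping[str, str]] = None,
                   extras: Sequence[TEConsensus] = (),
                   min_len: int = 80,
                   evalue_max: float = 1e-20,
                   min_mutual_cov: float = 0.8,
                   min_bits: float = 50.0) -> list[TEConsensus]:
    """Full curation: length filter, unknown renaming, redundancy removal,
    candidate import. Idempotent: curating a curated library is a no-op."""
    lib = filter_short(raw, min_len)
    if protein_lib:
        lib = rename_unknowns(lib, protein_lib, min_bits, decoys)
    lib, _ = remove_redundant(lib, evalue_max, min_mutual_cov)
    if extras:
        lib = import_candidates(lib, extras, evalue_max, min_mutual_cov)
    return lib
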