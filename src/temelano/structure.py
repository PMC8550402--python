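"""Structural characterization of candidate TEs.

Six-frame ORF calling, protein-domain scanning of ORF peptides against
user-supplied reference peptides (reverse transcriptase, endonuclease,
integrase, gag, RNaseH and the like), full-length genomic copy calling
(hits covering >= 90% of the consensus), Circoletto-style score-ratio color
binning, and per-position read-coverage profiles along the consensus.
"""

from __future__ import annotations

import re
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .align import protein_local_aligner
from .models import DomainHit, GenomeCopy, ORFRecord, ReadAssignment, RepeatHit, TEConsensus

_PEP_ALIGNER = protein_local_aligner()

_VALID_DNA = re.compile(r"^[ACGTN]*$")


def find_orfs(sequence: str, min_aa: int = 100) -> list[ORFRecord]:
    """ATG-initiated, stop-terminated ORFs of >= `min_aa` residues, six frames.

    Within each stop-bounded segment the 5'-most ATG defines the ORF (the
    longest candidate). Reverse-strand ORFs are reported in forward
    coordinates with a negative frame; `end - start` includes the stop codon.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = sequence.upper()
    if not _VALID_DNA.match(seq):
        raise ValueError("sequence contains non-ACGTN symbols")
    n = len(seq)
    orfs: list[ORFRecord] = []
    for strand in (1, -1):
        s = seq if strand == 1 else str(Seq(seq).reverse_complement())
        for offset in range(3):
            frame_seq = s[offset:]
            frame_seq = frame_seq[:len(frame_seq) - len(frame_seq) % 3]
            codons = [frame_seq[i:i + 3] for i in range(0, len(frame_seq), 3)]
            start_codon: Optional[int] = None
            for ci, codon in enumerate(codons):
                if codon in ("TAA", "TAG", "TGA"):
                    if start_codon is not None:
                        aa_len = ci - start_codon
                        if aa_len >= min_aa:
                            nt_start = offset + start_codon * 3
                            nt_end = offset + (ci + 1) * 3  # stop included
                            pep = str(Seq(frame_seq[start_codon * 3:ci * 3]).translate())
                            if strand == 1:
                                fwd_start, fwd_end = nt_start, nt_end
                            else:
                                fwd_start, fwd_end = n - nt_end, n - nt_start
                            orfs.append(ORFRecord(frame=strand * (offset + 1),
                                                  start=fwd_start, end=fwd_end,
                                                  peptide=pep))
                    start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = ci
    orfs.sort(key=lambda o: (o.start, o.end, o.frame))
    return orfs


def scan_domains(orfs: Sequence[ORFRecord],
                 domain_profiles: Mapping[str, str],
                 min_bits: float = 50.0) -> list[DomainHit]:
    """Best local BLOSUM62 alignment (gap open -11 / extend -1) of each ORF
    peptide against each labeled reference peptide; hits >= `min_bits`."""
    hits: list[DomainHit] = []
    for orf in orfs:
        for label, profile in domain_profiles.items():
            alignments = _PEP_ALIGNER.align(orf.peptide, profile)
            if len(alignments) == 0:
                continue
            aln = alignments[0]
            if aln.score < min_bits:
                continue
            t_blocks, _ = aln.aligned
            hits.append(DomainHit(orf=orf, domain_label=label,
                                  score=float(aln.score),
                                  peptide_start=int(t_blocks[0][0]),
                                  peptide_end=int(t_blocks[-1][1])))
    hits.sort(key=lambda h: (-h.score, h.domain_label))
    return hits


def full_length_copies(consensus: TEConsensus,
                       hits: Sequence[RepeatHit],
                       min_cov: float = 0.9) -> tuple[list[GenomeCopy], int]:
    """Flag genomic copies covering >= `min_cov` of the consensus.

    `hits` are the (merged) genomic copies of this family; each copy's
    consensus coverage is its consensus-interval length over the consensus
    length, and its score ratio is score / max family score. Returns the
    copies and the full-length count.
    """
    fam_hits = [h for h in hits if h.family_id == consensus.id]
    if not fam_hits:
        return [], 0
    max_score = max(h.score for h in fam_hits)
    if max_score <= 0:
        raise ValueError("max score per family must be > 0")
    copies = []
    for h in fam_hits:
        cov = (h.consensus_end - h.consensus_start) / consensus.length
        copies.append(GenomeCopy(family_id=h.family_id, chrom=h.chrom,
                                 start=h.start, end=h.end, strand=h.strand,
                                 consensus_coverage=min(1.0, cov),
                                 score_ratio=h.score / max_score,
                                 full_length=cov >= min_cov))
    return copies, sum(c.full_length for c in copies)


def score_ratio_color(ratio: float) -> str:
    """Circoletto-style bin: blue <= 0.25 < green <= 0.70 < orange <= 0.90 < red."""
    if not 0 < ratio <= 1:
        raise ValueError("score ratio must be in (0, 1]")
    if ratio <= 0.25:
        return "blue"
    if ratio <= 0.70:
        return "green"
    if ratio <= 0.90:
        return "orange"
    return "red"


def score_ratio_bins(copies: Sequence[GenomeCopy]) -> dict[int, str]:
    """Color per copy (indexed by position in `copies`)."""
    return {i: score_ratio_color(c.score_ratio) for i, c in enumerate(copies)}


def consensus_read_coverage(assignments: Sequence[ReadAssignment],
                            consensus: TEConsensus) -> np.ndarray:
    """depth[i] = number of assigned reads covering consensus position i."""
    depth = np.zeros(consensus.length, dtype=np.int64)
    for a in assignments:
        if a.family_id != consensus.id:
            continue
        lo = max(0, a.consensus_start)
        hi = min(consensus.length, a.consensus_end)
        if hi > lo:
            depth[lo:hi] += 1
    return depth
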