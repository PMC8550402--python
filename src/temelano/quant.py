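"""Assign RNA-seq reads to TE consensi and relocate them on the genome.

Follows the two-pass design of the study: reads are first mapped to the TE
consensus library with multimapping allowed — when several locations share
the top score, one is chosen uniformly at random from a per-read
deterministic stream — then the TE-assigned reads are re-aligned to the
genome, reads with an excessive number of equal-best genomic locations are
dropped, isolated reads with no neighbor within 1 kb are removed, and the
surviving positions are annotated against gene models (last exon / other
exon / intron / intergenic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._rng import choose_index
from .align import KmerIndex, ScoringScheme, align_fragment, cluster_seeds, revcomp
from .models import CountMatrix, GenomicReadPos, ReadAssignment, Transcript

logger = logging.getLogger(__name__)


@dataclass
class _Placement:
    ref: str
    start: int
    end: int
    strand: str
    score: float


def _best_placements(seq: str, index: KmerIndex, min_score: float,
                     scheme: ScoringScheme, pad: int = 12) -> list[_Placement]:
    """All equal-top-score placements of a read in the indexed sequences."""
    placements: dict[tuple[str, int, str], _Placement] = {}
    for strand in "+-":
        query = seq if strand == "+" else revcomp(seq)
        for cl in cluster_seeds(query, index, min_seeds=1):
            target = index.seqs[cl.ref]
            t_lo = max(0, cl.t_start - cl.q_start - pad)
            t_hi = min(len(target), cl.t_end + (len(query) - cl.q_end) + pad)
            frag = align_fragment(query, target[t_lo:t_hi], scheme)
            if frag is None or frag.score < min_score:
                continue
            key = (cl.ref, t_lo + frag.target_start, strand)
            p = _Placement(cl.ref, t_lo + frag.target_start, t_lo + frag.target_end,
                           strand, frag.score)
            old = placements.get(key)
            if old is None or p.score > old.score:
                placements[key] = p
    if not placements:
        return []
    best = max(p.score for p in placements.values())
    ties = [p for p in placements.values() if p.score == best]
    ties.sort(key=lambda p: (p.ref, p.start, p.strand))
    return ties


def parse_fastq(path) -> tuple[list[tuple[str, str]], int]:
    """Lenient FASTQ reader: returns [(read id, sequence)] and the number of
    malformed records skipped (with a warning)."""
    reads = []
    skipped = 0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if (not header.startswith("@") or not plus.startswith("+")
                    or len(seq) != len(qual) or not seq):
                skipped += 1
                continue
            reads.append((header[1:].split()[0].strip(), seq))
    if skipped:
        logger.warning("parse_fastq: skipped %d malformed records", skipped)
    return reads, skipped


def map_reads(reads: Iterable[tuple[str, str]],
              library_index: KmerIndex | Mapping[str, str],
              min_score: float = 40.0,
              kmer: int = 12,
              seed: int = 0,
              scheme: ScoringScheme = ScoringScheme()) -> list[ReadAssignment]:
    """Map reads to the consensus library, multimapping allowed.

    Each read's best-scoring locations are found on both strands of every
    consensus; ties at the top score are broken uniformly at random from a
    stream keyed on (seed, read id), so the outcome is stable under read
    reordering. Reads scoring below `min_score` stay unassigned.
    """
    index = (library_index if isinstance(library_index, KmerIndex)
             else KmerIndex(library_index, kmer))
    out: list[ReadAssignment] = []
    for read_id, seq in reads:
        ties = _best_placements(seq, index, min_score, scheme)
        if not ties:
            continue
        pick = ties[choose_index(seed, read_id, len(ties))]
        out.append(ReadAssignment(read_id=read_id, family_id=pick.ref,
                                  consensus_start=pick.start, consensus_end=pick.end,
                                  strand=pick.strand, score=pick.score,
                                  n_equal_best=len(ties)))
    return out


def build_count_matrix(assignments_per_sample: Mapping[str, Sequence[ReadAssignment]],
                       families: Sequence[str],
                       conditions: Mapping[str, str]) -> CountMatrix:
    """Family x sample counts; all-zero families are retained."""
    samples = list(assignments_per_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    counts = pd.DataFrame(0, index=list(families), columns=samples, dtype=int)
    for sample, assignments in assignments_per_sample.items():
        for a in assignments:
            counts.loc[a.family_id, sample] += 1
    return CountMatrix(counts=counts, conditions=conditions)


def locate_reads_on_genome(assignments: Sequence[ReadAssignment],
                           reads: Mapping[str, str],
                           genome_index: KmerIndex | Mapping[str, str],
                           max_locations: int = 999,
                           min_score: float = 40.0,
                           kmer: int = 12,
                           seed: int = 0,
                           scheme: ScoringScheme = ScoringScheme()
                           ) -> list[GenomicReadPos]:
    """Re-align TE-assigned reads to the genome.

    Reads with more than `max_locations` equal-best genomic locations are
    dropped (highly repetitive placements); otherwise one location is kept
    under the same per-read random-choice contract as read mapping.
    """
    index = (genome_index if isinstance(genome_index, KmerIndex)
             else KmerIndex(genome_index, kmer))
    out: list[GenomicReadPos] = []
    for a in assignments:
        seq = reads.get(a.read_id)
        if seq is None:
            continue
        ties = _best_placements(seq, index, min_score, scheme)
        if not ties or len(ties) > max_locations:
            continue
        pick = ties[choose_index(seed, "genome:" + a.read_id, len(ties))]
        out.append(GenomicReadPos(read_id=a.read_id, chrom=pick.ref,
                                  start=pick.start, end=pick.end,
                                  strand=pick.strand, family_id=a.family_id))
    return out


def adjacency_filter(positions: Sequence[GenomicReadPos],
                     window: int = 1000) -> list[GenomicReadPos]:
    """Remove single reads with no neighboring read within `window`.

    Adjacency is start-to-start distance <= `window` (inclusive) on the same
    chromosome, computed with one sorted sweep; equivalent to the quadratic
    pairwise definition.
    """
    by_chrom: dict[str, list[GenomicReadPos]] = {}
    for p in positions:
        by_chrom.setdefault(p.chrom, []).append(p)
    kept: list[GenomicReadPos] = []
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.start)
        n = len(plist)
        for i, p in enumerate(plist):
            left_ok = i > 0 and p.start - plist[i - 1].start <= window
            right_ok = i < n - 1 and plist[i + 1].start - p.start <= window
            if left_ok or right_ok:
                kept.append(p)
    kept.sort(key=lambda p: (p.chrom, p.start, p.read_id))
    return kept


@dataclass
class AnnotationResult:
    categories: dict[str, str]  # read_id -> category
    gene_read_tally: pd.DataFrame  # gene_id x (exon_last, exon_other) read counts
    indeterminate: set[str] = field(default_factory=set)

    @property
    def category_counts(self) -> pd.Series:
        return pd.Series(self.categories).value_counts()

    def genes_with_last_exon_reads(self) -> int:
        return int((self.gene_read_tally["exon_last"] > 0).sum())

    def genes_with_other_exon_reads(self) -> int:
        return int((self.gene_read_tally["exon_other"] > 0).sum())


def annotate_genomic_positions(positions: Sequence[GenomicReadPos],
                               transcripts: Sequence[Transcript]) -> AnnotationResult:
    """Classify read positions as exon_last / exon_other / intron / intergenic.

    A read overlapping any exon is exonic; it is `exon_last` when it overlaps
    the 3'-most exon of an overlapped transcript (strand-aware), `exon_other`
    otherwise. A non-exonic read inside a gene span is intronic; everything
    else is intergenic. Reads overlapping several transcripts take the
    highest-precedence category (exon_last > exon_other > intron >
    intergenic). Exonic reads whose only supporting transcripts are
    unstranded are tallied as exon_other and flagged indeterminate.
    """
    exon_trees: dict[str, IntervalTree] = {}
    span_trees: dict[str, IntervalTree] = {}
    for tx in transcripts:
        et = exon_trees.setdefault(tx.chrom, IntervalTree())
        for i, (s, e) in enumerate(sorted(tx.exons)):
            et[s:e] = (tx, (s, e))
        s, e = tx.span
        span_trees.setdefault(tx.chrom, IntervalTree())[s:e] = tx

    categories: dict[str, str] = {}
    indeterminate: set[str] = set()
    tally: dict[str, dict[str, int]] = {}
    for p in positions:
        exon_hits = exon_trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end)
        if exon_hits:
            is_last = False
            any_stranded = False
            genes_last: set[str] = set()
            genes_other: set[str] = set()
            for iv in exon_hits:
                tx, exon = iv.data
                if tx.strand in "+-":
                    any_stranded = True
                    if exon == tx.last_exon:
                        is_last = True
                        genes_last.add(tx.gene_id)
                    else:
                        genes_other.add(tx.gene_id)
                else:
                    genes_other.add(tx.gene_id)
            if not any_stranded:
                indeterminate.add(p.read_id)
            categories[p.read_id] = "exon_last" if is_last else "exon_other"
            for g in genes_last:
                tally.setdefault(g, {"exon_last": 0, "exon_other": 0})["exon_last"] += 1
            for g in genes_other - genes_last:
                tally.setdefault(g, {"exon_last": 0, "exon_other": 0})["exon_other"] += 1
        elif span_trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end):
            categories[p.read_id] = "intron"
        else:
            categories[p.read_id] = "intergenic"
    gene_df = pd.DataFrame.from_dict(tally, orient="index").fillna(0).astype(int)
    if gene_df.empty:
        gene_df = pd.DataFrame(columns=["exon_last", "exon_other"], dtype=int)
    gene_df.index.name = "gene_id"
    return AnnotationResult(categories=categories, gene_read_tally=gene_df,
                            indeterminate=indeterminate)
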