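"""Locate TE copies in a genome and post-process the hit set.

The masker is a desk-scale seeded aligner (k-mer seeds, diagonal chaining,
edit-distance verification, ungapped X-drop end extension). Post-processing
follows the repeat-annotation conventions used for the medaka TE census:
overlapping hits are resolved by keeping the highest-scoring element, and
same-family fragments closer than 20 bp are merged. Coverage accounting
reports per-class Mb, percent of genome and percent of total TE coverage.
"""

from __future__ import annotations

import bisect
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .align import (KmerIndex, ScoringScheme, align_fragment, cluster_seeds,
                    extend_ungapped, revcomp)
from .models import RepeatHit, TEConsensus


def find_hits(genome: Mapping[str, str],
              library: Sequence[TEConsensus],
              min_score: float = 50.0,
              kmer: int = 12,
              *,
              min_seeds: int = 2,
              scheme: ScoringScheme = ScoringScheme(),
              window_pad: int = 40) -> list[RepeatHit]:
    """Scan a genome for copies of each library consensus, both strands.

    For every seed cluster the consensus fragment spanned by the seeds is
    verified inside a padded genomic window with edit-distance alignment,
    rescored under `scheme`, and its ends are extended ungapped with an
    X-drop rule so copy boundaries are recovered even when no seed sits at
    the very end. Hits below `min_score` are dropped. Deterministic.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    if not library:
        raise ValueError("empty library")
    index = KmerIndex(genome, kmer)
    hits: list[RepeatHit] = []
    for cons in library:
        for strand in "+-":
            query = cons.sequence if strand == "+" else revcomp(cons.sequence)
            for cl in cluster_seeds(query, index, min_seeds=min_seeds):
                target = genome[cl.ref]
                q_lo, q_hi = cl.q_start, cl.q_end
                t_lo = max(0, cl.t_start - window_pad)
                t_hi = min(len(target), cl.t_end + window_pad)
                frag = align_fragment(query[q_lo:q_hi], target[t_lo:t_hi], scheme)
                if frag is None:
                    continue
                g_start = t_lo + frag.target_start
                g_end = t_lo + frag.target_end
                score = frag.score
                matches, mismatches = frag.matches, frag.mismatches
                gaps = frag.gaps
                # extend ends beyond the outermost seeds
                lq, lt, lscore, lm, lx = extend_ungapped(query, target, q_lo, g_start,
                                                         -1, scheme)
                rq, rt, rscore, rm, rx = extend_ungapped(query, target, q_hi, g_end,
                                                         +1, scheme)
                q_lo -= lq
                q_hi += rq
                g_start -= lt
                g_end += rt
                score += lscore + rscore
                matches += lm + rm
                mismatches += lx + rx
                if score < min_score:
                    continue
                columns = matches + mismatches + gaps
                identity = matches / columns if columns else 0.0
                if strand == "+":
                    c_start, c_end = q_lo, q_hi
                else:
                    c_start, c_end = cons.length - q_hi, cons.length - q_lo
                hits.append(RepeatHit(family_id=cons.id, chrom=cl.ref,
                                      start=g_start, end=g_end, strand=strand,
                                      score=score, identity=identity,
                                      consensus_start=c_start, consensus_end=c_end))
    hits.sort(key=lambda h: (h.chrom, h.start, h.end, -h.score, h.family_id, h.strand))
    return hits


def resolve_overlaps(hits: Sequence[RepeatHit]) -> list[RepeatHit]:
    """Discard lower-scoring hits that overlap a kept hit by >= 1 bp.

    Hits are visited in descending score (ties: longer first, then leftmost,
    then family id ascending); a hit is kept iff it overlaps no already-kept
    hit on its chromosome. Whole hits are discarded, never trimmed.
    """
    order = sorted(hits, key=lambda h: (-h.score, -(h.end - h.start),
                                        h.chrom, h.start, h.family_id))
    kept_per_chrom: dict[str, list[tuple[int, int]]] = {}
    kept: list[RepeatHit] = []
    for h in order:
        intervals = kept_per_chrom.setdefault(h.chrom, [])
        i = bisect.bisect_left(intervals, (h.start, h.end))
        clash = False
        for j in (i - 1, i):
            if 0 <= j < len(intervals):
                s, e = intervals[j]
                if h.start < e and s < h.end:
                    clash = True
                    break
        if not clash:
            bisect.insort(intervals, (h.start, h.end))
            kept.append(h)
    kept.sort(key=lambda h: (h.chrom, h.start, h.end))
    return kept


def merge_adjacent(hits: Sequence[RepeatHit], max_gap: int = 20) -> list[RepeatHit]:
    """Merge same-family, same-strand fragments separated by < `max_gap` bp.

    Gap is measured in half-open coordinates (next.start - prev.end); the
    boundary is strict, so a gap of exactly `max_gap` is NOT merged. Merging
    is transitive along a chain. Score is summed; identity is length-weighted;
    the consensus interval becomes the union.
    """
    by_chrom: dict[str, list[RepeatHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    out: list[RepeatHit] = []
    for chrom in sorted(by_chrom):
        chrom_hits = sorted(by_chrom[chrom], key=lambda h: (h.start, h.end))
        cur: Optional[RepeatHit] = None
        for h in chrom_hits:
            if (cur is not None and h.family_id == cur.family_id
                    and h.strand == cur.strand and h.start - cur.end < max_gap):
                w_cur, w_h = cur.end - cur.start, h.end - h.start
                cur = RepeatHit(
                    family_id=cur.family_id, chrom=chrom,
                    start=cur.start, end=max(cur.end, h.end), strand=cur.strand,
                    score=cur.score + h.score,
                    identity=(cur.identity * w_cur + h.identity * w_h) / (w_cur + w_h),
                    consensus_start=min(cur.consensus_start, h.consensus_start),
                    consensus_end=max(cur.consensus_end, h.consensus_end))
            else:
                if cur is not None:
                    out.append(cur)
                cur = h
        if cur is not None:
            out.append(cur)
    return out


def coverage_shares(coverage_mb: Mapping[str, float],
                    genome_mb: Optional[float] = None) -> pd.DataFrame:
    """Per-class TE coverage table from Mb values.

    Columns: coverage_mb, pct_genome (when `genome_mb` given), pct_tes.
    Full precision is retained; use :func:`rounded` for report output.
    """
    classes = list(coverage_mb)
    mb = np.array([coverage_mb[c] for c in classes], dtype=float)
    if (mb < 0).any():
        raise ValueError("negative coverage")
    total = mb.sum()
    df = pd.DataFrame(index=pd.Index(classes, name="class"))
    df["coverage_mb"] = mb
    if genome_mb is not None:
        df["pct_genome"] = mb / genome_mb * 100.0
    df["pct_tes"] = mb / total * 100.0 if total > 0 else 0.0
    return df


def coverage_table(hits: Sequence[RepeatHit],
                   genome_length: int,
                   class_of: Mapping[str, str]) -> pd.DataFrame:
    """Per-class coverage of non-overlapping hits, in Mb and percent.

    `class_of` maps family id -> TE class; an unknown family is an error.
    A 'Total' row holds the summed coverage and its genome percentage.
    """
    bp: dict[str, int] = {}
    for h in hits:
        if h.family_id not in class_of:
            raise KeyError(f"family {h.family_id!r} missing from class map")
        cls = class_of[h.family_id]
        bp[cls] = bp.get(cls, 0) + (h.end - h.start)
    genome_mb = genome_length / 1e6
    df = coverage_shares({c: v / 1e6 for c, v in sorted(bp.items())},
                         genome_mb=genome_mb)
    total = pd.DataFrame({"coverage_mb": [df["coverage_mb"].sum()],
                          "pct_genome": [df["coverage_mb"].sum() / genome_mb * 100.0],
                          "pct_tes": [100.0 if len(df) else 0.0]},
                         index=pd.Index(["Total"], name="class"))
    return pd.concat([df, total]) if len(df) else total


def rounded(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """One-decimal report rounding of a coverage table."""
    return table.round(decimals)
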