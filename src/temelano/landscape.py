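"""TE divergence landscape.

For each family the genomic copies are placed in a common coordinate frame by
consensus-anchored star alignment (each copy globally aligned to the family
consensus, insertions relative to the consensus opening shared gap columns).
Pairwise identity is computed over columns where neither copy has a gap, and
per-family identity histograms are scaled so each family's total mass equals
its genomic density — old, diverged families and young, homogeneous families
then occupy the landscape in proportion to their genome share.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .align import dna_global_aligner, revcomp
from .models import LandscapePoint, RepeatHit, TEConsensus

logger = logging.getLogger(__name__)

_ANCHOR_ALIGNER = dna_global_aligner(match=1.0, mismatch=-1.0, gap=-2.0,
                                     free_end_gaps=True)


@dataclass
class MultipleAlignment:
    """Star alignment of copies in the consensus coordinate frame."""

    ids: list[str]
    rows: list[str]
    excluded: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def _project_copy(copy: str, consensus: str) -> tuple[np.ndarray, dict[int, str]]:
    """Align one copy to the consensus; return (per-position residues with
    '-' for deletions, insertions keyed by consensus position)."""
    aln = _ANCHOR_ALIGNER.align(consensus, copy)[0]
    t_blocks, q_blocks = aln.aligned
    row = np.full(len(consensus), ord("-"), dtype=np.uint8)
    insertions: dict[int, str] = {}
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None and qs > prev_q:
            insertions[int(ts)] = copy[prev_q:qs]
        seg = np.frombuffer(copy[qs:qe].encode(), dtype=np.uint8)
        row[ts:te] = seg
        prev_t, prev_q = int(te), int(qe)
    return row, insertions


def anchor_align_copies(copies: Mapping[str, str] | Sequence[str],
                        consensus: TEConsensus,
                        min_alignable: float = 0.5) -> MultipleAlignment:
    """Consensus-anchored star alignment of genomic copies.

    Each copy is globally aligned to the consensus (free end gaps, so
    truncated copies pay no penalty); copies sharing an inserted stretch at
    the same consensus position share gap columns. A copy with fewer than
    `min_alignable` of its bases aligned to the consensus is excluded and
    logged.
    """
    if isinstance(copies, Mapping):
        items = list(copies.items())
    else:
        items = [(f"copy{i}", s) for i, s in enumerate(copies)]
    if len(items) < 2:
        raise ValueError("need at least 2 copies")
    projected = []
    insert_len: dict[int, int] = {}
    excluded = []
    for name, seq in items:
        row, ins = _project_copy(seq, consensus.sequence)
        aligned_bases = int((row != ord("-")).sum())
        if aligned_bases < min_alignable * len(seq):
            excluded.append(name)
            logger.info("anchor_align_copies: excluded %s (%d/%d alignable)",
                        name, aligned_bases, len(seq))
            continue
        projected.append((name, row, ins))
        for pos, s in ins.items():
            insert_len[pos] = max(insert_len.get(pos, 0), len(s))
    if len(projected) < 2:
        raise ValueError("fewer than 2 copies remain after exclusion")

    ids, rows = [], []
    ins_positions = sorted(insert_len)
    for name, row, ins in projected:
        parts = []
        prev = 0
        for pos in ins_positions:
            parts.append(row[prev:pos].tobytes().decode())
            s = ins.get(pos, "")
            parts.append(s + "-" * (insert_len[pos] - len(s)))
            prev = pos
        parts.append(row[prev:].tobytes().decode())
        ids.append(name)
        rows.append("".join(parts))
    return MultipleAlignment(ids=ids, rows=rows, excluded=excluded)


def pairwise_identity(alignment: MultipleAlignment) -> np.ndarray:
    """Symmetric identity matrix: matches / columns where neither has a gap.

    Pairs with zero comparable columns are NaN; the diagonal is 1.
    """
    if len(alignment.rows) < 2:
        raise ValueError("need at least 2 rows")
    mat = np.array([np.frombuffer(r.encode(), dtype=np.uint8)
                    for r in alignment.rows])
    gap = ord("-")
    n = len(mat)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] != gap) & (mat[j] != gap)
            total = int(both.sum())
            if total == 0:
                out[i, j] = out[j, i] = np.nan
                continue
            ident = float((mat[i][both] == mat[j][both]).sum() / total)
            out[i, j] = out[j, i] = ident
    return out


def build_landscape(families: Mapping[str, Sequence[float]],
                    density: Mapping[str, float],
                    bin_width: float = 1.0) -> list[LandscapePoint]:
    """Density-weighted identity histograms.

    `families` maps family id -> pairwise identities (fractions in [0, 1]);
    `density` maps family id -> genomic fraction. Each family's histogram is
    scaled so its bin masses sum to the family's density, conserving total
    genomic TE mass across the landscape.
    """
    edges = np.arange(0.0, 100.0 + bin_width / 2, bin_width)
    points: list[LandscapePoint] = []
    for fam in sorted(families):
        dens = float(density[fam])
        if dens < 0:
            raise ValueError(f"negative density for {fam}")
        idents = np.asarray([x for x in families[fam] if not np.isnan(x)], dtype=float)
        if idents.size == 0 or dens == 0:
            continue
        hist, _ = np.histogram(idents * 100.0, bins=edges)
        total = hist.sum()
        for b, count in enumerate(hist):
            if count:
                points.append(LandscapePoint(family_id=fam,
                                             bin_lower=float(edges[b]),
                                             bin_upper=float(edges[b + 1]),
                                             mass=dens * count / total))
    return points


def landscape_from_hits(genome: Mapping[str, str],
                        hits: Sequence[RepeatHit],
                        library: Sequence[TEConsensus],
                        bin_width: float = 1.0,
                        min_copies: int = 2) -> list[LandscapePoint]:
    """End-to-end landscape from resolved/merged genomic hits."""
    lib = {c.id: c for c in library}
    by_family: dict[str, list[RepeatHit]] = {}
    for h in hits:
        by_family.setdefault(h.family_id, []).append(h)
    genome_bp = sum(len(s) for s in genome.values())
    identities: dict[str, np.ndarray] = {}
    densities: dict[str, float] = {}
    for fam, fam_hits in by_family.items():
        densities[fam] = sum(h.end - h.start for h in fam_hits) / genome_bp
        if len(fam_hits) < min_copies:
            continue
        copies = {}
        for i, h in enumerate(fam_hits):
            seq = genome[h.chrom][h.start:h.end]
            copies[f"{h.chrom}:{h.start}-{h.end}"] = (
                seq if h.strand == "+" else revcomp(seq))
        aln = anchor_align_copies(copies, lib[fam])
        mat = pairwise_identity(aln)
        iu = np.triu_indices(len(mat), k=1)
        identities[fam] = mat[iu]
    return build_landscape(identities,
                           {f: densities[f] for f in identities},
                           bin_width=bin_width)
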