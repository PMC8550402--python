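"""Shared alignment machinery.

A desk-scale seeded aligner: exact k-mer seeds located through a sorted
numpy index, chained on near-constant diagonals, verified with edlib
edit-distance alignment and rescored under a configurable match/mismatch/gap
scheme, then extended ungapped with an X-drop rule. This is the workhorse
behind genome masking, read-to-consensus mapping and read relocation.

Pairwise scoring of library consensi and peptides goes through
Bio.Align.PairwiseAligner; the ungapped Karlin-Altschul statistics used for
redundancy e-values are computed here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional

import edlib
import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.optimize import brentq

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """2-bit encode; non-ACGT positions get 255 (excluded from k-mers)."""
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmer_codes(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mer codes of `seq` and their start positions (N-free only)."""
    enc = encode(seq)
    n = len(enc) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(enc, k)
    valid = (windows != 255).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    codes = windows.astype(np.uint64) @ powers
    pos = np.nonzero(valid)[0]
    return codes[valid], pos


@dataclass
class ScoringScheme:
    """Raw alignment scoring; defaults match the masker contract."""

    match: float = 1.0
    mismatch: float = -2.0
    gap: float = -3.0  # per gapped base


@dataclass
class FragmentAlignment:
    """Alignment of a query fragment placed inside a target window."""

    target_start: int
    target_end: int
    matches: int
    mismatches: int
    gaps: int
    score: float

    @property
    def columns(self) -> int:
        return self.matches + self.mismatches + self.gaps

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


class KmerIndex:
    """Sorted-array exact k-mer index over a set of named sequences."""

    def __init__(self, seqs: Mapping[str, str], k: int):
        if not 8 <= k <= 32:
            raise ValueError("k must be in [8, 32]")
        if not seqs:
            raise ValueError("empty sequence set")
        self.k = k
        self.names = list(seqs)
        self.seqs = dict(seqs)
        codes_parts, pos_parts, ref_parts = [], [], []
        self.lengths = {}
        for ref_idx, (name, seq) in enumerate(seqs.items()):
            self.lengths[name] = len(seq)
            codes, pos = kmer_codes(seq, k)
            codes_parts.append(codes)
            pos_parts.append(pos)
            ref_parts.append(np.full(len(pos), ref_idx, dtype=np.int32))
        codes = np.concatenate(codes_parts)
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.positions = np.concatenate(pos_parts)[order]
        self.refs = np.concatenate(ref_parts)[order]

    def seed_matches(self, query: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(query_pos, ref_idx, ref_pos) of every exact k-mer match."""
        qcodes, qpos = kmer_codes(query, self.k)
        if len(qcodes) == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z.astype(np.int32), z
        lo = np.searchsorted(self.codes, qcodes, side="left")
        hi = np.searchsorted(self.codes, qcodes, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z.astype(np.int32), z
        q_out = np.repeat(qpos, counts)
        idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        return q_out, self.refs[idx], self.positions[idx]


@dataclass
class SeedCluster:
    ref: str
    q_start: int
    q_end: int  # on query, half-open, includes k
    t_start: int
    t_end: int
    n_seeds: int


def cluster_seeds(query: str, index: KmerIndex, *, band: int = 50,
                  max_seed_gap: int = 400, min_seeds: int = 1) -> list[SeedCluster]:
    """Chain seed matches into candidate loci.

    Matches on the same reference whose diagonals agree within `band` and
    whose target positions advance by less than `max_seed_gap` form one
    cluster; this tolerates point divergence and small indels.
    """
    qpos, refs, tpos = index.seed_matches(query)
    if len(qpos) == 0:
        return []
    diag = tpos - qpos
    order = np.lexsort((tpos, diag, refs))
    qpos, refs, tpos, diag = qpos[order], refs[order], tpos[order], diag[order]
    k = index.k
    clusters: list[SeedCluster] = []
    cur: Optional[list] = None  # [ref, qlo, qhi, tlo, thi, n, last_diag, last_t]
    for q, r, t, d in zip(qpos, refs, tpos, diag):
        if (cur is None or r != cur[0] or abs(int(d) - cur[6]) > band
                or int(t) - cur[7] > max_seed_gap):
            if cur is not None and cur[5] >= min_seeds:
                clusters.append(SeedCluster(index.names[cur[0]], cur[1], cur[2] + k,
                                            cur[3], cur[4] + k, cur[5]))
            cur = [int(r), int(q), int(q), int(t), int(t), 1, int(d), int(t)]
        else:
            cur[1] = min(cur[1], int(q))
            cur[2] = max(cur[2], int(q))
            cur[3] = min(cur[3], int(t))
            cur[4] = max(cur[4], int(t))
            cur[5] += 1
            cur[6] = int(d)
            cur[7] = int(t)
    if cur is not None and cur[5] >= min_seeds:
        clusters.append(SeedCluster(index.names[cur[0]], cur[1], cur[2] + k,
                                    cur[3], cur[4] + k, cur[5]))
    return clusters


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    matches = mismatches = gaps = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        if op == "=":
            matches += n
        elif op in "XM":
            mismatches += n
        else:
            gaps += n
    return matches, mismatches, gaps


def align_fragment(query: str, target: str,
                   scheme: ScoringScheme = ScoringScheme()) -> Optional[FragmentAlignment]:
    """Best placement of the whole `query` inside `target` (edlib HW mode).

    The edit-distance-optimal path is rescored under `scheme`; for the
    substitution-dominated divergence this pipeline handles, the two optima
    coincide for all practical purposes.
    """
    if not query or not target:
        return None
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    t0, t1 = res["locations"][0]
    m, x, g = _cigar_stats(res["cigar"])
    score = m * scheme.match + x * scheme.mismatch + g * scheme.gap
    return FragmentAlignment(t0, t1 + 1, m, x, g, score)


def extend_ungapped(query: str, target: str, q_pos: int, t_pos: int,
                    direction: int, scheme: ScoringScheme = ScoringScheme(),
                    xdrop: float = 30.0) -> tuple[int, int, float, int, int]:
    """Greedy ungapped X-drop extension from (q_pos, t_pos).

    direction +1 extends to the right starting AT the given positions;
    -1 extends to the left starting just BEFORE them. Returns
    (q_extent, t_extent, score_gain, matches, mismatches) of the best prefix.

    Only the best-scoring prefix is reported, so a generous `xdrop` cannot
    extend a hit into flanking sequence; it governs how large a local
    mismatch cluster the extension survives (a dip of 30 under +1/-2 scoring
    is vanishingly unlikely below ~50% local divergence).
    """
    best = (0, 0, 0.0, 0, 0)
    score = 0.0
    matches = mismatches = 0
    i = 0
    while True:
        if direction > 0:
            q, t = q_pos + i, t_pos + i
            if q >= len(query) or t >= len(target):
                break
        else:
            q, t = q_pos - 1 - i, t_pos - 1 - i
            if q < 0 or t < 0:
                break
        if query[q] == target[t]:
            score += scheme.match
            matches += 1
        else:
            score += scheme.mismatch
            mismatches += 1
        i += 1
        if score > best[2]:
            best = (i, i, score, matches, mismatches)
        elif best[2] - score > xdrop:
            break
    return best


# ---------------------------------------------------------------------------
# Pairwise aligners (Bio.Align) and Karlin-Altschul statistics
# ---------------------------------------------------------------------------

def dna_local_aligner(match: float = 1.0, mismatch: float = -2.0,
                      gap: float = -3.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def dna_global_aligner(match: float = 1.0, mismatch: float = -1.0,
                       gap: float = -2.0, free_end_gaps: bool = True) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    if free_end_gaps:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    return aligner


def protein_local_aligner(open_gap: float = -11.0, extend_gap: float = -1.0) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def alignment_identity(alignment) -> tuple[int, int, float]:
    """(matches, columns, identity) of a Bio.Align alignment.

    Columns count aligned pairs plus internal gaps; identity = matches/columns.
    """
    target = alignment.target
    query = alignment.query
    matches = 0
    aligned_cols = 0
    gap_cols = 0
    blocks_t, blocks_q = alignment.aligned
    prev_t_end = prev_q_end = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t_end is not None:
            gap_cols += (ts - prev_t_end) + (qs - prev_q_end)
        for a, b in zip(target[ts:te], query[qs:qe]):
            if a == b:
                matches += 1
        aligned_cols += te - ts
        prev_t_end, prev_q_end = te, qe
    columns = aligned_cols + gap_cols
    return matches, columns, (matches / columns if columns else 0.0)


@lru_cache(maxsize=None)
def karlin_lambda(match: float = 1.0, mismatch: float = -2.0) -> float:
    """Ungapped Karlin-Altschul lambda for a uniform-composition DNA scheme.

    Solves sum_ij p_i p_j exp(lambda * s_ij) = 1 with p = 1/4.
    """

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-6, 10.0))


# K is held constant: only a monotone transform of the score is needed for a
# fixed-threshold redundancy cut, and 0.1 is a typical ungapped DNA value.
KARLIN_K = 0.1


def karlin_evalue(score: float, m: int, n: int,
                  match: float = 1.0, mismatch: float = -2.0) -> float:
    lam = karlin_lambda(match, mismatch)
    # exp() underflows to 0.0 for strong scores, which is the right limit
    with np.errstate(under="ignore"):
        return float(KARLIN_K * m * n * np.exp(-lam * score))
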