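"""Synthetic data with planted ground truth.

Generates TE consensus libraries, genomes carrying full-length and fragmented
insertions at controlled divergence, two-condition negative-binomial count
matrices with planted log2 fold changes, error-bearing reads, and small-n
qPCR Ct tables. Every generator is deterministic for a fixed seed; the
zero-noise limits reproduce their inputs exactly, which the test suite uses
as oracles.

The default study design mirrors a two-condition larval RNA-seq comparison
(10 wildtype vs 10 transgenic melanoma samples).
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._rng import stream
from .align import revcomp
from .models import CountMatrix, SimulationTruth, TEConsensus, TE_CLASSES, format_family_id

BASES = np.array(list("ACGT"))

# Superfamily labels attached per class in generated ids (field vocabulary).
_SUPERFAMILIES = {
    "DNA": ["hAT-Ac", "TcMar-Tc1", "PIF-Harbinger"],
    "RC": ["Helitron"],
    "LINE": ["I", "L1", "L2", "Rex-Babar"],
    "SINE": ["tRNA", "5S"],
    "LTR": ["Gypsy", "Copia", "ERVK", "Pao"],
    "Retro non-LTR": ["Penelope"],
    "Retro unclassified": [None],
    "Unknown": [None],
}

DEFAULT_CLASS_MIX = {"DNA": 0.35, "LINE": 0.25, "LTR": 0.20, "SINE": 0.05,
                     "RC": 0.05, "Unknown": 0.10}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def generate_te_library(n_families: int,
                        class_mix: Optional[Mapping[str, float]] = None,
                        length_range: tuple[int, int] = (500, 3000),
                        seed: int = 0,
                        ltr_length: int = 300,
                        polya_length: int = 20) -> list[TEConsensus]:
    """Random consensus library with class-informed structure.

    LTR consensi carry identical terminal repeats of `ltr_length`; LINE
    consensi end in a poly-A tract. Class counts follow `class_mix` by
    largest-remainder apportionment so the realized mix matches the requested
    proportions as closely as integers allow.
    """
    if n_families <= 0:
        raise ValueError("n_families must be positive")
    class_mix = dict(DEFAULT_CLASS_MIX) if class_mix is None else dict(class_mix)
    if not class_mix:
        raise ValueError("empty class_mix")
    unknown = set(class_mix) - set(TE_CLASSES)
    if unknown:
        raise ValueError(f"unknown TE classes: {sorted(unknown)}")
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    lo, hi = length_range
    if lo < 80:
        raise ValueError("minimum consensus length must be >= 80")

    # largest-remainder apportionment of n_families over classes
    raw = {c: p * n_families for c, p in class_mix.items()}
    counts = {c: math.floor(v) for c, v in raw.items()}
    short = n_families - sum(counts.values())
    for c in sorted(raw, key=lambda c: (raw[c] - counts[c], c), reverse=True)[:short]:
        counts[c] += 1

    rng = stream(seed, "te_library")
    consensi: list[TEConsensus] = []
    i = 0
    for te_class in sorted(counts):
        for _ in range(counts[te_class]):
            length = int(rng.integers(lo, hi + 1))
            if te_class == "LTR":
                length = max(length, 2 * ltr_length + 100)
                ltr = _random_seq(rng, ltr_length)
                internal = _random_seq(rng, length - 2 * ltr_length)
                seq = ltr + internal + ltr
            elif te_class == "LINE":
                length = max(length, polya_length + 80)
                seq = _random_seq(rng, length - polya_length) + "A" * polya_length
            else:
                seq = _random_seq(rng, length)
            supers = _SUPERFAMILIES.get(te_class, [None])
            superfamily = supers[int(rng.integers(0, len(supers)))]
            fam_id = format_family_id(f"Olat_sim_family-{i}", te_class, superfamily)
            consensi.append(TEConsensus(id=fam_id, sequence=seq, te_class=te_class,
                                        superfamily=superfamily))
            i += 1
    return consensi


def mutate(sequence: str, divergence: float, rng: np.random.Generator,
           indel_rate: float = 0.0) -> str:
    """Point-substitute a fraction `divergence` of positions (plus optional
    indels); each substituted base is replaced by a different base."""
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    arr = np.frombuffer(sequence.encode(), dtype=np.uint8).copy()
    n = len(arr)
    hit = rng.random(n) < divergence
    idx = np.nonzero(hit)[0]
    lut = {ord(b): [ord(x) for x in "ACGT" if x != b] for b in "ACGT"}
    for i in idx:
        choices = lut.get(arr[i])
        if choices:
            arr[i] = choices[int(rng.integers(0, 3))]
    seq = arr.tobytes().decode()
    if indel_rate > 0:
        out = []
        for ch in seq:
            r = rng.random()
            if r < indel_rate / 2:
                continue  # deletion
            out.append(ch)
            if r > 1 - indel_rate / 2:
                out.append(str(BASES[rng.integers(0, 4)]))  # insertion
        seq = "".join(out)
    return seq


def plant_insertions(genome_length: int,
                     library: Sequence[TEConsensus],
                     copies_per_family: Mapping[str, int],
                     divergence_spec: Mapping[str, Sequence[float]],
                     truncation_prob: float = 0.0,
                     seed: int = 0,
                     indel_rate: float = 0.0,
                     min_gap: int = 50,
                     chrom: str = "chr1",
                     max_retries: int = 200) -> tuple[dict[str, str], SimulationTruth]:
    """Plant diverged TE copies into a random background genome.

    Each copy is the consensus mutated at its stated divergence, reverse
    complemented with probability 1/2, and with probability `truncation_prob`
    truncated to a uniform(0.2, 0.7) fraction from the 5' or 3' end (fragments
    thus never reach the 90% full-length mark). Placement is non-overlapping
    with at least `min_gap` bp between copies so downstream 20 bp fragment
    merging cannot fuse independent insertions.
    """
    lib = {c.id: c for c in library}
    rng = stream(seed, "plant_insertions")
    planned: list[tuple[str, str, bool, float]] = []  # (family, seq, full, div)
    for fam in sorted(copies_per_family):
        n_copies = copies_per_family[fam]
        divs = list(divergence_spec.get(fam, [0.0]))
        for j in range(n_copies):
            div = float(divs[j % len(divs)])
            seq = mutate(lib[fam].sequence, div, rng, indel_rate=indel_rate)
            full = True
            if truncation_prob > 0 and rng.random() < truncation_prob:
                frac = rng.uniform(0.2, 0.7)
                keep = max(50, int(len(seq) * frac))
                seq = seq[:keep] if rng.random() < 0.5 else seq[-keep:]
                full = False
            if rng.random() < 0.5:
                seq = revcomp(seq)
                strand = "-"
            else:
                strand = "+"
            planned.append((fam, seq, full, div, strand))
    total_len = sum(len(p[1]) for p in planned)
    if total_len >= genome_length:
        raise ValueError("total planted length exceeds genome length")

    background = _random_seq(rng, genome_length)
    placed: list[tuple[int, int]] = []  # sorted occupied intervals

    def fits(s: int, e: int) -> bool:
        import bisect
        i = bisect.bisect_left(placed, (s, e))
        for j in (i - 1, i):
            if 0 <= j < len(placed):
                ps, pe = placed[j]
                if s < pe + min_gap and ps < e + min_gap:
                    return False
        return True

    import bisect
    insertions = []
    flags = []
    for fam, seq, full, div, strand in planned:
        L = len(seq)
        for _ in range(max_retries):
            s = int(rng.integers(0, genome_length - L))
            if fits(s, s + L):
                bisect.insort(placed, (s, s + L))
                insertions.append((fam, chrom, s, s + L, strand, div, seq))
                flags.append(full)
                break
        else:
            raise RuntimeError("could not place insertion without overlap; "
                               "reduce copies or enlarge the genome")

    genome = list(background)
    for fam, _, s, e, strand, div, seq in insertions:
        genome[s:e] = seq
    truth = SimulationTruth(
        seed=seed,
        planted_insertions=[(f, c, s, e, st, d) for f, c, s, e, st, d, _ in insertions],
        full_length_flags=flags,
    )
    return {chrom: "".join(genome)}, truth


def simulate_read_counts(library: Sequence[TEConsensus],
                         n_per_condition: int,
                         base_mean: Mapping[str, float],
                         log2fc: Mapping[str, float],
                         dispersion: Mapping[str, float],
                         seed: int = 0,
                         conditions: tuple[str, str] = ("wildtype", "tg"),
                         ) -> tuple[CountMatrix, SimulationTruth]:
    """Two-condition NB counts: mean = base_mean in condition A and
    base_mean * 2**log2fc in condition B, var = mu + alpha * mu^2."""
    if n_per_condition < 2:
        raise ValueError("need at least 2 samples per condition")
    rng = stream(seed, "read_counts")
    fams = [c.id for c in library]
    cond_a, cond_b = conditions
    samples = ([f"{cond_a}_{i + 1}" for i in range(n_per_condition)]
               + [f"{cond_b}_{i + 1}" for i in range(n_per_condition)])
    cond_map = {s: (cond_a if i < n_per_condition else cond_b)
                for i, s in enumerate(samples)}
    mat = np.zeros((len(fams), 2 * n_per_condition), dtype=np.int64)
    for i, fam in enumerate(fams):
        mu_a = float(base_mean.get(fam, 0.0))
        if mu_a < 0:
            raise ValueError("base_mean must be >= 0")
        alpha = float(dispersion.get(fam, 0.0))
        if alpha < 0:
            raise ValueError("dispersion must be >= 0")
        mu_b = mu_a * 2.0 ** float(log2fc.get(fam, 0.0))
        for j, mu in enumerate([mu_a] * n_per_condition + [mu_b] * n_per_condition):
            if mu == 0:
                continue
            if alpha == 0:
                mat[i, j] = rng.poisson(mu)
            else:
                r = 1.0 / alpha
                mat[i, j] = rng.negative_binomial(r, r / (r + mu))
    counts = pd.DataFrame(mat, index=fams, columns=samples)
    truth = SimulationTruth(seed=seed,
                            planted_log2fc={f: float(log2fc.get(f, 0.0)) for f in fams},
                            true_counts=counts.copy())
    return CountMatrix(counts=counts, conditions=cond_map), truth


def render_reads(sources: Mapping[str, str],
                 true_counts: Mapping[str, int],
                 read_length: int = 100,
                 error_rate: float = 0.0,
                 seed: int = 0) -> list[tuple[str, str, str]]:
    """Sample reads uniformly along each source sequence.

    Returns (read_id, description, sequence) triplets; the description
    carries the truth tag (`src=<name> start=<pos>`) and is never consumed by
    production code paths. Substitution errors are i.i.d. at `error_rate`.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    shortest = min((len(s) for n, s in sources.items() if true_counts.get(n, 0) > 0),
                   default=read_length)
    if read_length > shortest:
        raise ValueError("read_length exceeds shortest source with reads")
    rng = stream(seed, "render_reads")
    reads = []
    serial = 0
    for name in sorted(true_counts):
        n_reads = true_counts[name]
        seq = sources[name]
        for _ in range(n_reads):
            start = int(rng.integers(0, len(seq) - read_length + 1))
            frag = seq[start:start + read_length]
            if error_rate > 0:
                frag = mutate(frag, error_rate, rng)
            reads.append((f"r{serial:07d}", f"src={name} start={start}", frag))
            serial += 1
    return reads


def simulate_ct_table(n_per_group: int,
                      true_dct_shift: float,
                      sd: float,
                      seed: int = 0,
                      groups: tuple[str, str] = ("wildtype", "tg"),
                      target_gene: str = "te_target",
                      reference_gene: str = "efa1",
                      base_reference_ct: float = 18.0,
                      base_dct: float = 5.0) -> pd.DataFrame:
    """Small-n Ct table: per sample one target and one reference record.

    Group 2's Delta-Ct differs from group 1's by `true_dct_shift`; Gaussian
    noise of `sd` cycles is applied to every Ct measurement independently.
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = stream(seed, "ct_table")
    rows = []
    for g_idx, group in enumerate(groups):
        dct = base_dct + (true_dct_shift if g_idx == 1 else 0.0)
        for i in range(n_per_group):
            sample = f"{group}_{i + 1}"
            ct_ref = base_reference_ct + rng.normal(0.0, sd) if sd > 0 else base_reference_ct
            ct_tgt = base_reference_ct + dct + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            rows.append((sample, group, reference_gene, ct_ref))
            rows.append((sample, group, target_gene, ct_tgt))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
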