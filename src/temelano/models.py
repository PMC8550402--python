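"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere in memory; conversion to 1-based
happens only at BED/GFF boundaries in :mod:`temelano.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import pandas as pd

# Class vocabulary used throughout (mirrors the repeat-annotation convention
# of a curated fish TE library).
TE_CLASSES = (
    "DNA",
    "RC",
    "LINE",
    "SINE",
    "LTR",
    "Retro non-LTR",
    "Retro unclassified",
    "Unknown",
)

SOURCES = ("denovo", "helitron_candidate", "ltr_candidate", "sine_candidate")


def parse_family_id(family_id: str) -> tuple[str, str, Optional[str]]:
    """Split a `Name#Class/Superfamily` identifier.

    Returns (name, te_class, superfamily); superfamily is None when absent.
    Identifiers without a '#' are treated as class Unknown.
    """
    if "#" not in family_id:
        return family_id, "Unknown", None
    name, _, rest = family_id.partition("#")
    te_class, _, superfamily = rest.partition("/")
    return name, te_class, superfamily or None


def format_family_id(name: str, te_class: str, superfamily: Optional[str] = None) -> str:
    if superfamily:
        return f"{name}#{te_class}/{superfamily}"
    return f"{name}#{te_class}"


@dataclass
class TEConsensus:
    """One curated repeat-family consensus sequence."""

    id: str
    sequence: str
    te_class: str = "Unknown"
    superfamily: Optional[str] = None
    source: str = "denovo"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def name(self) -> str:
        return parse_family_id(self.id)[0]

    @classmethod
    def from_header(cls, header: str, sequence: str, source: str = "denovo") -> "TEConsensus":
        name, te_class, superfamily = parse_family_id(header)
        return cls(id=header, sequence=sequence, te_class=te_class,
                   superfamily=superfamily, source=source)

    def reclassified(self, te_class: str, superfamily: Optional[str] = None) -> "TEConsensus":
        """Copy with a new classification and id suffix updated to match."""
        new_id = format_family_id(self.name, te_class, superfamily)
        return replace(self, id=new_id, te_class=te_class, superfamily=superfamily)


@dataclass
class PairwiseMatch:
    """One scored alignment between two library consensi."""

    query_id: str
    subject_id: str
    align_len_query: int
    align_len_subject: int
    identity: float
    score: float
    evalue: float


@dataclass
class TerminalRepeat:
    """A repeated pair near the two ends of a consensus (LTR/satellite flag)."""

    left: tuple[int, int]
    right: tuple[int, int]
    identity: float
    length: int


@dataclass
class RepeatHit:
    """One scored genomic alignment of a consensus."""

    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    score: float
    identity: float
    consensus_start: int
    consensus_end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.start}..{self.end}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadAssignment:
    """A read assigned to one consensus location (ties broken at random)."""

    read_id: str
    family_id: str
    consensus_start: int
    consensus_end: int
    strand: str
    score: float
    n_equal_best: int


@dataclass
class GenomicReadPos:
    """Genomic relocation of a TE-assigned read."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    family_id: str


@dataclass
class CountMatrix:
    """Family x sample integer read counts with condition labels."""

    counts: pd.DataFrame  # index = family ids, columns = sample ids
    conditions: Mapping[str, str]  # sample id -> condition label

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]


@dataclass
class LandscapePoint:
    """One (family, identity bin) point of the divergence landscape."""

    family_id: str
    bin_lower: float  # percent
    bin_upper: float
    mass: float  # genome-fraction units


@dataclass
class ORFRecord:
    """An ATG-initiated, stop-terminated open reading frame."""

    frame: int  # +1,+2,+3,-1,-2,-3
    start: int  # forward-strand coordinates, 0-based half-open, stop included
    end: int
    peptide: str


@dataclass
class DomainHit:
    """A protein-domain similarity hit inside one ORF."""

    orf: ORFRecord
    domain_label: str
    score: float
    peptide_start: int
    peptide_end: int


@dataclass
class GenomeCopy:
    """One genomic copy of a family with consensus coverage and score ratio."""

    family_id: str
    chrom: str
    start: int
    end: int
    strand: str
    consensus_coverage: float
    score_ratio: float
    full_length: bool = False


@dataclass
class Transcript:
    """Minimal gene model: ordered exons of one transcript."""

    gene_id: str
    tx_id: str
    chrom: str
    strand: str  # '+', '-' or '.' (unstranded)
    exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.exons), max(e for _, e in self.exons)

    @property
    def last_exon(self) -> tuple[int, int]:
        """3'-most exon (strand-aware); None-like ValueError if unstranded."""
        exons = sorted(self.exons)
        if self.strand == "+":
            return exons[-1]
        if self.strand == "-":
            return exons[0]
        raise ValueError("unstranded transcript has no defined last exon")


@dataclass
class SimulationTruth:
    """Ground truth of a synthetic dataset."""

    seed: int
    planted_insertions: list[tuple[str, str, int, int, str, float]] = field(
        default_factory=list)  # (family, chrom, start, end, strand, divergence)
    full_length_flags: list[bool] = field(default_factory=list)
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    true_counts: Optional[pd.DataFrame] = None

    def insertions_of(self, family_id: str) -> list[tuple[str, str, int, int, str, float]]:
        return [t for t in self.planted_insertions if t[0] == family_id]


def as_int_array(values) -> np.ndarray:
    arr = np.asarray(values)
    if not np.issubdtype(arr.dtype, np.integer):
        raise TypeError("integer array required")
    return arr
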