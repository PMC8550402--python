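"""File-format boundaries.

FASTA/FASTQ through Biopython, GFF3 through gffutils, tables through pandas.
All in-memory coordinates are 0-based half-open; conversion to 1-based
happens here and only here (GFF3 input, BED output is already half-open).
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (GenomicReadPos, LandscapePoint, RepeatHit, TEConsensus,
                     Transcript)

HIT_COLUMNS = ["family_id", "chrom", "start", "end", "strand", "score",
               "identity", "consensus_start", "consensus_end"]


def read_library(path) -> list[TEConsensus]:
    """Read a consensus library FASTA with `Name#Class/Superfamily` headers."""
    return [TEConsensus.from_header(rec.id, str(rec.seq))
            for rec in SeqIO.parse(str(path), "fasta")]


def write_library(library: Sequence[TEConsensus], path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in library]
    SeqIO.write(records, str(path), "fasta")


def read_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_genome(genome: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    """Write (read_id, description, sequence) triplets as Phred+33 FASTQ with
    constant quality 'I' (Q40)."""
    with open(path, "w") as fh:
        for read_id, description, seq in reads:
            header = f"@{read_id} {description}".rstrip()
            fh.write(f"{header}\n{seq}\n+\n{'I' * len(seq)}\n")


def hits_to_frame(hits: Sequence[RepeatHit]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(h, c) for c in HIT_COLUMNS} for h in hits],
                        columns=HIT_COLUMNS)


def write_hits(hits: Sequence[RepeatHit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits(path) -> list[RepeatHit]:
    df = pd.read_csv(path, sep="\t")
    return [RepeatHit(**{c: row[c] for c in HIT_COLUMNS})
            for _, row in df.iterrows()]


def write_hits_bed(hits: Sequence[RepeatHit], path) -> None:
    """BED6 export: name = family id, score clipped to 0-1000."""
    with open(path, "w") as fh:
        for h in hits:
            score = int(min(1000, max(0, round(h.score))))
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\t{h.family_id}\t{score}\t{h.strand}\n")


def write_positions_bed(positions: Sequence[GenomicReadPos], path) -> None:
    with open(path, "w") as fh:
        for p in positions:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.read_id}\t0\t{p.strand}\n")


def write_landscape(points: Sequence[LandscapePoint], path) -> None:
    pd.DataFrame([{"family_id": p.family_id, "bin_lower": p.bin_lower,
                   "bin_upper": p.bin_upper, "mass": p.mass}
                  for p in points]).to_csv(path, sep="\t", index=False)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="family_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="family_id")


def write_conditions(conditions: Mapping[str, str], path) -> None:
    pd.Series(conditions, name="condition").rename_axis("sample").to_csv(path, sep="\t")


def read_conditions(path) -> dict[str, str]:
    return pd.read_csv(path, sep="\t", index_col="sample")["condition"].to_dict()


def read_ct_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_gff3_transcripts(path) -> list[Transcript]:
    """Load transcripts with ordered exons from a GFF3 file (via gffutils)."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    transcripts = []
    for tx in db.features_of_type(("mRNA", "transcript")):
        exons = [(e.start - 1, e.end)  # GFF3 is 1-based closed
                 for e in db.children(tx, featuretype="exon", order_by="start")]
        if not exons:
            continue
        parents = list(db.parents(tx, featuretype="gene"))
        gene_id = parents[0].id if parents else tx.attributes.get("Parent", [tx.id])[0]
        transcripts.append(Transcript(gene_id=gene_id, tx_id=tx.id, chrom=tx.seqid,
                                      strand=tx.strand if tx.strand in "+-" else ".",
                                      exons=exons))
    return transcripts


def read_protein_fasta(path) -> dict[str, str]:
    """Peptide FASTA as label -> sequence (label = full header id)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
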