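"""Transcript-space reference models: FASTA + GFF3 + biotype table in, validated models out.

All internal coordinates are 0-based half-open on the transcript; GFF3 I/O
converts to/from the 1-based closed convention. Position 0 of every
downstream metagene anchor is the first nucleotide of the start (or stop)
codon, which this convention makes unambiguous.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: hierarchical-mapping category order; reads are assigned to the first
#: category in this list where they hit.
CATEGORY_ORDER = ("rRNA", "tRNA", "snRNA", "snoRNA", "miRNA", "lncRNA", "mRNA")

BIOTYPES = frozenset(CATEGORY_ORDER)

UTR5, CDS, UTR3 = "utr5", "cds", "utr3"


class AnnotationError(ValueError):
    """Raised for inconsistent or incomplete reference input."""


@dataclass
class TranscriptModel:
    """One transcript: sequence (5'->3'), biotype, and UTR/CDS geometry.

    ``cds_start``/``cds_end`` are 0-based half-open transcript coordinates;
    they are ``None`` for non-mRNA biotypes. ``non_canonical`` flags mRNAs
    whose CDS length is not a multiple of three.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    sequence: str
    cds_start: int | None = None
    cds_end: int | None = None
    non_canonical: bool = False

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise AnnotationError(
                f"{self.transcript_id}: unknown biotype {self.biotype!r}"
            )
        if self.biotype == "mRNA":
            if self.cds_start is None or self.cds_end is None:
                raise AnnotationError(f"{self.transcript_id}: mRNA without CDS")
            if not (0 <= self.cds_start < self.cds_end <= len(self.sequence)):
                raise AnnotationError(
                    f"{self.transcript_id}: CDS [{self.cds_start}, {self.cds_end})"
                    f" outside transcript of length {len(self.sequence)}"
                )
            if (self.cds_end - self.cds_start) % 3 != 0 and not self.non_canonical:
                warnings.warn(
                    f"{self.transcript_id}: CDS length not a multiple of 3;"
                    " flagged non_canonical",
                    stacklevel=2,
                )
                self.non_canonical = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_mrna(self) -> bool:
        return self.biotype == "mRNA"

    @property
    def utr5_len(self) -> int:
        if not self.is_mrna:
            raise AnnotationError(f"{self.transcript_id}: no regions (not mRNA)")
        return self.cds_start

    @property
    def utr3_len(self) -> int:
        if not self.is_mrna:
            raise AnnotationError(f"{self.transcript_id}: no regions (not mRNA)")
        return self.length - self.cds_end

    @property
    def cds_len(self) -> int:
        return self.cds_end - self.cds_start

    def region_of(self, pos: int) -> str:
        return region_of(self, pos)


def region_of(transcript: TranscriptModel, pos: int) -> str:
    """Region (utr5/cds/utr3) containing transcript position ``pos``.

    Half-open convention: ``pos == cds_start`` is cds, ``pos == cds_end``
    is utr3.
    """
    if not transcript.is_mrna:
        raise AnnotationError(f"{transcript.transcript_id}: no regions (not mRNA)")
    if not 0 <= pos < transcript.length:
        raise AnnotationError(
            f"{transcript.transcript_id}: position {pos} out of bounds"
        )
    if pos < transcript.cds_start:
        return UTR5
    if pos < transcript.cds_end:
        return CDS
    return UTR3


@dataclass
class ReferenceSet:
    """All transcripts of a reference keyed by id, plus the category order."""

    transcripts: dict[str, TranscriptModel]
    category_order: tuple[str, ...] = CATEGORY_ORDER

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self.transcripts

    def __len__(self) -> int:
        return len(self.transcripts)

    def by_category(self, biotype: str) -> list[TranscriptModel]:
        return sorted(
            (t for t in self.transcripts.values() if t.biotype == biotype),
            key=lambda t: t.transcript_id,
        )

    def mrnas(self) -> list[TranscriptModel]:
        return self.by_category("mRNA")

    def categories_present(self) -> list[str]:
        present = {t.biotype for t in self.transcripts.values()}
        return [c for c in self.category_order if c in present]


def _read_biotype_table(biotype_table: str) -> dict[str, str]:
    df = pd.read_csv(
        io.StringIO(biotype_table),
        sep="\t",
        header=None,
        names=["transcript_id", "biotype"],
        dtype=str,
        comment="#",
    )
    return dict(zip(df.transcript_id, df.biotype))


def parse_reference(
    fasta_text: str, gff_text: str, biotype_table: str
) -> ReferenceSet:
    """Parse transcript FASTA + transcript-space GFF3 + biotype TSV.

    GFF coordinates (1-based closed) are converted to internal 0-based
    half-open. Every GFF transcript must have a FASTA sequence and a
    biotype-table entry; an mRNA whose CDS length is not a multiple of
    three is kept but flagged ``non_canonical`` with a warning.
    """
    seqs = {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(io.StringIO(fasta_text), "fasta")
    }
    biotypes = _read_biotype_table(biotype_table)
    db = gffutils.create_db(
        gff_text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    transcripts: dict[str, TranscriptModel] = {}
    cds_bounds: dict[str, list[int]] = {}
    for feat in db.features_of_type("CDS"):
        lo, hi = feat.start - 1, feat.end  # 1-based closed -> 0-based half-open
        if feat.seqid in cds_bounds:
            cds_bounds[feat.seqid][0] = min(cds_bounds[feat.seqid][0], lo)
            cds_bounds[feat.seqid][1] = max(cds_bounds[feat.seqid][1], hi)
        else:
            cds_bounds[feat.seqid] = [lo, hi]

    for feat in db.features_of_type("transcript"):
        tid = feat.seqid
        if tid not in seqs:
            raise AnnotationError(f"{tid}: transcript in GFF but not in FASTA")
        if tid not in biotypes:
            raise AnnotationError(f"{tid}: no biotype-table entry")
        biotype = biotypes[tid]
        gene_id = feat.attributes.get("gene_id", [tid])[0]
        cds_start = cds_end = None
        if biotype == "mRNA":
            if tid not in cds_bounds:
                raise AnnotationError(f"{tid}: mRNA without CDS feature")
            cds_start, cds_end = cds_bounds[tid]
        transcripts[tid] = TranscriptModel(
            transcript_id=tid,
            gene_id=gene_id,
            biotype=biotype,
            sequence=seqs[tid],
            cds_start=cds_start,
            cds_end=cds_end,
        )
    if not transcripts:
        raise AnnotationError("no transcript features in GFF")
    return ReferenceSet(transcripts=transcripts)


def write_reference(ref: ReferenceSet) -> tuple[str, str, str]:
    """Serialize a ReferenceSet back to (fasta_text, gff_text, biotype_tsv).

    Deterministic: transcripts are emitted in sorted id order, so the same
    ReferenceSet always yields byte-identical text.
    """
    fasta_records = []
    gff_lines = ["##gff-version 3"]
    biotype_lines = []
    for tid in sorted(ref.transcripts):
        t = ref.transcripts[tid]
        fasta_records.append(
            SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        )
        biotype_lines.append(f"{t.transcript_id}\t{t.biotype}")
        gff_lines.append(
            f"{tid}\tseedribo\ttranscript\t1\t{t.length}\t.\t+\t.\t"
            f"ID={tid};gene_id={t.gene_id};biotype={t.biotype}"
        )
        if t.is_mrna:
            if t.cds_start > 0:
                gff_lines.append(
                    f"{tid}\tseedribo\tfive_prime_UTR\t1\t{t.cds_start}\t.\t+\t.\t"
                    f"ID={tid}.utr5;Parent={tid}"
                )
            gff_lines.append(
                f"{tid}\tseedribo\tCDS\t{t.cds_start + 1}\t{t.cds_end}\t.\t+\t0\t"
                f"ID={tid}.cds;Parent={tid}"
            )
            if t.cds_end < t.length:
                gff_lines.append(
                    f"{tid}\tseedribo\tthree_prime_UTR\t{t.cds_end + 1}\t{t.length}"
                    f"\t.\t+\t.\tID={tid}.utr3;Parent={tid}"
                )
    fasta_io = io.StringIO()
    SeqIO.write(fasta_records, fasta_io, "fasta")
    return fasta_io.getvalue(), "\n".join(gff_lines) + "\n", "\n".join(biotype_lines) + "\n"
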