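"""Genome sequences and gene models.

Defines the coordinate conventions used throughout the package:

* internal coordinates are 0-based half-open on the forward genomic strand;
* GFF3 input/output converts at the boundary (1-based inclusive);
* ``phase0`` is the number of leading CDS bases (in transcription order)
  that belong to a codon begun upstream of the annotated CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import FormatError, ModelError

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class Contig:
    """A named genomic sequence over the alphabet {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise FormatError("contig name must be non-empty")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"contig {self.name!r}: illegal characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on a contig strand.

    ``start``/``end`` are always forward-strand offsets regardless of
    ``strand``; strand only affects transcription order.
    """

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ModelError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Transcript:
    """Exon/CDS geometry of one transcript.

    ``exons`` and ``cds`` are sorted by ascending genomic start; transcription
    order is ascending for '+' and descending for '-' transcripts.
    """

    id: str
    gene_id: str
    gene_name: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: tuple[GenomicInterval, ...]
    phase0: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        object.__setattr__(self, "cds", tuple(self.cds))
        if not self.exons:
            raise ModelError(f"transcript {self.id}: no exons")
        contigs = {iv.contig for iv in self.exons} | {iv.contig for iv in self.cds}
        strands = {iv.strand for iv in self.exons} | {iv.strand for iv in self.cds}
        if len(contigs) != 1 or strands != {self.strand}:
            raise ModelError(
                f"transcript {self.id}: exons/CDS must share one contig and strand"
            )
        for group_name, group in (("exons", self.exons), ("cds", self.cds)):
            for a, b in zip(group, group[1:]):
                if b.start < a.end:
                    raise ModelError(
                        f"transcript {self.id}: {group_name} overlap or are unsorted"
                    )
        for c in self.cds:
            if not any(e.start <= c.start and c.end <= e.end for e in self.exons):
                raise ModelError(
                    f"transcript {self.id}: CDS [{c.start},{c.end}) not contained "
                    "in any exon"
                )
        if self.cds_length < 3:
            raise ModelError(f"transcript {self.id}: total CDS length < 3")
        if self.phase0 not in (0, 1, 2):
            raise ModelError(f"transcript {self.id}: phase0 must be 0, 1 or 2")

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def cds_length(self) -> int:
        return sum(iv.length for iv in self.cds)

    @property
    def cds_transcription_order(self) -> tuple[GenomicInterval, ...]:
        """CDS intervals ordered 5'→3' along the transcript."""
        return self.cds if self.strand == "+" else tuple(reversed(self.cds))

    @property
    def n_codons(self) -> int:
        """Number of complete codons after discarding leader bases."""
        return (self.cds_length - self.phase0) // 3

    @property
    def protein_length(self) -> int:
        """Residue count, treating the final complete codon as the stop."""
        return self.n_codons - 1

    def cds_sequence(self, genome_index: dict[str, Contig]) -> str:
        """Spliced CDS in transcription order, leader bases included."""
        contig = genome_index[self.contig]
        parts = [contig.sequence[iv.start : iv.end] for iv in self.cds]
        seq = "".join(parts)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelError(f"gene {self.gene_id}: no transcripts")
        if any(t.gene_id != self.gene_id for t in self.transcripts):
            raise ModelError(f"gene {self.gene_id}: transcript gene_id mismatch")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneModel):
            return NotImplemented
        return (
            self.gene_id == other.gene_id
            and self.gene_name == other.gene_name
            and self.transcripts == other.transcripts
        )


def genome_index(contigs: Iterable[Contig]) -> dict[str, Contig]:
    """Index contigs by name, rejecting duplicates."""
    index: dict[str, Contig] = {}
    for c in contigs:
        if c.name in index:
            raise FormatError(f"duplicate contig name {c.name!r}")
        index[c.name] = c
    return index


def read_genome(path: str | Path) -> list[Contig]:
    """Read a multi-record FASTA into :class:`Contig` values.

    Sequences are upper-cased and U is converted to T; any residual character
    outside {A,C,G,T,N} raises :class:`FormatError`.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"duplicate contig name {record.id!r} in {path}")
        seen.add(record.id)
        seq = str(record.seq).upper().replace("U", "T")
        contigs.append(Contig(name=record.id, sequence=seq))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return contigs


def write_genome(contigs: Sequence[Contig], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.name}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def _downstream_phases(cds_lengths: Sequence[int], phase0: int) -> list[int]:
    """GFF3 phase for each CDS segment in transcription order."""
    phases = [phase0]
    consumed = -phase0
    for length in cds_lengths[:-1]:
        consumed += length
        phases.append((3 - consumed % 3) % 3)
    return phases


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon/CDS rows, ID/Parent links).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    ``phase0`` is read from the phase column of the transcription-order-first
    CDS row; downstream phases are recomputed from cumulative length and a
    warning is logged when the file disagrees.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        gene_name = gene.attributes.get("Name", [gene_id])[0]
        transcripts: list[Transcript] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            tx_id = mrna.attributes.get("ID", [mrna.id])[0]
            exon_rows = list(db.children(mrna, featuretype="exon", order_by="start"))
            cds_rows = list(db.children(mrna, featuretype="CDS", order_by="start"))
            if not cds_rows:
                logger.warning("mRNA %s has no CDS rows; skipped", tx_id)
                continue
            strand = mrna.strand
            exons = tuple(
                GenomicInterval(f.seqid, f.start - 1, f.end, strand)
                for f in exon_rows
            )
            cds = tuple(
                GenomicInterval(f.seqid, f.start - 1, f.end, strand)
                for f in cds_rows
            )
            # transcription-order-first CDS row: smallest start on '+',
            # largest start on '-'
            first_row = cds_rows[0] if strand == "+" else cds_rows[-1]
            if first_row.frame in (".", None):
                logger.warning(
                    "transcript %s: first CDS row has no phase; assuming 0", tx_id
                )
                phase0 = 0
            else:
                phase0 = int(first_row.frame)
            tx = Transcript(
                id=tx_id,
                gene_id=gene_id,
                gene_name=gene_name,
                strand=strand,
                exons=exons,
                cds=cds,
                phase0=phase0,
            )
            ordered_rows = cds_rows if strand == "+" else list(reversed(cds_rows))
            expected = _downstream_phases(
                [iv.length for iv in tx.cds_transcription_order], phase0
            )
            for row, want in zip(ordered_rows[1:], expected[1:]):
                if row.frame not in (".", None) and int(row.frame) != want:
                    logger.warning(
                        "transcript %s: CDS row at %d has phase %s, recomputed %d",
                        tx_id,
                        row.start,
                        row.frame,
                        want,
                    )
            transcripts.append(tx)
        if not transcripts:
            logger.warning("gene %s has no coding transcripts; skipped", gene_id)
            continue
        transcripts.sort(key=lambda t: t.id)
        models.append(GeneModel(gene_id=gene_id, gene_name=gene_name, transcripts=transcripts))
    models.sort(key=lambda g: g.gene_id)
    return models


def write_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3 (inverse of :func:`read_gene_models`)."""
    lines = ["##gff-version 3"]
    for gene in sorted(models, key=lambda g: g.gene_id):
        lo = min(t.exons[0].start for t in gene.transcripts)
        hi = max(t.exons[-1].end for t in gene.transcripts)
        contig = gene.transcripts[0].contig
        strand = gene.transcripts[0].strand
        lines.append(
            f"{contig}\tgenestruct\tgene\t{lo + 1}\t{hi}\t.\t{strand}\t.\t"
            f"ID={gene.gene_id};Name={gene.gene_name}"
        )
        for t in sorted(gene.transcripts, key=lambda t: t.id):
            lines.append(
                f"{t.contig}\tgenestruct\tmRNA\t{t.exons[0].start + 1}\t"
                f"{t.exons[-1].end}\t.\t{t.strand}\t.\tID={t.id};Parent={gene.gene_id}"
            )
            for e in t.exons:
                lines.append(
                    f"{t.contig}\tgenestruct\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{t.strand}\t.\tParent={t.id}"
                )
            phases = _downstream_phases(
                [iv.length for iv in t.cds_transcription_order], t.phase0
            )
            by_interval = dict(zip(t.cds_transcription_order, phases))
            for c in t.cds:
                lines.append(
                    f"{t.contig}\tgenestruct\tCDS\t{c.start + 1}\t{c.end}\t.\t"
                    f"{t.strand}\t{by_interval[c]}\tParent={t.id}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


#: Finding codes returned by :func:`validate_transcript`.
TRUNCATED = "truncated"
INTERNAL_STOP = "internal_stop"
NON_ATG_START = "non_atg_start"


def validate_transcript(t: Transcript, genome: Sequence[Contig]) -> list[str]:
    """Check a transcript against its genome; returns finding codes, never raises.

    Codes: ``truncated`` (CDS length minus phase0 not divisible by 3),
    ``internal_stop``, ``non_atg_start``. Empty list means clean.
    """
    findings: list[str] = []
    if (t.cds_length - t.phase0) % 3 != 0:
        findings.append(TRUNCATED)
    index = genome_index(genome)
    coding = t.cds_sequence(index)[t.phase0 :]
    coding = coding[: len(coding) - len(coding) % 3]
    if coding[:3] != "ATG":
        findings.append(NON_ATG_START)
    translated = str(Seq(coding).translate())
    if "*" in translated[:-1]:
        findings.append(INTERNAL_STOP)
    return findings
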