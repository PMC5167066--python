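"""Bidirectional arithmetic between genomic and protein coordinates.

Forward queries (:func:`genomic_to_protein`) and reverse queries
(:func:`protein_to_codon`) are computed by interval arithmetic over the CDS
segments — no per-base table is materialised. :func:`cds_base_order`
enumerates bases explicitly and is the basis of the independent oracle used
in the test-suite.

Conventions: leader bases (the first ``phase0`` CDS bases in transcription
order) belong to an upstream, unannotated codon and map to nothing; the final
complete codon is treated as the stop codon and likewise has no residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .errors import CoordinateRangeError
from .genome_model import Contig, Transcript, genome_index

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class ProteinPosition:
    """A residue of a transcript's protein, plus which codon base was hit."""

    transcript_id: str
    protein_pos: int  # 1-based
    codon_offset: int  # 0..2, transcription order


@dataclass(frozen=True)
class CodonLocus:
    """The three genomic bases (transcription order) encoding one residue."""

    transcript_id: str
    protein_pos: int
    contig: str
    strand: str
    base_positions: tuple[int, int, int]
    codon: str
    amino_acid: str


def cds_base_order(t: Transcript) -> list[int]:
    """Every CDS base exactly once, as genomic offsets in transcription order.

    The first ``t.phase0`` entries are leader bases excluded from codon
    numbering; codon *i* (1-based) occupies entries
    ``phase0 + 3*(i-1) .. phase0 + 3*i - 1``.
    """
    order: list[int] = []
    if t.strand == "+":
        for iv in t.cds:
            order.extend(range(iv.start, iv.end))
    else:
        for iv in reversed(t.cds):
            order.extend(range(iv.end - 1, iv.start - 1, -1))
    return order


def _cds_index(t: Transcript, pos: int) -> int | None:
    """Transcription-order CDS index of a genomic offset, or None."""
    cum = 0
    if t.strand == "+":
        for iv in t.cds:
            if iv.contains(pos):
                return cum + (pos - iv.start)
            cum += iv.length
    else:
        for iv in reversed(t.cds):
            if iv.contains(pos):
                return cum + (iv.end - 1 - pos)
            cum += iv.length
    return None


def genomic_to_protein(t: Transcript, pos: int) -> ProteinPosition | None:
    """Map a genomic offset to a residue of ``t``.

    Returns ``None`` for intronic/intergenic/UTR offsets, leader bases and
    the stop codon.
    """
    idx = _cds_index(t, pos)
    if idx is None:
        return None
    k = idx - t.phase0
    if k < 0:
        return None  # leader base of an upstream codon
    protein_pos = k // 3 + 1
    if protein_pos > t.protein_length:
        return None  # stop codon or trailing partial codon
    return ProteinPosition(
        transcript_id=t.id, protein_pos=protein_pos, codon_offset=k % 3
    )


def _genomic_offset(t: Transcript, cds_idx: int) -> int:
    """Inverse of :func:`_cds_index` by cumulative interval lengths."""
    cum = 0
    if t.strand == "+":
        for iv in t.cds:
            if cds_idx < cum + iv.length:
                return iv.start + (cds_idx - cum)
            cum += iv.length
    else:
        for iv in reversed(t.cds):
            if cds_idx < cum + iv.length:
                return iv.end - 1 - (cds_idx - cum)
            cum += iv.length
    raise CoordinateRangeError(f"CDS index {cds_idx} out of range for {t.id}")


def protein_to_codon(
    t: Transcript, protein_pos: int, genome: Sequence[Contig]
) -> CodonLocus:
    """The codon of residue ``protein_pos`` (1-based) of transcript ``t``.

    A codon spanning an exon junction yields non-contiguous base positions.
    """
    if not 1 <= protein_pos <= t.protein_length:
        raise CoordinateRangeError(
            f"protein_pos {protein_pos} outside valid range "
            f"[1, {t.protein_length}] for transcript {t.id}"
        )
    base = t.phase0 + 3 * (protein_pos - 1)
    positions = tuple(_genomic_offset(t, base + o) for o in range(3))
    contig = genome_index(genome)[t.contig]
    if t.strand == "+":
        codon = "".join(contig.sequence[p] for p in positions)
    else:
        codon = "".join(contig.sequence[p] for p in positions).translate(_COMPLEMENT)
    return CodonLocus(
        transcript_id=t.id,
        protein_pos=protein_pos,
        contig=t.contig,
        strand=t.strand,
        base_positions=positions,  # type: ignore[arg-type]
        codon=codon,
        amino_acid=translate_codon(codon),
    )


def translate_codon(codon: str) -> str:
    """Standard-code translation; any codon containing N translates to X."""
    if "N" in codon:
        aa = str(Seq(codon).translate())
        return aa if aa in "*ACDEFGHIKLMNPQRSTVWY" else "X"
    return str(Seq(codon).translate())


def translate_transcript(t: Transcript, genome: Sequence[Contig]) -> str:
    """Translate the spliced CDS of ``t`` (standard genetic code).

    Leader bases are skipped, the trailing stop is removed, and an internal
    stop truncates the translation with a logged warning.
    """
    index = genome_index(genome)
    coding = t.cds_sequence(index)[t.phase0 :]
    coding = coding[: len(coding) - len(coding) % 3]
    residues = [translate_codon(coding[i : i + 3]) for i in range(0, len(coding), 3)]
    if residues and residues[-1] == "*":
        residues.pop()
    if "*" in residues:
        cut = residues.index("*")
        logger.warning(
            "transcript %s: internal stop at codon %d; translation truncated",
            t.id,
            cut + 1,
        )
        residues = residues[:cut]
    return "".join(residues)


def coding_offsets(t: Transcript) -> set[int]:
    """All genomic offsets that belong to a (non-stop, non-leader) codon."""
    order = cds_base_order(t)
    return set(order[t.phase0 : t.phase0 + 3 * t.protein_length])
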