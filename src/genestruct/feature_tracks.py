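"""Provenance-tagged annotation tracks on the canonical sequence.

Implements the track data model behind a protein feature viewer: exon
structure, variants, structure coverage, sequence mismatches and free-form
user features, serialized as deterministic JSON; structure coverage can also
be exported back to genome space as BED6 records.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio.SeqUtils import seq1

from . import codon_mapper
from .errors import FormatError
from .genome_model import Transcript
from .structure_mapper import MappingResources, ResidueMapping

logger = logging.getLogger(__name__)

FEATURE_TYPES = frozenset(
    {"exon", "variant", "pdb_coverage", "mismatch", "modification", "domain", "user"}
)

PROVENANCE_COLORS = {
    "UniProt": "green",
    "PDB": "blue",
    "computed": "grey",
    "user": "orange",
}


@dataclass(frozen=True)
class Feature:
    """A ranged annotation, 1-based inclusive on the canonical sequence."""

    start: int
    end: int
    type: str
    label: str
    attributes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(f"invalid feature range [{self.start}, {self.end}]")
        if self.type not in FEATURE_TYPES:
            raise FormatError(f"unknown feature type {self.type!r}")
        object.__setattr__(self, "attributes", tuple(self.attributes))

    @property
    def attributes_dict(self) -> dict[str, str]:
        return dict(self.attributes)


@dataclass(frozen=True)
class FeatureTrack:
    name: str
    provenance: str
    features: tuple[Feature, ...]
    color_hint: str = ""

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCE_COLORS:
            raise FormatError(f"unknown provenance {self.provenance!r}")
        if not self.color_hint:
            object.__setattr__(
                self, "color_hint", PROVENANCE_COLORS[self.provenance]
            )
        object.__setattr__(
            self,
            "features",
            tuple(sorted(self.features, key=lambda f: (f.start, f.end, f.label))),
        )


def _attrs(**kwargs: object) -> tuple[tuple[str, str], ...]:
    return tuple(sorted((k, str(v)) for k, v in kwargs.items()))


def build_exon_track(t: Transcript, resources: MappingResources) -> FeatureTrack:
    """Map each coding exon onto the canonical sequence.

    A codon spanning an exon junction is attributed to the exon holding its
    first base (transcription order). Codons whose canonical projection is
    undefined are dropped; an exon with no projectable codon yields no
    feature. Labels are ``exon1..exonN`` in transcription order over coding
    exons.
    """
    ctx = resources.context(t)
    exons_tx = t.exons if t.strand == "+" else tuple(reversed(t.exons))
    # canonical positions grouped by the exon owning the codon's first base
    per_exon: dict[int, list[int]] = {}
    for protein_pos in range(1, t.protein_length + 1):
        locus = codon_mapper.protein_to_codon(t, protein_pos, resources.genome)
        first_base = locus.base_positions[0]
        exon_idx = next(
            i for i, e in enumerate(exons_tx) if e.contains(first_base)
        )
        canonical_pos = ctx.protein_to_canonical(protein_pos)
        if canonical_pos is not None:
            per_exon.setdefault(exon_idx, []).append(canonical_pos)
    coding_exon_indices = sorted(
        {
            i
            for i, e in enumerate(exons_tx)
            if any(c.start < e.end and e.start < c.end for c in t.cds)
        }
    )
    features = []
    for label_no, exon_idx in enumerate(coding_exon_indices, start=1):
        positions = per_exon.get(exon_idx)
        if not positions:
            continue
        features.append(
            Feature(
                start=min(positions),
                end=max(positions),
                type="exon",
                label=f"exon{label_no}",
                attributes=_attrs(transcript_id=t.id),
            )
        )
    return FeatureTrack(
        name=f"exons:{t.id}", provenance="UniProt", features=tuple(features)
    )


def parse_variant(text: str) -> tuple[str, int, str, str]:
    """Parse ``contig:pos:ref:alt`` (pos 1-based) into a variant tuple."""
    parts = text.strip().split(":")
    if len(parts) != 4:
        raise FormatError(f"malformed variant {text!r}; expected contig:pos:ref:alt")
    contig, pos_s, ref, alt = parts
    try:
        pos = int(pos_s)
    except ValueError:
        raise FormatError(f"malformed variant {text!r}: non-integer position") from None
    if not ref or not alt or set(ref + alt) - set("ACGT"):
        raise FormatError(f"malformed variant {text!r}: bad alleles")
    return contig, pos, ref, alt


def read_variants(path: str | Path) -> list[tuple[str, int, str, str]]:
    """Read a variant TSV (contig, pos, ref, alt), pos 1-based, no header."""
    variants = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise FormatError(f"{path} line {line_no}: expected 4 columns")
        variants.append(parse_variant(":".join(fields)))
    return variants


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def build_variant_track(
    variants: Sequence[tuple[str, int, str, str]],
    resources: MappingResources,
    accession: str | None = None,
) -> FeatureTrack:
    """Project genomic SNVs to canonical positions with amino-acid labels.

    Each mappable SNV becomes a length-1 feature labeled like ``A3T``
    (reference residue, canonical position, predicted alternate residue).
    A reference-allele mismatch skips the variant with a logged warning.
    """
    features: list[Feature] = []
    seen: set[tuple] = set()
    for contig, pos1, ref, alt in variants:
        if len(ref) != 1 or len(alt) != 1:
            raise FormatError(f"only SNVs supported, got {ref}>{alt}")
        offset = pos1 - 1
        contig_obj = resources.genome_index.get(contig)
        if contig_obj is None or not 0 <= offset < contig_obj.length:
            logger.warning("variant %s:%d outside genome; skipped", contig, pos1)
            continue
        if contig_obj.sequence[offset] != ref:
            logger.warning(
                "variant %s:%d ref %s does not match genome base %s; skipped",
                contig,
                pos1,
                ref,
                contig_obj.sequence[offset],
            )
            continue
        hit_any = False
        for t in resources.transcripts(contig):
            ppos = codon_mapper.genomic_to_protein(t, offset)
            if ppos is None:
                continue
            ctx = resources.context(t)
            if ctx.match_kind == "none":
                continue
            if accession is not None and ctx.accession != accession:
                continue
            canonical_pos = ctx.protein_to_canonical(ppos.protein_pos)
            if canonical_pos is None:
                continue
            locus = codon_mapper.protein_to_codon(t, ppos.protein_pos, resources.genome)
            alt_base = alt if t.strand == "+" else alt.translate(_COMPLEMENT)
            mutated = list(locus.codon)
            mutated[ppos.codon_offset] = alt_base
            alt_aa = codon_mapper.translate_codon("".join(mutated))
            consequence = (
                "synonymous"
                if alt_aa == locus.amino_acid
                else ("nonsense" if alt_aa == "*" else "missense")
            )
            label = f"{locus.amino_acid}{canonical_pos}{alt_aa}"
            key = (canonical_pos, label, ctx.accession)
            if key in seen:
                continue
            seen.add(key)
            hit_any = True
            features.append(
                Feature(
                    start=canonical_pos,
                    end=canonical_pos,
                    type="variant",
                    label=label,
                    attributes=_attrs(
                        consequence=consequence,
                        genomic=f"{contig}:{pos1}:{ref}:{alt}",
                        transcript_id=t.id,
                    ),
                )
            )
        if not hit_any:
            logger.warning("variant %s:%d maps to no codon; skipped", contig, pos1)
    return FeatureTrack(name="variants", provenance="UniProt", features=tuple(features))


def _runs(positions: Sequence[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers in an ascending sequence."""
    runs: list[tuple[int, int]] = []
    for p in positions:
        if runs and p == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], p)
        else:
            runs.append((p, p))
    return runs


def build_coverage_track(
    maps: Sequence[ResidueMapping], accession: str
) -> FeatureTrack:
    """Structure coverage of the canonical sequence, one feature per run.

    For each (pdb, chain), maximal runs of consecutive mapped canonical
    positions become features; attributes record the observed fraction.
    """
    features = []
    for m in sorted(maps, key=lambda m: (m.pdb_id, m.chain_id)):
        if m.accession != accession:
            continue
        observed = {p for p, ref in m.pairs if ref.observed}
        for start, end in _runs(m.canonical_positions):
            n = end - start + 1
            n_observed = sum(1 for p in range(start, end + 1) if p in observed)
            features.append(
                Feature(
                    start=start,
                    end=end,
                    type="pdb_coverage",
                    label=f"{m.pdb_id}:{m.chain_id}",
                    attributes=_attrs(
                        observed=n_observed,
                        observed_fraction=f"{n_observed}/{n}",
                    ),
                )
            )
    return FeatureTrack(name="pdb coverage", provenance="PDB", features=tuple(features))


def _to_one_letter(res_name: str) -> str:
    return res_name if len(res_name) == 1 else seq1(res_name)


def detect_mismatches(mapping: ResidueMapping, canon_seq: str) -> FeatureTrack:
    """Positions where the deposited residue differs from the canonical one.

    Mismatches are grouped into maximal runs of consecutive canonical
    positions; a run touching either end of the mapped range is classified
    ``terminal_extension`` (expression-tag heuristic), else ``substitution``.
    """
    mismatch_positions = []
    residues: dict[int, tuple[str, str]] = {}
    for canonical_pos, ref in mapping.pairs:
        if not 1 <= canonical_pos <= len(canon_seq):
            continue
        canonical_aa = canon_seq[canonical_pos - 1]
        structure_aa = _to_one_letter(ref.res_name)
        if structure_aa != canonical_aa:
            mismatch_positions.append(canonical_pos)
            residues[canonical_pos] = (canonical_aa, structure_aa)
    features = []
    if mismatch_positions:
        mapped = mapping.canonical_positions
        lo, hi = mapped[0], mapped[-1]
        for start, end in _runs(mismatch_positions):
            classification = (
                "terminal_extension" if start == lo or end == hi else "substitution"
            )
            if start == end:
                canonical_aa, structure_aa = residues[start]
                label = f"{canonical_aa}{start}{structure_aa}"
            else:
                label = f"{classification}[{start}-{end}]"
            features.append(
                Feature(
                    start=start,
                    end=end,
                    type="mismatch",
                    label=label,
                    attributes=_attrs(
                        classification=classification,
                        chain=f"{mapping.pdb_id}:{mapping.chain_id}",
                    ),
                )
            )
    return FeatureTrack(
        name=f"mismatches:{mapping.pdb_id}:{mapping.chain_id}",
        provenance="PDB",
        features=tuple(features),
    )


def read_user_features(path: str | Path, accession: str) -> FeatureTrack:
    """Read a user feature TSV (accession, start, end, type, label)."""
    features = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise FormatError(f"{path} line {line_no}: expected 5 columns")
        acc, start, end, ftype, label = fields
        if acc != accession:
            continue
        features.append(
            Feature(
                start=int(start),
                end=int(end),
                type=ftype if ftype in FEATURE_TYPES else "user",
                label=label,
                attributes=_attrs(source="user_tsv"),
            )
        )
    return FeatureTrack(name="user features", provenance="user", features=tuple(features))


def tracks_to_json(
    tracks: Sequence[FeatureTrack], accession: str, canon_len: int
) -> str:
    """Serialize tracks to deterministic JSON (sorted keys, fixed layout)."""
    for track in tracks:
        for f in track.features:
            if f.end > canon_len:
                raise FormatError(
                    f"feature [{f.start},{f.end}] exceeds canonical length {canon_len}"
                )
    document = {
        "accession": accession,
        "length": canon_len,
        "tracks": [
            {
                "name": tr.name,
                "provenance": tr.provenance,
                "color_hint": tr.color_hint,
                "features": [
                    {
                        "start": f.start,
                        "end": f.end,
                        "type": f.type,
                        "label": f.label,
                        "attributes": f.attributes_dict,
                    }
                    for f in tr.features
                ],
            }
            for tr in tracks
        ],
    }
    return json.dumps(document, sort_keys=True, indent=2) + "\n"


def tracks_from_json(text: str) -> dict:
    """Parse and validate a track document against the shipped schema."""
    from .track_schema import TrackDocument

    document = json.loads(text)
    TrackDocument.model_validate(document)
    return document


def export_coverage_bed(
    t: Transcript, mapping: ResidueMapping, resources: MappingResources
) -> list[tuple[str, int, int, str, int, str]]:
    """Genomic BED6 records covered by codons of structure-mapped residues.

    Adjacent codon bases are merged; records are 0-based half-open, named
    ``pdb:chain``, sorted ascending regardless of strand.
    """
    ctx = resources.context(t)
    if ctx.match_kind == "none" or ctx.accession != mapping.accession:
        return []
    bases: set[int] = set()
    for canonical_pos, _ref in mapping.pairs:
        protein_pos = ctx.canonical_to_protein(canonical_pos)
        if protein_pos is None or not 1 <= protein_pos <= t.protein_length:
            continue
        locus = codon_mapper.protein_to_codon(t, protein_pos, resources.genome)
        bases.update(locus.base_positions)
    records = []
    for start, end in _runs(sorted(bases)):
        records.append(
            (t.contig, start, end + 1, f"{mapping.pdb_id}:{mapping.chain_id}", 0, t.strand)
        )
    records.sort(key=lambda r: (r[0], r[1]))
    return records


def write_bed(records: Sequence[tuple[str, int, int, str, int, str]], path: str | Path) -> None:
    lines = [
        f"{c}\t{s}\t{e}\t{name}\t{score}\t{strand}"
        for c, s, e, name, score, strand in sorted(records, key=lambda r: (r[0], r[1]))
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
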