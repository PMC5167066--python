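"""Residue-level sequence↔structure mapping and the composed pipeline.

Residue mappings are expressed against the canonical sequence of an
accession in a tab-separated dialect (see :func:`read_residue_mapping`).
:class:`MappingResources` wires genome, gene models, isoform sets and
residue mappings together and caches per-transcript isoform selection, so a
genomic position can be pushed all the way to structure residues and back.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import codon_mapper, isoform_mapper
from .codon_mapper import CodonLocus, ProteinPosition
from .errors import FormatError
from .genome_model import Contig, GeneModel, Transcript, genome_index
from .isoform_mapper import IsoformAlignment, IsoformSet

logger = logging.getLogger(__name__)

MAPPING_COLUMNS = [
    "pdb_id",
    "chain_id",
    "accession",
    "canonical_pos",
    "auth_num",
    "ins_code",
    "observed",
    "res_name",
]

# stage names / truncation reasons used in pipeline results
STAGE_GENOMIC = "genomic_to_protein"
STAGE_ISOFORM = "select_isoform"
STAGE_CANONICAL = "isoform_to_canonical"
STAGE_STRUCTURE = "canonical_to_structure"
REASON_NON_CODING = "non-coding"
REASON_NO_ISOFORM = "no isoform match"
REASON_NOT_IN_CANONICAL = "not in canonical"
REASON_NOT_IN_ISOFORM = "not in isoform"


@dataclass(frozen=True)
class ResidueRef:
    """One structure residue: chain, author numbering, observation flag."""

    pdb_id: str
    chain_id: str
    auth_num: int
    ins_code: str
    observed: bool
    res_name: str

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.pdb_id, self.chain_id, self.auth_num, self.ins_code)


@dataclass(frozen=True)
class ResidueMapping:
    """Per-residue correspondence of one chain to a canonical sequence."""

    pdb_id: str
    chain_id: str
    accession: str
    pairs: tuple[tuple[int, ResidueRef], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))
        canon = [p for p, _ in self.pairs]
        if len(set(canon)) != len(canon):
            raise FormatError(
                f"{self.pdb_id}:{self.chain_id}: duplicate canonical_pos"
            )
        keys = [r.key for _, r in self.pairs]
        if len(set(keys)) != len(keys):
            raise FormatError(
                f"{self.pdb_id}:{self.chain_id}: duplicate structure residues"
            )
        if canon != sorted(canon):
            raise FormatError(
                f"{self.pdb_id}:{self.chain_id}: rows not monotonic in canonical_pos"
            )

    @property
    def canonical_positions(self) -> list[int]:
        return [p for p, _ in self.pairs]

    def by_canonical(self, pos: int) -> ResidueRef | None:
        for p, ref in self.pairs:
            if p == pos:
                return ref
        return None


def read_residue_mapping(path: str | Path) -> list[ResidueMapping]:
    """Read the residue-mapping TSV dialect.

    Tab-separated with a required header; columns ``pdb_id, chain_id,
    accession, canonical_pos, auth_num, ins_code, observed, res_name``.
    ``ins_code`` uses ``.`` for blank; ``observed`` is 0/1. Rows are grouped
    by (pdb_id, chain_id, accession).
    """
    df = pd.read_csv(str(path), sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != MAPPING_COLUMNS:
        raise FormatError(
            f"{path}: expected columns {MAPPING_COLUMNS}, got {list(df.columns)}"
        )
    groups: dict[tuple[str, str, str], list[tuple[int, ResidueRef]]] = {}
    seen_pos: dict[tuple[str, str, str], set[int]] = {}
    for row_number, row in enumerate(df.itertuples(index=False), start=2):
        for col in ("canonical_pos", "auth_num"):
            value = getattr(row, col)
            try:
                int(value)
            except ValueError:
                raise FormatError(
                    f"{path} row {row_number}: non-integer {col} {value!r}"
                ) from None
        key = (row.pdb_id, row.chain_id, row.accession)
        canonical_pos = int(row.canonical_pos)
        if canonical_pos in seen_pos.setdefault(key, set()):
            raise FormatError(
                f"{path} row {row_number}: duplicate canonical_pos "
                f"{canonical_pos} for {row.pdb_id}:{row.chain_id}"
            )
        seen_pos[key].add(canonical_pos)
        ref = ResidueRef(
            pdb_id=row.pdb_id,
            chain_id=row.chain_id,
            auth_num=int(row.auth_num),
            ins_code="" if row.ins_code == "." else row.ins_code,
            observed=row.observed == "1",
            res_name=row.res_name,
        )
        groups.setdefault(key, []).append((canonical_pos, ref))
    return [
        ResidueMapping(pdb_id=k[0], chain_id=k[1], accession=k[2], pairs=tuple(v))
        for k, v in sorted(groups.items())
    ]


def write_residue_mapping(maps: Sequence[ResidueMapping], path: str | Path) -> None:
    """Write mappings in the TSV dialect, sorted by pdb, chain, canonical_pos."""
    lines = ["\t".join(MAPPING_COLUMNS)]
    for m in sorted(maps, key=lambda m: (m.pdb_id, m.chain_id, m.accession)):
        for canonical_pos, ref in sorted(m.pairs):
            lines.append(
                "\t".join(
                    [
                        ref.pdb_id,
                        ref.chain_id,
                        m.accession,
                        str(canonical_pos),
                        str(ref.auth_num),
                        ref.ins_code or ".",
                        "1" if ref.observed else "0",
                        ref.res_name,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def canonical_to_structure(
    maps: Sequence[ResidueMapping], accession: str, canonical_pos: int
) -> list[ResidueRef]:
    """All structure residues mapped to a canonical position.

    Unobserved residues are included (flagged ``observed=False``); the list
    is empty when the position is unmapped. Ordered by pdb_id then chain_id.
    """
    hits = [
        ref
        for m in maps
        if m.accession == accession
        for p, ref in m.pairs
        if p == canonical_pos
    ]
    hits.sort(key=lambda r: (r.pdb_id, r.chain_id, r.auth_num, r.ins_code))
    return hits


def structure_to_canonical(
    maps: Sequence[ResidueMapping],
    pdb_id: str,
    chain_id: str,
    auth_num: int,
    ins_code: str = "",
) -> tuple[str, int] | None:
    """Inverse lookup: (accession, canonical_pos) of a structure residue."""
    for m in maps:
        if m.pdb_id != pdb_id or m.chain_id != chain_id:
            continue
        for canonical_pos, ref in m.pairs:
            if ref.auth_num == auth_num and ref.ins_code == ins_code:
                return (m.accession, canonical_pos)
    return None


@dataclass(frozen=True)
class TranscriptIsoformContext:
    """Cached per-transcript routing through isoform space."""

    transcript: Transcript
    translation: str
    accession: str  # "" when no isoform set matched
    isoform_id: str
    match_kind: str  # exact | best_alignment | none
    to_isoform: IsoformAlignment | None  # translation → matched isoform
    to_canonical: IsoformAlignment | None  # matched isoform → canonical

    def protein_to_canonical(self, protein_pos: int) -> int | None:
        if self.to_isoform is None or self.to_canonical is None:
            return None
        iso_pos = isoform_mapper.isoform_to_canonical(self.to_isoform, protein_pos)
        if iso_pos is None:
            return None
        return isoform_mapper.isoform_to_canonical(self.to_canonical, iso_pos)

    def canonical_to_protein(self, canonical_pos: int) -> int | None:
        if self.to_isoform is None or self.to_canonical is None:
            return None
        iso_pos = isoform_mapper.canonical_to_isoform(self.to_canonical, canonical_pos)
        if iso_pos is None:
            return None
        return isoform_mapper.canonical_to_isoform(self.to_isoform, iso_pos)


class MappingResources:
    """All loaded resources plus per-transcript isoform-selection caches."""

    def __init__(
        self,
        genome: Sequence[Contig],
        gene_models: Sequence[GeneModel],
        isoform_sets: Sequence[IsoformSet],
        residue_mappings: Sequence[ResidueMapping] = (),
        identity_threshold: float = isoform_mapper.DEFAULT_IDENTITY_THRESHOLD,
    ) -> None:
        self.genome = list(genome)
        self.genome_index = genome_index(self.genome)
        self.gene_models = sorted(gene_models, key=lambda g: g.gene_id)
        self.isoform_sets = {s.accession: s for s in isoform_sets}
        self.residue_mappings = list(residue_mappings)
        self.identity_threshold = identity_threshold
        for m in self.residue_mappings:
            if m.accession not in self.isoform_sets:
                raise FormatError(
                    f"residue mapping {m.pdb_id}:{m.chain_id} refers to unknown "
                    f"accession {m.accession}"
                )
        self._contexts: dict[str, TranscriptIsoformContext] = {}

    @classmethod
    def from_paths(
        cls,
        genome_path: str | Path,
        gff3_path: str | Path,
        isoform_path: str | Path,
        mapping_path: str | Path | None = None,
        identity_threshold: float = isoform_mapper.DEFAULT_IDENTITY_THRESHOLD,
    ) -> "MappingResources":
        from .genome_model import read_gene_models, read_genome

        maps: list[ResidueMapping] = []
        if mapping_path is not None:
            maps = read_residue_mapping(mapping_path)
        return cls(
            genome=read_genome(genome_path),
            gene_models=read_gene_models(gff3_path),
            isoform_sets=isoform_mapper.read_isoform_fasta(isoform_path),
            residue_mappings=maps,
            identity_threshold=identity_threshold,
        )

    # -- lookup helpers -------------------------------------------------

    def transcripts(self, contig: str | None = None) -> list[Transcript]:
        out = [
            t
            for g in self.gene_models
            for t in g.transcripts
            if contig is None or t.contig == contig
        ]
        return sorted(out, key=lambda t: t.id)

    def transcript(self, transcript_id: str) -> Transcript:
        for g in self.gene_models:
            for t in g.transcripts:
                if t.id == transcript_id:
                    return t
        from .errors import ResourceLookupError

        raise ResourceLookupError(f"unknown transcript {transcript_id!r}")

    def context(self, t: Transcript) -> TranscriptIsoformContext:
        """Translation + isoform selection for a transcript, cached."""
        if t.id in self._contexts:
            return self._contexts[t.id]
        translation = codon_mapper.translate_transcript(t, self.genome)
        best: tuple[str, str, str] | None = None  # (accession, isoform_id, kind)
        for accession in sorted(self.isoform_sets):
            iso_id, kind = isoform_mapper.select_isoform(
                translation,
                self.isoform_sets[accession],
                identity_threshold=self.identity_threshold,
            )
            if kind == "exact":
                best = (accession, iso_id, kind)
                break
            if kind == "best_alignment" and best is None:
                best = (accession, iso_id, kind)
        if best is None:
            ctx = TranscriptIsoformContext(t, translation, "", "", "none", None, None)
        else:
            accession, iso_id, kind = best
            iso_set = self.isoform_sets[accession]
            isoform = iso_set.get(iso_id)
            if kind == "exact":
                to_isoform = isoform_mapper.identity_alignment(
                    translation, isoform_id=iso_id, accession=accession
                )
            else:
                to_isoform = isoform_mapper.align_isoform_to_canonical(
                    translation, isoform.sequence, isoform_id=iso_id, accession=accession
                )
            if isoform.is_canonical:
                to_canonical = isoform_mapper.identity_alignment(
                    isoform.sequence, isoform_id=iso_id, accession=accession
                )
            else:
                to_canonical = isoform_mapper.align_isoform_to_canonical(
                    isoform.sequence,
                    iso_set.canonical.sequence,
                    isoform_id=iso_id,
                    accession=accession,
                )
            ctx = TranscriptIsoformContext(
                t, translation, accession, iso_id, kind, to_isoform, to_canonical
            )
        self._contexts[t.id] = ctx
        return ctx


@dataclass
class TranscriptStageResult:
    """Outcome of one transcript's pass through the forward pipeline."""

    transcript_id: str
    stage: str  # last stage reached
    reason: str  # "" when complete
    protein_pos: int | None = None
    codon_offset: int | None = None
    accession: str = ""
    isoform_id: str = ""
    canonical_pos: int | None = None
    hits: list[ResidueRef] = field(default_factory=list)


@dataclass
class GenomeToStructureResult:
    contig: str
    pos: int  # 0-based genomic offset
    entries: list[TranscriptStageResult] = field(default_factory=list)


def map_genome_to_structure(
    pos: int, contig: str, resources: MappingResources
) -> GenomeToStructureResult:
    """Compose genomic→protein→isoform→canonical→structure for one offset.

    Every transcript on the contig gets an entry; a stage returning nothing
    truncates the entry there with a stated reason, never an exception.
    """
    result = GenomeToStructureResult(contig=contig, pos=pos)
    for t in resources.transcripts(contig):
        entry = TranscriptStageResult(transcript_id=t.id, stage=STAGE_GENOMIC, reason="")
        result.entries.append(entry)
        ppos = codon_mapper.genomic_to_protein(t, pos)
        if ppos is None:
            entry.reason = REASON_NON_CODING
            continue
        entry.protein_pos = ppos.protein_pos
        entry.codon_offset = ppos.codon_offset
        entry.stage = STAGE_ISOFORM
        ctx = resources.context(t)
        if ctx.match_kind == "none":
            entry.reason = REASON_NO_ISOFORM
            continue
        entry.accession = ctx.accession
        entry.isoform_id = ctx.isoform_id
        entry.stage = STAGE_CANONICAL
        canonical_pos = ctx.protein_to_canonical(ppos.protein_pos)
        if canonical_pos is None:
            entry.reason = REASON_NOT_IN_CANONICAL
            continue
        entry.canonical_pos = canonical_pos
        entry.stage = STAGE_STRUCTURE
        entry.hits = canonical_to_structure(
            resources.residue_mappings, ctx.accession, canonical_pos
        )
    return result


@dataclass
class StructureToGenomeEntry:
    transcript_id: str
    stage: str
    reason: str
    codon: CodonLocus | None = None


@dataclass
class StructureToGenomeResult:
    pdb_id: str
    chain_id: str
    auth_num: int
    ins_code: str
    accession: str = ""
    canonical_pos: int | None = None
    entries: list[StructureToGenomeEntry] = field(default_factory=list)

    @property
    def codons(self) -> list[CodonLocus]:
        return [e.codon for e in self.entries if e.codon is not None]


def map_structure_to_genome(
    pdb_id: str,
    chain_id: str,
    auth_num: int,
    ins_code: str,
    resources: MappingResources,
) -> StructureToGenomeResult:
    """Reverse pipeline: structure residue → canonical → isoform → codon.

    Returns per-transcript entries (ordered by transcript id) for every
    transcript whose selected accession matches; ``result.codons`` collects
    the successful :class:`CodonLocus` values.
    """
    result = StructureToGenomeResult(
        pdb_id=pdb_id, chain_id=chain_id, auth_num=auth_num, ins_code=ins_code
    )
    located = structure_to_canonical(
        resources.residue_mappings, pdb_id, chain_id, auth_num, ins_code
    )
    if located is None:
        return result
    accession, canonical_pos = located
    result.accession = accession
    result.canonical_pos = canonical_pos
    for t in resources.transcripts():
        ctx = resources.context(t)
        if ctx.accession != accession:
            continue
        entry = StructureToGenomeEntry(
            transcript_id=t.id, stage=STAGE_CANONICAL, reason=""
        )
        result.entries.append(entry)
        protein_pos = ctx.canonical_to_protein(canonical_pos)
        if protein_pos is None:
            entry.reason = REASON_NOT_IN_ISOFORM
            continue
        entry.stage = STAGE_GENOMIC
        entry.codon = codon_mapper.protein_to_codon(t, protein_pos, resources.genome)
    return result
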