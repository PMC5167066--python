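"""Deterministic synthetic fixtures with independently-derived ground truth.

Two generators:

* :func:`make_fixed_fixtures` — a hand-specified 400 bp contig ``chrT`` with
  four transcripts (plus/minus strand, exon-junction codons, an
  exon-skipped variant and an insertion-carrying variant), isoform sets,
  residue mappings and SNVs. Every value is written out explicitly so the
  bundle regenerates byte-identically.
* :func:`make_random_fixtures` — seeded random genes for stress-testing the
  coordinate arithmetic.

Ground truth (genomic offset → residue/codon-offset per transcript) is built
by a one-pass per-base walk over the CDS segments, deliberately independent
of the interval arithmetic in :mod:`genestruct.codon_mapper`.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .errors import ParameterError
from .genome_model import (
    Contig,
    GeneModel,
    GenomicInterval,
    Transcript,
    write_gene_models,
    write_genome,
)
from .isoform_mapper import Isoform, IsoformSet, write_isoform_fasta
from .structure_mapper import ResidueMapping, ResidueRef, write_residue_mapping

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOP_CODONS = ("TAA", "TAG", "TGA")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _res3(aa: str) -> str:
    return seq3(aa).upper()


@dataclass
class FixtureBundle:
    """Everything needed to exercise the full pipeline, plus ground truth."""

    contigs: list[Contig]
    gene_models: list[GeneModel]
    isoform_sets: list[IsoformSet]
    residue_mappings: list[ResidueMapping]
    variants: list[tuple[str, int, str, str]]  # contig, 1-based pos, ref, alt
    user_features: list[tuple[str, int, int, str, str]]
    #: (transcript_id, genomic offset) → (protein_pos, codon_offset)
    ground_truth: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)
    #: mapping rows replayed as independent per-residue truth
    residue_truth: list[tuple[str, int, str, str, int, str, bool]] = field(
        default_factory=list
    )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "gff3": out / "genes.gff3",
            "isoforms": out / "isoforms.fa",
            "mapping": out / "mapping.tsv",
            "variants": out / "variants.tsv",
            "user_features": out / "user_features.tsv",
            "ground_truth": out / "ground_truth.tsv",
        }
        write_genome(self.contigs, paths["genome"])
        write_gene_models(self.gene_models, paths["gff3"])
        write_isoform_fasta(self.isoform_sets, paths["isoforms"])
        write_residue_mapping(self.residue_mappings, paths["mapping"])
        paths["variants"].write_text(
            "".join(
                f"{c}\t{p}\t{r}\t{a}\n" for c, p, r, a in sorted(self.variants)
            )
        )
        paths["user_features"].write_text(
            "".join(
                f"{acc}\t{s}\t{e}\t{t}\t{lab}\n"
                for acc, s, e, t, lab in sorted(self.user_features)
            )
        )
        truth_lines = ["transcript_id\toffset\tprotein_pos\tcodon_offset"]
        for (tx, offset), (pp, co) in sorted(self.ground_truth.items()):
            truth_lines.append(f"{tx}\t{offset}\t{pp}\t{co}")
        paths["ground_truth"].write_text("\n".join(truth_lines) + "\n")
        return paths

    def resources(self, identity_threshold: float = 0.95):
        from .structure_mapper import MappingResources

        return MappingResources(
            genome=self.contigs,
            gene_models=self.gene_models,
            isoform_sets=self.isoform_sets,
            residue_mappings=self.residue_mappings,
            identity_threshold=identity_threshold,
        )


def per_base_truth(t: Transcript) -> dict[int, tuple[int, int]]:
    """Per-base oracle: genomic offset → (protein_pos, codon_offset).

    Walks the CDS base by base in transcription order with a simple counter;
    leader bases and the final complete codon (the stop) are excluded.
    """
    bases: list[int] = []
    if t.strand == "+":
        for iv in t.cds:
            for p in range(iv.start, iv.end):
                bases.append(p)
    else:
        for iv in reversed(t.cds):
            for p in range(iv.end - 1, iv.start - 1, -1):
                bases.append(p)
    coding = bases[t.phase0 :]
    n_complete = len(coding) // 3
    truth: dict[int, tuple[int, int]] = {}
    counter = 0
    for offset in coding:
        codon_no = counter // 3  # 0-based
        if codon_no >= n_complete - 1:
            break  # stop codon (and any trailing partial bases)
        truth[offset] = (codon_no + 1, counter % 3)
        counter += 1
    return truth


def _bundle_truth(bundle: FixtureBundle) -> None:
    bundle.ground_truth = {}
    for gene in bundle.gene_models:
        for t in gene.transcripts:
            for offset, value in per_base_truth(t).items():
                bundle.ground_truth[(t.id, offset)] = value
    bundle.residue_truth = [
        (m.accession, pos, m.pdb_id, m.chain_id, ref.auth_num, ref.ins_code, ref.observed)
        for m in bundle.residue_mappings
        for pos, ref in m.pairs
    ]


# --------------------------------------------------------------------------
# fixed fixtures
# --------------------------------------------------------------------------

#: codons of transcript T1 (19 residues + stop), transcription order
T1_CODONS = [
    "ATG", "AAA", "GCT", "CTG", "GAA", "TTC", "GGT", "CAC", "CGT", "GTT",
    "TGG", "GAT", "GAG", "ATC", "AAG", "CTT", "AAC", "CCT", "CAA", "TAA",
]
T1_PROTEIN = "MKALEFGHRVWDEIKLNPQ"
T2_PROTEIN = "MVSTYAGHK"
T2_CODONS = ["ATG", "GTT", "TCT", "ACT", "TAT", "GCT", "GGT", "CAT", "AAA", "TGA"]
ISO2_SEQUENCE = T1_PROTEIN[:4] + T1_PROTEIN[8:]  # residues 5-8 deleted
ISO3_SEQUENCE = T1_PROTEIN[:10] + "SP" + T1_PROTEIN[10:]  # SP inserted after 10

CHRT_LENGTH = 400


def _chrT_sequence() -> str:
    base = list("ACGT" * (CHRT_LENGTH // 4))

    def put(offset: int, segment: str) -> None:
        base[offset : offset + len(segment)] = list(segment)

    put(100, "".join(T1_CODONS[:10]))  # codons 1-10: offsets 100..129
    put(130, T1_CODONS[10][0])  # first base of junction codon 11
    put(200, T1_CODONS[10][1:] + "".join(T1_CODONS[11:19]) + T1_CODONS[19])
    put(160, "CACCGT")  # T4 mini-exon: codes S,P then re-uses 'T' at 165
    put(300, _revcomp("".join(T2_CODONS)))  # minus-strand gene
    return "".join(base)


def make_fixed_fixtures() -> FixtureBundle:
    """The hand-specified fixture bundle used throughout the test-suite.

    * ``T1`` (+): CDS [100,131)∪[200,229); translation ``T1_PROTEIN`` (19 aa),
      codon 11 spans the exon junction (130|200,201).
    * ``T2`` (−): CDS [300,330); translation ``T2_PROTEIN`` (9 aa).
    * ``T3`` (+): T1 with codons 5-8 removed; translation = isoform ACC1-2.
    * ``T4`` (+): T1 with a 6 bp mini-exon inserting residues S,P after
      residue 10; translation = isoform ACC1-3 (insertions project to no
      canonical position).
    * MAP1: 1XYZ:A ↔ ACC1 canonical 3-17 (auth 101-115; 12-13 unobserved).
    * MAP2: 2ABC:B ↔ ACC1 canonical 5-14 with one insertion-code residue
      (auth 107, ins A) and a res_name conflict (ALA at canonical 10).
    * MAP3: 3DEF:C ↔ ACC2 canonical 2-8 (minus-strand coverage).
    """
    chrT = Contig(name="chrT", sequence=_chrT_sequence())

    def iv(start: int, end: int, strand: str) -> GenomicInterval:
        return GenomicInterval("chrT", start, end, strand)

    t1 = Transcript(
        id="T1", gene_id="GENE1", gene_name="GENE1", strand="+",
        exons=(iv(90, 140, "+"), iv(195, 240, "+")),
        cds=(iv(100, 131, "+"), iv(200, 229, "+")),
    )
    t3 = Transcript(
        id="T3", gene_id="GENE1", gene_name="GENE1", strand="+",
        exons=(iv(90, 112, "+"), iv(124, 140, "+"), iv(195, 240, "+")),
        cds=(iv(100, 112, "+"), iv(124, 131, "+"), iv(200, 229, "+")),
    )
    t4 = Transcript(
        id="T4", gene_id="GENE1", gene_name="GENE1", strand="+",
        exons=(iv(90, 140, "+"), iv(160, 166, "+"), iv(195, 240, "+")),
        cds=(iv(100, 131, "+"), iv(160, 166, "+"), iv(200, 229, "+")),
    )
    t2 = Transcript(
        id="T2", gene_id="GENE2", gene_name="GENE2", strand="-",
        exons=(iv(290, 340, "-"),),
        cds=(iv(300, 330, "-"),),
    )
    gene_models = [
        GeneModel(gene_id="GENE1", gene_name="GENE1", transcripts=[t1, t3, t4]),
        GeneModel(gene_id="GENE2", gene_name="GENE2", transcripts=[t2]),
    ]
    isoform_sets = [
        IsoformSet(
            accession="ACC1",
            isoforms=(
                Isoform("ACC1-1", T1_PROTEIN, True),
                Isoform("ACC1-2", ISO2_SEQUENCE, False),
                Isoform("ACC1-3", ISO3_SEQUENCE, False),
            ),
        ),
        IsoformSet(
            accession="ACC2",
            isoforms=(Isoform("ACC2-1", T2_PROTEIN, True),),
        ),
    ]

    def ref(pdb: str, chain: str, auth: int, ins: str, observed: bool, aa: str) -> ResidueRef:
        return ResidueRef(pdb, chain, auth, ins, observed, _res3(aa))

    map1 = ResidueMapping(
        pdb_id="1XYZ", chain_id="A", accession="ACC1",
        pairs=tuple(
            (pos, ref("1XYZ", "A", 101 + pos - 3, "", pos not in (12, 13), T1_PROTEIN[pos - 1]))
            for pos in range(3, 18)
        ),
    )
    map2_rows = []
    auth = 105
    for pos in range(5, 15):
        ins = ""
        if pos == 8:
            auth -= 1  # re-use previous author number with an insertion code
            ins = "A"
        aa = "A" if pos == 10 else T1_PROTEIN[pos - 1]  # engineered ALA at 10
        map2_rows.append((pos, ref("2ABC", "B", auth, ins, True, aa)))
        auth += 1
    map2 = ResidueMapping(pdb_id="2ABC", chain_id="B", accession="ACC1", pairs=tuple(map2_rows))
    map3 = ResidueMapping(
        pdb_id="3DEF", chain_id="C", accession="ACC2",
        pairs=tuple(
            (pos, ref("3DEF", "C", pos - 1, "", True, T2_PROTEIN[pos - 1]))
            for pos in range(2, 9)
        ),
    )

    bundle = FixtureBundle(
        contigs=[chrT],
        gene_models=gene_models,
        isoform_sets=isoform_sets,
        residue_mappings=[map1, map2, map3],
        variants=[
            ("chrT", 107, "G", "A"),  # codon 3 GCT→ACT: A3T missense
            ("chrT", 112, "G", "A"),  # codon 4 CTG→CTA: synonymous
            ("chrT", 151, "G", "C"),  # intronic
        ],
        user_features=[("ACC1", 2, 6, "domain", "DemoDomain")],
    )
    _bundle_truth(bundle)
    return bundle


# --------------------------------------------------------------------------
# random fixtures
# --------------------------------------------------------------------------


def _random_gene(
    rng: random.Random, index: int, exon_count_range: tuple[int, int], strand_mix: float
) -> tuple[Contig, GeneModel, IsoformSet, ResidueMapping | None]:
    n_residues = rng.randint(9, 40)
    codons = ["ATG"] + [rng.choice(_SENSE_CODONS) for _ in range(n_residues - 1)]
    codons.append(rng.choice(_STOP_CODONS))
    protein = "".join(str(Seq(c).translate()) for c in codons[:-1])
    phase0 = rng.randint(0, 2)
    leader = "".join(rng.choice("ACGT") for _ in range(phase0))
    cds_seq = leader + "".join(codons)  # transcription order
    total = len(cds_seq)
    strand = "-" if rng.random() < strand_mix else "+"

    n_exons = rng.randint(*exon_count_range)
    n_exons = min(n_exons, total)
    cuts = sorted(rng.sample(range(1, total), n_exons - 1)) if n_exons > 1 else []
    bounds = [0, *cuts, total]
    seg_lengths_tx = [b - a for a, b in zip(bounds, bounds[1:])]

    contig_name = f"chr{index + 1}"
    # ascending-genomic segment lengths; for '-' the transcription order is
    # the reverse of the genomic order
    seg_lengths_genomic = (
        seg_lengths_tx if strand == "+" else list(reversed(seg_lengths_tx))
    )
    genomic_cds = cds_seq if strand == "+" else _revcomp(cds_seq)

    cursor = rng.randint(40, 80)
    intervals: list[GenomicInterval] = []
    pieces: list[tuple[int, str]] = []
    consumed = 0
    for length in seg_lengths_genomic:
        intervals.append(GenomicInterval(contig_name, cursor, cursor + length, strand))
        pieces.append((cursor, genomic_cds[consumed : consumed + length]))
        consumed += length
        cursor = cursor + length + rng.randint(25, 60)
    contig_len = intervals[-1].end + rng.randint(30, 60)
    base = [rng.choice("ACGT") for _ in range(contig_len)]
    for offset, segment in pieces:
        base[offset : offset + len(segment)] = list(segment)
    contig = Contig(name=contig_name, sequence="".join(base))

    exons = tuple(
        GenomicInterval(
            contig_name,
            max(0, ivl.start - rng.randint(0, 10)),
            min(contig_len, ivl.end + rng.randint(0, 10)),
            strand,
        )
        for ivl in intervals
    )
    gene_id = f"G{index + 1:03d}"
    tx = Transcript(
        id=f"{gene_id}.t1", gene_id=gene_id, gene_name=gene_id, strand=strand,
        exons=exons, cds=tuple(intervals), phase0=phase0,
    )
    gene = GeneModel(gene_id=gene_id, gene_name=gene_id, transcripts=[tx])

    accession = f"RACC{index + 1:03d}"
    isoforms = [Isoform(f"{accession}-1", protein, True)]
    if rng.random() < 0.5 and len(protein) > 6:
        start = rng.randint(2, len(protein) - 4)
        length = rng.randint(1, min(4, len(protein) - 1 - start))
        alt_seq = protein[: start - 1] + protein[start - 1 + length :]
        if alt_seq != protein:
            isoforms.append(Isoform(f"{accession}-2", alt_seq, False))
    iso_set = IsoformSet(accession=accession, isoforms=tuple(isoforms))

    mapping: ResidueMapping | None = None
    if rng.random() < 0.8:
        a = rng.randint(1, max(1, len(protein) - 5))
        b = rng.randint(a, len(protein))
        pdb_id = f"{index + 1:04d}"[:4]
        ins_at = rng.randint(a, b) if rng.random() < 0.2 and b > a else None
        pairs = []
        auth = rng.randint(1, 200)
        for pos in range(a, b + 1):
            ins = ""
            if pos == ins_at:
                auth -= 1
                ins = "A"
            pairs.append(
                (
                    pos,
                    ResidueRef(
                        pdb_id, "A", auth, ins, rng.random() > 0.15, _res3(protein[pos - 1])
                    ),
                )
            )
            auth += 1
        mapping = ResidueMapping(
            pdb_id=pdb_id, chain_id="A", accession=accession, pairs=tuple(pairs)
        )
    return contig, gene, iso_set, mapping


def make_random_fixtures(
    seed: int,
    n_genes: int,
    exon_count_range: tuple[int, int] = (1, 8),
    strand_mix: float = 0.5,
) -> FixtureBundle:
    """Seeded random genes (one per contig) with per-base ground truth."""
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    lo, hi = exon_count_range
    if not 1 <= lo <= hi:
        raise ParameterError(f"invalid exon_count_range {exon_count_range!r}")
    if not 0.0 <= strand_mix <= 1.0:
        raise ParameterError(f"invalid strand_mix {strand_mix!r}")
    rng = random.Random(seed)
    contigs, genes, iso_sets, mappings = [], [], [], []
    variants: list[tuple[str, int, str, str]] = []
    for i in range(n_genes):
        contig, gene, iso_set, mapping = _random_gene(rng, i, (lo, hi), strand_mix)
        contigs.append(contig)
        genes.append(gene)
        iso_sets.append(iso_set)
        if mapping is not None:
            mappings.append(mapping)
        # one random SNV per gene, anywhere on the contig
        offset = rng.randrange(contig.length)
        ref_base = contig.sequence[offset]
        alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
        variants.append((contig.name, offset + 1, ref_base, alt_base))
    bundle = FixtureBundle(
        contigs=contigs,
        gene_models=genes,
        isoform_sets=iso_sets,
        residue_mappings=mappings,
        variants=variants,
        user_features=[],
    )
    _bundle_truth(bundle)
    return bundle
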