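import pytest

from genestruct.errors import FormatError, ModelError
from genestruct.fixtures import make_fixed_fixtures, make_random_fixtures
from genestruct.genome_model import (
    Contig,
    GenomicInterval,
    Transcript,
    read_gene_models,
    read_genome,
    validate_transcript,
    write_gene_models,
    write_genome,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadGenome:
    def test_single_record(self, tmp_path):
        seq = "ACGT" * 100
        path = _write(tmp_path, "g.fa", f">chrT\n{seq}\n")
        contigs = read_genome(path)
        assert len(contigs) == 1
        assert contigs[0].name == "chrT"
        assert contigs[0].length == 400

    def test_lowercase_normalized(self, tmp_path):
        path = _write(tmp_path, "g.fa", ">c\nacgt\n")
        assert read_genome(path)[0].sequence == "ACGT"

    def test_u_converted_to_t(self, tmp_path):
        path = _write(tmp_path, "g.fa", ">c\nACGU\n")
        assert read_genome(path)[0].sequence == "ACGT"

    def test_illegal_character_rejected(self, tmp_path):
        path = _write(tmp_path, "g.fa", ">c\nACXGT\n")
        with pytest.raises(FormatError):
            read_genome(path)

    def test_duplicate_names_rejected(self, tmp_path):
        path = _write(tmp_path, "g.fa", ">c\nACGT\n>c\nACGT\n")
        with pytest.raises(FormatError):
            read_genome(path)

    def test_empty_file_rejected(self, tmp_path):
        path = _write(tmp_path, "g.fa", "")
        with pytest.raises(FormatError):
            read_genome(path)

    def test_n_bases_legal(self, tmp_path):
        path = _write(tmp_path, "g.fa", ">c\nACGTN\n")
        assert read_genome(path)[0].sequence == "ACGTN"


GFF_HEADER = "##gff-version 3\n"


class TestReadGeneModels:
    def test_one_based_conversion(self, tmp_path):
        gff = GFF_HEADER + "\n".join(
            [
                "chrT\tx\tgene\t101\t131\t.\t+\t.\tID=G1",
                "chrT\tx\tmRNA\t101\t131\t.\t+\t.\tID=M1;Parent=G1",
                "chrT\tx\texon\t101\t131\t.\t+\t.\tParent=M1",
                "chrT\tx\tCDS\t101\t131\t.\t+\t0\tParent=M1",
            ]
        )
        models = read_gene_models(_write(tmp_path, "a.gff3", gff))
        exon = models[0].transcripts[0].exons[0]
        assert (exon.start, exon.end) == (100, 131)

    def test_minus_strand_phase0_from_largest_start(self, tmp_path):
        # transcription-order-first CDS row on '-' is the one with the
        # LARGEST genomic start; its phase column is 1 here
        gff = GFF_HEADER + "\n".join(
            [
                "chrT\tx\tgene\t101\t230\t.\t-\t.\tID=G1",
                "chrT\tx\tmRNA\t101\t230\t.\t-\t.\tID=M1;Parent=G1",
                "chrT\tx\texon\t101\t130\t.\t-\t.\tParent=M1",
                "chrT\tx\texon\t201\t230\t.\t-\t.\tParent=M1",
                "chrT\tx\tCDS\t101\t130\t.\t-\t2\tParent=M1",
                "chrT\tx\tCDS\t201\t230\t.\t-\t1\tParent=M1",
            ]
        )
        models = read_gene_models(_write(tmp_path, "b.gff3", gff))
        assert models[0].transcripts[0].phase0 == 1

    def test_two_mrnas_grouped_under_one_gene(self, tmp_path):
        gff = GFF_HEADER + "\n".join(
            [
                "chrT\tx\tgene\t1\t300\t.\t+\t.\tID=G1",
                "chrT\tx\tmRNA\t1\t300\t.\t+\t.\tID=M1;Parent=G1",
                "chrT\tx\texon\t1\t300\t.\t+\t.\tParent=M1",
                "chrT\tx\tCDS\t10\t30\t.\t+\t0\tParent=M1",
                "chrT\tx\tmRNA\t1\t300\t.\t+\t.\tID=M2;Parent=G1",
                "chrT\tx\texon\t1\t300\t.\t+\t.\tParent=M2",
                "chrT\tx\tCDS\t10\t21\t.\t+\t0\tParent=M2",
            ]
        )
        models = read_gene_models(_write(tmp_path, "c.gff3", gff))
        assert len(models) == 1
        assert [t.id for t in models[0].transcripts] == ["M1", "M2"]

    def test_cds_outside_exon_is_model_error(self, tmp_path):
        gff = GFF_HEADER + "\n".join(
            [
                "chrT\tx\tgene\t1\t300\t.\t+\t.\tID=G1",
                "chrT\tx\tmRNA\t1\t300\t.\t+\t.\tID=M1;Parent=G1",
                "chrT\tx\texon\t1\t100\t.\t+\t.\tParent=M1",
                "chrT\tx\tCDS\t150\t200\t.\t+\t0\tParent=M1",
            ]
        )
        with pytest.raises(ModelError, match="M1"):
            read_gene_models(_write(tmp_path, "d.gff3", gff))

    def test_mrna_without_cds_skipped_with_warning(self, tmp_path, caplog):
        gff = GFF_HEADER + "\n".join(
            [
                "chrT\tx\tgene\t1\t300\t.\t+\t.\tID=G1",
                "chrT\tx\tmRNA\t1\t300\t.\t+\t.\tID=M1;Parent=G1",
                "chrT\tx\texon\t1\t300\t.\t+\t.\tParent=M1",
                "chrT\tx\tCDS\t10\t30\t.\t+\t0\tParent=M1",
                "chrT\tx\tmRNA\t1\t300\t.\t+\t.\tID=M2;Parent=G1",
                "chrT\tx\texon\t1\t300\t.\t+\t.\tParent=M2",
            ]
        )
        with caplog.at_level("WARNING"):
            models = read_gene_models(_write(tmp_path, "e.gff3", gff))
        assert [t.id for t in models[0].transcripts] == ["M1"]
        assert "M2" in caplog.text


class TestGff3RoundTrip:
    def test_fixed_bundle_round_trips(self, bundle, tmp_path):
        path = tmp_path / "rt.gff3"
        write_gene_models(bundle.gene_models, path)
        assert read_gene_models(path) == sorted(
            bundle.gene_models, key=lambda g: g.gene_id
        )

    def test_random_bundle_round_trips(self, tmp_path):
        rnd = make_random_fixtures(seed=7, n_genes=12)
        path = tmp_path / "rnd.gff3"
        write_gene_models(rnd.gene_models, path)
        assert read_gene_models(path) == rnd.gene_models


class TestInvariants:
    def test_cds_bases_subset_of_exon_bases(self):
        rnd = make_random_fixtures(seed=3, n_genes=15)
        for gene in rnd.gene_models + make_fixed_fixtures().gene_models:
            for t in gene.transcripts:
                exon_bases = set()
                for e in t.exons:
                    exon_bases.update(range(e.start, e.end))
                for c in t.cds:
                    assert set(range(c.start, c.end)) <= exon_bases

    def test_interval_validation(self):
        with pytest.raises(ModelError):
            GenomicInterval("c", 5, 5, "+")
        with pytest.raises(ModelError):
            GenomicInterval("c", -1, 5, "+")
        with pytest.raises(ModelError):
            GenomicInterval("c", 0, 5, "*")

    def test_transcript_rejects_overlapping_cds(self):
        iv = lambda s, e: GenomicInterval("c", s, e, "+")
        with pytest.raises(ModelError):
            Transcript(
                id="t", gene_id="g", gene_name="g", strand="+",
                exons=(iv(0, 100),), cds=(iv(10, 40), iv(30, 60)),
            )


class TestValidateTranscript:
    def test_fixture_t1_is_clean(self, bundle, resources):
        t1 = resources.transcript("T1")
        assert validate_transcript(t1, bundle.contigs) == []

    def test_all_fixed_transcripts_clean(self, bundle, resources):
        for t in resources.transcripts():
            assert validate_transcript(t, bundle.contigs) == []

    def test_shortened_cds_is_truncated(self, bundle, resources):
        t1 = resources.transcript("T1")
        shortened = Transcript(
            id="T1s", gene_id=t1.gene_id, gene_name=t1.gene_name, strand="+",
            exons=t1.exons,
            cds=(t1.cds[0], GenomicInterval("chrT", 200, 228, "+")),
        )
        assert (shortened.cds_length - shortened.phase0) % 3 == 2  # 59 % 3
        assert "truncated" in validate_transcript(shortened, bundle.contigs)

    def test_internal_stop_detected(self, bundle, resources):
        t1 = resources.transcript("T1")
        chrT = bundle.contigs[0]
        # overwrite codon 5 (offsets 112..114) with TAA
        seq = chrT.sequence[:112] + "TAA" + chrT.sequence[115:]
        mutated = [Contig(name="chrT", sequence=seq)]
        assert "internal_stop" in validate_transcript(t1, mutated)

    def test_non_atg_start_detected(self, bundle, resources):
        t1 = resources.transcript("T1")
        chrT = bundle.contigs[0]
        seq = chrT.sequence[:100] + "TTG" + chrT.sequence[103:]
        mutated = [Contig(name="chrT", sequence=seq)]
        assert "non_atg_start" in validate_transcript(t1, mutated)

    def test_findings_never_raise(self, bundle, resources):
        t1 = resources.transcript("T1")
        chrT = bundle.contigs[0]
        seq = "N" * chrT.length
        findings = validate_transcript(t1, [Contig(name="chrT", sequence=seq)])
        assert isinstance(findings, list)


def test_write_genome_round_trip(bundle, tmp_path):
    path = tmp_path / "g.fa"
    write_genome(bundle.contigs, path)
    assert read_genome(path) == bundle.contigs
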