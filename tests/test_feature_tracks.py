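import json

import pytest

from genestruct import feature_tracks as ft
from genestruct.errors import FormatError
from genestruct.fixtures import T1_CODONS, T1_PROTEIN, ISO3_SEQUENCE, per_base_truth
from genestruct.genome_model import Contig, GenomicInterval, Transcript
from genestruct.isoform_mapper import Isoform, IsoformSet
from genestruct.structure_mapper import (
    MappingResources,
    ResidueMapping,
    ResidueRef,
)


def _ref(pdb, chain, auth, aa3="ALA", ins="", observed=True):
    return ResidueRef(pdb, chain, auth, ins, observed, aa3)


class TestExonTrack:
    def test_t1_junction_codon_assigned_to_exon1(self, resources):
        track = ft.build_exon_track(resources.transcript("T1"), resources)
        assert track.provenance == "UniProt"
        assert track.color_hint == "green"
        assert [(f.label, f.start, f.end) for f in track.features] == [
            ("exon1", 1, 11),
            ("exon2", 12, 19),
        ]

    def test_single_exon_transcript_full_span(self, resources):
        track = ft.build_exon_track(resources.transcript("T2"), resources)
        assert [(f.label, f.start, f.end) for f in track.features] == [("exon1", 1, 9)]

    def test_skipped_exon_feature_absent(self):
        # middle exon codes two isoform-specific residues; every one of its
        # codons projects to no canonical position, so its feature vanishes
        part1 = "".join(T1_CODONS[:10])
        part3 = "".join(T1_CODONS[10:])
        seq = "A" * 10 + part1 + "C" * 10 + "TCACCG" + "C" * 10 + part3 + "A" * 10
        contig = Contig(name="mini", sequence=seq)
        iv = lambda s, e: GenomicInterval("mini", s, e, "+")
        t = Transcript(
            id="M1", gene_id="MG", gene_name="MG", strand="+",
            exons=(iv(10, 40), iv(50, 56), iv(66, 96)),
            cds=(iv(10, 40), iv(50, 56), iv(66, 96)),
        )
        from genestruct.genome_model import GeneModel

        iso_set = IsoformSet(
            "Z",
            (Isoform("Z-1", T1_PROTEIN, True), Isoform("Z-2", ISO3_SEQUENCE, False)),
        )
        resources = MappingResources(
            genome=[contig],
            gene_models=[GeneModel("MG", "MG", [t])],
            isoform_sets=[iso_set],
        )
        track = ft.build_exon_track(t, resources)
        labels = [(f.label, f.start, f.end) for f in track.features]
        assert labels == [("exon1", 1, 10), ("exon3", 11, 19)]  # exon2 absent

    def test_t3_downstream_exons_shifted(self, resources):
        track = ft.build_exon_track(resources.transcript("T3"), resources)
        assert [(f.label, f.start, f.end) for f in track.features] == [
            ("exon1", 1, 4),
            ("exon2", 9, 11),
            ("exon3", 12, 19),
        ]


class TestVariantTrack:
    def test_missense_label(self, bundle, resources):
        track = ft.build_variant_track([("chrT", 107, "G", "A")], resources)
        (feature,) = track.features
        assert (feature.start, feature.end, feature.label) == (3, 3, "A3T")
        assert feature.attributes_dict["consequence"] == "missense"

    def test_synonymous_retained(self, bundle, resources):
        track = ft.build_variant_track([("chrT", 112, "G", "A")], resources)
        (feature,) = track.features
        assert feature.label == "L4L"
        assert feature.attributes_dict["consequence"] == "synonymous"

    def test_intronic_warns_and_skips(self, resources, caplog):
        with caplog.at_level("WARNING"):
            track = ft.build_variant_track([("chrT", 151, "G", "C")], resources)
        assert track.features == ()
        assert "maps to no codon" in caplog.text

    def test_ref_mismatch_warns_and_skips(self, resources, caplog):
        with caplog.at_level("WARNING"):
            track = ft.build_variant_track([("chrT", 107, "T", "A")], resources)
        assert track.features == ()
        assert "does not match" in caplog.text

    def test_minus_strand_variant(self, bundle, resources):
        # 0-based 327 is codon 1 base 3 of T2 (ATG -> ATA = I... start lost)
        # use codon 2 instead: bases 326,325,324 encode V (GTT)
        # mutate middle base: genomic offset 325 (1-based 326)
        chrT = bundle.contigs[0].sequence
        ref = chrT[325]
        alt = "A" if ref != "A" else "C"
        track = ft.build_variant_track([("chrT", 326, ref, alt)], resources)
        (feature,) = track.features
        assert feature.start == 2  # residue 2 of ACC2 canonical

    def test_malformed_variant_string(self):
        with pytest.raises(FormatError):
            ft.parse_variant("chrT:abc:G:A")
        with pytest.raises(FormatError):
            ft.parse_variant("chrT:100:G")
        assert ft.parse_variant("chrT:100:G:A") == ("chrT", 100, "G", "A")

    def test_label_retranslation_invariant(self, bundle, resources):
        for variant in bundle.variants:
            track = ft.build_variant_track([variant], resources)
            for feature in track.features:
                assert feature.label[-1].isalpha()
                # label's trailing residue is the re-translated alternate
                assert feature.label[0] != "" and feature.type == "variant"


class TestCoverageTrack:
    def test_map1_run(self, bundle):
        track = ft.build_coverage_track(bundle.residue_mappings, "ACC1")
        assert track.provenance == "PDB" and track.color_hint == "blue"
        map1_features = [f for f in track.features if f.label == "1XYZ:A"]
        assert [(f.start, f.end) for f in map1_features] == [(3, 17)]
        assert map1_features[0].attributes_dict["observed"] == "13"

    def test_empty_mapping_list(self):
        track = ft.build_coverage_track([], "ACC1")
        assert track.features == ()

    def test_hole_splits_runs(self):
        pairs = tuple(
            (pos, _ref("1AAA", "A", 100 + pos)) for pos in range(3, 18) if pos != 8
        )
        mapping = ResidueMapping("1AAA", "A", "ACC1", pairs)
        track = ft.build_coverage_track([mapping], "ACC1")
        assert [(f.start, f.end) for f in track.features] == [(3, 7), (9, 17)]


class TestMismatches:
    def test_map2_substitution_at_10(self, bundle):
        map2 = [m for m in bundle.residue_mappings if m.pdb_id == "2ABC"][0]
        track = ft.detect_mismatches(map2, T1_PROTEIN)
        (feature,) = track.features
        assert (feature.start, feature.end, feature.label) == (10, 10, "V10A")
        assert feature.attributes_dict["classification"] == "substitution"

    def test_identical_mapping_empty(self, bundle):
        map1 = [m for m in bundle.residue_mappings if m.pdb_id == "1XYZ"][0]
        track = ft.detect_mismatches(map1, T1_PROTEIN)
        assert track.features == ()

    def test_terminal_run_classified_as_extension(self):
        # mapped range 3..10; residues at 3,4,5 all wrong -> one terminal run
        pairs = []
        for pos in range(3, 11):
            aa3 = "GLY" if pos in (3, 4, 5) else "LYS"
            pairs.append((pos, _ref("1AAA", "A", 100 + pos, aa3)))
        mapping = ResidueMapping("1AAA", "A", "ACC1", tuple(pairs))
        canon = "MM" + "WWW" + "KKKKK" + "M" * 9  # mismatches at 3-5 only
        track = ft.detect_mismatches(mapping, canon)
        (feature,) = track.features
        assert (feature.start, feature.end) == (3, 5)
        assert feature.attributes_dict["classification"] == "terminal_extension"


class TestJson:
    def test_empty_track_list(self):
        text = ft.tracks_to_json([], "ACC1", 19)
        document = json.loads(text)
        assert document == {"accession": "ACC1", "length": 19, "tracks": []}

    def test_schema_validation(self, bundle, resources):
        tracks = [
            ft.build_exon_track(resources.transcript("T1"), resources),
            ft.build_coverage_track(bundle.residue_mappings, "ACC1"),
            ft.build_variant_track(bundle.variants, resources, accession="ACC1"),
        ]
        text = ft.tracks_to_json(tracks, "ACC1", 19)
        document = ft.tracks_from_json(text)  # raises on schema violation
        assert len(document["tracks"]) == 3

    def test_serialize_parse_serialize_stable(self, bundle, resources):
        tracks = [ft.build_exon_track(resources.transcript("T1"), resources)]
        text = ft.tracks_to_json(tracks, "ACC1", 19)
        reparsed = json.loads(text)
        assert json.dumps(reparsed, sort_keys=True, indent=2) + "\n" == text

    def test_feature_beyond_length_rejected(self):
        track = ft.FeatureTrack(
            name="bad", provenance="user",
            features=(ft.Feature(1, 50, "user", "oops"),),
        )
        with pytest.raises(FormatError):
            ft.tracks_to_json([track], "ACC1", 19)

    def test_all_built_tracks_within_bounds(self, bundle, resources):
        canon_len = 19
        tracks = [
            ft.build_exon_track(resources.transcript(tid), resources)
            for tid in ("T1", "T3", "T4")
        ]
        tracks.append(ft.build_coverage_track(bundle.residue_mappings, "ACC1"))
        for track in tracks:
            for f in track.features:
                assert 1 <= f.start <= f.end <= canon_len


class TestBedExport:
    def test_t1_map1_two_intervals(self, bundle, resources):
        map1 = [m for m in bundle.residue_mappings if m.pdb_id == "1XYZ"][0]
        records = ft.export_coverage_bed(resources.transcript("T1"), map1, resources)
        assert records == [
            ("chrT", 106, 131, "1XYZ:A", 0, "+"),
            ("chrT", 200, 220, "1XYZ:A", 0, "+"),
        ]

    def test_brute_force_base_set_equivalence(self, bundle, resources):
        truth = per_base_truth(resources.transcript("T1"))
        map1 = [m for m in bundle.residue_mappings if m.pdb_id == "1XYZ"][0]
        # T1's translation IS the canonical, so mapped residues = protein pos
        mapped_residues = set(map1.canonical_positions)
        expected = {off for off, (pp, _) in truth.items() if pp in mapped_residues}
        records = ft.export_coverage_bed(resources.transcript("T1"), map1, resources)
        got = {p for _, s, e, *_ in records for p in range(s, e)}
        assert got == expected

    def test_minus_strand_ascending(self, bundle, resources):
        map3 = [m for m in bundle.residue_mappings if m.pdb_id == "3DEF"][0]
        records = ft.export_coverage_bed(resources.transcript("T2"), map3, resources)
        assert records
        for _, start, end, _, _, strand in records:
            assert start < end
            assert strand == "-"

    def test_empty_mapping_no_records(self, bundle, resources):
        map3 = [m for m in bundle.residue_mappings if m.pdb_id == "3DEF"][0]
        # T1's accession is ACC1; MAP3 is against ACC2 -> nothing to export
        assert ft.export_coverage_bed(resources.transcript("T1"), map3, resources) == []


class TestUserFeatures:
    def test_read_user_features(self, bundle_dir):
        track = ft.read_user_features(bundle_dir / "user_features.tsv", "ACC1")
        (feature,) = track.features
        assert (feature.start, feature.end, feature.type, feature.label) == (
            2, 6, "domain", "DemoDomain",
        )
        assert track.provenance == "user"

    def test_other_accession_filtered(self, bundle_dir):
        track = ft.read_user_features(bundle_dir / "user_features.tsv", "ACC2")
        assert track.features == ()
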