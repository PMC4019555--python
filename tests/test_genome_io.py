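"""Coordinate conventions, flat-file round trips, circular canonicalization."""

from __future__ import annotations

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from skbio import TreeNode

from mitofeatures import genome_io as gio


def _write_genbank(tmp_path, seq: str, features, topology="circular", name="test"):
    rec = SeqRecord(Seq(seq), id=name, name=name, description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = topology
    rec.features = features
    path = tmp_path / f"{name}.gb"
    SeqIO.write(rec, str(path), "genbank")
    return path


class TestFeatureInterval:
    def test_span_lengths_and_wrap(self):
        assert gio.FeatureInterval(1, 777).length() == 777
        wrapped = gio.FeatureInterval(150, 30, wraps_origin=True)
        assert wrapped.length(160) == (160 - 150 + 1) + 30

    def test_positions_enumerate_through_origin(self):
        iv = gio.FeatureInterval(158, 3, wraps_origin=True)
        assert list(iv.positions(160)) == [158, 159, 160, 1, 2, 3]

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(gio.CoordinateError):
            gio.FeatureInterval(0, 10)
        with pytest.raises(gio.CoordinateError):
            gio.FeatureInterval(20, 10)


class TestCircularGenome:
    def test_canonical_position_mapping(self):
        g = gio.CircularGenome("g", "ACGT" * 10)
        assert g.canonical(41) == 1
        assert g.canonical(40) == 40

    def test_fetch_minus_strand_is_revcomp(self):
        g = gio.CircularGenome("g", "AACCGGTT")
        assert g.fetch(gio.FeatureInterval(1, 4, "-")) == "GGTT"

    def test_gc_excludes_n(self):
        g = gio.CircularGenome("g", "GGCCNNNN")
        assert g.gc_fraction() == 1.0

    def test_non_dna_rejected(self):
        with pytest.raises(gio.GenomeIOError):
            gio.CircularGenome("g", "ACGX")


class TestGenBankReading:
    def test_joined_cds_becomes_exons_and_intron(self, tmp_path):
        seq = "A" * 400
        loc = CompoundLocation(
            [SimpleLocation(0, 100, strand=1), SimpleLocation(200, 300, strand=1)]
        )
        feat = SeqFeature(loc, type="CDS", qualifiers={"gene": ["demo"]})
        path = _write_genbank(tmp_path, seq, [feat])
        _, genes, _ = gio.read_annotated_genome(path, "genbank")
        (g,) = genes
        assert len(g.exons) == 2
        assert g.coding_length(400) == 200
        assert len(g.introns) == 1
        assert g.introns[0].interval.length(400) == 100

    def test_trna_locus_length_from_published_row(self, tmp_path):
        seq = "A" * 40000
        feat = SeqFeature(
            SimpleLocation(39442, 39514, strand=1),
            type="tRNA",
            qualifiers={"gene": ["trnI"], "product": ["tRNA-Ile"], "anticodon": ["GAU"]},
        )
        path = _write_genbank(tmp_path, seq, [feat])
        _, genes, anticodons = gio.read_annotated_genome(path, "genbank")
        assert anticodons[0].locus.length(40000) == 72
        assert anticodons[0].anticodon == "GAU"

    def test_origin_spanning_cds_merges_to_wrapping_interval(self, tmp_path):
        # brute-force expectation: positions 150..160 plus 1..30 = 41 bases
        expected = len(list(range(150, 161))) + len(list(range(1, 31)))
        seq = "A" * 160
        loc = CompoundLocation(
            [SimpleLocation(149, 160, strand=1), SimpleLocation(0, 30, strand=1)]
        )
        feat = SeqFeature(loc, type="CDS", qualifiers={"gene": ["wrap"]})
        path = _write_genbank(tmp_path, seq, [feat])
        _, genes, _ = gio.read_annotated_genome(path, "genbank")
        (g,) = genes
        assert len(g.exons) == 1
        assert g.exons[0].wraps_origin
        assert g.coding_length(160) == expected == 41

    def test_feature_beyond_linear_sequence_is_an_error(self, tmp_path):
        seq = "A" * 100
        loc = CompoundLocation(
            [SimpleLocation(89, 100, strand=1), SimpleLocation(0, 30, strand=1)]
        )
        feat = SeqFeature(loc, type="CDS", qualifiers={"gene": ["bad"]})
        path = _write_genbank(tmp_path, seq, [feat], topology="linear")
        # a backwards join can only be resolved on a circular molecule
        with pytest.raises(gio.GenomeIOError, match="bad"):
            gio.read_annotated_genome(path, "genbank")


class TestAnnotationRoundTrips:
    def test_gff3_round_trip_preserves_structure(self, tmp_path, default_truth):
        truth = default_truth
        gff = tmp_path / "t.gff3"
        fa = tmp_path / "t.fa"
        gio.write_genome_fasta(truth.genome, fa)
        gio.write_annotation(
            truth.genes, gff, "gff3", genome=truth.genome, anticodons=truth.anticodons
        )
        _, back, back_ac = gio.read_annotated_genome(gff, "gff3+fasta", fasta_path=fa)
        orig = {g.name: g for g in truth.genes}
        assert set(orig) == {g.name for g in back}
        for g in back:
            o = orig[g.name]
            assert g.strand == o.strand
            assert g.feature_class == o.feature_class
            assert g.stop_codon == o.stop_codon
            assert [(e.start, e.end, e.wraps_origin) for e in g.exons] == [
                (e.start, e.end, e.wraps_origin) for e in o.exons
            ]
            assert [
                (i.ordinal, i.interval.start, i.intron_type, i.he_label)
                for i in g.introns
            ] == [
                (i.ordinal, i.interval.start, i.intron_type, i.he_label)
                for i in o.introns
            ]
        assert {(a.anticodon, a.locus.start) for a in back_ac} == {
            (a.anticodon, a.locus.start) for a in truth.anticodons
        }

    def test_gff3_round_trip_preserves_wrapped_feature(self, tmp_path):
        genome = gio.CircularGenome("c", "ACGT" * 100)
        gene = gio.GeneModel(
            name="wrap",
            feature_class="protein",
            exons=[gio.FeatureInterval(395, 6, "+", wraps_origin=True)],
            strand="+",
            stop_codon="TAA",
        )
        fa = tmp_path / "c.fa"
        gff = tmp_path / "c.gff3"
        gio.write_genome_fasta(genome, fa)
        gio.write_annotation([gene], gff, "gff3", genome=genome)
        _, back, _ = gio.read_annotated_genome(gff, "gff3+fasta", fasta_path=fa)
        assert back[0].exons[0].wraps_origin
        assert (back[0].exons[0].start, back[0].exons[0].end) == (395, 6)

    def test_bed_is_zero_based_half_open(self, tmp_path):
        genome = gio.CircularGenome("c", "A" * 1000)
        gene = gio.GeneModel(
            "atp6", "protein", [gio.FeatureInterval(1, 777, "+")], "+", "TAA"
        )
        bed = tmp_path / "x.bed"
        gio.write_annotation([gene], bed, "bed", genome=genome)
        fields = bed.read_text().split("\t")
        assert (fields[1], fields[2]) == ("0", "777")

    def test_bed12_round_trip_two_exon_gene(self, tmp_path):
        genome = gio.CircularGenome("c", "A" * 1000)
        gene = gio.GeneModel(
            "two",
            "protein",
            [gio.FeatureInterval(101, 200, "+"), gio.FeatureInterval(301, 400, "+")],
            "+",
        )
        bed = tmp_path / "x.bed"
        gio.write_annotation([gene], bed, "bed", genome=genome)
        (back,) = gio.read_bed12(bed)
        assert [(e.start, e.end) for e in back.exons] == [(101, 200), (301, 400)]

    def test_bed_rejects_wrapping_feature(self, tmp_path):
        genome = gio.CircularGenome("c", "A" * 100)
        gene = gio.GeneModel(
            "w", "protein", [gio.FeatureInterval(90, 10, "+", wraps_origin=True)], "+"
        )
        with pytest.raises(gio.CoordinateError):
            gio.write_annotation([gene], tmp_path / "x.bed", "bed", genome=genome)


class TestNewick:
    def test_two_leaf_tree_serialization(self, tmp_path):
        tree = TreeNode.read(["(A:0.1,B:0.2);"])
        path = tmp_path / "t.nwk"
        gio.write_newick(tree, path)
        text = path.read_text().strip()
        assert text.startswith("(") and "A:0.1" in text and "B:0.2" in text

    def test_star_tree_multifurcation_preserved(self, tmp_path):
        tree = TreeNode.read(["(A:1,B:1,C:1);"])
        path = tmp_path / "t.nwk"
        gio.write_newick(tree, path)
        back = gio.read_newick(path)
        assert len(back.children) == 3

    def test_random_tree_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        leaves = [f"t{i}" for i in range(8)]
        nodes = [TreeNode(name=nm, length=round(float(rng.uniform(0.01, 1)), 6))
                 for nm in leaves]
        while len(nodes) > 1:
            a = nodes.pop(int(rng.integers(len(nodes))))
            b = nodes.pop(int(rng.integers(len(nodes))))
            parent = TreeNode(children=[a, b],
                              length=round(float(rng.uniform(0.01, 1)), 6))
            nodes.append(parent)
        tree = nodes[0]
        path = tmp_path / "t.nwk"
        gio.write_newick(tree, path)
        back = gio.read_newick(path)
        assert back.compare_rfd(tree) == 0
        for leaf in back.tips():
            orig = tree.find(leaf.name)
            assert abs(leaf.length - orig.length) < 1e-9


class TestCircularCanonicalization:
    def test_rotation_preserves_gene_lengths_and_distances(self, default_truth):
        truth = default_truth
        L = len(truth.genome)
        offset = L // 3
        rotated = truth.genome.rotate(offset)
        assert len(rotated) == L
        for g in truth.genes:
            span = g.span(L)
            shifted = span.shifted(offset, L)
            assert shifted.length(L) == span.length(L)
        # pairwise circular midpoint distances are invariant
        mids = []
        for g in truth.genes[:6]:
            s0, e0 = g.span(L).unrolled(L)
            mids.append(((s0 + e0) / 2) % L)
        shifted_mids = [(m - offset) % L for m in mids]
        for i in range(len(mids)):
            for j in range(i + 1, len(mids)):
                d1 = abs(mids[i] - mids[j])
                d2 = abs(shifted_mids[i] - shifted_mids[j])
                assert min(d1, L - d1) == pytest.approx(min(d2, L - d2))

    def test_rotation_round_trip_restores_sequence(self, default_truth):
        g = default_truth.genome
        assert g.rotate(1234).rotate(len(g) - 1234).residues == g.residues
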