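"""Domain types and format I/O: TSV feature tables, GenBank, FASTA, Newick."""

import tempfile
import warnings
from pathlib import Path

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoprofile import io as mio
from mitoprofile.align import Alignment
from mitoprofile.model import Feature, FeatureTable, Genome, MitoError, genetic_code, revcomp
from mitoprofile.tree import from_newick, to_newick

GENBANK_FIXTURE = """\
LOCUS       SYNTH01                15744 bp    DNA     circular INV 01-JAN-2024
DEFINITION  synthetic test record.
ACCESSION   SYNTH01
FEATURES             Location/Qualifiers
     source          1..15744
     CDS             205..1239
                     /gene="ND2"
     CDS             complement(6409..8143)
                     /gene="ND5"
     tRNA            join(15700..15744,1..10)
                     /product="tRNA-Wrap"
     D-loop          15010..15699
ORIGIN
{origin}
//
"""


def _genbank_text() -> str:
    seq = ("acgt" * 4000)[:15744]
    lines = []
    for i in range(0, len(seq), 60):
        chunk = seq[i : i + 60]
        parts = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    return GENBANK_FIXTURE.format(origin="\n".join(lines))


class TestGenome:
    def test_length_and_slice(self):
        g = Genome("g", "ACGTACGTAA")
        assert g.length == 10
        assert g.slice(2, 5) == "CGTA"

    def test_wraparound_slice_crosses_origin(self):
        g = Genome("g", "AAACCCGGGT")
        assert g.slice(9, 2) == "GTAA"

    def test_invalid_symbols_rejected(self):
        with pytest.raises(MitoError, match="invalid symbols"):
            Genome("g", "ACGTX")

    def test_u_mapped_to_t_and_uppercased(self):
        assert Genome("g", "acgu").sequence == "ACGT"

    def test_revcomp(self):
        assert revcomp("AACGTN") == "NACGTT"


class TestFeatureTable:
    def test_duplicate_names_rejected(self):
        f = [Feature("A", "tRNA", 1, 60), Feature("A", "tRNA", 70, 130)]
        with pytest.raises(MitoError, match="duplicate"):
            FeatureTable("g", f, 200)

    def test_out_of_range_rejected(self):
        with pytest.raises(MitoError, match="outside genome"):
            FeatureTable("g", [Feature("A", "tRNA", 1, 300)], 200)

    def test_anticodon_only_on_trna(self):
        with pytest.raises(MitoError, match="anticodon"):
            Feature("ND2", "PCG", 1, 90, anticodon="GAT")

    def test_strand_synonyms(self):
        assert Feature("A", "tRNA", 1, 60, strand="+").strand == "J"
        assert Feature("A", "tRNA", 1, 60, strand="-").strand == "N"


class TestFeatureTableIO:
    def test_reference_round_trip(self, ref_table, tmp_path):
        p = tmp_path / "ft.tsv"
        mio.write_feature_table(ref_table, p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = mio.read_feature_table(p, genome_length=ref_table.genome_length)
        assert [(f.name, f.cls, f.strand, f.start, f.end, f.anticodon) for f in back] == [
            (f.name, f.cls, f.strand, f.start, f.end, f.anticodon) for f in ref_table
        ]

    def test_reference_layout_counts(self, ref_table):
        assert len(ref_table) == 38
        assert len(ref_table.by_class("PCG")) == 13
        assert len(ref_table.by_class("tRNA")) == 22
        assert len(ref_table.by_class("rRNA")) == 2
        assert len(ref_table.by_class("CR")) == 1

    def test_empty_file_is_parse_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(MitoError, match="empty"):
            mio.read_feature_table(p)

    def test_malformed_coordinate_names_row(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tclass\tstrand\tstart\tend\nX\tPCG\tJ\tabc\t100\n")
        with pytest.raises(MitoError, match="row 2"):
            mio.read_feature_table(p)

    def test_thousands_separators_tolerated(self, tmp_path):
        p = tmp_path / "sep.tsv"
        p.write_text("gene\tclass\tstrand\tstart\tend\nX\tPCG\tJ\t1,205\t2,400\n")
        t = mio.read_feature_table(p)
        assert (t["X"].start, t["X"].end) == (1205, 2400)

    def test_printed_anticodon_typos_flagged_not_fatal(self):
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            t = mio.read_feature_table(
                mio._data_path("mflexura_features.tsv"), genome_length=15744
            )
        flagged = {f.name: f.anticodon_flag for f in t if f.anticodon_flag}
        assert flagged["tRNA-Asn"] == "descending"
        assert "tRNA-Val" in flagged
        assert any("suspicious anticodon" in str(w.message) for w in rec)

    @settings(max_examples=20, deadline=None)
    @given(st.lists(
        st.tuples(st.integers(1, 480), st.integers(20, 90), st.sampled_from("JN")),
        min_size=1, max_size=8))
    def test_round_trip_random_tables(self, spans):
        feats = []
        for i, (start, size, strand) in enumerate(sorted(spans)):
            feats.append(Feature(f"f{i}", "PCG", start, min(start + size, 600), strand))
        table = FeatureTable("g", feats, 600)
        with tempfile.TemporaryDirectory() as d:
            p = Path(d) / "t.tsv"
            mio.write_feature_table(table, p)
            back = mio.read_feature_table(p, genome_length=600)
        assert [(f.name, f.start, f.end, f.strand) for f in back] == [
            (f.name, f.start, f.end, f.strand) for f in table
        ]


@pytest.fixture(scope="module")
def record(tmp_path_factory):
    p = tmp_path_factory.mktemp("gb") / "synth.gb"
    p.write_text(_genbank_text())
    return mio.read_genbank(p)


class TestGenBank:
    def test_plain_cds_mapped(self, record):
        g, t = record
        f = t["ND2"]
        assert (f.start, f.end, f.strand, f.cls) == (205, 1239, "J", "PCG")
        assert f.size(g.length) == 1035

    def test_complement_maps_to_strand_n(self, record):
        _, t = record
        assert t["ND5"].strand == "N"

    def test_origin_join_becomes_wrap_feature(self, record):
        g, t = record
        f = t["tRNA-Wrap"]
        assert (f.start, f.end) == (15700, 10)
        assert f.size(g.length) == 55

    def test_dloop_mapped_to_cr(self, record):
        _, t = record
        assert len(t.by_class("CR")) == 1

    def test_genome_matches_origin(self, record):
        g, _ = record
        assert g.length == 15744 and g.circular

    def test_missing_origin_is_error(self, tmp_path):
        p = tmp_path / "noseq.gb"
        p.write_text(_genbank_text().split("ORIGIN")[0] + "ORIGIN\n//\n")
        with pytest.raises(MitoError):
            mio.read_genbank(p)


class TestFastaAlignmentNewick:
    def test_fasta_round_trip(self, tmp_path):
        p = tmp_path / "g.fasta"
        seq = "ACGT" * 50
        mio.write_fasta({"genome": seq}, p)
        assert mio.read_fasta(p).sequence == seq

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        mio.write_fasta({"A": "ACGT", "B": "ACG"}, p)
        with pytest.raises(MitoError, match="ragged"):
            mio.read_alignment(p)

    def test_alignment_bad_symbols_listed(self):
        with pytest.raises(MitoError, match=r"\['X'\]"):
            Alignment({"A": "ACXT"})

    def test_newick_round_trip_preserves_topology_and_lengths(self):
        nwk = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.07,E:0.15);"
        t = from_newick(nwk)
        back = from_newick(to_newick(t))
        assert back.splits() == t.splits()
        assert sorted(round(n.length, 10) for n in back.postorder()) == sorted(
            round(n.length, 10) for n in t.postorder()
        )


class TestGeneticCode:
    def test_table5_family_structure(self, code5):
        assert len(code5.families["L"]) == 6
        assert len(code5.families["S"]) == 8
        assert code5.forward["ATA"] == "M"
        assert code5.forward["TGA"] == "W"
        assert code5.forward["AGA"] == "S"

    def test_partition_covers_64_codons(self, code5):
        n = sum(len(f) for f in code5.families.values()) + len(code5.stop_codons)
        assert n == 64
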