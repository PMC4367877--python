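import pytest

from telandscape.annotation_io import (
    AnnotationFormatError,
    extract_features,
    read_annotation,
    write_annotation,
)
from telandscape.core_model import FORWARD, REVERSE

from .conftest import make_gene, make_genome

MINIMAL_GENBANK = """\
LOCUS       Chr1                    5000 bp    DNA     linear   PLN 01-JAN-2000
DEFINITION  synthetic test chromosome.
ACCESSION   Chr1
VERSION     Chr1
KEYWORDS    .
SOURCE      test organism
  ORGANISM  test organism
            .
FEATURES             Location/Qualifiers
     source          1..5000
                     /organism="test organism"
     gene            100..400
                     /locus_tag="g1"
                     /db_xref="GeneID:12345"
     gene            complement(1000..2000)
                     /locus_tag="g2"
     gene            join(2500..2600,2800..2900)
                     /locus_tag="g3"
     misc_RNA        3000..3100
                     /locus_tag="r1"
ORIGIN
//
"""

EMPTY_GENBANK = """\
LOCUS       Chr9                    1000 bp    DNA     linear   PLN 01-JAN-2000
DEFINITION  no features.
ACCESSION   Chr9
VERSION     Chr9
KEYWORDS    .
SOURCE      x
  ORGANISM  x
            .
FEATURES             Location/Qualifiers
     source          1..1000
ORIGIN
//
"""


@pytest.fixture
def gb_path(tmp_path):
    p = tmp_path / "mini.gb"
    p.write_text(MINIMAL_GENBANK)
    return p


class TestReadGenBank:
    def test_minimal_record(self, gb_path):
        genome = read_annotation(gb_path, "genbank")
        assert len(genome.chromosomes) == 1
        chrom = genome.chromosomes[0]
        assert chrom.chrom_id == "Chr1"
        assert chrom.length == 5000
        assert genome.organism == "test organism"
        g1 = next(f for f in chrom.features if f.gene_name == "g1")
        assert (g1.region.start, g1.region.end, g1.region.strand) == (100, 400, FORWARD)
        assert g1.kind == "gene"
        assert g1.gene_numeric_id == 12345

    def test_complement_location_gives_reverse_strand(self, gb_path):
        chrom = read_annotation(gb_path, "genbank").chromosomes[0]
        g2 = next(f for f in chrom.features if f.gene_name == "g2")
        assert (g2.region.start, g2.region.end, g2.region.strand) == (1000, 2000, REVERSE)

    def test_join_flattens_to_span_plus_exons(self, gb_path):
        chrom = read_annotation(gb_path, "genbank").chromosomes[0]
        g3 = [f for f in chrom.features if f.gene_name == "g3"]
        kinds = sorted(f.kind for f in g3)
        assert kinds == ["exon", "exon", "gene"]
        span = next(f for f in g3 if f.kind == "gene")
        assert (span.region.start, span.region.end) == (2500, 2900)
        exon_coords = sorted(
            (f.region.start, f.region.end) for f in g3 if f.kind == "exon"
        )
        assert exon_coords == [(2500, 2600), (2800, 2900)]

    def test_misc_rna_kind(self, gb_path):
        chrom = read_annotation(gb_path, "genbank").chromosomes[0]
        assert any(f.kind == "miscRNA" for f in chrom.features)

    def test_empty_feature_table_is_fine(self, tmp_path):
        p = tmp_path / "empty.gb"
        p.write_text(EMPTY_GENBANK)
        genome = read_annotation(p, "auto")
        assert genome.chromosomes[0].length == 1000
        assert genome.chromosomes[0].features == []

    def test_auto_sniffs_genbank(self, gb_path):
        assert read_annotation(gb_path, "auto").chromosomes[0].chrom_id == "Chr1"

    def test_missing_or_empty_file_rejected(self, tmp_path):
        with pytest.raises(AnnotationFormatError):
            read_annotation(tmp_path / "nope.gb")
        empty = tmp_path / "zero.gb"
        empty.write_text("")
        with pytest.raises(AnnotationFormatError):
            read_annotation(empty)


class TestDialectEquivalence:
    def _roundtrip(self, tmp_path, dialect):
        genes = [
            make_gene(start=100, end=400, name="a", numeric=1),
            make_gene(start=1000, end=2000, name="b", strand="-", kind="pseudogene"),
            make_gene(start=3000, end=3200, name="c", kind="miscRNA"),
        ]
        genome = make_genome(chrom_len=10_000, genes=genes)
        path = tmp_path / f"g.{dialect}"
        write_annotation(genome, path, dialect)
        return genome, read_annotation(path, "auto")

    @pytest.mark.parametrize("dialect", ["genbank", "embl", "native"])
    def test_written_file_parses_back_to_planted_features(self, tmp_path, dialect):
        planted, parsed = self._roundtrip(tmp_path, dialect)
        want = [
            (f.region.chrom, f.region.start, f.region.end, f.region.strand, f.kind, f.gene_name)
            for c in planted.chromosomes
            for f in c.features
        ]
        got = [
            (f.region.chrom, f.region.start, f.region.end, f.region.strand, f.kind, f.gene_name)
            for c in parsed.chromosomes
            for f in c.features
        ]
        assert got == want
        assert parsed.chromosomes[0].length == 10_000

    def test_native_bad_coordinates_name_the_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "#chromosome\tchr1\t1000\n" "chr1\t500\t100\t+\tgene\tg1\t\n"
        )
        with pytest.raises(AnnotationFormatError, match="end < start"):
            read_annotation(p, "native")


class TestExtractFeatures:
    def test_selects_and_sorts(self):
        genes = [
            make_gene(start=500, end=600, name="late"),
            make_gene(start=10, end=99, name="early"),
            make_gene(start=200, end=300, name="x", kind="exon"),
        ]
        rec = make_genome(genes=genes).chromosomes[0]
        got = extract_features(rec, {"gene"})
        assert [f.gene_name for f in got] == ["early", "late"]

    def test_all_kinds_is_identity_as_multiset(self):
        genes = [make_gene(start=i * 10, end=i * 10 + 5, name=f"g{i}") for i in range(1, 4)]
        rec = make_genome(genes=genes).chromosomes[0]
        all_kinds = {"gene", "exon", "pseudogene", "miscRNA", "five_prime_UTR", "three_prime_UTR"}
        assert sorted(f.gene_name for f in extract_features(rec, all_kinds)) == [
            "g1",
            "g2",
            "g3",
        ]

    def test_absent_kind_gives_empty_list(self):
        rec = make_genome(genes=[make_gene()]).chromosomes[0]
        assert extract_features(rec, {"five_prime_UTR"}) == []

    def test_unknown_kind_lists_valid_kinds(self):
        rec = make_genome(genes=[]).chromosomes[0]
        with pytest.raises(ValueError, match="valid kinds"):
            extract_features(rec, {"enhancer"})
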