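"""Catalogue readers: dialect parsing, filtering rules and round-trips."""

import pytest

from genecat.catalogue_io import (
    GENCODE, REFSEQ, UNIPROT,
    Catalogue, DuplicateAccessionError, GeneRecord, GtfParseError, SchemaError,
    read_catalogue_tsv, read_gencode_gtf, read_refseq_table,
    read_uniprot_table, write_catalogue_tsv, looks_ig_tr, normalise_chrom,
)

ATTRS = 'gene_id "ENSG00000000001"; gene_name "ALPHA1"; gene_type "protein_coding";'


def _gtf(tmp_path, lines, name="t.gtf"):
    p = tmp_path / name
    p.write_text("\n".join(lines) + "\n")
    return p


class TestGencodeGtf:
    def test_single_protein_coding_gene(self, tmp_path):
        path = _gtf(tmp_path, [
            f"chr1\tX\tgene\t100\t900\t.\t+\t.\t{ATTRS}",
            f'chr1\tX\ttranscript\t100\t900\t.\t+\t.\t{ATTRS} transcript_id "T1";',
            f'chr1\tX\texon\t100\t900\t.\t+\t.\t{ATTRS} transcript_id "T1";',
        ])
        cat = read_gencode_gtf(path)
        assert len(cat) == 1
        rec = cat.records[0]
        assert (rec.gene_id, rec.chrom, rec.start, rec.end) == \
            ("ENSG00000000001", "1", 100, 900)
        assert rec.tags == set()
        assert rec.exons == [(100, 900)]

    def test_readthrough_tag_when_all_transcripts_tagged(self, tmp_path):
        t = ATTRS + ' transcript_id "T1"; tag "readthrough_gene";'
        path = _gtf(tmp_path, [
            f"chr1\tX\tgene\t100\t900\t.\t+\t.\t{ATTRS}",
            f"chr1\tX\ttranscript\t100\t900\t.\t+\t.\t{t}",
        ])
        cat = read_gencode_gtf(path)
        assert cat.records[0].tags == {"readthrough"}

    def test_readthrough_all_vs_any_transcript_mode(self, tmp_path):
        t1 = ATTRS + ' transcript_id "T1"; tag "readthrough_gene";'
        t2 = ATTRS + ' transcript_id "T2";'
        lines = [f"chr1\tX\tgene\t100\t900\t.\t+\t.\t{ATTRS}",
                 f"chr1\tX\ttranscript\t100\t900\t.\t+\t.\t{t1}",
                 f"chr1\tX\ttranscript\t100\t900\t.\t+\t.\t{t2}"]
        path = _gtf(tmp_path, lines)
        assert read_gencode_gtf(path).records[0].tags == set()
        assert read_gencode_gtf(path, readthrough_mode="any") \
            .records[0].tags == {"readthrough"}

    def test_scaffold_gene_excluded_and_counted(self, tmp_path):
        path = _gtf(tmp_path, [
            f"GL000009.2\tX\tgene\t100\t900\t.\t+\t.\t{ATTRS}",
        ])
        cat = read_gencode_gtf(path)
        assert len(cat) == 0
        assert cat.skip_counts["chromosome_not_whitelisted"] == 1

    def test_non_coding_biotype_goes_to_side_list(self, tmp_path):
        attrs = 'gene_id "ENSG2"; gene_name "PSI1"; gene_type "processed_pseudogene";'
        path = _gtf(tmp_path, [f"chr2\tX\tgene\t10\t90\t.\t-\t.\t{attrs}"])
        cat = read_gencode_gtf(path)
        assert len(cat.records) == 0
        assert [r.status for r in cat.side_records] == ["processed_pseudogene"]

    def test_malformed_attribute_column_names_line(self, tmp_path):
        path = _gtf(tmp_path, [
            f"chr1\tX\tgene\t100\t900\t.\t+\t.\t{ATTRS}",
            "chr1\tX\tgene\t100\t900\t.\t+\t.",  # 8 columns
        ])
        with pytest.raises(GtfParseError) as err:
            read_gencode_gtf(path)
        assert err.value.line_no == 2


class TestRefseqTable:
    HEADER = ("gene_id\tsymbol\tchromosome\tstart\tend\tstrand\tgene_type"
              "\tassembly")

    def _read(self, tmp_path, rows):
        p = tmp_path / "r.tsv"
        p.write_text("\n".join([self.HEADER] + rows) + "\n")
        return read_refseq_table(p)

    def test_grch38_protein_coding_row_kept(self, tmp_path):
        cat = self._read(tmp_path,
                         ["101\tB1\t1\t10\t90\t+\tprotein-coding\tGRCh38"])
        assert len(cat) == 1 and cat.records[0].gene_id == "101"

    def test_other_assembly_excluded(self, tmp_path):
        cat = self._read(tmp_path,
                         ["101\tB1\t1\t10\t90\t+\tprotein-coding\tT2T-CHM13"])
        assert len(cat) == 0
        assert cat.skip_counts["other_assembly"] == 1

    def test_ig_fragment_typed_other_goes_to_side_list(self, tmp_path):
        cat = self._read(tmp_path, ["102\tIGHV1-1\t14\t10\t90\t+\tother\tGRCh38"])
        assert len(cat.records) == 0
        assert cat.side_records[0].status == "other"

    def test_missing_column_raises_schema_error(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("gene_id\tsymbol\n1\tA\n")
        with pytest.raises(SchemaError) as err:
            read_refseq_table(p)
        assert "chromosome" in err.value.missing


class TestUniprotTable:
    HEADER = "accession\treviewed\tgene_symbols\tchrom\tstart\tend\tstrand\tplacement"

    def _read(self, tmp_path, rows):
        p = tmp_path / "u.tsv"
        p.write_text("\n".join([self.HEADER] + rows) + "\n")
        return read_uniprot_table(p)

    def test_reviewed_entry_kept(self, tmp_path):
        cat = self._read(tmp_path, ["P00001\tyes\tC1\t1\t10\t90\t+\tgenome"])
        assert len(cat) == 1
        assert cat.records[0].hgnc_symbol == "C1"

    def test_unreviewed_entry_skipped_and_counted(self, tmp_path):
        cat = self._read(tmp_path, ["A00001\tno\tC1\t1\t10\t90\t+\tgenome"])
        assert len(cat) == 0
        assert cat.skip_counts["unreviewed"] == 1

    def test_scaffold_only_entry_tagged(self, tmp_path):
        cat = self._read(tmp_path, ["P00001\tyes\tC1\t\t\t\t\tscaffold"])
        assert cat.records[0].tags == {"scaffold_only"}

    def test_no_genomic_mapping_tagged_and_coordinates_nulled(self, tmp_path):
        cat = self._read(tmp_path, ["P00001\tyes\tC1\t1\t10\t90\t+\tnone"])
        rec = cat.records[0]
        assert rec.tags == {"no_coordinates"}
        assert rec.chrom is None and rec.start is None

    def test_duplicate_accession_raises(self, tmp_path):
        with pytest.raises(DuplicateAccessionError):
            self._read(tmp_path, ["P00001\tyes\tC1\t1\t10\t90\t+\tgenome",
                                  "P00001\tno\tC2\t1\t10\t90\t+\tgenome"])

    def test_multiple_symbols_all_retained(self, tmp_path):
        cat = self._read(tmp_path, ["P00001\tyes\tC1;C2;C3\t1\t10\t90\t+\tgenome"])
        assert cat.records[0].symbols == ("C1", "C2", "C3")
        assert cat.records[0].hgnc_symbol == "C1"


class TestRecordModel:
    def test_start_after_end_rejected(self):
        with pytest.raises(ValueError):
            GeneRecord("g", GENCODE, "S", "1", 100, 50, "+")

    def test_exon_outside_span_rejected(self):
        with pytest.raises(ValueError):
            GeneRecord("g", GENCODE, "S", "1", 100, 200, "+", exons=[(90, 150)])

    def test_overlapping_exons_merged_and_sorted(self):
        rec = GeneRecord("g", GENCODE, "S", "1", 1, 1000, "+",
                         exons=[(500, 700), (100, 200), (150, 300)])
        assert rec.exons == [(100, 300), (500, 700)]
        assert rec.introns() == [(301, 499)]

    @pytest.mark.parametrize("symbol,expected", [
        ("IGHV1-69", True), ("TRBV5-1", True), ("IGKC", True),
        ("TP53", False), ("TRIM21", False), ("IGF1", False),
    ])
    def test_ig_tr_symbol_heuristic(self, symbol, expected):
        assert looks_ig_tr(symbol) is expected

    @pytest.mark.parametrize("raw,norm", [
        ("chr1", "1"), ("chrM", "MT"), ("X", "X"), ("MT", "MT"), (None, None)])
    def test_chromosome_normalisation(self, raw, norm):
        assert normalise_chrom(raw) == norm


class TestRoundTrip:
    def test_normalised_tsv_round_trip_identity(self, tmp_path, small_bundle):
        """Writing and re-reading each catalogue reproduces every field."""
        from genecat.catalogue_io import _record_to_row
        for source, cat in small_bundle.catalogues.items():
            path = tmp_path / f"{source}.tsv"
            write_catalogue_tsv(cat, path)
            back = read_catalogue_tsv(path)
            assert back.source == cat.source
            assert len(back.records) == len(cat.records)
            for a, b in zip(cat.records, back.records):
                assert _record_to_row(a, False) == _record_to_row(b, False)
            for a, b in zip(cat.side_records, back.side_records):
                assert _record_to_row(a, True) == _record_to_row(b, True)

    def test_dialect_readers_reproduce_in_memory_catalogues(self, tmp_path,
                                                            small_bundle):
        """The GTF/TSV dialect writers and readers agree with the in-memory
        records (row conservation and field equality)."""
        from genecat.catalogue_io import _record_to_row
        paths = small_bundle.write(tmp_path)
        parsed = {
            GENCODE: read_gencode_gtf(paths["gencode_gtf"]),
            REFSEQ: read_refseq_table(paths["refseq_tsv"]),
            UNIPROT: read_uniprot_table(paths["uniprot_tsv"]),
        }
        for source, cat in small_bundle.catalogues.items():
            got = parsed[source]
            key = lambda r: r.gene_id
            for mine, theirs in (
                    (sorted(cat.records, key=key), sorted(got.records, key=key)),
                    (sorted(cat.side_records, key=key),
                     sorted(got.side_records, key=key))):
                assert len(mine) == len(theirs)
                for a, b in zip(mine, theirs):
                    assert a.gene_id == b.gene_id
                    assert a.hgnc_symbol == b.hgnc_symbol
                    assert (a.chrom, a.start, a.end, a.strand) == \
                        (b.chrom, b.start, b.end, b.strand)
                    assert a.tags == b.tags
                    if source == GENCODE:
                        assert a.exons == b.exons or not a.exons
                        assert sorted(a.utr_intervals) == sorted(b.utr_intervals)
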