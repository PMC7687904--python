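import numpy as np
import pytest

from qtlannot.ingest import (DatasetManifest, GeneIndex, IngestError,
                             QtlStore, TissueNormalizationMap,
                             ingest_manifest, read_genes, read_gwas_catalog,
                             read_qtl_table, read_store_tsv, read_tads,
                             write_store_tsv)

from conftest import make_gene

QTL_HEADER = "rsid\tchrom\tpos\tgene\ttissue\tp\tbeta\tea\tnea\n"


@pytest.fixture
def gene_index():
    return GeneIndex([make_gene("G1", "SYM1"),
                      make_gene("G2", "SYM2", start1=3_000_000,
                                end1=3_050_000)])


def write_qtl(tmp_path, rows, header=QTL_HEADER):
    path = tmp_path / "qtls.tsv"
    path.write_text(header + "".join(rows))
    return str(path)


def manifest_entry(path, **kw):
    kw.setdefault("source", "SrcA")
    kw.setdefault("study", "StudyA")
    return DatasetManifest(path=path, **kw)


class TestReadQtlTable:
    def test_three_row_toy_table(self, tmp_path, gene_index):
        path = write_qtl(tmp_path, [
            "rs1\t1\t1000500\tSYM1\tLiver\t1e-5\t0.2\tA\tG\n",
            "rs2\t1\t1000600\tSYM1\tLiver\t1e-8\t-0.1\tT\tC\n",
            "rs3\t1\t3000100\tSYM2\tBlood\t0.5\t\t\t\n"])
        records, report = read_qtl_table(path, manifest_entry(path),
                                         gene_index)
        assert len(records) == 3
        assert report.n_rows == 3 and report.n_rejected == 0

    def test_empty_beta_retained_as_absent(self, tmp_path, gene_index):
        path = write_qtl(tmp_path,
                         ["rs1\t1\t1000500\tSYM1\tLiver\t1e-5\t\tA\tG\n"])
        records, _ = read_qtl_table(path, manifest_entry(path), gene_index)
        assert records[0].beta is None
        assert records[0].effect_allele == "A"

    def test_p_zero_rejected_with_diagnostic(self, tmp_path, gene_index):
        path = write_qtl(tmp_path, [
            "rs1\t1\t1000500\tSYM1\tLiver\t0\t0.2\tA\tG\n",
            "rs2\t1\t1000600\tSYM1\tLiver\t1e-8\t0.1\tA\tG\n"])
        records, report = read_qtl_table(path, manifest_entry(path),
                                         gene_index)
        assert len(records) == 1
        assert report.n_rejected == 1
        assert any("(0,1]" in msg for msg in report.rejections)

    def test_missing_mandatory_column_hard_error(self, tmp_path, gene_index):
        path = tmp_path / "bad.tsv"
        path.write_text("rsid\tgene\ttissue\n" "rs1\tSYM1\tLiver\n")
        with pytest.raises(IngestError, match="mandatory column"):
            read_qtl_table(str(path), manifest_entry(str(path)), gene_index)

    def test_unmappable_tissue_hard_error_lists_offenders(self, tmp_path,
                                                          gene_index):
        path = write_qtl(tmp_path,
                         ["rs1\t1\t1000500\tSYM1\tMysteryTissue\t1e-5\t\t\t\n"])
        tmap = TissueNormalizationMap(mapping={"Liver": "Liver"},
                                      allow_identity=False)
        with pytest.raises(IngestError, match="MysteryTissue"):
            read_qtl_table(path, manifest_entry(path), gene_index, tmap)

    def test_duplicate_quadruple_keeps_smallest_p(self, tmp_path, gene_index):
        path = write_qtl(tmp_path, [
            "rs1\t1\t1000500\tSYM1\tLiver\t1e-5\t0.2\tA\tG\n",
            "rs1\t1\t1000500\tSYM1\tLiver\t1e-9\t0.2\tA\tG\n"])
        records, report = read_qtl_table(path, manifest_entry(path),
                                         gene_index)
        assert len(records) == 1
        assert records[0].p_value == 1e-9
        assert report.n_duplicates == 1

    def test_tissue_normalization_applied(self, tmp_path, gene_index):
        path = write_qtl(tmp_path,
                         ["rs1\t1\t1000500\tSYM1\tArtery - Aorta\t1e-5\t\t\t\n"])
        records, _ = read_qtl_table(path, manifest_entry(path), gene_index)
        assert records[0].study.tissue == "Artery-Aorta"


class TestReadTads:
    def test_bed_coordinate_convention(self, tmp_path):
        path = tmp_path / "tads.bed"
        path.write_text("chr1\t1000\t5000\n")
        tads, _ = read_tads(str(path))
        # covers 1-based positions 1001..5000, i.e. 0-based 1000..4999
        assert tads.contains("1", 1000) and tads.contains("1", 4999)
        assert not tads.contains("1", 999) and not tads.contains("1", 5000)

    def test_empty_file_empty_set(self, tmp_path):
        path = tmp_path / "tads.bed"
        path.write_text("")
        tads, _ = read_tads(str(path))
        assert len(tads) == 0

    def test_invalid_interval_rejected(self, tmp_path):
        path = tmp_path / "tads.bed"
        path.write_text("chr1\t5000\t1000\nchr1\t0\t100\n")
        tads, report = read_tads(str(path))
        assert len(tads) == 1 and report.n_rejected == 1

    def test_summary_reproduces_synthetic_moments(self, tmp_path):
        """A boundary set generated to published moments (3054 intervals,
        mean 853 kb, min 0.8 kb, max 4.44 Mb) reads back unchanged."""
        rng = np.random.default_rng(5)
        lengths = np.clip(rng.gamma(2.0, 853_000 / 2.0, size=3054),
                          800, 4_440_000).astype(int)
        lengths[0], lengths[1] = 800, 4_440_000
        # rescale interior lengths so the mean is exactly 853 kb
        target_sum = 853_000 * 3054 - lengths[0] - lengths[1]
        interior = lengths[2:]
        interior = np.clip(interior * (target_sum / interior.sum()),
                           800, 4_440_000).astype(int)
        lengths = np.concatenate([lengths[:2], interior])
        path = tmp_path / "tads.bed"
        with open(path, "w") as fh:
            cursor = 0
            for ln in lengths:
                fh.write(f"chr1\t{cursor}\t{cursor + ln}\n")
                cursor += int(ln) + 1000
        tads, report = read_tads(str(path))
        s = tads.summary()
        assert s["n"] == 3054 == report.n_records
        assert s["mean_length"] == pytest.approx(lengths.mean())
        assert s["mean_length"] == pytest.approx(853_000, rel=0.01)
        assert s["min_length"] == 800
        assert s["max_length"] == 4_440_000


class TestReadGenes:
    def test_tsv_and_gtf_dialects_agree(self, tmp_path):
        tsv = tmp_path / "genes.tsv"
        tsv.write_text("gene_id\tsymbol\tchrom\tstart\tend\tstrand\tsynonyms\n"
                       "G1\tSYM1\t1\t1001\t5000\t+\tALT1,ALT2\n")
        gtf = tmp_path / "genes.gtf"
        gtf.write_text('1\tsrc\tgene\t1001\t5000\t.\t+\t.\t'
                       'gene_id "G1"; gene_name "SYM1"; '
                       'gene_synonym "ALT1"; gene_synonym "ALT2";\n')
        a = read_genes(str(tsv)).get("G1")
        b = read_genes(str(gtf)).get("G1")
        assert a == b
        assert a.start == 1000 and a.end == 5000

    def test_duplicate_gene_id_hard_error(self, tmp_path):
        tsv = tmp_path / "genes.tsv"
        tsv.write_text("gene_id\tsymbol\tchrom\tstart\tend\n"
                       "G1\tSYM1\t1\t1\t100\nG1\tSYM1B\t1\t200\t300\n")
        with pytest.raises(IngestError, match="duplicate"):
            read_genes(str(tsv))

    def test_shared_symbol_both_indexed(self, tmp_path):
        tsv = tmp_path / "genes.tsv"
        tsv.write_text("gene_id\tsymbol\tchrom\tstart\tend\n"
                       "G1\tSHARED\t1\t1\t100\nG2\tSHARED\t1\t200\t300\n")
        index = read_genes(str(tsv))
        assert index.by_symbol["SHARED"] == ["G1", "G2"]


class TestGwasCatalog:
    def test_variant_and_gene_indexing(self, tmp_path):
        path = tmp_path / "gwas.tsv"
        path.write_text("rsid\tgene\tphenotype\taccession\n"
                        "rs42\t\tTraitA\tGCST1\n"
                        "\tSYM9\tTraitB\tGCST2\n")
        idx, report = read_gwas_catalog(str(path))
        assert idx.has_variant("rs42") and not idx.has_variant("rs43")
        assert idx.has_gene("SYM9") and not idx.has_gene("SYM1")
        assert report.n_records == 2

    def test_malformed_rows_skipped_with_count(self, tmp_path):
        path = tmp_path / "gwas.tsv"
        rows = ["rs1\t\tT1\tA1\n", "rs2\tG2\tT2\tA2\n", "\tG3\tT3\tA3\n",
                "rs4\t\tT4\tA4\n", "\t\tT5\tA5\n"]
        path.write_text("rsid\tgene\tphenotype\taccession\n" + "".join(rows))
        idx, report = read_gwas_catalog(str(path))
        assert report.n_records == 4 and report.n_rejected == 1

    def test_catalog_download_dialect(self, tmp_path):
        path = tmp_path / "gwas.tsv"
        path.write_text("SNPS\tMAPPED_GENE\tDISEASE/TRAIT\tSTUDY ACCESSION\n"
                        "rs2306374\tMRAS\tCoronary artery disease\tGCST000998\n")
        idx, _ = read_gwas_catalog(str(path))
        assert idx.has_variant("rs2306374") and idx.has_gene("MRAS")


class TestStoreRoundtrip:
    def test_ingestion_idempotent_bitwise(self, bundle, tmp_path):
        """Re-reading the same files yields a bitwise-identical export."""
        gene_index = read_genes(str(bundle.genes))
        store1 = ingest_manifest(str(bundle.manifest), gene_index)
        out1 = tmp_path / "a.tsv"
        write_store_tsv(store1, str(out1))
        store2 = read_store_tsv(str(out1), gene_index)
        out2 = tmp_path / "b.tsv"
        write_store_tsv(store2, str(out2))
        assert out1.read_bytes() == out2.read_bytes()
        store3 = ingest_manifest(str(bundle.manifest), gene_index)
        out3 = tmp_path / "c.tsv"
        write_store_tsv(store3, str(out3))
        assert out1.read_bytes() == out3.read_bytes()

    def test_row_accounting_reconciles(self, bundle):
        gene_index = read_genes(str(bundle.genes))
        store = ingest_manifest(str(bundle.manifest), gene_index)
        for rep in store.reports:
            rep.check()
            assert rep.n_records == rep.n_rows - rep.n_rejected \
                - rep.n_duplicates

    def test_mixed_builds_rejected(self):
        from qtlannot.core import QtlRecord, StudyKey, VariantKey

        g = make_gene()
        recs = [QtlRecord(variant=VariantKey(rsid="rs1", build=b), gene=g,
                          study=StudyKey(source="S", study="S", tissue="T"),
                          p_value=0.5) for b in ("hg19", "hg38")]
        with pytest.raises(IngestError, match="build"):
            QtlStore(records=recs)
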