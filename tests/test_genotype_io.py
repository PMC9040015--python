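"""Conversion of VCF/PLINK/HapMap/numeric inputs into the file-backed store."""

import json

import numpy as np
import pandas as pd
import pytest

from gwaskit import genotype_io as gio
from gwaskit.genotype_io import (
    GenotypeIOError, GenotypeStore, align_samples, convert, load_phenotype,
    marker_stats,
)

VCF_TEXT = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4
1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\t./.
1\t200\trs2\tC\tT\t.\t.\t.\tGT\t0/1\t0/1\t0/0\t./1
2\t50\trs3\tG\tA\t.\t.\t.\tGT\t1/1\t1/1\t1/1\t1/1
2\t80\trs4\tT\tA,C\t.\t.\t.\tGT\t0/1\t0/0\t0/2\t0/0
"""


@pytest.fixture
def vcf_store(tmp_path):
    vcf = tmp_path / "toy.vcf"
    vcf.write_text(VCF_TEXT)
    with pytest.warns(UserWarning, match="multiallelic"):
        store = convert(vcf, "vcf", tmp_path / "store")
    return store


class TestVCF:
    def test_gt_additive_coding(self, vcf_store):
        # 0/0, 0/1, 1/1 code as 0, 1, 2 copies of the alternate allele
        np.testing.assert_array_equal(vcf_store.dosage_row(0)[:3], [0, 1, 2])

    def test_fully_missing_genotype(self, vcf_store):
        assert np.isnan(vcf_store.dosage_row(0)[3])

    def test_half_missing_treated_missing(self, vcf_store):
        assert np.isnan(vcf_store.dosage_row(1)[3])

    def test_multiallelic_skipped_and_counted(self, vcf_store):
        assert vcf_store.n_markers == 3
        assert vcf_store.meta["skipped_multiallelic"] == 1

    def test_marker_map_populated(self, vcf_store):
        mk = vcf_store.markers
        assert list(mk["snp_id"]) == ["rs1", "rs2", "rs3"]
        assert list(mk["pos"]) == [100, 200, 50]
        assert list(mk["chrom"]) == ["1", "1", "2"]

    def test_conversion_idempotent(self, tmp_path, vcf_store):
        vcf = tmp_path / "toy.vcf"
        with pytest.warns(UserWarning):
            convert(vcf, "vcf", tmp_path / "store2")
        b1 = (vcf_store.path / "dosages.bin").read_bytes()
        b2 = (tmp_path / "store2" / "dosages.bin").read_bytes()
        assert b1 == b2


class TestPlinkBed:
    def test_handwritten_bed_decodes(self, tmp_path):
        # 4 samples, 2 markers, SNP-major. Genotypes (A1 dosage):
        #   m1: 2, 1, 0, missing -> codes 00, 10, 11, 01 -> byte 01_11_10_00
        #   m2: 0, 0, 2, 1       -> codes 11, 11, 00, 10 -> byte 10_00_11_11
        bed = bytes([0x6C, 0x1B, 0x01, 0b01111000, 0b10001111])
        (tmp_path / "toy.bed").write_bytes(bed)
        (tmp_path / "toy.bim").write_text(
            "1\tsnpA\t0\t100\tA\tG\n1\tsnpB\t0\t200\tC\tT\n")
        (tmp_path / "toy.fam").write_text(
            "\n".join(f"f{i} i{i} 0 0 0 -9" for i in range(4)) + "\n")
        store = convert(tmp_path / "toy", "plink_bed", tmp_path / "store")
        row0 = store.dosage_row(0)
        np.testing.assert_array_equal(row0[:3], [2, 1, 0])
        assert np.isnan(row0[3])
        np.testing.assert_array_equal(store.dosage_row(1), [0, 0, 2, 1])
        assert store.samples == ["i0", "i1", "i2", "i3"]

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(b"\x00\x00\x00")
        (tmp_path / "x.bim").write_text("1\ts\t0\t1\tA\tG\n")
        (tmp_path / "x.fam").write_text("f i 0 0 0 -9\n")
        with pytest.raises(GenotypeIOError, match="magic"):
            convert(tmp_path / "x", "plink_bed", tmp_path / "store")

    def test_fam_bed_size_mismatch(self, tmp_path):
        (tmp_path / "x.bed").write_bytes(bytes([0x6C, 0x1B, 0x01, 0, 0, 0]))
        (tmp_path / "x.bim").write_text("1\ts\t0\t1\tA\tG\n")
        (tmp_path / "x.fam").write_text("f i 0 0 0 -9\n")
        with pytest.raises(GenotypeIOError, match="inconsistent"):
            convert(tmp_path / "x", "plink_bed", tmp_path / "store")


class TestHapMap:
    HEADER = ("rs#\talleles\tchrom\tpos\tstrand\tassembly#\tcenter\tprotLSID"
              "\tassayLSID\tpanelLSID\tQCcode")

    def test_two_letter_and_iupac_codes(self, tmp_path):
        text = (f"{self.HEADER}\tS1\tS2\tS3\n"
                "rs1\tA/G\t1\t500\t+\t.\t.\t.\t.\t.\t.\tAA\tAG\tGG\n"
                "rs2\tC/T\t1\t900\t+\t.\t.\t.\t.\t.\t.\tY\tC\tNN\n")
        (tmp_path / "h.hmp.txt").write_text(text)
        store = convert(tmp_path / "h.hmp.txt", "hapmap", tmp_path / "store")
        np.testing.assert_array_equal(store.dosage_row(0), [0, 1, 2])
        row1 = store.dosage_row(1)
        assert row1[0] == 1 and row1[1] == 0 and np.isnan(row1[2])

    def test_malformed_header_errors(self, tmp_path):
        (tmp_path / "bad.txt").write_text("id\talleles\tchr\tbp\tS1\nr\tA/G\t1\t5\tAA\n")
        with pytest.raises(GenotypeIOError, match="header"):
            convert(tmp_path / "bad.txt", "hapmap", tmp_path / "store")


class TestNumeric:
    def test_round_trip_identity(self, tmp_path):
        mat = np.array([[0, 1, 2, 1], [2, 2, 0, 0], [1, 0, 1, 2]])
        path = tmp_path / "geno.tsv"
        pd.DataFrame(mat, columns=["a", "b", "c", "d"]).to_csv(
            path, sep="\t", index=False)
        store = convert(path, "numeric", tmp_path / "store")
        np.testing.assert_array_equal(store.dosage_block(0, 3), mat)
        assert store.samples == ["a", "b", "c", "d"]

    def test_fractional_dosage_float_store(self, tmp_path):
        pd.DataFrame([[0.1, 0.3, 0.6]], columns=["a", "b", "c"]).to_csv(
            tmp_path / "g.csv", index=False)
        store = convert(tmp_path / "g.csv", "numeric", tmp_path / "store")
        assert store.dtype == np.float32
        np.testing.assert_allclose(store.dosage_row(0), [0.1, 0.3, 0.6],
                                   atol=1e-6)

    def test_out_of_range_rejected(self, tmp_path):
        pd.DataFrame([[0, 3]], columns=["a", "b"]).to_csv(
            tmp_path / "g.csv", index=False)
        with pytest.raises(GenotypeIOError, match=r"\[0, 2\]"):
            convert(tmp_path / "g.csv", "numeric", tmp_path / "store")

    def test_unknown_format(self, tmp_path):
        with pytest.raises(GenotypeIOError, match="unknown"):
            convert(tmp_path, "bimbam", tmp_path / "store")


def test_vcf_numeric_equivalence(tmp_path, vcf_store):
    """The same cohort coded as VCF and as a numeric matrix gives identical dosages."""
    mat = pd.DataFrame(
        np.nan_to_num(vcf_store.dosage_block(0, 3), nan=1.0).astype(int),
        columns=vcf_store.samples)
    # re-insert the missing entries as NaN is not expressible in the numeric
    # dialect, so compare on the complete markers only
    mat = mat.iloc[[2]]
    mat.to_csv(tmp_path / "g.tsv", sep="\t", index=False)
    store2 = convert(tmp_path / "g.tsv", "numeric", tmp_path / "store_num")
    np.testing.assert_array_equal(store2.dosage_row(0), vcf_store.dosage_row(2))


class TestAlignSamples:
    @pytest.fixture
    def store3(self, tmp_path):
        pd.DataFrame(np.zeros((2, 3), dtype=int), columns=["A", "B", "C"]).to_csv(
            tmp_path / "g.tsv", sep="\t", index=False)
        return convert(tmp_path / "g.tsv", "numeric", tmp_path / "store")

    def test_intersection_preserves_store_order(self, store3):
        pheno = pd.DataFrame({"id": ["C", "A"], "t": [1.0, 2.0]})
        al = align_samples(store3, pheno)
        np.testing.assert_array_equal(al.sample_index, [0, 2])
        np.testing.assert_array_equal(al.y, [2.0, 1.0])

    def test_identity(self, store3):
        pheno = pd.DataFrame({"id": ["A", "B", "C"], "t": [1.0, 2.0, 3.0]})
        al = align_samples(store3, pheno)
        np.testing.assert_array_equal(al.sample_index, [0, 1, 2])

    def test_missing_trait_dropped_and_counted(self, store3):
        pheno = pd.DataFrame({"id": ["A", "B", "C"], "t": [1.0, np.nan, 3.0]})
        al = align_samples(store3, pheno)
        np.testing.assert_array_equal(al.sample_index, [0, 2])
        assert al.n_dropped_missing == 1

    def test_empty_intersection(self, store3):
        pheno = pd.DataFrame({"id": ["X", "Y"], "t": [1.0, 2.0]})
        with pytest.raises(GenotypeIOError, match="overlapping"):
            align_samples(store3, pheno)


class TestMarkerStats:
    def make(self, tmp_path, rows):
        df = pd.DataFrame(rows, columns=list("abcd"), dtype=float)
        df.to_csv(tmp_path / "g.tsv", sep="\t", index=False)
        return convert(tmp_path / "g.tsv", "numeric", tmp_path / "store")

    def test_half_frequency(self, tmp_path):
        st = self.make(tmp_path, [[0, 0, 2, 2]])
        stats = marker_stats(st)
        assert stats.loc[0, "maf"] == 0.5
        assert not stats.loc[0, "monomorphic"]

    def test_monomorphic_flag(self, tmp_path):
        st = self.make(tmp_path, [[2, 2, 2, 2]])
        assert bool(marker_stats(st).loc[0, "monomorphic"])

    def test_missing_excluded_from_maf(self, tmp_path):
        st = self.make(tmp_path, [[0, 1, 2, np.nan]])
        stats = marker_stats(st)
        assert stats.loc[0, "maf"] == 0.5
        assert stats.loc[0, "missing_rate"] == 0.25


def test_single_row_read_is_O_n(small_store):
    """Reading one marker row must not materialize the full matrix."""
    import tracemalloc
    store, *_ = small_store
    store.dosage_row(0)  # warm caches
    tracemalloc.start()
    for i in range(0, store.n_markers, 50):
        store.dosage_row(i)
    _, peak = tracemalloc.get_traced_memory()
    tracemalloc.stop()
    # a handful of O(n_samples) buffers, far below the full m x n matrix
    assert peak < 50 * store.n_samples * 8


def test_store_reopen_identical(small_store):
    store, *_ = small_store
    again = GenotypeStore(store.path)
    np.testing.assert_array_equal(
        store.dosage_block(0, 50), again.dosage_block(0, 50))
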