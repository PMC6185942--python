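"""Genotype encoding and PLINK-text / TSV round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairscan import (
    GenotypeMatrix,
    encode_genotypes,
    read_matrix_tsv,
    read_plink_text,
    write_matrix_tsv,
    write_plink_text,
)
from pairscan.genotype_io import GenotypeIOError, MultiAllelicError


class TestEncoding:
    def test_encoding_scheme(self):
        codes, (major, minor) = encode_genotypes(
            [("A", "A"), ("A", "G"), ("G", "G"), ("0", "0")]
        )
        assert codes.tolist() == [1, 2, 3, 0]
        assert (major, minor) == ("A", "G")

    def test_all_missing_flags_alleles_undefined(self):
        codes, alleles = encode_genotypes([("0", "0"), ("0", "0")])
        assert codes.tolist() == [0, 0]
        assert alleles is None

    def test_tie_breaks_lexicographically(self):
        codes, (major, minor) = encode_genotypes([("A", "A"), ("G", "G")])
        assert (major, minor) == ("A", "G")
        assert codes.tolist() == [1, 3]

    def test_half_missing_call_is_missing(self):
        codes, _ = encode_genotypes([("A", "0"), ("A", "A")])
        assert codes.tolist() == [0, 1]

    def test_monomorphic_gets_placeholder_minor(self):
        codes, (major, minor) = encode_genotypes([("T", "T"), ("T", "T")])
        assert codes.tolist() == [1, 1]
        assert major == "T" and minor == "."

    def test_multiallelic_rejected(self):
        with pytest.raises(MultiAllelicError):
            encode_genotypes([("A", "C"), ("G", "G")])

    @given(
        st.lists(
            st.tuples(st.sampled_from("AG0"), st.sampled_from("AG0")),
            min_size=1,
            max_size=30,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_major_homozygote_at_least_as_common(self, calls):
        codes, _ = encode_genotypes(calls)
        # major-allele definition: allele 'major' count >= 'minor' count
        n_major = 2 * (codes == 1).sum() + (codes == 2).sum()
        n_minor = 2 * (codes == 3).sum() + (codes == 2).sum()
        assert n_major >= n_minor


class TestPlinkText:
    PED = (
        "FAM1 S1 0 0 0 2 A A A G\n"
        "FAM2 S2 0 0 0 1 A G G G\n"
    )
    MAP = "1 rs1 0 1000\n1 rs2 0 2000\n"

    def _write(self, tmp_path, ped=PED, map_=MAP):
        (tmp_path / "d.ped").write_text(ped)
        (tmp_path / "d.map").write_text(map_)
        return tmp_path / "d.ped", tmp_path / "d.map"

    def test_toy_fixture_encodes_as_expected(self, tmp_path):
        # hand-encoded: rs1 has alleles A,A / A,G -> major A: codes 1, 2;
        # rs2 has A,G / G,G -> major G: codes 2, 1
        mat = read_plink_text(*self._write(tmp_path))
        assert mat.genotypes.tolist() == [[1, 2], [2, 1]]
        assert mat.phenotype.tolist() == [True, False]
        assert mat.snp_ids == ["rs1", "rs2"]
        assert mat.snp_loci == [("1", 1000), ("1", 2000)]
        assert mat.alleles == [("A", "G"), ("G", "A")]

    def test_unknown_phenotype_dropped(self, tmp_path):
        ped = self.PED + "FAM3 S3 0 0 0 0 A A A A\n"
        mat = read_plink_text(*self._write(tmp_path, ped=ped))
        assert mat.sample_ids == ["S1", "S2"]

    def test_empty_map_errors(self, tmp_path):
        with pytest.raises(GenotypeIOError):
            read_plink_text(*self._write(tmp_path, map_=""))

    def test_malformed_line_names_line_number(self, tmp_path):
        ped = self.PED + "FAM3 S3 0 0 0 2 A A\n"
        with pytest.raises(GenotypeIOError, match="line 3"):
            read_plink_text(*self._write(tmp_path, ped=ped))

    def test_multiallelic_snp_dropped_with_diagnostic(self, tmp_path, caplog):
        ped = "FAM1 S1 0 0 0 2 A C A G\nFAM2 S2 0 0 0 1 G T G G\n"
        with caplog.at_level("WARNING"):
            mat = read_plink_text(*self._write(tmp_path, ped=ped))
        assert mat.snp_ids == ["rs2"]
        assert "rs1" in caplog.text

    def test_roundtrip_preserves_calls(self, tmp_path, rng):
        geno = rng.integers(0, 4, size=(20, 5)).astype(np.uint8)
        geno[:, 2] = [1] * 12 + [2, 2, 2, 2, 3, 3, 3, 3]  # clear major allele
        mat = GenotypeMatrix(
            genotypes=geno,
            phenotype=np.arange(20) < 10,
            snp_ids=[f"rs{j}" for j in range(5)],
            sample_ids=[f"S{s}" for s in range(20)],
            snp_loci=[("2", 100 * (j + 1)) for j in range(5)],
            alleles=[("A", "G")] * 5,
        )
        write_plink_text(mat, tmp_path / "o.ped", tmp_path / "o.map")
        back = read_plink_text(tmp_path / "o.ped", tmp_path / "o.map")
        # encode/decode round trip preserves non-missing calls up to
        # major/minor relabelling (codes 1 and 3 may swap per column)
        for j in range(5):
            a, b = mat.genotypes[:, j], back.genotypes[:, j]
            assert ((a == 0) == (b == 0)).all()
            assert ((a == 2) == (b == 2)).all()
            flipped = {1: 3, 2: 2, 3: 1, 0: 0}
            assert b.tolist() == a.tolist() or b.tolist() == [flipped[v] for v in a]


class TestMatrixTsv:
    def _table1_like(self, tmp_path):
        # 4-sample layout: one case then three controls over 3 SNPs
        text = (
            "Sample\tSNP_1\tSNP_2\tSNP_3\tStatus\n"
            "Sample_1\t1\t1\t1\tT\n"
            "Sample_2\t2\t1\t2\tF\n"
            "Sample_3\t3\t2\t2\tF\n"
            "Sample_4\t3\t2\t2\tF\n"
        )
        path = tmp_path / "m.tsv"
        path.write_text(text)
        return path, text

    def test_table_layout_roundtrips_bit_exactly(self, tmp_path):
        path, text = self._table1_like(tmp_path)
        mat = read_matrix_tsv(path)
        assert mat.genotypes.tolist() == [[1, 1, 1], [2, 1, 2], [3, 2, 2], [3, 2, 2]]
        assert mat.phenotype.tolist() == [True, False, False, False]
        out = tmp_path / "back.tsv"
        write_matrix_tsv(mat, out)
        assert out.read_text() == text

    def test_single_cell_matrix(self, tmp_path):
        path = tmp_path / "one.tsv"
        path.write_text("Sample\trs1\tStatus\nS1\t2\tcase\n")
        mat = read_matrix_tsv(path)
        assert mat.genotypes.shape == (1, 1)
        assert mat.phenotype.tolist() == [True]

    def test_bad_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("Sample\trs1\trs2\tStatus\nS1\t1\t4\tF\n")
        with pytest.raises(GenotypeIOError, match="row 1.*column 2"):
            read_matrix_tsv(path)

    def test_status_spellings(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text(
            "Sample\trs1\tStatus\nS1\t1\tT\nS2\t1\t0\nS3\t2\tcase\nS4\t3\tcontrol\n"
        )
        assert read_matrix_tsv(path).phenotype.tolist() == [True, False, True, False]

    def test_missing_status_column_errors(self, tmp_path):
        path = tmp_path / "ns.tsv"
        path.write_text("Sample\trs1\trs2\nS1\t1\t2\n")
        with pytest.raises(GenotypeIOError):
            read_matrix_tsv(path)
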