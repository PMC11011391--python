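import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from multisurv import formats
from multisurv.formats import (
    CnvSegment,
    FeatureMatrix,
    FormatError,
    GeneSetCollection,
    VariantRecord,
)
from tests.conftest import make_variant


class TestVariantRecord:
    def test_rejects_identical_alleles(self):
        with pytest.raises(ValueError, match="identical"):
            make_variant(ref="C", alt="C")

    @pytest.mark.parametrize("ref,alt", [("N", "A"), ("A", "N"), ("", "A"), ("A", "")])
    def test_rejects_non_acgt_alleles(self, ref, alt):
        with pytest.raises(ValueError):
            VariantRecord(sample_id="s", chrom="c", pos=1, ref=ref, alt=alt)

    def test_rejects_nonpositive_position(self):
        with pytest.raises(ValueError, match="pos"):
            make_variant(pos=0)


class TestMaf:
    def test_reads_maf_columns(self, tmp_path):
        p = tmp_path / "x.maf"
        p.write_text(
            "Tumor_Sample_Barcode\tChromosome\tStart_Position\tReference_Allele\t"
            "Tumor_Seq_Allele2\n"
            "S1\tchr1\t100\tC\tT\n"
            "S2\tchr2\t5\tA\tG\n"
        )
        recs = formats.read_maf(p)
        assert len(recs) == 2
        assert recs[0].sample_id == "S1" and recs[0].pos == 100
        assert recs[1].effect.value == "other"  # no classification column

    def test_missing_column_names_the_column(self, tmp_path):
        p = tmp_path / "x.maf"
        p.write_text("Tumor_Sample_Barcode\tChromosome\tStart_Position\tReference_Allele\n"
                     "S1\tchr1\t100\tC\n")
        with pytest.raises(FormatError, match="alt"):
            formats.read_maf(p)

    def test_bad_allele_reports_line_number(self, tmp_path):
        p = tmp_path / "x.maf"
        p.write_text(
            "sample\tchrom\tpos\tref\talt\nS1\tchr1\t100\tN\tT\n")
        with pytest.raises(FormatError, match="line 2"):
            formats.read_maf(p)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(
        st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT"),
                  st.integers(1, 10_000), st.sampled_from(["Missense_Mutation", "Silent", ""]))
        .filter(lambda t: t[0] != t[1]),
        min_size=1, max_size=20))
    def test_roundtrip_preserves_fields(self, tmp_path_factory, rows):
        recs = [make_variant(ref=r, alt=a, pos=p, sample=f"S{i}", classification=c)
                for i, (r, a, p, c) in enumerate(rows)]
        path = tmp_path_factory.mktemp("maf") / "rt.maf"
        formats.write_maf(recs, path)
        assert formats.read_maf(path) == recs


class TestSeg:
    def test_single_row(self, tmp_path):
        p = tmp_path / "x.seg"
        p.write_text("ID\tchrom\tloc.start\tloc.end\tseg.mean\nS1\tchr1\t100\t200\t0.5\n")
        segs = formats.read_seg(p)
        assert segs == [CnvSegment("S1", "chr1", 100, 200, 0.5)]

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "x.seg"
        p.write_text("ID\tchrom\tloc.start\tloc.end\tseg.mean\nS1\tchr1\t300\t200\t0.5\n")
        with pytest.raises(FormatError, match="line 2"):
            formats.read_seg(p)

    def test_non_numeric_mean_reports_line(self, tmp_path):
        p = tmp_path / "x.seg"
        p.write_text("ID\tchrom\tloc.start\tloc.end\tseg.mean\n"
                     "S1\tchr1\t100\t200\t0.5\nS2\tchr1\t1\t2\thigh\n")
        with pytest.raises(FormatError, match="line 3"):
            formats.read_seg(p)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.tuples(st.integers(1, 1000), st.integers(0, 500),
                              st.floats(-3, 3, allow_nan=False)), min_size=1, max_size=10))
    def test_roundtrip(self, tmp_path_factory, rows):
        segs = [CnvSegment(f"S{i}", "chr1", a, a + w, m) for i, (a, w, m) in enumerate(rows)]
        path = tmp_path_factory.mktemp("seg") / "rt.seg"
        formats.write_seg(segs, path)
        assert formats.read_seg(path) == segs


class TestGmt:
    def test_basic_set(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("SETA\tdesc\tEGFR\tKRAS\n")
        gs = formats.read_gmt(p)
        assert gs["SETA"] == ["EGFR", "KRAS"]

    def test_duplicate_gene_collapses(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("SETA\tdesc\tEGFR\tEGFR\tKRAS\n")
        assert formats.read_gmt(p)["SETA"] == ["EGFR", "KRAS"]

    def test_two_sets_order_preserved(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("B\td\tX\nA\td\tY\n")
        assert list(formats.read_gmt(p)) == ["B", "A"]

    def test_short_line_errors(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("SETA\tdesc\n")
        with pytest.raises(FormatError, match="line 1"):
            formats.read_gmt(p)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            GeneSetCollection({"S": []})


class TestBed:
    def test_coordinates_converted_to_one_based(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t49\t149\tEGFR\n")
        (m,) = formats.read_bed_genes(p)
        assert (m.start, m.end) == (50, 149)

    def test_roundtrip(self, tmp_path, gene_models):
        p = tmp_path / "g.bed"
        formats.write_bed_genes(gene_models, p)
        assert formats.read_bed_genes(p) == gene_models


class TestFeatureMatrix:
    def test_duplicate_feature_ids_rejected(self):
        df = pd.DataFrame(np.zeros((2, 2)), columns=["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureMatrix(df, "mrna", "raw")

    def test_tsv_roundtrip_with_provenance(self, tmp_path, feature_matrix):
        p, s = tmp_path / "m.tsv", tmp_path / "m.prov.tsv"
        feature_matrix.to_tsv(p, s)
        back = FeatureMatrix.from_tsv(p, s)
        pd.testing.assert_frame_equal(back.values, feature_matrix.values)
        pd.testing.assert_frame_equal(back.provenance, feature_matrix.provenance)

    def test_concat_aligns_on_shared_samples(self, feature_matrix):
        other = FeatureMatrix(
            feature_matrix.values.iloc[:5].rename(columns=lambda c: c + "_cn"),
            omics="cnv", method="gene")
        combined = FeatureMatrix.concat([feature_matrix, other])
        assert combined.shape == (5, 8)
        assert set(combined.provenance["omics"]) == {"mrna", "cnv"}

    def test_missing_values_propagate(self, tmp_path, feature_matrix):
        feature_matrix.values.iloc[0, 0] = np.nan
        p = tmp_path / "m.tsv"
        feature_matrix.to_tsv(p)
        back = FeatureMatrix.from_tsv(p)
        assert np.isnan(back.values.iloc[0, 0])


class TestClinical:
    def test_roundtrip(self, tmp_path):
        from tests.conftest import make_clinical

        recs = [make_clinical("S1", 500, True, True), make_clinical("S2", 900, False)]
        p = tmp_path / "c.tsv"
        formats.write_clinical(recs, p)
        assert formats.read_clinical(p) == recs

    def test_negative_days_reports_line(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("sample_id\tdays_to_last_contact_or_death\tvital_status\n"
                     "S1\t-3\talive\n")
        with pytest.raises(FormatError, match="line 2"):
            formats.read_clinical(p)
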