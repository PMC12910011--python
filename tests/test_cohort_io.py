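"""Cohort file readers/writers: schema validation, missing-value
policy, coordinate conventions, and round-trip stability."""

import random

import pytest

from geneburden.cohort_io import (
    RegionMask,
    RowError,
    SchemaError,
    apply_region_mask,
    ingest_vcf,
    is_x_nonpar,
    read_cnv_table,
    read_region_bed,
    read_sample_manifest,
    read_variant_table,
    write_cnv_table,
    write_sample_manifest,
    write_variant_table,
)

from conftest import make_sample, make_variant


SAMPLES_TSV = """\
sample_id\tsex\tgroup\tassay\tage_at_testing\tsubgroup\thpo_terms
P1\tmale\tcase\tES\t34\tataxia\tHP:0000001;HP:0000002
P2\tFemale\tControl\tgs\t\t\t
"""


class TestSampleManifest:
    def test_two_row_fixture(self, tmp_path):
        path = tmp_path / "samples.tsv"
        path.write_text(SAMPLES_TSV)
        records = read_sample_manifest(path)
        assert len(records) == 2
        assert records[0].hpo_terms == ("HP:0000001", "HP:0000002")
        assert records[1].hpo_terms == ()
        assert records[1].age_at_testing is None

    def test_mixed_case_vocabulary_normalized(self, tmp_path):
        path = tmp_path / "samples.tsv"
        path.write_text(SAMPLES_TSV)
        records = read_sample_manifest(path)
        assert records[1].sex == "female"
        assert records[1].group == "control"
        assert records[1].assay == "GS"

    def test_duplicate_sample_id_rejected(self, tmp_path):
        path = tmp_path / "samples.tsv"
        path.write_text(SAMPLES_TSV + "P1\tmale\tcase\tES\t\t\t\n")
        with pytest.raises(RowError, match="duplicate"):
            read_sample_manifest(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "samples.tsv"
        path.write_text("sample_id\tsex\tgroup\nP1\tmale\tcase\n")
        with pytest.raises(SchemaError, match="assay"):
            read_sample_manifest(path)

    def test_unknown_vocabulary_value_carries_row(self, tmp_path):
        path = tmp_path / "samples.tsv"
        path.write_text(
            SAMPLES_TSV + "P3\tmale\tpatient\tES\t\t\t\n"
        )
        with pytest.raises(RowError, match="row 4"):
            read_sample_manifest(path)

    def test_round_trip(self, tmp_path):
        records = [
            make_sample("P1", age_at_testing=34.0, subgroup="ataxia",
                        hpo_terms=("HP:0000001",)),
            make_sample("P2", group="control", sex="female", assay="GS"),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sample_manifest(records, p1)
        again = read_sample_manifest(p1)
        assert again == records
        write_sample_manifest(again, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestVariantTable:
    def test_missing_maf_and_cadd_parse_as_missing(self, tmp_path):
        path = tmp_path / "variants.tsv"
        write_variant_table([make_variant("P1")], path)
        (v,) = read_variant_table(path)
        assert v.maf is None and v.cadd is None

    def test_hemi_on_autosome_rejected(self):
        with pytest.raises(RowError, match="hemi"):
            make_variant("P1", chrom="2", genotype="hemi")

    def test_hemi_for_female_rejected(self, tmp_path):
        path = tmp_path / "variants.tsv"
        write_variant_table(
            [make_variant("P1", chrom="X", genotype="hemi")], path
        )
        samples = [make_sample("P1", sex="female")]
        with pytest.raises(RowError, match="female"):
            read_variant_table(path, samples)

    def test_five_row_round_trip(self, tmp_path):
        variants = [
            make_variant("P1", maf=0.0005, cadd=25.5),
            make_variant("P2", gene="GENE2", consequence="missense_variant",
                         impact="moderate", cadd=31.0),
            make_variant("P3", chrom="X", pos=150_000_000, genotype="hemi"),
            make_variant("P4", genotype="hom", maf=0.001),
            make_variant("P5", quality_pass=False),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_variant_table(variants, p1)
        again = read_variant_table(p1)
        assert again == variants
        write_variant_table(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_maf_outside_unit_interval_rejected(self):
        with pytest.raises(RowError, match="MAF"):
            make_variant("P1", maf=1.5)


class TestCnvTable:
    def test_round_trip(self, tmp_path):
        from geneburden.cohort_io import CnvCall

        cnvs = [
            CnvCall("P1", "X", 1000, 2000, ("GENE1",), 0, 20.0, 0.95, "ES"),
            CnvCall("P2", "2", 5, 50, ("GENE2", "GENE3"), 1, 3.5, 0.6,
                    "GS", True, 0.02),
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_cnv_table(cnvs, p1)
        again = read_cnv_table(p1)
        assert again == cnvs
        write_cnv_table(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_inverted_interval_rejected(self, tmp_path):
        path = tmp_path / "cnvs.tsv"
        path.write_text(
            "sample_id\tchrom\tstart\tend\tgenes\tcopy_number\t"
            "log_likelihood\treference_correlation\tassay\t"
            "polymorphism_overlap\tinhouse_maf\n"
            "P1\t1\t500\t100\tG\t0\t20\t0.9\tES\tfalse\t\n"
        )
        with pytest.raises(RowError, match="row 2"):
            read_cnv_table(path)


class TestRegionMask:
    def test_overlapping_intervals_merged(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("1\t10\t20\n1\t15\t30\n")
        mask = read_region_bed(bed)
        assert mask.intervals["1"].tolist() == [[10, 30]]

    def test_empty_bed_disables_mask(self, tmp_path):
        bed = tmp_path / "mask.bed"
        bed.write_text("")
        mask = read_region_bed(bed)
        assert not mask
        variants = [make_variant("P1", pos=5)]
        assert apply_region_mask(variants, mask) == variants

    def test_total_length_matches_integer_union(self, tmp_path):
        intervals = [(10, 20), (15, 30), (30, 35), (100, 101), (98, 100),
                     (200, 260)]
        bed = tmp_path / "mask.bed"
        bed.write_text("".join(f"7\t{s}\t{e}\n" for s, e in intervals))
        mask = read_region_bed(bed)
        union = set()
        for s, e in intervals:
            union |= set(range(s, e))
        assert mask.total_length() == len(union)
        for pos in range(0, 300):
            assert mask.contains("7", pos) == (pos in union)

    def test_boundary_half_open_semantics(self):
        mask = RegionMask({"1": [(9, 10)]})
        kept = apply_region_mask([make_variant("P1", pos=10)], mask)
        assert len(kept) == 1  # pos 10 -> 0-based 9, inside [9,10)
        mask2 = RegionMask({"1": [(10, 20)]})
        kept2 = apply_region_mask([make_variant("P1", pos=10)], mask2)
        assert kept2 == []  # 0-based 9 not in [10,20)

    def test_mask_matches_membership_oracle_and_idempotent(self):
        rng = random.Random(99)
        intervals = sorted(
            (s := rng.randrange(0, 5000), s + rng.randrange(1, 300))
            for _ in range(12)
        )
        mask = RegionMask({"3": intervals})
        union = set()
        for s, e in intervals:
            union |= set(range(s, e))
        variants = [
            make_variant(f"P{i}", chrom="3", pos=rng.randrange(1, 6000))
            for i in range(100)
        ]
        kept = apply_region_mask(variants, mask)
        expected = [v for v in variants if (v.pos - 1) in union]
        assert kept == expected
        assert apply_region_mask(kept, mask) == kept  # idempotent


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=A,Type=String,Description="gene">
##INFO=<ID=CSQ_CONSEQUENCE,Number=A,Type=String,Description="csq">
##INFO=<ID=IMPACT,Number=A,Type=String,Description="impact">
##INFO=<ID=CADD,Number=A,Type=Float,Description="cadd">
##INFO=<ID=GNOMAD_AF,Number=A,Type=Float,Description="af">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1>
##contig=<ID=chrX>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


class TestVcfIngestion:
    def _write(self, tmp_path, body):
        path = tmp_path / "sample.vcf"
        path.write_text(VCF_HEADER + body)
        return path

    def test_male_x_nonpar_hom_becomes_hemi(self, tmp_path):
        body = (
            "chrX\t150000000\t.\tA\tT\t50\tPASS\t"
            "GENE=XLGENE1;CSQ_CONSEQUENCE=stop_gained;IMPACT=HIGH;"
            "CADD=35;GNOMAD_AF=0.0001\tGT\t1/1\n"
        )
        (v,) = ingest_vcf(self._write(tmp_path, body), "S1", sex="male")
        assert v.genotype == "hemi"
        assert v.gene == "XLGENE1"
        assert v.impact == "high"

    def test_autosomal_het(self, tmp_path):
        body = (
            "1\t1000\t.\tA\tT\t50\tPASS\t"
            "GENE=G1;CSQ_CONSEQUENCE=missense_variant;IMPACT=MODERATE;"
            "CADD=22.5;GNOMAD_AF=0.001\tGT\t0/1\n"
        )
        (v,) = ingest_vcf(self._write(tmp_path, body), "S1", sex="male")
        assert v.genotype == "het"
        assert v.cadd == pytest.approx(22.5)
        assert v.maf == pytest.approx(0.001)

    def test_par_hom_stays_hom(self, tmp_path):
        assert not is_x_nonpar("chrX", 1_000_000)
        body = (
            "chrX\t1000000\t.\tA\tT\t50\tPASS\t"
            "GENE=G1;CSQ_CONSEQUENCE=stop_gained;IMPACT=HIGH\tGT\t1/1\n"
        )
        (v,) = ingest_vcf(self._write(tmp_path, body), "S1", sex="male")
        assert v.genotype == "hom"

    def test_multiallelic_split_yields_four_rows(self, tmp_path):
        body = (
            "1\t1000\t.\tA\tT\t50\tPASS\t"
            "GENE=G1;CSQ_CONSEQUENCE=stop_gained;IMPACT=HIGH\tGT\t0/1\n"
            "1\t2000\t.\tA\tT,G\t50\tPASS\t"
            "GENE=G1,G1;CSQ_CONSEQUENCE=stop_gained,missense_variant;"
            "IMPACT=HIGH,MODERATE\tGT\t1/2\n"
            "1\t3000\t.\tC\tG\t50\tPASS\t"
            "GENE=G2;CSQ_CONSEQUENCE=missense_variant;IMPACT=MODERATE\t"
            "GT\t1/1\n"
        )
        variants = ingest_vcf(self._write(tmp_path, body), "S1")
        assert len(variants) == 4
        multi = [v for v in variants if v.pos == 2000]
        assert {v.alt for v in multi} == {"T", "G"}
        assert {v.consequence for v in multi} == {
            "stop_gained",
            "missense_variant",
        }

    def test_missing_gt_skipped(self, tmp_path):
        body = (
            "1\t1000\t.\tA\tT\t50\tPASS\t"
            "GENE=G1;CSQ_CONSEQUENCE=stop_gained;IMPACT=HIGH\tGT\t./.\n"
        )
        assert ingest_vcf(self._write(tmp_path, body), "S1") == []

    def test_filter_fail_sets_quality_flag(self, tmp_path):
        body = (
            "1\t1000\t.\tA\tT\t50\tq10\t"
            "GENE=G1;CSQ_CONSEQUENCE=stop_gained;IMPACT=HIGH\tGT\t0/1\n"
        )
        (v,) = ingest_vcf(self._write(tmp_path, body), "S1")
        assert v.quality_pass is False

    def test_round_trip_from_variant_list(self, tmp_path):
        """A VCF synthesized from SmallVariant records is recovered."""
        originals = [
            make_variant("S1", chrom="1", pos=1000, maf=0.0005, cadd=30.0,
                         genotype="het"),
            make_variant("S1", chrom="1", pos=2000, gene="GENE2",
                         consequence="missense_variant", impact="moderate",
                         cadd=25.0, maf=0.002, genotype="hom"),
        ]
        lines = []
        for v in originals:
            gt = {"het": "0/1", "hom": "1/1"}[v.genotype]
            info = (
                f"GENE={v.gene};CSQ_CONSEQUENCE={v.consequence};"
                f"IMPACT={v.impact};CADD={v.cadd};GNOMAD_AF={v.maf}"
            )
            lines.append(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t50\tPASS\t"
                f"{info}\tGT\t{gt}\n"
            )
        ingested = ingest_vcf(
            self._write(tmp_path, "".join(lines)), "S1"
        )
        for orig, got in zip(originals, ingested):
            assert got.gene == orig.gene
            assert got.genotype == orig.genotype
            assert got.maf == pytest.approx(orig.maf, rel=1e-6)
            assert got.cadd == pytest.approx(orig.cadd, rel=1e-6)
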