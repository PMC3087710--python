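import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircnv import (
    GenomicInterval,
    call_cnv_mirnas,
    classify_dosage,
    classify_flanks,
    copy_number_summary,
    dedupe_loci,
    disease_region_overlap,
    minimal_region,
)
from mircnv.annotation import GeneModelSketch, is_multiallelic
from mircnv.io import CnvRegion, MirnaLocus


def region(chrom, start1, end1, **kw):
    return CnvRegion(interval=GenomicInterval(chrom, start1 - 1, end1), **kw)


class TestCallCnvMirnas:
    def test_table1_call_counts(self, all_table1_calls):
        smc, dc = all_table1_calls
        assert len(smc) == 4
        assert len(dc) == 8

    def test_mir650_flanks(self, all_table1_calls):
        _, dc = all_table1_calls
        call = next(c for c in dc if c.locus.id == "mir-650")
        assert call.fully_contained
        assert call.flanks == (784251, 83585)

    def test_no_regions_on_locus_chromosomes(self):
        loci = [MirnaLocus("m", GenomicInterval("chr7", 100, 200))]
        assert call_cnv_mirnas(loci, [region("chr8", 1, 1000)]) == []

    def test_every_table1_locus_fully_contained(self, all_table1_calls):
        smc, dc = all_table1_calls
        assert all(c.fully_contained for c in smc + dc)
        for c in smc + dc:
            assert c.overlap_bp == c.locus.interval.length

    def test_duplicate_locus_rows_collapse_to_one_call(self):
        iv = GenomicInterval("chr1", 100, 200)
        loci = [MirnaLocus("m", iv), MirnaLocus("m", iv)]
        calls = call_cnv_mirnas(loci, [region("chr1", 1, 1000)])
        assert len(calls) == 1

    def test_partial_overlap_call(self):
        loci = [MirnaLocus("m", GenomicInterval("chr1", 90, 110))]
        calls = call_cnv_mirnas(loci, [region("chr1", 1, 100)])
        (c,) = calls
        assert not c.fully_contained
        assert c.overlap_bp == 10
        assert c.flanks is None
        assert c.flank_class == "partial_overlap"

    def test_deterministic_ordering(self, fixtures):
        a = call_cnv_mirnas(fixtures.dc_loci, list(fixtures.dc_regions))
        b = call_cnv_mirnas(list(reversed(fixtures.dc_loci)), list(fixtures.dc_regions))
        assert [c.locus.identity for c in a] == [c.locus.identity for c in b]


class TestDedupeLoci:
    def test_smc_union_dc_is_11(self, all_table1_calls):
        smc, dc = all_table1_calls
        assert len(dedupe_loci(smc + dc)) == 11

    def test_single_set_identity(self, all_table1_calls):
        smc, _ = all_table1_calls
        assert len(dedupe_loci(smc)) == len(smc)

    def test_same_locus_in_three_sets(self):
        loci = [MirnaLocus("m", GenomicInterval("chr1", 100, 200))]
        calls = []
        for label in ("a", "b", "c"):
            calls += call_cnv_mirnas(loci, [region("chr1", 1, 1000)], set_label=label)
        assert len(dedupe_loci(calls)) == 1

    def test_mir1233_two_loci_count_twice(self, all_table1_calls):
        smc, dc = all_table1_calls
        idents = dedupe_loci(smc + dc)
        mir1233 = [t for t in idents if t[0] == "mir-1233"]
        assert len(mir1233) == 2  # two distinct chr15 loci

    def test_dedupe_bounded_by_sum(self, all_table1_calls):
        smc, dc = all_table1_calls
        assert len(dedupe_loci(smc + dc)) <= len(smc) + len(dc)


class TestMinimalRegion:
    def test_three_records_around_locus(self):
        locus = MirnaLocus("m", GenomicInterval("c", 499, 600))
        records = [
            GenomicInterval("c", 99, 900),
            GenomicInterval("c", 399, 1200),
            GenomicInterval("c", 449, 800),
        ]
        iv, n, contains = minimal_region(locus, records)
        assert iv == GenomicInterval("c", 449, 800)
        assert n == 3 and contains
        # brute-force base intersection
        expect = set.intersection(*(set(range(r.start, r.end)) for r in records))
        assert set(range(iv.start, iv.end)) == expect

    def test_single_record(self):
        locus = MirnaLocus("m", GenomicInterval("c", 10, 20))
        iv, n, contains = minimal_region(locus, [GenomicInterval("c", 5, 30)])
        assert iv == GenomicInterval("c", 5, 30) and n == 1 and contains

    def test_records_not_all_containing_locus_flagged(self):
        locus = MirnaLocus("m", GenomicInterval("c", 100, 200))
        records = [GenomicInterval("c", 50, 150), GenomicInterval("c", 120, 300)]
        iv, n, contains = minimal_region(locus, records)
        assert iv == GenomicInterval("c", 120, 150)
        assert not contains

    def test_empty_record_set_errors(self):
        with pytest.raises(ValueError):
            minimal_region(MirnaLocus("m", GenomicInterval("c", 0, 10)), [])

    def test_non_overlapping_record_rejected(self):
        locus = MirnaLocus("m", GenomicInterval("c", 100, 200))
        with pytest.raises(ValueError, match="does not overlap"):
            minimal_region(locus, [GenomicInterval("c", 500, 600)])

    def test_table2_minimal_regions_contain_their_loci(self, fixtures):
        for entry in fixtures.table2:
            assert entry.minimal_region.contains(entry.locus.interval)


class TestCopyNumberSummary:
    def test_table1_range_0_to_6(self, all_table1_calls):
        smc, dc = all_table1_calls
        summ = copy_number_summary(smc + dc)
        assert summ.copy_min == 0
        assert summ.copy_max == 6

    def test_mir384_deletion_not_multiallelic(self):
        assert not is_multiallelic((0, 1, 2))

    def test_paper_multiallelic_examples(self):
        assert is_multiallelic((2, 3, 4, 5, 6))  # mir-1268
        assert is_multiallelic((0, 1, 2, 3))  # mir-1233

    def test_constant_genotype(self):
        call_like = call_cnv_mirnas(
            [MirnaLocus("m", GenomicInterval("c", 100, 200))],
            [region("c", 1, 1000, genotypes=(2,))],
        )
        summ = copy_number_summary(call_like)
        assert summ.copy_min == summ.copy_max == 2
        assert summ.multiallelic_calls == (False,)

    def test_no_genotypes_raises(self):
        calls = call_cnv_mirnas(
            [MirnaLocus("m", GenomicInterval("c", 100, 200))], [region("c", 1, 1000)]
        )
        with pytest.raises(ValueError):
            copy_number_summary(calls)


class TestClassifyFlanks:
    def test_table1_short_both_membership(self, all_table1_calls):
        smc, dc = all_table1_calls
        by_class: dict[str, set[str]] = {}
        for ident in dedupe_loci(smc + dc):
            call = next(c for c in smc + dc if c.locus.identity == ident)
            by_class.setdefault(classify_flanks(call), set()).add(
                (call.locus.id, call.locus.interval.start)
            )
        short = {name for name, _ in by_class["short_both"]}
        assert short == {"mir-384", "mir-1977", "mir-1275"}

    def test_mir1268_large_both(self, all_table1_calls):
        smc, _ = all_table1_calls
        call = next(c for c in smc if c.locus.id == "mir-1268")
        assert call.flanks == (211223, 74742)
        assert classify_flanks(call) == "large_both"

    def test_zero_flanks_are_short_both(self):
        iv = GenomicInterval("c", 100, 200)
        (call,) = call_cnv_mirnas([MirnaLocus("m", iv)], [CnvRegion(interval=iv)])
        assert call.flanks == (0, 0)
        assert classify_flanks(call) == "short_both"

    def test_mir1302_2_left_flank_below_20kb_is_mixed(self, all_table1_calls):
        _, dc = all_table1_calls
        call = next(c for c in dc if c.locus.id == "mir-1302-2")
        assert call.flanks[0] == 19659
        assert classify_flanks(call) == "mixed"

    def test_threshold_boundaries(self):
        loci = [MirnaLocus("m", GenomicInterval("c", 20_000, 20_100))]
        (call,) = call_cnv_mirnas(loci, [region("c", 1, 40_100)])
        assert call.flanks == (20_000, 20_000)
        assert classify_flanks(call) == "large_both"
        (call2,) = call_cnv_mirnas(
            [MirnaLocus("m", GenomicInterval("c", 4_999, 5_099))], [region("c", 1, 10_098)]
        )
        assert call2.flanks == (4_999, 4_999)
        assert classify_flanks(call2) == "short_both"


class TestClassifyDosage:
    @pytest.fixture()
    def gene(self):
        # transcript 1000..10000, hairpin 4000..4100, promoter at 1000
        return GeneModelSketch(
            transcript=GenomicInterval("c", 1000, 10_000),
            hairpin=GenomicInterval("c", 4000, 4100),
        )

    def test_whole_gene(self, gene):
        whole = GenomicInterval("c", 500, 11_000)
        assert classify_dosage(gene, whole, "deletion") == "decrease"
        assert classify_dosage(gene, whole, "duplication") == "increase"

    def test_five_prime_portion(self, gene):
        five = GenomicInterval("c", 500, 3000)  # promoter, no hairpin
        assert classify_dosage(gene, five, "deletion") == "decrease"
        assert classify_dosage(gene, five, "duplication") == "none"

    def test_three_prime_portion(self, gene):
        three = GenomicInterval("c", 5000, 11_000)  # downstream of hairpin
        assert classify_dosage(gene, three, "deletion") == "indeterminate"
        assert classify_dosage(gene, three, "duplication") == "none"

    def test_intragenic_tandem_duplication_with_hairpin(self, gene):
        seg = GenomicInterval("c", 3500, 4500)
        assert classify_dosage(gene, seg, "duplication") == "increase"

    def test_intragenic_deletion_sparing_hairpin_and_promoter(self, gene):
        seg = GenomicInterval("c", 2000, 3000)
        assert classify_dosage(gene, seg, "deletion") == "none"

    def test_hairpin_deletion_decreases(self, gene):
        seg = GenomicInterval("c", 4050, 4060)  # clips the hairpin
        assert classify_dosage(gene, seg, "deletion") == "decrease"

    def test_no_overlap_errors(self, gene):
        with pytest.raises(ValueError, match="does not overlap"):
            classify_dosage(gene, GenomicInterval("c", 20_000, 21_000), "deletion")

    def test_unknown_kind(self, gene):
        with pytest.raises(ValueError, match="unknown CNV kind"):
            classify_dosage(gene, GenomicInterval("c", 500, 11_000), "inversion")

    @given(
        st.integers(1000, 9_000),
        st.integers(1, 4_000),
        st.sampled_from(["deletion", "duplication"]),
    )
    @settings(max_examples=100)
    def test_total_and_whole_gene_never_flips_sign(self, start, length, kind, ):
        gene = GeneModelSketch(
            transcript=GenomicInterval("c", 1000, 10_000),
            hairpin=GenomicInterval("c", 4000, 4100),
        )
        cnv = GenomicInterval("c", start, min(start + length, 12_000))
        from mircnv.intervals import overlap_bp

        if overlap_bp(cnv, gene.transcript) < 1:
            return
        partial = classify_dosage(gene, cnv, kind)
        assert partial in {"increase", "decrease", "none", "indeterminate"}
        whole = classify_dosage(gene, GenomicInterval("c", 500, 11_000), kind)
        # enlarging to the whole gene never flips increase <-> decrease
        assert {partial, whole} not in ({"increase", "decrease"},)
        if kind == "deletion":
            assert partial != "increase"
        else:
            assert partial in {"increase", "none"}


class TestDiseaseRegionOverlap:
    def test_six_loci_in_one_syndrome_region(self):
        loci = [
            MirnaLocus(f"mir-{i}", GenomicInterval("chr22", 1000 * i, 1000 * i + 80))
            for i in range(1, 7)
        ]
        syndrome = region("chr22", 1, 10_000, cnv_id="DiGeorge-like")
        grouped = disease_region_overlap(loci, [syndrome])
        assert set(grouped) == {"DiGeorge-like"}
        assert len(grouped["DiGeorge-like"]) == 6
        assert all(c.region.set_label == "disease" for c in grouped["DiGeorge-like"])

    def test_empty_disease_set(self):
        loci = [MirnaLocus("m", GenomicInterval("chr1", 100, 200))]
        assert disease_region_overlap(loci, []) == {}

    def test_straddling_locus_called(self):
        loci = [MirnaLocus("m", GenomicInterval("chr1", 90, 110))]
        grouped = disease_region_overlap(loci, [region("chr1", 1, 100, cnv_id="r")])
        assert len(grouped["r"]) == 1
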