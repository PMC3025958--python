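import numpy as np
import pytest

from ercross.genomic_io import ChromSizes, GenomicInterval
from ercross.interval_algebra import (
    BindingRegion,
    RegionIndex,
    SiteClass,
    classify_six,
    extend,
    merge,
    partition_subtypes,
    prevalent_sites,
    raw_overlap_report,
    tag_density_filter,
)

from conftest import random_intervals
from oracles import (
    classify_six_bruteforce,
    graph_merge,
    mask_merge,
    mask_overlaps_any,
)


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


def spans(regions):
    return sorted((r.chrom, r.start, r.end) for r in regions)


class TestExtend:
    def test_plain_arithmetic(self, toy_sizes):
        (out,) = extend([iv("chr1", 5000, 5200)], 1000, toy_sizes)
        assert (out.start, out.end) == (4000, 6200)

    def test_clipping_at_boundaries(self):
        sizes = ChromSizes.from_mapping({"chr1": 10_000})
        (out,) = extend([iv("chr1", 300, 500)], 1000, sizes)
        assert (out.start, out.end) == (0, 1500)
        (out,) = extend([iv("chr1", 9_500, 9_900)], 1000, sizes)
        assert (out.start, out.end) == (8_500, 10_000)

    def test_zero_flank_is_identity(self, toy_sizes):
        original = [iv("chr1", 10, 20, id="a"), iv("chr2", 30, 40, id="b")]
        assert extend(original, 0, toy_sizes) == original

    def test_unknown_chromosome_rejected(self, toy_sizes):
        with pytest.raises(ValueError, match="absent"):
            extend([iv("chr9", 0, 10)], 100, toy_sizes)

    def test_negative_flank_rejected(self, toy_sizes):
        with pytest.raises(ValueError):
            extend([iv("chr1", 0, 10)], -1, toy_sizes)

    def test_flank_composition(self, rng, toy_sizes):
        # away from boundaries, extend(a) then extend(b) == extend(a+b)
        intervals = [iv("chr1", int(s), int(s) + 50) for s in rng.integers(5000, 90_000, 50)]
        twice = extend(extend(intervals, 300, toy_sizes), 200, toy_sizes)
        once = extend(intervals, 500, toy_sizes)
        assert twice == once

    def test_clipped_extension_is_subset(self, rng, toy_sizes):
        intervals = random_intervals(rng, 100, toy_sizes)
        twice = extend(extend(intervals, 60_000, toy_sizes), 60_000, toy_sizes)
        once = extend(intervals, 120_000, toy_sizes)
        for a, b in zip(twice, once):
            assert b.start <= a.start and a.end <= b.end


class TestMerge:
    def test_simple_example(self):
        regions = merge(
            [iv("chr1", 0, 100, id="a"), iv("chr1", 50, 150, id="b"),
             iv("chr1", 200, 300, id="c")]
        )
        assert spans(regions) == [("chr1", 0, 150), ("chr1", 200, 300)]
        assert regions[0].member_ids == ("a", "b")
        assert regions[1].member_ids == ("c",)

    def test_bookended_not_merged_by_default(self):
        regions = merge([iv("chr1", 0, 100), iv("chr1", 100, 200)])
        assert len(regions) == 2
        regions = merge([iv("chr1", 0, 100), iv("chr1", 100, 200)], bookended=True)
        assert spans(regions) == [("chr1", 0, 200)]

    def test_bookended_merge_matches_mask_oracle_random_200(self, rng):
        # a per-bp mask cannot distinguish touching intervals, so the mask
        # oracle checks the book-ended dialect
        chrom_lens = {"chr1": 100_000}
        intervals = random_intervals(rng, 200, chrom_lens, max_len=800)
        got = spans(merge(intervals, bookended=True))
        expected = sorted(mask_merge(
            [(i.chrom, i.start, i.end) for i in intervals], chrom_lens
        ))
        assert got == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_strict_merge_matches_graph_oracle(self, seed):
        rng = np.random.default_rng(seed)
        chrom_lens = {"chr1": 20_000, "chr2": 20_000}
        intervals = random_intervals(rng, 60, chrom_lens, max_len=900)
        got = spans(merge(intervals))
        expected = graph_merge([(i.chrom, i.start, i.end) for i in intervals])
        assert got == expected

    def test_idempotent(self, rng, toy_sizes):
        intervals = random_intervals(rng, 150, toy_sizes)
        once = merge(intervals)
        twice = merge([iv(r.chrom, r.start, r.end) for r in once])
        assert spans(once) == spans(twice)

    def test_union_of_spans_preserved(self, rng, toy_sizes):
        intervals = random_intervals(rng, 80, toy_sizes)
        total_in = sum(
            e - s for _, s, e in mask_merge(
                [(i.chrom, i.start, i.end) for i in intervals], toy_sizes
            )
        )
        total_out = sum(r.end - r.start for r in merge(intervals))
        assert total_in == total_out

    def test_every_member_extension_overlaps_region(self, rng, toy_sizes):
        peaks = random_intervals(rng, 100, toy_sizes)
        extended = extend(peaks, 1000, toy_sizes)
        by_id = {p.id: p for p in extended}
        for region in merge(extended):
            for member in region.member_ids:
                assert by_id[member].overlaps(
                    GenomicInterval(region.chrom, region.start, region.end)
                )


class TestPartitionSubtypes:
    def test_overlapping_pair(self):
        beta = merge([iv("chr1", 0, 100)])
        alpha = merge([iv("chr1", 50, 150)])
        part = partition_subtypes(beta, alpha)
        assert spans(part.heterodimer) == [("chr1", 0, 100)]
        assert part.homodimer_beta == () and part.homodimer_alpha == ()

    def test_disjoint_singletons(self):
        part = partition_subtypes(merge([iv("chr1", 0, 100)]),
                                  merge([iv("chr1", 500, 600)]))
        assert part.heterodimer == ()
        assert len(part.homodimer_beta) == 1 and len(part.homodimer_alpha) == 1

    def test_counts_conserved(self, rng, toy_sizes):
        beta = merge(extend(random_intervals(rng, 60, toy_sizes), 500, toy_sizes))
        alpha = merge(extend(random_intervals(rng, 60, toy_sizes), 500, toy_sizes))
        part = partition_subtypes(beta, alpha)
        assert len(part.heterodimer) + len(part.homodimer_beta) == len(beta)
        assert len(part.alpha_partners) + len(part.homodimer_alpha) == len(alpha)

    def test_matches_mask_oracle(self, rng):
        chrom_lens = {"chr1": 50_000}
        beta = merge(random_intervals(rng, 40, chrom_lens, max_len=600))
        alpha = merge(random_intervals(rng, 40, chrom_lens, max_len=600))
        part = partition_subtypes(beta, alpha)
        alpha_triples = [(r.chrom, r.start, r.end) for r in alpha]
        for r in beta:
            expected = mask_overlaps_any(
                (r.chrom, r.start, r.end), alpha_triples, chrom_lens
            )
            assert (r in part.heterodimer) == expected

    def test_internal_overlap_rejected(self):
        bad = [
            BindingRegion("chr1", 0, 100, ("a",)),
            BindingRegion("chr1", 50, 150, ("b",)),
        ]
        with pytest.raises(ValueError, match="overlap"):
            partition_subtypes(bad, [])


class TestPrevalentSites:
    def test_lone_beta_peak(self, toy_sizes):
        beta = [iv("chr1", 5000, 5200, id="b1")]
        beta_regions = merge(extend(beta, 1000, toy_sizes))
        beta_only, alpha_only = prevalent_sites(beta, [], beta_regions, [])
        assert [p.id for p in beta_only] == ["b1"] and alpha_only == []

    def test_nearby_peaks_disqualify_both(self, toy_sizes):
        # 500 bp apart: after +-1000 extension the regions overlap
        beta = [iv("chr1", 5000, 5200, id="b1")]
        alpha = [iv("chr1", 5700, 5900, id="a1")]
        br = merge(extend(beta, 1000, toy_sizes))
        ar = merge(extend(alpha, 1000, toy_sizes))
        beta_only, alpha_only = prevalent_sites(beta, alpha, br, ar)
        assert beta_only == [] and alpha_only == []

    def test_distant_peaks_both_prevalent(self, toy_sizes):
        beta = [iv("chr1", 5000, 5200, id="b1")]
        alpha = [iv("chr1", 9000, 9200, id="a1")]
        br = merge(extend(beta, 1000, toy_sizes))
        ar = merge(extend(alpha, 1000, toy_sizes))
        beta_only, alpha_only = prevalent_sites(beta, alpha, br, ar)
        assert [p.id for p in beta_only] == ["b1"]
        assert [p.id for p in alpha_only] == ["a1"]

    def test_mismatched_peak_region_sets_rejected(self, toy_sizes):
        beta = [iv("chr1", 5000, 5200, id="b1")]
        wrong_regions = merge(extend([iv("chr2", 0, 100)], 1000, toy_sizes))
        with pytest.raises(ValueError, match="not contained"):
            prevalent_sites(beta, [], wrong_regions, [])


def build_region_sets(beta, tap, wt, sizes, flank=1000):
    return (
        merge(extend(beta, flank, sizes)),
        merge(extend(tap, flank, sizes)),
        merge(extend(wt, flank, sizes)),
    )


class TestClassifySix:
    def test_definitions(self, toy_sizes):
        beta = [iv("chr1", 10_000, 10_200, id="b1"),  # + wt only -> 1
                iv("chr1", 20_000, 20_200, id="b2"),  # + both -> 2
                iv("chr1", 30_000, 30_200, id="b3"),  # alone -> 3
                iv("chr1", 40_000, 40_200, id="b4")]  # + tap only -> 4
        wt = [iv("chr1", 10_100, 10_300, id="w1"), iv("chr1", 20_100, 20_300, id="w2"),
              iv("chr1", 60_000, 60_200, id="w3")]
        tap = [iv("chr1", 20_050, 20_250, id="t2"), iv("chr1", 40_100, 40_300, id="t4"),
               iv("chr1", 50_000, 50_200, id="t5"),  # isolated -> 5
               iv("chr1", 60_100, 60_300, id="t6")]  # with wt -> 6
        br, tr, wr = build_region_sets(beta, tap, wt, toy_sizes)
        labels = classify_six(beta, br, tr, wr, tap)
        assert labels["b1"] is SiteClass.CLASS1_COMPETITION
        assert labels["b2"] is SiteClass.CLASS2_BETA_PLUS_ALPHA
        assert labels["b3"] is SiteClass.CLASS3_BETA_SPECIFIC
        assert labels["b4"] is SiteClass.CLASS4_HETERODIMER_SPECIFIC
        assert labels["t5"] is SiteClass.CLASS5_ALPHA_DISPLACEMENT
        assert labels["t6"] is SiteClass.CLASS6_ALPHA_SPECIFIC
        # alpha peaks sharing a region with beta take the shared class
        assert labels["t2"] is SiteClass.CLASS2_BETA_PLUS_ALPHA
        assert labels["t4"] is SiteClass.CLASS4_HETERODIMER_SPECIFIC

    def test_exhaustive_and_disjoint(self, toy_sizes, rng):
        beta = random_intervals(rng, 20, {"chr1": 90_000}, max_len=200)
        tap = random_intervals(np.random.default_rng(7), 20, {"chr1": 90_000}, max_len=200)
        wt = random_intervals(np.random.default_rng(8), 20, {"chr1": 90_000}, max_len=200)
        br, tr, wr = build_region_sets(beta, tap, wt, toy_sizes)
        labels = classify_six(beta, br, tr, wr, tap)
        assert set(labels) == {p.id for p in beta} | {p.id for p in tap}

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_oracle(self, seed, toy_sizes):
        rng = np.random.default_rng(seed)
        beta = [
            GenomicInterval("chr1", s, s + 150, id=f"b{i}")
            for i, s in enumerate(map(int, rng.integers(2000, 90_000, 20)))
        ]
        tap = [
            GenomicInterval("chr1", s, s + 150, id=f"t{i}")
            for i, s in enumerate(map(int, rng.integers(2000, 90_000, 20)))
        ]
        wt = [
            GenomicInterval("chr1", s, s + 150, id=f"w{i}")
            for i, s in enumerate(map(int, rng.integers(2000, 90_000, 20)))
        ]
        br, tr, wr = build_region_sets(beta, tap, wt, toy_sizes)
        got = {k: f"CLASS{v.value}" for k, v in classify_six(beta, br, tr, wr, tap).items()}
        expected = classify_six_bruteforce(
            [(p.id, p.chrom, p.start, p.end) for p in beta],
            [(r.chrom, r.start, r.end) for r in br],
            [(r.chrom, r.start, r.end) for r in tr],
            [(r.chrom, r.start, r.end) for r in wr],
            [(p.id, p.chrom, p.start, p.end) for p in tap],
        )
        assert got == expected


class TestTagDensityFilter:
    def test_above_threshold_kept(self):
        assert tag_density_filter([iv("chrM", 0, 100, tag_count=60)]) != []

    def test_below_threshold_removed(self):
        assert tag_density_filter([iv("chrM", 0, 100, tag_count=40)]) == []

    def test_boundary_density_kept(self):
        assert tag_density_filter([iv("chrM", 0, 100, tag_count=50)]) != []

    def test_missing_tag_count_rejected(self):
        with pytest.raises(ValueError, match="tag_count"):
            tag_density_filter([iv("chrM", 0, 100)])


class TestRegionIndex:
    def test_containing(self):
        regions = merge([iv("chr1", 0, 100), iv("chr1", 200, 300)])
        index = RegionIndex(regions)
        assert index.containing(iv("chr1", 10, 20)).start == 0
        assert index.containing(iv("chr1", 90, 110)) is None
        assert index.containing(iv("chr2", 10, 20)) is None


def test_raw_overlap_report():
    beta = [iv("chr1", 0, 100, id="b1"), iv("chr1", 500, 600, id="b2")]
    alpha = [iv("chr1", 50, 150, id="a1")]
    report = raw_overlap_report(beta, alpha)
    assert report["beta_overlapping_alpha"] == 1
    assert report["alpha_overlapping_beta"] == 1
    assert report["beta_peaks"] == 2
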