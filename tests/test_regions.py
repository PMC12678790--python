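"""Region merging, categorization, gene mapping, feature overlap."""

import numpy as np
import pandas as pd
import pytest

from methgrad import regions
from methgrad.regions import (
    ChangingRegion,
    categorize_members,
    feature_overlap_proportions,
    load_gene_models,
    map_regions_to_genes,
    merge_changing_sites,
    merge_intervals,
    promoter_interval,
    region_methylation_profile,
    sites_in_track,
)


def _sites(positions, classes, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "pos": positions, "class": classes})


class TestMerge:
    def test_three_sites_within_gaps_form_one_region(self):
        out = merge_changing_sites(_sites([100, 300, 500], ["steep_rise"] * 3))
        assert len(out) == 1
        r = out[0]
        assert (r.start, r.end) == (99, 500)
        assert r.member_positions == [100, 300, 500]

    def test_gap_of_251_breaks_the_run(self):
        out = merge_changing_sites(_sites([100, 351, 400], ["steep_rise"] * 3))
        assert out == []

    def test_two_sites_do_not_form_a_region(self):
        assert merge_changing_sites(_sites([100, 200], ["shallow_rise"] * 2)) == []

    def test_direction_change_splits_run(self):
        out = merge_changing_sites(
            _sites(
                [100, 150, 200, 250, 300, 350],
                ["steep_rise"] * 3 + ["steep_decline"] * 3,
            )
        )
        assert len(out) == 2
        assert out[0].category == "steep_rise"
        assert out[1].category == "steep_decline"

    def test_direction_agnostic_mode_flags_bidirectional(self):
        out = merge_changing_sites(
            _sites([100, 150, 200], ["steep_rise", "steep_decline", "steep_rise"]),
            direction_aware=False,
        )
        assert len(out) == 1
        assert out[0].category == "discarded_bidirectional"

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            merge_changing_sites(_sites([300, 100, 200], ["steep_rise"] * 3))

    def test_unordered_sites_ignored(self):
        out = merge_changing_sites(
            _sites([100, 150, 200, 250], ["steep_rise", "unordered", "steep_rise", "steep_rise"])
        )
        # the unordered site is not a member, but it does not break the run either:
        # gaps are measured between consecutive *changing* sites
        assert len(out) == 1
        assert out[0].member_positions == [100, 200, 250]


def _brute_force_merge(positions, classes, max_gap=250, min_sites=3):
    """Independent run-scan: grow maximal same-direction runs pairwise."""
    runs = []
    i = 0
    while i < len(positions):
        j = i
        while (
            j + 1 < len(positions)
            and positions[j + 1] - positions[j] <= max_gap
            and classes[j + 1].split("_")[1] == classes[j].split("_")[1]
        ):
            j += 1
        if j - i + 1 >= min_sites:
            runs.append((positions[i], positions[j], j - i + 1))
        i = j + 1
    return runs


def test_merge_matches_brute_force_on_random_chromosomes(rng):
    classes = ["steep_rise", "steep_decline", "shallow_rise", "shallow_decline"]
    for _ in range(200):
        n = int(rng.integers(1, 30))
        positions = np.sort(rng.choice(np.arange(1, 5000), size=n, replace=False))
        cls = list(rng.choice(classes, size=n))
        got = merge_changing_sites(_sites(positions, cls))
        expect = _brute_force_merge(list(positions), cls)
        assert [(r.member_positions[0], r.member_positions[-1], r.n_sites) for r in got] == expect


class TestCategorize:
    @pytest.mark.parametrize(
        "members,expected",
        [
            (["shallow_decline"] * 3, "shallow_decline"),
            (["steep_rise", "steep_rise", "shallow_rise"], "mixed_rise"),
            (["steep_rise", "shallow_decline", "steep_rise"], "discarded_bidirectional"),
            (["steep_decline"] * 4, "steep_decline"),
        ],
    )
    def test_member_combinations(self, members, expected):
        assert categorize_members(members) == expected


class TestRegionProfile:
    def test_median_of_three_members(self):
        from methgrad.meth_io import CohortMatrix

        meth = pd.DataFrame(
            {("A", "TC"): [0.1, 0.2, 0.9]},
            index=pd.MultiIndex.from_tuples(
                [("chr1", 100), ("chr1", 200), ("chr1", 300)], names=["chrom", "pos"]
            ),
        )
        meth.columns = pd.MultiIndex.from_tuples(meth.columns, names=["patient", "region"])
        cohort = CohortMatrix(meth=meth, coverage=meth.notna().astype(int) * 20)
        region = ChangingRegion("chr1", 99, 300, [100, 200, 300], ["steep_rise"] * 3)
        assert region_methylation_profile(region, cohort)[("A", "TC")] == pytest.approx(0.2)

    def test_even_count_after_missingness_gives_midpoint(self):
        from methgrad.meth_io import CohortMatrix

        meth = pd.DataFrame(
            {("A", "TC"): [0.1, np.nan, 0.5, 0.7]},
            index=pd.MultiIndex.from_tuples(
                [("chr1", p) for p in (100, 150, 200, 250)], names=["chrom", "pos"]
            ),
        )
        meth.columns = pd.MultiIndex.from_tuples(meth.columns, names=["patient", "region"])
        cohort = CohortMatrix(meth=meth, coverage=meth.notna().astype(int) * 20)
        region = ChangingRegion("chr1", 99, 250, [100, 150, 200, 250], ["steep_rise"] * 4)
        assert region_methylation_profile(region, cohort)[("A", "TC")] == pytest.approx(0.5)


class TestGeneModels:
    def test_plus_strand_promoter(self):
        assert promoter_interval((10_000, 20_000), "+") == (8_000, 10_000)

    def test_minus_strand_promoter(self):
        assert promoter_interval((10_000, 20_000), "-") == (20_000, 22_000)

    def test_promoter_never_overlaps_body(self, tmp_path):
        from methgrad.synthetic import generate_annotation_fixture

        paths = generate_annotation_fixture(10, seed=2, out_dir=tmp_path)
        for g in load_gene_models(paths["gtf"]):
            s, e = g.promoter
            assert e <= g.body[0] or s >= g.body[1]

    def test_gtf_1based_conversion(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text('chr1\tx\tgene\t10001\t20000\t.\t+\t.\tgene_id "G1"; gene_name "N1";\n')
        (g,) = load_gene_models(gtf)
        assert g.body == (10_000, 20_000)
        assert g.promoter == (8_000, 10_000)

    def test_missing_strand_skipped_with_warning(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text('chr1\tx\tgene\t100\t200\t.\t.\t.\tgene_id "G1";\n')
        with pytest.warns(UserWarning, match="strand"):
            assert load_gene_models(gtf) == []


class TestMapRegions:
    def _gene(self):
        from methgrad.regions import GeneModel

        return GeneModel("G1", "N1", "chr1", "+", (10_000, 20_000))

    def _region(self, start, end):
        return ChangingRegion("chr1", start, end, [start + 1, end], ["steep_rise"] * 3)

    def test_region_inside_body_hits_once(self):
        hits = map_regions_to_genes([self._region(12_000, 12_500)], [self._gene()])
        assert [h.compartment for h in hits] == ["gene_body"]

    def test_region_straddling_tss_hits_both_compartments(self):
        hits = map_regions_to_genes([self._region(9_900, 10_100)], [self._gene()])
        assert sorted(h.compartment for h in hits) == ["gene_body", "promoter"]

    def test_unannotated_contig_hits_nothing(self):
        region = ChangingRegion("chrUn", 5, 50, [6, 20, 50], ["steep_rise"] * 3)
        assert map_regions_to_genes([region], [self._gene()]) == []

    def test_chr_prefix_mismatch_normalized(self):
        region = ChangingRegion("1", 12_000, 12_500, [12_001, 12_500], ["steep_rise"] * 3)
        with pytest.warns(UserWarning, match="naming"):
            hits = map_regions_to_genes([region], [self._gene()])
        assert len(hits) == 1


class TestFeatureOverlap:
    def test_all_inside_single_interval(self):
        sites = pd.DataFrame({"chrom": ["chr1"] * 3, "pos": [10, 20, 30]})
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100]})
        out = feature_overlap_proportions({"s": sites}, {"t": track})
        assert out.loc["s", "t"] == 1.0

    def test_empty_track_gives_zero(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [10]})
        track = pd.DataFrame({"chrom": [], "start": [], "end": []})
        out = feature_overlap_proportions({"s": sites}, {"t": track})
        assert out.loc["s", "t"] == 0.0

    def test_membership_matches_linear_scan(self, rng):
        sites = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], 300), "pos": rng.integers(1, 1000, 300)}
        )
        track = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], 40),
                "start": (s := rng.integers(0, 950, 40)),
                "end": s + rng.integers(5, 60, 40),
            }
        )
        got = sites_in_track(sites, track)
        for i in range(len(sites)):
            p0 = sites.pos[i] - 1
            expect = any(
                track.chrom[j] == sites.chrom[i] and track.start[j] <= p0 < track.end[j]
                for j in range(len(track))
            )
            assert got[i] == expect

    def test_overlapping_intervals_merged(self):
        track = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 50], "end": [60, 100]}
        )
        merged = merge_intervals(track)["chr1"]
        assert merged.tolist() == [[0, 100]]
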