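import math
import random

import pytest

from musmosaic.filters import (
    FilterConfig,
    annotate_indel_distance,
    filter_all,
    filter_site,
)
from tests.conftest import make_site

CFG = FilterConfig()


class TestIndelDistance:
    def test_distance_to_nearest_indel_anchor(self):
        sites = [
            make_site(position=97, ref="AT", alts=["A"]),
            make_site(position=100),
            make_site(position=200, ref="A", alts=["AGG"]),
        ]
        annotate_indel_distance(sites)
        assert sites[1].indel_distance == 3  # |100 - 97|

    def test_indel_free_chromosome_gives_infinity(self):
        sites = [make_site(position=100), make_site(position=5000)]
        annotate_indel_distance(sites)
        assert all(math.isinf(s.indel_distance) for s in sites)

    def test_distance_one_fails_strict_rule(self, tiny_layout):
        sites = [
            make_site(position=99, ref="AT", alts=["A"]),
            make_site(position=100),
        ]
        annotate_indel_distance(sites)
        assert sites[1].indel_distance == 1
        verdict = filter_site(sites[1], CFG, tiny_layout, "focalA")
        assert "NEAR_INDEL" in verdict.reasons

    def test_indels_on_other_chromosome_ignored(self):
        sites = [
            make_site(chrom="chr1", position=100),
            make_site(chrom="chr2", position=101, ref="AT", alts=["A"]),
        ]
        annotate_indel_distance(sites)
        assert math.isinf(sites[0].indel_distance)

    def test_unsorted_input_fatal(self):
        sites = [make_site(position=500), make_site(position=100)]
        with pytest.raises(ValueError, match="sorted"):
            annotate_indel_distance(sites)

    def test_chromosome_repeat_fatal(self):
        sites = [
            make_site(chrom="chr1", position=1),
            make_site(chrom="chr2", position=1),
            make_site(chrom="chr1", position=2),
        ]
        with pytest.raises(ValueError, match="sorted"):
            annotate_indel_distance(sites)


class TestFilterSite:
    def test_site_inside_every_bound_passes(self, tiny_layout):
        site = make_site(dp=50, mq=30, alt_support=10)
        site.indel_distance = 100
        verdict = filter_site(site, CFG, tiny_layout, "focalA")
        assert verdict.passed and not verdict.reasons

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(dp=5, alt_support=5), {"LOW_DP", "LOW_ALT_SUPPORT"}),
            (dict(dp=100), {"HIGH_DP"}),
            (dict(mq=20.0), {"LOW_MQ"}),
            (dict(alt_support=5), {"LOW_ALT_SUPPORT"}),
        ],
    )
    def test_boundary_values_fail_strict_comparisons(
        self, tiny_layout, kwargs, expected
    ):
        site = make_site(**kwargs)
        assert filter_site(site, CFG, tiny_layout, "focalA").reasons == frozenset(
            expected
        )

    def test_mitochondrial_rule_no_upper_bound(self, tiny_layout):
        ok = make_site(chrom="chrM", position=100, dp=351, mq=30, alt_support=10)
        assert filter_site(ok, CFG, tiny_layout, "focalA").passed
        low = make_site(chrom="chrM", position=100, dp=350, mq=30, alt_support=10)
        assert filter_site(low, CFG, tiny_layout, "focalA").reasons == {"LOW_DP"}
        huge = make_site(chrom="chrM", position=100, dp=5000, mq=30, alt_support=10)
        assert filter_site(huge, CFG, tiny_layout, "focalA").passed

    @pytest.mark.parametrize("gt", [(0, 1), None])
    def test_het_or_missing_focal_fails_homozygosity(self, tiny_layout, gt):
        site = make_site(genotypes={"focalA": gt})
        assert "NOT_HOMOZYGOUS" in filter_site(site, CFG, tiny_layout, "focalA").reasons

    def test_hom_ref_focal_passes_homozygosity(self, tiny_layout):
        site = make_site(genotypes={"focalA": (0, 0)})
        assert "NOT_HOMOZYGOUS" not in filter_site(
            site, CFG, tiny_layout, "focalA"
        ).reasons

    def test_absent_statistics_fail_conservatively(self, tiny_layout):
        site = make_site(dp=None, alt_support=None)
        assert "MISSING_STAT" in filter_site(site, CFG, tiny_layout, "focalA").reasons

    def test_indel_exempt_from_proximity_rule(self, tiny_layout):
        site = make_site(ref="AT", alts=["A"])
        site.indel_distance = 0
        assert "NEAR_INDEL" not in filter_site(site, CFG, tiny_layout, "focalA").reasons


def reference_verdict(site, config, mito, focal):
    """Straight-line re-statement of the filter rules, kept independent of
    the package implementation."""
    reasons = set()
    if site.site_depth is None:
        reasons.add("MISSING_STAT")
    elif mito:
        if site.site_depth <= config.mito_depth_min:
            reasons.add("LOW_DP")
    else:
        if site.site_depth <= config.nuclear_depth_min:
            reasons.add("LOW_DP")
        if site.site_depth >= config.nuclear_depth_max:
            reasons.add("HIGH_DP")
    if site.mapping_quality is None:
        reasons.add("MISSING_STAT")
    elif site.mapping_quality <= config.mq_min:
        reasons.add("LOW_MQ")
    if site.alt_support is None:
        reasons.add("MISSING_STAT")
    elif site.alt_support <= config.alt_support_min:
        reasons.add("LOW_ALT_SUPPORT")
    if site.variant_class == "SNV" and site.indel_distance <= config.indel_distance_min:
        reasons.add("NEAR_INDEL")
    gt = site.genotypes.get(focal)
    if gt is None or gt[0] != gt[1]:
        reasons.add("NOT_HOMOZYGOUS")
    return frozenset(reasons)


def randomized_sites(n, seed, with_boundaries=True):
    rng = random.Random(seed)
    dp_pool = [0, 4, 5, 6, 50, 99, 100, 101, 349, 350, 351, 500, None]
    mq_pool = [0.0, 19.9, 20.0, 20.1, 45.0, None]
    dist_pool = [0, 1, 2, 3, 4, 100, math.inf]
    sites = []
    pos = 0
    for i in range(n):
        pos += rng.randint(3, 50)
        chrom = rng.choice(["chr1", "chr2", "chrM"])
        dp = rng.choice(dp_pool) if with_boundaries else rng.randint(0, 120)
        alt_pool = [0, 4, 5, 6, 20, None]
        alt = rng.choice([a for a in alt_pool if a is None or dp is None or a <= dp])
        is_indel = rng.random() < 0.2
        site = make_site(
            chrom=chrom,
            position=pos,
            ref="AT" if is_indel else "A",
            alts=["A"] if is_indel else ["G"],
            dp=dp,
            mq=rng.choice(mq_pool),
            alt_support=alt,
            genotypes={"focalA": rng.choice([(0, 0), (1, 1), (0, 1), None])},
        )
        site.indel_distance = rng.choice(dist_pool)
        sites.append(site)
    return sites


class TestFilterAll:
    def test_empty_input(self, tiny_layout):
        passed, failed, counts = filter_all([], CFG, tiny_layout, "focalA")
        assert passed == [] and failed == [] and sum(counts.values()) == 0

    def test_partition_and_per_reason_counting(self, tiny_layout):
        ok = make_site(position=10)
        multi = make_site(position=20, mq=10.0, alt_support=2)
        passed, failed, counts = filter_all([ok, multi], CFG, tiny_layout, "focalA")
        assert [s.position for s in passed] == [10]
        assert [s.position for s in failed] == [20]
        assert counts["LOW_MQ"] == 1 and counts["LOW_ALT_SUPPORT"] == 1

    def test_matches_scalar_filter_site_and_reference(self, tiny_layout):
        sites = randomized_sites(400, seed=11)
        passed, failed, counts = filter_all(sites, CFG, tiny_layout, "focalA")
        assert len(passed) + len(failed) == len(sites)
        for s in sites:
            mito = s.chrom == "chrM"
            expected = reference_verdict(s, CFG, mito, "focalA")
            assert s.filter_reasons == expected
            assert filter_site(s, CFG, tiny_layout, "focalA").reasons == expected

    def test_raising_mq_only_shrinks_pass_set(self, tiny_layout):
        sites = randomized_sites(300, seed=5)
        loose, _, _ = filter_all(sites, FilterConfig(mq_min=10), tiny_layout, "focalA")
        strict, _, _ = filter_all(sites, FilterConfig(mq_min=40), tiny_layout, "focalA")
        loose_ids = {id(s) for s in loose}
        assert all(id(s) in loose_ids for s in strict)

    def test_widening_depth_window_only_grows_pass_set(self, tiny_layout):
        sites = randomized_sites(300, seed=6)
        narrow, _, _ = filter_all(
            sites, FilterConfig(nuclear_depth_min=10, nuclear_depth_max=60),
            tiny_layout, "focalA",
        )
        wide, _, _ = filter_all(
            sites, FilterConfig(nuclear_depth_min=1, nuclear_depth_max=400),
            tiny_layout, "focalA",
        )
        wide_ids = {id(s) for s in wide}
        assert all(id(s) in wide_ids for s in narrow)

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            FilterConfig(nuclear_depth_min=100, nuclear_depth_max=50)
        with pytest.raises(ValueError):
            FilterConfig(mq_min=-1)
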