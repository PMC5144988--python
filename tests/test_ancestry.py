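import random

import pytest

from musmosaic.ancestry import (
    Excluded,
    PaintConfig,
    exclusive_sharing,
    paint_windows,
    polarize,
    summarize_ancestry,
)
from musmosaic.genome import Interval, normalize_mask
from tests.conftest import make_site

REP_OF = {"dom": "rep_dom", "mus": "rep_mus", "cas": "rep_cas"}


class TestPolarize:
    def test_outgroup_hom_ref_makes_alt_derived(self, panel):
        ps = polarize(make_site(), panel, "focalA")
        assert ps.derived_allele == "G" and ps.focal_has_derived

    def test_outgroup_hom_alt_flips_polarity(self, panel):
        site = make_site(genotypes={"outgroup": (1, 1), "focalA": (0, 0)})
        ps = polarize(site, panel, "focalA")
        assert ps.derived_allele == "A"  # the reference allele can be derived
        assert ps.focal_has_derived  # focal hom-ref = hom-derived here

    @pytest.mark.parametrize("og", [(0, 1), None])
    def test_unresolved_outgroup_excluded(self, panel, og):
        site = make_site(genotypes={"outgroup": og})
        out = polarize(site, panel, "focalA")
        assert isinstance(out, Excluded) and out.reason == "outgroup_unresolved"

    def test_multiallelic_and_indel_excluded(self, panel):
        multi = make_site(alts=["G", "T"])
        assert polarize(multi, panel, "focalA").reason == "multiallelic"
        indel = make_site(ref="AT", alts=["A"])
        assert polarize(indel, panel, "focalA").reason == "not_snv"

    def test_het_focal_does_not_count_as_derived(self, panel):
        site = make_site(genotypes={"focalA": (0, 1)})
        assert not polarize(site, panel, "focalA").focal_has_derived

    def test_missing_representative_makes_sharing_undecidable(self, panel):
        site = make_site(genotypes={"rep_mus": None})
        ps = polarize(site, panel, "focalA")
        assert ps.sharing is None
        assert exclusive_sharing(ps) is None

    def test_het_representative_counts_as_carrying(self, panel):
        site = make_site(genotypes={"rep_cas": (0, 1)})
        assert polarize(site, panel, "focalA").sharing == frozenset({"cas"})


class TestExclusiveSharing:
    @pytest.mark.parametrize(
        "carriers,expected",
        [
            ({"dom"}, "dom"),
            ({"mus"}, "mus"),
            ({"dom", "mus"}, None),
            (set(), None),
            ({"dom", "mus", "cas"}, None),
        ],
    )
    def test_exactly_one_rule(self, panel, carriers, expected):
        gts = {REP_OF[k]: (1, 1) for k in carriers}
        ps = polarize(make_site(genotypes=gts), panel, "focalA")
        assert exclusive_sharing(ps) == expected


def scenario_sites(spec):
    """Build biallelic SNVs from (position, sharing subset or marker) pairs.

    Markers: 'og_het' (unpolarizable), 'focal_ref' (focal lacks derived),
    'rep_missing' (sharing undecidable).
    """
    sites = []
    for pos, what in spec:
        gts = {}
        if what == "og_het":
            gts["outgroup"] = (0, 1)
        elif what == "focal_ref":
            gts["focalA"] = (0, 0)
        elif what == "rep_missing":
            gts["rep_dom"] = None
        else:
            gts.update({REP_OF[k]: (1, 1) for k in what})
        sites.append(make_site(position=pos, genotypes=gts))
    return sites


class TestPaintWindows:
    def windows(self, n=4, width=1000):
        return [Interval("chr1", i * width, (i + 1) * width) for i in range(n)]

    def test_majority_label_and_counts(self, panel):
        spec = [(i, {"dom"}) for i in range(1, 31)]
        spec += [(i, {"mus"}) for i in range(31, 33)]
        sites = scenario_sites(spec)
        (w,) = paint_windows(
            sites, self.windows(1), normalize_mask([]), panel, "focalA",
            PaintConfig(min_sites=5),
        )
        assert w.counts == {"dom": 30, "mus": 2, "cas": 0}
        assert w.label == "dom" and w.n_informative == 32

    def test_tie_gives_ambiguous(self, panel):
        spec = [(i, {"dom"}) for i in range(1, 5)] + [
            (i, {"mus"}) for i in range(5, 9)
        ]
        (w,) = paint_windows(
            scenario_sites(spec), self.windows(1), normalize_mask([]), panel,
            "focalA", PaintConfig(min_sites=8),
        )
        assert w.label == "ambiguous"

    def test_sparse_window_uninformative(self, panel):
        spec = [(i, {"dom"}) for i in range(1, 6)]
        (w,) = paint_windows(
            scenario_sites(spec), self.windows(1), normalize_mask([]), panel,
            "focalA", PaintConfig(min_sites=10),
        )
        assert w.label == "uninformative"

    def test_mostly_masked_window_carries_no_counts(self, panel):
        mask = normalize_mask([Interval("chr1", 0, 600)])  # 60% of window 0
        spec = [(i, {"dom"}) for i in range(1, 30)]
        ws = paint_windows(
            scenario_sites(spec), self.windows(2), normalize_mask(mask.intervals),
            panel, "focalA", PaintConfig(min_sites=5),
        )
        assert ws[0].label == "masked" and ws[0].counts == {}

    def test_half_masked_window_still_analyzed(self, panel):
        mask = normalize_mask([Interval("chr1", 0, 500)])  # exactly threshold
        spec = [(i, {"dom"}) for i in range(1, 30)]
        ws = paint_windows(
            scenario_sites(spec), self.windows(1), mask, panel, "focalA",
            PaintConfig(min_sites=5),
        )
        assert ws[0].label == "dom"

    def test_site_outside_windows_fatal(self, panel):
        sites = scenario_sites([(5000, {"dom"})])
        with pytest.raises(ValueError, match="outside"):
            paint_windows(
                sites, self.windows(4), normalize_mask([]), panel, "focalA"
            )

    def test_matches_brute_force_per_site_loop(self, panel):
        """Randomized instance checked against an independent per-site loop
        over raw genotypes."""
        rng = random.Random(17)
        sites = []
        for pos in sorted(rng.sample(range(1, 8001), 600)):
            gts = {
                "outgroup": rng.choice([(0, 0), (0, 0), (0, 0), (1, 1), (0, 1), None]),
                "focalA": rng.choice([(1, 1), (1, 1), (0, 0), (0, 1)]),
            }
            for rep in REP_OF.values():
                gts[rep] = rng.choice([(0, 0), (0, 0), (1, 1), (0, 1), None])
            sites.append(make_site(position=pos, genotypes=gts))
        windows = self.windows(8)
        mask = normalize_mask([Interval("chr1", 2000, 3000)])
        cfg = PaintConfig(min_sites=3)
        got = paint_windows(sites, windows, mask, panel, "focalA", cfg)

        for w, win in zip(windows, got):
            masked = mask.overlap_bases(w) / w.length > cfg.mask_threshold
            if masked:
                assert win.label == "masked"
                continue
            counts = {"dom": 0, "mus": 0, "cas": 0}
            n_sites = 0
            for s in sites:
                pos0 = s.position - 1
                if not (w.start <= pos0 < w.end):
                    continue
                n_sites += 1
                og = s.genotypes["outgroup"]
                if og is None or og[0] != og[1]:
                    continue
                derived = 1 - og[0]
                reps = {k: s.genotypes[v] for k, v in REP_OF.items()}
                if any(g is None for g in reps.values()):
                    continue
                fa = s.genotypes["focalA"]
                if fa != (derived, derived):
                    continue
                sharing = [k for k, g in reps.items() if derived in g]
                if len(sharing) == 1:
                    counts[sharing[0]] += 1
            assert win.counts == counts
            assert win.n_sites == n_sites
            n_inf = sum(counts.values())
            if n_inf < cfg.min_sites:
                assert win.label == "uninformative"
            else:
                best = max(counts.values())
                winners = [k for k, v in counts.items() if v == best]
                assert win.label == (winners[0] if len(winners) == 1 else "ambiguous")

    def test_bookkeeping_identity_per_window(self, panel):
        rng = random.Random(23)
        sites = []
        for pos in sorted(rng.sample(range(1, 4001), 300)):
            gts = {
                "outgroup": rng.choice([(0, 0), (1, 1), (0, 1), None]),
                "focalA": rng.choice([(1, 1), (0, 0), (0, 1)]),
                "rep_dom": rng.choice([(0, 0), (1, 1), None]),
                "rep_mus": rng.choice([(0, 0), (1, 1)]),
            }
            sites.append(make_site(position=pos, genotypes=gts))
        for w in paint_windows(
            sites, self.windows(4), normalize_mask([]), panel, "focalA"
        ):
            total = (
                sum(w.counts.values())
                + w.n_nonexclusive
                + w.n_focal_not_derived
                + w.n_excluded
            )
            assert total == w.n_sites


class TestSummarizeAncestry:
    def painted(self, labels, width=1000):
        from musmosaic.ancestry import AncestryWindow

        return [
            AncestryWindow(
                interval=Interval("chr1", i * width, (i + 1) * width), label=lab
            )
            for i, lab in enumerate(labels)
        ]

    def test_fraction_over_analyzed_windows(self):
        s = summarize_ancestry(self.painted(["dom"] * 92 + ["mus"] * 8))
        assert s.fraction["dom"] == pytest.approx(0.92)
        assert s.masked_fraction == 0.0

    def test_all_masked_is_error(self):
        with pytest.raises(ValueError):
            summarize_ancestry(self.painted(["masked"] * 5))

    def test_single_window(self):
        s = summarize_ancestry(self.painted(["cas"]))
        assert s.fraction == {"cas": 1.0}

    def test_masked_fraction_reported_separately(self):
        s = summarize_ancestry(self.painted(["dom", "dom", "masked", "mus"]))
        assert s.masked_fraction == pytest.approx(0.25)
        assert sum(s.fraction.values()) == pytest.approx(1.0)
        assert sum(s.fraction_length_weighted.values()) == pytest.approx(1.0)
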