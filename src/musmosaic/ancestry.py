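"""Windowed local-ancestry painting via outgroup polarization.

Alleles are polarized against an outgroup species assumed to carry the
ancestral state: the outgroup's homozygous allele is ancestral and the other
allele derived. Within fixed-width windows, sites where the focal strain is
homozygous for the derived allele and exactly one subspecies representative
(dom/mus/cas) carries it are tallied; the window takes the majority
subspecies. Windows mostly covered by the introgression/contamination mask
are excluded, and windows with too few informative sites are left
uninformative. No HMM smoothing — the statistic is the plain windowed count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import Interval, MaskTrack, mask_overlap_fraction
from .variants import SamplePanel, VariantSite, carries, is_hom, is_missing

__all__ = [
    "AncestrySummary",
    "AncestryWindow",
    "Excluded",
    "PaintConfig",
    "PolarizedSite",
    "SUBSPECIES",
    "exclusive_sharing",
    "paint_windows",
    "polarize",
    "summarize_ancestry",
]

SUBSPECIES = ("dom", "mus", "cas")
LABELS = (*SUBSPECIES, "uninformative", "masked", "ambiguous")


@dataclass(frozen=True)
class PolarizedSite:
    chrom: str
    position: int
    derived_allele: str
    focal_has_derived: bool
    # representatives carrying the derived allele; None when any
    # representative genotype is missing (sharing undecidable)
    sharing: frozenset[str] | None


@dataclass(frozen=True)
class Excluded:
    reason: str  # outgroup_unresolved | multiallelic | not_snv


def polarize(
    site: VariantSite, panel: SamplePanel, focal: str
) -> PolarizedSite | Excluded:
    """Assign ancestral/derived polarity from the outgroup genotype.

    The ancestral allele is the outgroup's homozygous allele; the other
    allele is derived (the reference allele can be derived). Excluded when
    the site is multiallelic or not an SNV, or the outgroup is heterozygous
    or missing.
    """
    if site.multiallelic:
        return Excluded("multiallelic")
    if site.variant_class != "SNV":
        return Excluded("not_snv")
    og = site.genotypes.get(panel.outgroup)
    if is_missing(og) or og[0] != og[1]:
        return Excluded("outgroup_unresolved")
    ancestral_idx = og[0]
    if ancestral_idx not in (0, 1):
        return Excluded("outgroup_unresolved")
    derived_idx = 1 - ancestral_idx
    derived_allele = site.alts[0] if derived_idx == 1 else site.ref

    focal_gt = site.genotypes.get(focal)
    focal_has_derived = is_hom(focal_gt, derived_idx)

    sharing: frozenset[str] | None
    rep_gts = {k: site.genotypes.get(v) for k, v in panel.representatives.items()}
    if any(is_missing(g) for g in rep_gts.values()):
        sharing = None
    else:
        sharing = frozenset(
            k for k, g in rep_gts.items() if carries(g, derived_idx)
        )
    return PolarizedSite(
        chrom=site.chrom,
        position=site.position,
        derived_allele=derived_allele,
        focal_has_derived=focal_has_derived,
        sharing=sharing,
    )


def exclusive_sharing(ps: PolarizedSite) -> str | None:
    """The single subspecies sharing the derived allele, or None when zero
    or several representatives share it (or sharing is undecidable)."""
    if ps.sharing is None or len(ps.sharing) != 1:
        return None
    return next(iter(ps.sharing))


@dataclass
class PaintConfig:
    min_sites: int = 10  # informative sites needed to label a window
    mask_threshold: float = 0.5  # mask overlap fraction above which a window is masked


@dataclass
class AncestryWindow:
    interval: Interval
    label: str
    n_informative: int = 0
    counts: dict[str, int] = field(default_factory=dict)
    # bookkeeping over pass-filter biallelic SNVs in the window:
    n_sites: int = 0  # total such sites
    n_excluded: int = 0  # polarization failed or representative missing
    n_focal_not_derived: int = 0
    n_nonexclusive: int = 0  # derived in focal but shared with 0/2/3 reps


def paint_windows(
    sites: list[VariantSite],
    windows: list[Interval],
    mask: MaskTrack,
    panel: SamplePanel,
    focal: str,
    config: PaintConfig | None = None,
) -> list[AncestryWindow]:
    """Label each window by exclusive derived-allele sharing counts.

    Only biallelic SNVs among ``sites`` (assumed pass-filter) contribute.
    Windows with mask overlap above the threshold are ``masked`` and carry no
    counts; windows with fewer informative sites than ``min_sites`` are
    ``uninformative``; otherwise the argmax subspecies wins, ties giving
    ``ambiguous``. Per window the tallies satisfy
    counts + non-exclusive + focal-not-derived + excluded = n_sites.
    """
    config = config or PaintConfig()
    by_chrom: dict[str, list[tuple[Interval, int]]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append((w, i))
    for chrom, lst in by_chrom.items():
        lst.sort(key=lambda t: t[0].start)

    out = [
        AncestryWindow(
            interval=w,
            label="masked" if mask_overlap_fraction(w, mask) > config.mask_threshold else "",
            counts={k: 0 for k in SUBSPECIES},
        )
        for w in windows
    ]

    import bisect

    starts_by_chrom = {
        chrom: [w.start for w, _ in lst] for chrom, lst in by_chrom.items()
    }

    for site in sites:
        if not site.is_biallelic_snv:
            continue
        lst = by_chrom.get(site.chrom)
        if lst is None:
            raise ValueError(f"site on chromosome outside windows: {site.chrom}")
        pos0 = site.position - 1
        j = bisect.bisect_right(starts_by_chrom[site.chrom], pos0) - 1
        if j < 0 or not (lst[j][0].start <= pos0 < lst[j][0].end):
            raise ValueError(
                f"site {site.chrom}:{site.position} falls outside all windows"
            )
        win = out[lst[j][1]]
        if win.label == "masked":
            continue
        win.n_sites += 1
        ps = polarize(site, panel, focal)
        if isinstance(ps, Excluded) or ps.sharing is None:
            win.n_excluded += 1
            continue
        if not ps.focal_has_derived:
            win.n_focal_not_derived += 1
            continue
        key = exclusive_sharing(ps)
        if key is None:
            win.n_nonexclusive += 1
        else:
            win.counts[key] += 1

    for win in out:
        if win.label == "masked":
            win.counts = {}
            continue
        win.n_informative = sum(win.counts.values())
        if win.n_informative < config.min_sites:
            win.label = "uninformative"
            continue
        best = max(win.counts.values())
        winners = [k for k, v in win.counts.items() if v == best]
        win.label = winners[0] if len(winners) == 1 else "ambiguous"
    return out


@dataclass
class AncestrySummary:
    """Per-label fractions of analyzed (non-masked) windows, the separately
    reported masked fraction, and a length-weighted alternative (identical
    except for truncated final windows)."""

    fraction: dict[str, float]
    n_windows: dict[str, int]
    masked_fraction: float
    fraction_length_weighted: dict[str, float]

    @property
    def n_analyzed(self) -> int:
        return sum(self.n_windows.values())


def summarize_ancestry(windows: list[AncestryWindow]) -> AncestrySummary:
    analyzed = [w for w in windows if w.label != "masked"]
    if not analyzed:
        raise ValueError("no analyzed windows: everything is masked")
    n_windows: dict[str, int] = {}
    bp: dict[str, int] = {}
    for w in analyzed:
        n_windows[w.label] = n_windows.get(w.label, 0) + 1
        bp[w.label] = bp.get(w.label, 0) + w.interval.length
    n = len(analyzed)
    total_bp = sum(bp.values())
    return AncestrySummary(
        fraction={k: v / n for k, v in n_windows.items()},
        n_windows=n_windows,
        masked_fraction=(len(windows) - n) / len(windows),
        fraction_length_weighted={k: v / total_bp for k, v in bp.items()},
    )
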