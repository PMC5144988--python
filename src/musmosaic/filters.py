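"""Hard filters for candidate variants.

All threshold comparisons are strict, mirroring the originating pipeline's
"> 5, < 100" notation: a nuclear site passes depth only with DP > 5 and
DP < 100; mitochondrial sites need DP > 350 with no upper bound (mtDNA is
high-copy). Mapping quality must exceed 20, alternate-allele support must
exceed 5 reads, SNVs must sit more than 2 bp from the nearest indel anchor,
and the focal genotype must be homozygous (inbred strains). A site missing a
statistic a filter needs fails conservatively with MISSING_STAT.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .genome import ChromKind, GenomeLayout
from .variants import SNV, VariantSite, is_het, is_missing

__all__ = [
    "FilterConfig",
    "FilterVerdict",
    "REASONS",
    "annotate_indel_distance",
    "filter_all",
    "filter_site",
]

REASONS = (
    "LOW_DP",
    "HIGH_DP",
    "LOW_MQ",
    "LOW_ALT_SUPPORT",
    "NEAR_INDEL",
    "NOT_HOMOZYGOUS",
    "MISSING_STAT",
)


@dataclass
class FilterConfig:
    """Thresholds; every comparison against them is strict (exclusive)."""

    nuclear_depth_min: int = 5
    nuclear_depth_max: int = 100
    mito_depth_min: int = 350
    mq_min: float = 20.0
    alt_support_min: int = 5
    indel_distance_min: int = 2  # SNVs only
    require_homozygous: bool = True

    def __post_init__(self) -> None:
        for name in (
            "nuclear_depth_min",
            "nuclear_depth_max",
            "mito_depth_min",
            "mq_min",
            "alt_support_min",
            "indel_distance_min",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.nuclear_depth_min >= self.nuclear_depth_max:
            raise ValueError("nuclear_depth_min must be below nuclear_depth_max")


@dataclass(frozen=True)
class FilterVerdict:
    passed: bool
    reasons: frozenset[str]

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when reasons is empty")


def _verdict(reasons: set[str]) -> FilterVerdict:
    return FilterVerdict(passed=not reasons, reasons=frozenset(reasons))


def annotate_indel_distance(sites: list[VariantSite]) -> list[VariantSite]:
    """Set each SNV's distance (bp) to the nearest indel anchor on the same
    chromosome; infinity when the chromosome carries no indel.

    Input must be sorted by (chromosome, position); distance is the absolute
    difference of VCF anchor positions (no allele-span expansion).
    """
    seen_chroms: list[str] = []
    last_pos = -1
    for s in sites:
        if not seen_chroms or s.chrom != seen_chroms[-1]:
            if s.chrom in seen_chroms:
                raise ValueError(f"sites not sorted: chromosome {s.chrom} repeats")
            seen_chroms.append(s.chrom)
            last_pos = -1
        if s.position < last_pos:
            raise ValueError(
                f"sites not sorted at {s.chrom}:{s.position} (after {last_pos})"
            )
        last_pos = s.position

    by_chrom: dict[str, list[int]] = {}
    for s in sites:
        if s.variant_class != SNV:
            by_chrom.setdefault(s.chrom, []).append(s.position)
    for s in sites:
        if s.variant_class != SNV:
            s.indel_distance = math.inf
            continue
        indels = by_chrom.get(s.chrom)
        if not indels:
            s.indel_distance = math.inf
            continue
        arr = np.asarray(indels)
        i = int(np.searchsorted(arr, s.position))
        best = math.inf
        if i < len(arr):
            best = min(best, abs(int(arr[i]) - s.position))
        if i > 0:
            best = min(best, abs(int(arr[i - 1]) - s.position))
        s.indel_distance = float(best)
    return sites


def filter_site(
    site: VariantSite,
    config: FilterConfig,
    layout: GenomeLayout,
    focal: str,
) -> FilterVerdict:
    """Verdict for one site against the hard filters (total function)."""
    reasons: set[str] = set()
    mito = layout.kind(site.chrom) is ChromKind.MITOCHONDRIAL

    if site.site_depth is None:
        reasons.add("MISSING_STAT")
    elif mito:
        if not site.site_depth > config.mito_depth_min:
            reasons.add("LOW_DP")
    else:
        if not site.site_depth > config.nuclear_depth_min:
            reasons.add("LOW_DP")
        if not site.site_depth < config.nuclear_depth_max:
            reasons.add("HIGH_DP")

    if site.mapping_quality is None:
        reasons.add("MISSING_STAT")
    elif not site.mapping_quality > config.mq_min:
        reasons.add("LOW_MQ")

    if site.alt_support is None:
        reasons.add("MISSING_STAT")
    elif not site.alt_support > config.alt_support_min:
        reasons.add("LOW_ALT_SUPPORT")

    if site.variant_class == SNV and not site.indel_distance > config.indel_distance_min:
        reasons.add("NEAR_INDEL")

    if config.require_homozygous:
        gt = site.genotypes.get(focal)
        if is_missing(gt) or is_het(gt):
            reasons.add("NOT_HOMOZYGOUS")

    return _verdict(reasons)


def filter_all(
    sites: list[VariantSite],
    config: FilterConfig,
    layout: GenomeLayout,
    focal: str,
) -> tuple[list[VariantSite], list[VariantSite], Counter]:
    """Partition sites into (pass, fail) and count failures per reason.

    Vectorized over the site arrays; a site failing several filters counts
    toward each reason. Each returned site carries its verdict in
    ``filter_reasons``.
    """
    n = len(sites)
    if n == 0:
        return [], [], Counter()

    mito_names = {
        c.name for c in layout.chromosomes if c.kind is ChromKind.MITOCHONDRIAL
    }
    # layout.kind raises on unknown chromosomes; check once up front
    known = set(layout.lengths)
    for s in sites:
        if s.chrom not in known:
            raise KeyError(f"unknown chromosome {s.chrom}")

    dp = np.array(
        [-1 if s.site_depth is None else s.site_depth for s in sites], dtype=float
    )
    dp_missing = np.array([s.site_depth is None for s in sites])
    mq = np.array(
        [np.nan if s.mapping_quality is None else s.mapping_quality for s in sites]
    )
    mq_missing = np.isnan(mq)
    alt = np.array(
        [-1 if s.alt_support is None else s.alt_support for s in sites], dtype=float
    )
    alt_missing = np.array([s.alt_support is None for s in sites])
    is_mito = np.array([s.chrom in mito_names for s in sites])
    is_snv = np.array([s.variant_class == SNV for s in sites])
    dist = np.array([s.indel_distance for s in sites])
    focal_bad = np.array(
        [
            is_missing(s.genotypes.get(focal)) or is_het(s.genotypes.get(focal))
            for s in sites
        ]
    )

    low_dp = ~dp_missing & (
        (is_mito & ~(dp > config.mito_depth_min))
        | (~is_mito & ~(dp > config.nuclear_depth_min))
    )
    high_dp = ~dp_missing & ~is_mito & ~(dp < config.nuclear_depth_max)
    low_mq = ~mq_missing & ~(mq > config.mq_min)
    low_alt = ~alt_missing & ~(alt > config.alt_support_min)
    near_indel = is_snv & ~(dist > config.indel_distance_min)
    not_hom = focal_bad if config.require_homozygous else np.zeros(n, dtype=bool)
    missing_stat = dp_missing | mq_missing | alt_missing

    reason_masks = {
        "LOW_DP": low_dp,
        "HIGH_DP": high_dp,
        "LOW_MQ": low_mq,
        "LOW_ALT_SUPPORT": low_alt,
        "NEAR_INDEL": near_indel,
        "NOT_HOMOZYGOUS": not_hom,
        "MISSING_STAT": missing_stat,
    }
    any_fail = np.zeros(n, dtype=bool)
    for m in reason_masks.values():
        any_fail |= m

    passed: list[VariantSite] = []
    failed: list[VariantSite] = []
    counts: Counter = Counter({r: 0 for r in REASONS})
    for i, s in enumerate(sites):
        reasons = frozenset(r for r, m in reason_masks.items() if m[i])
        s.filter_reasons = reasons
        if any_fail[i]:
            failed.append(s)
            for r in reasons:
                counts[r] += 1
        else:
            passed.append(s)
    return passed, failed, counts
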