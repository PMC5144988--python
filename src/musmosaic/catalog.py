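"""Private/shared variant classification and catalog summaries.

A variant is private to a strain when its alternate allele is absent from
every strain in the known-variant panel and carried (homozygous) by exactly
one focal strain; carried by both focal strains and absent from the panel it
is shared exclusively; any panel strain carrying the allele (het counts as
carrying — conservative for novelty claims) makes it known. Privacy is an
allele property: multiallelic sites are classified per alternate allele.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .variants import SNV, SamplePanel, VariantSite, carries, is_hom, is_missing

__all__ = [
    "CATEGORIES",
    "CatalogSummary",
    "PrivacyCall",
    "classify_site",
    "is_transition",
    "summarize_catalog",
]

PRIVATE_A = "private_A"
PRIVATE_B = "private_B"
SHARED_EXCLUSIVE = "shared_exclusive"
KNOWN = "known"
UNCLASSIFIABLE = "unclassifiable"
CATEGORIES = (PRIVATE_A, PRIVATE_B, SHARED_EXCLUSIVE, KNOWN, UNCLASSIFIABLE)

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


@dataclass(frozen=True)
class PrivacyCall:
    category: str
    variant_class: str  # SNV or indel
    alt_index: int = 1


def classify_site(
    site: VariantSite, panel: SamplePanel, alt_index: int = 1
) -> PrivacyCall:
    """Classify one alternate allele of a site.

    Precedence: any known-panel strain carrying the allele decides ``known``
    outright; otherwise a missing panel genotype makes the call
    ``unclassifiable`` (absence cannot be established); otherwise the focal
    homozygous carriers decide private/shared. A site neither focal strain
    carries homozygously is unclassifiable (it is not a variant of either
    focal strain — the pipeline never reaches here with one).
    """
    if not site.alts:
        raise ValueError(f"{site.chrom}:{site.position}: site has no alt allele")
    if not 1 <= alt_index <= len(site.alts):
        raise ValueError(f"alt_index {alt_index} out of range")
    vclass = site.variant_class

    panel_missing = False
    for name in panel.known_panel:
        gt = site.genotypes.get(name)
        if carries(gt, alt_index):
            return PrivacyCall(KNOWN, vclass, alt_index)
        if is_missing(gt):
            panel_missing = True
    if panel_missing:
        return PrivacyCall(UNCLASSIFIABLE, vclass, alt_index)

    hom_carriers = [f for f in panel.focal if is_hom(site.genotypes.get(f), alt_index)]
    if len(hom_carriers) == len(panel.focal) == 2:
        return PrivacyCall(SHARED_EXCLUSIVE, vclass, alt_index)
    if len(hom_carriers) == 1:
        cat = PRIVATE_A if hom_carriers[0] == panel.focal[0] else PRIVATE_B
        return PrivacyCall(cat, vclass, alt_index)
    return PrivacyCall(UNCLASSIFIABLE, vclass, alt_index)


def is_transition(ref: str, alt: str) -> bool:
    """Purine<->purine or pyrimidine<->pyrimidine single-base change."""
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV allele pair: {ref!r}/{alt!r}")
    pair = {ref, alt}
    if pair - (_PURINES | _PYRIMIDINES):
        raise ValueError(f"non-ACGT alleles: {ref!r}/{alt!r}")
    return pair <= _PURINES or pair <= _PYRIMIDINES


@dataclass
class CatalogSummary:
    """Counts per (category, variant class) plus the transition:transversion
    ratio over the novel (non-known) biallelic SNVs."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)
    ts_count: int = 0
    tv_count: int = 0

    @property
    def ts_tv_ratio(self) -> float:
        if self.tv_count == 0:
            return math.nan
        return self.ts_count / self.tv_count

    def total(self, category: str | None = None) -> int:
        return sum(
            n
            for (cat, _), n in self.counts.items()
            if category is None or cat == category
        )


def summarize_catalog(
    calls: list[tuple[VariantSite, PrivacyCall]]
) -> CatalogSummary:
    """Tabulate classification counts and Ts:Tv.

    Counts partition the input; Ts:Tv is computed over novel biallelic SNVs
    (categories other than known/unclassifiable). Order-independent.
    """
    summary = CatalogSummary()
    for cat in CATEGORIES:
        for vclass in (SNV, "indel"):
            summary.counts[(cat, vclass)] = 0
    for site, call in calls:
        summary.counts[(call.category, call.variant_class)] += 1
        if (
            call.category in (PRIVATE_A, PRIVATE_B, SHARED_EXCLUSIVE)
            and site.is_biallelic_snv
        ):
            if is_transition(site.ref, site.alts[0]):
                summary.ts_count += 1
            else:
                summary.tv_count += 1
    return summary
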