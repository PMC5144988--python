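"""Variant records and I/O for the supported VCF v4.2 subset.

Fields used: CHROM POS REF ALT FILTER INFO{DP, MQ, DP4 or AD} FORMAT{GT}.
Alt-supporting read count is the sum of the two alt-strand DP4 counts when
DP4 is present, else the alt depth from the focal sample's AD. Genotypes are
stored as allele-index pairs, ``None`` for missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import pysam

from .depth import DEPTH_COLUMNS, DepthTrack
from .genome import GenomeLayout

__all__ = [
    "Genotype",
    "SamplePanel",
    "VariantSite",
    "read_depth_track",
    "read_vcf",
    "write_depth_track",
    "write_vcf",
]

Genotype = tuple[int, int] | None

SNV = "SNV"
INDEL = "indel"
MAX_INDEL_LEN = 10  # in-scope small indels have |len(ref)-len(alt)| < 10


def is_missing(gt: Genotype) -> bool:
    return gt is None or None in gt


def is_het(gt: Genotype) -> bool:
    return not is_missing(gt) and gt[0] != gt[1]


def is_hom(gt: Genotype, allele: int) -> bool:
    return not is_missing(gt) and gt[0] == allele and gt[1] == allele


def carries(gt: Genotype, allele: int) -> bool:
    """Whether the genotype includes at least one copy of ``allele``."""
    return not is_missing(gt) and allele in gt


def trim_shared_prefix(ref: str, alt: str) -> tuple[str, str, int]:
    """Left-trim the shared prefix of a ref/alt pair, keeping one anchor base.

    Returns (ref, alt, offset) where offset is the number of bases trimmed.
    No full left-alignment is attempted (no reference FASTA in scope).
    """
    off = 0
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        off += 1
    return ref, alt, off


@dataclass
class VariantSite:
    """One candidate variant site with its quality statistics and genotypes.

    ``position`` is 1-based as in VCF. ``site_depth`` (DP), ``mapping_quality``
    (MQ) and ``alt_support`` may be None when absent from the record; filters
    that need them then fail with MISSING_STAT.
    """

    chrom: str
    position: int
    ref: str
    alts: list[str]
    site_depth: int | None
    mapping_quality: float | None
    alt_support: int | None
    genotypes: dict[str, Genotype]
    filter_reasons: frozenset[str] | None = None  # None = not yet filtered
    indel_distance: float = math.inf

    def __post_init__(self) -> None:
        alleles = [self.ref, *self.alts]
        for a in alleles:
            if not a or set(a) - set("ACGT"):
                raise ValueError(
                    f"{self.chrom}:{self.position}: allele {a!r} must be "
                    "non-empty uppercase A/C/G/T"
                )
        if self.site_depth is not None and self.alt_support is not None:
            if not (self.site_depth >= self.alt_support >= 0):
                raise ValueError(
                    f"{self.chrom}:{self.position}: need "
                    "site_depth >= alt_support >= 0"
                )

    @property
    def multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and all(len(a) == 1 for a in self.alts):
            return SNV
        return INDEL

    @property
    def is_biallelic_snv(self) -> bool:
        return not self.multiallelic and self.variant_class == SNV

    @property
    def passed(self) -> bool:
        return self.filter_reasons is not None and len(self.filter_reasons) == 0


@dataclass
class SamplePanel:
    """Sample roles: one or two focal strains, one representative per
    subspecies (dom/mus/cas), an outgroup assumed ancestral, and an optional
    panel of previously sequenced strains (the known-variant catalog)."""

    focal: list[str]
    representatives: dict[str, str]  # keys: dom, mus, cas
    outgroup: str
    known_panel: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.focal) <= 2:
            raise ValueError("panel needs 1 or 2 focal samples")
        if set(self.representatives) != {"dom", "mus", "cas"}:
            raise ValueError("representatives must map exactly dom, mus, cas")
        names = self.all_samples
        if len(set(names)) != len(names):
            raise ValueError("sample names must be distinct")

    @property
    def all_samples(self) -> list[str]:
        return [
            *self.focal,
            *self.representatives.values(),
            self.outgroup,
            *self.known_panel,
        ]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SamplePanel":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            focal=list(doc["focal"]),
            representatives=dict(doc["representatives"]),
            outgroup=doc["outgroup"],
            known_panel=list(doc.get("known_panel", [])),
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "focal": self.focal,
                    "representatives": self.representatives,
                    "outgroup": self.outgroup,
                    "known_panel": self.known_panel,
                },
                fh,
                sort_keys=False,
            )


def _site_from_record(rec: pysam.VariantRecord, panel: SamplePanel) -> VariantSite:
    info = rec.info
    dp = int(info["DP"]) if "DP" in info else None
    mq = float(info["MQ"]) if "MQ" in info else None
    alt_support: int | None = None
    if "DP4" in info:
        dp4 = info["DP4"]
        alt_support = int(dp4[2]) + int(dp4[3])
    genotypes: dict[str, Genotype] = {}
    for name in panel.all_samples:
        gt = rec.samples[name].get("GT")
        if gt is None or any(a is None for a in gt):
            genotypes[name] = None
        else:
            genotypes[name] = (int(gt[0]), int(gt[1]))
    if alt_support is None:
        ad = rec.samples[panel.focal[0]].get("AD")
        if ad is not None and len(ad) > 1 and ad[1] is not None:
            alt_support = sum(int(a) for a in ad[1:] if a is not None)
    reasons: frozenset[str] | None = None
    if rec.filter.keys():
        keys = [k for k in rec.filter.keys() if k != "PASS"]
        reasons = frozenset(keys)
    return VariantSite(
        chrom=rec.chrom,
        position=rec.pos,
        ref=rec.ref,
        alts=list(rec.alts or ()),
        site_depth=dp,
        mapping_quality=mq,
        alt_support=alt_support,
        genotypes=genotypes,
        filter_reasons=reasons,
    )


def read_vcf(path: str | Path, panel: SamplePanel) -> Iterator[VariantSite]:
    """Stream VariantSites from a VCF in file order (gzip-transparent).

    All panel samples must be present in the header; a missing sample is
    fatal with its name. A record pysam cannot parse aborts the stream with
    the record index reported — records are never silently dropped.
    """
    with pysam.VariantFile(str(path)) as vf:
        have = set(vf.header.samples)
        missing = [s for s in panel.all_samples if s not in have]
        if missing:
            raise ValueError(f"VCF is missing required samples: {missing}")
        n = 0
        try:
            for rec in vf:
                n += 1
                yield _site_from_record(rec, panel)
        except (ValueError, OSError) as exc:
            raise ValueError(f"malformed VCF record after record {n}: {exc}") from exc


FILTER_DESCRIPTIONS = {
    "LOW_DP": "site depth at or below the minimum",
    "HIGH_DP": "site depth at or above the nuclear maximum",
    "LOW_MQ": "mapping quality at or below the minimum",
    "LOW_ALT_SUPPORT": "too few reads supporting the alternate allele",
    "NEAR_INDEL": "SNV within the exclusion distance of an indel",
    "NOT_HOMOZYGOUS": "focal genotype heterozygous or missing",
    "MISSING_STAT": "a statistic required by a filter is absent",
}


def write_vcf(
    sites: Iterable[VariantSite],
    path: str | Path,
    samples: list[str],
    layout: GenomeLayout | None = None,
) -> None:
    """Write sites as VCF v4.2. FILTER is PASS / semicolon-joined reason
    codes / '.' for unfiltered sites. Round-trips losslessly with read_vcf
    for the supported subset."""
    header = pysam.VariantHeader()
    header.add_line("##source=musmosaic")
    header.info.add("DP", 1, "Integer", "Raw read depth at the site")
    header.info.add("MQ", 1, "Float", "RMS mapping quality")
    header.info.add(
        "DP4", 4, "Integer", "Ref-fwd, ref-rev, alt-fwd, alt-rev read counts"
    )
    header.formats.add("GT", 1, "String", "Genotype")
    for code, desc in FILTER_DESCRIPTIONS.items():
        header.filters.add(code, None, None, desc)
    sites = list(sites)
    if layout is not None:
        for c in layout.chromosomes:
            header.contigs.add(c.name, length=c.length)
    else:
        seen: dict[str, None] = {}
        for s in sites:
            seen.setdefault(s.chrom)
        for name in seen:
            header.contigs.add(name)
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for site in sites:
            rec = out.new_record(
                contig=site.chrom,
                start=site.position - 1,
                alleles=(site.ref, *site.alts),
            )
            if site.site_depth is not None:
                rec.info["DP"] = site.site_depth
            if site.mapping_quality is not None:
                rec.info["MQ"] = site.mapping_quality
            if site.alt_support is not None and site.site_depth is not None:
                ref_reads = site.site_depth - site.alt_support
                rec.info["DP4"] = (
                    ref_reads - ref_reads // 2,
                    ref_reads // 2,
                    site.alt_support - site.alt_support // 2,
                    site.alt_support // 2,
                )
            for name in samples:
                gt = site.genotypes.get(name)
                rec.samples[name]["GT"] = (None, None) if is_missing(gt) else gt
            if site.filter_reasons is not None:
                if site.filter_reasons:
                    for code in sorted(site.filter_reasons):
                        rec.filter.add(code)
                else:
                    rec.filter.add("PASS")
            out.write(rec)


def read_depth_track(
    path: str | Path, layout: GenomeLayout, sample: str | None = None
) -> DepthTrack:
    """Read a windowed depth TSV (chrom, start, end, depth_mq20, depth_total).

    Windows are validated against the layout; depth_mq20 <= depth_total and
    non-negative depths are enforced (violations name the offending row).
    """
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in DEPTH_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"depth track {path} missing columns: {missing}")
    lengths = layout.lengths
    for _, row in frame.iterrows():
        if row["chrom"] not in lengths:
            raise ValueError(f"depth window on unknown chromosome {row['chrom']}")
        if row["start"] < 0 or row["end"] > lengths[row["chrom"]]:
            raise ValueError(
                "depth window outside chromosome: "
                f"{row['chrom']}:{int(row['start'])}-{int(row['end'])}"
            )
    name = sample if sample is not None else Path(path).stem
    return DepthTrack(name, frame[DEPTH_COLUMNS].copy())


def write_depth_track(track: DepthTrack, path: str | Path) -> None:
    track.frame.to_csv(path, sep="\t", index=False)
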