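"""Genome coordinate system: layout, intervals, windows, and masks.

All coordinates are 0-based half-open internally (the BED convention).
VCF positions (1-based) are converted at the I/O boundary.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ChromKind",
    "Chromosome",
    "GenomeLayout",
    "Interval",
    "MaskTrack",
    "make_windows",
    "mask_overlap_fraction",
    "normalize_mask",
    "read_bed",
    "write_bed",
]

DEFAULT_CENTROMERE_PROXIMAL_BP = 5_000_000


class ChromKind(str, Enum):
    AUTOSOME = "autosome"
    X = "X"
    MITOCHONDRIAL = "mitochondrial"


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersection_length(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    kind: ChromKind


@dataclass
class GenomeLayout:
    """Chromosome names/lengths/kinds plus annotations used downstream.

    ``centromere_proximal`` maps chromosome name to the interval adjacent to
    its centromere (mouse chromosomes are acrocentric, so the low-coordinate
    end). ``rb_chromosomes`` lists chromosomes involved in Robertsonian
    fusions in the focal strain.
    """

    chromosomes: list[Chromosome]
    centromere_proximal: dict[str, Interval] = field(default_factory=dict)
    rb_chromosomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for c in self.chromosomes:
            if c.length <= 0:
                raise ValueError(f"chromosome {c.name} has non-positive length")
            if not isinstance(c.kind, ChromKind):
                raise ValueError(f"chromosome {c.name}: unknown kind {c.kind!r}")
        lengths = self.lengths
        for name, iv in self.centromere_proximal.items():
            if name not in lengths:
                raise ValueError(f"centromere interval on unknown chromosome {name}")
            if iv.chrom != name or iv.start < 0 or iv.end > lengths[name]:
                raise ValueError(
                    f"centromere interval {iv} outside chromosome {name}"
                )
        unknown = self.rb_chromosomes - set(names)
        if unknown:
            raise ValueError(f"rb_chromosomes not in layout: {sorted(unknown)}")

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def kind(self, chrom: str) -> ChromKind:
        for c in self.chromosomes:
            if c.name == chrom:
                return c.kind
        raise KeyError(f"unknown chromosome {chrom}")

    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.kind is ChromKind.AUTOSOME]

    def nuclear(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.kind is not ChromKind.MITOCHONDRIAL]

    def with_default_centromeres(
        self, radius: int = DEFAULT_CENTROMERE_PROXIMAL_BP
    ) -> "GenomeLayout":
        """Set centromere-proximal intervals to the first ``radius`` bp of
        each nuclear chromosome (truncated at the chromosome end)."""
        cen = {
            c.name: Interval(c.name, 0, min(radius, c.length))
            for c in self.nuclear()
        }
        return GenomeLayout(self.chromosomes, cen, set(self.rb_chromosomes))

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        centromere_bed: str | Path | None = None,
        centromere_radius: int = DEFAULT_CENTROMERE_PROXIMAL_BP,
    ) -> "GenomeLayout":
        """Read a layout TSV with columns name, length, kind and an optional
        fourth column rb (0/1) marking Robertsonian-fusion chromosomes."""
        chroms: list[Chromosome] = []
        rb: set[str] = set()
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"layout row needs >=3 columns: {line!r}")
                name, length, kind = parts[0], int(parts[1]), parts[2]
                try:
                    k = ChromKind(kind)
                except ValueError:
                    raise ValueError(
                        f"chromosome {name}: unknown kind {kind!r}"
                    ) from None
                chroms.append(Chromosome(name, length, k))
                if len(parts) >= 4 and parts[3].strip() in {"1", "rb", "true"}:
                    rb.add(name)
        layout = cls(chroms, {}, rb).with_default_centromeres(centromere_radius)
        if centromere_bed is not None:
            cen = {iv.chrom: iv for iv in read_bed(centromere_bed)}
            layout = cls(chroms, cen, rb)
        return layout

    def to_table(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                rb = "1" if c.name in self.rb_chromosomes else "0"
                fh.write(f"{c.name}\t{c.length}\t{c.kind.value}\t{rb}\n")


def make_windows(layout: GenomeLayout, width: int) -> list[Interval]:
    """Tile each chromosome with consecutive half-open windows of ``width``
    bp; the final window is truncated at the chromosome end. Every base is
    covered exactly once."""
    if width <= 0:
        raise ValueError("window width must be positive")
    windows: list[Interval] = []
    for c in layout.chromosomes:
        for start in range(0, c.length, width):
            windows.append(Interval(c.name, start, min(start + width, c.length)))
    return windows


class MaskTrack:
    """Normalized (sorted, disjoint) set of masked intervals.

    Build via :func:`normalize_mask`. Overlap queries run on per-chromosome
    sorted coordinate arrays.
    """

    def __init__(self, intervals: Sequence[Interval]):
        # assumes already normalized; normalize_mask is the public entry
        self.intervals: list[Interval] = list(intervals)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        by_chrom: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            self._starts[chrom] = np.array([iv.start for iv in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([iv.end for iv in ivs], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def total_masked(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def overlap_bases(self, window: Interval) -> int:
        starts = self._starts.get(window.chrom)
        if starts is None:
            return 0
        ends = self._ends[window.chrom]
        i0 = int(np.searchsorted(ends, window.start, side="right"))
        i1 = int(np.searchsorted(starts, window.end, side="left"))
        if i1 <= i0:
            return 0
        lo = np.maximum(starts[i0:i1], window.start)
        hi = np.minimum(ends[i0:i1], window.end)
        return int(np.sum(hi - lo))


def normalize_mask(
    intervals: Iterable[Interval], layout: GenomeLayout | None = None
) -> MaskTrack:
    """Merge overlapping and adjacent intervals into a sorted disjoint set.

    With a layout, intervals must lie on known chromosomes and within bounds.
    """
    ivs = sorted(intervals)
    if layout is not None:
        lengths = layout.lengths
        for iv in ivs:
            if iv.chrom not in lengths:
                raise ValueError(f"mask interval on unknown chromosome: {iv}")
            if iv.end > lengths[iv.chrom]:
                raise ValueError(f"mask interval exceeds chromosome bounds: {iv}")
    merged: list[Interval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = Interval(prev.chrom, prev.start, iv.end)
        else:
            merged.append(iv)
    return MaskTrack(merged)


def mask_overlap_fraction(window: Interval, mask: MaskTrack) -> float:
    """Fraction of the window's bases covered by the mask, in [0, 1]."""
    return mask.overlap_bases(window) / window.length


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_bed(path: str | Path) -> list[Interval]:
    """Read a >=3 column BED file (gzip-transparent) into intervals."""
    out: list[Interval] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"BED row needs >=3 columns: {line!r}")
            out.append(Interval(parts[0], int(parts[1]), int(parts[2])))
    return out


def write_bed(
    intervals: Iterable[Interval],
    path: str | Path,
    names: Iterable[str] | None = None,
) -> None:
    """Write intervals as BED3, or BED4 when per-interval names are given."""
    with open(path, "w") as fh:
        if names is None:
            for iv in intervals:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
        else:
            for iv, name in zip(intervals, names):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
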