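"""Windowed read-depth analytics.

Depth enters as per-window means (no per-base pileups): normalization to the
autosome-wide median, genetic-sex inference from the X:autosome depth ratio,
callable-genome fraction, a run-length CNV screen against a panel of control
tracks, and the centromere-proximal check for Robertsonian-fusion
chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import ChromKind, GenomeLayout, Interval

__all__ = [
    "CnvCall",
    "CnvConfig",
    "DepthTrack",
    "SexCall",
    "call_cnvs",
    "callable_fraction",
    "centromere_screen",
    "infer_sex",
    "normalize_depth",
]

DEPTH_COLUMNS = ["chrom", "start", "end", "depth_mq20", "depth_total"]


@dataclass
class DepthTrack:
    """Per-window mean depths for one sample.

    ``frame`` has columns chrom, start, end, depth_mq20 (reads with mapping
    quality > 20), depth_total. ``normalized`` marks tracks already divided
    by the autosomal median (ratio scale).
    """

    sample: str
    frame: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in DEPTH_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"depth track missing columns: {missing}")
        f = self.frame
        if (f["depth_mq20"] < 0).any() or (f["depth_total"] < 0).any():
            bad = f.index[(f["depth_mq20"] < 0) | (f["depth_total"] < 0)][0]
            raise ValueError(f"negative depth at row {bad}")
        over = f["depth_mq20"] > f["depth_total"] + 1e-9
        if over.any():
            row = f[over].iloc[0]
            raise ValueError(
                "depth_mq20 exceeds depth_total at "
                f"{row['chrom']}:{int(row['start'])}-{int(row['end'])}"
            )

    @property
    def n_windows(self) -> int:
        return len(self.frame)

    def window_lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    def same_grid(self, other: "DepthTrack") -> bool:
        a, b = self.frame, other.frame
        return len(a) == len(b) and bool(
            (a["chrom"].to_numpy() == b["chrom"].to_numpy()).all()
            and (a["start"].to_numpy() == b["start"].to_numpy()).all()
            and (a["end"].to_numpy() == b["end"].to_numpy()).all()
        )


@dataclass(frozen=True)
class SexCall:
    label: str  # "male" or "female"
    x_auto_ratio: float


@dataclass(frozen=True)
class CnvCall:
    interval: Interval
    kind: str  # "deletion" or "duplication"
    mean_ratio: float
    n_windows: int
    private: bool


@dataclass
class CnvConfig:
    """Thresholds for the windowed CNV screen (all on the normalized-ratio
    scale). A run of at least ``min_consecutive`` adjacent windows below
    ``del_ratio`` (or above ``dup_ratio``) becomes a call; a call is private
    when every panel track stays within ``panel_normal`` over the same span.
    """

    min_consecutive: int = 3
    del_ratio: float = 0.25
    dup_ratio: float = 1.5
    panel_normal: tuple[float, float] = (0.75, 1.25)


def _kinds(track: DepthTrack, layout: GenomeLayout) -> pd.Series:
    kind_of = {c.name: c.kind for c in layout.chromosomes}
    unknown = set(track.frame["chrom"]) - set(kind_of)
    if unknown:
        raise ValueError(f"depth track on unknown chromosomes: {sorted(unknown)}")
    return track.frame["chrom"].map(kind_of)


def normalize_depth(track: DepthTrack, layout: GenomeLayout) -> DepthTrack:
    """Divide window depths by the autosome-wide median depth_mq20.

    The autosomal median of the returned ratios is 1 by construction, so the
    operation is idempotent.
    """
    kinds = _kinds(track, layout)
    auto = track.frame.loc[kinds == ChromKind.AUTOSOME, "depth_mq20"]
    if len(auto) == 0:
        raise ValueError("track has no autosomal windows")
    med = float(auto.median())
    if med <= 0:
        raise ValueError("autosomal median depth is zero; cannot normalize")
    f = track.frame.copy()
    f["depth_mq20"] = f["depth_mq20"] / med
    f["depth_total"] = f["depth_total"] / med
    return DepthTrack(track.sample, f, normalized=True)


def infer_sex(
    track: DepthTrack, layout: GenomeLayout, male_below: float = 0.75
) -> SexCall:
    """Infer genetic sex from relative X-chromosome depth.

    The ratio is the median normalized depth over X windows (autosomal median
    is 1). One X in males halves relative X depth, so ratio < ``male_below``
    is called male; the boundary itself is assigned female.
    """
    norm = track if track.normalized else normalize_depth(track, layout)
    kinds = _kinds(norm, layout)
    x = norm.frame.loc[kinds == ChromKind.X, "depth_mq20"]
    if len(x) == 0:
        raise ValueError("track has no X-chromosome windows")
    ratio = float(x.median())
    return SexCall("male" if ratio < male_below else "female", ratio)


def callable_fraction(track: DepthTrack, threshold: float = 10.0) -> float:
    """Length-weighted fraction of bases in windows with raw depth_mq20 at
    least ``threshold`` (inclusive)."""
    if track.normalized:
        raise ValueError("callable_fraction needs raw (unnormalized) depths")
    lengths = track.window_lengths()
    total = lengths.sum()
    if total == 0:
        return 0.0
    ok = (track.frame["depth_mq20"].to_numpy() >= threshold)
    return float(lengths[ok].sum() / total)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open index ranges."""
    out = []
    i, n = 0, len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def call_cnvs(
    focal: DepthTrack,
    panel: list[DepthTrack],
    config: CnvConfig | None = None,
) -> list[CnvCall]:
    """Screen a normalized focal track for deletion/duplication runs.

    All tracks must share the window grid. A call is marked private when the
    mean ratio of every panel track over the call interval lies inside the
    normal band — i.e. the deviation is seen in the focal sample only.
    """
    config = config or CnvConfig()
    if not focal.normalized or any(not p.normalized for p in panel):
        raise ValueError("call_cnvs expects normalized tracks")
    for p in panel:
        if not focal.same_grid(p):
            raise ValueError(
                f"panel track {p.sample} window grid disagrees with focal"
            )
    calls: list[CnvCall] = []
    f = focal.frame
    for chrom, sub in f.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        ratio = sub["depth_mq20"].to_numpy()
        for kind, flags in (
            ("deletion", ratio < config.del_ratio),
            ("duplication", ratio > config.dup_ratio),
        ):
            for i, j in _runs(flags):
                if j - i < config.min_consecutive:
                    continue
                rows = idx[i:j]
                iv = Interval(
                    chrom,
                    int(f.loc[rows[0], "start"]),
                    int(f.loc[rows[-1], "end"]),
                )
                private = True
                for p in panel:
                    m = float(p.frame.loc[rows, "depth_mq20"].mean())
                    if not (config.panel_normal[0] <= m <= config.panel_normal[1]):
                        private = False
                        break
                calls.append(
                    CnvCall(
                        interval=iv,
                        kind=kind,
                        mean_ratio=float(ratio[i:j].mean()),
                        n_windows=j - i,
                        private=private,
                    )
                )
    return calls


def centromere_screen(calls: list[CnvCall], layout: GenomeLayout) -> pd.DataFrame:
    """Report private CNV calls overlapping the centromere-proximal interval
    of each Robertsonian-fusion chromosome.

    Every Rb chromosome gets a row even with zero overlapping calls, so an
    empty screen is an explicit negative finding.
    """
    rows = []
    for chrom in sorted(layout.rb_chromosomes, key=layout.names.index):
        region = layout.centromere_proximal.get(chrom)
        if region is None:
            raise ValueError(f"no centromere-proximal interval for {chrom}")
        hits = [
            c for c in calls if c.private and c.interval.overlaps(region)
        ]
        rows.append(
            {
                "chrom": chrom,
                "region_start": region.start,
                "region_end": region.end,
                "n_private_calls": len(hits),
                "calls": ";".join(
                    f"{c.kind}:{c.interval.start}-{c.interval.end}" for c in hits
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "region_start", "region_end", "n_private_calls", "calls"],
    )
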