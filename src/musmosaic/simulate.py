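"""Synthetic study inputs with known truth.

Generates, from a single seed, everything the pipeline consumes: a variant
panel whose focal genome is an ancestry mosaic over three subspecies (with a
truth segment track), privacy categories realized in the panel genotypes, an
outgroup carrying the ancestral allele at polarizable sites, an
introgression/contamination mask, and windowed depth tracks with
sex-dependent X depth and injectable copy-number changes.

Sharing patterns are generated directly (no coalescent machinery): the
downstream statistic consumes only sharing patterns, so simulating them
keeps the truth exact at desk scale. The noise channel (exclusive sharing
with a wrong representative) stands in for incomplete lineage sorting and
homoplasy.

Randomness uses one root ``numpy.random.SeedSequence`` split into named
child streams (mosaic, variants, mask, one per depth track), so adding a
component never perturbs earlier streams.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .depth import DepthTrack
from .genome import (
    ChromKind,
    GenomeLayout,
    Interval,
    MaskTrack,
    make_windows,
    normalize_mask,
    write_bed,
)
from .variants import SamplePanel, VariantSite, write_depth_track, write_vcf

__all__ = [
    "SimConfig",
    "SimResult",
    "TruthSet",
    "default_layout",
    "default_panel",
    "simulate_all",
    "simulate_depth",
    "simulate_mask",
    "simulate_mosaic",
    "simulate_variants",
    "window_truth",
    "write_simulation",
]

FOCAL_A = "focalA"
FOCAL_B = "focalB"
REPS = {"dom": "rep_dom", "mus": "rep_mus", "cas": "rep_cas"}
OUTGROUP = "outgroup"
KNOWN_PANEL = ["panel1", "panel2", "panel3"]

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

# expected Ts:Tv of 2.14 among simulated SNVs
DEFAULT_P_TRANSITION = 2.14 / 3.14


def default_panel() -> SamplePanel:
    return SamplePanel(
        focal=[FOCAL_A, FOCAL_B],
        representatives=dict(REPS),
        outgroup=OUTGROUP,
        known_panel=list(KNOWN_PANEL),
    )


def default_layout(
    n_autosomes: int = 5,
    autosome_length: int = 10_000_000,
    x_length: int = 10_000_000,
    mito_length: int = 16_299,
    rb_chromosomes: tuple[str, ...] = ("chr1", "chr3"),
) -> GenomeLayout:
    """Small mouse-like layout: acrocentric autosomes, an X, and a
    mitochondrion, with centromere-proximal = the first 5 Mb."""
    from .genome import Chromosome

    chroms = [
        Chromosome(f"chr{i + 1}", autosome_length, ChromKind.AUTOSOME)
        for i in range(n_autosomes)
    ]
    chroms.append(Chromosome("chrX", x_length, ChromKind.X))
    chroms.append(Chromosome("chrM", mito_length, ChromKind.MITOCHONDRIAL))
    names = {c.name for c in chroms}
    rb = set(rb_chromosomes) & names
    return GenomeLayout(chroms, {}, rb).with_default_centromeres()


@dataclass
class SimConfig:
    """Study conditions for one synthetic genome.

    Defaults emulate the sequenced wild-derived strains: ~18x autosomal
    depth, a genome that is ~92% M. m. domesticus with minority introgressed
    ancestry, 19% of the genome masked, one candidate variant per ~500 bp,
    and sharing/polarization rates that leave most windows decisively
    paintable while keeping the recovery task non-trivial.
    """

    layout: GenomeLayout = field(default_factory=default_layout)
    seed: int = 0
    # variants
    snv_density: float = 1 / 500
    indel_fraction: float = 0.1
    p_transition: float = DEFAULT_P_TRANSITION
    pass_fraction: float = 0.9
    privacy_spec: dict[str, float] = field(
        default_factory=lambda: {
            "private_A": 0.33,
            "private_B": 0.33,
            "shared_exclusive": 0.14,
            "known": 0.20,
        }
    )
    # ancestry
    mosaic_spec: dict[str, float] = field(
        default_factory=lambda: {"dom": 0.92, "mus": 0.08}
    )
    segment_length_mean: int = 1_000_000
    p_polarizable: float = 0.9
    p_exclusive_correct: float = 0.8
    p_noise_share: float = 0.05
    p_rep_missing: float = 0.02
    mask_fraction: float = 0.19
    # depth
    sex: str = "female"
    depth_mean: float = 18.0
    depth_dispersion: float = 0.02  # window read-count var = n + 0.02 n^2
    read_length: int = 100
    mito_depth_mean: float = 1000.0
    depth_window: int = 25_000
    cnv_spec: list[tuple[Interval, float]] = field(default_factory=list)
    n_depth_panel: int = 3

    def __post_init__(self) -> None:
        for name in (
            "p_transition",
            "pass_fraction",
            "p_polarizable",
            "p_exclusive_correct",
            "p_noise_share",
            "p_rep_missing",
            "mask_fraction",
            "indel_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} not a probability")
        if self.snv_density <= 0:
            raise ValueError("snv_density must be positive")
        if abs(sum(self.mosaic_spec.values()) - 1) > 1e-9:
            raise ValueError("mosaic_spec fractions must sum to 1")
        if abs(sum(self.privacy_spec.values()) - 1) > 1e-9:
            raise ValueError("privacy_spec proportions must sum to 1")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be male or female")

    @classmethod
    def from_dict(cls, doc: dict, seed: int | None = None) -> "SimConfig":
        """Build a config from a plain mapping (YAML-friendly).

        ``layout`` may be a mapping of :func:`default_layout` arguments or a
        path to a layout TSV; ``cnv_spec`` entries are
        [chrom, start, end, copy_ratio] lists.
        """
        doc = dict(doc)
        if seed is not None:
            doc["seed"] = seed
        layout = doc.get("layout")
        if isinstance(layout, dict):
            if "rb_chromosomes" in layout:
                layout["rb_chromosomes"] = tuple(layout["rb_chromosomes"])
            doc["layout"] = default_layout(**layout)
        elif isinstance(layout, str):
            doc["layout"] = GenomeLayout.from_table(layout)
        if "cnv_spec" in doc:
            doc["cnv_spec"] = [
                (Interval(c, int(s), int(e)), float(r))
                for c, s, e, r in doc["cnv_spec"]
            ]
        return cls(**doc)

    def streams(self) -> dict[str, np.random.Generator]:
        root = np.random.SeedSequence(self.seed)
        names = ["mosaic", "variants", "mask", "depth_focal"] + [
            f"depth_panel{i}" for i in range(self.n_depth_panel)
        ]
        children = root.spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass
class TruthSet:
    ancestry_segments: list[tuple[Interval, str]]
    privacy_truth: dict[tuple[str, int], str]
    cnv_truth: list[tuple[Interval, str]]
    sex_truth: str


@dataclass
class SimResult:
    config: SimConfig
    panel: SamplePanel
    sites: list[VariantSite]
    truth: TruthSet
    mask: MaskTrack
    depth: dict[str, DepthTrack]  # focal sample first, then depth panel


def simulate_mosaic(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[tuple[Interval, str]]:
    """Partition each nuclear chromosome into ancestry segments.

    Segment lengths are exponential with mean ``segment_length_mean``; the
    ancestry of each new segment is drawn with weights proportional to each
    ancestry's remaining base-pair deficit against its target fraction, a
    self-correcting scheme that keeps realized fractions within a few
    tenths of a point of targets on genomes of >= 100 expected segments.
    """
    rng = rng or config.streams()["mosaic"]
    labels = list(config.mosaic_spec)
    targets = np.array([config.mosaic_spec[k] for k in labels], dtype=float)
    nuclear = config.layout.nuclear()
    total = sum(c.length for c in nuclear)
    if total < config.segment_length_mean:
        warnings.warn(
            "genome shorter than one expected segment; emitting single segments",
            stacklevel=2,
        )
    assigned = np.zeros(len(labels))
    segments: list[tuple[Interval, str]] = []
    done = 0
    for chrom in nuclear:
        pos = 0
        while pos < chrom.length:
            length = max(1, int(rng.exponential(config.segment_length_mean)))
            length = min(length, chrom.length - pos)
            deficit = np.maximum(targets * (done + length) - assigned, 0.0)
            weights = deficit if deficit.sum() > 0 else targets
            k = int(rng.choice(len(labels), p=weights / weights.sum()))
            segments.append((Interval(chrom.name, pos, pos + length), labels[k]))
            assigned[k] += length
            done += length
            pos += length
    return segments


def _derive_privacy(
    genotypes: dict[str, tuple[int, int] | None], panel: SamplePanel
) -> str:
    """Straight-line privacy rule applied to the genotypes as emitted, so
    the recorded truth always matches the realized data."""

    def missing(gt):
        return gt is None or None in gt

    for name in panel.known_panel:
        gt = genotypes[name]
        if not missing(gt) and 1 in gt:
            return "known"
    if any(missing(genotypes[name]) for name in panel.known_panel):
        return "unclassifiable"
    hom = [
        f for f in panel.focal if not missing(genotypes[f]) and genotypes[f] == (1, 1)
    ]
    if len(hom) == 2:
        return "shared_exclusive"
    if len(hom) == 1:
        return "private_A" if hom[0] == panel.focal[0] else "private_B"
    return "unclassifiable"


def simulate_variants(
    config: SimConfig,
    segments: list[tuple[Interval, str]],
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantSite], dict[tuple[str, int], str]]:
    """Place candidate variants by a Poisson process and realize genotypes.

    Per site: the privacy category (drawn from ``privacy_spec``) fixes the
    focal and known-panel genotypes; the segment ancestry fixes the
    representative sharing pattern (exclusive-correct / exclusive-wrong /
    non-exclusive); the outgroup is homozygous ancestral (= reference) with
    probability ``p_polarizable``, else heterozygous or missing. Site
    statistics are drawn so that ``pass_fraction`` of sites satisfy the hard
    filters, the rest violating one filter chosen at random.
    """
    rng = rng or config.streams()["variants"]
    panel = default_panel()
    starts_tmp: dict[str, list[int]] = {}
    anc_tmp: dict[str, list[str]] = {}
    for iv, anc in segments:
        starts_tmp.setdefault(iv.chrom, []).append(iv.start)
        anc_tmp.setdefault(iv.chrom, []).append(anc)
    seg_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {
        c: (np.array(starts_tmp[c]), anc_tmp[c]) for c in starts_tmp
    }

    categories = list(config.privacy_spec)
    cat_p = np.array([config.privacy_spec[c] for c in categories])
    rep_names = list(REPS)  # dom, mus, cas

    sites: list[VariantSite] = []
    privacy_truth: dict[tuple[str, int], str] = {}

    for chrom in config.layout.chromosomes:
        mito = chrom.kind is ChromKind.MITOCHONDRIAL
        n = int(rng.poisson(chrom.length * config.snv_density))
        if n == 0:
            continue
        positions = np.unique(rng.integers(1, chrom.length + 1, size=n))
        for pos in positions:
            pos = int(pos)
            genotypes: dict[str, tuple[int, int] | None] = {}

            # alleles
            is_indel = (not mito) and rng.random() < config.indel_fraction
            ref_base = _BASES[rng.integers(4)]
            if is_indel:
                d = int(rng.integers(1, 10))
                tail = "".join(_BASES[i] for i in rng.integers(0, 4, size=d))
                if rng.random() < 0.5:
                    ref, alt = ref_base, ref_base + tail  # insertion
                else:
                    ref, alt = ref_base + tail, ref_base  # deletion
            else:
                ref = ref_base
                if rng.random() < config.p_transition:
                    alt = _TRANSITION[ref]
                else:
                    tv = [b for b in _BASES if b != ref and b != _TRANSITION[ref]]
                    alt = tv[int(rng.integers(2))]

            # privacy category -> focal + known-panel genotypes
            category = categories[int(rng.choice(len(categories), p=cat_p))]
            genotypes[FOCAL_A] = (0, 0) if category == "private_B" else (1, 1)
            genotypes[FOCAL_B] = (0, 0) if category == "private_A" else (1, 1)
            for name in KNOWN_PANEL:
                genotypes[name] = (0, 0)
            if category == "known":
                genotypes[KNOWN_PANEL[int(rng.integers(len(KNOWN_PANEL)))]] = (1, 1)

            # outgroup polarization
            if rng.random() < config.p_polarizable:
                genotypes[OUTGROUP] = (0, 0)
            else:
                genotypes[OUTGROUP] = (0, 1) if rng.random() < 0.5 else None

            # representative sharing driven by local ancestry
            if mito:
                ancestry = None
            else:
                starts, ancs = seg_by_chrom[chrom.name]
                ancestry = ancs[int(np.searchsorted(starts, pos - 1, "right")) - 1]
            for k in rep_names:
                genotypes[REPS[k]] = (0, 0)
            if ancestry in rep_names:
                u = rng.random()
                if u < config.p_exclusive_correct:
                    genotypes[REPS[ancestry]] = (1, 1)
                elif u < config.p_exclusive_correct + config.p_noise_share:
                    others = [k for k in rep_names if k != ancestry]
                    genotypes[REPS[others[int(rng.integers(2))]]] = (1, 1)
                else:
                    mode = int(rng.integers(3))  # none / two / all three share
                    if mode == 1:
                        drop = rep_names[int(rng.integers(3))]
                        for k in rep_names:
                            if k != drop:
                                genotypes[REPS[k]] = (1, 1)
                    elif mode == 2:
                        for k in rep_names:
                            genotypes[REPS[k]] = (1, 1)
            for k in rep_names:
                if rng.random() < config.p_rep_missing:
                    genotypes[REPS[k]] = None

            # site statistics: most sites pass every filter, the rest violate one
            if mito:
                dp_lo, dp_hi = int(config.mito_depth_mean * 0.5), int(
                    config.mito_depth_mean * 1.5
                )
                dp_lo = max(dp_lo, 351)
            else:
                dp_lo, dp_hi = 10, 60
            dp = int(rng.integers(dp_lo, dp_hi + 1))
            mq = float(rng.uniform(30, 60))
            alt_support = int(rng.integers(6, min(dp, 200) + 1))
            if rng.random() >= config.pass_fraction:
                violations = ["low_dp", "low_mq", "low_alt", "het_focal"]
                if not mito:
                    violations.append("high_dp")
                v = violations[int(rng.integers(len(violations)))]
                if v == "low_dp":
                    bound = 350 if mito else 5
                    dp = int(rng.integers(0, bound + 1))
                    alt_support = int(rng.integers(0, dp + 1))
                elif v == "high_dp":
                    dp = int(rng.integers(100, 201))
                    alt_support = int(rng.integers(6, 61))
                elif v == "low_mq":
                    mq = float(rng.uniform(0, 20))
                elif v == "low_alt":
                    alt_support = int(rng.integers(0, 6))
                elif v == "het_focal":
                    which = FOCAL_A if genotypes[FOCAL_A] == (1, 1) else FOCAL_B
                    genotypes[which] = (0, 1)

            site = VariantSite(
                chrom=chrom.name,
                position=pos,
                ref=ref,
                alts=[alt],
                site_depth=dp,
                mapping_quality=mq,
                alt_support=alt_support,
                genotypes=genotypes,
            )
            sites.append(site)
            privacy_truth[(chrom.name, pos)] = _derive_privacy(genotypes, panel)
    return sites, privacy_truth


def simulate_mask(
    config: SimConfig, rng: np.random.Generator | None = None
) -> MaskTrack:
    """Random introgression/contamination mask covering ``mask_fraction`` of
    the nuclear genome (interval lengths exponential, mean 500 kb)."""
    rng = rng or config.streams()["mask"]
    nuclear = config.layout.nuclear()
    total = sum(c.length for c in nuclear)
    target = config.mask_fraction * total
    if target <= 0:
        return MaskTrack([])
    weights = np.array([c.length for c in nuclear], dtype=float)
    weights /= weights.sum()
    intervals: list[Interval] = []
    track = MaskTrack([])
    for _ in range(10_000):
        deficit = target - track.total_masked
        if deficit <= 0:
            break
        c = nuclear[int(rng.choice(len(nuclear), p=weights))]
        length = max(10_000, int(rng.exponential(500_000)))
        length = min(length, c.length, max(10_000, int(deficit)))
        start = int(rng.integers(0, c.length - length + 1))
        intervals.append(Interval(c.name, start, start + length))
        track = normalize_mask(intervals, config.layout)
    return track


def _cnv_ratio(window: Interval, cnv_spec: list[tuple[Interval, float]]) -> float:
    ratio = 1.0
    for iv, r in cnv_spec:
        frac = window.intersection_length(iv) / window.length
        if frac > 0:
            ratio += frac * (r - 1.0)
    return max(ratio, 0.0)


def simulate_depth(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    sample: str = FOCAL_A,
    sex: str | None = None,
    cnv_spec: list[tuple[Interval, float]] | None = None,
) -> DepthTrack:
    """Windowed depth track over autosomes and X.

    depth_mq20 per window is the mean per-base depth implied by an
    overdispersed read count: the window's read count is drawn from the
    continuous gamma analog of the negative binomial with mean
    depth_mean x copy_ratio x sex_factor x window/read_length (sex_factor
    0.5 on X for males) and variance mean + dispersion * mean^2, then
    converted back to depth. Modeling counts rather than the mean itself
    keeps window-mean noise at the realistic scale (CV ~ sqrt(dispersion)
    for well-covered windows). depth_total adds a small low-MQ excess.
    """
    rng = rng or config.streams()["depth_focal"]
    sex = sex or config.sex
    cnv_spec = config.cnv_spec if cnv_spec is None else cnv_spec
    for i, (a, _) in enumerate(cnv_spec):
        for b, _ in cnv_spec[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"overlapping cnv_spec intervals: {a} / {b}")
    nuclear_layout = GenomeLayout(
        config.layout.nuclear(), {}, set()
    )
    rows = []
    for w in make_windows(nuclear_layout, config.depth_window):
        sexf = 0.5 if (sex == "male" and config.layout.kind(w.chrom) is ChromKind.X) else 1.0
        m = config.depth_mean * _cnv_ratio(w, cnv_spec) * sexf
        per_read = config.read_length / w.length

        def draw(mean_depth: float) -> float:
            if mean_depth <= 0:
                return 0.0
            reads = mean_depth / per_read
            # gamma with mean `reads`, variance reads + dispersion * reads^2
            scale = 1.0 + config.depth_dispersion * reads
            return float(rng.gamma(reads / scale, scale)) * per_read

        mq20 = draw(m)
        low_mq = draw(0.12 * m)
        rows.append(
            {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "depth_mq20": mq20,
                "depth_total": mq20 + low_mq,
            }
        )
    return DepthTrack(sample, pd.DataFrame(rows))


def simulate_all(config: SimConfig) -> SimResult:
    """Run every generator component off one seed."""
    streams = config.streams()
    segments = simulate_mosaic(config, streams["mosaic"])
    sites, privacy_truth = simulate_variants(config, segments, streams["variants"])
    mask = simulate_mask(config, streams["mask"])
    depth = {
        FOCAL_A: simulate_depth(
            config, streams["depth_focal"], sample=FOCAL_A, sex=config.sex
        )
    }
    for i in range(config.n_depth_panel):
        name = f"depth_panel{i}"
        depth[name] = simulate_depth(
            config, streams[name], sample=name, sex="female", cnv_spec=[]
        )
    cnv_truth = [
        (iv, "deletion" if r < 1 else "duplication")
        for iv, r in config.cnv_spec
        if r != 1
    ]
    truth = TruthSet(
        ancestry_segments=segments,
        privacy_truth=privacy_truth,
        cnv_truth=cnv_truth,
        sex_truth=config.sex,
    )
    return SimResult(config, default_panel(), sites, truth, mask, depth)


def window_truth(
    segments: list[tuple[Interval, str]], windows: list[Interval]
) -> list[tuple[str, bool]]:
    """True ancestry per window: (majority-by-bp label, fully-inside flag).

    fully-inside is True when one segment covers the entire window.
    """
    out = []
    for w in windows:
        cover: dict[str, int] = {}
        inside = False
        for iv, anc in segments:
            ovl = w.intersection_length(iv)
            if ovl:
                cover[anc] = cover.get(anc, 0) + ovl
                if ovl == w.length:
                    inside = True
        label = max(cover, key=lambda k: cover[k]) if cover else "none"
        out.append((label, inside))
    return out


def write_simulation(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write every synthetic artifact as plain text (byte-reproducible from
    the config and seed). Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["layout"] = outdir / "layout.tsv"
    result.config.layout.to_table(paths["layout"])

    paths["panel"] = outdir / "panel.yaml"
    result.panel.to_yaml(paths["panel"])

    paths["vcf"] = outdir / "sites.vcf"
    write_vcf(
        result.sites,
        paths["vcf"],
        samples=result.panel.all_samples,
        layout=result.config.layout,
    )

    paths["mask"] = outdir / "mask.bed"
    write_bed(result.mask.intervals, paths["mask"])

    paths["truth_segments"] = outdir / "truth_segments.bed"
    write_bed(
        [iv for iv, _ in result.truth.ancestry_segments],
        paths["truth_segments"],
        names=[anc for _, anc in result.truth.ancestry_segments],
    )

    paths["truth_privacy"] = outdir / "truth_privacy.tsv"
    with open(paths["truth_privacy"], "w") as fh:
        fh.write("chrom\tposition\tcategory\n")
        for (chrom, pos), cat in sorted(result.truth.privacy_truth.items()):
            fh.write(f"{chrom}\t{pos}\t{cat}\n")

    paths["truth_cnv"] = outdir / "truth_cnv.bed"
    write_bed(
        [iv for iv, _ in result.truth.cnv_truth],
        paths["truth_cnv"],
        names=[k for _, k in result.truth.cnv_truth],
    )

    for name, track in result.depth.items():
        p = outdir / f"depth_{name}.tsv"
        write_depth_track(track, p)
        paths[f"depth_{name}"] = p

    meta = {"sex_truth": result.truth.sex_truth, "seed": result.config.seed}
    paths["meta"] = outdir / "truth_meta.json"
    paths["meta"].write_text(json.dumps(meta, sort_keys=True) + "\n")
    return paths
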