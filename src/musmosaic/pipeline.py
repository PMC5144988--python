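"""End-to-end orchestration: simulate (optional) -> filter -> catalog ->
paint -> depth, with a run report rendered as TSV, JSON, or markdown.

Every number in the report is reproducible from the effective configuration
plus the seed; the merged configuration is echoed into the output directory
alongside the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from .ancestry import (
    PaintConfig,
    paint_windows,
    summarize_ancestry,
)
from .catalog import classify_site, summarize_catalog
from .depth import (
    CnvConfig,
    call_cnvs,
    callable_fraction,
    centromere_screen,
    infer_sex,
    normalize_depth,
)
from .filters import FilterConfig, annotate_indel_distance, filter_all
from .genome import GenomeLayout, make_windows, normalize_mask, read_bed
from .simulate import SimConfig, simulate_all, write_simulation
from .variants import SamplePanel, read_depth_track, read_vcf

__all__ = [
    "RunConfig",
    "StageError",
    "ValidationError",
    "render_report",
    "run_pipeline",
]

log = logging.getLogger("musmosaic")

ALL_STAGES = ("filter", "catalog", "paint", "depth")


class ValidationError(Exception):
    """Configuration or input problem detected before any stage runs."""


class StageError(Exception):
    """A pipeline stage failed; message names the stage and cause."""


@dataclass
class RunConfig:
    """One pipeline run. Either ``simulate`` is set (synthetic inputs are
    generated into the output directory) or the input paths are."""

    outdir: Path
    seed: int = 0
    simulate: SimConfig | None = None
    # file inputs, used when simulate is None
    layout_path: Path | None = None
    vcf_path: Path | None = None
    mask_path: Path | None = None
    panel_path: Path | None = None
    depth_focal_path: Path | None = None
    depth_panel_paths: list[Path] = field(default_factory=list)
    # stage configuration
    stages: tuple[str, ...] = ALL_STAGES
    focal: str | None = None  # default: first focal sample of the panel
    window: int = 25_000
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    paint_config: PaintConfig = field(default_factory=PaintConfig)
    cnv_config: CnvConfig = field(default_factory=CnvConfig)

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        if self.simulate is None:
            required = {
                "layout": self.layout_path,
                "vcf": self.vcf_path,
                "mask": self.mask_path,
                "panel": self.panel_path,
            }
            if "depth" in self.stages:
                required["depth_focal"] = self.depth_focal_path
            for name, p in required.items():
                if p is None:
                    raise ValidationError(f"missing required input path: {name}")
                if not Path(p).exists():
                    raise ValidationError(f"{name} file not found: {p}")
            for p in self.depth_panel_paths:
                if not Path(p).exists():
                    raise ValidationError(f"depth panel file not found: {p}")


def _echo_config(config: RunConfig, outdir: Path) -> None:
    def default(o: Any):
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(map(str, o)) if isinstance(o, (set, frozenset)) else list(o)
        return str(o)

    payload = {
        k: v
        for k, v in asdict(config).items()
        if k not in ("simulate",)  # layout objects are unwieldy; echo flags instead
    }
    payload["synthetic"] = config.simulate is not None
    (outdir / "effective_config.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=default) + "\n"
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _echo_config(config, outdir)

    if config.simulate is not None:
        sim = config.simulate
        if sim.seed != config.seed:
            sim = SimConfig(**{**asdict_shallow(sim), "seed": config.seed})
        result = simulate_all(sim)
        write_simulation(result, outdir / "sim")
        layout = sim.layout
        panel = result.panel
        sites = result.sites
        mask = result.mask
        tracks = list(result.depth.values())
        depth_focal, depth_panel = tracks[0], tracks[1:]
    else:
        layout = GenomeLayout.from_table(config.layout_path)
        panel = SamplePanel.from_yaml(config.panel_path)
        sites = list(read_vcf(config.vcf_path, panel))
        mask = normalize_mask(read_bed(config.mask_path), layout)
        depth_focal = depth_panel = None
        if "depth" in config.stages:
            depth_focal = read_depth_track(config.depth_focal_path, layout)
            depth_panel = [
                read_depth_track(p, layout) for p in config.depth_panel_paths
            ]

    focal = config.focal or panel.focal[0]
    if focal not in panel.all_samples:
        raise ValidationError(f"focal sample {focal} not in panel")
    report: dict[str, Any] = {
        "seed": config.seed,
        "focal": focal,
        "stages": list(config.stages),
    }

    order = {name: i for i, name in enumerate(layout.names)}
    try:
        sites.sort(key=lambda s: (order[s.chrom], s.position))
    except KeyError as exc:
        raise ValidationError(f"VCF chromosome not in layout: {exc}") from exc

    passed = sites
    if "filter" in config.stages:
        try:
            annotate_indel_distance(sites)
            log.info(
                "filter thresholds: %s", json.dumps(asdict(config.filter_config))
            )
            passed, failed, counts = filter_all(
                sites, config.filter_config, layout, focal
            )
        except Exception as exc:
            raise StageError(f"filter: {exc}") from exc
        report["filter"] = {
            "n_input": len(sites),
            "n_pass": len(passed),
            "n_fail": len(failed),
            "fail_reasons": dict(sorted(counts.items())),
        }

    if "catalog" in config.stages:
        try:
            calls = [
                (s, classify_site(s, panel, k))
                for s in passed
                for k in range(1, len(s.alts) + 1)
            ]
            summary = summarize_catalog(calls)
        except Exception as exc:
            raise StageError(f"catalog: {exc}") from exc
        report["catalog"] = {
            "private_snvs": {
                "A": summary.counts[("private_A", "SNV")],
                "B": summary.counts[("private_B", "SNV")],
                "shared": summary.counts[("shared_exclusive", "SNV")],
            },
            "private_indels": {
                "A": summary.counts[("private_A", "indel")],
                "B": summary.counts[("private_B", "indel")],
                "shared": summary.counts[("shared_exclusive", "indel")],
            },
            "known": {
                "SNV": summary.counts[("known", "SNV")],
                "indel": summary.counts[("known", "indel")],
            },
            "unclassifiable": {
                "SNV": summary.counts[("unclassifiable", "SNV")],
                "indel": summary.counts[("unclassifiable", "indel")],
            },
            "ts": summary.ts_count,
            "tv": summary.tv_count,
            "ts_tv_ratio": round(summary.ts_tv_ratio, 4),
        }

    if "paint" in config.stages:
        try:
            nuclear = GenomeLayout(layout.nuclear(), {}, set())
            windows = make_windows(nuclear, config.window)
            nuclear_names = set(nuclear.lengths)
            log.info(
                "paint: window=%d min_sites=%d mask_threshold=%.2f",
                config.window,
                config.paint_config.min_sites,
                config.paint_config.mask_threshold,
            )
            painted = paint_windows(
                [s for s in passed if s.chrom in nuclear_names],
                windows,
                mask,
                panel,
                focal,
                config.paint_config,
            )
            asum = summarize_ancestry(painted)
        except Exception as exc:
            raise StageError(f"paint: {exc}") from exc
        per_chrom: dict[str, dict[str, int]] = {}
        for w in painted:
            per_chrom.setdefault(w.interval.chrom, {})
            per_chrom[w.interval.chrom][w.label] = (
                per_chrom[w.interval.chrom].get(w.label, 0) + 1
            )
        report["ancestry"] = {
            "fraction": {k: round(v, 6) for k, v in sorted(asum.fraction.items())},
            "fraction_length_weighted": {
                k: round(v, 6) for k, v in sorted(asum.fraction_length_weighted.items())
            },
            "n_windows": dict(sorted(asum.n_windows.items())),
            "masked_fraction": round(asum.masked_fraction, 6),
            "per_chromosome": {c: dict(sorted(d.items())) for c, d in sorted(per_chrom.items())},
        }
        report["_painted_windows"] = painted  # dropped at render time

    if "depth" in config.stages:
        try:
            log.info("depth thresholds: %s", json.dumps(asdict(config.cnv_config)))
            sex = infer_sex(depth_focal, layout)
            callable_frac = callable_fraction(depth_focal)
            focal_norm = normalize_depth(depth_focal, layout)
            panel_norm = [normalize_depth(t, layout) for t in depth_panel]
            cnvs = call_cnvs(focal_norm, panel_norm, config.cnv_config)
            screen = centromere_screen(cnvs, layout)
        except Exception as exc:
            raise StageError(f"depth: {exc}") from exc
        report["sex"] = {"label": sex.label, "x_auto_ratio": round(sex.x_auto_ratio, 4)}
        report["callable"] = {"fraction_ge_10x": round(callable_frac, 6)}
        report["cnv"] = {
            "n_calls": len(cnvs),
            "n_private": sum(1 for c in cnvs if c.private),
            "calls": [
                {
                    "chrom": c.interval.chrom,
                    "start": c.interval.start,
                    "end": c.interval.end,
                    "kind": c.kind,
                    "mean_ratio": round(c.mean_ratio, 4),
                    "n_windows": c.n_windows,
                    "private": c.private,
                }
                for c in cnvs
            ],
        }
        report["centromere_screen"] = screen.to_dict(orient="records")
    return report


def asdict_shallow(obj) -> dict:
    """dataclass fields without recursing into values (layouts stay objects)."""
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}


def _flatten(prefix: str, value: Any, rows: list[tuple[str, Any]]) -> None:
    if isinstance(value, dict):
        for k, v in value.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _flatten(f"{prefix}[{i}]", v, rows)
    else:
        rows.append((prefix, value))


def render_report(
    report: dict, outdir: str | Path, formats: tuple[str, ...] = ("json", "tsv", "markdown")
) -> dict[str, Path]:
    """Write the report in each requested format; the numeric content is
    identical across formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    painted = report.pop("_painted_windows", None)
    paths: dict[str, Path] = {}
    for fmt in formats:
        if fmt == "json":
            p = outdir / "report.json"
            p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        elif fmt == "tsv":
            rows: list[tuple[str, Any]] = []
            _flatten("", report, rows)
            p = outdir / "report.tsv"
            with open(p, "w") as fh:
                fh.write("key\tvalue\n")
                for k, v in rows:
                    fh.write(f"{k}\t{v}\n")
        elif fmt == "markdown":
            p = outdir / "report.md"
            p.write_text(_markdown(report))
        else:
            raise ValidationError(f"unknown report format: {fmt}")
        paths[fmt] = p
    if painted is not None:
        report["_painted_windows"] = painted
    return paths


def _markdown(report: dict) -> str:
    lines = ["# musmosaic run report", ""]
    for section, value in report.items():
        lines.append(f"## {section}")
        lines.append("")
        if section == "ancestry" and isinstance(value, dict):
            for k, v in value.items():
                if k == "per_chromosome":
                    continue
                lines.append(f"- **{k}**: {v}")
            per = value.get("per_chromosome", {})
            if per:
                labels = sorted({lab for d in per.values() for lab in d})
                lines.append("")
                lines.append("| chromosome | " + " | ".join(labels) + " |")
                lines.append("|---" * (len(labels) + 1) + "|")
                for chrom, d in per.items():
                    cells = [str(d.get(lab, 0)) for lab in labels]
                    lines.append(f"| {chrom} | " + " | ".join(cells) + " |")
        else:
            rows: list[tuple[str, Any]] = []
            _flatten("", value, rows)
            for k, v in rows:
                lines.append(f"- **{k or section}**: {v}")
        lines.append("")
    return "\n".join(lines)
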