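#!/usr/bin/env python
"""Paint windowed local ancestry of the focal genome and compare to truth.

Alleles at pass-filter biallelic SNVs are polarized against the outgroup;
in 25-kb windows the derived alleles the focal strain shares with exactly
one subspecies representative (dom/mus/cas) are counted, and the window
takes the majority subspecies. Windows mostly inside the introgression/
contamination mask are excluded.

Reads results/filter/pass.vcf + results/sim/; writes results/ancestry/.
"""

from pathlib import Path

from musmosaic.ancestry import PaintConfig, paint_windows, summarize_ancestry
from musmosaic.genome import (
    GenomeLayout,
    Interval,
    make_windows,
    normalize_mask,
    read_bed,
    write_bed,
)
from musmosaic.simulate import window_truth
from musmosaic.variants import SamplePanel, read_vcf

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = RESULTS / "sim"
    layout = GenomeLayout.from_table(sim / "layout.tsv")
    panel = SamplePanel.from_yaml(sim / "panel.yaml")
    mask = normalize_mask(read_bed(sim / "mask.bed"), layout)
    nuclear = GenomeLayout(layout.nuclear(), {}, set())
    windows = make_windows(nuclear, 25_000)
    names = set(nuclear.lengths)
    sites = [
        s for s in read_vcf(RESULTS / "filter" / "pass.vcf", panel)
        if s.chrom in names
    ]

    painted = paint_windows(sites, windows, mask, panel, panel.focal[0], PaintConfig())
    summary = summarize_ancestry(painted)

    outdir = RESULTS / "ancestry"
    outdir.mkdir(parents=True, exist_ok=True)
    write_bed(
        [w.interval for w in painted], outdir / "windows.bed",
        names=[w.label for w in painted],
    )
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("label\tn_windows\tfraction\n")
        for label in sorted(summary.n_windows):
            fh.write(
                f"{label}\t{summary.n_windows[label]}\t{summary.fraction[label]:.6f}\n"
            )

    truth_segments = []
    for line in (sim / "truth_segments.bed").read_text().splitlines():
        chrom, start, end, ancestry = line.split("\t")
        truth_segments.append((Interval(chrom, int(start), int(end)), ancestry))
    truth = window_truth(truth_segments, windows)
    analyzed = [(w, t) for w, t in zip(painted, truth) if w.label != "masked"]
    truth_dom = sum(1 for _, (lab, _) in analyzed if lab == "dom") / len(analyzed)

    print(f"windows: {len(painted)} total, {len(analyzed)} analyzed, "
          f"{summary.masked_fraction:.1%} masked")
    for label, frac in sorted(summary.fraction.items()):
        print(f"  {label:14s} {frac:.2%} of analyzed windows")
    print(f"true dom fraction among analyzed windows: {truth_dom:.2%} "
          f"(inferred {summary.fraction.get('dom', 0):.2%})")


if __name__ == "__main__":
    main()
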