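#!/usr/bin/env python
"""Apply the hard filters to the candidate variants.

Thresholds follow the variant-calling pipeline's rules for these genomes:
read depth >5 and <100 (nuclear) or >350 (mitochondrial), mapping quality
>20, >5 reads supporting the alternate allele, SNVs >2 bp from the nearest
indel, and a homozygous focal genotype — all comparisons strict.

Reads results/sim/; writes results/filter/ (pass/fail VCFs, summary TSV).
"""

from pathlib import Path

from musmosaic.filters import FilterConfig, annotate_indel_distance, filter_all
from musmosaic.genome import GenomeLayout
from musmosaic.variants import SamplePanel, read_vcf, write_vcf

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = RESULTS / "sim"
    layout = GenomeLayout.from_table(sim / "layout.tsv")
    panel = SamplePanel.from_yaml(sim / "panel.yaml")
    sites = list(read_vcf(sim / "sites.vcf", panel))
    order = {n: i for i, n in enumerate(layout.names)}
    sites.sort(key=lambda s: (order[s.chrom], s.position))
    annotate_indel_distance(sites)

    config = FilterConfig()
    passed, failed, counts = filter_all(sites, config, layout, panel.focal[0])

    outdir = RESULTS / "filter"
    outdir.mkdir(parents=True, exist_ok=True)
    write_vcf(passed, outdir / "pass.vcf", panel.all_samples, layout)
    write_vcf(failed, outdir / "fail.vcf", panel.all_samples, layout)
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("metric\tcount\n")
        fh.write(f"input\t{len(sites)}\npass\t{len(passed)}\nfail\t{len(failed)}\n")
        for reason, n in sorted(counts.items()):
            fh.write(f"{reason}\t{n}\n")

    print(f"{len(sites):,} candidates -> {len(passed):,} pass "
          f"({len(passed) / len(sites):.1%}), {len(failed):,} fail")
    for reason, n in sorted(counts.items(), key=lambda t: -t[1]):
        if n:
            print(f"  {reason}: {n:,}")


if __name__ == "__main__":
    main()
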