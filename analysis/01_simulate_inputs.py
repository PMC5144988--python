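#!/usr/bin/env python
"""Generate the synthetic study inputs every later step consumes.

Emulates the sequencing study's conditions on a desk-scale 50-Mb genome:
a focal strain pair at ~18x depth whose genome is a 92/8 domesticus/
musculus ancestry mosaic, one candidate variant per ~500 bp, subspecies
representatives + outgroup + a 3-strain known-variant panel, 19% of the
genome masked, and depth tracks for the focal sample and three controls.

Writes results/sim/ (layout TSV, VCF, mask BED, truth tracks, depth TSVs).
"""

import argparse
from pathlib import Path

from musmosaic.simulate import SimConfig, simulate_all, write_simulation

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed, mosaic_spec={"dom": 0.92, "mus": 0.08})
    result = simulate_all(cfg)
    paths = write_simulation(result, RESULTS / "sim")

    nuclear_bp = sum(c.length for c in cfg.layout.nuclear())
    print(f"genome: {nuclear_bp / 1e6:.0f} Mb nuclear + chrM, seed {args.seed}")
    print(f"candidate variants: {len(result.sites):,}")
    print(f"ancestry segments: {len(result.truth.ancestry_segments)}")
    print(f"mask: {result.mask.total_masked / nuclear_bp:.1%} of nuclear genome")
    print(f"sex truth: {result.truth.sex_truth}")
    for key, p in paths.items():
        print(f"  wrote {key}: {p}")


if __name__ == "__main__":
    main()
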