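#!/usr/bin/env python
"""Generate the study-condition synthetic dataset.

Two 300-kb chromosomes, 60 genes, 15x mean depth, context baselines
mCG/mCHG/mCHH = 0.48/0.38/0.07, non-conversion 0.25%/0.61%, and twenty
planted 1-kb differential regions (|delta ML| = 0.3, two-thirds hypo in the
sterile-line sample, promoter-biased).  Writes cytosine reports, gene models,
TE intervals and the truth manifest under results/sim/.
"""

import sys
from pathlib import Path

import numpy as np

from methdiff import io, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"


def main():
    config = simulate.default_simulation(seed=SEED)
    genes = simulate.simulate_gene_models(config)
    sample_a, sample_b, truth = simulate.simulate_methylome_pair(config, outdir=OUT)
    simulate.write_gene_models_gff3(genes, OUT / "genes.gff3")
    tes = simulate.simulate_te_intervals(config, np.random.default_rng(config.seed + 5))
    io.write_table(tes, OUT / "te_intervals.tsv")
    print(f"seed {SEED}: {len(sample_a.records):,} cytosines per sample, "
          f"{len(genes)} genes, {len(truth.planted)} planted DMRs "
          f"({sum(1 for d in truth.planted if d.direction == 'hypo')} hypo)")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
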