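#!/usr/bin/env python
"""Metagene profiles, TE density and expression strata.

Derives promoters (2 kb upstream of the TSS), UTRs, exons and introns from
the gene models, bins each region kind into 20 equal parts and averages the
methylation density per bin and context; tiles the genome into 20-kb windows
for TE fraction; and groups genes into the five FPKM strata.
"""

import sys
from pathlib import Path

from methdiff import io, profiles, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
RES = Path(__file__).resolve().parent.parent / "results"


def main():
    genes = io.read_gene_models(RES / "sim" / "genes.gff3")
    chrom_sizes = {c: 300_000 for c in {g.chrom for g in genes}}
    regions = profiles.derive_functional_regions(genes, chrom_sizes=chrom_sizes)
    calls = io.read_table(RES / "sites_A.tsv")
    profile = profiles.metagene_profile(calls, regions)
    io.write_table(profile, RES / "metagene_A.tsv")
    prom = profile[(profile["kind"] == "promoter") & (profile["context"] == "all")]["density"].mean()
    exon = profile[(profile["kind"] == "exon") & (profile["context"] == "all")]["density"].mean()
    print(f"{len(regions)} functional regions from {len(genes)} genes")
    print(f"mean metagene density: promoter {prom:.3f}, exon {exon:.3f}")

    tes = io.read_table(RES / "sim" / "te_intervals.tsv")
    track = profiles.te_density(tes, chrom_sizes, window_size=20_000)
    io.write_table(track, RES / "te_density.tsv")
    print(f"TE fraction: mean {track['te_fraction'].mean():.3f} over {len(track)} windows")

    config = simulate.default_simulation(seed=SEED)
    truth = simulate.SyntheticTruth.from_json(RES / "sim" / "truth.json")
    expr = simulate.simulate_expression(config, truth, genes)
    io.write_table(expr, RES / "expression.tsv")
    records = [
        io.ExpressionRecord(r.gene_id, r.fpkm_a, r.fpkm_b, r.log2fc, r.fdr)
        for r in expr.itertuples(index=False)
    ]
    strata = profiles.expression_strata(records)
    sizes = {k: len(v) for k, v in strata.items()}
    print(f"expression strata sizes: {sizes} (sum {sum(sizes.values())})")


if __name__ == "__main__":
    main()
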