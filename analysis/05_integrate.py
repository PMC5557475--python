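#!/usr/bin/env python
"""Term enrichment and methylation-expression integration.

Tests the DMG set for term over-representation (hypergeometric upper tail,
BH-adjusted) against a synthetic term map, classifies differential expression
(|log2FC| >= 1, FDR <= 0.05), quantifies qRT-PCR relative expression by
2^-ddCt, and summarises the negative methylation-expression concordance of
promoter-coupled genes.
"""

import sys
from pathlib import Path

import numpy as np

from methdiff import enrich, expression, io, simulate

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
RES = Path(__file__).resolve().parent.parent / "results"


def main():
    dmg_df = io.read_table(RES / "dmgs.tsv")
    genes = io.read_gene_models(RES / "sim" / "genes.gff3")
    term_map = simulate.simulate_term_map(genes, np.random.default_rng(SEED + 6))
    results = enrich.enrich_terms(dmg_df["gene_id"].tolist(), term_map)
    io.write_table(enrich.enrichment_to_frame(results), RES / "enrichment.tsv")
    n_sig = sum(1 for r in results if r.p < 0.05)
    print(f"enrichment: {len(results)} terms with >= 1 DMG, {n_sig} at p < 0.05")

    truth = simulate.SyntheticTruth.from_json(RES / "sim" / "truth.json")
    expr = io.read_table(RES / "expression.tsv")
    de_calls = {
        r.gene_id: expression.classify_de(r.log2fc, r.fdr) for r in expr.itertuples(index=False)
    }
    # fill coupled-gene map for the qPCR panel
    if not truth.coupled_genes:
        config = simulate.default_simulation(seed=SEED)
        simulate.simulate_expression(config, truth, genes)
    ct = simulate.simulate_qpcr(truth, expr)
    io.write_table(ct, RES / "qpcr_ct.tsv")
    qpcr = expression.qpcr_from_ct_table(ct)
    qpcr_calls = {q.gene_id: q.call for q in qpcr}
    print(f"qPCR panel: {len(qpcr)} genes, "
          f"{sum(1 for q in qpcr if q.call == 'down')} down by 2^-ddCt")

    mdir = {}
    for g in genes:
        p_s, p_e = (
            (max(1, g.tss - 2000), g.tss - 1) if g.strand == "+" else (g.tss + 1, g.tss + 2000)
        )
        for d in truth.planted:
            if d.chrom == g.chrom and d.start <= p_e and p_s <= d.end:
                mdir[g.gene_id] = d.direction
    conc = expression.sign_concordance(mdir, {**de_calls, **qpcr_calls})
    io.write_table(conc, RES / "concordance.tsv")
    frac = conc["negative_concordant"].mean()
    print(f"methylation-expression concordance: "
          f"{int(conc['negative_concordant'].sum())}/{len(conc)} genes negative ({frac:.0%})")


if __name__ == "__main__":
    main()
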