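"""End-to-end orchestration of the differential-methylation pipeline.

Stages: simulate (or load) two-sample cytosine reports -> binomial site
calling -> genome summaries and metagene profiles -> sliding-window Fisher
DMR detection -> DMG annotation/classification -> term enrichment ->
methylation-expression integration.  Every threshold is carried in a
PipelineConfig whose defaults are the analysis' stated values, and the fully
resolved config is echoed into the run manifest so no stage can silently
swallow a parameter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import core, dmg, dmr, enrich, expression, io, profiles, simulate

log = logging.getLogger("methdiff")


@dataclass
class PipelineConfig:
    seed: int = 0
    min_depth: int = 5
    site_q_max: float = 0.05
    site_window: int = 3000
    site_step: int = 600
    dmr_window: int = 1000
    dmr_step: int = 100
    dmr_fdr: float = 0.05
    promoter_len: int = 2000
    bins: int = 20
    min_overlap: int = 1
    fc_min: float = 1.0
    de_fdr_max: float = 0.05
    enrich_p_max: float = 0.05
    per_context: bool = False
    min_fold_change: float | None = None
    sim: dict = field(default_factory=dict)  # overrides for SimulationConfig


def run_all(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a default-config simulation; returns the result bundle.

    Writes stage outputs and a manifest (resolved config + produced files)
    under ``outdir``; outputs are deterministic for a given config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("resolved config: %s", asdict(config))

    sim_config = simulate.default_simulation(seed=config.seed, **config.sim)
    genes = simulate.simulate_gene_models(sim_config)
    sample_a, sample_b, truth = simulate.simulate_methylome_pair(sim_config, outdir=outdir)
    tes = simulate.simulate_te_intervals(sim_config, np.random.default_rng(sim_config.seed + 5))

    # --- site calling and genome summaries
    calls = {}
    summaries = {}
    for sample in (sample_a, sample_b):
        calls[sample.sample_id] = core.call_methylated_sites(
            sample, min_depth=config.min_depth, q_max=config.site_q_max
        )
        summaries[sample.sample_id] = core.genome_summary(calls[sample.sample_id])
        io.write_table(calls[sample.sample_id], outdir / f"sites_{sample.sample_id}.tsv")
    window_track = core.window_methylation(sample_a, w=config.site_window, step=config.site_step)
    io.write_table(window_track, outdir / "windows_3000_600_A.tsv")

    # --- functional regions and profiles
    regions = profiles.derive_functional_regions(
        genes, promoter_len=config.promoter_len, chrom_sizes=sample_a.chrom_sizes
    )
    profile = profiles.metagene_profile(calls["A"], regions, bins=config.bins)
    io.write_table(profile, outdir / "metagene_A.tsv")
    te_track = profiles.te_density(tes, sample_a.chrom_sizes, window_size=20_000)
    io.write_table(te_track, outdir / "te_density.tsv")

    # --- expression strata
    expr_table = simulate.simulate_expression(sim_config, truth, genes, promoter_len=config.promoter_len)
    io.write_table(expr_table, outdir / "expression.tsv")
    expr_records = [
        io.ExpressionRecord(r.gene_id, r.fpkm_a, r.fpkm_b, r.log2fc, r.fdr)
        for r in expr_table.itertuples(index=False)
    ]
    strata = profiles.expression_strata(expr_records)

    # --- DMR detection
    windows, dmrs = dmr.call_dmrs(
        sample_a,
        sample_b,
        w=config.dmr_window,
        step=config.dmr_step,
        fdr=config.dmr_fdr,
        min_depth=config.min_depth,
        min_fold_change=config.min_fold_change,
    )
    io.write_table(windows, outdir / "dmr_windows.tsv")
    io.write_dmr_bed(dmrs, outdir / "dmrs.bed")
    log.info(
        "windows tested=%d significant=%d merged DMRs=%d",
        len(windows),
        int((windows["direction"] != "none").sum()) if not windows.empty else 0,
        len(dmrs),
    )

    # --- DMG annotation
    hits = dmg.overlap_dmrs_regions(dmrs, regions, min_overlap=config.min_overlap)
    dmgs = dmg.classify_dmgs(hits)
    region_summary = dmg.summarize_regions(dmgs)
    io.write_table(dmg.dmgs_to_frame(dmgs), outdir / "dmgs.tsv")
    io.write_table(region_summary, outdir / "region_summary.tsv")

    # --- enrichment on a synthetic term map
    term_map = simulate.simulate_term_map(genes, np.random.default_rng(sim_config.seed + 6))
    enrichment = enrich.enrich_terms(
        [g.gene_id for g in dmgs], term_map, p_max=config.enrich_p_max
    )
    io.write_table(enrich.enrichment_to_frame(enrichment), outdir / "enrichment.tsv")

    # --- expression integration
    de_calls = {
        r.gene_id: expression.classify_de(r.log2fc, r.fdr, config.fc_min, config.de_fdr_max)
        for r in expr_table.itertuples(index=False)
    }
    ct_table = simulate.simulate_qpcr(truth, expr_table)
    qpcr = expression.qpcr_from_ct_table(ct_table)
    qpcr_calls = {q.gene_id: q.call for q in qpcr}
    mdir = {g.gene_id: g.status for g in dmgs if g.status in ("hyper", "hypo")}
    concordance = expression.sign_concordance(mdir, {**de_calls, **qpcr_calls})
    io.write_table(concordance, outdir / "concordance.tsv")

    results = {
        "summaries": summaries,
        "strata_sizes": {k: len(v) for k, v in strata.items()},
        "n_windows_tested": int(len(windows)),
        "n_dmrs": len(dmrs),
        "dmrs": dmrs,
        "dmgs": dmgs,
        "dmg_status_counts": dmg.status_counts(dmgs),
        "enrichment": enrichment,
        "concordance": concordance,
        "truth": truth,
    }
    manifest = {
        "config": asdict(config),
        "files": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        "n_dmrs": len(dmrs),
        "n_dmgs": len(dmgs),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return results


def recovery_metrics(dmrs, planted, min_breadth: float = 0.5) -> dict:
    """Sensitivity and observed false-discovery fraction of DMR calls against
    the planted truth.

    A planted region counts as recovered when called DMRs of its direction
    cover >= ``min_breadth`` of its width; a called DMR is a false discovery
    when it overlaps no planted region at all.
    """
    recovered = 0
    for p in planted:
        covered = 0
        ivs = sorted(
            (max(d.start, p.start), min(d.end, p.end))
            for d in dmrs
            if d.chrom == p.chrom and d.direction == p.direction and d.start <= p.end and p.start <= d.end
        )
        last_end = 0
        for s, e in ivs:
            s = max(s, last_end + 1)
            if e >= s:
                covered += e - s + 1
                last_end = e
        if covered / (p.end - p.start + 1) >= min_breadth:
            recovered += 1
    false = sum(
        1
        for d in dmrs
        if not any(d.chrom == p.chrom and d.start <= p.end and p.start <= d.end for p in planted)
    )
    return {
        "n_planted": len(planted),
        "n_recovered": recovered,
        "sensitivity": recovered / len(planted) if planted else float("nan"),
        "n_called": len(dmrs),
        "n_false": false,
        "fdr": false / len(dmrs) if dmrs else 0.0,
    }
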