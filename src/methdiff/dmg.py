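"""DMR-to-gene annotation and classification.

A differentially methylated gene (DMG) is a gene whose promoter or gene body
(5'UTR, exon, intron, 3'UTR) overlaps a DMR by at least 1 bp.  A gene hit
only by hypo-methylated DMRs is classed hypo, only hyper-methylated hyper,
and a gene hit by both directions (possibly in different functional regions)
is methylation-unstable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import round_half_up
from .dmr import Dmr
from .profiles import REGION_KINDS, FunctionalRegion


@dataclass
class Dmg:
    gene_id: str
    hits: list[tuple[str, int, str, int]]  # (region kind, dmr index, direction, overlap bp)
    status: str  # hypo | hyper | unstable

    def __post_init__(self):
        if not self.hits:
            raise ValueError("a DMG must have at least one hit")
        dirs = {h[2] for h in self.hits}
        expected = "unstable" if len(dirs) > 1 else next(iter(dirs))
        if self.status != expected:
            raise ValueError(f"status {self.status} inconsistent with hit directions {dirs}")


def overlap_dmrs_regions(
    dmrs: list[Dmr], regions: list[FunctionalRegion], min_overlap: int = 1
) -> pd.DataFrame:
    """All (DMR, region) pairs overlapping by >= min_overlap bp.

    Returns a frame with gene_id, kind, dmr_index (position in the input
    list), direction and overlap_bp.  Output order is deterministic and
    independent of input order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    rows = []
    by_chrom: dict[str, list[tuple[int, Dmr]]] = {}
    for i, d in enumerate(dmrs):
        by_chrom.setdefault(d.chrom, []).append((i, d))
    for reg in regions:
        for i, d in by_chrom.get(reg.chrom, ()):
            ov = min(reg.end, d.end) - max(reg.start, d.start) + 1
            if ov >= min_overlap:
                rows.append((reg.gene_id, reg.kind, i, d.direction, int(ov)))
    df = pd.DataFrame(rows, columns=["gene_id", "kind", "dmr_index", "direction", "overlap_bp"])
    return df.sort_values(["gene_id", "kind", "dmr_index"], kind="stable").reset_index(drop=True)


def classify_dmgs(hits: pd.DataFrame) -> list[Dmg]:
    """One Dmg per gene with >= 1 hit; status from the set of hit directions
    across all functional-region kinds."""
    dmgs = []
    for gene_id, sub in hits.groupby("gene_id", sort=True):
        hit_list = [
            (r.kind, int(r.dmr_index), r.direction, int(r.overlap_bp))
            for r in sub.itertuples(index=False)
        ]
        dirs = {h[2] for h in hit_list}
        status = "unstable" if len(dirs) > 1 else next(iter(dirs))
        dmgs.append(Dmg(gene_id=str(gene_id), hits=hit_list, status=status))
    return dmgs


def status_counts(dmgs: list[Dmg]) -> dict[str, int]:
    out = {"hypo": 0, "hyper": 0, "unstable": 0}
    for g in dmgs:
        out[g.status] += 1
    return out


def status_percentages(dmgs: list[Dmg], ndigits: int = 1) -> dict[str, float]:
    """Share of DMGs per class in percent, half-up rounded."""
    counts = status_counts(dmgs)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no DMGs")
    return {k: round_half_up(100.0 * v / total, ndigits) for k, v in counts.items()}


def summarize_regions(dmgs: list[Dmg], ndigits: int = 1) -> pd.DataFrame:
    """Per-functional-region DMG counts and genome rates.

    For each region kind: the number of distinct genes with >= 1 hypo hit,
    >= 1 hyper hit, and >= 1 hit of any direction in that kind; the rate is
    the any-direction count over the total number of DMGs, in percent.  A
    gene hit by both directions within one kind is counted once in the total
    but appears in both the hypo and hyper columns.
    """
    total_dmgs = len(dmgs)
    rows = []
    for kind in REGION_KINDS:
        hypo_genes, hyper_genes, any_genes = set(), set(), set()
        for g in dmgs:
            for k, _i, direction, _ov in g.hits:
                if k != kind:
                    continue
                any_genes.add(g.gene_id)
                if direction == "hypo":
                    hypo_genes.add(g.gene_id)
                elif direction == "hyper":
                    hyper_genes.add(g.gene_id)
        rate = round_half_up(100.0 * len(any_genes) / total_dmgs, ndigits) if total_dmgs else np.nan
        rows.append((kind, len(hypo_genes), len(hyper_genes), len(any_genes), rate))
    return pd.DataFrame(rows, columns=["kind", "n_hypo", "n_hyper", "n_total", "rate_pct"])


def dmgs_to_frame(dmgs: list[Dmg]) -> pd.DataFrame:
    rows = [
        (g.gene_id, g.status, len(g.hits), ";".join(f"{k}:{d}:{ov}" for k, _i, d, ov in g.hits))
        for g in dmgs
    ]
    return pd.DataFrame(rows, columns=["gene_id", "status", "n_hits", "hits"])
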