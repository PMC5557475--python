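"""Functional regions and methylation-density profiles.

The genome is partitioned around each gene into a promoter (the 2-kb region
upstream of the TSS) and a gene body of 5'UTR, exon, intron and 3'UTR.
Methylation density over an interval is sites(mC)/sites(mC+umC): the fraction
of covered cytosines that were called methylated.  Metagene profiles scale
each region of a kind to 20 equal bins (bin 1 is 5'-most) and average the
per-bin densities across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel

REGION_KINDS = ("promoter", "five_prime_UTR", "exon", "intron", "three_prime_UTR")

# FPKM strata: half-open on the left boundary, per the 0-1 / 1-3 / 3-15 /
# 15-60 / >60 grouping of genes by expression.
STRATA = (
    ("silent", 0.0, 1.0),
    ("low", 1.0, 3.0),
    ("moderate", 3.0, 15.0),
    ("high", 15.0, 60.0),
    ("highest", 60.0, float("inf")),
)


@dataclass(frozen=True)
class FunctionalRegion:
    gene_id: str
    kind: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("region start must not exceed end")
        if self.kind not in REGION_KINDS:
            raise ValueError(f"unknown region kind {self.kind}")


def derive_functional_regions(
    genes: list[GeneModel],
    promoter_len: int = 2000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[FunctionalRegion]:
    """Promoters, UTRs, exons and inferred introns for each gene.

    The promoter is [tss - promoter_len, tss - 1] on +, [tss + 1,
    tss + promoter_len] on -, truncated to chromosome bounds; a TSS flush
    against the chromosome edge yields no promoter.  Introns are the
    within-gene complement of the (sorted, merged) exons.
    """
    regions: list[FunctionalRegion] = []
    for g in genes:
        if g.strand == "+":
            p_start, p_end = g.tss - promoter_len, g.tss - 1
        else:
            p_start, p_end = g.tss + 1, g.tss + promoter_len
        p_start = max(1, p_start)
        if chrom_sizes and g.chrom in chrom_sizes:
            p_end = min(p_end, chrom_sizes[g.chrom])
        if p_start <= p_end:
            regions.append(FunctionalRegion(g.gene_id, "promoter", g.chrom, p_start, p_end, g.strand))
        for kind, s, e in g.features:
            if kind in ("five_prime_UTR", "three_prime_UTR"):
                regions.append(FunctionalRegion(g.gene_id, kind, g.chrom, s, e, g.strand))
        exons = g.exons()
        for s, e in exons:
            regions.append(FunctionalRegion(g.gene_id, "exon", g.chrom, s, e, g.strand))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 > e1 + 1:
                regions.append(FunctionalRegion(g.gene_id, "intron", g.chrom, e1 + 1, s2 - 1, g.strand))
    return regions


def methylation_density(
    calls: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    context: str | None = None,
) -> float:
    """Called-methylated / covered cytosines within an interval (NaN if none covered)."""
    sub = calls.loc[(calls["chrom"] == chrom) & (calls["pos"] >= start) & (calls["pos"] <= end)]
    if context is not None:
        sub = sub.loc[sub["context"] == context]
    if sub.empty:
        return float("nan")
    return float(sub["called"].mean())


def _bin_index(pos: np.ndarray, start: int, end: int, strand: str, bins: int) -> np.ndarray:
    """Bin of each position after scaling [start, end] to ``bins`` equal parts,
    strand-aware so bin 0 is 5'-most.  Fractional bin edges keep regions
    shorter than ``bins`` bp well defined."""
    length = end - start + 1
    frac = (pos - start) / length  # in [0, 1)
    idx = np.minimum((frac * bins).astype(int), bins - 1)
    if strand == "-":
        idx = bins - 1 - idx
    return idx


def metagene_profile(
    calls: pd.DataFrame,
    regions: list[FunctionalRegion],
    bins: int = 20,
    contexts=("CG", "CHG", "CHH", "all"),
    mode: str = "calls",
) -> pd.DataFrame:
    """Average binned methylation density per region kind and context.

    ``mode='calls'`` averages the called-site density (sites(mC)/sites(C));
    ``mode='ml'`` averages the per-site corrected methylation level instead.
    Each region contributes its own per-bin densities; the profile is the
    unweighted mean across regions of the kind (bins a region does not cover
    are ignored for that region).  Output columns: kind, bin (1-based from
    the 5' end), context, density, n_regions.
    """
    if mode not in ("calls", "ml"):
        raise ValueError("mode must be 'calls' or 'ml'")
    value_col = "called" if mode == "calls" else "ml_corrected"
    calls_by_chrom = {c: sub.sort_values("pos") for c, sub in calls.groupby("chrom")}
    # accumulate sum and count per (kind, context, bin)
    acc: dict[tuple, np.ndarray] = {}
    cnt: dict[tuple, np.ndarray] = {}
    for kind in REGION_KINDS:
        for ctx in contexts:
            acc[(kind, ctx)] = np.zeros(bins)
            cnt[(kind, ctx)] = np.zeros(bins, dtype=int)
    for reg in regions:
        sub = calls_by_chrom.get(reg.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, reg.start, side="left")
        hi = np.searchsorted(pos, reg.end, side="right")
        if hi == lo:
            continue
        window = sub.iloc[lo:hi]
        idx = _bin_index(window["pos"].to_numpy(), reg.start, reg.end, reg.strand, bins)
        vals = window[value_col].to_numpy(dtype=float)
        ctx_arr = window["context"].to_numpy()
        for ctx in contexts:
            mask = np.ones(len(window), dtype=bool) if ctx == "all" else ctx_arr == ctx
            if not mask.any():
                continue
            sums = np.bincount(idx[mask], weights=vals[mask], minlength=bins)
            ns = np.bincount(idx[mask], minlength=bins)
            covered = ns > 0
            # per-region density per bin, then averaged across regions
            acc[(reg.kind, ctx)][covered] += sums[covered] / ns[covered]
            cnt[(reg.kind, ctx)][covered] += 1
    rows = []
    for (kind, ctx), sums in acc.items():
        ns = cnt[(kind, ctx)]
        for b in range(bins):
            density = sums[b] / ns[b] if ns[b] else float("nan")
            rows.append((kind, b + 1, ctx, density, int(ns[b])))
    return pd.DataFrame(rows, columns=["kind", "bin", "context", "density", "n_regions"])


def _tiling_windows(length: int, window_size: int):
    starts = np.arange(1, length + 1, window_size)
    ends = np.minimum(starts + window_size - 1, length)
    return starts, ends


def chromosome_density(
    calls: pd.DataFrame, chrom_sizes: dict[str, int], window_size: int = 20_000_000
) -> pd.DataFrame:
    """Methylation density in non-overlapping tiling windows along each chromosome."""
    rows = []
    for chrom, length in sorted(chrom_sizes.items()):
        sub = calls.loc[calls["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        called = np.concatenate([[0], np.cumsum(sub["called"].to_numpy(dtype=float))])
        starts, ends = _tiling_windows(length, window_size)
        for s, e in zip(starts, ends):
            lo = np.searchsorted(pos, s, side="left")
            hi = np.searchsorted(pos, e, side="right")
            n = hi - lo
            rows.append((chrom, int(s), int(e), (called[hi] - called[lo]) / n if n else float("nan")))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "density"])


def te_density(
    te_intervals: pd.DataFrame, chrom_sizes: dict[str, int], window_size: int = 20_000
) -> pd.DataFrame:
    """Fraction of each tiling window covered by transposable elements."""
    rows = []
    for chrom, length in sorted(chrom_sizes.items()):
        tes = te_intervals.loc[te_intervals["chrom"] == chrom]
        covered = np.zeros(length + 2, dtype=np.int8)
        for te in tes.itertuples(index=False):
            covered[max(1, te.start) : min(length, te.end) + 1] = 1
        cum = np.concatenate([[0], np.cumsum(covered[1:])])
        starts, ends = _tiling_windows(length, window_size)
        for s, e in zip(starts, ends):
            frac = (cum[e] - cum[s - 1]) / (e - s + 1)
            rows.append((chrom, int(s), int(e), float(frac)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "te_fraction"])


def expression_strata(expr_records) -> dict[str, list[str]]:
    """Partition genes into five FPKM groups (mean of the two samples):
    [0,1) silent, [1,3) low, [3,15) moderate, [15,60) high, [60,inf) highest."""
    groups: dict[str, list[str]] = {name: [] for name, _, _ in STRATA}
    for rec in expr_records:
        fpkm = (rec.fpkm_a + rec.fpkm_b) / 2.0
        if fpkm < 0:
            raise ValueError(f"gene {rec.gene_id}: negative FPKM")
        for name, lo, hi in STRATA:
            if lo <= fpkm < hi:
                groups[name].append(rec.gene_id)
                break
    return groups
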