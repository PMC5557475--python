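"""Site- and genome-level methylation statistics.

The per-site methylation level is ML = m/(m+u) over uniquely-mapped reads;
bisulfite non-conversion inflates it by the rate r (one minus the conversion
rate measured for the library), so the corrected level is
(ML - r)/(1 - r), clamped at zero.  A cytosine is called methylated when its
methylated-read count is inconsistent with pure non-conversion noise: the
count is modelled as Binomial(depth, r), the one-sided upper-tail p-value is
adjusted across all tested sites by Benjamini-Hochberg, and sites with
q below the threshold (default 0.05) at depth >= 5 are called.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._util import enumerate_windows

CONTEXTS = ("CG", "CHG", "CHH")


@dataclass
class MethylomeSample:
    """One sample's strand-resolved cytosine counts plus its non-conversion rate."""

    sample_id: str
    records: pd.DataFrame
    nonconversion_rate: float
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 <= self.nonconversion_rate < 1.0:
            raise ValueError("non-conversion rate must lie in [0, 1)")
        key = self.records[["chrom", "pos", "strand"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, strand) records in sample")

    def chrom_length(self, chrom: str) -> int:
        if chrom in self.chrom_sizes:
            return self.chrom_sizes[chrom]
        sub = self.records.loc[self.records["chrom"] == chrom, "pos"]
        if sub.empty:
            raise KeyError(f"no records on chromosome {chrom}")
        return int(sub.max())


@dataclass
class GenomeSummary:
    """Called-site counts and percentages, genome-wide and per context."""

    pct_mC: float
    pct_mCG: float
    pct_mCHG: float
    pct_mCHH: float
    n_mC: int
    n_mCG: int
    n_mCHG: int
    n_mCHH: int

    def __post_init__(self):
        if self.n_mCG + self.n_mCHG + self.n_mCHH != self.n_mC:
            raise ValueError("context counts must partition the total")


def site_ml(n_meth: int, n_unmeth: int) -> float:
    """Methylation level m/(m+u); undefined at zero depth."""
    depth = n_meth + n_unmeth
    if depth <= 0:
        raise ValueError("methylation level undefined at zero depth")
    return n_meth / depth


def correct_ml(ml, r: float):
    """Non-conversion-corrected level (ML - r)/(1 - r), clamped at 0.

    Accepts scalars or arrays.  r is the fraction of unmethylated cytosines
    that escape conversion and therefore read as methylated.
    """
    if r >= 1.0 or r < 0.0:
        raise ValueError("non-conversion rate must lie in [0, 1)")
    corrected = (np.asarray(ml, dtype=float) - r) / (1.0 - r)
    corrected = np.maximum(corrected, 0.0)
    if np.ndim(ml) == 0:
        return float(corrected)
    return corrected


def binomial_tail_p(n_meth, depth, r: float):
    """P(X >= n_meth) for X ~ Binomial(depth, r); vectorised, exact at r=0."""
    n_meth = np.asarray(n_meth)
    depth = np.asarray(depth)
    return stats.binom.sf(n_meth - 1, depth, r)


def call_methylated_sites(
    sample: MethylomeSample, min_depth: int = 5, q_max: float = 0.05
) -> pd.DataFrame:
    """Binomial methylated-site calling with BH correction across tested sites.

    Sites with depth < ``min_depth`` are not tested.  Returns the tested
    records with columns p, q, called (q < ``q_max``) and ml / ml_corrected.
    """
    from .dmr import bh_adjust

    rec = sample.records
    depth = rec["n_meth"].to_numpy() + rec["n_unmeth"].to_numpy()
    tested = rec.loc[depth >= min_depth].copy()
    tdepth = tested["n_meth"].to_numpy() + tested["n_unmeth"].to_numpy()
    if tested.empty:
        tested["depth"] = tested["p"] = tested["q"] = tested["ml"] = tested["ml_corrected"] = []
        tested["called"] = []
        return tested
    tested["depth"] = tdepth
    p = binomial_tail_p(tested["n_meth"].to_numpy(), tdepth, sample.nonconversion_rate)
    tested["p"] = p
    tested["q"] = bh_adjust(p)
    tested["ml"] = tested["n_meth"].to_numpy() / tdepth
    tested["ml_corrected"] = correct_ml(tested["ml"].to_numpy(), sample.nonconversion_rate)
    tested["called"] = tested["q"] < q_max
    return tested.reset_index(drop=True)


def genome_summary(calls: pd.DataFrame) -> GenomeSummary:
    """Summarise a call table: percent methylated among covered (tested) sites,
    overall and within each context, plus called-site counts."""
    if calls.empty:
        raise ValueError("no covered cytosines to summarise")
    n_called = {c: int(calls.loc[(calls["context"] == c) & calls["called"]].shape[0]) for c in CONTEXTS}
    n_covered = {c: int((calls["context"] == c).sum()) for c in CONTEXTS}
    n_mC = sum(n_called.values())

    def pct(c):
        return 100.0 * n_called[c] / n_covered[c] if n_covered[c] else 0.0

    return GenomeSummary(
        pct_mC=100.0 * n_mC / len(calls),
        pct_mCG=pct("CG"),
        pct_mCHG=pct("CHG"),
        pct_mCHH=pct("CHH"),
        n_mC=n_mC,
        n_mCG=n_called["CG"],
        n_mCHG=n_called["CHG"],
        n_mCHH=n_called["CHH"],
    )


def context_shares(n_mCG: int, n_mCHG: int, n_mCHH: int, ndigits: int = 1) -> dict[str, float]:
    """Share of all called methylated sites falling in each context, in percent.

    This is the 'x% of all mC' decomposition of a genome summary; rounding is
    half-up to ``ndigits`` decimals as percentage tables are printed.
    """
    from ._util import round_half_up

    total = n_mCG + n_mCHG + n_mCHH
    if total <= 0:
        raise ValueError("no called methylated sites")
    return {
        "CG": round_half_up(100.0 * n_mCG / total, ndigits),
        "CHG": round_half_up(100.0 * n_mCHG / total, ndigits),
        "CHH": round_half_up(100.0 * n_mCHH / total, ndigits),
    }


def window_methylation(
    sample: MethylomeSample, w: int = 3000, step: int = 600
) -> pd.DataFrame:
    """Pooled counts and methylation level in sliding windows.

    Windows start at 1, 1+step, ... per chromosome; a final partial window is
    emitted and flagged.  Each window reports the summed methylated and
    unmethylated counts of the cytosines it contains, the pooled ML, and a
    zero-depth flag.
    """
    out = []
    for chrom, sub in sample.records.groupby("chrom", sort=True):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        cm = np.concatenate([[0], np.cumsum(sub["n_meth"].to_numpy())])
        cu = np.concatenate([[0], np.cumsum(sub["n_unmeth"].to_numpy())])
        length = sample.chrom_length(chrom)
        for start, end, partial in enumerate_windows(length, w, step):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            m = int(cm[hi] - cm[lo])
            u = int(cu[hi] - cu[lo])
            depth = m + u
            out.append(
                (
                    chrom,
                    start,
                    end,
                    m,
                    u,
                    m / depth if depth else np.nan,
                    depth == 0,
                    partial,
                )
            )
    return pd.DataFrame(
        out,
        columns=["chrom", "start", "end", "n_meth", "n_unmeth", "ml", "zero_depth", "partial"],
    )
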