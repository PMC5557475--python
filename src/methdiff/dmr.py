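"""Two-sample sliding-window DMR detection.

Each 1-kb window (100-bp step) pools methylated/unmethylated counts over the
cytosines covered at depth >= 5 in both samples, is tested with a two-sided
Fisher exact test on the resulting 2x2 table, and windows passing an FDR
threshold after Benjamini-Hochberg adjustment are assigned a direction by the
sign of the pooled methylation-level difference (sample A relative to B) and
merged, per direction, into maximal differentially methylated regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from ._util import enumerate_windows
from .core import MethylomeSample

__all__ = [
    "WindowTest",
    "Dmr",
    "enumerate_windows",
    "fisher_window_test",
    "bh_adjust",
    "call_dmrs",
    "merge_windows",
    "dmr_effect_summary",
]

_FISHER_REL_TOL = 1e-7


@dataclass
class WindowTest:
    chrom: str
    start: int
    end: int
    a_meth: int
    a_unmeth: int
    b_meth: int
    b_unmeth: int
    p: float
    q: float = float("nan")
    direction: str = "none"


@dataclass
class Dmr:
    """A maximal run of merged significant windows of one direction."""

    chrom: str
    start: int
    end: int
    direction: str
    n_windows: int
    min_q: float
    ml_a: float
    ml_b: float
    context_counts: dict = field(default_factory=dict)


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_window_test(a_meth: int, a_unmeth: int, b_meth: int, b_unmeth: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a_meth, a_unmeth], [b_meth, b_unmeth]].

    Enumerates the tables sharing the observed margins and sums the
    probabilities of those no more likely than the observed table (within a
    relative tolerance guarding against log-space round-off).
    """
    for c in (a_meth, a_unmeth, b_meth, b_unmeth):
        if c < 0:
            raise ValueError("counts must be non-negative")
    r1 = a_meth + a_unmeth
    r2 = b_meth + b_unmeth
    if r1 == 0 or r2 == 0:
        raise ValueError("both samples need at least one read in the window")
    n = r1 + r2
    c1 = a_meth + b_meth
    if c1 == 0 or c1 == n:
        return 1.0
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    a = np.arange(lo, hi + 1)
    logp = (
        _log_comb(r1, a)
        + _log_comb(r2, c1 - a)
        - _log_comb(n, c1)
    )
    p_obs = logp[a_meth - lo]
    total = np.exp(logp[logp <= p_obs + np.log1p(_FISHER_REL_TOL)]).sum()
    return float(min(1.0, total))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _pool_windows(chrom, length, pos, a_m, a_u, b_m, b_u, w, step):
    """Pool per-site counts into sliding windows via cumulative sums."""
    order = np.argsort(pos, kind="stable")
    pos = pos[order]
    cums = {
        name: np.concatenate([[0], np.cumsum(arr[order])])
        for name, arr in (("a_m", a_m), ("a_u", a_u), ("b_m", b_m), ("b_u", b_u))
    }
    nsite = np.concatenate([[0], np.cumsum(np.ones_like(pos))])
    rows = []
    for start, end, partial in enumerate_windows(length, w, step):
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="right")
        if nsite[hi] - nsite[lo] < 1:
            continue  # no eligible cytosine: test skipped
        rows.append(
            (
                chrom,
                start,
                end,
                int(cums["a_m"][hi] - cums["a_m"][lo]),
                int(cums["a_u"][hi] - cums["a_u"][lo]),
                int(cums["b_m"][hi] - cums["b_m"][lo]),
                int(cums["b_u"][hi] - cums["b_u"][lo]),
            )
        )
    return rows


def joint_site_table(sample_a: MethylomeSample, sample_b: MethylomeSample, min_depth: int = 5) -> pd.DataFrame:
    """Inner join of the two samples on (chrom, pos, strand), keeping only
    cytosines covered at depth >= min_depth in BOTH samples."""
    a = sample_a.records.rename(columns={"n_meth": "a_m", "n_unmeth": "a_u"})
    b = sample_b.records.rename(columns={"n_meth": "b_m", "n_unmeth": "b_u"})[
        ["chrom", "pos", "strand", "b_m", "b_u"]
    ]
    joint = a.merge(b, on=["chrom", "pos", "strand"], how="inner")
    keep = ((joint["a_m"] + joint["a_u"]) >= min_depth) & ((joint["b_m"] + joint["b_u"]) >= min_depth)
    return joint.loc[keep].reset_index(drop=True)


def call_dmrs(
    sample_a: MethylomeSample,
    sample_b: MethylomeSample,
    w: int = 1000,
    step: int = 100,
    fdr: float = 0.05,
    min_depth: int = 5,
    context: str | None = None,
    min_delta: float = 0.1,
    min_fold_change: float | None = None,
) -> tuple[pd.DataFrame, list[Dmr]]:
    """Fisher-test sliding windows and merge significant ones into DMRs.

    Counts are pooled per window over cytosines with depth >= ``min_depth``
    in both samples (all contexts pooled unless ``context`` restricts to one
    of CG/CHG/CHH).  BH is applied across all tested windows; windows with
    q <= ``fdr`` and a pooled methylation-level difference of at least
    ``min_delta`` get a direction from sign(ML_A - ML_B), and same-direction
    overlapping or book-ended windows merge into maximal DMRs.

    ``min_delta`` is an effect-size floor: at high read totals the exact test
    detects biologically meaningless sub-percent shifts, and because truly
    differential windows merge into few regions while spurious ones stay as
    isolated single-window calls, FDR measured per merged region would far
    exceed the window-level level without it.  Set it to 0 to threshold on
    q alone.  ``min_fold_change`` optionally adds the alternative reading of
    a fold-change filter: significant windows must also satisfy
    max(ML_A, ML_B)/min(ML_A, ML_B) >= min_fold_change.

    Returns (window table, DMR list).
    """
    chroms_a = set(sample_a.records["chrom"])
    chroms_b = set(sample_b.records["chrom"])
    if not chroms_a & chroms_b:
        raise ValueError("samples share no chromosome")
    joint = joint_site_table(sample_a, sample_b, min_depth)
    if context is not None:
        joint = joint.loc[joint["context"] == context]

    rows = []
    for chrom, sub in joint.groupby("chrom", sort=True):
        length = max(sample_a.chrom_length(chrom), sample_b.chrom_length(chrom))
        rows.extend(
            _pool_windows(
                chrom,
                length,
                sub["pos"].to_numpy(),
                sub["a_m"].to_numpy(),
                sub["a_u"].to_numpy(),
                sub["b_m"].to_numpy(),
                sub["b_u"].to_numpy(),
                w,
                step,
            )
        )
    windows = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "a_meth", "a_unmeth", "b_meth", "b_unmeth"]
    )
    if windows.empty:
        windows["p"] = windows["q"] = []
        windows["direction"] = []
        return windows, []

    windows = windows.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    windows["p"] = [
        fisher_window_test(r.a_meth, r.a_unmeth, r.b_meth, r.b_unmeth)
        for r in windows.itertuples(index=False)
    ]
    windows["q"] = bh_adjust(windows["p"].to_numpy())
    ml_a = windows["a_meth"] / (windows["a_meth"] + windows["a_unmeth"])
    ml_b = windows["b_meth"] / (windows["b_meth"] + windows["b_unmeth"])
    windows["ml_a"], windows["ml_b"] = ml_a, ml_b
    sig = (windows["q"] <= fdr) & ((ml_a - ml_b).abs() >= max(min_delta, np.finfo(float).tiny))
    if min_fold_change is not None:
        eps = 1e-12
        fold = np.maximum(ml_a, ml_b) / np.maximum(np.minimum(ml_a, ml_b), eps)
        sig &= fold >= min_fold_change
    windows["direction"] = "none"
    windows.loc[sig & (ml_a > ml_b), "direction"] = "hyper"
    windows.loc[sig & (ml_a < ml_b), "direction"] = "hypo"

    dmrs = merge_windows(windows.loc[windows["direction"] != "none"], joint)
    return windows, dmrs


def merge_windows(sig_windows: pd.DataFrame, joint: pd.DataFrame | None = None) -> list[Dmr]:
    """Merge overlapping or book-ended significant windows of equal direction
    into maximal DMRs; opposite directions never merge.  Idempotent and
    independent of input row order."""
    dmrs: list[Dmr] = []
    sw = sig_windows.sort_values(["chrom", "start", "end"], kind="stable")
    for (chrom, direction), sub in sw.groupby(["chrom", "direction"], sort=True):
        cur = None
        members: list = []
        for row in sub.itertuples(index=False):
            if cur is not None and row.start <= cur[1] + 1:
                cur = (cur[0], max(cur[1], row.end))
                members.append(row)
            else:
                if cur is not None:
                    dmrs.append(_finalise_dmr(chrom, direction, cur, members, joint))
                cur = (row.start, row.end)
                members = [row]
        if cur is not None:
            dmrs.append(_finalise_dmr(chrom, direction, cur, members, joint))
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.direction))
    return dmrs


def _finalise_dmr(chrom, direction, span, members, joint):
    start, end = span
    min_q = min(m.q for m in members)
    ctx_counts: dict = {}
    if joint is not None and not joint.empty:
        sub = joint.loc[
            (joint["chrom"] == chrom) & (joint["pos"] >= start) & (joint["pos"] <= end)
        ]
        am, au = int(sub["a_m"].sum()), int(sub["a_u"].sum())
        bm, bu = int(sub["b_m"].sum()), int(sub["b_u"].sum())
        ml_a = am / (am + au) if am + au else float("nan")
        ml_b = bm / (bm + bu) if bm + bu else float("nan")
        if "context" in sub.columns:
            for ctx, csub in sub.groupby("context"):
                ctx_counts[ctx] = {
                    "a_meth": int(csub["a_m"].sum()),
                    "a_unmeth": int(csub["a_u"].sum()),
                    "b_meth": int(csub["b_m"].sum()),
                    "b_unmeth": int(csub["b_u"].sum()),
                }
    else:
        am = sum(m.a_meth for m in members)
        au = sum(m.a_unmeth for m in members)
        bm = sum(m.b_meth for m in members)
        bu = sum(m.b_unmeth for m in members)
        ml_a = am / (am + au) if am + au else float("nan")
        ml_b = bm / (bm + bu) if bm + bu else float("nan")
    return Dmr(
        chrom=chrom,
        start=int(start),
        end=int(end),
        direction=direction,
        n_windows=len(members),
        min_q=float(min_q),
        ml_a=float(ml_a),
        ml_b=float(ml_b),
        context_counts=ctx_counts,
    )


def dmr_effect_summary(dmr: Dmr, sample_a: MethylomeSample, sample_b: MethylomeSample) -> dict:
    """Pooled corrected methylation level per sample over the DMR and their
    difference (A minus B); the sign agrees with the DMR direction."""
    from .core import correct_ml

    out = {}
    for name, sample in (("a", sample_a), ("b", sample_b)):
        sub = sample.records.loc[
            (sample.records["chrom"] == dmr.chrom)
            & (sample.records["pos"] >= dmr.start)
            & (sample.records["pos"] <= dmr.end)
        ]
        m, u = int(sub["n_meth"].sum()), int(sub["n_unmeth"].sum())
        ml = m / (m + u) if m + u else float("nan")
        out[f"ml_{name}"] = correct_ml(ml, sample.nonconversion_rate) if m + u else float("nan")
    out["delta"] = out["ml_a"] - out["ml_b"]
    return out


def dmrs_to_frame(dmrs: list[Dmr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.chrom, d.start, d.end, d.direction, d.n_windows, d.min_q, d.ml_a, d.ml_b)
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "direction", "n_windows", "min_q", "ml_a", "ml_b"],
    )
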