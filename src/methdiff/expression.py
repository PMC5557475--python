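"""Differential expression calls, relative qRT-PCR quantification and the
methylation-expression sign-concordance summary.

A gene is differentially expressed when |log2 fold change| >= 1 at
FDR <= 0.05 (both bounds inclusive).  Relative expression from qRT-PCR uses
2^-ddCt with the maintainer sample as calibrator: dCt = Ct(target) -
Ct(reference) within each sample, ddCt = dCt_A - dCt_B, and a value above 1
is up-regulation in A.  Negative methylation-expression concordance means a
hyper-methylated gene is down-regulated or a hypo-methylated gene is
up-regulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass
class QpcrMeasurement:
    gene_id: str
    ct_target_a: float
    ct_ref_a: float
    ct_target_b: float
    ct_ref_b: float
    rel_expr: float = float("nan")
    call: str = ""
    pvalue: float | None = None


def classify_de(log2fc: float, fdr: float, fc_min: float = 1.0, fdr_max: float = 0.05) -> str:
    """'up' / 'down' / 'not_de' from a DE table row; boundaries inclusive."""
    if not 0.0 <= fdr <= 1.0:
        raise ValueError("FDR must lie in [0, 1]")
    if fdr <= fdr_max:
        if log2fc >= fc_min:
            return "up"
        if log2fc <= -fc_min:
            return "down"
    return "not_de"


def delta_delta_ct(q: QpcrMeasurement) -> QpcrMeasurement:
    """Fill rel_expr = 2^-ddCt and the up/down/unchanged call."""
    for v in (q.ct_target_a, q.ct_ref_a, q.ct_target_b, q.ct_ref_b):
        if not math.isfinite(v):
            raise ValueError("Ct values must be finite")
    dct_a = q.ct_target_a - q.ct_ref_a
    dct_b = q.ct_target_b - q.ct_ref_b
    ddct = dct_a - dct_b
    q.rel_expr = 2.0 ** (-ddct)
    if q.rel_expr > 1.0:
        q.call = "up"
    elif q.rel_expr < 1.0:
        q.call = "down"
    else:
        q.call = "unchanged"
    return q


def qpcr_from_ct_table(ct_table: pd.DataFrame, sample_a: str = "A", sample_b: str = "B") -> list[QpcrMeasurement]:
    """Average replicate Cts per gene and sample, then apply 2^-ddCt.

    When per-replicate values are present (>1 replicate per gene/sample) a
    two-sample t-test on the replicate-level 2^-ddCt values is reported in
    the measurement's ``pvalue`` attribute; means-only input skips testing.
    """
    out = []
    for gene_id, sub in ct_table.groupby("gene_id", sort=True):
        a = sub.loc[sub["sample"] == sample_a]
        b = sub.loc[sub["sample"] == sample_b]
        if a.empty or b.empty:
            raise ValueError(f"gene {gene_id}: missing sample rows")
        q = QpcrMeasurement(
            gene_id=str(gene_id),
            ct_target_a=float(a["ct_target"].mean()),
            ct_ref_a=float(a["ct_reference"].mean()),
            ct_target_b=float(b["ct_target"].mean()),
            ct_ref_b=float(b["ct_reference"].mean()),
        )
        delta_delta_ct(q)
        if len(a) > 1 and len(b) > 1:
            # replicate-level relative expression, calibrated on B's mean dCt
            dct_b_mean = q.ct_target_b - q.ct_ref_b
            rel_a = 2.0 ** (-((a["ct_target"] - a["ct_reference"]) - dct_b_mean))
            rel_b = 2.0 ** (-((b["ct_target"] - b["ct_reference"]) - dct_b_mean))
            if rel_a.nunique() == 1 and rel_b.nunique() == 1:  # degenerate: no replicate spread
                q.pvalue = 0.0 if q.rel_expr != 1.0 else 1.0
            else:
                q.pvalue = float(stats.ttest_ind(rel_a, rel_b).pvalue)
        out.append(q)
    return out


def sign_concordance(methylation_direction: dict[str, str], expr_calls: dict[str, str]) -> pd.DataFrame:
    """Per-gene negative-concordance flags for genes present in both inputs.

    ``methylation_direction`` maps gene -> hyper/hypo (unstable genes have no
    single direction and are excluded); ``expr_calls`` maps gene -> up/down/
    unchanged/not_de.  Negative concordance = (hyper and down) or (hypo and
    up).  The summary count is the number of flagged genes.
    """
    rows = []
    for gene in sorted(set(methylation_direction) & set(expr_calls)):
        mdir = methylation_direction[gene]
        call = expr_calls[gene]
        if mdir not in ("hyper", "hypo"):
            continue
        concordant = (mdir == "hyper" and call == "down") or (mdir == "hypo" and call == "up")
        rows.append((gene, mdir, call, concordant))
    return pd.DataFrame(rows, columns=["gene_id", "methylation", "expression", "negative_concordant"])
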