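"""Hypergeometric over-representation of DMG sets in term-to-gene maps.

For a term annotating K of N background genes, with n of the DMGs annotated
at all and k of them in the term, the enrichment p-value is the upper
hypergeometric tail P(X >= k).  BH q-values are reported alongside; the
significance cut follows the raw p by default, matching over-representation
pipelines that threshold the unadjusted p at 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .dmr import bh_adjust


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # DMGs in term
    n: int  # DMGs annotated to any term
    K: int  # background genes in term
    N: int  # background annotated genes
    p: float
    q: float = float("nan")


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def read_term_map(path) -> dict[str, set[str]]:
    """Two-column TSV (term_id, gene_id), or GMT (term, description, genes...)."""
    term_map: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
        fh.seek(0)
        is_gmt = str(path).endswith(".gmt") or len(first.rstrip("\n").split("\t")) > 2
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            if is_gmt:
                term, genes = parts[0], parts[2:]
            else:
                term, genes = parts[0], [parts[1]]
            term_map.setdefault(term, set()).update(g for g in genes if g)
    return term_map


def enrich_terms(
    dmg_ids,
    term_map: dict[str, set[str]],
    background_ids=None,
    p_max: float = 0.05,
    term_names: dict[str, str] | None = None,
) -> list[EnrichmentResult]:
    """Test every term containing >= 1 DMG; sorted by p ascending.

    The background defaults to all genes with at least one term annotation;
    DMGs outside the background are ignored (they carry no annotation to
    test).  Significance at raw p < ``p_max`` is marked by result order and
    the reported p; BH q-values are attached for FDR-based filtering.
    """
    annotated = set().union(*term_map.values()) if term_map else set()
    background = set(background_ids) if background_ids is not None else annotated
    dmgs = set(dmg_ids) & background
    n, N = len(dmgs), len(background)
    results = []
    for term, genes in term_map.items():
        genes_bg = genes & background
        k = len(dmgs & genes_bg)
        if k < 1:
            continue
        K = len(genes_bg)
        results.append(
            EnrichmentResult(
                term_id=term,
                term_name=(term_names or {}).get(term, ""),
                k=k,
                n=n,
                K=K,
                N=N,
                p=hypergeometric_pvalue(k, n, K, N),
            )
        )
    if results:
        qs = bh_adjust([r.p for r in results])
        for r, q in zip(results, qs):
            r.q = float(q)
    results.sort(key=lambda r: (r.p, r.term_id))
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.term_name, r.k, r.n, r.K, r.N, r.p, r.q) for r in results],
        columns=["term_id", "term_name", "k", "n", "K", "N", "p", "q"],
    )
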