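"""Readers and writers for the formats the pipeline touches.

All in-memory coordinates are 1-based inclusive (the convention of both the
Bismark cytosine report and GFF3); BED is converted at the boundary to
0-based half-open.  Reading is gzip-transparent throughout.  This module does
no computation beyond validation.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VALID_CONTEXTS = ("CG", "CHG", "CHH")

CX_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tricontext"]


class FormatError(ValueError):
    """A malformed record in an input file; message names the offending line."""


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-resolved cytosine with its read support and context."""

    chrom: str
    pos: int
    strand: str
    n_meth: int
    n_unmeth: int
    context: str
    tricontext: str

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass
class GeneModel:
    """A gene reduced to one transcript's structure.

    ``features`` holds (kind, start, end) with kind in {five_prime_UTR, exon,
    three_prime_UTR}; introns are inferred downstream as the within-gene
    complement of the exons.  ``tss`` is the 5'-most coordinate on +, the
    3'-most on -.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int
    features: list[tuple[str, int, int]] = field(default_factory=list)

    def exons(self) -> list[tuple[int, int]]:
        return sorted((s, e) for k, s, e in self.features if k == "exon")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    fpkm_a: float
    fpkm_b: float
    log2fc: float
    fdr: float


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return _io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def context_of_trinucleotide(tri: str) -> str | None:
    """CG/CHG/CHH classification of a 3-mer read 5'->3' from the cytosine.

    Returns None when the trinucleotide contains bases outside ACGT (e.g. at
    contig edges), in which case consistency cannot be checked.
    """
    if len(tri) != 3 or any(b not in "ACGT" for b in tri):
        return None
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a Bismark-style cytosine (CX) report.

    Tab-separated, 7 columns: chrom, 1-based position, strand, methylated
    count, unmethylated count, context (CG/CHG/CHH), trinucleotide.  Records
    are returned in file order; zero-depth rows are retained (depth filters
    are applied downstream).  Malformed rows raise :class:`FormatError`
    naming the line number.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 7:
                raise FormatError(f"line {lineno}: expected 7 tab-separated fields, got {len(parts)}")
            chrom, pos_s, strand, m_s, u_s, context, tri = parts
            try:
                pos, n_meth, n_unmeth = int(pos_s), int(m_s), int(u_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer position or count") from None
            if pos < 1:
                raise FormatError(f"line {lineno}: position {pos} is not 1-based positive")
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: unknown strand {strand!r}")
            if n_meth < 0 or n_unmeth < 0:
                raise FormatError(f"line {lineno}: negative read count")
            if context not in VALID_CONTEXTS:
                raise FormatError(f"line {lineno}: unknown context token {context!r}")
            expected = context_of_trinucleotide(tri)
            if expected is not None and expected != context:
                raise FormatError(
                    f"line {lineno}: context {context} inconsistent with trinucleotide {tri}"
                )
            rows.append((chrom, pos, strand, n_meth, n_unmeth, context, tri))
    df = pd.DataFrame(rows, columns=CX_COLUMNS)
    if df.empty:
        df = df.astype({"pos": int, "n_meth": int, "n_unmeth": int})
    return df


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", header=False, index=False, columns=CX_COLUMNS)


def read_gene_models(path_gff3, transcript_policy: str = "longest") -> list[GeneModel]:
    """Parse gene models from GFF3.

    For multi-transcript genes, ``transcript_policy='longest'`` keeps the
    transcript with the largest summed exon length; ``'union'`` merges the
    exon union across transcripts.  A child feature whose Parent chain does
    not resolve to a gene raises :class:`FormatError`.
    """
    import gffutils

    if transcript_policy not in ("longest", "union"):
        raise ValueError("transcript_policy must be 'longest' or 'union'")
    db = gffutils.create_db(
        str(path_gff3),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        transcripts = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not transcripts:
            transcripts = [gene]  # single-level gene entries
        per_tx: list[list[tuple[str, int, int]]] = []
        for tx in transcripts:
            feats: list[tuple[str, int, int]] = []
            for kind in ("five_prime_UTR", "exon", "three_prime_UTR"):
                for child in db.children(tx, featuretype=kind, order_by="start"):
                    if child.seqid != gene.seqid:
                        raise FormatError(
                            f"feature {child.id} lies on {child.seqid}, not gene chromosome {gene.seqid}"
                        )
                    feats.append((kind, child.start, child.end))
            per_tx.append(feats)
        if transcript_policy == "longest":
            chosen = max(
                per_tx,
                key=lambda fs: sum(e - s + 1 for k, s, e in fs if k == "exon"),
            )
        else:
            merged_exons = _merge_intervals(
                [(s, e) for fs in per_tx for k, s, e in fs if k == "exon"]
            )
            chosen = [(k, s, e) for fs in per_tx for k, s, e in fs if k != "exon"]
            chosen += [("exon", s, e) for s, e in merged_exons]
        tss = gene.start if gene.strand == "+" else gene.end
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                tss=tss,
                start=gene.start,
                end=gene.end,
                features=chosen,
            )
        )
    # orphan check: any feature whose parent chain hits a missing ID
    for feat in db.all_features():
        for parent_id in feat.attributes.get("Parent", []):
            try:
                db[parent_id]
            except gffutils.FeatureNotFoundError:
                raise FormatError(f"feature {feat.id} has unresolvable parent {parent_id}") from None
    return genes


def _merge_intervals(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_te_bed(path) -> pd.DataFrame:
    """Transposable-element intervals from BED (>=3 cols); returns 1-based inclusive."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise FormatError(f"line {lineno}: empty or inverted BED interval")
            rows.append((chrom, start0 + 1, end0))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_dmr_bed(dmrs: Sequence, path) -> None:
    """BED6 for DMRs: 0-based half-open, name = direction, score = -10*log10(q) capped at 1000."""
    from ._util import bed_score

    with open(path, "w", encoding="utf-8") as fh:
        for d in dmrs:
            fh.write(
                f"{d.chrom}\t{d.start - 1}\t{d.end}\t{d.direction}\t{bed_score(d.min_q)}\t.\n"
            )


def read_dmr_bed(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            chrom, start0, end0, name, score, strand = line.split("\t")[:6]
            rows.append((chrom, int(start0) + 1, int(end0), name, int(score)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "score"])


def write_table(rows: pd.DataFrame, path) -> None:
    """TSV with header; the lossless counterpart of :func:`read_table`."""
    rows.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression_table(path) -> list[ExpressionRecord]:
    """Expression + DE table: gene_id, fpkm_a, fpkm_b, log2fc, fdr (TSV, header)."""
    df = read_table(path)
    recs = []
    for row in df.itertuples(index=False):
        if not 0.0 <= row.fdr <= 1.0:
            raise FormatError(f"gene {row.gene_id}: FDR {row.fdr} outside [0,1]")
        if row.fpkm_a < 0 or row.fpkm_b < 0:
            raise FormatError(f"gene {row.gene_id}: negative FPKM")
        recs.append(
            ExpressionRecord(row.gene_id, float(row.fpkm_a), float(row.fpkm_b), float(row.log2fc), float(row.fdr))
        )
    return recs


def read_ct_table(path) -> pd.DataFrame:
    """qRT-PCR table: gene_id, sample, replicate, ct_target, ct_reference."""
    df = read_table(path)
    required = {"gene_id", "sample", "replicate", "ct_target", "ct_reference"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"Ct table missing columns: {sorted(missing)}")
    return df
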