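"""Synthetic two-sample bisulfite methylome with planted differential regions.

The generator emulates the data-generating structure of a soybean
flower-bud WGBS comparison between a cytoplasmic male-sterile line (sample
A) and its near-isogenic maintainer (sample B): a random genome with tunable
GC content, strand-resolved cytosines classified into CG/CHG/CHH contexts,
context-specific baseline methylation (mCG 0.48, mCHG 0.38, mCHH 0.07),
Poisson sequencing depth, beta-binomial overdispersion of methylated counts,
per-sample bisulfite non-conversion (conversion failures make unmethylated
cytosines read as methylated at rate r), planted differentially methylated
regions of configured width and effect in sample A, and gene expression
negatively coupled to promoter methylation differences.  Every random draw
flows from the single seed in the config; a config reproduces its output
byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MethylomeSample
from .io import GeneModel, write_cytosine_report

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class PlantedDmr:
    """One planted differential region: sample A's true methylation level is
    shifted by delta_ml (clipped to [0,1]) at every cytosine inside."""

    chrom: str
    start: int
    end: int
    delta_ml: float

    @property
    def direction(self) -> str:
        return "hyper" if self.delta_ml > 0 else "hypo"


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 300_000
    n_genes: int = 60
    gc_content: float = 0.35
    base_ml: dict = field(default_factory=lambda: {"CG": 0.48, "CHG": 0.38, "CHH": 0.07})
    depth_mean: float = 15.0
    overdispersion: float = 0.05  # beta-binomial rho
    r_a: float = 0.0025  # non-conversion, sample A (conversion 99.75%)
    r_b: float = 0.0061  # non-conversion, sample B (conversion 99.39%)
    planted: list = field(default_factory=list)  # PlantedDmr entries
    expression_slope: float = -5.0  # log2FC per unit promoter |delta ML|
    expression_noise_sd: float = 0.4
    ct_noise_sd: float = 0.0
    n_tes: int = 40

    def __post_init__(self):
        for p in list(self.base_ml.values()) + [self.gc_content, self.overdispersion]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for r in (self.r_a, self.r_b):
            if not 0.0 <= r < 1.0:
                raise ValueError("non-conversion rate must lie in [0, 1)")
        spans: dict[str, list[tuple[int, int]]] = {}
        for d in self.planted:
            if d.start < 1 or d.end > self.chrom_length or d.start > d.end:
                raise ValueError(f"planted region {d} outside the genome")
            for s, e in spans.get(d.chrom, []):
                if d.start <= e and s <= d.end:
                    raise ValueError(f"planted regions overlap on {d.chrom}")
            spans.setdefault(d.chrom, []).append((d.start, d.end))


@dataclass
class SyntheticTruth:
    """Ground-truth manifest: what was planted, with which parameters."""

    planted: list
    r_a: float
    r_b: float
    seed: int
    chrom_sizes: dict
    coupled_genes: dict = field(default_factory=dict)  # gene_id -> true log2fc
    expression_class: dict = field(default_factory=dict)  # gene_id -> up/down/not_de

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "r_a": self.r_a,
            "r_b": self.r_b,
            "chrom_sizes": self.chrom_sizes,
            "planted": [asdict(p) for p in self.planted],
            "coupled_genes": self.coupled_genes,
            "expression_class": self.expression_class,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            planted=[PlantedDmr(**p) for p in payload["planted"]],
            r_a=payload["r_a"],
            r_b=payload["r_b"],
            seed=payload["seed"],
            chrom_sizes=payload["chrom_sizes"],
            coupled_genes=payload.get("coupled_genes", {}),
            expression_class=payload.get("expression_class", {}),
        )


def _chrom_names(n: int) -> list[str]:
    return [f"Chr{i + 1:02d}" for i in range(n)]


def simulate_genome(config: SimulationConfig) -> dict[str, str]:
    """Random genome sequences with the configured GC content."""
    rng = np.random.default_rng(config.seed)
    probs = [
        (1 - config.gc_content) / 2,  # A
        config.gc_content / 2,  # C
        config.gc_content / 2,  # G
        (1 - config.gc_content) / 2,  # T
    ]
    bases = np.array(list("ACGT"))
    genome = {}
    for chrom in _chrom_names(config.n_chrom):
        seq = rng.choice(bases, size=config.chrom_length, p=probs)
        genome[chrom] = "".join(seq)
    return genome


def cytosine_sites(genome: dict[str, str]) -> pd.DataFrame:
    """Strand-resolved cytosines with trinucleotide context.

    A '+' site is a C read left-to-right; a '-' site is a G on the top strand,
    whose context is the reverse complement read 5'->3' on the bottom strand.
    Sites too close to a contig edge for a full trinucleotide are skipped.
    """
    rows = []
    for chrom in sorted(genome):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        plus = np.flatnonzero(arr == b"C")
        plus = plus[plus <= len(seq) - 3]
        minus = np.flatnonzero(arr == b"G")
        minus = minus[minus >= 2]
        for idx, strand in ((plus, "+"), (minus, "-")):
            for i in idx:
                if strand == "+":
                    tri = seq[i : i + 3]
                else:
                    tri = "".join(_COMP[b] for b in reversed(seq[i - 2 : i + 1]))
                if tri[1] == "G":
                    ctx = "CG"
                elif tri[2] == "G":
                    ctx = "CHG"
                else:
                    ctx = "CHH"
                rows.append((chrom, int(i) + 1, strand, ctx, tri))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "tricontext"])
    return df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)


def simulate_gene_models(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Non-overlapping gene models with UTRs and 2-5 exons, leaving >= 2.5 kb
    intergenic room so every gene keeps a full promoter.

    Deterministic in the config: when no generator is passed, one is derived
    from the config seed, so repeated calls yield identical models.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 4)
    genes: list[GeneModel] = []
    chroms = _chrom_names(config.n_chrom)
    per_chrom = int(np.ceil(config.n_genes / config.n_chrom))
    gid = 0
    for chrom in chroms:
        cursor = 2500
        for _ in range(per_chrom):
            if gid >= config.n_genes:
                break
            length = int(rng.integers(2000, 6001))
            start = cursor + int(rng.integers(0, 1500))
            end = start + length - 1
            if end > config.chrom_length - 2500:
                break
            n_exons = int(rng.integers(2, 6))
            cuts = np.sort(rng.choice(np.arange(start + 50, end - 50), size=2 * n_exons - 2, replace=False))
            bounds = [start, *cuts.tolist(), end]
            exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)]
            strand = "+" if rng.random() < 0.5 else "-"
            utr5 = exons[0] if strand == "+" else exons[-1]
            utr3 = exons[-1] if strand == "+" else exons[0]
            features = [("exon", s, e) for s, e in exons]
            features.append(("five_prime_UTR", utr5[0], utr5[1]))
            features.append(("three_prime_UTR", utr3[0], utr3[1]))
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    tss=start if strand == "+" else end,
                    start=start,
                    end=end,
                    features=features,
                )
            )
            cursor = end + 2500
    return genes


def simulate_te_intervals(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom in _chrom_names(config.n_chrom):
        n = max(1, config.n_tes // config.n_chrom)
        starts = rng.integers(1, config.chrom_length - 5000, size=n)
        for s in np.sort(starts):
            length = int(rng.integers(500, 5001))
            rows.append((chrom, int(s), min(int(s) + length - 1, config.chrom_length)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def plant_dmrs_in_promoters(
    config: SimulationConfig,
    genes: list[GeneModel],
    rng: np.random.Generator,
    n_dmrs: int = 20,
    width: int = 1000,
    delta_ml: float = 0.3,
    promoter_fraction: float = 0.6,
) -> list[PlantedDmr]:
    """Choose planted regions: a fraction sit inside gene promoters (so
    expression coupling has substrate), the rest land intergenically.
    Directions alternate hypo/hyper with more hypo, mirroring the field
    observation that hypo-methylation dominates in the sterile line."""
    planted: list[PlantedDmr] = []
    candidates = [g for g in genes if g.strand in "+-"]
    rng.shuffle(candidates)
    n_prom = int(round(n_dmrs * promoter_fraction))
    used: dict[str, list[tuple[int, int]]] = {}

    def free(chrom, s, e):
        return all(not (s <= ee and ss <= e) for ss, ee in used.get(chrom, []))

    for g in candidates:
        if len(planted) >= n_prom:
            break
        if g.strand == "+":
            s = max(1, g.tss - width - 200)
        else:
            s = g.tss + 200
        e = s + width - 1
        if e > config.chrom_length or not free(g.chrom, s, e):
            continue
        sign = -1.0 if (len(planted) % 3) != 2 else 1.0  # 2/3 hypo, 1/3 hyper
        planted.append(PlantedDmr(g.chrom, s, e, sign * delta_ml))
        used.setdefault(g.chrom, []).append((s, e))
    attempts = 0
    while len(planted) < n_dmrs and attempts < 1000:
        attempts += 1
        chrom = _chrom_names(config.n_chrom)[int(rng.integers(config.n_chrom))]
        s = int(rng.integers(1, config.chrom_length - width))
        e = s + width - 1
        if not free(chrom, s, e):
            continue
        sign = -1.0 if (len(planted) % 3) != 2 else 1.0
        planted.append(PlantedDmr(chrom, s, e, sign * delta_ml))
        used.setdefault(chrom, []).append((s, e))
    return planted


def _site_methylome(rng, baseline, rho):
    """Per-site true methylation levels: a beta draw around the context
    baseline with intraclass correlation rho (site-to-site heterogeneity of
    the tissue's methylome).  rho = 0 collapses to the baseline exactly."""
    ml = np.asarray(baseline, dtype=float).copy()
    if rho > 0:
        inner = (1.0 - rho) / rho
        interior = (ml > 0) & (ml < 1)
        if interior.any():
            ml[interior] = rng.beta(ml[interior] * inner, (1.0 - ml[interior]) * inner)
    return ml


def simulate_methylome_pair(
    config: SimulationConfig, outdir: str | Path | None = None
) -> tuple[MethylomeSample, MethylomeSample, SyntheticTruth]:
    """Two-sample cytosine reports with planted differential regions.

    One underlying methylome is drawn for the tissue: each cytosine's true
    methylation level is a beta perturbation of its context baseline with
    intraclass correlation rho, so observed counts are marginally
    beta-binomial.  Both samples share that methylome — the study compares
    two near-isogenic lines without biological replicates, and the
    window-level Fisher test models only read-sampling noise — except inside
    planted regions, where sample A's level is shifted by delta (clipped to
    [0, 1]).  Per sample and cytosine, depth ~ Poisson(depth_mean) and the
    methylated count is Binomial(depth, mu) with apparent rate
    mu = ML + (1 - ML) * r: conversion failures inflate apparent methylation
    of the unmethylated fraction at the sample's non-conversion rate.
    """
    genome = simulate_genome(config)
    sites = cytosine_sites(genome)
    rng = np.random.default_rng(config.seed + 1)

    baseline = sites["context"].map(config.base_ml).to_numpy(dtype=float)
    ml_b = _site_methylome(rng, baseline, config.overdispersion)
    ml_a = ml_b.copy()
    for d in config.planted:
        mask = (sites["chrom"] == d.chrom).to_numpy() & (
            (sites["pos"] >= d.start) & (sites["pos"] <= d.end)
        ).to_numpy()
        ml_a[mask] = np.clip(ml_a[mask] + d.delta_ml, 0.0, 1.0)

    samples = {}
    for sample_id, ml, r in (("A", ml_a, config.r_a), ("B", ml_b, config.r_b)):
        depth = rng.poisson(config.depth_mean, size=len(sites))
        mu = ml + (1.0 - ml) * r
        n_meth = rng.binomial(depth, np.clip(mu, 0.0, 1.0))
        rec = sites.copy()
        rec["n_meth"] = n_meth.astype(int)
        rec["n_unmeth"] = (depth - n_meth).astype(int)
        rec = rec[["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "tricontext"]]
        samples[sample_id] = MethylomeSample(
            sample_id=sample_id,
            records=rec,
            nonconversion_rate=r,
            chrom_sizes={c: config.chrom_length for c in genome},
        )
    truth = SyntheticTruth(
        planted=list(config.planted),
        r_a=config.r_a,
        r_b=config.r_b,
        seed=config.seed,
        chrom_sizes={c: config.chrom_length for c in genome},
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cytosine_report(samples["A"].records, outdir / "sample_a.cx.tsv")
        write_cytosine_report(samples["B"].records, outdir / "sample_b.cx.tsv")
        truth.to_json(outdir / "truth.json")
    return samples["A"], samples["B"], truth


def simulate_expression(
    config: SimulationConfig, truth: SyntheticTruth, genes: list[GeneModel], promoter_len: int = 2000
) -> pd.DataFrame:
    """FPKM + DE table with expression coupled to planted promoter methylation.

    Genes whose promoter overlaps a planted region receive
    log2FC = slope * delta_ml + noise (so promoter hyper-methylation in A
    pushes expression down when slope < 0) and a near-zero FDR; uncoupled
    genes get log2FC ~ N(0, 0.3) and a large FDR.  The truth manifest gains
    each gene's true fold change and expression class.
    """
    rng = np.random.default_rng(config.seed + 2)
    rows = []
    for g in genes:
        if g.strand == "+":
            p_s, p_e = max(1, g.tss - promoter_len), g.tss - 1
        else:
            p_s, p_e = g.tss + 1, g.tss + promoter_len
        delta = 0.0
        for d in truth.planted:
            if d.chrom == g.chrom and d.start <= p_e and p_s <= d.end:
                delta = d.delta_ml
                break
        base_fpkm = float(10 ** rng.normal(0.7, 0.6))
        if delta != 0.0:
            log2fc = config.expression_slope * delta + rng.normal(0.0, config.expression_noise_sd)
            fdr = float(rng.uniform(0.0, 0.01))
            truth.coupled_genes[g.gene_id] = float(log2fc)
        else:
            log2fc = float(rng.normal(0.0, 0.3))
            fdr = float(rng.uniform(0.1, 1.0))
        fpkm_b = base_fpkm
        fpkm_a = base_fpkm * 2.0**log2fc
        if log2fc >= 1 and fdr <= 0.05:
            truth.expression_class[g.gene_id] = "up"
        elif log2fc <= -1 and fdr <= 0.05:
            truth.expression_class[g.gene_id] = "down"
        else:
            truth.expression_class[g.gene_id] = "not_de"
        rows.append((g.gene_id, fpkm_a, fpkm_b, float(log2fc), fdr))
    return pd.DataFrame(rows, columns=["gene_id", "fpkm_a", "fpkm_b", "log2fc", "fdr"])


def simulate_qpcr(
    truth: SyntheticTruth,
    expression: pd.DataFrame,
    genes=None,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    seed_offset: int = 3,
) -> pd.DataFrame:
    """Ct tables whose 2^-ddCt reproduces the simulated fold change.

    Reference-gene Cts are fixed at 20; target Cts in the calibrator (B) sit
    near 24 and sample A's target Ct is back-computed so that
    ddCt = -log2(fold change) exactly.  Optional per-replicate Gaussian
    noise models pipetting variation.
    """
    rng = np.random.default_rng(truth.seed + seed_offset)
    gene_ids = genes if genes is not None else sorted(truth.coupled_genes)
    expr = expression.set_index("gene_id")
    rows = []
    for gene_id in gene_ids:
        log2fc = float(expr.loc[gene_id, "log2fc"])
        ct_ref = 20.0
        ct_target_b = 24.0
        ct_target_a = ct_target_b - log2fc  # ddCt = -log2fc
        for rep in range(1, n_replicates + 1):
            rows.append(
                (gene_id, "A", rep, ct_target_a + rng.normal(0, ct_noise_sd) if ct_noise_sd else ct_target_a, ct_ref)
            )
            rows.append(
                (gene_id, "B", rep, ct_target_b + rng.normal(0, ct_noise_sd) if ct_noise_sd else ct_target_b, ct_ref)
            )
    return pd.DataFrame(rows, columns=["gene_id", "sample", "replicate", "ct_target", "ct_reference"])


def simulate_term_map(
    genes: list[GeneModel], rng: np.random.Generator, n_terms: int = 25, mean_size: int = 8
) -> dict[str, set[str]]:
    """Random term->gene map so enrichment can run end-to-end on simulated data."""
    ids = [g.gene_id for g in genes]
    term_map = {}
    for t in range(1, n_terms + 1):
        size = max(2, int(rng.poisson(mean_size)))
        term_map[f"TERM:{t:04d}"] = set(rng.choice(ids, size=min(size, len(ids)), replace=False))
    return term_map


def write_gene_models_gff3(genes: list[GeneModel], path) -> None:
    """Emit gene models as GFF3 (gene > mRNA > exon/UTR) for io round-trips."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tsim\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            tx = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsim\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={tx};Parent={g.gene_id}\n"
            )
            for i, (kind, s, e) in enumerate(sorted(g.features, key=lambda f: (f[1], f[0])), 1):
                fh.write(
                    f"{g.chrom}\tsim\t{kind}\t{s}\t{e}\t.\t{g.strand}\t.\tID={tx}.{kind}.{i};Parent={tx}\n"
                )


def default_simulation(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-condition config: two 300-kb chromosomes, 60 genes, depth 15,
    rho 0.05, Table-1 non-conversion rates, and twenty planted 1-kb regions
    with |delta ML| = 0.3 (promoter-biased, two-thirds hypo in A)."""
    config = SimulationConfig(seed=seed, **{k: v for k, v in overrides.items() if k != "n_dmrs"})
    genes = simulate_gene_models(config)
    rng = np.random.default_rng(seed + 17)
    config.planted = plant_dmrs_in_promoters(
        config, genes, rng, n_dmrs=overrides.get("n_dmrs", 20)
    )
    return config
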