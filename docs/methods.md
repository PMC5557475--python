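# Methods

`methdiff` reimplements, as a tested pipeline, the bioinformatic stages of a
two-sample whole-genome bisulfite sequencing (WGBS) comparison between a
cytoplasmic male-sterile (CMS) soybean line and its near-isogenic maintainer:
methylation-level computation, methylated-site calling, density profiles,
differentially methylated region (DMR) and gene (DMG) identification, term
enrichment, and methylation–expression integration.  This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic data does and does not establish.

## Methylation levels and non-conversion correction

The methylation level at a strand-resolved cytosine is

    ML = m / (m + u)

with m and u the methylated/unmethylated read counts from uniquely mapped
reads.  Bisulfite conversion is imperfect: a fraction r of unmethylated
cytosines escapes conversion and reads as methylated (r = 1 − conversion
rate; the two libraries here measure 99.75% and 99.39% conversion, so
r_A = 0.0025 and r_B = 0.0061).  The corrected level is

    ML_corrected = (ML − r) / (1 − r)

clamped at 0 when ML < r — a proportion cannot be negative, and sampling
noise routinely produces ML slightly below r at genuinely unmethylated
sites.

## Methylated-site calling

The methylated count at a covered site is modelled under the null of "no
methylation, only conversion failure" as Binomial(m + u, r).  Sites with
depth ≥ 5 are tested with the one-sided upper tail P(X ≥ m), p-values are
adjusted across all tested sites by Benjamini–Hochberg, and sites with
q < 0.05 are called methylated.  The null rate r is the sample-wide
non-conversion rate: it is the only rate the conversion-control measurement
quantifies, so no per-site rate is attempted.  The depth-5 floor is applied
per site; a descriptive 3000-bp/600-bp sliding-window track of pooled counts
is computed separately (both units are exposed; per-site calling with BH
across sites is the default because pooling windows before calling would
conflate neighbouring sites of different contexts).  The q-value procedure
is Benjamini–Hochberg throughout the package; no Storey-style estimation of
the null proportion is used.

## Functional regions and density profiles

The promoter is the 2-kb region upstream of the transcription start site
(strand-aware, truncated at chromosome bounds and omitted when the TSS is
flush against the edge); the gene body is 5′UTR, exons, introns (the
within-gene complement of the exons) and 3′UTR.  For multi-transcript genes
the transcript with the largest summed exon length is used (configurable to
the exon union).

Methylation *density* over an interval is sites(mC)/sites(C): the fraction
of covered cytosines called methylated.  Metagene profiles scale each region
of a kind to 20 equal bins (bin 1 at the 5′ end; fractional bin edges keep
sub-20-bp regions well defined, each site falling in the bin containing its
position) and average per-bin densities across regions *unweighted* — each
region contributes equally regardless of length or coverage; a pooled-bp
mode would weight long exons more heavily and is not the default.  Because
a density of called sites and a mean of corrected MLs can both reproduce
the published profile shapes, both are implemented (`mode='calls'` default,
`mode='ml'`).

Chromosome-scale tracks tile the genome into non-overlapping windows
(20 kb for TE fraction, 20 Mb for methylation density at genome scale);
expression strata split genes by FPKM into [0,1) silent, [1,3) low, [3,15)
moderate, [15,60) high and [60,∞) highest.  The published "0–1, 1–3, …"
bounds are ambiguous at the boundaries; left-closed half-open intervals
were chosen so every gene lands in exactly one stratum.

## DMR detection

Windows of 1000 bp at 100-bp step are enumerated per chromosome, starting
at position 1; the final partial window is emitted and flagged so no
sequence is silently dropped.  Within a window, counts are pooled over the
cytosines covered at depth ≥ 5 **in both samples** (the depth threshold is
read as minimum per-cytosine coverage, consistent with the site-calling
depth rule; a fold-change reading is available behind
`min_fold_change`), all contexts pooled by default with a per-context mode.
Each window's 2×2 table (sample × methylation state) is tested with the
two-sided Fisher exact test — implemented by enumerating the fixed-margin
tables and summing the probabilities not exceeding the observed table's
(relative tolerance 1e-7 against log-space round-off) — and BH is applied
across all tested windows.

Windows with q ≤ 0.05 *and* a pooled methylation-level difference
|ML_A − ML_B| ≥ 0.1 are assigned a direction by the sign of the difference
(hyper = higher in the CMS line), and overlapping or book-ended
same-direction windows are merged into maximal DMRs; opposite directions
never merge, which is what allows a gene to be hit by both and classed
methylation-unstable.  The effect-size floor deserves a comment, because it
is the one knob beyond the significance threshold: at window read totals in
the thousands, an exact test flags sub-percent level differences that no
analyst would call differential methylation, and since truly differential
windows merge many-to-one into regions while isolated borderline windows
each become a region of their own, a q-threshold alone lets region-level
false discoveries far exceed the window-level FDR.  A 0.1 floor (10
percentage points, well below any plausibly interesting effect and well
above pooled-count noise at ≥5× depth) restores region-level control;
setting `min_delta=0` recovers pure q-thresholding.  Ties in BH are broken
by genomic order purely for deterministic output.

## DMG annotation and classification

A DMR hits a gene when it overlaps any functional region of that gene by
≥ 1 bp.  Gene status is hypo if all its hits are hypo-directed, hyper if all
hyper, unstable if both occur (across any kinds).  Per-kind summaries count
*distinct genes* with ≥ 1 hit of the given direction and with any hit; the
rate is the any-direction count over the total DMG count.  A gene hit in one
kind by both directions is counted once in that kind's total but appears in
both direction columns — with the published data no gene does both within a
kind, which is why the published per-kind hypo + hyper sums equal the totals.
Percentages are rounded half-up to one decimal (57.938 → 57.9).  Note the
published hyper-gene share "18.2%" is 18.14% by this arithmetic (88/485);
the package reports 18.1 and does not attempt to reproduce the discrepancy.

## Enrichment

Term over-representation uses the hypergeometric upper tail
P(X ≥ k | N, K, n) for a term with K annotated background genes, n annotated
DMGs and k DMGs in the term, with BH q-values attached.  The background
defaults to all genes carrying at least one annotation, configurable.  This
is a plain over-representation test: no transcript-length bias correction
(the Wallenius-weighting approach used by GOseq for GO) and no GO-DAG
propagation; term→gene maps are user-supplied (two-column TSV or GMT).

## Expression integration

Differential expression: up if log2FC ≥ 1 and FDR ≤ 0.05, down if
log2FC ≤ −1 and FDR ≤ 0.05 (bounds inclusive as stated), else not
differential.  qRT-PCR relative expression is 2^−ΔΔCt with the maintainer
as calibrator; a value above 1 is up-regulation, below 1 down-regulation,
and exactly 1 (defined only by the two inequalities in the source protocol)
is reported "unchanged".  When per-replicate Cts are supplied, a two-sample
t-test on replicate-level 2^−ΔΔCt values is attached; means-only input
skips testing.  Negative methylation–expression concordance is
(hyper ∧ down) ∨ (hypo ∧ up), summarised per gene and in total.

## Synthetic data: what it emulates, and what it does not

The generator draws a random genome (GC 0.35, near the soybean euchromatic
average), classifies every strand-resolved cytosine into CG/CHG/CHH from
its trinucleotide, and assigns context baselines mCG = 0.48, mCHG = 0.38,
mCHH = 0.07 — the published context-level means for these libraries.  One
*tissue methylome* is drawn: each site's true level is a beta perturbation
of its baseline with intraclass correlation ρ = 0.05, so observed counts
are marginally beta-binomial.  Both samples share that methylome — each
line was sequenced from a single pooled flower-bud sample, so the Fisher
stage sees exactly the read-sampling noise it models — except inside
planted regions, where the CMS-line sample's level is shifted by ΔML
(clipped to [0,1]).  Per sample, depth is Poisson (mean 15 by default; 30
in the recovery analysis) and the methylated count is Binomial(depth, μ)
with apparent rate μ = ML + (1 − ML)·r, the observable consequence of
non-conversion.  Default planting: twenty 1-kb regions, |ΔML| = 0.3,
two-thirds hypo in the CMS line (mirroring the observed dominance of
hypo-methylation), placed preferentially in promoters so the expression
coupling has substrate.  Expression: coupled genes receive
log2FC = −5·ΔML + N(0, 0.4) with near-zero FDR — promoter hyper-methylation
silences — and uncoupled genes N(0, 0.3) with large FDR.  Ct tables are
back-computed so 2^−ΔΔCt reproduces the simulated fold change exactly
(replicate noise is a knob, default 0).  All randomness flows from the
single config seed; output is byte-identical per config.

What passing on this data does **not** show: robustness to between-sample
biological variance (two tissue pools drawn independently would break the
Fisher model's assumptions, and region-level FDR would rise — a known
limitation of pooled-count exact-test DMR callers), bimodal CG methylation
landscapes (real plant CG methylation is near-0/near-1 bimodal; the
generator uses unimodal per-context baselines, so *calling* rates per
context exceed the published percentages even though pooled *levels* match),
mapping artefacts, coverage biases, or context-specific DMR behaviour.
The published genome-scale counts (48.5 M called sites, 3527 DMRs, 485
DMGs) derive from undeposited raw data and are exercised only through the
arithmetic of the summary and classification stages on the printed counts.

## Problem sizes and numerical choices

The bundled analyses use two 300-kb chromosomes with 60 genes (~2×10⁵
cytosine records per sample; ~6×10³ DMR windows), and the null-calibration
run uses two ~1-Mb chromosomes (~2×10⁴ windows) — sizes chosen so each
property is measured with comfortable statistical resolution.  Fisher
p-values are computed in log space via log-gamma (max observed deviation
from exact integer enumeration over all tables with N ≤ 40: ~5×10⁻¹⁴);
binomial and hypergeometric tails come from scipy's survival functions;
BH from statsmodels.  Degenerate inputs are explicit: zero-depth sites are
kept on read and filtered by depth rules, windows with no eligible cytosine
are skipped and flagged, zero-margin Fisher tables are rejected, and an
empty call table raises rather than returning a vacuous summary.
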