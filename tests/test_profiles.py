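import numpy as np
import pandas as pd
import pytest

from methdiff import profiles
from methdiff.io import ExpressionRecord, GeneModel


def gene(gene_id="g1", chrom="Chr01", strand="+", start=5000, end=8000, exons=None):
    exons = exons or [(start, end)]
    tss = start if strand == "+" else end
    feats = [("exon", s, e) for s, e in exons]
    return GeneModel(gene_id, chrom, strand, tss, start, end, feats)


class TestFunctionalRegions:
    def test_promoter_plus_strand(self):
        regs = profiles.derive_functional_regions([gene(strand="+", start=5000)])
        prom = next(r for r in regs if r.kind == "promoter")
        assert (prom.start, prom.end) == (3000, 4999)

    def test_promoter_minus_strand(self):
        regs = profiles.derive_functional_regions([gene(strand="-", end=8000)])
        prom = next(r for r in regs if r.kind == "promoter")
        assert (prom.start, prom.end) == (8001, 10000)

    def test_promoter_truncated_at_chromosome_start(self):
        regs = profiles.derive_functional_regions([gene(start=500, end=2000)])
        prom = next(r for r in regs if r.kind == "promoter")
        assert (prom.start, prom.end) == (1, 499)

    def test_promoter_omitted_when_no_room(self):
        regs = profiles.derive_functional_regions([gene(start=1, end=2000)])
        assert not [r for r in regs if r.kind == "promoter"]

    def test_promoter_truncated_at_chromosome_end_minus_strand(self):
        regs = profiles.derive_functional_regions(
            [gene(strand="-", end=8000)], chrom_sizes={"Chr01": 9000}
        )
        prom = next(r for r in regs if r.kind == "promoter")
        assert (prom.start, prom.end) == (8001, 9000)

    def test_intron_is_exon_complement(self):
        g = gene(start=100, end=400, exons=[(100, 200), (300, 400)])
        regs = profiles.derive_functional_regions([g])
        intron = next(r for r in regs if r.kind == "intron")
        assert (intron.start, intron.end) == (201, 299)


def calls_frame(positions, called, chrom="Chr01", context="CG"):
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": positions,
            "strand": "+",
            "context": context,
            "called": called,
            "ml_corrected": np.asarray(called, dtype=float),
        }
    )


class TestDensity:
    def test_fraction_of_called_sites(self):
        calls = calls_frame(range(1, 11), [True] * 3 + [False] * 7)
        assert profiles.methylation_density(calls, "Chr01", 1, 10) == pytest.approx(0.3)

    def test_extremes_and_uncovered(self):
        calls = calls_frame([5, 6], [True, True])
        assert profiles.methylation_density(calls, "Chr01", 1, 10) == 1.0
        assert np.isnan(profiles.methylation_density(calls, "Chr01", 100, 200))

    def test_context_filter(self):
        calls = pd.concat(
            [calls_frame([1], [True], context="CG"), calls_frame([2], [False], context="CHH")]
        )
        assert profiles.methylation_density(calls, "Chr01", 1, 10, context="CHH") == 0.0


class TestMetagene:
    def test_five_prime_half_methylated_region(self):
        # 100-bp exon methylated only in its 5' half: bins 1-10 at 1, 11-20 at 0
        g = gene(start=1, end=100, exons=[(1, 100)])
        regs = [r for r in profiles.derive_functional_regions([g]) if r.kind == "exon"]
        calls = calls_frame(range(1, 101), [True] * 50 + [False] * 50)
        prof = profiles.metagene_profile(calls, regs, contexts=("all",))
        exon = prof[(prof["kind"] == "exon")].set_index("bin")["density"]
        assert (exon.loc[1:10] == 1.0).all()
        assert (exon.loc[11:20] == 0.0).all()

    def test_minus_strand_mirrors_plus(self):
        calls = calls_frame(range(1, 101), [True] * 50 + [False] * 50)
        plus = [profiles.FunctionalRegion("g", "exon", "Chr01", 1, 100, "+")]
        minus = [profiles.FunctionalRegion("g", "exon", "Chr01", 1, 100, "-")]
        p_prof = profiles.metagene_profile(calls, plus, contexts=("all",))
        m_prof = profiles.metagene_profile(calls, minus, contexts=("all",))
        p_vals = p_prof[p_prof["kind"] == "exon"].sort_values("bin")["density"].to_numpy()
        m_vals = m_prof[m_prof["kind"] == "exon"].sort_values("bin")["density"].to_numpy()
        assert np.allclose(p_vals, m_vals[::-1])

    def test_uniform_methylome_flat_profile(self, small_sim):
        from methdiff import core

        calls = core.call_methylated_sites(small_sim["a"])
        calls = calls.assign(called=True)
        regs = profiles.derive_functional_regions(small_sim["genes"])
        prof = profiles.metagene_profile(calls, regs, contexts=("all",))
        covered = prof.dropna(subset=["density"])
        assert (covered["density"] == 1.0).all()

    def test_region_shorter_than_bin_count(self):
        regs = [profiles.FunctionalRegion("g", "exon", "Chr01", 10, 14, "+")]
        calls = calls_frame([10, 12, 14], [True, False, True])
        prof = profiles.metagene_profile(calls, regs, contexts=("all",))
        exon = prof[prof["kind"] == "exon"].dropna(subset=["density"])
        assert len(exon) == 3  # one bin per covered site
        assert set(exon["density"]) == {0.0, 1.0}

    def test_promoter_enriched_methylome_shape(self, small_sim):
        """With hypermethylated promoters planted upstream of genes, promoter
        bins should exceed gene-body bins on average."""
        from methdiff import core
        from methdiff.profiles import FunctionalRegion

        calls = core.call_methylated_sites(small_sim["a"])
        # synthetic planted shape: mark promoter windows as fully called
        g = small_sim["genes"][0]
        regs = profiles.derive_functional_regions([g])
        prom = next(r for r in regs if r.kind == "promoter")
        boosted = calls.copy()
        in_prom = (
            (boosted["chrom"] == prom.chrom)
            & (boosted["pos"] >= prom.start)
            & (boosted["pos"] <= prom.end)
        )
        in_body = (boosted["chrom"] == g.chrom) & (boosted["pos"] >= g.start) & (boosted["pos"] <= g.end)
        boosted.loc[in_prom, "called"] = True
        boosted.loc[in_body, "called"] = False
        prof = profiles.metagene_profile(boosted, regs, contexts=("all",))
        prom_mean = prof[prof["kind"] == "promoter"]["density"].mean()
        exon_mean = prof[prof["kind"] == "exon"]["density"].dropna().mean()
        assert prom_mean > exon_mean


class TestTracks:
    def test_te_fraction_arithmetic(self):
        tes = pd.DataFrame({"chrom": ["Chr01"], "start": [1], "end": [10_000]})
        track = profiles.te_density(tes, {"Chr01": 20_000}, window_size=20_000)
        assert track.iloc[0].te_fraction == pytest.approx(0.5)

    def test_te_full_and_empty_windows(self):
        tes = pd.DataFrame({"chrom": ["Chr01"], "start": [1], "end": [20_000]})
        track = profiles.te_density(tes, {"Chr01": 40_000}, window_size=20_000)
        assert track.iloc[0].te_fraction == 1.0
        assert track.iloc[1].te_fraction == 0.0

    def test_tiling_windows_cover_chromosome_exactly_once(self):
        track = profiles.te_density(
            pd.DataFrame(columns=["chrom", "start", "end"]), {"Chr01": 50_500}, window_size=20_000
        )
        assert track.iloc[0].start == 1
        assert (track["start"].iloc[1:].to_numpy() == track["end"].iloc[:-1].to_numpy() + 1).all()
        assert track.iloc[-1].end == 50_500
        assert (track["end"] - track["start"] + 1).sum() == 50_500

    def test_chromosome_density_basic(self):
        calls = calls_frame([100, 30_000], [True, False])
        track = profiles.chromosome_density(calls, {"Chr01": 40_000}, window_size=20_000)
        assert track.iloc[0].density == 1.0 and track.iloc[1].density == 0.0


class TestExpressionStrata:
    def rec(self, gid, fpkm):
        return ExpressionRecord(gid, fpkm, fpkm, 0.0, 1.0)

    def test_boundary_assignment(self):
        groups = profiles.expression_strata(
            [
                self.rec("silent", 0.5),
                self.rec("low_edge", 1.0),
                self.rec("high", 20.0),
                self.rec("highest", 100.0),
                self.rec("highest_edge", 60.0),
            ]
        )
        assert "silent" in groups["silent"]
        assert "low_edge" in groups["low"]
        assert "high" in groups["high"]
        assert {"highest", "highest_edge"} <= set(groups["highest"])

    def test_partition(self):
        rng = np.random.default_rng(0)
        recs = [self.rec(f"g{i}", float(f)) for i, f in enumerate(rng.exponential(20, 200))]
        groups = profiles.expression_strata(recs)
        assert sum(len(v) for v in groups.values()) == len(recs)

    def test_negative_fpkm_rejected(self):
        with pytest.raises(ValueError):
            profiles.expression_strata([ExpressionRecord("g", -1.0, 0.0, 0.0, 1.0)])
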