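"""Windowed diversity estimators and downstream contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hsrscan.divergence_stats import (
    exon_density,
    hsr_fst_enrichment,
    pool_frequency_distance,
    rate_contrast,
    windowed_diversity,
    windowed_dxy,
    windowed_fst,
    windowed_pi,
)
from hsrscan.genomic_io import ExonSet, IntervalSet, RecombMap, union_intervals
from hsrscan.overlap_model import OverlapTrack

from conftest import make_panel


def brute_pi(haps, accessible):
    n = haps.shape[0]
    total = sum(
        np.sum(haps[i] != haps[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2) / accessible


def brute_dxy(a, b, accessible):
    total = sum(np.sum(ha != hb) for ha in a for hb in b)
    return total / (a.shape[0] * b.shape[0]) / accessible


class TestPi:
    def test_identical_haplotypes_zero(self):
        panel = make_panel(np.tile([0, 1, 0], (4, 1)))
        out = windowed_pi(panel, "query", 1000, {"chr1": 1000})
        assert out["pi"].iloc[0] == 0.0

    def test_single_difference(self):
        panel = make_panel(np.array([[0], [1]]), pos=np.array([10]))
        out = windowed_pi(panel, "query", 1000, {"chr1": 1000})
        assert out["pi"].iloc[0] == pytest.approx(0.001)

    def test_matches_all_pairs_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 10))
            m = int(rng.integers(1, 30))
            haps = rng.integers(0, 2, (n, m))
            panel = make_panel(haps, pos=np.arange(m))
            out = windowed_pi(panel, "query", 5000, {"chr1": 5000})
            assert out["pi"].iloc[0] == pytest.approx(brute_pi(haps, 5000))

    def test_relabeling_invariant(self):
        rng = np.random.default_rng(1)
        haps = rng.integers(0, 2, (6, 40))
        a = windowed_pi(make_panel(haps), "query", 5000, {"chr1": 5000})
        b = windowed_pi(make_panel(haps[::-1]), "query", 5000, {"chr1": 5000})
        assert a["pi"].iloc[0] == pytest.approx(b["pi"].iloc[0])


class TestDxy:
    def test_fixed_difference(self):
        a = make_panel(np.array([[1], [1]]), pos=np.array([10]))
        b = make_panel(np.array([[0], [0]]), pos=np.array([10]))
        out = windowed_dxy(a, b, 1000, {"chr1": 1000})
        assert out["dxy"].iloc[0] == pytest.approx(0.001)

    def test_symmetric_in_groups(self):
        rng = np.random.default_rng(2)
        ha, hb = rng.integers(0, 2, (3, 30)), rng.integers(0, 2, (4, 30))
        a, b = make_panel(ha), make_panel(hb)
        d1 = windowed_dxy(a, b, 5000, {"chr1": 5000})["dxy"].iloc[0]
        d2 = windowed_dxy(b, a, 5000, {"chr1": 5000})["dxy"].iloc[0]
        assert d1 == pytest.approx(d2)

    def test_matches_cross_pairs_loop(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            ha = rng.integers(0, 2, (int(rng.integers(2, 6)), 20))
            hb = rng.integers(0, 2, (int(rng.integers(2, 6)), 20))
            out = windowed_dxy(make_panel(ha), make_panel(hb), 2000, {"chr1": 2000})
            assert out["dxy"].iloc[0] == pytest.approx(brute_dxy(ha, hb, 2000))


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        a = make_panel(np.ones((4, 1), dtype=int), pos=np.array([10]))
        b = make_panel(np.zeros((6, 1), dtype=int), pos=np.array([10]))
        out = windowed_fst(a, b, 1000, {"chr1": 1000}, maf=0.0)
        assert out["fst"].iloc[0] == pytest.approx(1.0)

    def test_single_site_direct_evaluation(self):
        """p1=0.2, p2=0.8, n1=n2=16 evaluates to 0.498."""
        from hsrscan.divergence_stats import hudson_fst_sums

        num, den = hudson_fst_sums(np.array([0.2]), np.array([0.8]), 16, 16)
        assert num / den == pytest.approx(0.498, abs=5e-4)

    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(4)
        haps = rng.integers(0, 2, (40, 400))
        a, b = make_panel(haps[:20]), make_panel(haps[20:])
        out = windowed_fst(a, b, 40_000, {"chr1": 40_000}, maf=0.0)
        assert abs(out["fst"].iloc[0]) < 0.05

    def test_monomorphic_window_missing(self):
        a = make_panel(np.zeros((4, 1), dtype=int), pos=np.array([10]))
        b = make_panel(np.zeros((4, 1), dtype=int), pos=np.array([10]))
        out = windowed_fst(a, b, 1000, {"chr1": 1000})
        assert np.isnan(out["fst"].iloc[0])

    def test_matches_ratio_of_sums_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = int(rng.integers(1, 20))
            ha = rng.integers(0, 2, (8, m))
            hb = rng.integers(0, 2, (6, m))
            out = windowed_fst(make_panel(ha), make_panel(hb), 5000, {"chr1": 5000}, maf=0.0)
            p1, p2 = ha.mean(0), hb.mean(0)
            num = ((p1 - p2) ** 2 - p1 * (1 - p1) / 7 - p2 * (1 - p2) / 5).sum()
            den = (p1 * (1 - p2) + p2 * (1 - p1)).sum()
            if den == 0:
                assert np.isnan(out["fst"].iloc[0])
            else:
                assert out["fst"].iloc[0] == pytest.approx(num / den)


class TestEnrichment:
    @staticmethod
    def track_for(regions, length, k=1):
        edges = [0]
        counts = []
        for _, s, e in sorted(regions):
            if s > edges[-1]:
                counts.append(0)
                edges.append(s)
            counts.append(k)
            edges.append(e)
        if edges[-1] < length:
            counts.append(0)
            edges.append(length)
        return OverlapTrack("A", 8, {"c": np.array(edges)}, {"c": np.array(counts)})

    def test_binomial_tail_closed_form(self):
        """10 windows in the bin, 8 high-F_ST, genome fraction ~0.1."""
        n = 100
        fst = np.full(n, 0.1)
        fst[:8] = 0.9  # 8 high windows, inside the k=1 region
        fst[50:52] = 0.9  # 2 high outside -> genome fraction 10/100
        df = pd.DataFrame({"chrom": "c", "start": np.arange(n) * 5000,
                           "end": (np.arange(n) + 1) * 5000, "fst": fst})
        track = self.track_for([("c", 0, 50_000)], n * 5000)  # windows 0..9
        out = hsr_fst_enrichment(track, df, high_fst=0.5)
        row = out[out["k"] == 1].iloc[0]
        p0 = 0.1
        expect = sum(
            stats.binom.pmf(j, 10, p0) for j in range(8, 11)
        )
        assert row["p_binomial"] == pytest.approx(expect, rel=1e-9)
        assert row["n_windows"] == 10 and row["n_high_fst"] == 8

    def test_bin_at_genome_fraction_not_enriched(self):
        rng = np.random.default_rng(6)
        n = 400
        fst = np.where(rng.random(n) < 0.3, 0.9, 0.1)
        df = pd.DataFrame({"chrom": "c", "start": np.arange(n) * 5000,
                           "end": (np.arange(n) + 1) * 5000, "fst": fst})
        track = self.track_for([("c", 0, n * 5000 // 2)], n * 5000)
        out = hsr_fst_enrichment(track, df, high_fst=0.5)
        row = out[out["k"] == 1].iloc[0]
        assert abs(row["m_value"]) < 0.5
        assert row["p_binomial"] > 0.01

    def test_zero_high_fst_all_fractions_zero(self):
        n = 50
        df = pd.DataFrame({"chrom": "c", "start": np.arange(n) * 5000,
                           "end": (np.arange(n) + 1) * 5000, "fst": np.full(n, 0.2)})
        track = self.track_for([("c", 0, 100_000)], n * 5000)
        out = hsr_fst_enrichment(track, df, high_fst=0.6)
        assert (out["fraction_high"] == 0).all()

    def test_pvalues_uniform_under_null(self):
        """Random region placement over iid window flags: the binomial tail
        p-values are uniform (KS not rejected at alpha = 0.01)."""
        rng = np.random.default_rng(42)
        n_win = 2000
        L = n_win * 5000
        pvals = []
        for _ in range(200):
            fst = np.where(rng.random(n_win) < 0.3, 0.7, 0.1)
            df = pd.DataFrame({"chrom": "c", "start": np.arange(n_win) * 5000,
                               "end": (np.arange(n_win) + 1) * 5000, "fst": fst})
            s = int(rng.integers(0, L - 2_500_000))
            track = OverlapTrack("A", 8, {"c": np.array([0, s, s + 2_500_000, L])},
                                 {"c": np.array([0, 1, 0])})
            out = hsr_fst_enrichment(track, df, high_fst=0.5)
            pvals.append(float(out.loc[out["k"] == 1, "p_binomial"].iloc[0]))
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestExonDensity:
    def test_region_inside_exon(self):
        regions = IntervalSet.from_records([("c", 100, 200)])
        exons = ExonSet(IntervalSet.from_records([("c", 0, 500)]), 1000)
        assert exon_density(regions, exons) == pytest.approx(1.0)

    def test_no_overlap_zero(self):
        regions = IntervalSet.from_records([("c", 100, 200)])
        exons = ExonSet(IntervalSet.from_records([("c", 300, 400)]), 1000)
        assert exon_density(regions, exons) == 0.0

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(7)
        L = 5000
        for _ in range(200):
            ex = []
            for _ in range(3):
                s = int(rng.integers(0, L - 100))
                ex.append(("c", s, min(s + int(rng.integers(10, 200)), L)))
            rg = []
            for _ in range(int(rng.integers(1, 4))):
                s = int(rng.integers(0, L - 200))
                rg.append(("c", s, min(s + int(rng.integers(50, 400)), L)))
            exon_iv = union_intervals(IntervalSet.from_records(ex))
            regions = IntervalSet.from_records(rg)
            exons = ExonSet(exon_iv, L)
            e_mask = np.zeros(L, dtype=bool)
            for _, s, e in exon_iv.records():
                e_mask[s:e] = True
            r_mask = np.zeros(L, dtype=bool)
            for _, s, e in rg:
                r_mask[s:e] = True
            expect = (e_mask & r_mask).sum() / r_mask.sum()
            assert exon_density(regions, exons) == pytest.approx(expect)


class TestRateContrast:
    @staticmethod
    def flat_map(rate_by_window, win=100_000):
        n = len(rate_by_window)
        return RecombMap(
            starts={"c": np.arange(n) * win},
            ends={"c": (np.arange(n) + 1) * win},
            rates={"c": np.asarray(rate_by_window, dtype=float)},
        )

    def test_identical_sets_no_difference(self):
        rmap = self.flat_map([1.0, 2.0, 3.0, 4.0])
        iv = IntervalSet.from_records([("c", 0, 400_000)])
        out = rate_contrast(iv, rmap, background=iv)
        assert out["region_mean_cM_per_Mb"] == pytest.approx(out["background_mean_cM_per_Mb"])

    def test_uniform_map_equal_means(self):
        rmap = self.flat_map([2.0] * 10)
        iv = IntervalSet.from_records([("c", 100_000, 300_000)])
        out = rate_contrast(iv, rmap)
        assert out["region_mean_cM_per_Mb"] == pytest.approx(2.0)
        assert out["background_mean_cM_per_Mb"] == pytest.approx(2.0)

    def test_welch_matches_textbook_formula(self):
        rmap = self.flat_map([0.5, 0.6, 0.7, 3.0, 3.5, 4.0, 4.5, 5.0])
        iv = IntervalSet.from_records([("c", 0, 300_000)])
        out = rate_contrast(iv, rmap)
        x = np.array([0.5, 0.6, 0.7])
        y = np.array([3.0, 3.5, 4.0, 4.5, 5.0])
        t = (x.mean() - y.mean()) / np.sqrt(x.var(ddof=1) / 3 + y.var(ddof=1) / 5)
        assert out["t_statistic"] == pytest.approx(t)

    def test_region_outside_map_rejected(self):
        rmap = self.flat_map([1.0])
        iv = IntervalSet.from_records([("c", 50_000, 200_000)])
        with pytest.raises(ValueError):
            rate_contrast(iv, rmap)


class TestPoolDistance:
    def test_identical_pools_zero(self):
        df = pd.DataFrame({"p1": [0.1, 0.5], "p2": [0.1, 0.5]})
        d = pool_frequency_distance(df)
        assert d.loc["p1", "p2"] == 0.0

    def test_constant_half_difference(self):
        df = pd.DataFrame({"p1": [0.0, 0.2], "p2": [0.5, 0.7]})
        assert pool_frequency_distance(df).loc["p1", "p2"] == pytest.approx(0.5)

    def test_missing_rejected(self):
        df = pd.DataFrame({"p1": [0.1, np.nan], "p2": [0.2, 0.3]})
        with pytest.raises(ValueError):
            pool_frequency_distance(df)

    def test_matches_loop(self):
        rng = np.random.default_rng(8)
        arr = rng.random((30, 4))
        df = pd.DataFrame(arr, columns=list("abcd"))
        d = pool_frequency_distance(df)
        for i, ci in enumerate("abcd"):
            for j, cj in enumerate("abcd"):
                assert d.loc[ci, cj] == pytest.approx(np.abs(arr[:, i] - arr[:, j]).mean())


def test_diversity_table_on_synthetic(default_sim):
    """Combined 5 kb table is internally consistent on the default dataset."""
    cfg, panels, _, _ = default_sim
    div = windowed_diversity(panels, "ref_A", "ref_B", 5_000, cfg.chrom_lengths())
    assert len(div) == cfg.chrom_length_bp // 5_000
    assert ((div["dxy"] >= 0) & (div["dxy"] <= 1)).all()
    assert ((div["pi_ref_A"] >= 0) & (div["pi_ref_A"] <= 1)).all()
    ok = div["fst"].dropna()
    assert (ok <= 1.0 + 1e-9).all()
    # species are deeply diverged: dxy exceeds both within-species pi
    assert div["dxy"].mean() > div["pi_ref_A"].mean()
    assert div["dxy"].mean() > div["pi_ref_B"].mean()
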