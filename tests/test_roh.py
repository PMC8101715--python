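import numpy as np
import pandas as pd
import pytest

from herdgen import (
    GenotypeDataset,
    RohParams,
    SnpMap,
    compare_inbreeding_measures,
    detect_roh,
    froh_chromosomal,
    froh_length,
    froh_nsnp,
    rank_chromosomes,
)
from herdgen.io_formats import MISSING

from .oracles import naive_roh_scan


def even_map(n_snps, spacing_kb=66.0, chrom=1, start=1):
    pos = [int(start + j * spacing_kb * 1000) for j in range(n_snps)]
    return SnpMap.from_arrays([f"c{chrom}s{j}" for j in range(n_snps)], [chrom] * n_snps, pos)


def one_ind(snp_map, calls):
    return GenotypeDataset(snp_map, ["x"], np.asarray([calls], dtype=np.int8))


class TestDetection:
    def test_all_heterozygous_no_segment(self):
        m = even_map(300)
        assert detect_roh(one_ind(m, [1] * 300)) == []

    def test_short_run_below_thresholds(self):
        # 20 homozygous SNPs over ~200 kb in a het background: fails both
        # the SNP-count and length minima
        m = even_map(300, spacing_kb=10.0)
        calls = [1] * 140 + [0] * 20 + [1] * 140
        assert detect_roh(one_ind(m, calls)) == []

    def test_long_run_with_one_het_detected(self):
        # 150 homozygous SNPs spanning ~9.9 Mb with one het in the middle
        m = even_map(350, spacing_kb=66.0)
        calls = [1] * 100 + [2] * 150 + [1] * 100
        calls[100 + 75] = 1
        segs = detect_roh(one_ind(m, calls))
        assert len(segs) == 1
        s = segs[0]
        # the run's outermost SNPs sit mostly in windows that reach into the
        # heterozygous background, so their hit rate falls below the 5%
        # threshold: the accepted run holds 148 of the 150 homozygous SNPs
        assert s.n_snps == 148
        assert m.positions_bp[100] <= s.start_bp <= m.positions_bp[102]
        assert m.positions_bp[247] <= s.end_bp <= m.positions_bp[249]
        oracle = naive_roh_scan(calls, m.positions_bp)
        assert [(s.start_bp, s.end_bp, s.n_snps)] == oracle

    def test_gap_splits_run(self):
        pos = [1 + j * 50_000 for j in range(150)]
        pos += [pos[-1] + 2_000_000 + j * 50_000 for j in range(150)]
        m = SnpMap.from_arrays([f"s{j}" for j in range(300)], [1] * 300, pos)
        segs = detect_roh(one_ind(m, [0] * 300))
        assert len(segs) == 2

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_naive_oracle_on_random_chromosomes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(60, 500))
        spacing = float(rng.uniform(5, 120))
        pos = np.cumsum(rng.integers(1000, int(spacing * 2000), size=n)) + 1
        m = SnpMap.from_arrays([f"s{j}" for j in range(n)], [1] * n, pos)
        # blocky genotypes so runs actually occur
        calls = []
        while len(calls) < n:
            block = int(rng.integers(10, 200))
            kind = rng.random()
            if kind < 0.5:
                calls += [int(rng.integers(0, 2)) * 2] * block  # homozygous block
            else:
                calls += list(rng.integers(0, 3, size=block))
        calls = np.asarray(calls[:n], dtype=np.int8)
        calls[rng.random(n) < 0.01] = MISSING
        params = RohParams(min_run_snps=25, min_run_kb=300.0)
        segs = detect_roh(one_ind(m, calls), params)
        oracle = naive_roh_scan(
            calls, pos, min_run_snps=25, min_run_kb=300.0,
        )
        assert [(s.start_bp, s.end_bp, s.n_snps) for s in segs] == oracle

    def test_relaxing_min_run_kb_is_monotone(self, small_cohort):
        ds = small_cohort.genotypes
        strict = RohParams(min_run_snps=25, min_run_kb=2000.0)
        loose = RohParams(min_run_snps=25, min_run_kb=500.0)
        f_strict = froh_length(detect_roh(ds, strict), ds.snp_map, ds.individual_ids)
        f_loose = froh_length(detect_roh(ds, loose), ds.snp_map, ds.individual_ids)
        assert (f_loose >= f_strict - 1e-15).all()

    def test_params_validation(self):
        with pytest.raises(ValueError):
            RohParams(window_snps=0)
        with pytest.raises(ValueError):
            RohParams(max_gap_kb=-1)


class TestFrohMeasures:
    def test_no_segments_zero(self):
        m = even_map(200)
        fl = froh_length([], m, ["x"])
        fn = froh_nsnp([], m, ["x"])
        assert fl["x"] == 0.0 and fn["x"] == 0.0

    def test_length_fraction_identity(self):
        from herdgen import RohSegment

        m = even_map(200, spacing_kb=10.0)
        l_auto = m.l_auto_kb
        length_bp = int(l_auto * 100)  # a tenth of the coverage, in bp
        seg = RohSegment("x", 1, 1, length_bp, 120)
        assert froh_length([seg], m, ["x"])["x"] == pytest.approx(0.1)

    def test_froh_n_fraction(self):
        from herdgen import RohSegment

        # 4,075 of 40,753 SNPs inside ROH
        pos = np.arange(1, 40_754) * 1000
        m = SnpMap.from_arrays([f"s{j}" for j in range(40_753)], [1] * 40_753, pos)
        seg = RohSegment("x", 1, 1, 10, 4075)
        assert froh_nsnp([seg], m, ["x"])["x"] == pytest.approx(4075 / 40753)

    def test_chromosomal_partition_toy(self):
        from herdgen import RohSegment

        # chr1 coverage 100 kb, chr2 coverage 300 kb; one 50-kb segment on chr1
        m = SnpMap.from_arrays(
            ["a", "b", "c", "d"], [1, 1, 2, 2], [1, 100_000, 1, 300_000]
        )
        seg = RohSegment("x", 1, 1, 50_000, 30)
        kk, ka, mean_kk = froh_chromosomal([seg], m, ["x"])
        assert kk.loc["x", 1] == pytest.approx(0.5)
        assert kk.loc["x", 2] == 0.0
        assert ka.loc["x", 1] == pytest.approx(0.125)
        assert mean_kk["x"] == pytest.approx(0.25)
        assert froh_length([seg], m, ["x"])["x"] == pytest.approx(0.125)

    def test_partition_identity_on_simulation(self, small_cohort):
        ds = small_cohort.genotypes
        segs = detect_roh(ds, RohParams(min_run_snps=25, min_run_kb=500.0))
        fl = froh_length(segs, ds.snp_map, ds.individual_ids)
        _, ka, _ = froh_chromosomal(segs, ds.snp_map, ds.individual_ids)
        assert np.allclose(ka.sum(axis=1).to_numpy(), fl.to_numpy(), rtol=0, atol=1e-15)

    def test_whole_chromosome_segment(self):
        from herdgen import RohSegment

        m = SnpMap.from_arrays(["a", "b", "c", "d"], [1, 1, 2, 2],
                               [1, 1_000_000, 1, 3_000_000])
        seg = RohSegment("x", 1, 1, 1_000_000, 100)
        kk, ka, _ = froh_chromosomal([seg], m, ["x"])
        assert kk.loc["x", 1] == pytest.approx(1.0)
        assert ka.loc["x", 1] == pytest.approx(m.coverage_kb(1) / m.l_auto_kb)


class TestRanking:
    def test_single_loaded_chromosome(self):
        kk = pd.DataFrame({1: [0.2, 0.4], 2: [0.0, 0.0]})
        ka = pd.DataFrame({1: [0.1, 0.2], 2: [0.0, 0.0]})
        r = rank_chromosomes(kk, ka)
        assert r.loc[0, "chromosome_by_KA"] == 1
        assert r.loc[0, "cumulative_pct_KA"] == pytest.approx(100.0)

    def test_uniform_density_follows_length(self):
        # uniform per-kb ROH density: KA ranks by chromosome length,
        # KK ties broken by chromosome number
        cov = {1: 4000.0, 2: 3000.0, 3: 2000.0}
        density = 1e-4
        ka = pd.DataFrame({c: [cov[c] * density / sum(cov.values())] for c in cov})
        kk = pd.DataFrame({c: [density] for c in cov})
        r = rank_chromosomes(kk, ka)
        assert list(r["chromosome_by_KA"]) == [1, 2, 3]
        assert list(r["chromosome_by_KK"]) == [1, 2, 3]

    def test_cumulative_monotone_to_100(self, small_cohort):
        ds = small_cohort.genotypes
        segs = detect_roh(ds, RohParams(min_run_snps=25, min_run_kb=500.0))
        kk, ka, _ = froh_chromosomal(segs, ds.snp_map, ds.individual_ids)
        r = rank_chromosomes(kk, ka)
        cum = r["cumulative_pct_KA"].to_numpy()
        assert (np.diff(cum) >= -1e-9).all()
        assert cum[-1] == pytest.approx(100.0)


class TestComparison:
    def test_self_correlation(self):
        t = pd.DataFrame({"F_PED": [0.0, 0.1, 0.2, 0.3], "F_ROH_L": [0.01, 0.12, 0.19, 0.33]})
        res = compare_inbreeding_measures(t)
        assert res["correlations"].loc["F_PED", "F_PED"] == pytest.approx(1.0)

    def test_hand_computed_regression(self):
        x = np.array([0.0, 0.05, 0.10, 0.15, 0.20])
        y = np.array([0.02, 0.06, 0.13, 0.18, 0.21])
        t = pd.DataFrame({"F_PED": x, "F_ROH_L": y})
        res = compare_inbreeding_measures(t)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        r = sxy / np.sqrt(sxx * ((y - y.mean()) ** 2).sum())
        assert res["regressions"]["F_ROH_L"]["slope"] == pytest.approx(slope)
        assert res["correlations"].loc["F_PED", "F_ROH_L"] == pytest.approx(r)

    def test_zero_variance_flagged(self):
        t = pd.DataFrame({"F_PED": [0.1, 0.1, 0.1], "F_ROH_L": [0.0, 0.1, 0.2]})
        with pytest.warns(UserWarning, match="zero variance"):
            res = compare_inbreeding_measures(t)
        assert np.isnan(res["correlations"].loc["F_PED", "F_ROH_L"])
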