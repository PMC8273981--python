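"""Sex-specific SNP calling, F_ST, exact association, SLR demarcation and
strata segmentation, each checked against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from slrscape import sexlink_scan as sx
from slrscape import synthetic_data as sd
from conftest import make_variant_table


class TestSexSpecificSnps:
    def test_all_males_het_all_females_hom(self):
        vt = make_variant_table([[1] * 10 + [0] * 10])
        assert len(sx.call_sex_specific_snps(vt)) == 1
        # hom-alt females also count as homozygous
        vt2 = make_variant_table([[1] * 10 + [2] * 10])
        assert len(sx.call_sex_specific_snps(vt2)) == 1

    def test_one_nonconforming_male_rejects_site(self):
        vt = make_variant_table([[1] * 9 + [0] + [0] * 10])
        assert len(sx.call_sex_specific_snps(vt)) == 0

    def test_missingness_rules(self):
        row = [1] * 10 + [0] * 10
        missing_ok = list(row)
        missing_ok[3] = -1  # 5% missing, rest conforms
        too_missing = [-1] * 5 + [1] * 5 + [0] * 5 + [-1] * 5  # 50%
        vt = make_variant_table([missing_ok, too_missing])
        assert list(sx.call_sex_specific_snps(vt).index) == [0]

    def test_female_specific_mode_symmetric(self):
        vt = make_variant_table([[0] * 10 + [1] * 10])
        assert len(sx.call_sex_specific_snps(vt, mode="female")) == 1
        assert len(sx.call_sex_specific_snps(vt, mode="male")) == 0

    def test_acceptance_probability_matches_enumeration_oracle(self):
        """P(random HWE site at p=0.3 is called male-specific) equals the
        product of genotype probabilities; simulated frequency within 3 SD."""
        p = 0.3
        p_het = 2 * p * (1 - p)
        p_hom = p**2 + (1 - p) ** 2
        oracle = p_het**10 * p_hom**10
        rng = np.random.default_rng(12)
        n = 200_000
        g = rng.binomial(2, p, size=(n, 20)).astype(np.int8)
        vt = make_variant_table(g, positions=np.arange(1, n + 1))
        freq = len(sx.call_sex_specific_snps(vt)) / n
        assert abs(freq - oracle) <= 3 * math.sqrt(oracle * (1 - oracle) / n)


def test_window_counts_conservation():
    sites = pd.DataFrame({"chrom": "chr1", "pos": [1, 10, 49_000, 60_000, 60_001, 75_000, 99_999]})
    track = sx.window_counts(sites, {"chr1": 150_000}, window=50_000)
    vals = track.on("chr1").value.tolist()
    assert vals == [3, 4, 0]
    assert sum(vals) == len(sites)
    empty = sx.window_counts(sites.iloc[:0], {"chr1": 150_000})
    assert (empty.df.value == 0).all()


class TestWindowFst:
    def test_fixed_difference_gives_one(self):
        g = np.tile([2] * 10 + [0] * 10, (45, 1))
        vt = make_variant_table(g, positions=np.arange(1, 46) * 1000)
        track = sx.window_fst(vt, {"chr1": 50_000})
        assert track.df.value.iloc[0] == pytest.approx(1.0)

    def test_equal_frequencies_give_near_zero(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.5, size=(45, 20)).astype(np.int8)
        vt = make_variant_table(g, positions=np.arange(1, 46) * 1000)
        val = sx.window_fst(vt, {"chr1": 50_000}).df.value.iloc[0]
        assert abs(val) < 0.15

    def test_min_variant_filter(self):
        g = np.tile([2] * 10 + [0] * 10, (39, 1))
        vt = make_variant_table(g, positions=np.arange(1, 40) * 1000)
        track = sx.window_fst(vt, {"chr1": 50_000}, min_variants=40)
        assert np.isnan(track.df.value.iloc[0])  # 39 variants -> missing

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, size=(60, 20)).astype(np.int8)
        vt = make_variant_table(g, positions=np.arange(1, 61) * 500)
        swapped = make_variant_table(2 - g, positions=np.arange(1, 61) * 500)
        a = sx.window_fst(vt, {"chr1": 50_000}).df.value
        b = sx.window_fst(swapped, {"chr1": 50_000}).df.value
        assert np.allclose(a.dropna(), b.dropna())


def _fisher_oracle(table):
    """Exhaustive two-sided hypergeometric summation with math.comb."""
    (a, b), (c, d) = table
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = math.comb(n, col1)
    p_obs = math.comb(row1, a) * math.comb(row2, c) / denom
    total = 0.0
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        pk = math.comb(row1, k) * math.comb(row2, col1 - k) / denom
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return total


class TestAssocScan:
    def test_fully_sex_linked_matches_enumeration(self):
        vt = make_variant_table([[1] * 10 + [0] * 10])
        res = sx.assoc_scan(vt)
        # alleles: males 10 alt / 10 ref, females 0 alt / 20 ref
        oracle = _fisher_oracle(((10, 10), (0, 20)))
        assert res.neglog10_p.iloc[0] == pytest.approx(-math.log10(oracle), abs=1e-9)

    def test_monomorphic_and_balanced_sites(self):
        vt = make_variant_table([[0] * 20, [1] * 20])
        res = sx.assoc_scan(vt)
        assert res.neglog10_p.iloc[0] == 0.0  # monomorphic
        assert res.neglog10_p.iloc[1] == 0.0  # identical counts in both sexes

    def test_sex_label_swap_invariance(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        vt = make_variant_table(g)
        flipped = make_variant_table(np.hstack([g[:, 10:], g[:, :10]]))
        assert np.allclose(
            sx.assoc_scan(vt).neglog10_p, sx.assoc_scan(flipped).neglog10_p
        )

    def test_sex_specific_sites_attain_design_maximum(self):
        """Every fully sex-specific site at 10+10 reaches the largest
        -log10 p possible for that design."""
        vt = make_variant_table([[1] * 10 + [0] * 10, [1] * 10 + [2] * 10])
        res = sx.assoc_scan(vt)
        best = -math.log10(_fisher_oracle(((10, 10), (0, 20))))
        assert res.neglog10_p.iloc[0] == pytest.approx(best, abs=1e-9)


class TestDemarcate:
    def _track(self, counts):
        df = pd.DataFrame(
            {"chrom": "chr1",
             "start": np.arange(len(counts)) * 50_000,
             "end": (np.arange(len(counts)) + 1) * 50_000,
             "value": np.asarray(counts, dtype=float)}
        )
        return sx.WindowTrack(df, window_size=50_000)

    def test_single_marked_window(self):
        call = sx.demarcate_slr(self._track([0, 0, 5, 0, 0]))
        assert call.interval == (100_000, 150_000)
        assert call.par_intervals == [(0, 100_000), (150_000, 250_000)]

    def test_longest_run_wins(self):
        counts = [0] * 5 + [4] * 10 + [0] * 10 + [4] * 40 + [0] * 5
        call = sx.demarcate_slr(self._track(counts))
        assert call.interval == (25 * 50_000, 65 * 50_000)

    def test_gap_merging(self):
        counts = [0, 5, 0, 0, 5, 0]
        call = sx.demarcate_slr(self._track(counts), max_gap_windows=5)
        assert call.interval == (50_000, 250_000)
        call2 = sx.demarcate_slr(self._track(counts), max_gap_windows=1)
        assert call2.length == 50_000

    def test_no_window_passes(self):
        call = sx.demarcate_slr(self._track([0, 1, 2]))
        assert call.interval is None and call.length == 0


class TestXYSimilarity:
    def test_identical_haplotypes(self):
        x = "ACGT" * 50_000
        track = sx.xy_window_similarity(x, x, [(0, 200_000)], window=100_000)
        assert np.allclose(track.df.value, 1.0)

    def test_fully_exonic_window_missing(self):
        x = "ACGT" * 50_000
        track = sx.xy_window_similarity(x, x, [(0, 100_000)], window=100_000)
        assert track.df.value.iloc[0] == 1.0
        assert np.isnan(track.df.value.iloc[1])  # no intronic bases compared

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            sx.xy_window_similarity("ACGT", "ACG", [(0, 4)])


class TestSegmentStrata:
    def test_exact_wilcoxon_matches_permutation_oracle(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        p = sx.ranksum_p(a, b)
        # enumerate all 20 assignments of ranks to the first group
        pooled = a + b
        obs = sum(sorted(pooled).index(v) + 1 for v in a)
        stats = []
        for comb in itertools.combinations(range(6), 3):
            stats.append(sum(c + 1 for c in comb))
        lo, hi = min(obs, 21 - obs), max(obs, 21 - obs)
        p_oracle = sum(1 for s in stats if s <= lo or s >= hi) / len(stats)
        assert p == pytest.approx(p_oracle) == pytest.approx(0.1)

    def _sim_track(self, div, start=0):
        n = len(div)
        df = pd.DataFrame(
            {"chrom": "chrY",
             "start": start + np.arange(n) * 100_000,
             "end": start + (np.arange(n) + 1) * 100_000,
             "value": 1.0 - np.asarray(div)}
        )
        return sx.WindowTrack(df, window_size=100_000)

    def test_planted_changepoint_recovered(self):
        rng = np.random.default_rng(17)
        div = np.concatenate([
            rng.normal(0.012, 0.0005, 30), rng.normal(0.008, 0.0005, 40)
        ])
        call = sx.segment_strata(self._sim_track(div), (0, 7_000_000), "chrY")
        assert len(call.strata) == 2
        assert call.strata[0][0][1] == 3_000_000  # boundary at window 30
        assert call.wilcoxon_p < 0.05
        r1 = sx.higher_divergence_stratum(call)
        assert r1[0] == (0, 3_000_000)

    def test_constant_divergence_stays_single_stratum(self):
        splits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            div = rng.normal(0.01, 0.0005, 70)
            call = sx.segment_strata(self._sim_track(div), (0, 7_000_000), "chrY")
            splits += len(call.strata) == 2
        assert splits <= 1  # p >= 0.05 in >= 90% of seeds

    def test_too_few_windows_single_stratum(self):
        call = sx.segment_strata(self._sim_track([0.01] * 4), (0, 400_000), "chrY")
        assert len(call.strata) == 1 and call.wilcoxon_p is None


def test_planted_slr_recovery_over_seeds():
    """Zigzag-preset recovery: demarcated SLR within 7.0 +/- 0.3 Mb and
    changepoint within 20 +/- 0.2 Mb across 10 seeds."""
    lengths, boundaries = [], []
    for seed in range(10):
        cfg = sd.single_chrom_config(
            27_900_000, seed=seed, slr_interval=(17_000_000, 24_000_000),
            strata_boundary=20_000_000, track_only=(seed % 2 == 0),
        )
        b = sd.gen_genome(cfg)
        vt = sd.gen_population_genotypes(b)
        sss = sx.call_sex_specific_snps(vt)
        call = sx.demarcate_slr(sx.window_counts(sss, b.chrom_lengths))
        lengths.append(call.length / 1e6)
        if not cfg.track_only:
            x, y = b.haplotypes("chr1")
            sim = sx.xy_window_similarity(x, y, b.intron_intervals("chr1"), chrom="chr1")
            st = sx.segment_strata(sim, call.interval, "chr1")
            if len(st.strata) == 2:
                boundaries.append(st.strata[0][0][1] / 1e6)
    assert all(abs(l - 7.0) <= 0.3 for l in lengths)
    assert len(boundaries) == 5
    assert all(abs(bd - 20.0) <= 0.2 for bd in boundaries)
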