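"""Diversity statistics against brute-force oracles and analytic identities."""

import itertools

import numpy as np
import pytest

from yampop.popgen import (bin_statistics, make_bins, site_diversity,
                           tajima_constants, tajimas_d, tajimas_d_from_codes,
                           weir_cockerham_fst)
from yampop.tables import MISSING


def brute_force_site_pi(codes_row):
    """Mean pairwise difference over all allele-copy pairs at one site."""
    alleles = []
    for g in codes_row:
        if g == MISSING:
            continue
        alleles += [1] * int(g) + [0] * (2 - int(g))
    diffs = [a != b for a, b in itertools.combinations(alleles, 2)]
    return np.mean(diffs)


def brute_force_wc_fst(codes1, codes2):
    """Weir & Cockerham (1984) components written longhand, per site."""
    a_sum = d_sum = 0.0
    for s in range(codes1.shape[0]):
        ns, ps, hs = [], [], []
        for codes in (codes1[s], codes2[s]):
            obs = [g for g in codes if g != MISSING]
            n_i = len(obs)
            ns.append(n_i)
            ps.append(sum(obs) / (2 * n_i))
            hs.append(sum(1 for g in obs if g == 1) / n_i)
        r = 2
        n_bar = sum(ns) / r
        n_c = (r * n_bar - sum(n**2 for n in ns) / (r * n_bar)) / (r - 1)
        p_bar = sum(n * p for n, p in zip(ns, ps)) / (r * n_bar)
        s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * n_bar)
        h_bar = sum(n * h for n, h in zip(ns, hs)) / (r * n_bar)
        a = n_bar / n_c * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4)
                           / (n_bar - 1))
        b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2
                                   - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
        c = h_bar / 2
        a_sum += a
        d_sum += a + b + c
    return a_sum / d_sum


class TestSiteDiversity:
    def test_monomorphic_site_is_zero(self):
        assert site_diversity(np.zeros((1, 6), dtype=np.int8))[0] == 0.0

    def test_balanced_site_formula(self):
        # 4 diploids with allele counts 4/4: pi = (8/7) * 2 * 0.5 * 0.5
        codes = np.array([[1, 1, 1, 1]], dtype=np.int8)
        assert site_diversity(codes)[0] == pytest.approx(8 / 7 * 0.5, abs=1e-12)

    def test_equals_brute_force_mean_pairwise_difference(self, rng):
        codes = rng.integers(0, 3, size=(20, 7)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.15] = MISSING
        pi = site_diversity(codes)
        for s in range(20):
            obs = codes[s][codes[s] != MISSING]
            if len(obs) < 2:
                continue
            assert pi[s] == pytest.approx(brute_force_site_pi(codes[s]), abs=1e-12)

    def test_invariant_to_allele_label_swap(self, rng):
        codes = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        assert np.allclose(site_diversity(codes), site_diversity(2 - codes))


class TestTajimasD:
    def test_numerator_identity_gives_exact_zero(self):
        c = tajima_constants(10)
        s = 7
        assert tajimas_d(s / c["a1"], s, 10) == 0.0

    def test_three_singletons_hand_enumeration(self):
        # 4 haplotypes, 3 singleton sites: k_bar = 9/6 = 1.5, S/a1 = 3/1.833
        codes = np.array([[1, 0], [0, 1], [1, 0]], dtype=np.int8)
        # treat the 4 haplotypes as 2 diploids: allele counts per site 1/4
        d = tajimas_d_from_codes(codes)
        c = tajima_constants(4)
        k_bar = 3 * (4 / 3) * 2 * 0.25 * 0.75  # = 1.5
        expected = (k_bar - 3 / c["a1"]) / np.sqrt(c["e1"] * 3 + c["e2"] * 6)
        assert d == pytest.approx(expected, abs=1e-12)
        assert d < 0

    def test_no_segregating_sites_undefined(self):
        assert np.isnan(tajimas_d_from_codes(np.zeros((5, 4), dtype=np.int8)))

    def test_neutral_equilibrium_mean_near_zero(self):
        # coalescent oracle: msprime neutral simulations should average D ~ 0
        msprime = pytest.importorskip("msprime")
        ds = []
        rng = np.random.default_rng(5)
        for rep in range(120):
            ts = msprime.sim_ancestry(samples=5, sequence_length=5e4,
                                      recombination_rate=0, population_size=1e4,
                                      random_seed=1000 + rep)
            mts = msprime.sim_mutations(ts, rate=2e-8, random_seed=2000 + rep)
            geno = mts.genotype_matrix()
            if geno.shape[0] == 0:
                continue
            codes = geno[:, 0::2] + geno[:, 1::2]
            d = tajimas_d_from_codes(codes.astype(np.int8))
            if np.isfinite(d):
                ds.append(d)
        assert abs(np.mean(ds)) < 0.12


class TestMakeBins:
    def test_three_sites_one_bin(self):
        bins = make_bins(np.array(["c1"] * 3), np.array([10, 50_010, 99_999]))
        assert len(bins) == 1
        assert bins.iloc[0]["n_snps"] == 3
        assert (bins.iloc[0]["start"], bins.iloc[0]["end"]) == (1, 100_000)

    def test_sparse_bin_excluded(self):
        bins = make_bins(np.array(["c1"] * 2), np.array([10, 20]))
        assert bins.empty

    def test_bin_boundary_is_half_open(self):
        pos = np.array([99_999, 100_000, 100_001, 100_002, 199_999, 100_500])
        bins = make_bins(np.array(["c1"] * 6), pos)
        # 100_000 belongs to the first bin (1-based), 100_001+ to the second
        assert bins.iloc[0]["n_snps"] == 4  # 100_001..199_999 bin
        assert len(bins) == 1  # first bin holds only 2 SNPs -> dropped


class TestWeirCockerhamFst:
    def test_identical_frequencies_near_zero(self, rng):
        p = rng.uniform(0.3, 0.7, 200)
        c1 = rng.binomial(2, p[:, None], (200, 30)).astype(np.int8)
        c2 = rng.binomial(2, p[:, None], (200, 30)).astype(np.int8)
        _, fst = weir_cockerham_fst(c1, c2)
        assert abs(fst) < 0.02

    def test_alternate_fixation_is_one(self):
        c1 = np.zeros((10, 6), dtype=np.int8)
        c2 = np.full((10, 6), 2, dtype=np.int8)
        per_site, fst = weir_cockerham_fst(c1, c2)
        assert fst == pytest.approx(1.0)
        assert np.allclose(per_site, 1.0)

    def test_equals_brute_force_variance_components(self, rng):
        # includes the spec's toy frequencies: 8 alt of 20 vs 14 alt of 20
        c1 = np.array([[0, 1, 1, 1, 1, 0, 2, 0, 1, 1]], dtype=np.int8)
        c2 = np.array([[2, 2, 1, 1, 2, 0, 1, 1, 2, 2]], dtype=np.int8)
        assert c1.sum() == 8 and c2.sum() == 14
        _, fst = weir_cockerham_fst(c1, c2)
        assert fst == pytest.approx(brute_force_wc_fst(c1, c2), abs=1e-12)
        multi1 = rng.integers(0, 3, size=(25, 9)).astype(np.int8)
        multi2 = rng.integers(0, 3, size=(25, 11)).astype(np.int8)
        _, fst_m = weir_cockerham_fst(multi1, multi2)
        assert fst_m == pytest.approx(brute_force_wc_fst(multi1, multi2), abs=1e-12)

    def test_small_population_rejected(self):
        with pytest.raises(ValueError):
            weir_cockerham_fst(np.zeros((5, 1), dtype=np.int8),
                               np.zeros((5, 4), dtype=np.int8))

    def test_label_swap_invariance(self, rng):
        c1 = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
        c2 = rng.integers(0, 3, size=(40, 10)).astype(np.int8)
        _, f = weir_cockerham_fst(c1, c2)
        _, f_swapped = weir_cockerham_fst(2 - c1, 2 - c2)
        assert f == pytest.approx(f_swapped, abs=1e-12)

    def test_monotone_in_split_time(self):
        from yampop.popgen import weir_cockerham_fst
        from yampop.synth import PopConfig, simulate_founders
        fsts = []
        for t in (50, 300, 1200):
            cfg = PopConfig(n_pops=2, split_times=(t,), pop_sizes=(400, 400),
                            n_sites=2500, seed=17)
            founders, _ = simulate_founders(cfg, n_per_pop=15)
            by_pop = {}
            for acc in founders:
                by_pop.setdefault(acc.pop_label, []).append(acc.dosage)
            codes = [np.array(v).T for v in by_pop.values()]
            fsts.append(weir_cockerham_fst(codes[0], codes[1])[1])
        assert fsts[0] < fsts[1] < fsts[2]


class TestBinStatistics:
    def test_sample_order_invariance(self, rng):
        codes = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
        pos = np.sort(rng.integers(1, 200_000, 50))
        from yampop.tables import GenotypeMatrix
        gm1 = GenotypeMatrix([f"s{i}" for i in range(8)], np.array(["c1"] * 50), pos, codes)
        perm = rng.permutation(8)
        gm2 = GenotypeMatrix([f"s{i}" for i in perm], np.array(["c1"] * 50), pos,
                             codes[:, perm])
        b1 = bin_statistics(gm1)
        b2 = bin_statistics(gm2)
        assert np.allclose(b1["pi"], b2["pi"])
        assert np.allclose(b1["tajima_d"], b2["tajima_d"], equal_nan=True)

    def test_per_bp_mode_divides_by_width(self, rng):
        codes = rng.integers(0, 3, size=(30, 6)).astype(np.int8)
        pos = np.sort(rng.integers(1, 100_000, 30))
        from yampop.tables import GenotypeMatrix
        gm = GenotypeMatrix([f"s{i}" for i in range(6)], np.array(["c1"] * 30), pos, codes)
        per_site = bin_statistics(gm, per_bp=False)
        per_bp = bin_statistics(gm, per_bp=True)
        ratio = per_site.iloc[0]["pi"] * per_site.iloc[0]["n_snps"] / 100_000
        assert per_bp.iloc[0]["pi"] == pytest.approx(ratio, rel=1e-9)
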